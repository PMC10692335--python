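"""Classify centromeres by their cohesin distribution along the chromosome.

Simulates a spread whose particles carry three cohesin patterns (split /
uniform / central), ranks each particle by its center-enriched ratio
(intensity within 120 nm of the center over the 160-320 nm off-center band)
and partitions the ranking at the published 200/150/113 boundaries.  A
Kruskal-Wallis test asks whether inter-CENP-A distances differ between
classes; the generator draws them from one distribution, so they should not.
"""

from censpa.io import RunConfig
from censpa.pipeline import run_pipeline

mix = {"split": 200 / 463, "uniform": 150 / 463, "central": 113 / 463}
result = run_pipeline(RunConfig(n_particles=93, seed=5, class_mix=mix))

summary = result.class_summary
print("class sizes:", summary.class_sizes)
for label, seps in summary.separation_by_class.items():
    print(f"  {label:8s} mean inter-CENP-A = {seps.mean():.0f} nm (n={len(seps)})")
print(f"Kruskal-Wallis H = {summary.kw_statistic:.2f}, p = {summary.kw_pvalue:.3f}")
print("(p > 0.05: the cohesin pattern does not set the sister spacing)")
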