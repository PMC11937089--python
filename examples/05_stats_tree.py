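"""The normality-gated statistics tree on a synthetic feature table.

A 28-subject table with a +1.24 dB partial-automation effect and a rising
time profile is drawn from the effect model and pushed through the tree:
Shapiro-Wilk gate, then either a 2 x 6 within-subject ANOVA (Mauchly-
gated Greenhouse-Geisser correction, partial eta squared, Holm-corrected
paired t post-hocs) or per-mode Friedman + Conover with between-mode
Wilcoxon tests.
"""

import numpy as np

from drivevigil.stats import analyze_feature
from drivevigil.synth import CohortConfig, sample_feature_table

table = sample_feature_table(
    base=-98.0, mode_delta=1.24,
    time_profile=[0.0, 0.68, 1.05, 1.12, 1.18, 1.33],
    cohort=CohortConfig(n_subjects=28),
    rng=np.random.default_rng(5), feature="parietal alpha")

report = analyze_feature(table, "parietal alpha")
print(report.summary())
mode = report.effect("mode")
print(f"\nmode effect: F({mode['df_str']}) = {mode['stat']:.2f}, "
      f"p = {mode['p']:.2g}, partial eta^2 = {mode['partial_eta_sq']:.2f}")
print("GG correction applied:", mode["gg_applied"],
      f"(Mauchly p = {mode['sphericity_p']:.3f}, "
      f"epsilon = {mode['epsilon']:.3f})")

sig = report.posthoc[report.posthoc["p_holm"] < 0.05]
print(f"\n{len(sig)} Holm-significant post-hoc pairs, e.g.:")
print(sig.head(5).to_string(index=False))
# The injected alpha rise reaches significance from early sections on,
# mirroring how spectral markers lead behavioral ones.
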