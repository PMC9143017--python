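"""Probe-delivery kinetics and the dual- vs single-injection comparison.

Simulates per-subject uptake curves over the standard 2-60 min schedule for a
single-probe arm and a dual-probe arm with identical kinetics, then tests the
between-arm effect with a mixed repeated-measures ANOVA.  A non-significant p
is the desired outcome: co-injection does not alter delivery.
"""

import numpy as np

from turbispec import (
    CohortDesign,
    UptakeKinetics,
    mammary_aging_design,
    synthesize_uptake_trial,
    uptake_anova,
    uptake_curve,
)

design = CohortDesign(mammary_aging_design().groups, uptake=UptakeKinetics(rate_constant=0.05))
curve = uptake_curve(design, plateau_value=1.0)
print("ideal delivery curve, k = 0.05 /min (fraction of plateau):")
for t, v in curve.items():
    print(f"  t = {t:5.0f} min   v = {v:.4f}")
print(f"by 60 min the signal reaches {curve.loc[60.0]:.1%} of plateau, "
      "which is why endpoint analyses use the 60-min measurement.\n")

curves = synthesize_uptake_trial(
    {"single": (0.05, 1.0), "dual": (0.05, 1.0)},  # identical kinetics
    n_subjects=9, subject_sd=0.1, noise_sd=0.05, seed=21,
)
p = uptake_anova(curves)
print(f"mixed RM-ANOVA, single vs dual injection (identical kinetics): p = {p:.3f}")
print("p > 0.05: no between-arm effect — measuring both probes simultaneously "
      "does not distort either probe's delivery curve.")
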