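"""Kaplan-Meier/logrank comparison and cluster-robust Cox on TMA fractions.

Generates a synthetic cohort with a planted group effect and a planted
log-hazard of 0.02 per percentage point of marker-positive cells, thresholds
the per-nucleus intensities into per-core positive fractions, and fits the
multivariate Cox model with cluster-robust variance over patients.
"""

from routescape import survival as sv
from routescape.synthetic import SurvivalSpec, gen_survival_tma

spec = SurvivalSpec(n_subjects=120, group_effect=0.7, marker_beta=0.02, seed=5)
surv, nuclei = gen_survival_tma(spec)

subjects = surv.groupby("patient").first().reset_index()
km = sv.km_logrank(subjects, group_col="group")
print(
    f"logrank test between the two groups: chi2 = {km['chi2']:.2f} "
    f"(df = {km['df']}), p = {km['p']:.3g}"
)

fractions = sv.tma_fractions(nuclei, {"MARKER": surv.attrs["threshold"]})
print(
    f"positive-cell fractions across {len(fractions)} cores: "
    f"mean {fractions['fraction'].mean():.2f}"
)

cox = sv.cox_marker(surv)
lo, hi = cox["ci"]
print(
    f"Cox hazard ratio per percentage point positive: {cox['hr']:.3f} "
    f"(95% CI [{lo:.3f}, {hi:.3f}], p = {cox['p']:.3g})"
)
print(f"planted log-hazard 0.02 -> HR {2.718281828**0.02:.3f}; the model,")
print("with age, sex and subtype as covariates and patient-clustered variance,")
print("recovers it from the thresholded core fractions.")
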