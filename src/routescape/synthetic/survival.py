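"""Synthetic survival cohorts with planted group and marker log-hazards.

Event times are exponential with hazard
``lambda0 * exp(group_effect * group + marker_beta * fraction_pct)`` where the
marker fraction (percent of positive cells) varies across subjects.  Each
subject contributes several TMA cores; per-core nucleus intensities are
bimodal (negative vs positive population) so fixed-threshold classification
recovers the subject's planted positive fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalSpec", "gen_survival_tma"]


@dataclass
class SurvivalSpec:
    n_subjects: int = 60
    group_effect: float = 0.0  # log-hazard of group 1 vs 0
    marker_beta: float = 0.0  # log-hazard per percentage point positive
    cores_per_subject: int = 2
    nuclei_per_core: int = 200
    censor_rate: float = 0.0
    baseline_hazard: float = 1.0 / 200.0  # per day
    fraction_range: tuple[float, float] = (10.0, 50.0)  # percent
    intensity_modes: tuple[float, float] = (1.0, 4.0)
    intensity_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need at least two subjects per group")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")


def gen_survival_tma(spec: SurvivalSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (survival table, per-nucleus intensity table).

    The survival table has one row per (subject, core) as in a TMA study
    (duplicate survival times within subject, for cluster-robust variance),
    with columns time, event, group, age, sex, subtype, true_fraction_pct and
    fraction_pct (the noisy per-core realized fraction).  The nucleus table
    has per-nucleus intensities with planted positives at the high mode.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    group = (np.arange(n) % 2).astype(int)
    frac_pct = rng.uniform(*spec.fraction_range, n)
    lam = spec.baseline_hazard * np.exp(
        spec.group_effect * group + spec.marker_beta * frac_pct
    )
    times = rng.exponential(1.0 / lam)
    event = np.ones(n, dtype=int)
    censored = rng.random(n) < spec.censor_rate
    times = np.where(censored, times * rng.random(n), times)
    event[censored] = 0

    age = rng.uniform(40, 75, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    subtype = rng.choice(["classical", "mesenchymal", "proneural"], n)

    surv_rows, nuc_rows = [], []
    lo_mode, hi_mode = spec.intensity_modes
    threshold_gap_ok = hi_mode - lo_mode > 4 * spec.intensity_sd
    for i in range(n):
        for c in range(spec.cores_per_subject):
            n_nuc = spec.nuclei_per_core
            # exact planted positive count per core (then shuffled), so the
            # core's true positive fraction is the subject's planted fraction
            k = int(round(frac_pct[i] / 100.0 * n_nuc))
            pos = np.zeros(n_nuc, dtype=bool)
            pos[:k] = True
            rng.shuffle(pos)
            intens = np.where(
                pos,
                rng.normal(hi_mode, spec.intensity_sd, n_nuc),
                rng.normal(lo_mode, spec.intensity_sd, n_nuc),
            )
            core_id = f"core{c}"
            for v in intens:
                nuc_rows.append(
                    {
                        "patient": f"P{i:03d}",
                        "core": core_id,
                        "marker": "MARKER",
                        "intensity": float(v),
                    }
                )
            surv_rows.append(
                {
                    "patient": f"P{i:03d}",
                    "core": core_id,
                    "time": float(times[i]),
                    "event": int(event[i]),
                    "group": int(group[i]),
                    "age": float(age[i]),
                    "sex": sex[i],
                    "subtype": subtype[i],
                    "true_fraction_pct": float(frac_pct[i]),
                    "fraction_pct": 100.0 * float(pos.mean()),
                }
            )
    surv = pd.DataFrame(surv_rows)
    nuclei = pd.DataFrame(nuc_rows)
    surv.attrs["modes_well_separated"] = bool(threshold_gap_ok)
    surv.attrs["threshold"] = (lo_mode + hi_mode) / 2
    return surv, nuclei
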