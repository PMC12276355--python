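"""Survival statistics: Kaplan-Meier/logrank, TMA marker fractions, Cox models.

Covers the two survival analyses of the study design: (a) mouse cohorts
compared by Kaplan-Meier curves and the logrank test, and (b) patient tissue
microarrays where per-core positive-cell fractions (nuclei above a fixed
marker threshold) enter a multivariate Cox proportional-hazards model with
age, sex and transcriptional subtype as covariates and cluster-robust
variance over patient id (multiple cores per patient).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "km_logrank",
    "tma_fractions",
    "cox_marker",
    "phenotype_concordance",
]

SUBTYPE_LEVELS = ("classical", "mesenchymal", "proneural")  # classical = baseline


def km_logrank(
    records: pd.DataFrame,
    group_col: str = "group",
    time_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Kaplan-Meier curves per group plus the logrank test.

    Returns a dict with per-group survival tables and (chi2, df, p); df is
    the number of groups minus one.  With no censoring the KM estimate equals
    the empirical survival function.
    """
    groups = sorted(records[group_col].unique())
    if len(groups) < 2:
        raise ValueError("logrank needs at least two groups")
    curves = {}
    for g in groups:
        sub = records[records[group_col] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col], label=str(g))
        curves[g] = kmf.survival_function_
    res = multivariate_logrank_test(
        records[time_col], records[group_col], records[event_col]
    )
    return {
        "curves": curves,
        "chi2": float(res.test_statistic),
        "df": len(groups) - 1,
        "p": float(res.p_value),
    }


def tma_fractions(
    nucleus_table: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Positive-cell fraction per core from per-nucleus marker intensities.

    ``nucleus_table`` has columns patient, core, marker, intensity; a nucleus
    is positive when its intensity is at or above the marker's fixed
    threshold (one threshold per marker across the whole set).  Returns one
    row per (patient, core, marker) with the fraction and nucleus count.
    """
    missing = set(nucleus_table["marker"].unique()) - set(thresholds)
    if missing:
        raise ValueError(f"no threshold for markers: {sorted(missing)}")
    rows = []
    for (patient, core, marker), sub in nucleus_table.groupby(
        ["patient", "core", "marker"], sort=True
    ):
        pos = (sub["intensity"] >= thresholds[marker]).sum()
        rows.append(
            {
                "patient": patient,
                "core": core,
                "marker": marker,
                "fraction": pos / len(sub),
                "n_nuclei": len(sub),
            }
        )
    return pd.DataFrame(rows)


def cox_marker(
    records: pd.DataFrame,
    marker_col: str = "fraction_pct",
    time_col: str = "time",
    event_col: str = "event",
    cluster_col: str = "patient",
) -> dict:
    """Cluster-robust Cox PH of survival on a marker fraction.

    One row per core; the marker predictor is on the percentage scale (0-100),
    so the hazard ratio is per percentage point of positive cells.  Covariates
    are age, sex and transcriptional subtype (classical as baseline); the
    variance is cluster-robust over patient id.  Returns HR with 95% CI and p
    for the marker term.
    """
    if records[event_col].sum() == 0:
        raise ValueError("no events; Cox model is not identified")
    df = records.copy()
    df["sex_male"] = (df["sex"].astype(str) == "male").astype(float)
    for lev in SUBTYPE_LEVELS[1:]:
        df[f"subtype_{lev}"] = (df["subtype"].astype(str) == lev).astype(float)
    covs = [marker_col, "age", "sex_male"] + [
        f"subtype_{lev}" for lev in SUBTYPE_LEVELS[1:]
    ]
    covs = [c for c in covs if df[c].nunique() > 1]
    X = df[covs].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))]))
    if rank < X.shape[1] + 1:
        warnings.warn("collinear covariates detected; estimates may be unstable")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(
            df[[time_col, event_col, cluster_col] + covs],
            duration_col=time_col,
            event_col=event_col,
            cluster_col=cluster_col,
        )
    s = cph.summary.loc[marker_col]
    return {
        "log_hr": float(s["coef"]),
        "hr": float(s["exp(coef)"]),
        "ci": (float(np.exp(s["coef lower 95%"])), float(np.exp(s["coef upper 95%"]))),
        "p": float(s["p"]),
        "se": float(s["se(coef)"]),
        "model": cph,
    }


def phenotype_concordance(
    phenotypes: pd.DataFrame,
    line_col: str = "line",
    phenotype_cols: list[str] | None = None,
) -> pd.Series:
    """Replicate concordance per phenotype: modal agreement within each line.

    For every phenotype column, the fraction of mouse replicates whose call
    equals the line's modal call is computed per cell line and averaged over
    lines (expressed in percent).
    """
    cols = phenotype_cols or [c for c in phenotypes.columns if c != line_col]
    out = {}
    for col in cols:
        per_line = []
        for _line, sub in phenotypes.groupby(line_col):
            calls = sub[col]
            modal = calls.mode().iloc[0]
            per_line.append((calls == modal).mean())
        out[col] = 100.0 * float(np.mean(per_line))
    return pd.Series(out, name="concordance_pct")
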