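"""Meta-analysis of per-sample regulator x gene-module coefficient tables.

Each sample contributes a table with regulators (transcription factors and
kinases) as rows and gene modules as columns, together with the gene content
of every module and a (growth condition, patient, invasion route) annotation
per module.  The meta-analysis merges the tables over the union of
regulators, z-transforms each regulator row, clusters module columns by
complete-linkage hierarchical clustering with Euclidean distance, cuts the
dendrogram into metamodules, derives metamodule gene signatures (genes shared
by at least four member modules), quantifies overlap with external signatures
by the Jaccard index, and ranks regulator selectivity for annotation factors
by one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from . import scstates

__all__ = [
    "RegulatoryTable",
    "MetaModule",
    "merge_landscape",
    "cluster_modules",
    "cut_metamodules",
    "metamodule_signatures",
    "jaccard_overlap",
    "fit_route_signatures",
    "regulator_anova",
]


@dataclass
class RegulatoryTable:
    """One sample's regulator x module coefficients plus module metadata."""

    sample: str
    coefficients: pd.DataFrame  # regulators x modules
    gene_sets: dict[str, set[str]]  # module id -> gene symbols
    annotations: pd.DataFrame  # module id -> growth_condition, patient, route

    def __post_init__(self) -> None:
        mods = list(self.coefficients.columns)
        if set(self.gene_sets) != set(mods) or set(self.annotations.index) != set(mods):
            raise ValueError("module ids inconsistent between fields")


@dataclass
class MetaModule:
    """A recurring cluster of gene modules and its shared-gene signature."""

    id: int
    members: list[str]
    signature: set[str]
    min_support: int


def merge_landscape(
    tables: list[RegulatoryTable],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]]]:
    """Merge per-sample tables and z-transform each regulator row.

    Module columns are concatenated (prefixed with the sample name to keep ids
    unique); regulators absent from a sample contribute zeros.  Each row is
    centered and scaled to unit population standard deviation across modules;
    constant rows stay at zero.  Returns (merged z matrix, per-module
    annotations, module gene sets).
    """
    if not tables:
        raise ValueError("no tables to merge")
    frames, annots, gene_sets = [], [], {}
    for t in tables:
        renamed = t.coefficients.add_prefix(f"{t.sample}:")
        frames.append(renamed)
        a = t.annotations.copy()
        a.index = [f"{t.sample}:{m}" for m in a.index]
        annots.append(a)
        for m, gs in t.gene_sets.items():
            gene_sets[f"{t.sample}:{m}"] = set(gs)
    merged = pd.concat(frames, axis=1).fillna(0.0)
    ann = pd.concat(annots, axis=0).loc[merged.columns]
    vals = merged.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    z = np.divide(vals - mean, sd, out=np.zeros_like(vals), where=sd > 0)
    return pd.DataFrame(z, index=merged.index, columns=merged.columns), ann, gene_sets


def cluster_modules(merged: pd.DataFrame) -> np.ndarray:
    """Complete-linkage hierarchical clustering of module columns (Euclidean).

    Returns the scipy linkage matrix; merge heights are non-decreasing.
    """
    return linkage(merged.to_numpy().T, method="complete", metric="euclidean")


def cut_metamodules(
    dendrogram: np.ndarray,
    modules: list[str],
    height: float | None = None,
    n_metamodules: int | None = None,
) -> pd.Series:
    """Flat module -> metamodule assignment from a dendrogram cut.

    Provide either ``height`` (cut distance; the study's dataset used 36,
    yielding 13 metamodules there) or ``n_metamodules`` (cut to a target
    count).
    """
    if (height is None) == (n_metamodules is None):
        raise ValueError("specify exactly one of height / n_metamodules")
    if height is not None:
        flat = fcluster(dendrogram, t=height, criterion="distance")
    else:
        flat = fcluster(dendrogram, t=n_metamodules, criterion="maxclust")
    return pd.Series(flat, index=modules, name="metamodule")


def metamodule_signatures(
    assignment: pd.Series,
    gene_sets: dict[str, set[str]],
    min_support: int = 4,
) -> list[MetaModule]:
    """Signature of each metamodule: genes present in >= min_support members."""
    out = []
    for mm in sorted(assignment.unique()):
        members = assignment.index[assignment == mm].tolist()
        counts: dict[str, int] = {}
        for m in members:
            for g in gene_sets[m]:
                counts[g] = counts.get(g, 0) + 1
        signature = {g for g, c in counts.items() if c >= min_support}
        out.append(MetaModule(int(mm), members, signature, min_support))
    return out


def jaccard_overlap(
    sets_a: dict[str, set[str]], sets_b: dict[str, set[str]]
) -> pd.DataFrame:
    """Jaccard index |A∩B| / |A∪B| for every pair of gene sets."""
    rows = {}
    for ka, a in sets_a.items():
        rows[ka] = {
            kb: (len(a & b) / len(a | b)) if (a | b) else 0.0
            for kb, b in sets_b.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def fit_route_signatures(
    expr,
    route_labels: pd.Series,
    n_genes: int = 50,
    padj_max: float = 0.01,
) -> dict[str, list[str]]:
    """Fit per-route gene signatures by one-vs-rest differential expression.

    For each invasion route, genes with padj < ``padj_max`` are ranked by
    log2 fold change and the top ``n_genes`` kept.  Routes with fewer than two
    cells are skipped with a warning.
    """
    routes = sorted(pd.Series(route_labels).unique())
    out: dict[str, list[str]] = {}
    for r in routes:
        n_r = int((np.asarray(route_labels) == r).sum())
        if n_r < 2 or len(route_labels) - n_r < 2:
            warnings.warn(f"route {r!r} has too few cells; signature omitted")
            continue
        table = scstates.dge(expr, route_labels, group=r)
        hits = table[(table["padj"] < padj_max) & (table["log2fc"] > 0)]
        out[r] = hits.sort_values("log2fc", ascending=False).head(n_genes).index.tolist()
    return out


def regulator_anova(
    merged: pd.DataFrame, annotations: pd.DataFrame, factor: str
) -> pd.DataFrame:
    """One-way ANOVA of each regulator's module coefficients across a factor.

    ``factor`` names a column of ``annotations`` (growth_condition, patient or
    invasion route).  Two-sided, unadjusted.  Regulators constant across all
    modules (F undefined) are reported with NaN.
    """
    if factor not in annotations.columns:
        raise ValueError(f"unknown factor {factor!r}")
    groups = annotations.loc[merged.columns, factor]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("factor needs at least two levels")
    idx = [np.where((groups == lev).to_numpy())[0] for lev in levels]
    rows = []
    vals = merged.to_numpy(dtype=float)
    for i, reg in enumerate(merged.index):
        samples = [vals[i, j] for j in idx]
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            rows.append({"regulator": reg, "F": np.nan, "p": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*samples)
        rows.append({"regulator": reg, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows).set_index("regulator")
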