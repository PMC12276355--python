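"""Single-cell QC, signature scoring, state embedding and route association.

Works on an :class:`anndata.AnnData` of raw counts (cells x genes).  The
pipeline applies the study's QC rules, library-size normalization
(10,000 counts + log1p), expression-bin-matched signature scoring, cell-cycle
score regression, graph clustering (Louvain with multilevel refinement), the
four-state MES/AC/OPC/NPC quadrant embedding, a chi-square association test
between state and invasion route with standardized residuals, Wilcoxon
differential expression with Benjamini-Hochberg adjustment, and shortlisting
of route regulators by padj and fold-change thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize_log",
    "score_signature",
    "cc_regress",
    "cluster_cells",
    "neftel_embedding",
    "state_route_association",
    "dge",
    "select_route_regulators",
]


@dataclass
class QCThresholds:
    """Quality-control thresholds.

    Defaults follow the study's rules: cells must express at least 500 genes;
    genes must be expressed in at least 10 cells; detected-gene ceilings of
    7200 (v3 kit) and 5100 (v2 kit) remove likely doublets; cells with more
    than 30% mitochondrial counts are removed; flagged ribosomal,
    mitochondrial and hemoglobin genes are dropped at the end.
    """

    min_genes: int = 500
    min_cells_per_gene: int = 10
    doublet_ceiling: dict[str, int] = field(
        default_factory=lambda: {"v2": 5100, "v3": 7200}
    )
    max_mito: float = 0.30


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def qc_filter(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, pd.Series]:
    """Apply the QC rules in order and report removal counts per rule.

    Order: gene floor -> gene prevalence -> kit-specific doublet ceiling ->
    mitochondrial fraction -> removal of flagged genes.  Requires ``kit`` in
    ``adata.obs`` and boolean ``mito``/``ribo``/``hemoglobin`` flags in
    ``adata.var``.
    """
    th = thresholds or QCThresholds()
    if "kit" not in adata.obs.columns:
        raise ValueError("qc_filter requires a 'kit' annotation per cell")
    report = {}
    a = adata

    genes_per_cell = np.asarray((_dense(a.X) > 0).sum(axis=1)).ravel()
    keep = genes_per_cell >= th.min_genes
    report["low_gene_cells"] = int((~keep).sum())
    a = a[keep].copy()

    cells_per_gene = np.asarray((_dense(a.X) > 0).sum(axis=0)).ravel()
    keepg = cells_per_gene >= th.min_cells_per_gene
    report["rare_genes"] = int((~keepg).sum())
    a = a[:, keepg].copy()

    genes_per_cell = np.asarray((_dense(a.X) > 0).sum(axis=1)).ravel()
    ceilings = a.obs["kit"].map(th.doublet_ceiling)
    if ceilings.isna().any():
        raise ValueError("unknown kit version in 'kit' annotation")
    keep = genes_per_cell <= ceilings.to_numpy()
    report["doublet_cells"] = int((~keep).sum())
    a = a[keep].copy()

    if a.n_obs and a.n_vars:
        total = np.asarray(_dense(a.X).sum(axis=1)).ravel()
        mito = np.asarray(_dense(a[:, a.var["mito"]].X).sum(axis=1)).ravel()
        frac = np.divide(mito, total, out=np.zeros_like(total, dtype=float), where=total > 0)
        keep = frac <= th.max_mito
    else:
        keep = np.ones(a.n_obs, dtype=bool)
    report["high_mito_cells"] = int((~keep).sum())
    a = a[keep].copy()

    flagged = (a.var["mito"] | a.var["ribo"] | a.var["hemoglobin"]).to_numpy()
    report["flagged_genes"] = int(flagged.sum())
    a = a[:, ~flagged].copy()

    return a, pd.Series(report)


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalization to ``target_sum`` counts per cell + log1p."""
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def score_signature(
    expr: ad.AnnData,
    genes: list[str],
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched signature score per cell.

    Score = mean expression of the signature genes minus the mean of a
    control set built by drawing ``nctrl`` genes from the average-expression
    bin of each signature gene (``nbin`` bins over all genes).  Missing
    signature genes are dropped with a warning; deterministic given ``seed``.
    """
    present = [g for g in genes if g in expr.var_names]
    if len(present) < len(genes):
        warnings.warn(f"{len(genes) - len(present)} signature genes missing")
    if not present:
        raise ValueError("no signature genes present in the matrix")
    rng = np.random.default_rng(seed)
    X = _dense(expr.X)
    avg = X.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = np.minimum((ranks * nbin) // len(order), nbin - 1)
    name_to_idx = {g: i for i, g in enumerate(expr.var_names)}
    sig_idx = np.array([name_to_idx[g] for g in present])
    ctrl: set[int] = set()
    for gi in sig_idx:
        pool = np.where(bins == bins[gi])[0]
        take = min(nctrl, len(pool))
        ctrl.update(rng.choice(pool, take, replace=False).tolist())
    ctrl_idx = np.fromiter(ctrl, dtype=int)
    return X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


def cc_regress(
    expr: ad.AnnData,
    s_genes: list[str],
    g2m_genes: list[str],
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
) -> ad.AnnData:
    """Regress the S-minus-G2M cell-cycle score difference out of every gene.

    Each gene is regressed (with intercept) on d = score_S - score_G2M; the
    returned matrix holds residuals plus the gene means.  If d is constant the
    regression is skipped and the data returned unchanged.
    """
    s_score = score_signature(expr, s_genes, nbin, nctrl, seed)
    g2m_score = score_signature(expr, g2m_genes, nbin, nctrl, seed + 1)
    d = s_score - g2m_score
    out = expr.copy()
    out.obs["S_score"] = s_score
    out.obs["G2M_score"] = g2m_score
    dc = d - d.mean()
    denom = dc @ dc
    if denom == 0:
        return out
    X = _dense(out.X).astype(float)
    mean = X.mean(axis=0)
    beta = (dc @ (X - mean)) / denom
    out.X = X - np.outer(dc, beta)
    return out


def cluster_cells(
    expr: ad.AnnData,
    resolution: float = 0.3,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """PCA -> kNN graph -> Louvain community detection (multilevel refinement).

    Returns integer cluster labels per cell.  A single cell trivially forms
    one cluster.
    """
    if expr.n_obs == 1:
        return np.zeros(1, dtype=int)
    a = expr.copy()
    n_pcs = int(min(n_pcs, a.n_obs - 1, a.n_vars - 1))
    sc.pp.pca(a, n_comps=max(n_pcs, 1), random_state=seed)
    sc.pp.neighbors(a, n_neighbors=min(n_neighbors, a.n_obs - 1), random_state=seed)
    adj = a.obsp["connectivities"].tocoo()
    edges = [(int(i), int(j)) for i, j, _ in zip(adj.row, adj.col, adj.data) if i < j]
    weights = [float(w) for i, j, w in zip(adj.row, adj.col, adj.data) if i < j]
    g = igraph.Graph(n=a.n_obs, edges=edges)
    import random as _random

    igraph.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership, dtype=int)


_QUADRANTS = {(False, False): "AC", (False, True): "MES", (True, False): "OPC", (True, True): "NPC"}


def neftel_embedding(scores: pd.DataFrame) -> pd.DataFrame:
    """Four-state quadrant embedding from per-cell MES/AC/OPC/NPC scores.

    The vertical coordinate is D = max(OPC, NPC) - max(AC, MES); when D > 0
    the horizontal coordinate is sign(NPC-OPC) * log2(|NPC-OPC| + 1), else
    sign(MES-AC) * log2(|MES-AC| + 1).  Quadrants: upper-left OPC, upper-right
    NPC, lower-left AC, lower-right MES.  Ties (x = 0 or y = 0) are broken
    toward the lower-left (AC) and flagged in the ``tie`` column.  Rows with
    missing scores are dropped with a warning.
    """
    cols = ["MES", "AC", "OPC", "NPC"]
    missing = [c for c in cols if c not in scores.columns]
    if missing:
        raise ValueError(f"missing score columns: {missing}")
    sc_ = scores[cols].astype(float)
    ok = sc_.notna().all(axis=1)
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} cells with missing scores")
        sc_ = sc_[ok]
    D = np.maximum(sc_["OPC"], sc_["NPC"]) - np.maximum(sc_["AC"], sc_["MES"])
    upper = D > 0
    dx_up = sc_["NPC"] - sc_["OPC"]
    dx_lo = sc_["MES"] - sc_["AC"]
    dx = np.where(upper, dx_up, dx_lo)
    x = np.sign(dx) * np.log2(np.abs(dx) + 1)
    y = D.to_numpy()
    state = sc_.idxmax(axis=1)
    quadrant = [
        _QUADRANTS[(yy > 0, xx > 0)] for yy, xx in zip(y, x)
    ]
    return pd.DataFrame(
        {
            "MES": sc_["MES"],
            "AC": sc_["AC"],
            "OPC": sc_["OPC"],
            "NPC": sc_["NPC"],
            "x": x,
            "y": y,
            "state": state,
            "quadrant": quadrant,
            "tie": (x == 0) | (y == 0),
        },
        index=sc_.index,
    )


def state_route_association(
    states: pd.Series, routes: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square test of independence between state and route.

    Returns (chi2, df, p, standardized residuals), where the residual of cell
    (i, j) is (O - E) / sqrt(E * (1 - row share) * (1 - column share)).
    """
    table = pd.crosstab(states, routes)
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    n = table.to_numpy().sum()
    row_p = table.sum(axis=1).to_numpy() / n
    col_p = table.sum(axis=0).to_numpy() / n
    resid = (table.to_numpy() - expected) / np.sqrt(
        expected * (1 - row_p[:, None]) * (1 - col_p[None, :])
    )
    resid = pd.DataFrame(resid, index=table.index, columns=table.columns)
    return float(chi2), int(df), float(p), resid


def dge(
    expr: ad.AnnData,
    group_labels: pd.Series | np.ndarray,
    group: str | None = None,
    counts: ad.AnnData | None = None,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two groups.

    ``group`` selects the focal level (one-vs-rest when more than two levels
    are present); with exactly two levels it defaults to the first sorted
    level.  Returns per-gene log2 fold change of group means (pseudocount 1),
    two-sided rank-sum p, Benjamini-Hochberg padj, and the MA abscissa
    ``log2_total_count`` (log2 of the gene's total raw count when ``counts``
    is supplied, else of total expression).
    """
    labels = pd.Series(np.asarray(group_labels), index=expr.obs_names)
    levels = sorted(labels.unique())
    if group is None:
        if len(levels) != 2:
            raise ValueError("specify `group` when there are not exactly 2 levels")
        group = levels[0]
    in_a = (labels == group).to_numpy()
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        raise ValueError("both groups must be non-empty")
    X = _dense(expr.X)
    A, B = X[in_a], X[~in_a]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ties/zero-variance genes
        stat, p = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = np.log2(A.mean(axis=0) + 1) - np.log2(B.mean(axis=0) + 1)
    padj = multipletests(p, method="fdr_bh")[1]
    tot = _dense(counts.X).sum(axis=0) if counts is not None else X.sum(axis=0)
    return pd.DataFrame(
        {
            "gene": list(expr.var_names),
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "log2_total_count": np.log2(np.asarray(tot).ravel() + 1),
        }
    ).set_index("gene")


def select_route_regulators(
    dge_table: pd.DataFrame,
    regulators: list[str],
    padj_max: float = 0.01,
    min_abs_log2fc: float = 0.5,
    up_label: str = "perivascular",
    down_label: str = "diffuse",
) -> pd.DataFrame:
    """Shortlist landscape regulators that pass the DGE thresholds.

    A regulator is selected when padj < ``padj_max`` and |log2FC| >
    ``min_abs_log2fc``; the direction column labels positive fold changes with
    ``up_label`` and negative ones with ``down_label``.
    """
    present = [r for r in regulators if r in dge_table.index]
    sub = dge_table.loc[present]
    hit = (sub["padj"] < padj_max) & (sub["log2fc"].abs() > min_abs_log2fc)
    sel = sub[hit].copy()
    sel["direction"] = np.where(sel["log2fc"] > 0, up_label, down_label)
    return sel.sort_values("padj")
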