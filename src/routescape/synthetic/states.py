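"""Synthetic single-cell counts with planted state structure and QC violators.

Cells are drawn from a negative-binomial baseline; each cell's state
(MES / AC / OPC / NPC) upshifts its state's signature genes by a fold change.
Designated QC-failure cells each violate exactly one quality filter (gene
floor, kit-specific doublet ceiling, mitochondrial fraction), and a block of
rare genes violates the gene-prevalence rule.  Ground truth (state, sample,
invasion route, planted violation) is carried in the cell metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["StatePopulationSpec", "gen_state_counts", "STATES"]

STATES = ("MES", "AC", "OPC", "NPC")

#: default mapping from invasion route to state mixture, mirroring the
#: perivascular (MES/OPC-dominated) vs diffuse (AC/NPC-dominated) association;
#: the leptomeningeal route is given its own intermediate profile.
ROUTE_PROFILES = {
    "perivascular": {"MES": 0.45, "AC": 0.05, "OPC": 0.45, "NPC": 0.05},
    "diffuse": {"MES": 0.05, "AC": 0.45, "OPC": 0.05, "NPC": 0.45},
    "leptomeningeal": {"MES": 0.25, "AC": 0.25, "OPC": 0.25, "NPC": 0.25},
}


@dataclass
class StatePopulationSpec:
    """Parameters of one synthetic cell population.

    ``n_cells_per_state`` fixes the number of ordinary (QC-passing) cells per
    state.  ``signature_fold`` multiplies the baseline mean of a state's
    signature genes.  ``noise="nb"`` draws negative-binomial counts;
    ``noise="none"`` emits the rounded expected counts (pure-state cells with
    no sampling noise).  QC thresholds are carried here so violators can be
    planted consistently at any scale.
    """

    n_cells_per_state: dict[str, int] = field(
        default_factory=lambda: {s: 250 for s in STATES}
    )
    n_genes: int = 2000
    signature_size: int = 50
    signature_fold: float = 4.0
    mito_fraction_outliers: float = 0.0
    doublet_rate: float = 0.0
    low_gene_rate: float = 0.0
    cycling_fraction: float = 0.0
    noise: str = "nb"
    nb_dispersion: float = 2.0  # NB shape parameter (smaller = noisier)
    baseline_mean: float = 0.6
    seed: int = 0

    # QC thresholds the planted violators are defined against
    min_genes: int = 500
    doublet_ceiling: dict[str, int] = field(
        default_factory=lambda: {"v2": 5100, "v3": 7200}
    )
    max_mito: float = 0.30
    min_cells_per_gene: int = 10
    n_rare_genes: int = 5

    def __post_init__(self) -> None:
        for p in (
            self.mito_fraction_outliers,
            self.doublet_rate,
            self.low_gene_rate,
            self.cycling_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError("proportions must lie in [0, 1]")
        if self.signature_size * 4 > self.n_genes:
            raise ValueError("four disjoint signatures exceed n_genes")


def _gene_names(spec: StatePopulationSpec) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    n = spec.n_genes
    names = np.array([f"G{i:05d}" for i in range(n)], dtype=object)
    # flagged housekeeping genes at the tail of the panel
    n_mito, n_ribo, n_hb = 13, 20, 4
    k = n - (n_mito + n_ribo + n_hb)
    names[k : k + n_mito] = [f"MT-{i}" for i in range(n_mito)]
    names[k + n_mito : k + n_mito + n_ribo] = [f"RPL{i}" for i in range(n_ribo)]
    names[k + n_mito + n_ribo :] = [f"HBB-{i}" for i in range(n_hb)]
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["mito"] = np.char.startswith(names.astype(str), "MT-")
    var["ribo"] = np.char.startswith(names.astype(str), "RPL")
    var["hemoglobin"] = np.char.startswith(names.astype(str), "HBB")
    sigs = {
        s: np.arange(i * spec.signature_size, (i + 1) * spec.signature_size)
        for i, s in enumerate(STATES)
    }
    cyc0 = 4 * spec.signature_size + spec.n_rare_genes
    sigs["S"] = np.arange(cyc0, cyc0 + 25)
    sigs["G2M"] = np.arange(cyc0 + 25, cyc0 + 50)
    return var, sigs


def gen_state_counts(
    spec: StatePopulationSpec,
) -> tuple[ad.AnnData, dict[str, list[str]]]:
    """Generate counts with planted states; returns (AnnData, signature genes).

    The AnnData carries raw counts in ``X`` (CSR int32), per-cell metadata
    (``true_state``, ``sample``, ``route``, ``kit``, ``planted_violation``)
    and gene flags (``mito``/``ribo``/``hemoglobin``).
    """
    rng = np.random.default_rng(spec.seed)
    var, sig_idx = _gene_names(spec)
    n_genes = spec.n_genes

    # per-gene baseline means; flagged genes moderately expressed, rare genes
    # (prevalence-rule violators) essentially absent
    base = rng.lognormal(np.log(spec.baseline_mean), 0.4, n_genes)
    flagged = (var["mito"] | var["ribo"] | var["hemoglobin"]).to_numpy()
    base[flagged] = 1.0
    rare = np.zeros(n_genes, dtype=bool)
    if spec.n_rare_genes:
        rare_idx = np.arange(4 * spec.signature_size, 4 * spec.signature_size + spec.n_rare_genes)
        rare[rare_idx] = True
        base[rare] = 0.0

    cells: list[dict] = []
    for state in STATES:
        for _ in range(int(spec.n_cells_per_state.get(state, 0))):
            cells.append({"true_state": state, "planted_violation": "none"})
    n_ok = len(cells)
    n_mito_out = int(round(spec.mito_fraction_outliers * n_ok))
    n_doub = int(round(spec.doublet_rate * n_ok))
    n_lowg = int(round(spec.low_gene_rate * n_ok))
    for kind, n_extra in (
        ("mito", n_mito_out),
        ("doublet", n_doub),
        ("low_genes", n_lowg),
    ):
        for _ in range(n_extra):
            cells.append(
                {
                    "true_state": rng.choice(STATES),
                    "planted_violation": kind,
                }
            )
    if not cells:
        X = sp.csr_matrix((0, n_genes), dtype=np.int32)
        obs = pd.DataFrame(
            {
                "true_state": pd.Series(dtype=object),
                "planted_violation": pd.Series(dtype=object),
                "sample": pd.Series(dtype=object),
                "route": pd.Series(dtype=object),
                "kit": pd.Series(dtype=object),
            }
        )
        adata = ad.AnnData(X=X, obs=obs, var=var)
        sig_names = {s: var.index[idx].tolist() for s, idx in sig_idx.items()}
        return adata, sig_names

    obs = pd.DataFrame(cells)
    obs.index = pd.Index([f"cell{i:05d}" for i in range(len(obs))], name="cell")

    # route / sample assignment conditioned on state
    routes = list(ROUTE_PROFILES)
    probs = np.array(
        [[ROUTE_PROFILES[r][s] for r in routes] for s in STATES]
    )
    probs = probs / probs.sum(axis=1, keepdims=True)
    state_pos = {s: i for i, s in enumerate(STATES)}
    route_draw = [
        routes[rng.choice(len(routes), p=probs[state_pos[st]])]
        for st in obs["true_state"]
    ]
    obs["route"] = route_draw
    obs["sample"] = [f"S_{r}_{rng.integers(1, 3)}" for r in obs["route"]]
    obs["kit"] = np.where(rng.random(len(obs)) < 0.5, "v2", "v3")

    # expected mean matrix per cell
    mu = np.tile(base, (len(obs), 1))
    for s in STATES:
        rows = (obs["true_state"] == s).to_numpy()
        mu[np.ix_(rows, sig_idx[s])] *= spec.signature_fold
    # cycling cells: upshift S or G2M program
    n_cyc = int(round(spec.cycling_fraction * len(obs)))
    cyc_rows = rng.choice(len(obs), n_cyc, replace=False) if n_cyc else []
    phase = np.full(len(obs), "none", dtype=object)
    for i in cyc_rows:
        ph = "S" if rng.random() < 0.5 else "G2M"
        phase[i] = ph
        mu[i, sig_idx[ph]] *= 3.0
    obs["phase"] = phase

    # scale factors implementing the planted QC violations
    scale = np.ones(len(obs))
    viol = obs["planted_violation"].to_numpy()
    scale[viol == "low_genes"] = 0.05
    if spec.noise == "none":
        X = np.rint(mu * scale[:, None]).astype(np.int32)
    elif spec.noise == "nb":
        m = mu * scale[:, None]
        r = spec.nb_dispersion
        X = rng.negative_binomial(r, r / (r + np.maximum(m, 1e-12)), m.shape).astype(
            np.int32
        )
        X[m == 0] = 0
    else:
        raise ValueError("noise must be 'nb' or 'none'")

    # doublets: force detected-gene count just above the kit ceiling
    for i in np.where(viol == "doublet")[0]:
        ceiling = spec.doublet_ceiling[obs["kit"].iloc[i]]
        margin = max(1, min(50, n_genes - ceiling - 1))
        if ceiling + margin > n_genes:
            raise ValueError("doublet ceiling exceeds gene panel size")
        on = rng.choice(n_genes, ceiling + margin, replace=False)
        X[i, on] = np.maximum(X[i, on], 1)

    # mito outliers: replace mitochondrial counts so the fraction exceeds max
    mito_cols = np.where(var["mito"].to_numpy())[0]
    for i in np.where(viol == "mito")[0]:
        other = int(X[i].sum() - X[i, mito_cols].sum())
        target = int(np.ceil(other * spec.max_mito / (1 - spec.max_mito) * 1.5))
        X[i, mito_cols] = 0
        X[i, mito_cols[0]] = max(target, 1)

    adata = ad.AnnData(X=sp.csr_matrix(X), obs=obs, var=var)
    sig_names = {s: var.index[idx].tolist() for s, idx in sig_idx.items()}
    return adata, sig_names
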