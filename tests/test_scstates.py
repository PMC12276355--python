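"""Unit tests for QC, signature scoring, embedding, association and DGE."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from routescape import scstates as ss
from routescape.synthetic import STATES, StatePopulationSpec, gen_state_counts


def brute_force_qc_counts(adata, th):
    """Independent recount of per-rule removals (explicit loops)."""
    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    report = {}
    keep_cells = []
    for i in range(X.shape[0]):
        keep_cells.append((X[i] > 0).sum() >= th.min_genes)
    report["low_gene_cells"] = sum(1 for k in keep_cells if not k)
    X = X[np.array(keep_cells, bool)]
    obs = adata.obs[np.array(keep_cells, bool)]
    keep_genes = []
    for j in range(X.shape[1]):
        keep_genes.append((X[:, j] > 0).sum() >= th.min_cells_per_gene)
    report["rare_genes"] = sum(1 for k in keep_genes if not k)
    X = X[:, np.array(keep_genes, bool)]
    var = adata.var[np.array(keep_genes, bool)]
    keep_cells = []
    for i in range(X.shape[0]):
        ceiling = th.doublet_ceiling[obs["kit"].iloc[i]]
        keep_cells.append((X[i] > 0).sum() <= ceiling)
    report["doublet_cells"] = sum(1 for k in keep_cells if not k)
    X = X[np.array(keep_cells, bool)]
    keep_cells = []
    mito = var["mito"].to_numpy()
    for i in range(X.shape[0]):
        tot = X[i].sum()
        frac = X[i][mito].sum() / tot if tot else 0.0
        keep_cells.append(frac <= th.max_mito)
    report["high_mito_cells"] = sum(1 for k in keep_cells if not k)
    report["flagged_genes"] = int(
        (var["mito"] | var["ribo"] | var["hemoglobin"]).sum()
    )
    return report


class TestQCFilter:
    def _small_spec(self, seed, **kw):
        kw.setdefault("doublet_ceiling", {"v2": 1400, "v3": 1700})
        return StatePopulationSpec(
            n_cells_per_state={s: 40 for s in STATES},
            seed=seed,
            **kw,
        )

    def test_cell_below_gene_floor_removed(self):
        # 499 expressed genes: exactly one below the floor
        X = np.ones((2, 1000), dtype=np.int32)
        X[0, 499:] = 0  # 499 genes expressed
        obs = pd.DataFrame({"kit": ["v3", "v3"]}, index=["low", "ok"])
        var = pd.DataFrame(
            {"mito": False, "ribo": False, "hemoglobin": False},
            index=[f"g{i}" for i in range(1000)],
        )
        a = ad.AnnData(X=X, obs=obs, var=var)
        th = ss.QCThresholds(min_cells_per_gene=0, doublet_ceiling={"v3": 1000})
        out, report = ss.qc_filter(a, th)
        assert report["low_gene_cells"] == 1
        assert list(out.obs_names) == ["ok"]

    def test_all_pass_matrix_unchanged(self):
        spec = self._small_spec(seed=0)
        adata, _ = gen_state_counts(spec)
        th = ss.QCThresholds(doublet_ceiling=spec.doublet_ceiling)
        out, report = ss.qc_filter(adata, th)
        assert report["low_gene_cells"] == 0
        assert report["doublet_cells"] == 0
        assert report["high_mito_cells"] == 0
        # only planted rare genes and flagged housekeeping genes removed
        assert out.n_obs == adata.n_obs

    def test_planted_violators_counted_exactly(self):
        spec = self._small_spec(
            seed=1, mito_fraction_outliers=0.05, doublet_rate=0.05, low_gene_rate=0.05
        )
        adata, _ = gen_state_counts(spec)
        th = ss.QCThresholds(doublet_ceiling=spec.doublet_ceiling)
        _, report = ss.qc_filter(adata, th)
        planted = adata.obs["planted_violation"].value_counts()
        assert report["low_gene_cells"] == planted["low_genes"]
        assert report["doublet_cells"] == planted["doublet"]
        assert report["high_mito_cells"] == planted["mito"]
        assert report["rare_genes"] == spec.n_rare_genes

    @pytest.mark.parametrize("seed", range(8))
    def test_report_matches_brute_force_recount(self, seed):
        spec = self._small_spec(
            seed=seed,
            mito_fraction_outliers=0.03,
            doublet_rate=0.03,
            low_gene_rate=0.03,
            n_genes=1200,
            signature_size=30,
            doublet_ceiling={"v2": 800, "v3": 1000},
        )
        adata, _ = gen_state_counts(spec)
        th = ss.QCThresholds(doublet_ceiling=spec.doublet_ceiling)
        _, report = ss.qc_filter(adata, th)
        assert dict(report) == brute_force_qc_counts(adata, th)

    def test_missing_kit_errors(self):
        a = ad.AnnData(X=np.ones((2, 5), dtype=np.int32))
        a.var["mito"] = a.var["ribo"] = a.var["hemoglobin"] = False
        with pytest.raises(ValueError, match="kit"):
            ss.qc_filter(a)


class TestScoreSignature:
    def _expr(self, rng, n_cells=80, n_genes=300):
        X = rng.lognormal(0, 0.5, (n_cells, n_genes))
        a = ad.AnnData(X=X)
        a.var_names = [f"g{i}" for i in range(n_genes)]
        return a

    def test_signature_of_everything_scores_near_zero(self, rng):
        a = self._expr(rng)
        s = ss.score_signature(a, list(a.var_names), seed=0)
        assert np.abs(s).max() < 0.05

    def test_planted_upshift_recovered(self, rng):
        # signature genes upshifted by delta in a small cell subset; their
        # average expression stays inside the bin of their matched background
        # genes, so the control set is expression-matched and the subset's
        # mean score recovers delta
        n_cells, n_genes, delta, n_up = 200, 1000, 1.5, 10
        base = rng.uniform(3.0, 7.0, n_genes)
        X = np.tile(base, (n_cells, 1)) + rng.normal(0, 0.01, (n_cells, n_genes))
        X[:n_up, :40] += delta
        a = ad.AnnData(X=X)
        a.var_names = [f"g{i}" for i in range(n_genes)]
        s = ss.score_signature(a, [f"g{i}" for i in range(40)], seed=1)
        assert s[:n_up].mean() == pytest.approx(delta, rel=0.15)
        assert abs(s[n_up:].mean()) < 0.2 * delta

    def test_deterministic_given_seed(self, rng):
        a = self._expr(rng)
        genes = list(a.var_names[:30])
        s1 = ss.score_signature(a, genes, seed=7)
        s2 = ss.score_signature(a, genes, seed=7)
        assert np.array_equal(s1, s2)

    def test_missing_genes_warn_and_empty_errors(self, rng):
        a = self._expr(rng)
        with pytest.warns(UserWarning):
            ss.score_signature(a, ["g0", "nope"], seed=0)
        with pytest.raises(ValueError):
            ss.score_signature(a, ["nope"], seed=0)


class TestCCRegress:
    def _adata_with_cycle(self, rng, slope=0.0, noise=0.1):
        n = 200
        # two pure score proxies: sets of genes equal to S / G2M programs
        s_prog = rng.normal(0, 1, n)
        g2m_prog = rng.normal(0, 1, n)
        X = rng.normal(3, 1, (n, 60))
        X[:, 0:10] = 3 + s_prog[:, None]
        X[:, 10:20] = 3 + g2m_prog[:, None]
        d = (3 + s_prog) - (3 + g2m_prog)
        X[:, 20] = slope * d + rng.normal(0, noise, n)
        a = ad.AnnData(X=X)
        a.var_names = [f"g{i}" for i in range(60)]
        return a, d

    def test_cycle_driven_gene_flattened(self, rng):
        a, d = self._adata_with_cycle(rng, slope=2.0, noise=0.1)
        out = ss.cc_regress(
            a, [f"g{i}" for i in range(10)], [f"g{i}" for i in range(10, 20)],
            nctrl=10,
        )
        resid = out.X[:, 20] - out.X[:, 20].mean()
        assert resid.var() < 0.25 * (2.0 * d).var()

    def test_uncorrelated_gene_nearly_unchanged(self, rng):
        a, _ = self._adata_with_cycle(rng, slope=0.0)
        before = a.X[:, 40].copy()
        out = ss.cc_regress(
            a, [f"g{i}" for i in range(10)], [f"g{i}" for i in range(10, 20)],
            nctrl=10,
        )
        # slope estimate on an uncorrelated gene is O(1/sqrt(n))
        assert np.corrcoef(before, out.X[:, 40])[0, 1] > 0.98

    def test_constant_difference_skips_regression(self, rng):
        a = ad.AnnData(X=rng.normal(3, 1, (50, 30)))
        a.var_names = [f"g{i}" for i in range(30)]
        a.X[:, :5] = 2.0  # S genes constant
        a.X[:, 5:10] = 2.0  # G2M genes constant -> d constant
        before = a.X.copy()
        out = ss.cc_regress(a, [f"g{i}" for i in range(5)], [f"g{i}" for i in range(5, 10)], nctrl=5)
        assert np.allclose(out.X, before)


class TestClusterCells:
    def test_two_blobs_two_clusters(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (80, 15)), rng.normal(5, 0.3, (80, 15))])
        labels = ss.cluster_cells(ad.AnnData(X=X), resolution=0.3, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:80])) == 1 and len(set(labels[80:])) == 1

    def test_resolution_sweep_non_decreasing(self, rng):
        X = np.vstack([rng.normal(i * 3, 0.4, (50, 10)) for i in range(4)])
        a = ad.AnnData(X=X)
        counts = [
            len(set(ss.cluster_cells(a, resolution=r, seed=0)))
            for r in (0.05, 0.3, 1.0)
        ]
        assert counts == sorted(counts)

    def test_single_cell_single_cluster(self, rng):
        a = ad.AnnData(X=rng.random((1, 10)))
        assert list(ss.cluster_cells(a)) == [0]


class TestNeftelEmbedding:
    def _scores(self, mes=0.0, acs=0.0, opc=0.0, npc=0.0):
        return pd.DataFrame({"MES": [mes], "AC": [acs], "OPC": [opc], "NPC": [npc]})

    def test_pure_mes_lands_lower_right(self):
        emb = ss.neftel_embedding(self._scores(mes=1.0))
        assert emb["y"].iloc[0] == -1.0
        assert emb["x"].iloc[0] == 1.0
        assert emb["quadrant"].iloc[0] == "MES"

    def test_all_equal_is_flagged_tie_at_origin(self):
        emb = ss.neftel_embedding(self._scores(0.3, 0.3, 0.3, 0.3))
        assert emb["x"].iloc[0] == 0.0 and emb["y"].iloc[0] == 0.0
        assert bool(emb["tie"].iloc[0])
        assert emb["quadrant"].iloc[0] == "AC"  # lower-left tie break

    @given(
        st.tuples(*[st.floats(-5, 5).map(lambda v: round(v, 6)) for _ in range(4)]),
        st.floats(-10, 10).map(lambda v: round(v, 6)),
    )
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_common_shift_and_unique_quadrant(self, scores, c):
        df = pd.DataFrame([dict(zip(["MES", "AC", "OPC", "NPC"], scores))])
        e1 = ss.neftel_embedding(df)
        e2 = ss.neftel_embedding(df + c)
        assert e1["x"].iloc[0] == pytest.approx(e2["x"].iloc[0], abs=1e-9)
        assert e1["y"].iloc[0] == pytest.approx(e2["y"].iloc[0], abs=1e-9)
        assert e1["quadrant"].iloc[0] in {"MES", "AC", "OPC", "NPC"}

    def test_missing_scores_dropped_with_warning(self):
        df = self._scores(mes=1.0)
        df.loc[1] = [np.nan, 0, 0, 0]
        with pytest.warns(UserWarning):
            emb = ss.neftel_embedding(df)
        assert len(emb) == 1


class TestStateRouteAssociation:
    def test_df_for_4x3_table_is_6(self, rng):
        states = pd.Series(rng.choice(list(STATES), 600))
        routes = pd.Series(rng.choice(["perivascular", "diffuse", "lepto"], 600))
        chi2, df, p, resid = ss.state_route_association(states, routes)
        assert df == 6
        assert resid.shape == (4, 3)

    def test_diagonal_2x2_closed_form(self):
        states = pd.Series(["a"] * 10 + ["b"] * 10)
        routes = pd.Series(["x"] * 10 + ["y"] * 10)
        chi2, df, p, _ = ss.state_route_association(states, routes)
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_null_p_uniform(self):
        ps = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            s = pd.Series(r.choice(["a", "b"], 200))
            t = pd.Series(r.choice(["x", "y", "z"], 200))
            ps.append(ss.state_route_association(s, t)[2])
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() < 0.12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_chi_square_small_tables(self, seed):
        r = np.random.default_rng(seed)
        nr, nc = r.integers(2, 6, 2)
        table = r.integers(1, 21, (nr, nc))
        states = np.repeat(
            [f"s{i}" for i in range(nr) for _ in range(nc)], table.ravel()
        )
        routes = np.concatenate(
            [np.repeat(f"r{j}", table[i, j]) for i in range(nr) for j in range(nc)]
        )
        chi2, df, p, _ = ss.state_route_association(pd.Series(states), pd.Series(routes))
        # textbook oracle
        obs = pd.crosstab(pd.Series(states), pd.Series(routes)).to_numpy()
        n = obs.sum()
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / n
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert df == (obs.shape[0] - 1) * (obs.shape[1] - 1)


class TestDGE:
    def _expr(self, A, B):
        X = np.vstack([A, B]).astype(float)
        a = ad.AnnData(X=X)
        a.var_names = [f"g{i}" for i in range(X.shape[1])]
        labels = np.array(["A"] * len(A) + ["B"] * len(B))
        return a, labels

    def test_identical_groups_null(self, rng):
        A = rng.poisson(3, (60, 30))
        a, labels = self._expr(A, A)
        t = ss.dge(a, labels, group="A")
        assert np.allclose(t["log2fc"], 0)
        assert (t["padj"] > 0.9).all()

    def test_fourfold_shift_log2fc_two(self, rng):
        A = rng.poisson(12.0, (150, 20))
        B = rng.poisson(12.0, (150, 20))
        A[:, 0] = rng.poisson(48.0, 150)
        a, labels = self._expr(A, B)
        t = ss.dge(a, labels, group="A")
        # log2((48+1)/(12+1)) ~ 1.91 for the planted gene
        assert t["log2fc"].iloc[0] == pytest.approx(np.log2(49 / 13), abs=0.15)
        assert t["padj"].iloc[0] < 1e-6

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        padj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(padj, [0.04, 0.04, 0.04, 0.04])


class TestSelectRouteRegulators:
    def _table(self):
        return pd.DataFrame(
            {
                "log2fc": [1.0, 0.4, -0.8, 0.6],
                "p": [1e-6, 1e-9, 1e-4, 0.5],
                "padj": [1e-5, 1e-8, 1e-3, 0.6],
                "log2_total_count": [10, 10, 10, 10],
            },
            index=["up_hit", "small_fc", "down_hit", "not_sig"],
        )

    def test_threshold_rules(self):
        sel = ss.select_route_regulators(self._table(), ["up_hit", "small_fc", "down_hit", "not_sig"])
        assert set(sel.index) == {"up_hit", "down_hit"}
        assert sel.loc["up_hit", "direction"] == "perivascular"
        assert sel.loc["down_hit", "direction"] == "diffuse"

    def test_empty_regulator_list(self):
        assert len(ss.select_route_regulators(self._table(), [])) == 0
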