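"""End-to-end orchestration of the synthetic demonstration pipeline.

A configuration selects stages and per-stage parameters; ``run_pipeline``
executes them in dependency order (simulate -> imaging / states / landscape /
tracking -> survival -> report), writing provenance-stamped CSVs into a run
directory.  A single global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence`` so stages are reproducible independently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging as im
from . import io, landscape as ls, scstates as ss, survival as sv, synthetic as syn
from . import tracking as tr

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "DEFAULT_CONFIG"]

STAGES = ("simulate", "imaging", "states", "landscape", "tracking", "survival")

DEFAULT_CONFIG: dict = {
    "stages": list(STAGES),
    "seed": 0,
    "imaging": {"penalty": 5.0, "k": 5, "eps": 1.0},
    "states": {"resolution": 0.3, "n_cells_per_state": 150, "n_genes": 2000},
    "landscape": {"n_metamodules": 3, "min_support": 4},
    "tracking": {"dilation_radius": 5, "bootstrap": 500},
    "survival": {"n_subjects": 60, "marker_beta": 0.02},
}


class PipelineConfig:
    """Validated pipeline configuration; round-trips losslessly to YAML."""

    def __init__(self, data: dict | None = None):
        data = {} if data is None else dict(data)
        unknown = set(data) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.data = {k: data.get(k, DEFAULT_CONFIG[k]) for k in DEFAULT_CONFIG}
        for stage_key in STAGES[1:]:
            if stage_key in self.data and isinstance(self.data[stage_key], dict):
                unknown = set(self.data[stage_key]) - set(DEFAULT_CONFIG[stage_key])
                if unknown:
                    raise ValueError(
                        f"unknown keys in config section {stage_key!r}: {sorted(unknown)}"
                    )
        bad = set(self.data["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    def __getitem__(self, key):
        return self.data[key]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    ss_ = np.random.SeedSequence([seed, STAGES.index(stage)])
    return int(ss_.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig | dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the configured stages; returns a dict of headline results.

    Every stage consumes only synthetic inputs generated under its own child
    seed, writes its outputs as CSV with a provenance header, and contributes
    summary numbers to ``report.json``.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    seed = cfg["seed"] if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(cfg.data)
    stages = cfg["stages"]
    report: dict = {"seed": seed, "config_hash": chash}
    log: list[str] = []

    def save(name: str, df: pd.DataFrame, **kw) -> None:
        io.write_csv(outdir / name, df, seed=seed, cfg_hash=chash, **kw)

    if "simulate" in stages:
        s = stage_seed(seed, "simulate")
        simdir = outdir / "simulated"
        simdir.mkdir(exist_ok=True)
        img, truth = syn.gen_multiplex_image(
            syn.ImageScenario(
                seed=s, height=256, width=256, bulk_radius=55.0,
                vessel_count=2, n_aggregates=4, n_elongated=12, n_band_cells=8,
            )
        )
        io.write_multiplex_tiff(simdir / "slide.tiff", img)
        adata, _sigs = syn.gen_state_counts(
            syn.StatePopulationSpec(
                n_cells_per_state={st: 50 for st in syn.STATES}, seed=s
            )
        )
        io.write_counts_mtx(simdir / "counts", adata)
        tables, _t = syn.gen_regulatory_tables(syn.LandscapeSpec(seed=s))
        for t in tables:
            save(f"simulated/regulatory_{t.sample}.csv", t.coefficients)
        surv, nuclei = syn.gen_survival_tma(syn.SurvivalSpec(seed=s))
        save("simulated/survival.csv", surv, index=False)
        report["simulate"] = {"written": sorted(p.name for p in simdir.iterdir())}
        log.append(f"simulate: wrote {len(report['simulate']['written'])} artifacts")

    if "imaging" in stages:
        s = stage_seed(seed, "imaging")
        scen = syn.ImageScenario(seed=s)
        img, truth = syn.gen_multiplex_image(scen)
        corrected = im.correct_channels(img, penalty=cfg["imaging"]["penalty"])
        T, V = im.segment_base(corrected, k=cfg["imaging"]["k"], seed=s)
        L = im.label_compartments((T, V), scen.compartment_params)
        scores = im.compartment_scores(corrected, L, eps=cfg["imaging"]["eps"])
        areas = im.compartment_areas(L)
        save("imaging_scores.csv", scores.scores)
        save("imaging_areas.csv", areas.to_frame("fraction"))
        pv_rank = scores.scores.loc["marker_pv"].idxmax()
        report["imaging"] = {
            "top_compartment_for_marker_pv": str(pv_rank),
            "tumor_area_fraction": float(np.mean(T)),
        }
        log.append(f"imaging: {L.labels.size} px labeled, {len(scores.scores)} proteins scored")

    if "states" in stages:
        s = stage_seed(seed, "states")
        p = cfg["states"]
        spec = syn.StatePopulationSpec(
            n_cells_per_state={st: p["n_cells_per_state"] for st in syn.STATES},
            n_genes=p["n_genes"],
            seed=s,
        )
        adata, sigs = syn.gen_state_counts(spec)
        filtered, qc_report = ss.qc_filter(adata)
        expr = ss.normalize_log(filtered)
        score_df = pd.DataFrame(
            {
                st: ss.score_signature(expr, sigs[st], seed=s + i)
                for i, st in enumerate(syn.STATES)
            },
            index=expr.obs_names,
        )
        emb = ss.neftel_embedding(score_df)
        emb["route"] = expr.obs["route"]
        chi2, df_, pval, resid = ss.state_route_association(
            emb["state"], emb["route"]
        )
        save("states_embedding.csv", emb)
        save("states_residuals.csv", resid)
        acc = float((emb["state"] == expr.obs["true_state"]).mean())
        report["states"] = {
            "qc_removed": {k: int(v) for k, v in qc_report.items()},
            "state_accuracy": acc,
            "chi2": chi2,
            "df": df_,
            "p": pval,
        }
        log.append(f"states: {filtered.n_obs} cells after QC, chi2={chi2:.1f}")

    if "landscape" in stages:
        s = stage_seed(seed, "landscape")
        tables, truth = syn.gen_regulatory_tables(syn.LandscapeSpec(seed=s))
        merged, ann, gene_sets = ls.merge_landscape(tables)
        Z = ls.cluster_modules(merged)
        assign = ls.cut_metamodules(
            Z, list(merged.columns), n_metamodules=cfg["landscape"]["n_metamodules"]
        )
        mms = ls.metamodule_signatures(
            assign, gene_sets, min_support=cfg["landscape"]["min_support"]
        )
        anova = ls.regulator_anova(merged, ann, "route")
        save("landscape_metamodules.csv", assign.to_frame())
        save("landscape_anova.csv", anova)
        top = anova.sort_values("F", ascending=False).head(5).index.tolist()
        report["landscape"] = {
            "n_metamodules": int(assign.nunique()),
            "signature_sizes": [len(m.signature) for m in mms],
            "top_route_regulators": top,
        }
        log.append(f"landscape: {assign.nunique()} metamodules")

    if "tracking" in stages:
        s = stage_seed(seed, "tracking")
        spec = syn.MotionSpec(vessel_fraction=0.6, seed=s)
        _stack, mask, truth_ts, dets = syn.gen_tracks_movie(spec)
        ts = tr.link_tracks(dets, dt=spec.dt, pixel_size=spec.pixel_size)
        speeds = tr.track_speeds(ts)
        ends = ts.table.groupby("track_id").last()
        assoc, prop = tr.vessel_association(
            ends[["x", "y"]].to_numpy(), mask, cfg["tracking"]["dilation_radius"]
        )
        save("tracking_tracks.csv", ts.table, index=False)
        report["tracking"] = {
            "n_tracks": int(len(ts.track_ids)),
            "mean_speed_um_per_h": float(speeds.mean()),
            "vessel_associated_fraction": prop,
        }
        log.append(f"tracking: {len(ts.track_ids)} tracks, assoc={prop:.2f}")

    if "survival" in stages:
        s = stage_seed(seed, "survival")
        p = cfg["survival"]
        spec = syn.SurvivalSpec(
            n_subjects=p["n_subjects"], marker_beta=p["marker_beta"],
            group_effect=0.7, seed=s,
        )
        surv, nuclei = syn.gen_survival_tma(spec)
        subjects = surv.groupby("patient").first().reset_index()
        km = sv.km_logrank(subjects, group_col="group")
        fracs = sv.tma_fractions(nuclei, {"MARKER": surv.attrs["threshold"]})
        cox = sv.cox_marker(surv)
        save("survival_fractions.csv", fracs, index=False)
        report["survival"] = {
            "logrank_chi2": km["chi2"],
            "logrank_df": km["df"],
            "logrank_p": km["p"],
            "marker_hr": cox["hr"],
            "marker_hr_ci": list(cox["ci"]),
        }
        log.append(f"survival: logrank chi2={km['chi2']:.2f}, HR={cox['hr']:.3f}")

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    cfg.to_yaml(outdir / "config.yaml")
    return report
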