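"""Synthetic regulator x module tables with planted metamodule block structure.

Emulates the output format of a regulatory-clustering method run per sample:
every sample contributes a coefficient table over a shared regulator panel.
Modules are assigned to planted metamodules; each metamodule has a set of
driver regulators whose coefficients are elevated in its member modules, and
a gene pool from which member modules sample their gene content (so genes
recur across members).  Per-factor selectivity effects shift designated
regulators' coefficients by growth condition, patient, or invasion route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..landscape import RegulatoryTable

__all__ = ["LandscapeSpec", "gen_regulatory_tables"]

ROUTES = ("perivascular", "diffuse", "leptomeningeal")


@dataclass
class LandscapeSpec:
    """Parameters of one synthetic landscape.

    ``selectivity_effects`` gives the coefficient shift applied to the
    designated selective regulators for each factor (growth_condition,
    patient, route); 0 disables that factor's planting.  ``driver_effect``
    is the elevation of a metamodule's driver regulators in its modules —
    this is what makes metamodules separable.
    """

    n_samples: int = 6
    n_regulators: int = 40
    modules_per_sample: int = 20
    n_metamodules: int = 3
    selectivity_effects: dict[str, float] = field(
        default_factory=lambda: {"growth_condition": 0.0, "patient": 0.0, "route": 0.8}
    )
    n_selective_per_factor: int = 3
    driver_effect: float = 2.5
    drivers_per_metamodule: int = 8
    noise_sd: float = 0.3
    pool_size: int = 60
    genes_per_module: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.n_samples * self.modules_per_sample
        if self.n_metamodules > total:
            raise ValueError("more metamodules than modules")
        # each planted metamodule must span >= 4 modules for the signature rule
        if total // self.n_metamodules < 4:
            raise ValueError("metamodules would span fewer than 4 modules")
        unknown = set(self.selectivity_effects) - {
            "growth_condition",
            "patient",
            "route",
        }
        if unknown:
            raise ValueError(f"unknown selectivity factors: {unknown}")


def gen_regulatory_tables(
    spec: LandscapeSpec,
) -> tuple[list[RegulatoryTable], dict]:
    """Generate per-sample tables; returns (tables, ground truth).

    Ground truth holds the module -> metamodule assignment (keyed by the
    prefixed module ids used after merging), the driver regulators per
    metamodule, the selective regulators per factor, and each metamodule's
    gene pool.
    """
    rng = np.random.default_rng(spec.seed)
    regs = [f"R{i:03d}" for i in range(spec.n_regulators)]
    genes = [f"G{i:04d}" for i in range(spec.n_metamodules * spec.pool_size)]
    pools = {
        mm: genes[mm * spec.pool_size : (mm + 1) * spec.pool_size]
        for mm in range(spec.n_metamodules)
    }
    drivers = {
        mm: rng.choice(spec.n_regulators, spec.drivers_per_metamodule, replace=False)
        for mm in range(spec.n_metamodules)
    }
    # selective regulators drawn disjointly from the non-driver pool
    used = set(np.concatenate(list(drivers.values())).tolist())
    free = [i for i in range(spec.n_regulators) if i not in used]
    rng.shuffle(free)
    selective: dict[str, list[int]] = {}
    k = 0
    for factor in ("growth_condition", "patient", "route"):
        if spec.selectivity_effects.get(factor, 0.0) != 0.0:
            selective[factor] = free[k : k + spec.n_selective_per_factor]
            k += spec.n_selective_per_factor
        else:
            selective[factor] = []

    tables, truth_assign = [], {}
    factor_levels = {
        "growth_condition": ("in_vitro", "in_vivo"),
        "route": ROUTES,
    }
    for s in range(spec.n_samples):
        sample = f"S{s}"
        growth = factor_levels["growth_condition"][s % 2]
        route = ROUTES[s % 3]
        patient = f"P{s}"
        coef = rng.normal(0.0, spec.noise_sd, (spec.n_regulators, spec.modules_per_sample))
        gene_sets, ann_rows, mod_ids = {}, [], []
        for m in range(spec.modules_per_sample):
            mm = (s * spec.modules_per_sample + m) % spec.n_metamodules
            mod = f"M{m:02d}"
            mod_ids.append(mod)
            truth_assign[f"{sample}:{mod}"] = mm
            coef[drivers[mm], m] += spec.driver_effect
            # factor-selective shifts for this module's annotation
            eff = spec.selectivity_effects
            if eff.get("growth_condition", 0.0) and growth == "in_vivo":
                coef[selective["growth_condition"], m] += eff["growth_condition"]
            if eff.get("patient", 0.0) and s % 2 == 0:
                coef[selective["patient"], m] += eff["patient"] * (s + 1) / spec.n_samples
            if eff.get("route", 0.0) and route == "perivascular":
                coef[selective["route"], m] += eff["route"]
            n_pick = min(spec.genes_per_module, spec.pool_size)
            gene_sets[mod] = set(rng.choice(pools[mm], n_pick, replace=False).tolist())
            ann_rows.append(
                {
                    "module": mod,
                    "growth_condition": growth,
                    "patient": patient,
                    "route": route,
                }
            )
        ann = pd.DataFrame(ann_rows).set_index("module")
        tables.append(
            RegulatoryTable(
                sample=sample,
                coefficients=pd.DataFrame(
                    coef, index=regs, columns=mod_ids
                ),
                gene_sets=gene_sets,
                annotations=ann,
            )
        )
    truth = {
        "assignment": pd.Series(truth_assign, name="metamodule"),
        "drivers": {mm: [regs[i] for i in idx] for mm, idx in drivers.items()},
        "selective": {f: [regs[i] for i in idx] for f, idx in selective.items()},
        "pools": pools,
    }
    return tables, truth
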