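"""Synthetic multiplex slides with planted spatial compartments.

The generator emulates a xenograft section: a dense tumor bulk with
medium- and low-density rims, tumor cells hugging blood vessels, circular
aggregates, a white-matter-like horizontal band containing elongated cells,
scattered elongated and round diffusely invading cells, and background
parenchyma.  Channels are linear mixtures (bleed-through matrix) of the
ground-truth signals plus clipped Gaussian noise.

Ground-truth labels are produced by applying the package's own labeling rule
engine to the clean planted masks, so recovery tests measure how well the
pipeline reconstructs those masks from the noisy mixed image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..imaging import (
    CompartmentParams,
    LabelingMatrix,
    MultiplexImage,
    label_compartments,
)

__all__ = ["ImageScenario", "gen_multiplex_image", "default_mixing"]


def default_mixing(bleed: float = 0.04) -> np.ndarray:
    """Channel bleed-through matrix: identity plus uniform off-diagonal bleed."""
    m = np.full((8, 8), bleed)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class ImageScenario:
    """Parameters of one synthetic slide.

    The fixed layout keeps structures in disjoint regions of the frame: the
    white-matter band along the top, an aggregate field upper-left, the bulk
    disk lower-left, vessels in the right half, elongated cells along the
    bottom, so the analytic area budget of each class is simple geometry.
    """

    height: int = 512
    width: int = 512
    vessel_count: int = 3
    bulk_radius: float = 110.0
    diffuse_density: float = 1.2e-4  # round diffuse cells per pixel^2
    mixing_matrix: np.ndarray = field(default_factory=default_mixing)
    noise_sd: float = 0.05
    seed: int = 0

    # planted structure (counts and densities)
    n_aggregates: int = 12
    n_elongated: int = 40
    n_band_cells: int = 25
    zone_densities: tuple[float, float, float] = (1.0, 0.65, 0.35)
    perivascular_density: float = 0.8
    vessel_halfwidth: int = 2  # vessel stroke radius in px (width 2r+1)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("image dimensions must be positive")
        m = np.asarray(self.mixing_matrix, dtype=float)
        if m.shape != (8, 8):
            raise ValueError("mixing_matrix must be 8x8")
        if np.any(np.diag(m) <= 0):
            raise ValueError("mixing_matrix diagonal must be positive")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("mixing_matrix is singular")
        self.mixing_matrix = m

    # ---- deterministic layout -------------------------------------------
    @property
    def band_rows(self) -> tuple[int, int]:
        return (int(0.04 * self.height), int(0.11 * self.height))

    @property
    def bulk_center(self) -> tuple[float, float]:
        return (0.63 * self.height, 0.33 * self.width)

    @property
    def compartment_params(self) -> CompartmentParams:
        """Labeling parameters matched to the planted densities.

        Absolute thresholds midway between the planted zone densities, so the
        box-filter transition crosses each threshold at the geometric zone
        boundary.
        """
        hi, med, lo = self.zone_densities
        band = np.zeros((self.height, self.width), dtype=bool)
        r0, r1 = self.band_rows
        band[r0:r1, :] = True
        return CompartmentParams(
            window=31,
            density_thresholds=((med + lo) / 2, (hi + med) / 2),
            density_mode="absolute",
            d_pv=10.0,
            band_mask=band,
        )

    def area_budget(self) -> dict[str, float]:
        """Analytic expected pixel fraction per ground-truth class.

        Geometry of the planted shapes: disk/annulus areas times their stipple
        densities, ellipse/circle areas times counts, vessel path length times
        stroke width.  Transition effects of the box filter are symmetric
        around each zone boundary and cancel to first order.
        """
        total = self.height * self.width
        R = self.bulk_radius
        hi_d, med_d, lo_d = self.zone_densities
        a_hi = np.pi * (0.6 * R) ** 2 * hi_d
        a_med = np.pi * ((0.85 * R) ** 2 - (0.6 * R) ** 2) * med_d
        a_low = np.pi * (R**2 - (0.85 * R) ** 2) * lo_d
        a_low += self.diffuse_density * total * _ROUND_CELL_AREA
        a_agg = self.n_aggregates * np.pi * _AGG_RADIUS**2
        a_el = self.n_elongated * _ELLIPSE_AREA
        a_cc = self.n_band_cells * _ELLIPSE_AREA
        vessel_len = self.vessel_count * _VESSEL_STEPS
        a_vessel = vessel_len * (2 * self.vessel_halfwidth + 1)
        # collar strips on both sides plus rounded end caps
        a_pv = (
            vessel_len * 2 * 10.0 + self.vessel_count * np.pi * 10.0**2
        ) * self.perivascular_density
        if self.vessel_count == 0:
            a_vessel = a_pv = 0.0
        fractions = {
            "high_density": a_hi,
            "medium_density": a_med,
            "low_density": a_low,
            "aggregate": a_agg,
            "perivascular": a_pv,
            "corpus_callosum": a_cc,
            "elongated": a_el,
            "vessel": a_vessel,
        }
        fractions = {k: v / total for k, v in fractions.items()}
        fractions["parenchyma"] = 1.0 - sum(fractions.values())
        return fractions


_AGG_RADIUS = 8.0
_ELLIPSE_AXES = (9.0, 2.5)
_ELLIPSE_AREA = np.pi * _ELLIPSE_AXES[0] * _ELLIPSE_AXES[1]
_ROUND_CELL_AREA = np.pi * 2.5**2
_VESSEL_STEPS = 185


def _span(rng, lo, hi, pad):
    """Uniform draw on [lo+pad, hi-pad], degrading gracefully on tight spans."""
    lo2, hi2 = lo + pad, hi - pad
    if hi2 <= lo2:
        mid = 0.5 * (lo + hi)
        return mid if hi <= lo else rng.uniform(min(lo, mid), max(hi, mid))
    return rng.uniform(lo2, hi2)


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, axes, theta):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    u = dy * np.cos(theta) + dx * np.sin(theta)
    v = -dy * np.sin(theta) + dx * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _stipple(mask: np.ndarray, density: float, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(mask)
    out[mask] = rng.random(int(mask.sum())) < density
    return out


def _vessel_paths(spec: ImageScenario, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random-walk polylines confined to the right half of the frame."""
    V = np.zeros((spec.height, spec.width), dtype=bool)
    r0 = spec.band_rows[1] + 25
    r1, c0, c1 = spec.height - 15, int(0.58 * spec.width), spec.width - 10
    n = spec.vessel_count
    for k in range(n):
        # each vessel wanders gently inside its own horizontal sub-band so
        # perivascular collars do not overlap between vessels
        band = (r1 - r0) / max(n, 1)
        pad = min(18.0, band / 3)
        b0 = r0 + k * band + pad
        b1 = r0 + (k + 1) * band - pad
        y = rng.uniform(b0, b1)
        x = float(c0 + 1)
        theta = rng.uniform(-0.2, 0.2)
        for _step in range(_VESSEL_STEPS):
            theta = np.clip(theta + rng.normal(0, 0.03), -0.5, 0.5)
            y2, x2 = y + np.sin(theta), x + np.cos(theta)
            if not (b0 < y2 < b1):
                theta = -theta
                y2 = y + np.sin(theta)
            if x2 >= c1:  # bounce back leftward on the far wall
                theta = np.pi - theta
                x2 = x + np.cos(theta)
            y, x = y2, max(x2, c0 + 1.0)
            V[int(round(y)), int(round(x))] = True
    if spec.vessel_count:
        V = ndimage.binary_dilation(
            V, structure=ndimage.generate_binary_structure(2, 2),
            iterations=spec.vessel_halfwidth,
        )
    return V


def gen_multiplex_image(spec: ImageScenario) -> tuple[MultiplexImage, LabelingMatrix]:
    """Generate one synthetic 8-channel slide and its ground-truth labeling.

    Channels: 0 DAPI (cellularity), 1 AF (smooth gradient), 2 tumor marker,
    3 vessel marker, 4 perivascular-enriched protein, 5 diffuse-enriched
    protein, 6 bulk-enriched protein, 7 ubiquitous tumor protein.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    shape = (H, W)

    V = _vessel_paths(spec, rng)

    # tumor bulk: dense core + stippled medium/low rims
    R = spec.bulk_radius
    hi_d, med_d, lo_d = spec.zone_densities
    core = _disk(shape, spec.bulk_center, 0.6 * R)
    med = _disk(shape, spec.bulk_center, 0.85 * R) & ~core
    low = _disk(shape, spec.bulk_center, R) & ~core & ~med
    T = _stipple(core, hi_d, rng) | _stipple(med, med_d, rng) | _stipple(low, lo_d, rng)

    # perivascular tumor: stipple in the d_pv collar around vessels
    pv_truth = np.zeros(shape, dtype=bool)
    if spec.vessel_count:
        dist = ndimage.distance_transform_edt(~V)
        collar = (dist > 0) & (dist <= spec.compartment_params.d_pv)
        pv_truth = _stipple(collar, spec.perivascular_density, rng)
        T |= pv_truth

    # circle-shaped aggregates in the upper-left field
    agg = np.zeros(shape, dtype=bool)
    r0 = spec.band_rows[1] + 25
    r1, c1 = int(spec.bulk_center[0] - R - 25), int(0.52 * W)
    for i in range(spec.n_aggregates):
        cy = _span(rng, r0, r1, 12)
        cx = _span(rng, 0, c1, 12)
        agg |= _disk(shape, (cy, cx), _AGG_RADIUS)
    T |= agg

    # elongated diffuse cells along the bottom-left margin
    el = np.zeros(shape, dtype=bool)
    rb0, rb1 = int(spec.bulk_center[0] + R + 20), H - 12
    for _ in range(spec.n_elongated):
        cy = _span(rng, rb0, rb1, 0)
        cx = _span(rng, 0, 0.52 * W, 12)
        el |= _ellipse(shape, (cy, cx), _ELLIPSE_AXES, rng.uniform(0, np.pi))
    T |= el

    # elongated cells in the white-matter band (horizontal orientation)
    band0, band1 = spec.band_rows
    cc = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_band_cells):
        cy = _span(rng, band0, band1, 5)
        cx = _span(rng, 0, W, 15)
        cc |= _ellipse(shape, (cy, cx), _ELLIPSE_AXES, np.pi / 2)
    T |= cc

    # scattered round diffusely invading cells in free parenchyma
    n_round = rng.poisson(spec.diffuse_density * H * W)
    for _ in range(n_round):
        cy = _span(rng, rb0, rb1, 0)
        cx = (
            _span(rng, 0.54 * W, W, 12)
            if rng.random() < 0.3
            else _span(rng, 0, 0.52 * W, 12)
        )
        # keep clear of vessels so these stay plain low-density cells
        if spec.vessel_count and dist[int(cy), int(cx)] <= 16:
            continue
        T |= _disk(shape, (cy, cx), 2.5)
    T &= ~V

    # ---- ground-truth labeling from the clean masks ----------------------
    truth = label_compartments((T, V), spec.compartment_params)

    # ---- ground-truth channel signals ------------------------------------
    col = np.linspace(0.0, 1.0, W)[None, :] * np.ones((H, 1))
    sig = np.zeros((H, W, 8))
    sig[:, :, 0] = 0.3 + 0.7 * T + 0.3 * V  # DAPI cellularity
    sig[:, :, 1] = 0.15 + 0.5 * col  # autofluorescence gradient
    sig[:, :, 2] = 1.8 * T  # tumor marker
    sig[:, :, 3] = 2.0 * V  # vessel marker
    sig[:, :, 4] = 2.0 * pv_truth + 0.15 * T  # perivascular protein
    sig[:, :, 5] = 2.0 * (el | cc) + 0.15 * T  # diffuse protein
    sig[:, :, 6] = 1.6 * (T & core) + 0.2 * T  # bulk protein
    sig[:, :, 7] = 0.9 * T  # ubiquitous tumor protein

    mixed = sig.reshape(-1, 8) @ spec.mixing_matrix.T
    if spec.noise_sd > 0:
        mixed = mixed + rng.normal(0, spec.noise_sd, mixed.shape)
    mixed = np.clip(mixed, 0.0, None).reshape(H, W, 8)

    roles = {
        "dapi": 0,
        "af": 1,
        "tumor": 2,
        "vessel": 3,
        "marker_pv": 4,
        "marker_diffuse": 5,
        "marker_bulk": 6,
        "marker_ubiquitous": 7,
    }
    return MultiplexImage(mixed, roles), truth
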