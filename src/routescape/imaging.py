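"""Spatial compartment analysis of multiplex immunofluorescence slides.

The computation chain mirrors how xenograft slides are quantified: each
pixel of an 8-channel scan is a point in channel space (DAPI, autofluorescence,
a tumor marker such as STEM121/NCL, an endothelial marker such as CD31, and up
to four proteins of interest).  The stages are

1. ``correct_channels`` — per-channel L2-regularized regression on the other
   channels to remove shared variation (bleed-through, broad background),
2. ``segment_base`` — k-means over the four common channels; the centroid
   maximal in the tumor channel yields the tumor mask T and the centroid
   maximal in the vessel channel yields the vascular mask V,
3. ``label_compartments`` — density stratification of T (box filter) plus
   morphological filters (perivascular proximity, circle-shaped aggregates,
   elongated diffusely invading cells, an optional white-matter band) giving a
   per-pixel labeling matrix L over an 8- or 9-class schema,
4. ``compartment_scores`` — cellularity-corrected mean intensity of every
   protein in every compartment:

       score(i, j) = (1/|S_j|) * sum_{(x,y) in S_j} z_i(x,y) / z_DAPI(x,y)

5. ``compartment_areas`` / ``spatial_de`` / ``score_ko_shift`` — relative
   compartment areas, per-(protein, compartment) Welch tests between invasion
   route groups, and knockout-vs-control area shifts with 90% t-intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as cc_label, regionprops
from sklearn.cluster import KMeans

__all__ = [
    "MultiplexImage",
    "CompartmentParams",
    "LabelingMatrix",
    "ScoreMatrix",
    "SCHEMA_9",
    "SCHEMA_8",
    "correct_channels",
    "segment_base",
    "label_compartments",
    "compartment_scores",
    "compartment_areas",
    "spatial_de",
    "score_ko_shift",
]

#: 9-class compartment schema (white-matter band mask supplied).
SCHEMA_9 = (
    "high_density",
    "medium_density",
    "low_density",
    "aggregate",
    "perivascular",
    "corpus_callosum",
    "elongated",
    "vessel",
    "parenchyma",
)

#: 8-class schema: corpus-callosum cells merge into the elongated class.
SCHEMA_8 = tuple(c for c in SCHEMA_9 if c != "corpus_callosum")


@dataclass
class MultiplexImage:
    """An H x W x C stack of nonnegative intensities with channel roles.

    ``channel_roles`` maps role names to channel indices and must contain
    exactly one each of ``dapi``, ``af``, ``tumor``, ``vessel``; remaining
    channels are proteins of interest, named by the caller.
    """

    pixels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        for role in ("dapi", "af", "tumor", "vessel"):
            if role not in self.channel_roles:
                raise ValueError(f"missing required channel role {role!r}")
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel roles must map to distinct channels")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel(self, role: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_roles[role]]

    @property
    def protein_roles(self) -> list[str]:
        return [
            r for r in self.channel_roles
            if r not in ("dapi", "af", "tumor", "vessel")
        ]


@dataclass
class CompartmentParams:
    """Tunable parameters for compartment labeling.

    window
        Side of the uniform box filter used to measure local tumor density.
    density_thresholds
        (low/medium, medium/high) cut points.  In ``quantile`` mode they are
        quantiles of the filtered density over tumor pixels; in ``absolute``
        mode they are density values in [0, 1].
    d_pv
        Distance (pixels) from the vascular mask within which tumor pixels
        count as perivascular.
    c_min, aggregate_area
        Circularity floor (4*pi*A/P^2) and area range for circle-shaped
        aggregates.
    e_min, min_elongated_area
        Eccentricity floor and minimum component area for elongated,
        diffusely invading cells (detected within the low-density region).
    band_mask
        Optional boolean anatomical band (e.g. corpus callosum); when given,
        elongated components mostly inside the band get the dedicated
        white-matter class and the schema has 9 classes, otherwise 8.
    """

    window: int = 31
    density_thresholds: tuple[float, float] = (0.5, 0.85)
    density_mode: str = "quantile"
    d_pv: float = 10.0
    c_min: float = 0.8
    aggregate_area: tuple[int, int] = (100, 2000)
    e_min: float = 0.9
    min_elongated_area: int = 15
    band_mask: np.ndarray | None = None

    @property
    def schema(self) -> tuple[str, ...]:
        return SCHEMA_9 if self.band_mask is not None else SCHEMA_8


@dataclass
class LabelingMatrix:
    """Per-pixel compartment classes plus the base masks they derive from."""

    labels: np.ndarray  # H x W integer index into schema
    schema: tuple[str, ...]
    tumor_mask: np.ndarray
    vessel_mask: np.ndarray

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == self.schema.index(name)

    def class_fractions(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.schema))
        return pd.Series(counts / self.labels.size, index=list(self.schema))


@dataclass
class ScoreMatrix:
    """Cellularity-normalized protein-by-compartment scores."""

    scores: pd.DataFrame  # proteins x classes, NaN where the class is empty
    pixel_counts: pd.Series


def correct_channels(
    img: MultiplexImage, penalty: float, unpenalized: tuple[str, ...] = ("dapi", "af")
) -> MultiplexImage:
    """Remove shared variation between channels by ridge regression.

    Each channel is replaced by its residual after (no-intercept) regression
    on the remaining channels, with pixels as observations.  The L2 penalty is
    0 for the DAPI and autofluorescence channels and ``penalty`` for all
    others; it is scaled by the pixel count so its strength is independent of
    image size.  Residuals are clipped at zero.  As penalty -> inf the
    correction vanishes and the raw channel is returned.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    if img.n_channels < 2:
        raise ValueError("need at least two channels to correct")
    flat = img.pixels.reshape(-1, img.n_channels)
    n = flat.shape[0]
    role_of = {v: k for k, v in img.channel_roles.items()}
    out = np.empty_like(flat)
    for c in range(img.n_channels):
        y = flat[:, c]
        if np.ptp(y) == 0:
            warnings.warn(f"channel {c} is constant; returned unchanged")
            out[:, c] = y
            continue
        X = np.delete(flat, c, axis=1)
        lam = 0.0 if role_of.get(c) in unpenalized else penalty
        gram = X.T @ X / n + lam * np.eye(X.shape[1])
        rhs = X.T @ y / n
        try:
            beta = np.linalg.solve(gram, rhs)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(gram) @ rhs
        out[:, c] = np.clip(y - X @ beta, 0.0, None)
    return MultiplexImage(
        out.reshape(img.pixels.shape), dict(img.channel_roles), img.pixel_size
    )


def segment_base(
    img: MultiplexImage, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """k-means segmentation of the four common channels into masks T and V.

    Pixels are clustered in (DAPI, AF, tumor, vessel) space; the cluster whose
    centroid is maximal in the tumor channel becomes the tumor mask T, the one
    maximal in the vessel channel becomes the vascular mask V.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    feats = np.stack(
        [img.channel(r).ravel() for r in ("dapi", "af", "tumor", "vessel")], axis=1
    )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
    ctr = km.cluster_centers_
    t_idx = int(np.argmax(ctr[:, 2]))
    v_idx = int(np.argmax(ctr[:, 3]))
    if t_idx == v_idx:
        raise ValueError("tumor and vessel centroids coincide; segmentation failed")
    # k-means may split a homogeneous population across near-duplicate
    # centroids; absorb clusters clearly dominated by the tumor (resp.
    # vessel) signal into the corresponding mask
    t_set, v_set = {t_idx}, {v_idx}
    for i in range(k):
        if i in (t_idx, v_idx):
            continue
        rel_t = ctr[i, 2] / ctr[t_idx, 2] if ctr[t_idx, 2] > 0 else 0.0
        rel_v = ctr[i, 3] / ctr[v_idx, 3] if ctr[v_idx, 3] > 0 else 0.0
        if max(rel_t, rel_v) >= 0.5:
            (t_set if rel_t >= rel_v else v_set).add(i)
    shape = img.pixels.shape[:2]
    labels = km.labels_.reshape(shape)
    return np.isin(labels, list(t_set)), np.isin(labels, list(v_set))


def _density(tumor_mask: np.ndarray, window: int) -> np.ndarray:
    if window > min(tumor_mask.shape):
        raise ValueError("box-filter window larger than image")
    return ndimage.uniform_filter(tumor_mask.astype(float), size=window)


def label_compartments(
    masks: tuple[np.ndarray, np.ndarray],
    params: CompartmentParams | None = None,
) -> LabelingMatrix:
    """Assign every pixel a compartment class from the masks T and V.

    Rules, in increasing precedence: density stratification of T (box filter
    + two thresholds); elongated components carved out of the low-density
    region (white-matter band class when a band mask is supplied); circle
    aggregates; perivascular tumor (T within ``d_pv`` of V); vessels.
    Remaining pixels are parenchyma.
    """
    params = params or CompartmentParams()
    T, V = (np.asarray(m, dtype=bool) for m in masks)
    if T.shape != V.shape:
        raise ValueError("mask shapes differ")
    schema = params.schema
    cls = {name: schema.index(name) for name in schema}
    labels = np.full(T.shape, cls["parenchyma"], dtype=np.int8)

    # tumor pixels excluding vessels (T ∩ V resolves to vessel below)
    Tonly = T & ~V
    dens = _density(Tonly, params.window)
    t_lo, t_hi = params.density_thresholds
    if params.density_mode == "quantile":
        if Tonly.any():
            vals = dens[Tonly]
            t_lo, t_hi = np.quantile(vals, [t_lo, t_hi])
    elif params.density_mode != "absolute":
        raise ValueError("density_mode must be 'quantile' or 'absolute'")
    labels[Tonly] = cls["low_density"]
    labels[Tonly & (dens >= t_lo)] = cls["medium_density"]
    labels[Tonly & (dens >= t_hi)] = cls["high_density"]

    # elongated diffuse cells, detected within the low-density region
    low = labels == cls["low_density"]
    comp = cc_label(low, connectivity=2)
    for rp in regionprops(comp):
        if rp.area < params.min_elongated_area or rp.eccentricity < params.e_min:
            continue
        px = comp == rp.label
        if params.band_mask is not None and (
            params.band_mask[px].mean() > 0.5
        ):
            labels[px] = cls["corpus_callosum"]
        else:
            labels[px] = cls["elongated"]

    # circle-shaped aggregates over whole-T connected components
    comp = cc_label(Tonly, connectivity=2)
    lo_a, hi_a = params.aggregate_area
    for rp in regionprops(comp):
        if not (lo_a <= rp.area <= hi_a):
            continue
        perim = rp.perimeter
        if perim == 0:
            continue
        circularity = 4.0 * np.pi * rp.area / perim**2
        if circularity >= params.c_min:
            labels[comp == rp.label] = cls["aggregate"]

    # perivascular: tumor pixels within d_pv of the vascular mask
    if V.any():
        dist = ndimage.distance_transform_edt(~V)
        labels[Tonly & (dist <= params.d_pv)] = cls["perivascular"]
    labels[V] = cls["vessel"]
    return LabelingMatrix(labels, schema, T, V)


def compartment_scores(
    img: MultiplexImage,
    L: LabelingMatrix,
    eps: float = 1.0,
    channels: list[str] | None = None,
) -> ScoreMatrix:
    """Cellularity-corrected mean intensity of each protein per compartment.

    Implements score(i,j) = mean over pixels of class j of z_i / z_DAPI, with
    z_DAPI floored at ``eps`` so empty-DAPI pixels do not blow up the ratio.
    Classes with no pixels get NaN.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if L.labels.shape != img.pixels.shape[:2]:
        raise ValueError("labeling and image shapes differ")
    channels = channels if channels is not None else img.protein_roles
    dapi = np.maximum(img.channel("dapi"), eps)
    n_cls = len(L.schema)
    counts = np.bincount(L.labels.ravel(), minlength=n_cls).astype(int)
    rows = {}
    for ch in channels:
        ratio = (img.channel(ch) / dapi).ravel()
        sums = np.bincount(L.labels.ravel(), weights=ratio, minlength=n_cls)
        with np.errstate(invalid="ignore"):
            rows[ch] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=list(L.schema))
    return ScoreMatrix(scores, pd.Series(counts, index=list(L.schema)))


def compartment_areas(L: LabelingMatrix) -> pd.Series:
    """Relative area (pixel fraction) of every compartment; sums to 1."""
    return L.class_fractions()


def spatial_de(
    scores: dict[str, ScoreMatrix], groups: dict[str, str]
) -> pd.DataFrame:
    """Per-(protein, compartment) Welch t-test between two slide groups.

    ``scores`` maps slide id -> ScoreMatrix, ``groups`` maps slide id to one
    of exactly two group labels (e.g. perivascular vs diffuse route).  The
    two-sided heteroscedastic t-test is applied per cell with no multiplicity
    adjustment; output includes -log10 p for volcano plotting.  Cells where a
    group has fewer than two finite values get NaN statistics with a warning.
    """
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise ValueError("spatial_de requires exactly two groups")
    by_level = {
        lev: [scores[s] for s in scores if groups[s] == lev] for lev in levels
    }
    for lev, mats in by_level.items():
        if len(mats) < 2:
            warnings.warn(f"group {lev!r} has fewer than 2 slides")
    any_mat = next(iter(scores.values()))
    records = []
    for protein in any_mat.scores.index:
        for comp in any_mat.scores.columns:
            samp = {}
            for lev in levels:
                vals = np.array(
                    [m.scores.loc[protein, comp] for m in by_level[lev]], dtype=float
                )
                samp[lev] = vals[np.isfinite(vals)]
            a, b = samp[levels[0]], samp[levels[1]]
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                diff = a.mean() - b.mean()
            else:
                t, p, diff = np.nan, np.nan, np.nan
            records.append(
                {
                    "protein": protein,
                    "compartment": comp,
                    "mean_diff": diff,
                    "t": t,
                    "p": p,
                    "neg_log10_p": -np.log10(p) if np.isfinite(p) and p > 0 else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)


def score_ko_shift(
    areas_ko: pd.DataFrame, areas_ctrl: pd.DataFrame, conf: float = 0.90
) -> pd.DataFrame:
    """Per-compartment area change (KO minus control) across mouse replicates.

    Inputs are replicate-by-compartment tables of relative areas.  Returns the
    mean difference with a two-sided t confidence interval at level ``conf``
    (default 90%, Welch degrees of freedom).
    """
    comps = [c for c in areas_ko.columns if c in areas_ctrl.columns]
    out = []
    for comp in comps:
        a = areas_ko[comp].to_numpy(dtype=float)
        b = areas_ctrl[comp].to_numpy(dtype=float)
        n1, n2 = len(a), len(b)
        if n1 < 2 or n2 < 2:
            raise ValueError("need at least two replicates per arm")
        diff = a.mean() - b.mean()
        se2 = a.var(ddof=1) / n1 + b.var(ddof=1) / n2
        se = np.sqrt(se2)
        if se == 0:
            lo = hi = diff
        else:
            df = se2**2 / (
                (a.var(ddof=1) / n1) ** 2 / (n1 - 1)
                + (b.var(ddof=1) / n2) ** 2 / (n2 - 1)
            )
            tcrit = stats.t.ppf(0.5 + conf / 2, df)
            lo, hi = diff - tcrit * se, diff + tcrit * se
        out.append(
            {"compartment": comp, "mean_diff": diff, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame.from_records(out)
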