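"""Time-lapse single-cell tracking and vessel-association quantification.

Blob detection on the tumor channel of each frame, frame-to-frame linking
with a constant-velocity Kalman filter and optimal (Hungarian) gated
assignment, per-track mean speeds, classification of cells as
vessel-associated via a morphologically dilated endothelial mask, and a
within-replicate bootstrap for proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import blob_log

__all__ = [
    "TrackSet",
    "detect_blobs",
    "link_tracks",
    "track_speeds",
    "vessel_association",
    "bootstrap_proportion",
]


@dataclass
class TrackSet:
    """Tracks as a long table (track_id, frame, x, y) plus scan metadata."""

    table: pd.DataFrame
    dt: float = 1.0  # hours per frame
    pixel_size: float = 1.0  # microns per pixel

    def positions(self, track_id: int) -> np.ndarray:
        sub = self.table[self.table["track_id"] == track_id].sort_values("frame")
        return sub[["frame", "x", "y"]].to_numpy()

    @property
    def track_ids(self) -> np.ndarray:
        return np.unique(self.table["track_id"])


def detect_blobs(
    frame: np.ndarray,
    min_sigma: float = 2.0,
    max_sigma: float = 6.0,
    threshold: float = 0.1,
) -> np.ndarray:
    """Laplacian-of-Gaussian blob detection; returns (n, 3) rows (x, y, r)."""
    blobs = blob_log(
        np.asarray(frame, dtype=float),
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        threshold=threshold,
    )
    if blobs.size == 0:
        return np.empty((0, 3))
    # blob_log returns (row, col, sigma); convert to (x, y, radius)
    return np.column_stack([blobs[:, 1], blobs[:, 0], blobs[:, 2] * np.sqrt(2)])


class _KalmanTrack:
    """Constant-velocity Kalman filter over state (x, y, vx, vy)."""

    _F = np.array(
        [[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float
    )
    _H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)

    def __init__(self, track_id, frame, xy, process_noise, meas_noise):
        self.id = track_id
        self.state = np.array([xy[0], xy[1], 0.0, 0.0])
        self.P = np.diag([meas_noise, meas_noise, 25.0, 25.0])
        self.Q = process_noise * np.diag([0.25, 0.25, 1.0, 1.0])
        self.R = meas_noise * np.eye(2)
        self.last_frame = frame
        self.missed = 0
        self.history: list[tuple[int, float, float]] = [(frame, xy[0], xy[1])]

    def predict(self) -> np.ndarray:
        self.state = self._F @ self.state
        self.P = self._F @ self.P @ self._F.T + self.Q
        return self.state[:2]

    def update(self, frame: int, xy: np.ndarray) -> None:
        z = np.asarray(xy, dtype=float)
        S = self._H @ self.P @ self._H.T + self.R
        K = self.P @ self._H.T @ np.linalg.inv(S)
        self.state = self.state + K @ (z - self._H @ self.state)
        self.P = (np.eye(4) - K @ self._H) @ self.P
        self.last_frame = frame
        self.missed = 0
        self.history.append((frame, float(z[0]), float(z[1])))


def link_tracks(
    detections: list[np.ndarray],
    process_noise: float = 0.01,
    meas_noise: float = 1.0,
    gate_radius: float = 15.0,
    max_gap: int = 0,
    dt: float = 1.0,
    pixel_size: float = 1.0,
) -> TrackSet:
    """Link per-frame detections into tracks.

    ``detections[t]`` is an (n_t, >=2) array of (x, y[, ...]) for frame t.
    Each live track is propagated by the constant-velocity Kalman prediction;
    detections are assigned to predictions by minimum-total-distance bipartite
    matching, gated at ``gate_radius``.  Unmatched detections seed new tracks;
    tracks unmatched for more than ``max_gap`` consecutive frames terminate.
    Stored positions are the measured (not filtered) coordinates.
    """
    live: list[_KalmanTrack] = []
    done: list[_KalmanTrack] = []
    next_id = 0
    for frame, det in enumerate(detections):
        det = np.asarray(det, dtype=float).reshape(-1, det.shape[1] if np.ndim(det) == 2 else 2)
        pts = det[:, :2] if det.size else np.empty((0, 2))
        preds = np.array([t.predict() for t in live]).reshape(-1, 2)
        assigned_det = set()
        matched_tracks = set()
        if len(live) and len(pts):
            cost = np.linalg.norm(preds[:, None, :] - pts[None, :, :], axis=2)
            big = 1e6
            gated = np.where(cost <= gate_radius, cost, big)
            rows, cols = linear_sum_assignment(gated)
            for r, c in zip(rows, cols):
                if gated[r, c] >= big:
                    continue
                live[r].update(frame, pts[c])
                assigned_det.add(c)
                matched_tracks.add(r)
        still_live = []
        for i, t in enumerate(live):
            if i in matched_tracks:
                still_live.append(t)
            else:
                t.missed += 1
                if t.missed > max_gap:
                    done.append(t)
                else:
                    still_live.append(t)
        live = still_live
        for c in range(len(pts)):
            if c not in assigned_det:
                live.append(
                    _KalmanTrack(next_id, frame, pts[c], process_noise, meas_noise)
                )
                next_id += 1
    done.extend(live)
    rows = [
        {"track_id": t.id, "frame": f, "x": x, "y": y}
        for t in done
        for (f, x, y) in t.history
    ]
    table = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    if len(table):
        table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackSet(table, dt=dt, pixel_size=pixel_size)


def track_speeds(tracks: TrackSet) -> pd.Series:
    """Mean speed (microns/hour) per track over its whole lifetime.

    Average of consecutive-detection displacements converted by pixel size
    and frame interval (gaps contribute displacement / elapsed time).
    Single-detection tracks get NaN.
    """
    speeds = {}
    for tid, sub in tracks.table.groupby("track_id"):
        sub = sub.sort_values("frame")
        if len(sub) < 2:
            speeds[tid] = np.nan
            continue
        d = np.hypot(np.diff(sub["x"]), np.diff(sub["y"]))
        dt_frames = np.diff(sub["frame"])
        speeds[tid] = float(
            np.mean(d * tracks.pixel_size / (dt_frames * tracks.dt))
        )
    return pd.Series(speeds, name="speed_um_per_h")


def vessel_association(
    positions: np.ndarray,
    vessel_mask: np.ndarray,
    dilation_radius: int = 5,
) -> tuple[np.ndarray, float]:
    """Classify cells as vessel-associated via a dilated endothelial mask.

    A cell is associated iff its (x, y) center falls inside the vessel mask
    dilated by ``dilation_radius``.  Returns (boolean classes, proportion).
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if dilation_radius > 0 and mask.any():
        yy, xx = np.ogrid[-dilation_radius : dilation_radius + 1, -dilation_radius : dilation_radius + 1]
        selem = xx**2 + yy**2 <= dilation_radius**2
        mask = ndimage.binary_dilation(mask, structure=selem)
    pos = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(pos) == 0:
        return np.zeros(0, dtype=bool), 0.0
    cols = np.clip(np.round(pos[:, 0]).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(pos[:, 1]).astype(int), 0, mask.shape[0] - 1)
    assoc = mask[rows, cols]
    return assoc, float(assoc.mean())


def bootstrap_proportion(
    classes_by_replicate: dict[str, np.ndarray],
    B: int = 2000,
    seed: int = 0,
    other: dict[str, np.ndarray] | None = None,
    conf: float = 0.95,
) -> dict:
    """Bootstrap a proportion by resampling cells within replicates.

    Each bootstrap replicate resamples every replicate's cells with
    replacement and averages the per-replicate proportions.  Returns the mean
    proportion, a percentile confidence interval, and — when a second group is
    supplied via ``other`` — a two-sided bootstrap p-value for the difference
    in proportions (sign-flip of the centered difference distribution).
    """
    rng = np.random.default_rng(seed)

    def draw(groups: dict[str, np.ndarray]) -> np.ndarray:
        reps = [np.asarray(v, dtype=float) for v in groups.values()]
        out = np.empty(B)
        for b in range(B):
            out[b] = np.mean([r[rng.integers(0, len(r), len(r))].mean() for r in reps])
        return out

    boot = draw(classes_by_replicate)
    point = float(
        np.mean([np.asarray(v, dtype=float).mean() for v in classes_by_replicate.values()])
    )
    alpha = 1 - conf
    ci = (
        float(np.quantile(boot, alpha / 2)),
        float(np.quantile(boot, 1 - alpha / 2)),
    )
    result = {"proportion": point, "ci": ci, "boot": boot}
    if other is not None:
        boot2 = draw(other)
        point2 = float(
            np.mean([np.asarray(v, dtype=float).mean() for v in other.values()])
        )
        diff = boot - boot2
        observed = point - point2
        centered = diff - diff.mean()
        p = (np.sum(np.abs(centered) >= abs(observed)) + 1) / (B + 1)
        result.update(
            {"proportion_other": point2, "difference": observed, "p": float(p)}
        )
    return result
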