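"""Synthetic time-lapse movies of migrating cells over a vessel network.

Particles move with constant velocity (optional positional jitter); a stated
fraction is constrained to move along a dilated vessel mask, emulating
perivascular migration in slice or co-culture assays.  Frames render each
particle as a Gaussian spot; detections can be dropped at random to exercise
gap bridging in the linker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ..tracking import TrackSet

__all__ = ["MotionSpec", "gen_tracks_movie"]


@dataclass
class MotionSpec:
    n_particles: int = 20
    frames: int = 50
    height: int = 256
    width: int = 256
    dt: float = 0.5  # hours per frame
    pixel_size: float = 2.0  # microns per pixel
    speed_range: tuple[float, float] = (5.0, 18.0)  # microns per hour
    vessel_fraction: float = 0.0
    detection_dropout: float = 0.0
    jitter_sd: float = 0.0  # pixels
    spot_sigma: float = 3.0
    spot_amplitude: float = 1.0
    dilation_radius: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames < 2:
            raise ValueError("need at least two frames")
        if min(self.speed_range) < 0:
            raise ValueError("speeds must be nonnegative")
        if not 0 <= self.vessel_fraction <= 1 or not 0 <= self.detection_dropout < 1:
            raise ValueError("fractions must lie in [0, 1]")


def _vessel_mask(spec: MotionSpec, rng: np.random.Generator) -> np.ndarray:
    """A few horizontal-ish vessel strands across the frame."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for k in range(3):
        y = (k + 1) * spec.height / 4 + rng.uniform(-8, 8)
        x = np.arange(spec.width)
        yy = y + 10 * np.sin(2 * np.pi * (x / spec.width) + rng.uniform(0, 2 * np.pi))
        mask[np.clip(np.round(yy).astype(int), 0, spec.height - 1), x] = True
    return ndimage.binary_dilation(mask, iterations=2)


def gen_tracks_movie(
    spec: MotionSpec,
) -> tuple[np.ndarray, np.ndarray, TrackSet, list[np.ndarray]]:
    """Generate (frame stack, vessel mask, ground-truth TrackSet, detections).

    The returned detections list gives, per frame, the exact (x, y, truth id)
    rows after dropout — the linker input for noiseless recovery tests.  The
    frame stack renders Gaussian spots at those positions for detector tests.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _vessel_mask(spec, rng)
    H, W = spec.height, spec.width
    dil = ndimage.binary_dilation(
        mask, iterations=spec.dilation_radius
    ) if spec.dilation_radius else mask
    ys, xs = np.nonzero(dil)

    speed_px = (
        rng.uniform(*spec.speed_range, spec.n_particles) * spec.dt / spec.pixel_size
    )
    travel = speed_px * (spec.frames - 1)
    if travel.max() > min(H, W) - 12:
        raise ValueError("speed x duration exceeds the frame; enlarge the image")
    n_vessel = int(round(spec.vessel_fraction * spec.n_particles))
    rows = []
    for i in range(spec.n_particles):
        on_vessel = i < n_vessel
        if on_vessel:
            j = rng.integers(len(ys))
            y0, x0 = float(ys[j]), float(xs[j])
            theta = 0.0 if x0 < W / 2 else np.pi  # move along the strand
        else:
            # rejection-sample a start and heading whose straight path stays
            # inside the frame and (best effort) clear of the dilated vessel
            # mask, so planted association fractions are unambiguous
            best = None
            for _try in range(800):
                y0 = rng.uniform(6, H - 7)
                x0 = rng.uniform(6, W - 7)
                theta = rng.uniform(0, 2 * np.pi)
                xe = x0 + travel[i] * np.cos(theta)
                ye = y0 + travel[i] * np.sin(theta)
                if not (5 <= xe <= W - 6 and 5 <= ye <= H - 6):
                    continue
                best = best or (y0, x0, theta)
                fs = np.arange(spec.frames)
                px = np.round(x0 + speed_px[i] * np.cos(theta) * fs).astype(int)
                py = np.round(y0 + speed_px[i] * np.sin(theta) * fs).astype(int)
                if not dil[np.clip(py, 0, H - 1), np.clip(px, 0, W - 1)].any():
                    best = (y0, x0, theta)
                    break
            if best is None:
                raise RuntimeError("could not place a particle inside the frame")
            y0, x0, theta = best
        vx, vy = speed_px[i] * np.cos(theta), speed_px[i] * np.sin(theta)
        for f in range(spec.frames):
            x = x0 + vx * f + (rng.normal(0, spec.jitter_sd) if spec.jitter_sd else 0.0)
            y = y0 + vy * f + (rng.normal(0, spec.jitter_sd) if spec.jitter_sd else 0.0)
            if on_vessel:
                # hold vessel-bound cells onto the dilated mask by clamping y
                yi = int(np.clip(round(y), 0, H - 1))
                xi = int(np.clip(round(x), 0, W - 1))
                if not dil[yi, xi]:
                    near = np.nonzero(dil[:, xi])[0]
                    if len(near):
                        y = float(near[np.argmin(np.abs(near - yi))])
            if on_vessel or spec.jitter_sd:
                x = float(np.clip(x, 0, W - 1))
                y = float(np.clip(y, 0, H - 1))
            rows.append(
                {
                    "track_id": i,
                    "frame": f,
                    "x": x,
                    "y": y,
                    "vessel_bound": on_vessel,
                }
            )
    truth = pd.DataFrame(rows)

    detections: list[np.ndarray] = []
    for f in range(spec.frames):
        sub = truth[truth["frame"] == f]
        keep = rng.random(len(sub)) >= spec.detection_dropout
        detections.append(sub.loc[keep, ["x", "y", "track_id"]].to_numpy())

    stack = np.zeros((spec.frames, H, W))
    r = int(np.ceil(4 * spec.spot_sigma))
    for f, det in enumerate(detections):
        img = stack[f]
        for x, y, _tid in det:
            r0, r1 = max(0, int(y) - r), min(H, int(y) + r + 1)
            c0, c1 = max(0, int(x) - r), min(W, int(x) + r + 1)
            yy = np.arange(r0, r1)[:, None]
            xx = np.arange(c0, c1)[None, :]
            img[r0:r1, c0:c1] += spec.spot_amplitude * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2 * spec.spot_sigma**2)
            )

    ts = TrackSet(
        truth[["track_id", "frame", "x", "y", "vessel_bound"]].copy(),
        dt=spec.dt,
        pixel_size=spec.pixel_size,
    )
    return stack, mask, ts, detections
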