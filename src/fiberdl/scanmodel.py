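"""Spiral-scan geometry: frame-rate arithmetic and radial down-sampling.

A resonant fiber scanner traces an open-close spiral pattern.  Two knobs set
the frame rate: the *scanning speed* (spirals traced per second, fixed by the
scanner resonance) and the *scanning density* (spirals per frame, i.e. the
radial sampling density).  Only the open phase of the pattern acquires data,
so

    frame_rate = duty_ratio * scanning_speed / scanning_density.

Reducing the radial density by an integer factor M multiplies the frame rate
by M at the cost of unsampled rings; :func:`radial_downsample` emulates that
acquisition digitally on a full-density Cartesian frame by keeping every M-th
concentric ring and filling the rest according to a regridding policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanConfig",
    "RingMap",
    "frame_rate",
    "build_ring_map",
    "radial_downsample",
    "FILL_POLICIES",
]

FILL_POLICIES = ("nearest_ring", "zero", "linear_radial")


@dataclass(frozen=True)
class ScanConfig:
    """Acquisition parameters of one spiral-scan imaging run.

    Parameters
    ----------
    scanning_speed : float
        Spirals traced per second (the scanner's resonant rate).
    scanning_density : int
        Spirals per frame at full density (radial sampling density).
    duty_ratio : float
        Fraction of the scan cycle spent acquiring (open phase of the
        open-close spiral), in (0, 1].  Typical hardware runs at 0.5-0.8.
    M : int
        Radial down-sampling factor; the effective density per frame is
        ``ceil(scanning_density / M)``.
    """

    scanning_speed: float
    scanning_density: int
    duty_ratio: float = 0.5
    M: int = 1

    def __post_init__(self) -> None:
        if self.scanning_speed <= 0:
            raise ValueError("scanning_speed must be positive")
        if self.scanning_density < 1:
            raise ValueError("scanning_density must be >= 1")
        if not (0.0 < self.duty_ratio <= 1.0):
            raise ValueError("duty_ratio must lie in (0, 1]")
        if self.M < 1:
            raise ValueError("down-sampling factor M must be a positive integer")

    @property
    def effective_density(self) -> int:
        """Spirals per frame actually acquired after down-sampling by M."""
        return math.ceil(self.scanning_density / self.M)


def frame_rate(cfg: ScanConfig) -> float:
    """Imaging frame rate in frames/second.

    ``duty_ratio * scanning_speed / effective_density`` — at full density
    (M=1) a 3360 spirals/s scanner with 512 spirals/frame and 50% duty yields
    ~3.3 fps; keeping every 8th spiral (64 spirals/frame) yields ~26 fps.
    """
    eff = cfg.effective_density
    if eff <= 0:
        raise ValueError("effective scanning density must be positive")
    return cfg.duty_ratio * cfg.scanning_speed / eff


@dataclass(frozen=True)
class RingMap:
    """Concentric-ring labelling of a square frame.

    ``ring_index[i, j]`` is the spiral (ring) to which pixel (i, j) belongs:
    the floor of its Euclidean distance from the frame center divided by the
    uniform ring width ``R_max / n_rings``, where R_max is the corner radius.
    Ring 0 contains the center; indices increase monotonically outward.
    """

    ring_index: np.ndarray
    n_rings: int
    center: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        if self.ring_index.ndim != 2:
            raise ValueError("ring_index must be a 2-D label image")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ring_index.shape  # type: ignore[return-value]


def build_ring_map(image_size: int, scanning_density: int) -> RingMap:
    """Label every pixel of an ``image_size``-square frame with its ring.

    The frame center sits at ((H-1)/2, (W-1)/2); the outermost ring reaches
    the corner radius, so exactly ``scanning_density`` ring labels tile the
    frame.  Densities finer than one pixel per ring are rejected.
    """
    if image_size < 2:
        raise ValueError("image_size must be >= 2")
    cy = cx = (image_size - 1) / 2.0
    corner_radius = math.hypot(cy, cx)
    if scanning_density < 1:
        raise ValueError("scanning_density must be >= 1")
    if scanning_density > corner_radius:
        raise ValueError(
            f"scanning_density {scanning_density} exceeds the corner radius "
            f"{corner_radius:.1f} px: rings would be thinner than one pixel"
        )
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - cy, xx - cx)
    dr = corner_radius / scanning_density
    idx = np.minimum((r / dr).astype(np.int64), scanning_density - 1)
    return RingMap(ring_index=idx, n_rings=scanning_density, center=(cy, cx))


def _ring_width(rings: RingMap) -> float:
    cy, cx = rings.center
    return math.hypot(cy, cx) / rings.n_rings


def radial_downsample(
    frame: np.ndarray,
    rings: RingMap,
    M: int,
    fill: str = "nearest_ring",
) -> np.ndarray:
    """Emulate acquisition at a scanning density reduced by the factor M.

    Pixels on kept rings (index ≡ 0 mod M) pass through bit-identically; the
    remaining pixels are regridded per ``fill``:

    - ``nearest_ring``: resample the input along the pixel's ray at the
      radius of the nearest kept ring (nearest-neighbour regridding, the
      default — outputs resemble a low-density reconstruction);
    - ``zero``: leave unsampled rings at zero (ring-striped frames);
    - ``linear_radial``: linear blend of the two bracketing kept rings along
      the ray.

    The kept-ring count is ``ceil(n_rings / M)``.
    """
    if frame.shape != rings.shape:
        raise ValueError(
            f"frame shape {frame.shape} does not match ring map {rings.shape}"
        )
    if M < 1:
        raise ValueError("M must be a positive integer")
    if fill not in FILL_POLICIES:
        raise ValueError(f"unknown fill policy {fill!r}; choose from {FILL_POLICIES}")
    if M == 1:
        return frame.copy()

    idx = rings.ring_index
    kept = (idx % M) == 0
    out = np.zeros_like(frame)
    out[kept] = frame[kept]
    if fill == "zero":
        return out

    cy, cx = rings.center
    H, W = frame.shape
    yy, xx = np.mgrid[0:H, 0:W]
    dy = yy - cy
    dx = xx - cx
    r = np.hypot(dy, dx)
    dr = _ring_width(rings)
    max_kept = ((rings.n_rings - 1) // M) * M

    def sample_at_ring(ring: np.ndarray) -> np.ndarray:
        # Sample the input (nearest pixel) where each pixel's ray crosses the
        # center radius of `ring`; the center pixel has no direction, keep it.
        target_r = (ring + 0.5) * dr
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(r > 0, target_r / np.maximum(r, 1e-12), 1.0)
        sy = np.clip(np.rint(cy + dy * s), 0, H - 1).astype(np.int64)
        sx = np.clip(np.rint(cx + dx * s), 0, W - 1).astype(np.int64)
        return frame[sy, sx]

    if fill == "nearest_ring":
        nearest = np.clip(np.rint(idx / M).astype(np.int64) * M, 0, max_kept)
        filled = sample_at_ring(nearest)
    else:  # linear_radial
        lo = (idx // M) * M
        hi = np.minimum(lo + M, max_kept)
        lo = np.minimum(lo, max_kept)
        w = np.where(hi > lo, (idx - lo) / np.maximum(hi - lo, 1), 0.0)
        v_lo = sample_at_ring(lo)
        v_hi = sample_at_ring(hi)
        blend = (1.0 - w) * v_lo + w * v_hi
        filled = blend.astype(frame.dtype) if np.issubdtype(
            frame.dtype, np.integer
        ) else blend

    out = np.where(kept, frame, filled)
    return out.astype(frame.dtype, copy=False)
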