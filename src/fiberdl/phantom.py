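"""Synthetic neuron phantoms: scenes, GCaMP-like activity, photon noise.

The generator emulates the content of two-photon fiberscopy recordings —
bright elliptical somas with thin curvilinear dendrites on a dim background —
together with calcium-indicator dynamics (Poisson spike trains convolved with
an exponential decay) and the photon-limited noise of a resonant scanner,
where the per-pixel dwell time, and hence the shot-noise level, is inversely
proportional to the scanning speed.  Every operation is a pure function of
its inputs and a seed, so any scene or movie regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "PhantomScene",
    "ActivityModel",
    "NoiseModel",
    "generate_scene",
    "simulate_activity",
    "apply_noise",
    "apply_noise_stack",
    "frame_average",
]

_MAX_PLACEMENT_ATTEMPTS = 2000


@dataclass(frozen=True)
class PhantomSpec:
    """Layout parameters of one synthetic neuron scene.

    All intensities are in 8-bit units; soma intensities must exceed the
    background level so ROI pixels are strictly brighter than background.
    """

    image_size: int = 128
    n_somas: int = 4
    soma_radius_range: tuple[float, float] = (4.0, 7.0)
    n_dendrites_per_soma: int = 2
    dendrite_width_range: tuple[float, float] = (1.0, 1.8)
    dendrite_length_range: tuple[float, float] = (15.0, 40.0)
    soma_intensity_range: tuple[float, float] = (120.0, 200.0)
    background_level: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_somas < 0:
            raise ValueError("n_somas must be non-negative")
        for name in (
            "soma_radius_range",
            "dendrite_width_range",
            "dendrite_length_range",
            "soma_intensity_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high")
        if not (0 <= self.background_level <= 255):
            raise ValueError("background_level must be within [0, 255]")
        lo, hi = self.soma_intensity_range
        if not (0 <= lo <= hi <= 255):
            raise ValueError("soma_intensity_range must be within [0, 255]")
        if lo <= self.background_level:
            raise ValueError(
                "soma intensities must exceed background_level so ROI pixels "
                "are brighter than background"
            )


@dataclass(frozen=True)
class PhantomScene:
    """A rendered noise-free scene with its ground-truth geometry.

    ``structure_map`` is the fluorophore-density image (background plus
    structures); ``roi_masks`` are the pairwise-disjoint soma masks;
    ``background_mask`` marks structure-free pixels; ``neuron_maps`` holds
    each neuron's own additive contribution (soma plus its dendrites), used
    to modulate brightness during activity simulation.
    """

    structure_map: np.ndarray
    roi_masks: list[np.ndarray]
    background_mask: np.ndarray
    neuron_maps: list[np.ndarray] = field(default_factory=list)
    background_level: float = 0.0


@dataclass(frozen=True)
class ActivityModel:
    """GCaMP-like transient statistics for an activity movie."""

    spike_rate: float = 0.05  # events / frame / neuron
    decay_tau: float = 8.0  # frames
    amplitude_range: tuple[float, float] = (0.5, 1.5)  # relative ΔF/F units
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        lo, hi = self.amplitude_range
        if lo > hi or lo < 0:
            raise ValueError("amplitude_range must satisfy 0 <= low <= high")


@dataclass(frozen=True)
class NoiseModel:
    """Photon-limited acquisition noise with dwell-time scaling.

    At the reference scanning speed each 8-bit intensity unit corresponds to
    ``photons_per_unit_at_ref_speed`` expected photons; at speed S the
    per-pixel dwell time, and so the photon yield, scales by ``ref_speed/S``.
    Gaussian read noise of ``read_noise_sigma`` 8-bit units is added after
    the shot-noise draw.
    """

    photons_per_unit_at_ref_speed: float = 4.0
    ref_speed: float = 1650.0  # spirals/sec
    read_noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_unit_at_ref_speed <= 0:
            raise ValueError("photon scale must be positive")
        if self.ref_speed <= 0:
            raise ValueError("ref_speed must be positive")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")

    def photons_per_unit(self, speed: float) -> float:
        """Effective photon yield per intensity unit at scanning speed S."""
        if speed <= 0:
            raise ValueError("scanning speed must be positive")
        return self.photons_per_unit_at_ref_speed * self.ref_speed / speed


def _render_soma(
    canvas: np.ndarray, cy: float, cx: float, ry: float, rx: float, theta: float
) -> np.ndarray:
    H, W = canvas.shape
    yy, xx = np.mgrid[0:H, 0:W]
    dy = yy - cy
    dx = xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _render_dendrite(
    shape: tuple[int, int],
    start: tuple[float, float],
    heading: float,
    length: float,
    width: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-profile tube along a smoothed random-walk polyline."""
    H, W = shape
    acc = np.zeros(shape, dtype=np.float64)
    y, x = start
    step = 1.0
    n_steps = int(length / step)
    yy, xx = np.mgrid[0:H, 0:W]
    sigma = width / 2.0
    rad = max(int(3 * sigma) + 1, 2)
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.25)
        y += step * np.sin(heading)
        x += step * np.cos(heading)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < H and 0 <= ix < W):
            break
        y0, y1 = max(iy - rad, 0), min(iy + rad + 1, H)
        x0, x1 = max(ix - rad, 0), min(ix + rad + 1, W)
        d2 = (yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2
        patch = np.exp(-d2 / (2.0 * sigma**2))
        np.maximum(acc[y0:y1, x0:x1], patch, out=acc[y0:y1, x0:x1])
    return acc


def generate_scene(spec: PhantomSpec) -> PhantomScene:
    """Render a scene of non-overlapping elliptical somas with dendrites.

    Somas are placed by rejection sampling (a bounded number of attempts;
    exceeding it raises an error naming the density constraint).  Each soma
    carries ``n_dendrites_per_soma`` curvilinear dendrites with a Gaussian
    cross-section at roughly half the soma brightness.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.image_size
    structure = np.full((N, N), spec.background_level, dtype=np.float64)
    occupied = np.zeros((N, N), dtype=bool)
    roi_masks: list[np.ndarray] = []
    neuron_maps: list[np.ndarray] = []

    margin = spec.soma_radius_range[1] + 2
    for _ in range(spec.n_somas):
        placed = False
        for _attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            cy = rng.uniform(margin, N - margin)
            cx = rng.uniform(margin, N - margin)
            ry = rng.uniform(*spec.soma_radius_range)
            rx = rng.uniform(*spec.soma_radius_range)
            theta = rng.uniform(0, np.pi)
            mask = _render_soma(structure, cy, cx, ry, rx, theta)
            # 2-px separation so ROI masks stay disjoint after rendering
            grown = ndimage.binary_dilation(mask, iterations=2)
            if not (grown & occupied).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {spec.n_somas} somas of radius "
                f"{spec.soma_radius_range} on a {N}x{N} frame without overlap: "
                "scene too dense"
            )
        intensity = rng.uniform(*spec.soma_intensity_range)
        contribution = np.zeros_like(structure)
        contribution[mask] = intensity - spec.background_level
        for _d in range(spec.n_dendrites_per_soma):
            heading = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(*spec.dendrite_length_range)
            width = rng.uniform(*spec.dendrite_width_range)
            r0 = max(ry, rx)
            start = (cy + r0 * np.sin(heading), cx + r0 * np.cos(heading))
            tube = _render_dendrite((N, N), start, heading, length, width, rng)
            dend = 0.5 * (intensity - spec.background_level) * tube
            dend[mask] = 0.0  # soma keeps its own flat intensity
            contribution = np.maximum(contribution, dend)
        occupied |= ndimage.binary_dilation(mask | (contribution > 1.0), iterations=1)
        roi_masks.append(mask)
        neuron_maps.append(contribution)
        structure = np.maximum(structure, spec.background_level + contribution)

    footprint = np.zeros((N, N), dtype=bool)
    for m in neuron_maps:
        footprint |= m > 0.5
    background_mask = ~footprint
    for m in roi_masks:
        background_mask &= ~m
    return PhantomScene(
        structure_map=structure,
        roi_masks=roi_masks,
        background_mask=background_mask,
        neuron_maps=neuron_maps,
        background_level=spec.background_level,
    )


def simulate_activity(
    scene: PhantomScene, model: ActivityModel
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free activity movie plus the exact per-neuron ΔF/F traces.

    Each neuron fires a Poisson spike train (``spike_rate`` events/frame);
    spikes with uniform amplitudes are convolved with a single-exponential
    kernel exp(-t/tau), and the resulting relative-fluorescence trace c(t)
    modulates that neuron's contribution multiplicatively: frame(t) =
    background + sum_n (1 + c_n(t)) * contribution_n.
    """
    rng = np.random.default_rng(model.seed)
    T = model.n_frames
    n = len(scene.neuron_maps)
    traces = np.zeros((n, T), dtype=np.float64)
    kernel = np.exp(-np.arange(T, dtype=np.float64) / model.decay_tau)
    for i in range(n):
        counts = rng.poisson(model.spike_rate, size=T)
        drive = np.zeros(T)
        for t in np.nonzero(counts)[0]:
            drive[t] = sum(
                rng.uniform(*model.amplitude_range) for _ in range(counts[t])
            )
        traces[i] = np.convolve(drive, kernel)[:T]
    movie = np.empty((T, *scene.structure_map.shape), dtype=np.float64)
    base = np.full_like(scene.structure_map, scene.background_level)
    for t in range(T):
        frame = base.copy()
        for i, contrib in enumerate(scene.neuron_maps):
            frame = np.maximum(frame, scene.background_level + (1.0 + traces[i, t]) * contrib)
        movie[t] = frame
    return movie, traces


def apply_noise(
    frame: np.ndarray,
    noise: NoiseModel,
    speed: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One noisy acquisition of a clean frame at scanning speed ``speed``.

    Intensities are scaled to expected photon counts via the dwell-time rule,
    Poisson-sampled, rescaled back to 8-bit units, perturbed with zero-mean
    Gaussian read noise, and clipped to [0, 255].
    """
    if speed <= 0:
        raise ValueError("scanning speed must be positive")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    frame = np.asarray(frame, dtype=np.float64)
    scale = noise.photons_per_unit(speed)
    photons = rng.poisson(np.clip(frame, 0, None) * scale)
    out = photons / scale
    if noise.read_noise_sigma > 0:
        out = out + rng.normal(0.0, noise.read_noise_sigma, size=frame.shape)
    return np.clip(out, 0.0, 255.0)


def apply_noise_stack(
    stack: np.ndarray,
    noise: NoiseModel,
    speed: float,
    seed: int | None = None,
) -> np.ndarray:
    """Apply :func:`apply_noise` frame-wise with a single seeded stream."""
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    return np.stack([apply_noise(f, noise, speed, rng=rng) for f in stack])


def frame_average(stack: np.ndarray, k: int, start: int = 0) -> np.ndarray:
    """Pixel-wise mean of ``k`` consecutive frames, at full float precision.

    Averaging k noisy acquisitions divides the per-pixel noise variance by k,
    which is how slow-scan ground-truth frames are produced.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (T, H, W)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if start < 0 or start + k > stack.shape[0]:
        raise IndexError(
            f"window [{start}, {start + k}) out of bounds for a stack of "
            f"{stack.shape[0]} frames"
        )
    return stack[start : start + k].astype(np.float64).mean(axis=0)
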