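"""Quantitative image- and trace-quality measures.

All definitions follow the conventions of the fiberscopy restoration
literature exactly as printed:

- SNR(dB) = 10 log10(P_signal / P_noise), soma mean over adjacent-background
  mean;
- per-neuron trace NRMSE = RMSE(F, F0) / (max F - min F), normalised by the
  *evaluated* trace's range;
- per-image NRMSE = RMSE(I, I0) / (max I - min I), normalised by the
  *evaluated* image's range (note the deliberate asymmetry: swapping the
  arguments changes the denominator);
- MS-SSIM with the canonical five-scale exponent weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RoiMask",
    "snr_db",
    "dff_trace",
    "nrmse_trace",
    "nrmse_image",
    "ms_ssim",
    "evaluate_sweep",
    "annulus_background",
    "MSSSIM_WEIGHTS",
]

#: Canonical per-scale exponent weights (5 dyadic scales).
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass(frozen=True)
class RoiMask:
    """One neuron soma mask paired with an adjacent background mask.

    ``mask`` selects the soma pixels; ``background_mask`` selects
    structure-free pixels next to the soma used as the noise reference.
    The two sets must be non-empty and disjoint.
    """

    mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        b = np.asarray(self.background_mask, dtype=bool)
        if m.shape != b.shape:
            raise ValueError("mask and background_mask must share geometry")
        if not m.any() or not b.any():
            raise ValueError("mask and background_mask must both be non-empty")
        if (m & b).any():
            raise ValueError("mask and background_mask must be disjoint")
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "background_mask", b)


def annulus_background(
    soma_mask: np.ndarray,
    exclude: np.ndarray | None = None,
    inner_gap: int = 2,
    width: int = 4,
) -> np.ndarray:
    """Morphological annulus around a soma, for use as its background mask.

    Dilates the soma by ``inner_gap`` (excluded buffer) and by
    ``inner_gap + width``; the difference, minus any pixels in ``exclude``
    (e.g. other structures), is the background ring.
    """
    soma = np.asarray(soma_mask, dtype=bool)
    inner = ndimage.binary_dilation(soma, iterations=inner_gap) if inner_gap else soma
    outer = ndimage.binary_dilation(soma, iterations=inner_gap + width)
    ring = outer & ~inner
    if exclude is not None:
        ring = ring & ~np.asarray(exclude, dtype=bool)
    return ring


def snr_db(frame: np.ndarray, roi: RoiMask) -> float:
    """Signal-to-noise ratio of one neuron in decibels.

    10 log10 of the mean intensity over the soma mask divided by the mean
    intensity over the adjacent background mask.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != roi.mask.shape:
        raise ValueError("frame geometry does not match the ROI masks")
    p_signal = frame[roi.mask].mean()
    p_noise = frame[roi.background_mask].mean()
    if p_noise <= 0:
        raise ValueError("mean background intensity is zero: SNR undefined")
    return float(10.0 * np.log10(p_signal / p_noise))


def dff_trace(
    stack: np.ndarray,
    roi: RoiMask,
    baseline_percentile: float = 10.0,
) -> np.ndarray:
    """Normalized ΔF/F time series of one neuron.

    Per frame, the soma-mean fluorescence minus the adjacent-background mean;
    the baseline F_b is a low percentile (default 10th) of that subtracted
    trace; ΔF/F = (F - F_b)/F_b is then divided by its maximum so the peak is
    exactly 1.  A trace with no positive excursion is returned as all zeros.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[1:] != roi.mask.shape:
        raise ValueError("stack must be (T, H, W) matching the ROI geometry")
    f = stack[:, roi.mask].mean(axis=1) - stack[:, roi.background_mask].mean(axis=1)
    f_b = np.percentile(f, baseline_percentile)
    if f_b <= 0:
        raise ValueError(
            f"baseline (percentile {baseline_percentile}) of the background-"
            "subtracted trace is non-positive; ΔF/F undefined"
        )
    dff = (f - f_b) / f_b
    peak = dff.max()
    if peak <= 0:
        return np.zeros_like(dff)
    return dff / peak


def nrmse_trace(F: np.ndarray, F0: np.ndarray) -> float:
    """Per-neuron trace NRMSE: RMSE / (max(F) - min(F)).

    ``F`` is the evaluated (e.g. network-output) normalized ΔF/F trace and
    ``F0`` the reference (raw-input) trace; the denominator is the range of
    ``F``, matching the printed definition.
    """
    F = np.asarray(F, dtype=np.float64)
    F0 = np.asarray(F0, dtype=np.float64)
    if F.shape != F0.shape or F.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    rng = F.max() - F.min()
    if rng <= 0:
        raise ValueError("evaluated trace is constant: NRMSE undefined")
    rmse = np.sqrt(np.mean((F - F0) ** 2))
    return float(rmse / rng)


def nrmse_image(I: np.ndarray, I0: np.ndarray) -> float:
    """Per-image NRMSE: RMSE / (max(I) - min(I)) over all m*n pixels.

    ``I`` is the evaluated (enhanced) image, ``I0`` the ground truth or
    reference; the denominator is the intensity range of ``I``.
    """
    I = np.asarray(I, dtype=np.float64)
    I0 = np.asarray(I0, dtype=np.float64)
    if I.shape != I0.shape or I.ndim != 2:
        raise ValueError("images must be 2-D and of identical dimensions")
    rng = I.max() - I.min()
    if rng <= 0:
        raise ValueError("evaluated image is constant: NRMSE undefined")
    rmse = np.sqrt(np.mean((I - I0) ** 2))
    return float(rmse / rng)


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_terms(
    x: np.ndarray,
    y: np.ndarray,
    data_range: float,
    win_size: int,
    sigma: float,
    k1: float,
    k2: float,
) -> tuple[float, float]:
    """Mean luminance*cs SSIM and mean contrast-structure term of one scale."""
    kernel = _gaussian_kernel(win_size, sigma)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    def filt(a: np.ndarray) -> np.ndarray:
        out = ndimage.correlate(a, kernel, mode="constant")
        # crop to the valid region so no padding enters the statistics
        h = win_size // 2
        return out[h:-h, h:-h]

    mu_x = filt(x)
    mu_y = filt(y)
    sxx = filt(x * x) - mu_x * mu_x
    syy = filt(y * y) - mu_y * mu_y
    sxy = filt(x * y) - mu_x * mu_y
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    cs = (2 * sxy + c2) / (sxx + syy + c2)
    return float((lum * cs).mean()), float(cs.mean())


def _downsample2(a: np.ndarray) -> np.ndarray:
    """2x2 average pooling (pad by edge replication if odd-sized)."""
    H, W = a.shape
    if H % 2 or W % 2:
        a = np.pad(a, ((0, H % 2), (0, W % 2)), mode="edge")
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def ms_ssim(
    I: np.ndarray,
    I0: np.ndarray,
    n_scales: int = 5,
    scale_weights: tuple[float, ...] | None = None,
    data_range: float = 255.0,
    win_size: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
) -> float:
    """Multi-scale structural similarity index in [0, 1].

    The contrast-structure term is evaluated at ``n_scales`` dyadic scales
    (2x average-pool between scales) and the luminance term only at the
    coarsest; the terms are combined with the exponent ``scale_weights``
    (canonical published five-scale weights by default).
    """
    x = np.asarray(I, dtype=np.float64)
    y = np.asarray(I0, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("images must be 2-D with identical dimensions")
    if scale_weights is None:
        if n_scales == len(MSSSIM_WEIGHTS):
            scale_weights = MSSSIM_WEIGHTS
        else:
            # truncated canonical weights, renormalized to unit sum
            w = np.asarray(MSSSIM_WEIGHTS[:n_scales], dtype=np.float64)
            scale_weights = tuple(w / w.sum())
    if len(scale_weights) != n_scales:
        raise ValueError("scale_weights length must equal n_scales")
    min_side = min(x.shape) // (2 ** (n_scales - 1))
    if min_side < win_size:
        raise ValueError(
            f"image too small for {n_scales} scales with a {win_size}-px "
            "window; reduce n_scales"
        )
    terms: list[float] = []
    for s in range(n_scales):
        ssim_mean, cs_mean = _ssim_terms(x, y, data_range, win_size, sigma, k1, k2)
        if s == n_scales - 1:
            terms.append(ssim_mean)
        else:
            terms.append(cs_mean)
            x = _downsample2(x)
            y = _downsample2(y)
    result = 1.0
    for t, w in zip(terms, scale_weights):
        # negative contrast-structure terms clamp to 0 (standard convention
        # with fractional exponent weights), keeping the index within [0, 1]
        result *= max(t, 0.0) ** w
    return float(result)


def evaluate_sweep(
    enhanced: dict[int, np.ndarray],
    reference: np.ndarray,
    data_range: float = 255.0,
    n_scales: int = 5,
) -> pd.DataFrame:
    """Per-down-sampling-factor restoration accuracy table.

    For each M, computes MS-SSIM and per-image NRMSE of every enhanced frame
    against the matching reference frame and reports their mean and standard
    deviation, one row per M (the shape of a density-sweep accuracy plot).
    """
    reference = np.asarray(reference, dtype=np.float64)
    rows = []
    for M in sorted(enhanced):
        stack = np.asarray(enhanced[M], dtype=np.float64)
        if stack.shape != reference.shape:
            raise ValueError(
                f"M={M}: enhanced stack shape {stack.shape} does not match "
                f"reference {reference.shape}"
            )
        ssims = [
            ms_ssim(stack[t], reference[t], n_scales=n_scales, data_range=data_range)
            for t in range(stack.shape[0])
        ]
        nrmses = [nrmse_image(stack[t], reference[t]) for t in range(stack.shape[0])]
        rows.append(
            {
                "M": M,
                "n_frames": stack.shape[0],
                "msssim_mean": float(np.mean(ssims)),
                "msssim_sd": float(np.std(ssims)),
                "nrmse_mean": float(np.mean(nrmses)),
                "nrmse_sd": float(np.std(nrmses)),
            }
        )
    return pd.DataFrame(rows)
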