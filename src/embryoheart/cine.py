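"""Cine-stack preprocessing for high-frequency ultrasound of the beating heart.

A recording consists of per-plane 2D+time image stacks acquired
sequentially over many cardiac cycles.  The operations here recover a
single synchronized cycle from them:

* cardiac-phase synchronization of frames within a plane, from the lag of
  the dominant peak of the whole-image intensity autocorrelation;
* timing synchronization of neighbouring planes, from whole-image
  cross-correlation (offsets chained from the first plane);
* phase-binned ensemble statistics over cycles: the arithmetic ensemble
  (per-phase pixel mean, enhancing tissue) and the quadratic ensemble
  (per-phase pixel variance across cycles, dimming coherently moving
  tissue and brightening the decorrelated blood pool);
* a normalized-cross-correlation block matcher with subpixel refinement,
  providing sparse frame-to-frame displacements for the motion model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CineStack",
    "EnsembleCycle",
    "estimate_cardiac_period",
    "align_plane_phases",
    "ensemble_average",
    "estimate_displacements",
]


@dataclass
class CineStack:
    """Per-plane 2D+time intensity arrays with acquisition metadata.

    ``planes[k]`` has shape (n_frames, H, W); all planes share frame
    interval (ms) and image size.  ``plane_z`` gives each plane's position
    (mm); ``plane_phase`` (ms) is filled by :func:`align_plane_phases`.
    """

    planes: list
    frame_interval: float
    plane_spacing: float  # um
    pixel_size: float  # um
    plane_z: np.ndarray = None
    plane_phase: np.ndarray | None = None
    period: float | None = None

    def __post_init__(self):
        if self.plane_spacing <= 0:
            raise ValueError("plane_spacing must be positive")
        shapes = {p.shape[1:] for p in self.planes}
        if len(shapes) > 1:
            raise ValueError("all planes must share the image size")
        if self.plane_z is None:
            self.plane_z = np.arange(len(self.planes)) * self.plane_spacing / 1000.0


@dataclass
class EnsembleCycle:
    """Phase-resolved ensemble statistics of one plane."""

    arithmetic: np.ndarray  # (n_bins, H, W) per-phase mean
    quadratic: np.ndarray  # (n_bins, H, W) per-phase variance across cycles
    period: float  # ms
    n_phase_bins: int

    def __post_init__(self):
        if self.arithmetic.shape != self.quadratic.shape:
            raise ValueError("arithmetic/quadratic shapes differ")
        if np.any(self.quadratic < -1e-9):
            raise ValueError("quadratic ensemble must be non-negative")


def _centered(frames: np.ndarray) -> np.ndarray:
    f = np.asarray(frames, dtype=float)
    return f - f.mean(axis=0)


def _frame_correlation_sequence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """r(lag) = sum_t <a_t, b_{t+lag}> via FFT over time, per-pixel summed."""
    T = a.shape[0]
    n = 2 * T
    fa = np.fft.rfft(a.reshape(T, -1), n=n, axis=0)
    fb = np.fft.rfft(b.reshape(T, -1), n=n, axis=0)
    corr = np.fft.irfft((np.conj(fa) * fb).sum(axis=1), n=n, axis=0)
    return corr  # index = lag (0..T-1), negative lags wrap at the end


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def estimate_cardiac_period(
    frames: np.ndarray,
    frame_interval: float,
    min_corr: float = 0.2,
    max_period_frames: int | None = None,
) -> float:
    """Cardiac period (ms) from whole-image autocorrelation of one plane.

    The period is the lag of the first dominant non-zero peak of the
    normalized frame-sequence autocorrelation, refined by parabolic
    interpolation.  Raises ``ValueError`` for aperiodic input (no peak
    above ``min_corr``).
    """
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    g = _centered(frames)
    power = float((g * g).sum())
    if power <= 0:
        raise ValueError("aperiodic input: constant image sequence")
    corr = _frame_correlation_sequence(g, g)[: T // 2 + 1]
    norm = np.maximum(T - np.arange(len(corr)), 1)
    corr = corr / norm  # unbiased-ish
    corr = corr / corr[0]
    lim = len(corr) if max_period_frames is None else min(len(corr), max_period_frames)
    c = corr[:lim]
    # local maxima beyond lag 1
    peaks = [
        i
        for i in range(2, len(c) - 1)
        if c[i] >= c[i - 1] and c[i] > c[i + 1] and c[i] > min_corr
    ]
    if not peaks:
        raise ValueError("aperiodic input: no autocorrelation peak above threshold")
    dominant = max(c[i] for i in peaks)
    first = next(i for i in peaks if c[i] >= 0.8 * dominant)
    lag = _parabolic_refine(c, first)
    return lag * frame_interval


def align_plane_phases(stack: CineStack, min_corr: float = 0.1) -> CineStack:
    """Fill per-plane acquisition phase offsets by chained cross-correlation.

    The offset of plane k relative to plane k-1 is the lag maximizing the
    whole-image cross-correlation of the two frame sequences; offsets are
    accumulated from plane 0 and reported modulo the period.  A plane whose
    correlation peak is below ``min_corr`` inherits its neighbour's phase
    (zero relative offset) with a warning.
    """
    periods = [
        estimate_cardiac_period(p, stack.frame_interval) for p in stack.planes
    ]
    period = float(np.median(periods))
    if max(periods) - min(periods) > 0.05 * period:
        raise ValueError("per-plane period estimates differ by more than 5%")
    offsets = [0.0]
    for k in range(1, len(stack.planes)):
        a = _centered(stack.planes[k - 1])
        b = _centered(stack.planes[k])
        T = a.shape[0]
        corr = _frame_correlation_sequence(a, b)
        scale = np.sqrt(float((a * a).sum()) * float((b * b).sum()))
        corr = corr / max(scale, 1e-30)
        pf = period / stack.frame_interval
        lim = int(np.ceil(pf)) + 1
        # candidate lags in [0, period)
        cand = np.concatenate([corr[:lim], corr[-lim:]])
        lags = np.concatenate([np.arange(lim), -np.arange(lim, 0, -1)])
        i = int(np.argmax(cand))
        if cand[i] < min_corr:
            warnings.warn(
                f"plane {k}: cross-correlation peak below threshold; "
                "propagating neighbour phase"
            )
            rel = 0.0
        else:
            # parabolic refinement on the circular sequence
            full = np.concatenate([corr[-lim:], corr[:lim]])
            j = int(np.argmax(full))
            rel = (_parabolic_refine(full, j) - lim) * stack.frame_interval
        # b lags a by `rel` means plane k started `-rel` later
        offsets.append((offsets[-1] - rel) % period)
    out = replace(stack)
    out.plane_phase = np.asarray(offsets) % period
    out.period = period
    return out


def ensemble_average(
    frames: np.ndarray,
    frame_interval: float,
    period: float,
    n_phase_bins: int | None = None,
    phase_offset: float = 0.0,
) -> EnsembleCycle:
    """Phase-binned pixelwise mean and variance across cycles.

    Frames are assigned to the nearest of ``n_phase_bins`` equal phase bins
    by acquisition timestamp modulo the period.  Requires at least two
    cycles; an empty phase bin raises with a suggestion to use fewer bins.
    """
    frames = np.asarray(frames, dtype=float)
    T = frames.shape[0]
    if T * frame_interval < 2 * period:
        raise ValueError("need at least two cardiac cycles for ensembles")
    if n_phase_bins is None:
        n_phase_bins = max(int(round(period / frame_interval)), 1)
    t = phase_offset + np.arange(T) * frame_interval
    phase = (t % period) / period
    bins = np.rint(phase * n_phase_bins).astype(int) % n_phase_bins
    counts = np.bincount(bins, minlength=n_phase_bins)
    if np.any(counts == 0):
        raise ValueError(
            f"empty phase bin with n_phase_bins={n_phase_bins}; use fewer bins"
        )
    H, W = frames.shape[1:]
    mean = np.zeros((n_phase_bins, H, W))
    var = np.zeros((n_phase_bins, H, W))
    np.add.at(mean, bins, frames)
    mean /= counts[:, None, None]
    np.add.at(var, bins, frames**2)
    var = var / counts[:, None, None] - mean**2
    np.maximum(var, 0.0, out=var)
    return EnsembleCycle(
        arithmetic=mean, quadratic=var, period=period, n_phase_bins=n_phase_bins
    )


def estimate_displacements(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 16,
    search: int = 8,
    step: int | None = None,
    min_peak_ratio: float = 1.2,
    min_correlation: float = 0.3,
):
    """Sparse displacement field from A to B by NCC block matching.

    Returns a dict of arrays: grid positions ``x``, ``y`` (pixels),
    displacements ``ux``, ``uy`` (pixels, subpixel-refined), and
    ``confidence`` (primary-to-secondary correlation peak ratio).  Low
    confidence vectors are dropped, not errors.
    """
    from skimage.feature import match_template

    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    step = step or window // 2
    H, W = a.shape
    xs, ys, uxs, uys, confs = [], [], [], [], []
    half = window // 2
    for cy in range(half + search, H - half - search + 1, step):
        for cx in range(half + search, W - half - search + 1, step):
            tpl = a[cy - half : cy + half, cx - half : cx + half]
            if tpl.std() < 1e-12:
                continue
            reg = b[
                cy - half - search : cy + half + search,
                cx - half - search : cx + half + search,
            ]
            ncc = match_template(reg, tpl)
            iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
            peak = ncc[iy, ix]
            if peak < min_correlation:
                continue
            # secondary peak outside a 3-px exclusion zone
            masked = ncc.copy()
            masked[
                max(iy - 3, 0) : iy + 4,
                max(ix - 3, 0) : ix + 4,
            ] = -np.inf
            second = masked.max()
            ratio = peak / max(second, 1e-9) if second > 0 else np.inf
            if ratio < min_peak_ratio:
                continue
            dy = _parabolic_refine(
                np.array([ncc[max(iy - 1, 0), ix], peak, ncc[min(iy + 1, ncc.shape[0] - 1), ix]]),
                1,
            ) - 1
            dx = _parabolic_refine(
                np.array([ncc[iy, max(ix - 1, 0)], peak, ncc[iy, min(ix + 1, ncc.shape[1] - 1)]]),
                1,
            ) - 1
            xs.append(cx)
            ys.append(cy)
            uxs.append(ix - search + dx)
            uys.append(iy - search + dy)
            confs.append(ratio)
    return {
        "x": np.array(xs, dtype=float),
        "y": np.array(ys, dtype=float),
        "ux": np.array(uxs, dtype=float),
        "uy": np.array(uys, dtype=float),
        "confidence": np.array(confs, dtype=float),
    }
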