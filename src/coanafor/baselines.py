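"""Comparison reconstructions: forward linear prediction with root
reflection, SIFT-style support projection, compressed sensing by iterative
soft thresholding, and Poisson-gap schedule generation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .reconstruct import Interferogram
from .signal_model import TimeGrid

__all__ = [
    "SamplingSchedule",
    "lp_coefficients",
    "lp_extend",
    "bright_mask",
    "sift_reconstruct",
    "poisson_gap_schedule",
    "ist_reconstruct",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingSchedule:
    """Sorted unique sampled indices out of ``n_total`` grid points."""

    indices: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise ValueError("schedule must contain at least one index")
        if idx[0] < 0 or idx[-1] >= self.n_total:
            raise ValueError(f"indices must lie in [0, {self.n_total})")
        if idx[0] != 0:
            raise ValueError("schedule must include index 0")

    @property
    def coverage(self) -> float:
        return self.indices.size / self.n_total

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_total, bool)
        m[self.indices] = True
        return m


def lp_coefficients(recorded, order: int) -> np.ndarray:
    """Forward linear-prediction coefficients by least squares over all
    complete prediction windows, stabilized by reflecting characteristic
    roots with modulus > 1 into the unit circle.

    The prediction model is ``x[k] = sum_{m=1..order} c[m-1] * x[k-m]``.
    """
    x = np.asarray(recorded, dtype=complex).ravel()
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if x.size < 2 * order:
        raise ValueError(
            f"need at least 2*order={2 * order} points for order {order}, got {x.size}"
        )
    n = x.size
    rows = n - order
    A = np.empty((rows, order), complex)
    for m in range(order):
        A[:, m] = x[order - 1 - m : n - 1 - m]
    b = x[order:]
    c, *_ = np.linalg.lstsq(A, b, rcond=None)

    # characteristic polynomial z^p - c1 z^{p-1} - ... - cp
    poly = np.concatenate(([1.0 + 0j], -c))
    roots = np.roots(poly)
    outside = np.abs(roots) > 1.0
    if outside.any():
        roots[outside] = roots[outside] / np.abs(roots[outside]) ** 2
        poly = np.poly(roots)
        c = -poly[1:]
    return c


def lp_extend(fid: Interferogram, order: int, target_n_points: int) -> Interferogram:
    """Extend a truncated interferogram by recursive forward prediction.

    Requires a contiguous recorded prefix; each appended point is the
    coefficient-weighted sum of the preceding ``order`` points.
    """
    obs = fid.recorded_indices
    n_rec = obs.size
    if n_rec == 0:
        raise ValueError("interferogram has no recorded points")
    if not np.array_equal(obs, np.arange(n_rec)):
        raise ValueError("linear prediction requires a contiguous recorded prefix")
    if target_n_points < n_rec:
        raise ValueError("target shorter than the recorded prefix")
    c = lp_coefficients(fid.data[:n_rec], order)
    out = np.zeros(target_n_points, complex)
    out[:n_rec] = fid.data[:n_rec]
    for k in range(n_rec, target_n_points):
        out[k] = np.dot(c, out[k - 1 : k - 1 - order : -1] if order > 1 else out[k - 1 : k])
    mask = np.zeros(target_n_points, bool)
    mask[:n_rec] = True
    return Interferogram(out, fid.grid.resized(target_n_points), mask)


def spectral_axis(n_points: int, dwell: float) -> np.ndarray:
    """Ascending frequency axis (Hz) of an ``n_points`` spectrum."""
    return np.fft.fftshift(np.fft.fftfreq(n_points, d=dwell))


def bright_mask(freqs, width_hz: float, n_points: int, dwell: float) -> np.ndarray:
    """Boolean support over the ascending spectral grid: True within
    +/- width/2 of any guide frequency (union of intervals)."""
    if width_hz <= 0:
        raise ValueError("width_hz must be > 0")
    axis = spectral_axis(n_points, dwell)
    mask = np.zeros(n_points, bool)
    for f in np.atleast_1d(np.asarray(freqs, dtype=float)):
        mask |= np.abs(axis - f) <= width_hz / 2.0
    return mask


def sift_reconstruct(
    fid: Interferogram,
    mask: np.ndarray,
    n_iter: int = 50,
    target_n_points: int | None = None,
) -> Interferogram:
    """Alternate projection between a frequency-domain support constraint
    (zero outside the bright regions) and time-domain data consistency.

    Each iteration: FT the current estimate, zero all spectrum points
    outside the mask, inverse FT, then overwrite recorded time points with
    the measured values.  Returns the estimate after the final restoration,
    so recorded points are conserved exactly.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = target_n_points if target_n_points is not None else fid.grid.n_points
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.size != n:
        raise ValueError(f"mask length {mask.size} != spectral grid size {n}")
    if not mask.any():
        logger.warning("SIFT bright mask is empty; result equals zero-fill")
    mask_fft = np.fft.ifftshift(mask)  # mask is on the ascending (shifted) axis
    obs = fid.recorded_indices
    if obs.size and obs[-1] >= n:
        raise ValueError("target shorter than the recorded extent")
    est = np.zeros(n, complex)
    est[obs] = fid.data[obs]
    for _ in range(n_iter):
        spec = np.fft.fft(est)
        spec[~mask_fft] = 0.0
        est = np.fft.ifft(spec)
        est[obs] = fid.data[obs]
    out_mask = np.zeros(n, bool)
    out_mask[obs] = True
    return Interferogram(est, fid.grid.resized(n), out_mask)


def poisson_gap_schedule(
    n_total: int,
    coverage: float,
    sine_weight: float = 2.0,
    seed: int = 0,
    max_trials: int = 1000,
) -> SamplingSchedule:
    """Sinusoidally weighted Poisson-gap sampling schedule.

    Gaps between consecutive sampled indices are Poisson draws whose mean
    grows as ``rate * sin(pi/2 * pos/n)**sine_weight`` across the grid, so
    sampling is densest at short evolution times.  The rate is adjusted
    iteratively until exactly ``round(coverage * n_total)`` indices are
    produced; index 0 is always included and the result is deterministic for
    a fixed seed.
    """
    if not 0 < coverage <= 1:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    target = int(round(coverage * n_total))
    target = max(target, 1)
    if target >= n_total:
        return SamplingSchedule(np.arange(n_total), n_total)

    # expected gap sum must absorb n_total - target skipped points;
    # mean of sin^w over [0, pi/2] is ~0.5 for w=2
    rate = 2.0 * (n_total - target) / target
    theta = (np.arange(1, n_total + 1) / (n_total + 1)) * (np.pi / 2.0)
    weights = np.sin(theta) ** sine_weight
    for trial in range(max_trials):
        rng = np.random.default_rng([seed, trial])
        idx = []
        pos = 0
        while pos < n_total:
            idx.append(pos)
            pos += 1
            pos += int(rng.poisson(rate * weights[min(pos, n_total) - 1]))
        if len(idx) == target:
            return SamplingSchedule(np.asarray(idx, dtype=np.intp), n_total)
        # multiplicative rate update toward the target count
        rate = max(rate * len(idx) / target, 1e-6)
    raise RuntimeError(
        f"failed to hit {target} sampled points in {max_trials} trials"
    )


def _soft_threshold(spec: np.ndarray, thr: float) -> np.ndarray:
    """Magnitude shrinkage with phase preserved."""
    mag = np.abs(spec)
    keep = mag > thr
    out = np.zeros_like(spec)
    out[keep] = spec[keep] * (mag[keep] - thr) / mag[keep]
    return out


def ist_reconstruct(
    fid: Interferogram,
    n_iter: int = 400,
    target_n_points: int | None = None,
) -> Interferogram:
    """Compressed-sensing reconstruction by iterative soft thresholding.

    The residual spectrum is repeatedly soft-thresholded and accumulated;
    the threshold decays linearly from the initial spectrum's maximum
    magnitude to zero across the iterations.  Sampled time points are
    conserved in the final output by a closing data-consistency step.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = target_n_points if target_n_points is not None else fid.grid.n_points
    obs = fid.recorded_indices
    if obs.size and obs[-1] >= n:
        raise ValueError("target shorter than the recorded extent")
    residual = np.zeros(n, complex)
    residual[obs] = fid.data[obs]
    accum = np.zeros(n, complex)
    thr0 = float(np.max(np.abs(np.fft.fft(residual)))) if obs.size else 0.0
    for it in range(n_iter):
        spec = np.fft.fft(residual)
        thr = thr0 * (1.0 - (it + 1) / n_iter)
        extracted = _soft_threshold(spec, thr)
        accum += extracted
        model = np.fft.ifft(accum)
        residual = np.zeros(n, complex)
        residual[obs] = fid.data[obs] - model[obs]
    out = np.fft.ifft(accum)
    out[obs] = fid.data[obs]  # final data consistency
    out_mask = np.zeros(n, bool)
    out_mask[obs] = True
    return Interferogram(out, fid.grid.resized(n), out_mask)
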