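"""Damped complex-sinusoid basis construction and Tikhonov-regularized
amplitude estimation.

The model underlying both ANAFOR-style replacement and Co-ANAFOR-style
insertion is a sum of exponentially damped complex sinusoids

    x(t) = sum_j a_j * exp(i 2 pi nu_j t - R t)

with known frequencies ``nu_j`` (taken from a guide peak list), a single
uniform decay rate ``R`` and unknown complex amplitudes ``a_j``.  The
amplitudes are estimated from the recorded time points by ridge-regularized
least squares and the model is then evaluated wherever points are needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeGrid",
    "SignalBasis",
    "AmplitudeSet",
    "build_basis",
    "solve_amplitudes",
    "synthesize",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform complex-point time grid: ``t_k = t0 + k * dwell``."""

    n_points: int
    dwell: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")
        if not self.dwell > 0:
            raise ValueError(f"dwell must be > 0, got {self.dwell}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dwell * np.arange(self.n_points)

    @property
    def spectral_width(self) -> float:
        """Spectral width in Hz (reciprocal of the dwell time)."""
        return 1.0 / self.dwell

    @property
    def t_max(self) -> float:
        """Largest evolution time on the grid."""
        return self.t0 + self.dwell * (self.n_points - 1)

    def resized(self, n_points: int) -> "TimeGrid":
        """Same dwell and origin with a different number of points."""
        return TimeGrid(n_points=n_points, dwell=self.dwell, t0=self.t0)


@dataclass
class SignalBasis:
    """Damped-exponential design matrix restricted to observed time points.

    ``matrix[k, j] = exp((i 2 pi frequencies[j] - relax_rate) * t_k)`` where
    ``t_k`` runs over ``grid.times[observed_indices]`` in ascending index
    order.
    """

    frequencies: np.ndarray
    relax_rate: float
    grid: TimeGrid
    observed_indices: np.ndarray
    matrix: np.ndarray = field(repr=False)

    @property
    def n_observed(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_signals(self) -> int:
        return self.matrix.shape[1]


@dataclass
class AmplitudeSet:
    """Complex amplitudes per basis frequency plus the regularization used."""

    amplitudes: np.ndarray
    reg_factor: float
    effective_lambda: float


def _close_frequency_pairs(freqs: np.ndarray, t_max: float) -> list[tuple[int, int]]:
    if t_max <= 0 or freqs.size < 2:
        return []
    tol = 1.0 / (2.0 * t_max)
    order = np.argsort(freqs)
    pairs = []
    for a, b in zip(order[:-1], order[1:]):
        if abs(freqs[b] - freqs[a]) < tol:
            pairs.append((int(a), int(b)))
    return pairs


def build_basis(
    frequencies,
    relax_rate: float,
    grid: TimeGrid,
    observed_indices=None,
) -> SignalBasis:
    """Construct the damped complex-exponential design matrix.

    Parameters
    ----------
    frequencies
        Offsets in Hz; each must lie within the Nyquist band
        ``[-sw/2, sw/2]`` of the grid.  An empty list yields a valid basis
        with zero columns.
    relax_rate
        Uniform decay rate ``R`` in 1/s, must be >= 0.
    grid
        The full target time grid.
    observed_indices
        Indices of the recorded time points (subset of ``range(n_points)``).
        ``None`` means all points.  Rows of the returned matrix follow
        ascending index order.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if relax_rate < 0:
        raise ValueError(f"relax_rate must be >= 0, got {relax_rate}")
    nyquist = grid.spectral_width / 2.0
    bad = np.flatnonzero(np.abs(freqs) > nyquist)
    if bad.size:
        j = int(bad[0])
        raise ValueError(
            f"frequency #{j} ({freqs[j]:g} Hz) lies outside the Nyquist band "
            f"+/-{nyquist:g} Hz of the grid"
        )
    if observed_indices is None:
        obs = np.arange(grid.n_points)
    else:
        obs = np.unique(np.asarray(observed_indices, dtype=np.intp))
        if obs.size and (obs[0] < 0 or obs[-1] >= grid.n_points):
            raise ValueError(
                f"observed indices must lie in [0, {grid.n_points}); "
                f"got range [{obs[0]}, {obs[-1]}]"
            )
    for a, b in _close_frequency_pairs(freqs, grid.t_max):
        logger.warning(
            "guide frequencies %g Hz and %g Hz are closer than the resolution "
            "limit 1/(2*t_max) = %g Hz; the fit relies on regularization",
            freqs[a], freqs[b], 1.0 / (2.0 * grid.t_max),
        )
    t = grid.times[obs]
    # (M, J) complex exponent; empty frequency list -> (M, 0) matrix
    exponent = np.outer(t, 2j * np.pi * freqs) - relax_rate * t[:, None]
    matrix = np.exp(exponent) if freqs.size else np.zeros((t.size, 0), complex)
    return SignalBasis(
        frequencies=freqs,
        relax_rate=float(relax_rate),
        grid=grid,
        observed_indices=obs,
        matrix=matrix,
    )


def solve_amplitudes(
    basis: SignalBasis,
    observed,
    reg_factor: float = 0.01,
    *,
    absolute_lambda: float | None = None,
) -> AmplitudeSet:
    """Ridge-regularized least-squares amplitude estimate.

    Minimizes ``||Phi a - y||^2 + lambda ||a||^2`` with
    ``lambda = reg_factor * mean(diag(Phi^H Phi))`` unless an absolute
    ``lambda`` is supplied directly.  The mean-diagonal scaling makes the
    dimensionless factor invariant to the number of observed points and to
    the decay envelope.

    With ``reg_factor == 0`` the minimum-norm unregularized solution is
    returned (exact least squares when ``Phi`` has full column rank).
    """
    y = np.asarray(observed, dtype=complex).ravel()
    if y.size != basis.n_observed:
        raise ValueError(
            f"observed vector length {y.size} != basis row count {basis.n_observed}"
        )
    if reg_factor < 0:
        raise ValueError(f"reg_factor must be >= 0, got {reg_factor}")
    J = basis.n_signals
    if J == 0:
        return AmplitudeSet(np.zeros(0, complex), float(reg_factor), 0.0)
    if basis.n_observed == 0:
        raise ValueError("cannot fit amplitudes with zero observed points")

    phi = basis.matrix
    gram = phi.conj().T @ phi
    if absolute_lambda is not None:
        lam = float(absolute_lambda)
        if lam < 0:
            raise ValueError("absolute_lambda must be >= 0")
    else:
        lam = float(reg_factor) * float(np.mean(np.real(np.diag(gram))))
    if lam > 0:
        amps = np.linalg.solve(gram + lam * np.eye(J), phi.conj().T @ y)
    else:
        amps, *_ = np.linalg.lstsq(phi, y, rcond=None)
    return AmplitudeSet(amplitudes=amps, reg_factor=float(reg_factor), effective_lambda=lam)


def synthesize(
    frequencies,
    relax_rate: float,
    amplitudes,
    grid: TimeGrid,
    indices=None,
) -> np.ndarray:
    """Evaluate ``sum_j a_j exp(i 2 pi nu_j t_k - R t_k)`` at the requested
    grid indices (all points when ``indices`` is None)."""
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    amps = np.asarray(
        amplitudes.amplitudes if isinstance(amplitudes, AmplitudeSet) else amplitudes,
        dtype=complex,
    ).ravel()
    if amps.size != freqs.size:
        raise ValueError(
            f"{amps.size} amplitudes for {freqs.size} frequencies"
        )
    if indices is None:
        t = grid.times
    else:
        idx = np.asarray(indices, dtype=np.intp)
        t = grid.times[idx]
    if freqs.size == 0:
        return np.zeros(t.size, complex)
    exponent = np.outer(t, 2j * np.pi * freqs) - relax_rate * t[:, None]
    return np.exp(exponent) @ amps
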