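"""Window functions, Fourier transformation and peak-height measurement.

FT convention: forward ``numpy.fft.fft`` without normalization, inverse with
the 1/N factor, frequency axis shifted so 0 Hz (the carrier) sits at the
center and frequencies ascend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .reconstruct import Interferogram
from .signal_model import TimeGrid

__all__ = ["WindowSpec", "Spectrum", "PeakHeight", "apply_window", "to_spectrum", "peak_height"]


@dataclass(frozen=True)
class WindowSpec:
    """Apodization spec: ``square_sine`` (sine-squared bell) or ``none``.

    For a phase shift of ``s = phase_shift_deg/180`` the weights are
    ``w_k = sin(pi * (s + (1 - s) * k / (N - 1)))**2``; the 90-degree shift
    starts at exactly 1 and decays monotonically to 0.
    """

    kind: str = "square_sine"
    phase_shift_deg: float = 90.0

    def __post_init__(self) -> None:
        if self.kind not in ("square_sine", "none"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if not 0 <= self.phase_shift_deg <= 90:
            raise ValueError("phase_shift_deg must be in [0, 90]")


@dataclass
class Spectrum:
    """Complex spectrum on an ascending Hz grid with processing provenance."""

    freqs_hz: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def real(self) -> np.ndarray:
        return self.values.real


class PeakHeight(NamedTuple):
    height: float
    freq_hz: float


def apply_window(fid, w: WindowSpec) -> np.ndarray:
    """Pointwise apodization of a complex vector."""
    x = np.asarray(fid, dtype=complex).ravel()
    if w.kind == "none":
        return x.copy()
    if x.size < 2:
        raise ValueError("window requires at least 2 points")
    s = w.phase_shift_deg / 180.0
    k = np.arange(x.size)
    weights = np.sin(np.pi * (s + (1.0 - s) * k / (x.size - 1))) ** 2
    return x * weights


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def to_spectrum(
    fid: Interferogram,
    w: WindowSpec = WindowSpec(),
    zero_fill_factor: int = 1,
    phase_deg: float = 0.0,
    first_point_scale: bool = True,
) -> Spectrum:
    """Window, zero-fill to ``factor * next_pow2(N)``, Fourier transform and
    apply a zero-order phase.

    The first point is halved before the transform when ``t0 == 0`` (DC
    offset convention); disable via ``first_point_scale``.
    """
    if zero_fill_factor < 1:
        raise ValueError("zero_fill_factor must be >= 1")
    x = apply_window(fid.data, w)
    if first_point_scale and fid.grid.t0 == 0:
        x[0] = x[0] * 0.5
    m = zero_fill_factor * _next_pow2(x.size)
    padded = np.zeros(m, complex)
    padded[: x.size] = x
    spec = np.fft.fftshift(np.fft.fft(padded))
    if phase_deg:
        spec = spec * np.exp(1j * np.deg2rad(phase_deg))
    freqs = np.fft.fftshift(np.fft.fftfreq(m, d=fid.grid.dwell))
    return Spectrum(
        freqs_hz=freqs,
        values=spec,
        provenance={
            "window": w.kind,
            "window_phase_shift_deg": w.phase_shift_deg,
            "zero_fill_factor": zero_fill_factor,
            "n_points_before_ft": fid.grid.n_points,
            "phase_deg": phase_deg,
        },
    )


def peak_height(spec: Spectrum, at_hz: float, search_window_hz: float = 27.0) -> PeakHeight:
    """Maximum of the real part within ``at_hz +/- search_window_hz/2``.

    Falls back to the nearest grid point when the window contains none.
    Returns the height together with the frequency where it was found.
    """
    f = spec.freqs_hz
    if not (f[0] <= at_hz <= f[-1]):
        raise ValueError(f"{at_hz:g} Hz lies outside the spectral range [{f[0]:g}, {f[-1]:g}]")
    sel = np.abs(f - at_hz) <= search_window_hz / 2.0
    if not sel.any():
        i = int(np.argmin(np.abs(f - at_hz)))
        return PeakHeight(float(spec.values.real[i]), float(f[i]))
    idx = np.flatnonzero(sel)
    local = spec.values.real[idx]
    j = idx[int(np.argmax(local))]
    return PeakHeight(float(spec.values.real[j]), float(f[j]))
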