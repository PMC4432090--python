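"""Plain-text interchange formats: complex-series tables, guide peak lists
(TSV) and sampling schedules (one index per line).

All floating-point values are serialized with 17 significant digits so that
write -> read round-trips are bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .baselines import SamplingSchedule
from .reconstruct import GuidePeak, GuidePeakList, Interferogram
from .signal_model import TimeGrid

__all__ = [
    "read_series",
    "write_series",
    "read_peaks",
    "write_peaks",
    "read_schedule",
    "write_schedule",
    "write_spectrum",
]

_G = "{:.17g}".format


class ParseError(ValueError):
    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def write_series(
    path,
    fid: Interferogram,
    axis_label: str | None = None,
    base_freq_mhz: float | None = None,
    extra_header: dict | None = None,
) -> None:
    """Complex-series table: '# key: value' header then TSV rows
    (index, real, imag, sampled)."""
    lines = [
        f"# n_points: {fid.grid.n_points}",
        f"# dwell: {_G(fid.grid.dwell)}",
        f"# t0: {_G(fid.grid.t0)}",
    ]
    if axis_label is not None:
        lines.append(f"# axis: {axis_label}")
    if base_freq_mhz is not None:
        lines.append(f"# base_freq_mhz: {_G(base_freq_mhz)}")
    for k, v in (extra_header or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("index\treal\timag\tsampled")
    for k in range(fid.grid.n_points):
        lines.append(
            f"{k}\t{_G(fid.data[k].real)}\t{_G(fid.data[k].imag)}\t"
            f"{int(fid.sampled_mask[k])}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_series(path) -> Interferogram:
    path = Path(path)
    header: dict[str, str] = {}
    data_rows: list[tuple[int, float, float, bool]] = []
    saw_columns = False
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                header[k.strip()] = v.strip()
            continue
        if not saw_columns:
            cols = line.split("\t")
            if cols[:4] != ["index", "real", "imag", "sampled"]:
                raise ParseError(path, line_no, f"unexpected column header {cols!r}")
            saw_columns = True
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(path, line_no, f"expected 4 tab-separated fields, got {len(parts)}")
        try:
            data_rows.append(
                (int(parts[0]), float(parts[1]), float(parts[2]), bool(int(parts[3])))
            )
        except ValueError as e:
            raise ParseError(path, line_no, f"malformed row: {e}") from None
    for key in ("n_points", "dwell"):
        if key not in header:
            raise ParseError(path, 1, f"missing required header '{key}'")
    n = int(header["n_points"])
    grid = TimeGrid(n, float(header["dwell"]), float(header.get("t0", 0.0)))
    if len(data_rows) != n:
        raise ParseError(path, 1, f"header says {n} points but found {len(data_rows)} rows")
    data = np.zeros(n, complex)
    mask = np.zeros(n, bool)
    for k, re, im, flag in data_rows:
        if not 0 <= k < n:
            raise ParseError(path, 1, f"row index {k} out of range [0, {n})")
        data[k] = complex(re, im)
        mask[k] = flag
    return Interferogram(data, grid, mask)


def write_peaks(path, peaks: GuidePeakList) -> None:
    lines = ["id\tdirect_ppm\tindirect_hz\tlinewidth_hz"]
    for p in peaks:
        direct = _G(p.direct_ppm) if p.direct_ppm is not None else ""
        lw = _G(p.linewidth_hz) if p.linewidth_hz is not None else ""
        lines.append(f"{p.id}\t{direct}\t{_G(p.indirect_hz)}\t{lw}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks(path, base_freq_mhz: float | None = None) -> GuidePeakList:
    """Guide peak list TSV.  Accepts an ``indirect_ppm`` column in place of
    ``indirect_hz`` when a base frequency (MHz) is supplied."""
    path = Path(path)
    lines = [l for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise ParseError(path, 1, "empty peak list")
    cols = lines[0].split("\t")
    if "id" not in cols or ("indirect_hz" not in cols and "indirect_ppm" not in cols):
        raise ParseError(path, 1, "need 'id' and an 'indirect_hz' or 'indirect_ppm' column")
    idx = {c: i for i, c in enumerate(cols)}
    peaks = []
    for line_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise ParseError(path, line_no, f"expected {len(cols)} fields, got {len(parts)}")

        def get(col):
            if col not in idx:
                return None
            v = parts[idx[col]].strip()
            return v or None

        try:
            if get("indirect_hz") is not None:
                hz = float(get("indirect_hz"))
            else:
                if base_freq_mhz is None:
                    raise ParseError(
                        path, line_no, "indirect_ppm given but no base_freq_mhz supplied"
                    )
                hz = float(get("indirect_ppm")) * base_freq_mhz
            direct = get("direct_ppm")
            lw = get("linewidth_hz")
            peaks.append(
                GuidePeak(
                    id=parts[idx["id"]].strip(),
                    indirect_hz=hz,
                    direct_ppm=float(direct) if direct is not None else None,
                    linewidth_hz=float(lw) if lw is not None else None,
                )
            )
        except ParseError:
            raise
        except ValueError as e:
            raise ParseError(path, line_no, f"malformed row: {e}") from None
    return GuidePeakList(peaks)


def write_spectrum(path, spectrum) -> None:
    """Two-column (Hz, real intensity) TSV for plotting."""
    lines = ["freq_hz\tintensity"]
    for f, v in zip(spectrum.freqs_hz, spectrum.values.real):
        lines.append(f"{_G(f)}\t{_G(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_schedule(path, schedule: SamplingSchedule) -> None:
    """One sampled index per line."""
    Path(path).write_text("\n".join(str(int(i)) for i in schedule.indices) + "\n")


def read_schedule(path, n_total: int) -> SamplingSchedule:
    path = Path(path)
    indices = []
    for line_no, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            indices.append(int(line.split()[0]))
        except ValueError:
            raise ParseError(path, line_no, f"expected an integer index, got {line!r}") from None
    return SamplingSchedule(np.asarray(indices, dtype=np.intp), n_total)
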