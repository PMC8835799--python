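"""Plain-text I/O for spectro-temporal surfaces and kinetic traces.

Pump-probe experiments (transient absorption, femtosecond stimulated Raman)
produce a 2-D matrix of signal versus spectral position and pump-probe delay.
This module defines the two in-memory containers the rest of the package
operates on — :class:`DelaySpectraSurface` and :class:`KineticTrace` — and a
small, diff-able text dialect (``matrix_v1``) for storing surfaces:

* optional leading ``# key=value`` comment lines carrying provenance metadata,
* a header row whose first cell is the axis-kind token (``wavelength_nm`` or
  ``raman_shift_cm``) followed by the delay grid in picoseconds,
* one row per spectral channel: the axis position followed by the signal at
  each delay.

Values are written with 17 significant digits so a write/read round trip is
bitwise lossless for IEEE doubles.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

AXIS_KINDS = ("wavelength_nm", "raman_shift_cm")

_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an on-disk matrix violates the matrix_v1 dialect."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclasses.dataclass(frozen=True)
class DelaySpectraSurface:
    """A spectro-temporal signal matrix with axis metadata.

    Parameters
    ----------
    axis : array
        Strictly increasing spectral positions, nm or cm^-1.
    delays : array
        Strictly increasing pump-probe delays in ps.
    values : array, shape (len(axis), len(delays))
        Signal: ΔA (OD) for transient absorption, Raman gain for FSRS.
    axis_kind : str
        ``"wavelength_nm"`` or ``"raman_shift_cm"``.
    meta : dict
        Free-form provenance strings, serialized as ``#`` comments.
    """

    axis: np.ndarray
    delays: np.ndarray
    values: np.ndarray
    axis_kind: str
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        axis = _as_float_array(self.axis, "axis")
        delays = _as_float_array(self.delays, "delays")
        values = _as_float_array(self.values, "values")
        if axis.ndim != 1 or axis.size == 0:
            raise ValueError("axis must be a non-empty 1-D array")
        if delays.ndim != 1 or delays.size == 0:
            raise ValueError("delays must be a non-empty 1-D array")
        if np.any(np.diff(axis) <= 0):
            bad = int(np.argmax(np.diff(axis) <= 0)) + 1
            raise ValueError(f"non-monotonic axis at row {bad}")
        if np.any(np.diff(delays) <= 0):
            bad = int(np.argmax(np.diff(delays) <= 0)) + 1
            raise ValueError(f"non-monotonic delays at column {bad}")
        if values.shape != (axis.size, delays.size):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"(axis, delays) = ({axis.size}, {delays.size})"
            )
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(
                f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}"
            )
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "meta", dict(self.meta))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def replace_values(self, values: np.ndarray, **meta_updates: str) -> "DelaySpectraSurface":
        """Return a copy with new signal values and optional extra metadata."""
        meta = dict(self.meta)
        meta.update({k: str(v) for k, v in meta_updates.items()})
        return DelaySpectraSurface(self.axis, self.delays, values, self.axis_kind, meta)


@dataclasses.dataclass(frozen=True)
class KineticTrace:
    """One band's signal versus delay, with optional per-point uncertainty."""

    delays: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        delays = _as_float_array(self.delays, "delays")
        values = _as_float_array(self.values, "values")
        if delays.shape != values.shape or delays.ndim != 1:
            raise ValueError("delays and values must be 1-D arrays of equal length")
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "values", values)
        if self.sigma is not None:
            sigma = _as_float_array(self.sigma, "sigma")
            if sigma.shape != delays.shape:
                raise ValueError("sigma must match delays in length")
            if np.any(sigma < 0):
                raise ValueError("sigma must be non-negative")
            object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return self.delays.size


# ---------------------------------------------------------------------------
# matrix_v1 dialect
# ---------------------------------------------------------------------------

def write_surface(surface: DelaySpectraSurface, path) -> None:
    """Write ``surface`` to ``path`` in the matrix_v1 text format."""
    path = Path(path)
    lines = []
    for key, value in surface.meta.items():
        lines.append(f"# {key}={value}")
    header = [surface.axis_kind] + [_FMT % d for d in surface.delays]
    lines.append("\t".join(header))
    for pos, row in zip(surface.axis, surface.values):
        lines.append("\t".join([_FMT % pos] + [_FMT % v for v in row]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_surface(path, dialect: str = "matrix_v1") -> DelaySpectraSurface:
    """Read a surface written by :func:`write_surface`.

    Tab- and comma-delimited files are both accepted; errors name the
    offending row and column (1-based, counting data rows).
    """
    if dialect != "matrix_v1":
        raise ValueError(f"unknown dialect {dialect!r}; supported: matrix_v1")
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        delim = "\t" if "\t" in line else ","
        rows.append([cell.strip() for cell in line.split(delim)])
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    axis_kind = header[0]
    if axis_kind not in AXIS_KINDS:
        raise FormatError(
            f"{path}: header cell (0,0) must be one of {AXIS_KINDS}, got {axis_kind!r}"
        )
    ncol = len(header)
    delays = _parse_row(header[1:], path, row_index=0, offset=1)
    axis = np.empty(len(rows) - 1)
    values = np.empty((len(rows) - 1, ncol - 1))
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != ncol:
            raise FormatError(
                f"{path}: row {i} has {len(row)} fields, expected {ncol}"
            )
        parsed = _parse_row(row, path, row_index=i, offset=0)
        axis[i - 1] = parsed[0]
        values[i - 1] = parsed[1:]
    try:
        return DelaySpectraSurface(axis, delays, values, axis_kind, meta)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _parse_row(cells, path, row_index: int, offset: int) -> np.ndarray:
    out = np.empty(len(cells))
    for j, cell in enumerate(cells):
        try:
            out[j] = float(cell)
        except ValueError as exc:
            raise FormatError(
                f"{path}: row {row_index}, column {j + offset}: "
                f"could not parse {cell!r} as a number"
            ) from exc
    if not np.all(np.isfinite(out)):
        j = int(np.argmax(~np.isfinite(out)))
        raise FormatError(
            f"{path}: row {row_index}, column {j + offset}: non-finite value"
        )
    return out


# ---------------------------------------------------------------------------
# trace extraction and trace/report files
# ---------------------------------------------------------------------------

def slice_trace(surface: DelaySpectraSurface, center: float, halfwidth: float) -> KineticTrace:
    """Average the spectral rows inside ``center ± halfwidth`` into one trace.

    Window membership uses closed intervals on axis values, so boundary ties
    are included and the result is reproducible across grids.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be non-negative")
    mask = (surface.axis >= center - halfwidth) & (surface.axis <= center + halfwidth)
    if not np.any(mask):
        raise ValueError(
            f"empty window: no axis points in [{center - halfwidth}, {center + halfwidth}]"
        )
    values = surface.values[mask].mean(axis=0)
    unit = "nm" if surface.axis_kind == "wavelength_nm" else "cm-1"
    return KineticTrace(
        surface.delays, values, label=f"{center:g}±{halfwidth:g} {unit}"
    )


def write_trace(trace: KineticTrace, path) -> None:
    """Write a trace as tab-separated columns (delay, value[, sigma])."""
    path = Path(path)
    lines = [f"# label={trace.label}"] if trace.label else []
    for i in range(len(trace)):
        cells = [_FMT % trace.delays[i], _FMT % trace.values[i]]
        if trace.sigma is not None:
            cells.append(_FMT % trace.sigma[i])
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path) -> KineticTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    label = ""
    cols: list[list[float]] = []
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("label="):
                label = body[len("label="):]
            continue
        delim = "\t" if "\t" in line else ","
        cols.append([float(c) for c in line.split(delim)])
    if not cols:
        raise FormatError(f"{path}: empty trace file")
    arr = np.asarray(cols)
    sigma = arr[:, 2] if arr.shape[1] >= 3 else None
    return KineticTrace(arr[:, 0], arr[:, 1], sigma=sigma, label=label)


def write_fit_report(report: dict, path) -> None:
    """Serialize a fit report (parameters, uncertainties, residuals) as JSON."""
    path = Path(path)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    path.write_text(json.dumps(report, indent=2, default=_default) + "\n", encoding="utf-8")
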