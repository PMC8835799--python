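"""Raw-surface conditioning: chirp, reference subtraction, baselines, band integrals.

The probe continuum in pump-probe experiments is chirped: group-velocity
dispersion makes the effective time zero depend on spectral position. The
chirp is estimated from the coherent artifact recorded around time zero
(in FSRS practice, from the transient-absorption background measured without
the Raman pump) and removed by resampling every channel onto a common time
axis. Fluorescence backgrounds under stimulated-Raman spectra are removed by
low-order polynomial fits (or, over short ranges, straight lines), and band
kinetics are extracted by fixed-bandwidth integration.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from numpy.polynomial import Polynomial
from numpy.polynomial import polynomial as P
from scipy import optimize

from .io import DelaySpectraSurface, KineticTrace, slice_trace

#: largest admissible time-zero spread across the axis, ps (sanity bound)
MAX_CHIRP_SPREAD = 10.0


class ChirpError(RuntimeError):
    """Raised when no usable coherent artifact is found for chirp estimation."""


@dataclasses.dataclass(frozen=True)
class ChirpModel:
    """Polynomial model of time zero versus spectral position.

    ``coeffs`` are lowest-order-first polynomial coefficients of t0 (ps)
    versus axis position; the applied correction is zero at
    ``reference_position``.
    """

    coeffs: tuple
    reference_position: float
    residual_rms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "coeffs", tuple(float(c) for c in self.coeffs))
        if len(self.coeffs) < 1 or len(self.coeffs) > 4:
            raise ValueError("chirp polynomial degree must be between 0 and 3")

    def t0(self, positions) -> np.ndarray:
        return P.polyval(np.asarray(positions, dtype=float), np.asarray(self.coeffs))

    def shift(self, positions) -> np.ndarray:
        """Correction to subtract: t0(ν) − t0(reference_position)."""
        return self.t0(positions) - self.t0(self.reference_position)


@dataclasses.dataclass(frozen=True)
class BaselineSpec:
    """Baseline removal recipe for one spectrum.

    ``full_range_poly`` fits an order-``order`` polynomial to all points
    outside the ``exclusion_windows`` (a list of (center, halfwidth) pairs
    masking real bands from the fit). ``local_linear`` draws a straight line
    through the 3-pixel means at the two ends of the range, the usual choice
    for narrow solvent-band windows.
    """

    order: int = 4
    exclusion_windows: tuple = ()
    mode: str = "full_range_poly"

    def __post_init__(self):
        if not 0 <= self.order <= 6:
            raise ValueError("polynomial order must be between 0 and 6")
        if self.mode not in ("full_range_poly", "local_linear"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        object.__setattr__(
            self, "exclusion_windows",
            tuple((float(c), float(h)) for c, h in self.exclusion_windows),
        )


# ---------------------------------------------------------------------------
# chirp
# ---------------------------------------------------------------------------

def _gauss_offset(t, amp, center, width, offset):
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2) + offset


def _channel_t0(delays, values, floor):
    """Time zero of one channel: center of a Gaussian fitted to |dS/dt|."""
    deriv = np.abs(np.gradient(values, delays))
    peak = float(np.max(deriv))
    if peak <= floor:
        return None
    i0 = int(np.argmax(deriv))
    # moment-based width guess, clipped to the window
    weights = deriv / deriv.sum()
    mean = float(np.sum(weights * delays))
    width = float(np.sqrt(np.sum(weights * (delays - mean) ** 2)))
    width = max(width, float(np.min(np.diff(delays))))
    try:
        with warnings.catch_warnings():
            # singular covariance on noise-free channels is expected; only
            # the fitted center is used
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _gauss_offset, delays, deriv,
                p0=(peak, delays[i0], width, 0.0), maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return None
    center = float(popt[1])
    if not delays[0] <= center <= delays[-1]:
        return None
    return center


def estimate_chirp(
    surface: DelaySpectraSurface,
    artifact_window: tuple,
    degree: int = 2,
) -> ChirpModel:
    """Fit the time-zero polynomial from the coherent artifact.

    Per channel, time zero is taken as the center of a Gaussian fitted to the
    magnitude of the time derivative of the signal inside ``artifact_window``
    (a (t_min, t_max) pair in ps) — an estimator that works for both
    step-like and dispersive artifact shapes. A degree-``degree`` polynomial
    of t0 versus axis position is then fitted by least squares.
    """
    lo, hi = artifact_window
    mask = (surface.delays >= lo) & (surface.delays <= hi)
    if mask.sum() < 5:
        raise ValueError("artifact_window contains fewer than 5 delay points")
    delays = surface.delays[mask]
    block = surface.values[:, mask]
    global_peak = float(np.max(np.abs(np.gradient(block, delays, axis=1))))
    if global_peak == 0.0:
        raise ChirpError("no artifact detected: surface is flat in the window")
    floor = 1e-3 * global_peak
    positions, t0s = [], []
    for i in range(surface.axis.size):
        t0 = _channel_t0(delays, block[i], floor)
        if t0 is not None:
            positions.append(surface.axis[i])
            t0s.append(t0)
    if len(t0s) < degree + 2:
        if not t0s:
            raise ChirpError("no artifact detected in any channel")
        raise ChirpError(
            f"only {len(t0s)} channels with usable artifact fits; "
            f"need at least {degree + 2} for degree {degree}"
        )
    positions = np.asarray(positions)
    t0s = np.asarray(t0s)
    poly = Polynomial.fit(positions, t0s, degree).convert()
    coeffs = np.zeros(degree + 1)
    coeffs[: poly.coef.size] = poly.coef
    residual_rms = float(np.sqrt(np.mean((P.polyval(positions, coeffs) - t0s) ** 2)))
    model = ChirpModel(
        coeffs=tuple(coeffs),
        reference_position=float(np.median(positions)),
        residual_rms=residual_rms,
    )
    spread = np.ptp(model.t0(surface.axis))
    if spread > MAX_CHIRP_SPREAD:
        raise ChirpError(
            f"estimated time-zero spread {spread:.3g} ps exceeds the "
            f"{MAX_CHIRP_SPREAD} ps sanity bound"
        )
    return model


def apply_chirp_correction(
    surface: DelaySpectraSurface, chirp: ChirpModel
) -> DelaySpectraSurface:
    """Resample every channel onto the common time axis of the reference.

    Each channel is linearly interpolated at ``delays + shift(ν)`` so that a
    feature at the channel's local time zero lands at the reference time zero;
    out-of-range ends repeat the edge value.
    """
    shifts = chirp.shift(surface.axis)
    if np.ptp(chirp.t0(surface.axis)) > MAX_CHIRP_SPREAD:
        raise ValueError(
            f"chirp time-zero spread exceeds the {MAX_CHIRP_SPREAD} ps sanity bound"
        )
    span = surface.delays[-1] - surface.delays[0]
    if np.max(np.abs(shifts)) > span / 2:
        raise ValueError("chirp shift exceeds half the delay span")
    if np.all(shifts == 0.0):
        return surface.replace_values(
            surface.values.copy(), chirp_coeffs=list(chirp.coeffs)
        )
    out = np.empty_like(surface.values)
    for i, delta in enumerate(shifts):
        out[i] = np.interp(surface.delays + delta, surface.delays, surface.values[i])
    return surface.replace_values(
        out,
        chirp_coeffs=list(chirp.coeffs),
        chirp_reference=f"{chirp.reference_position:g}",
    )


# ---------------------------------------------------------------------------
# reference subtraction
# ---------------------------------------------------------------------------

def subtract_reference(
    surface: DelaySpectraSurface, t_ref: float = -5.0
) -> DelaySpectraSurface:
    """Subtract the spectrum nearest ``t_ref`` from every delay column.

    This removes the static (ground-state) spectrum, leaving pump-induced
    difference spectra. Ties between equally near columns resolve to the
    earlier delay.
    """
    if not surface.delays[0] <= t_ref <= surface.delays[-1]:
        raise ValueError(
            f"t_ref={t_ref} outside the delay range "
            f"[{surface.delays[0]}, {surface.delays[-1]}]"
        )
    idx = int(np.argmin(np.abs(surface.delays - t_ref)))  # argmin: first=earlier
    out = surface.values - surface.values[:, idx][:, None]
    return surface.replace_values(out, reference_delay=f"{surface.delays[idx]:g}")


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def fit_baseline(axis, spectrum, spec: BaselineSpec):
    """Fit and remove a smooth background from one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum − baseline``
    exactly, so ``corrected + baseline`` reproduces the input bitwise.
    """
    axis = np.asarray(axis, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    if axis.shape != spectrum.shape or axis.ndim != 1:
        raise ValueError("axis and spectrum must be 1-D arrays of equal length")
    if spec.mode == "local_linear":
        if axis.size < 3:
            raise ValueError("local_linear baseline needs at least 3 points")
        k = min(3, axis.size)
        x1, y1 = float(np.mean(axis[:k])), float(np.mean(spectrum[:k]))
        x2, y2 = float(np.mean(axis[-k:])), float(np.mean(spectrum[-k:]))
        slope = (y2 - y1) / (x2 - x1)
        baseline = y1 + slope * (axis - x1)
    else:
        mask = np.ones(axis.size, dtype=bool)
        for center, halfwidth in spec.exclusion_windows:
            mask &= ~((axis >= center - halfwidth) & (axis <= center + halfwidth))
        if not np.any(mask):
            raise ValueError("all points masked: no baseline support left")
        if mask.sum() < spec.order + 1:
            raise ValueError(
                f"only {int(mask.sum())} unmasked points for a "
                f"degree-{spec.order} baseline"
            )
        poly = Polynomial.fit(axis[mask], spectrum[mask], spec.order)
        baseline = poly(axis)
    corrected = spectrum - baseline
    return baseline, corrected


# ---------------------------------------------------------------------------
# band integration
# ---------------------------------------------------------------------------

def band_integral(
    surface: DelaySpectraSurface, center: float, bandwidth: float = 25.0
) -> KineticTrace:
    """Band-intensity kinetics: mean signal inside ``center ± bandwidth/2``.

    The 25 cm⁻¹ default bandwidth is narrow enough to exclude inter-band
    spectral changes for well-separated Raman bands.
    """
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    return slice_trace(surface, center, bandwidth / 2.0)
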