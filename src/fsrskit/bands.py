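"""Spectral-domain band analysis.

Three operations: tracking a band's center frequency across pump-probe delay
(vibrational Stokes shift), decomposing a solvent band into fixed-position
sub-bands whose amplitudes report distinct solvent sub-populations (free
versus hydrogen-bonded DMSO), and the steady-state Stokes shift between
absorption and emission maxima.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import optimize

from .io import DelaySpectraSurface, KineticTrace

#: design-matrix condition number beyond which sub-bands are unresolvable
MAX_SUBBAND_CONDITION = 1e8


@dataclasses.dataclass(frozen=True)
class Subband:
    """One fixed-position component of a solvent band."""

    label: str
    center: float
    fwhm: float

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError("sub-band fwhm must be positive")


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    """A band window and, optionally, its sub-band decomposition."""

    label: str
    center: float
    window_halfwidth: float
    subbands: tuple = ()

    def __post_init__(self):
        if not self.window_halfwidth > 0:
            raise ValueError("window_halfwidth must be positive")
        subbands = tuple(
            sb if isinstance(sb, Subband) else Subband(*sb) for sb in self.subbands
        )
        lo = self.center - self.window_halfwidth
        hi = self.center + self.window_halfwidth
        for sb in subbands:
            if not lo <= sb.center <= hi:
                raise ValueError(
                    f"sub-band {sb.label!r} at {sb.center:g} lies outside the "
                    f"window [{lo:g}, {hi:g}]"
                )
        object.__setattr__(self, "subbands", subbands)


@dataclasses.dataclass
class PeakTrack:
    """Per-delay Gaussian-fit parameters of one band."""

    delays: np.ndarray
    center: np.ndarray
    width: np.ndarray
    amplitude: np.ndarray
    success: np.ndarray

    def good(self) -> "tuple[np.ndarray, np.ndarray]":
        """(delays, centers) restricted to successful fits."""
        return self.delays[self.success], self.center[self.success]


def _gauss_line(x, amp, center, fwhm, b0, b1):
    return amp * np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2) + b0 + b1 * x


def track_peak(surface: DelaySpectraSurface, band: BandDefinition) -> PeakTrack:
    """Track a band center through delay by per-spectrum Gaussian fits.

    Within the band window, each delay's spectrum is fitted with a Gaussian
    plus a straight-line baseline, initialized at the extremum of the
    line-detrended data. Delays where the fitted amplitude is below 3× the
    local residual RMS (or where the fit fails or runs out of the window) are
    flagged ``success=False`` and excluded from downstream shift fits.
    """
    lo = band.center - band.window_halfwidth
    hi = band.center + band.window_halfwidth
    mask = (surface.axis >= lo) & (surface.axis <= hi)
    if mask.sum() < 6:
        raise ValueError(
            f"window [{lo:g}, {hi:g}] covers only {int(mask.sum())} axis points; "
            "need at least 6"
        )
    x = surface.axis[mask]
    n = surface.delays.size
    centers = np.full(n, np.nan)
    widths = np.full(n, np.nan)
    amps = np.full(n, np.nan)
    success = np.zeros(n, dtype=bool)
    for j in range(n):
        y = surface.values[mask, j]
        # endpoint line as detrend for the initial guess
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
        line = y[0] + slope * (x - x[0])
        r = y - line
        i0 = int(np.argmax(np.abs(r)))
        p0 = (r[i0], x[i0], band.window_halfwidth / 2.0, y[0] - slope * x[0], slope)
        try:
            with warnings.catch_warnings():
                # noise-free spectra give singular covariance; unused here
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(_gauss_line, x, y, p0=p0, maxfev=4000)
        except (RuntimeError, ValueError):
            continue
        amp, center, fwhm = popt[0], popt[1], abs(popt[2])
        if not lo <= center <= hi:
            continue
        if not 0 < fwhm <= 3.0 * band.window_halfwidth:
            continue
        resid = y - _gauss_line(x, *popt)
        noise = float(np.sqrt(np.mean(resid**2)))
        if abs(amp) < 3.0 * noise or amp == 0.0:
            continue
        centers[j], widths[j], amps[j] = center, fwhm, amp
        success[j] = True
    return PeakTrack(
        delays=surface.delays.copy(),
        center=centers,
        width=widths,
        amplitude=amps,
        success=success,
    )


def subband_amplitudes(
    surface: DelaySpectraSurface, band: BandDefinition
) -> "list[KineticTrace]":
    """Decompose a band window into fixed-shape sub-band amplitude courses.

    For every delay, the window spectrum is solved by linear least squares
    against fixed-center, fixed-width Gaussian profiles plus a straight-line
    baseline; only the amplitudes are free. Returns one
    :class:`~fsrskit.io.KineticTrace` per sub-band, in definition order. The
    solve is exactly linear in the surface.
    """
    if len(band.subbands) < 2:
        raise ValueError("need at least 2 sub-bands to decompose")
    lo = band.center - band.window_halfwidth
    hi = band.center + band.window_halfwidth
    mask = (surface.axis >= lo) & (surface.axis <= hi)
    n_cols = len(band.subbands) + 2
    if mask.sum() < n_cols:
        raise ValueError("window too narrow for the number of sub-bands")
    x = surface.axis[mask]
    x_norm = (x - x.mean()) / max(np.ptp(x) / 2.0, 1.0)
    cols = [
        np.exp(-4.0 * np.log(2.0) * ((x - sb.center) / sb.fwhm) ** 2)
        for sb in band.subbands
    ]
    design = np.column_stack(cols + [np.ones_like(x), x_norm])
    cond = float(np.linalg.cond(design))
    if cond > MAX_SUBBAND_CONDITION:
        raise ValueError(
            f"sub-bands unresolvable: design condition number {cond:.3g} "
            f"exceeds {MAX_SUBBAND_CONDITION:g}"
        )
    coef, *_ = np.linalg.lstsq(design, surface.values[mask, :], rcond=None)
    return [
        KineticTrace(surface.delays, coef[k], label=sb.label)
        for k, sb in enumerate(band.subbands)
    ]


def stokes_shift(lambda_abs_nm: float, lambda_em_nm: float) -> float:
    """Stokes shift in cm⁻¹ between absorption and emission maxima in nm.

    Computed as 10⁷·(1/λ_abs − 1/λ_em); positive when emission is red of
    absorption, and antisymmetric under exchanging the two wavelengths.
    """
    if not (lambda_abs_nm > 0 and lambda_em_nm > 0):
        raise ValueError("wavelengths must be positive")
    return 1e7 * (1.0 / lambda_abs_nm - 1.0 / lambda_em_nm)
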