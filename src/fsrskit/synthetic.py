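"""Synthetic spectro-temporal surfaces with known ground truth.

This module generates transient-absorption (TA) and femtosecond
stimulated-Raman (FSRS) surfaces with the statistical and kinetic structure
the analysis pipeline assumes: multiexponential population kinetics convolved
with a Gaussian instrument response, Gaussian/Lorentzian spectral bands with
optional bi-exponential center drift, wavelength-dependent time zero (chirp),
a dispersive coherent artifact near time zero, broad fluorescence
backgrounds, and additive Gaussian noise.

Three named presets encode the photophysics of curcumin published for
chloroform and DMSO solutions: the kinetic time constants, band positions,
peak-drift and solvent sub-band parameters are the printed experimental
values, so parameter-recovery tests are anchored to real numbers. Band
amplitudes are unit-order design choices recorded in the presets themselves.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from numpy.polynomial import polynomial as P

from .io import DelaySpectraSurface
from .kinetics import CPMArtifact, IRFModel, conv_exp, cpm_signal, irf_step

logger = logging.getLogger(__name__)

PRESET_NAMES = ("curcumin_chloroform_ta", "curcumin_dmso_ta", "curcumin_dmso_fsrs")

# IRF width: sub-50-fs instruments; FWHM 50 fs -> sigma 0.021 ps
DEFAULT_IRF_SIGMA = 0.021
# default band FWHMs (spectral units): solute Raman, solvent Raman, TA
FWHM_SOLUTE_CM = 15.0
FWHM_SOLVENT_CM = 20.0
FWHM_SUBBAND_CM = 14.0
FWHM_TA_NM = 40.0


@dataclasses.dataclass(frozen=True)
class KineticScheme:
    """Set of first-order kinetic components.

    ``components`` is a tuple of (tau_ps, label). ``parallel`` components are
    independent decays (decay-associated-spectra convention); ``sequential``
    components form an ordered compartment chain with first-order transfer.
    """

    components: tuple
    mode: str = "parallel"

    def __post_init__(self):
        if not self.components:
            raise ValueError("at least one kinetic component is required")
        taus = [c[0] for c in self.components]
        labels = [c[1] for c in self.components]
        if any(not tau > 0 for tau in taus):
            raise ValueError("all time constants must be positive")
        if len(set(labels)) != len(labels):
            raise ValueError("component labels must be unique")
        if self.mode not in ("parallel", "sequential"):
            raise ValueError(f"mode must be parallel or sequential, got {self.mode!r}")
        object.__setattr__(self, "components", tuple((float(t), str(l)) for t, l in self.components))

    @property
    def taus(self) -> tuple:
        return tuple(c[0] for c in self.components)

    @property
    def labels(self) -> tuple:
        return tuple(c[1] for c in self.components)

    def __len__(self) -> int:
        return len(self.components)


@dataclasses.dataclass(frozen=True)
class SpectralBand:
    """One spectral band and its kinetic amplitudes.

    ``amplitude_per_component`` couples the band to each scheme component
    (decay-associated amplitudes). ``static_amplitude`` is an always-on
    contribution (ground-state Raman intensity, present before time zero);
    ``step_amplitude`` multiplies the IRF-convolved step (long-lived
    photoproduct plateaus). ``center_shift`` = (delta1, tau_s1, delta2,
    tau_s2) adds a bi-exponential drift to the band center:
    center(t) = center + delta1·c(t; tau_s1) + delta2·c(t; tau_s2), so
    ``center`` is the late-time (relaxed) position.
    """

    center: float
    fwhm: float
    amplitude_per_component: tuple
    shape: str = "gaussian"
    center_shift: tuple | None = None
    static_amplitude: float = 0.0
    step_amplitude: float = 0.0
    label: str = ""

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"shape must be gaussian or lorentzian, got {self.shape!r}")
        object.__setattr__(
            self, "amplitude_per_component",
            tuple(float(a) for a in self.amplitude_per_component),
        )
        if self.center_shift is not None:
            cs = tuple(float(v) for v in self.center_shift)
            if len(cs) != 4:
                raise ValueError("center_shift must be (delta1, tau_s1, delta2, tau_s2)")
            if cs[1] <= 0 or cs[3] <= 0:
                raise ValueError("center_shift time constants must be positive")
            object.__setattr__(self, "center_shift", cs)


@dataclasses.dataclass(frozen=True)
class InstrumentModel:
    """Time zero, Gaussian IRF width, probe chirp, and coherent artifact.

    ``chirp_coeffs`` are polynomial coefficients (lowest order first, degree
    <= 3) of the time-zero offset versus spectral position: the effective time
    zero at position ν is ``t0 + Σ_k c_k ν^k``.
    """

    t0: float = 0.0
    irf_sigma: float = DEFAULT_IRF_SIGMA
    chirp_coeffs: tuple = ()
    cpm: CPMArtifact | None = None

    def __post_init__(self):
        if not self.irf_sigma > 0:
            raise ValueError("irf_sigma must be positive")
        coeffs = tuple(float(c) for c in self.chirp_coeffs)
        if len(coeffs) > 4:
            raise ValueError("chirp polynomial degree must be <= 3")
        object.__setattr__(self, "chirp_coeffs", coeffs)

    @property
    def irf(self) -> IRFModel:
        return IRFModel(t0=self.t0, sigma=self.irf_sigma)

    def chirp_shift(self, positions) -> np.ndarray:
        """Time-zero offset (ps) at each spectral position."""
        positions = np.asarray(positions, dtype=float)
        if not self.chirp_coeffs:
            return np.zeros_like(positions)
        shift = P.polyval(positions, np.asarray(self.chirp_coeffs))
        if not np.all(np.isfinite(shift)):
            raise ValueError("chirp polynomial is non-finite over the axis")
        return shift


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise; identical seed gives identical draws."""

    additive_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be non-negative")


@dataclasses.dataclass(frozen=True)
class SyntheticPreset:
    """A named bundle of scheme, bands, instrument, and axis grids."""

    name: str
    scheme: KineticScheme
    bands: tuple
    instrument: InstrumentModel
    axis: np.ndarray
    axis_kind: str
    delays: np.ndarray

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        delays = np.asarray(self.delays, dtype=float)
        axis.setflags(write=False)
        delays.setflags(write=False)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "bands", tuple(self.bands))
        for band in self.bands:
            if len(band.amplitude_per_component) != len(self.scheme):
                raise ValueError(
                    f"band {band.label!r}: amplitude vector length "
                    f"{len(band.amplitude_per_component)} != "
                    f"{len(self.scheme)} scheme components"
                )


# ---------------------------------------------------------------------------
# population kinetics
# ---------------------------------------------------------------------------

def concentration_profiles(scheme: KineticScheme, instrument, delays) -> np.ndarray:
    """Component populations versus delay, IRF-convolved.

    Returns an array of shape (n_components, n_delays). In ``parallel`` mode
    each row is the convolved exponential of that component; in ``sequential``
    mode rows are the compartment populations of the first-order chain,
    assembled from convolved-exponential closed forms (Bateman solution).
    ``instrument`` may be an :class:`InstrumentModel` or an IRF model.
    """
    delays = np.asarray(delays, dtype=float)
    if delays.ndim != 1 or delays.size == 0:
        raise ValueError("delays must be a non-empty 1-D array")
    if np.any(np.diff(delays) <= 0):
        raise ValueError("delays must be strictly increasing")
    irf = instrument.irf if isinstance(instrument, InstrumentModel) else instrument
    taus = np.asarray(scheme.taus)
    if scheme.mode == "parallel":
        return np.vstack([conv_exp(delays, tau, irf) for tau in taus])
    # sequential: Bateman chain with unit initial population in compartment 1
    for i in range(len(taus)):
        for j in range(i + 1, len(taus)):
            if abs(taus[i] - taus[j]) <= 1e-9 * max(taus[i], taus[j]):
                raise ValueError(
                    "sequential scheme with (near-)duplicate time constants "
                    "is degenerate; perturb the taus"
                )
    rates = 1.0 / taus
    basis = [conv_exp(delays, tau, irf) for tau in taus]
    out = np.zeros((len(taus), delays.size))
    for j in range(len(taus)):
        prefactor = np.prod(rates[:j])
        for m in range(j + 1):
            denom = np.prod([rates[l] - rates[m] for l in range(j + 1) if l != m])
            out[j] += basis[m] / denom
        out[j] *= prefactor
    return out


# ---------------------------------------------------------------------------
# surface generation
# ---------------------------------------------------------------------------

def _band_profile(band: SpectralBand, axis, center):
    """Band line shape evaluated on ``axis`` for (possibly 2-D) center."""
    x = np.asarray(axis, dtype=float)
    if np.ndim(center) == 0:
        dev = x - center
    elif np.ndim(center) == 1:  # center varies with delay only
        dev = x[:, None] - np.asarray(center)[None, :]
    else:  # center varies with channel and delay (chirped drift)
        dev = x[:, None] - center
    if band.shape == "gaussian":
        profile = np.exp(-4.0 * np.log(2.0) * (dev / band.fwhm) ** 2)
        # flush denormal wings: keeps the surface exactly linear in amplitudes
        return np.where(profile < 1e-290, 0.0, profile)
    return 1.0 / (1.0 + 4.0 * (dev / band.fwhm) ** 2)


def generate_surface(
    preset: SyntheticPreset, noise: NoiseModel | None = None
) -> DelaySpectraSurface:
    """Render a preset into a :class:`DelaySpectraSurface`.

    The noise-free surface is the sum over bands of line shape × kinetic
    amplitude course, plus the coherent artifact; it is exactly linear in the
    band amplitudes and deterministic. Bands whose center lies outside the
    spectral axis are skipped with a warning. Noise is added from the seeded
    generator in ``noise``; ``additive_sigma = 0`` draws nothing.
    """
    axis = np.asarray(preset.axis, dtype=float)
    delays = np.asarray(preset.delays, dtype=float)
    if axis.size == 0 or delays.size == 0:
        raise ValueError("axes must be non-empty")
    if np.any(np.diff(axis) <= 0) or np.any(np.diff(delays) <= 0):
        raise ValueError("axes must be strictly increasing")
    inst = preset.instrument
    irf = inst.irf
    chirped = any(c != 0.0 for c in inst.chirp_coeffs)
    if chirped:
        shift = inst.chirp_shift(axis)
        # effective local time: t - chirp(ν); shape (n_axis, n_delays)
        t_eff = delays[None, :] - shift[:, None]
    else:
        t_eff = delays  # 1-D; broadcasting handles the rest

    taus = preset.scheme.taus
    if preset.scheme.mode == "parallel":
        pops = [conv_exp(t_eff, tau, irf) for tau in taus]
    else:
        if chirped:
            raise NotImplementedError(
                "sequential schemes with probe chirp are not supported"
            )
        pops = list(concentration_profiles(preset.scheme, inst, delays))
    step = irf_step(t_eff, irf)

    values = np.zeros((axis.size, delays.size))
    for band in preset.bands:
        if not (axis[0] <= band.center <= axis[-1]):
            msg = (
                f"band {band.label or band.center!r} at {band.center:g} lies "
                f"outside the spectral axis [{axis[0]:g}, {axis[-1]:g}]; skipped"
            )
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            logger.warning(msg)
            continue
        course = band.static_amplitude + band.step_amplitude * step
        for amp, pop in zip(band.amplitude_per_component, pops):
            if amp != 0.0:
                course = course + amp * pop
        if band.center_shift is not None:
            d1, ts1, d2, ts2 = band.center_shift
            center = (
                band.center
                + d1 * conv_exp(t_eff, ts1, irf)
                + d2 * conv_exp(t_eff, ts2, irf)
            )
            profile = _band_profile(band, axis, center)
            values += profile * np.atleast_2d(course)
        else:
            profile = _band_profile(band, axis, band.center)
            if np.ndim(course) == 1:
                values += profile[:, None] * course[None, :]
            else:
                values += profile[:, None] * course
    if inst.cpm is not None:
        artifact = cpm_signal(t_eff, irf, inst.cpm)
        values += np.atleast_2d(artifact)

    meta = {"preset": preset.name, "axis_kind": preset.axis_kind}
    if noise is not None and noise.additive_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        values = values + rng.normal(0.0, noise.additive_sigma, values.shape)
        meta["noise_sigma"] = f"{noise.additive_sigma:g}"
        meta["noise_seed"] = str(noise.seed)
    return DelaySpectraSurface(axis, delays, values, preset.axis_kind, meta)


def peak_signal(preset: SyntheticPreset) -> float:
    """Maximum |noise-free signal| of a preset; used to set SNR-based noise."""
    return float(np.max(np.abs(generate_surface(preset).values)))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _ta_delays() -> np.ndarray:
    early = np.arange(-1.0, 3.0, 0.04)
    late = np.geomspace(3.0, 800.0, 60)
    return np.concatenate([early, late])


def _fsrs_delays() -> np.ndarray:
    pre = np.arange(-5.0, -1.0, 0.5)
    early = np.arange(-1.0, 1.0, 0.01)
    mid = np.arange(1.0, 3.0, 0.05)
    late = np.geomspace(3.0, 100.0, 40)
    return np.concatenate([pre, early, mid, late])


def _chloroform_ta() -> SyntheticPreset:
    # time constants 0.79 / 6.3 / 210 ps: vibrational relaxation in the LE
    # state, enol S1 decay, triplet formation
    scheme = KineticScheme(
        components=((0.79, "vib_relax_le"), (6.3, "s1_decay"), (210.0, "triplet_formation")),
    )
    bands = (
        SpectralBand(center=485.0, fwhm=FWHM_TA_NM, label="se_485",
                     amplitude_per_component=(-0.15, -0.30, -0.50)),
        SpectralBand(center=580.0, fwhm=FWHM_TA_NM, label="esa_580",
                     amplitude_per_component=(0.30, 0.25, 0.60)),
        # triplet ESA rises with the 210 ps component toward a plateau
        SpectralBand(center=765.0, fwhm=FWHM_TA_NM, label="esa_triplet_765",
                     amplitude_per_component=(0.0, 0.0, -0.15), step_amplitude=0.15),
    )
    return SyntheticPreset(
        name="curcumin_chloroform_ta",
        scheme=scheme,
        bands=bands,
        instrument=InstrumentModel(),
        axis=np.arange(440.0, 800.0 + 1e-9, 2.5),
        axis_kind="wavelength_nm",
        delays=_ta_delays(),
    )


def _dmso_ta() -> SyntheticPreset:
    # 0.11 / 1.2 / 5.8 / 178 ps: LE vibrational relaxation, ICT, vibrational
    # relaxation in the CT state, CT-state lifetime
    scheme = KineticScheme(
        components=(
            (0.11, "vib_relax_le"),
            (1.2, "ict"),
            (5.8, "vib_relax_ct"),
            (178.0, "ct_lifetime"),
        ),
    )
    bands = (
        SpectralBand(center=460.0, fwhm=FWHM_TA_NM, label="le_se_460",
                     amplitude_per_component=(-0.45, -0.60, -0.05, -0.03)),
        SpectralBand(center=495.0, fwhm=FWHM_TA_NM, label="ct_esa_495",
                     amplitude_per_component=(0.15, -0.45, 0.25, 0.65)),
        SpectralBand(center=595.0, fwhm=FWHM_TA_NM, label="le_esa_595",
                     amplitude_per_component=(0.50, 0.75, 0.08, 0.04)),
        SpectralBand(center=660.0, fwhm=FWHM_TA_NM, label="ct_se_660",
                     amplitude_per_component=(-0.10, 0.35, -0.20, -0.55)),
    )
    return SyntheticPreset(
        name="curcumin_dmso_ta",
        scheme=scheme,
        bands=bands,
        instrument=InstrumentModel(),
        axis=np.arange(430.0, 780.0 + 1e-9, 2.5),
        axis_kind="wavelength_nm",
        delays=_ta_delays(),
    )


def _dmso_fsrs() -> SyntheticPreset:
    # one parallel scheme holding the union of the FSRS time constants:
    # 0.03 ps inter-sub-band reversal, 0.72 ps ICT, 1.3 ps ground-band
    # solvation response, 4.4 ps solvent relaxation, 7.1/8.4 ps ground-band
    # recoveries, 163 ps CT population decay
    scheme = KineticScheme(
        components=(
            (0.03, "hb_reversal"),
            (0.72, "ict"),
            (1.3, "gs_solvation"),
            (4.4, "solvent_relax"),
            (7.1, "gs_recovery_cc"),
            (8.4, "gs_recovery_8a"),
            (163.0, "ct_lifetime"),
        ),
    )

    def amps(**kwargs) -> tuple:
        order = ("hb_reversal", "ict", "gs_solvation", "solvent_relax",
                 "gs_recovery_cc", "gs_recovery_8a", "ct_lifetime")
        return tuple(float(kwargs.get(k, 0.0)) for k in order)

    bands = (
        # --- solvent ν_CSC sub-bands: free 657 converts to H-bonded 678 ---
        SpectralBand(center=657.0, fwhm=FWHM_SUBBAND_CM, label="csc_free_657",
                     static_amplitude=0.80,
                     amplitude_per_component=amps(hb_reversal=-0.30, ict=-0.18,
                                                  solvent_relax=-0.12, ct_lifetime=-0.10)),
        SpectralBand(center=678.0, fwhm=FWHM_SUBBAND_CM, label="csc_hb_678",
                     static_amplitude=0.60,
                     amplitude_per_component=amps(hb_reversal=0.30, ict=-0.15,
                                                  solvent_relax=-0.10, ct_lifetime=-0.08)),
        SpectralBand(center=697.0, fwhm=FWHM_SOLVENT_CM, label="csc_antisym_697",
                     static_amplitude=0.40,
                     amplitude_per_component=amps(ict=-0.08, solvent_relax=-0.05,
                                                  ct_lifetime=-0.03)),
        # --- solvent ν_S=O sub-bands: H-bonded 1027 converts to free 1058 ---
        SpectralBand(center=1027.0, fwhm=FWHM_SUBBAND_CM, label="so_hb_1027",
                     static_amplitude=0.60,
                     amplitude_per_component=amps(hb_reversal=-0.25, ict=-0.12,
                                                  solvent_relax=-0.08, ct_lifetime=-0.06)),
        SpectralBand(center=1058.0, fwhm=FWHM_SUBBAND_CM, label="so_free_1058",
                     static_amplitude=0.70,
                     amplitude_per_component=amps(hb_reversal=0.25, ict=-0.15,
                                                  solvent_relax=-0.10, ct_lifetime=-0.08)),
        # --- solvent δ_CH3 ---
        SpectralBand(center=1419.0, fwhm=FWHM_SOLVENT_CM, label="dch3_1419",
                     static_amplitude=0.90,
                     amplitude_per_component=amps(solvent_relax=-0.05)),
        # --- curcumin ground-state bands ---
        SpectralBand(center=1160.0, fwhm=FWHM_SOLUTE_CM, label="gs_1160",
                     static_amplitude=0.50, amplitude_per_component=amps()),
        SpectralBand(center=1186.0, fwhm=FWHM_SOLUTE_CM, label="gs_1186",
                     static_amplitude=0.45, amplitude_per_component=amps()),
        SpectralBand(center=1596.0, fwhm=FWHM_SOLUTE_CM, label="gs_nu8a_1596",
                     static_amplitude=0.80,
                     amplitude_per_component=amps(gs_recovery_8a=-0.35)),
        # ν_C=C,C=O ground-state band, stationary
        SpectralBand(center=1631.0, fwhm=FWHM_SOLUTE_CM, label="gs_cc_co_1631",
                     static_amplitude=1.00, amplitude_per_component=amps()),
        # ν_C=C,C=O depletion: negative band recovering with 1.3 + 7.1 ps,
        # center red-shifting 1633 -> 1626 cm^-1 with (0.23, 9.0) ps
        SpectralBand(center=1626.0, fwhm=FWHM_SOLUTE_CM, label="cc_co_depletion",
                     center_shift=(4.0, 0.23, 3.0, 9.0),
                     amplitude_per_component=amps(gs_solvation=-0.30,
                                                  gs_recovery_cc=-0.35)),
        # --- curcumin excited-state bands ---
        SpectralBand(center=767.0, fwhm=FWHM_SOLUTE_CM, label="le_767",
                     amplitude_per_component=amps(hb_reversal=0.10, ict=0.35,
                                                  ct_lifetime=0.02)),
        SpectralBand(center=815.0, fwhm=FWHM_SOLUTE_CM, label="le_815",
                     amplitude_per_component=amps(ict=0.30, ct_lifetime=0.02)),
        SpectralBand(center=1254.0, fwhm=FWHM_SOLUTE_CM, label="le_1254",
                     amplitude_per_component=amps(ict=0.25)),
        SpectralBand(center=1330.0, fwhm=FWHM_SOLUTE_CM, label="le_1330",
                     amplitude_per_component=amps(hb_reversal=0.08, ict=0.28)),
        SpectralBand(center=1485.0, fwhm=FWHM_SOLUTE_CM, label="ct_1485",
                     amplitude_per_component=amps(ict=-0.20, gs_recovery_cc=0.15,
                                                  ct_lifetime=0.30)),
        SpectralBand(center=1564.0, fwhm=FWHM_SOLUTE_CM, label="le_1564",
                     amplitude_per_component=amps(hb_reversal=0.06, ict=0.30,
                                                  ct_lifetime=0.03)),
        # --- broad fluorescence background following the CT population ---
        SpectralBand(center=1350.0, fwhm=1600.0, label="fluorescence_background",
                     amplitude_per_component=amps(ct_lifetime=0.50)),
    )
    return SyntheticPreset(
        name="curcumin_dmso_fsrs",
        scheme=scheme,
        bands=bands,
        # derivative bases peak at ~1/sigma and ~1/sigma^2; coefficients are
        # scaled so the rendered artifact is ~0.1-0.2 signal units
        instrument=InstrumentModel(cpm=CPMArtifact(a0=0.05, a1=0.005, a2=5e-5)),
        axis=np.arange(600.0, 1700.0 + 1e-9, 2.0),
        axis_kind="raman_shift_cm",
        delays=_fsrs_delays(),
    )


_BUILDERS = {
    "curcumin_chloroform_ta": _chloroform_ta,
    "curcumin_dmso_ta": _dmso_ta,
    "curcumin_dmso_fsrs": _dmso_fsrs,
}


def preset(name: str) -> SyntheticPreset:
    """Return the fully populated, immutable preset for ``name``."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None
    return builder()
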