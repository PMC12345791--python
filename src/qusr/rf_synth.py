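"""Synthetic RF ultrasound generation.

Point-scatterer fields are convolved per scan line with a Gaussian-enveloped
cosine pulse (no diffraction modelling).  Scatterers carry a Rayleigh (f^2
amplitude) response multiplied by a Gaussian form factor for their effective
radius; frequency-dependent attenuation is applied in depth strata.  The
module also builds reference phantoms of known backscatter/attenuation and
two-timepoint patient cohorts with known response labels, plus a purely
feature-level cohort generator for classifier tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .spectra import RFFrame

DEFAULT_SOUND_SPEED = 1540.0  # m/s
DEFAULT_SAMPLING_RATE = 40.0  # MHz
FORM_FACTOR_COEFF = 0.827  # Gaussian form factor: FF(f) = exp(-0.827 k^2 a^2)


@dataclass(frozen=True)
class PulseModel:
    """Pulse-echo system model: Gaussian-enveloped cosine pulse.

    Defaults emulate a 6.5 MHz linear-array transducer with a 3.0-8.5 MHz
    usable band sampled at 40 MHz.
    """

    centre_frequency: float = 6.5  # MHz
    fractional_bandwidth: float = 0.85
    sampling_rate: float = DEFAULT_SAMPLING_RATE  # MHz
    sound_speed: float = DEFAULT_SOUND_SPEED  # m/s

    def __post_init__(self) -> None:
        if self.centre_frequency <= 0:
            raise ValueError("centre_frequency must be positive")
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError("fractional_bandwidth must lie in (0, 2)")
        if self.sampling_rate <= 4.0 * self.centre_frequency:
            raise ValueError(
                "sampling_rate must exceed 4 x centre_frequency (Nyquist margin)"
            )

    @property
    def band(self) -> tuple[float, float]:
        half = 0.5 * self.fractional_bandwidth * self.centre_frequency
        return (self.centre_frequency - half, self.centre_frequency + half)

    @property
    def sound_speed_mm_us(self) -> float:
        return self.sound_speed / 1000.0

    @property
    def envelope_sigma_us(self) -> float:
        # -6 dB (FWHM) spectral width = fractional_bandwidth * fc
        sigma_f = self.fractional_bandwidth * self.centre_frequency / 2.3548200450309493
        return 1.0 / (2.0 * np.pi * sigma_f)

    def waveform(self) -> np.ndarray:
        """Sampled pulse, symmetric about its centre index ``len // 2``."""
        sigma = self.envelope_sigma_us
        half = int(np.ceil(4.0 * sigma * self.sampling_rate))
        t = np.arange(-half, half + 1) / self.sampling_rate
        return np.cos(2.0 * np.pi * self.centre_frequency * t) * np.exp(
            -0.5 * (t / sigma) ** 2
        )


@dataclass(frozen=True)
class ScattererField:
    """Random point-scatterer medium over a rectangular field of view.

    positions: (N, 2) array of (axial mm, lateral mm); amplitudes:
    dimensionless reflectivity; effective_radius_um sets the Gaussian
    form factor of every scatterer.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    depth_mm: float
    width_mm: float
    effective_radius_um: float = 0.0
    spacing_mode: str = "random"
    spacing_mm: float | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        amp = np.asarray(self.amplitudes, dtype=np.float64).ravel()
        if pos.shape[0] != amp.shape[0]:
            raise ValueError("positions and amplitudes length mismatch")
        if pos.size and (
            pos[:, 0].min() < 0
            or pos[:, 0].max() > self.depth_mm
            or pos[:, 1].min() < 0
            or pos[:, 1].max() > self.width_mm
        ):
            raise ValueError("scatterer positions outside declared field of view")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    @property
    def number_density(self) -> float:
        """Scatterers per mm^2."""
        area = self.depth_mm * self.width_mm
        return self.n_scatterers / area if area > 0 else 0.0


def random_field(
    depth_mm: float,
    width_mm: float,
    density_per_mm2: float,
    rng: np.random.Generator,
    amp_std: float = 1.0,
    effective_radius_um: float = 0.0,
) -> ScattererField:
    """Fully developed speckle medium: uniform positions, Gaussian amplitudes."""
    n = rng.poisson(density_per_mm2 * depth_mm * width_mm)
    pos = np.column_stack(
        [rng.uniform(0, depth_mm, n), rng.uniform(0, width_mm, n)]
    )
    amps = rng.normal(0.0, amp_std, n)
    return ScattererField(pos, amps, depth_mm, width_mm, effective_radius_um)


def quasi_periodic_field(
    depth_mm: float,
    width_mm: float,
    density_per_mm2: float,
    period_mm: float,
    rng: np.random.Generator,
    jitter_mm: float = 0.02,
    amp_std: float = 1.0,
    effective_radius_um: float = 0.0,
) -> ScattererField:
    """Scatterers on an axially periodic comb (period ``period_mm``) with
    Gaussian positional jitter — produces spectral ripple at c/(2 d)."""
    n = rng.poisson(density_per_mm2 * depth_mm * width_mm)
    n_periods = int(depth_mm / period_mm)
    k = rng.integers(0, n_periods, n)
    z = np.clip(k * period_mm + 0.5 * period_mm + rng.normal(0, jitter_mm, n), 0, depth_mm)
    x = rng.uniform(0, width_mm, n)
    amps = rng.normal(0.0, amp_std, n)
    return ScattererField(
        np.column_stack([z, x]),
        amps,
        depth_mm,
        width_mm,
        effective_radius_um,
        spacing_mode="quasi-periodic",
        spacing_mm=period_mm,
    )


def clustered_field(
    depth_mm: float,
    width_mm: float,
    density_per_mm2: float,
    rng: np.random.Generator,
    cluster_fraction: float = 0.5,
    cluster_std_mm: float = 0.4,
    clusters_per_mm2: float = 0.05,
    amp_std: float = 1.0,
    effective_radius_um: float = 0.0,
) -> ScattererField:
    """Partially aggregated medium: a fraction of scatterers drawn around
    random cluster centres, the rest uniform."""
    n = rng.poisson(density_per_mm2 * depth_mm * width_mm)
    n_clustered = int(round(cluster_fraction * n))
    n_uniform = n - n_clustered
    pos_u = np.column_stack(
        [rng.uniform(0, depth_mm, n_uniform), rng.uniform(0, width_mm, n_uniform)]
    )
    n_centres = max(1, rng.poisson(clusters_per_mm2 * depth_mm * width_mm))
    centres = np.column_stack(
        [rng.uniform(0, depth_mm, n_centres), rng.uniform(0, width_mm, n_centres)]
    )
    idx = rng.integers(0, n_centres, n_clustered)
    pos_c = centres[idx] + rng.normal(0, cluster_std_mm, (n_clustered, 2))
    pos = np.vstack([pos_u, pos_c])
    pos[:, 0] = np.clip(pos[:, 0], 0, depth_mm)
    pos[:, 1] = np.clip(pos[:, 1], 0, width_mm)
    amps = rng.normal(0.0, amp_std, n)
    return ScattererField(pos, amps, depth_mm, width_mm, effective_radius_um)


def _scatterer_response_db_free(
    f: np.ndarray, centre_frequency: float, radius_mm: float, sound_speed_mm_us: float
) -> np.ndarray:
    """Amplitude frequency response of a scatterer: Rayleigh f^2 (normalised
    at the pulse centre frequency) times the Gaussian form-factor amplitude."""
    k = 2.0 * np.pi * f / sound_speed_mm_us  # rad/mm, f in MHz
    ff_amp = np.exp(-0.5 * FORM_FACTOR_COEFF * (k * radius_mm) ** 2)
    return (f / centre_frequency) ** 2 * ff_amp


def simulate_rf_frame(
    fieldspec: ScattererField,
    pulse: PulseModel,
    attenuation: float = 0.0,
    *,
    n_lines: int = 256,
    line_pitch_mm: float = 0.23,
    depth_mm: float | None = None,
    n_depth_bins: int = 32,
    system_gain: Callable[[np.ndarray], np.ndarray] | None = None,
    gain_db: float = 0.0,
) -> RFFrame:
    """Simulate one RF frame by 1-D per-line convolution.

    Scatterers are binned to the nearest scan line; sub-sample echo delays are
    realised by linear interpolation onto the sample grid.  Attenuation
    (one-way, dB/cm/MHz) and the scatterer frequency response are applied as
    zero-phase filters per depth stratum, so the round-trip power loss is
    ``2 * attenuation * f * z_cm`` dB.  Deterministic given the field.
    """
    if attenuation < 0:
        raise ValueError("attenuation must be non-negative")
    if depth_mm is None:
        depth_mm = fieldspec.depth_mm
    c = pulse.sound_speed_mm_us
    fs = pulse.sampling_rate
    n_samples = int(round(2.0 * depth_mm / c * fs))
    out = np.zeros((n_samples, n_lines))

    if fieldspec.n_scatterers == 0:
        warnings.warn("empty scatterer field: returning all-zero frame", stacklevel=2)
        return RFFrame(out, fs, pulse.sound_speed, line_pitch_mm)

    z = fieldspec.positions[:, 0]
    x = fieldspec.positions[:, 1]
    amps = fieldspec.amplitudes * 10.0 ** (gain_db / 20.0)
    line_idx = np.round(x / line_pitch_mm).astype(int)
    keep = (line_idx >= 0) & (line_idx < n_lines) & (z <= depth_mm)
    z, amps, line_idx = z[keep], amps[keep], line_idx[keep]

    delay = 2.0 * z / c * fs  # fractional sample index
    inside = delay < n_samples - 1
    z, amps, delay, line_idx = z[inside], amps[inside], delay[inside], line_idx[inside]
    d0 = np.floor(delay).astype(int)
    frac = delay - d0

    base = pulse.waveform()
    centre = len(base) // 2
    nfft = 1
    while nfft < 4 * len(base):
        nfft *= 2
    buf = np.zeros(nfft)
    buf[:len(base)] = base
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    radius_mm = fieldspec.effective_radius_um / 1000.0
    resp = _scatterer_response_db_free(f, pulse.centre_frequency, radius_mm, c)
    if system_gain is not None:
        resp = resp * np.asarray(system_gain(f), dtype=float)
    base_spec = np.fft.rfft(buf)

    edges = np.linspace(0.0, depth_mm, n_depth_bins + 1)
    bin_of = np.clip(np.digitize(z, edges) - 1, 0, n_depth_bins - 1)
    margin = len(base)
    for b in range(n_depth_bins):
        sel = bin_of == b
        if not np.any(sel):
            continue
        z_cm = 0.5 * (edges[b] + edges[b + 1]) / 10.0
        atten_amp = 10.0 ** (-attenuation * f * z_cm / 10.0)  # round-trip
        pulse_b = np.fft.irfft(base_spec * resp * atten_amp)[: len(base)]
        # the bin's echoes occupy a contiguous sample band: convolve only there
        s_lo = max(0, int(d0[sel].min()) - 1)
        s_hi = min(n_samples, int(d0[sel].max()) + 2)
        imp = np.zeros((s_hi - s_lo + 1, n_lines))
        np.add.at(imp, (d0[sel] - s_lo, line_idx[sel]), amps[sel] * (1 - frac[sel]))
        np.add.at(imp, (d0[sel] - s_lo + 1, line_idx[sel]), amps[sel] * frac[sel])
        conv = fftconvolve(imp[:-1], pulse_b[:, None], mode="full", axes=0)
        o_lo = s_lo - centre
        c_lo = max(0, -o_lo)
        c_hi = min(conv.shape[0], n_samples - o_lo)
        if c_hi > c_lo:
            out[o_lo + c_lo : o_lo + c_hi] += conv[c_lo:c_hi]
    return RFFrame(out, fs, pulse.sound_speed, line_pitch_mm)


@dataclass
class RFScan:
    """A volumetric acquisition: parallel RF frames at fixed plane spacing."""

    frames: list[RFFrame]
    plane_spacing_cm: float = 0.5

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class ReferencePhantom:
    """Homogeneous reference acquisition with known ground truth."""

    scan: RFScan
    attenuation: float  # dB/cm/MHz
    density_per_mm2: float
    amp_std: float
    pulse: PulseModel

    def known_bsc_db(self, f: np.ndarray) -> np.ndarray:
        """Backscatter of the phantom in simulation units: Rayleigh f^4 times
        concentration (density x mean-square reflectivity)."""
        f = np.asarray(f, dtype=float)
        with np.errstate(divide="ignore"):
            ray = 40.0 * np.log10(f / self.pulse.centre_frequency)
        return ray + 10.0 * np.log10(self.density_per_mm2 * self.amp_std**2)


def simulate_reference_phantom(
    pulse: PulseModel,
    known_attenuation: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    density_per_mm2: float = 4.0,
    amp_std: float = 1.0,
    depth_mm: float = 40.0,
    n_lines: int = 256,
    line_pitch_mm: float = 0.23,
    n_frames: int = 3,
    system_gain: Callable[[np.ndarray], np.ndarray] | None = None,
) -> ReferencePhantom:
    """Simulate a homogeneous reference phantom of known backscatter and
    attenuation, several independent frames."""
    if density_per_mm2 <= 0 or amp_std <= 0:
        raise ValueError("phantom backscatter must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    width_mm = n_lines * line_pitch_mm
    frames = []
    for _ in range(n_frames):
        fld = random_field(depth_mm, width_mm, density_per_mm2, rng, amp_std)
        frames.append(
            simulate_rf_frame(
                fld,
                pulse,
                known_attenuation,
                n_lines=n_lines,
                line_pitch_mm=line_pitch_mm,
                depth_mm=depth_mm,
                system_gain=system_gain,
            )
        )
    return ReferencePhantom(
        RFScan(frames), known_attenuation, density_per_mm2, amp_std, pulse
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSizes:
    """Week-1 microstructural shift injected into responders.

    ``amp_scale_factor`` multiplies the scatterer reflectivity spread
    (a factor g raises mean backscattered power by 20 log10 g dB);
    ``cluster_fraction``/``cluster_std_mm`` control scatterer aggregation.
    """

    amp_scale_factor: float = 1.25
    cluster_fraction_increase: float = 0.2
    cluster_std_mm: float = 0.45
    radius_factor: float = 1.12


@dataclass(frozen=True)
class FrameGeometry:
    depth_mm: float = 40.0
    n_lines: int = 256
    line_pitch_mm: float = 0.23
    n_frames: int = 3
    plane_spacing_cm: float = 0.5

    @property
    def width_mm(self) -> float:
        return self.n_lines * self.line_pitch_mm


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients: int = 100
    nonresponder_fraction: float = 0.19
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    noise_sd: float = 0.5  # per-scan acquisition gain jitter, dB
    seed: int = 0
    geometry: FrameGeometry = field(default_factory=FrameGeometry)
    pulse: PulseModel = field(default_factory=PulseModel)
    base_density_per_mm2: float = 3.0
    base_amp_std: float = 1.0
    base_radius_um: float = 35.0
    attenuation: float = 0.5  # dB/cm/MHz, both timepoints
    roi_semiaxes_mm: tuple[float, float] = (8.0, 10.0)  # axial, lateral (>=1.5 cm extent)
    heterogeneity: float = 0.25  # baseline clustered fraction (realism knob)

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise ValueError("nonresponder_fraction must lie in [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class SyntheticPatient:
    patient_id: str
    rf_week0: RFScan
    rf_week1: RFScan
    roi_masks: list[np.ndarray]  # boolean, (n_samples, n_lines) per frame
    true_label: str  # "R" or "NR"
    attenuation: float = 0.0


def cohort_labels(config: SyntheticCohortConfig) -> list[str]:
    """Deterministic label assignment: exactly round(n * fraction) NR."""
    n_nr = int(round(config.n_patients * config.nonresponder_fraction))
    if n_nr == 0 or n_nr == config.n_patients:
        warnings.warn(
            "cohort contains a single class at the requested size", stacklevel=2
        )
    labels = ["NR"] * n_nr + ["R"] * (config.n_patients - n_nr)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    perm = rng.permutation(config.n_patients)
    return [labels[i] for i in perm]


def _ellipse_mask(frame: RFFrame, centre_mm, semiaxes_mm) -> np.ndarray:
    z = (np.arange(frame.n_samples) + 0.5) * frame.axial_step_mm
    x = (np.arange(frame.n_lines) + 0.5) * frame.line_pitch
    zz, xx = np.meshgrid(z, x, indexing="ij")
    cz, cx = centre_mm
    az, ax = semiaxes_mm
    return ((zz - cz) / az) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _patient_scan(
    rng: np.random.Generator,
    config: SyntheticCohortConfig,
    density: float,
    amp_std: float,
    radius_um: float,
    cluster_fraction: float,
    cluster_std_mm: float,
) -> RFScan:
    g = config.geometry
    gain_db = rng.normal(0.0, config.noise_sd)  # per-scan acquisition jitter
    frames = []
    for _ in range(g.n_frames):
        if cluster_fraction > 0:
            fld = clustered_field(
                g.depth_mm,
                g.width_mm,
                density,
                rng,
                cluster_fraction=cluster_fraction,
                cluster_std_mm=cluster_std_mm,
                amp_std=amp_std,
                effective_radius_um=radius_um,
            )
        else:
            fld = random_field(
                g.depth_mm, g.width_mm, density, rng, amp_std, radius_um
            )
        frames.append(
            simulate_rf_frame(
                fld,
                config.pulse,
                config.attenuation,
                n_lines=g.n_lines,
                line_pitch_mm=g.line_pitch_mm,
                depth_mm=g.depth_mm,
                gain_db=gain_db,
            )
        )
    return RFScan(frames, g.plane_spacing_cm)


def simulate_patient(
    config: SyntheticCohortConfig, index: int, label: str
) -> SyntheticPatient:
    """Generate one two-timepoint patient; pure function of (config, index)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, index]))
    # patient-level nuisance on the baseline microstructure
    density = config.base_density_per_mm2 * rng.lognormal(0.0, 0.10)
    amp_std = config.base_amp_std * rng.lognormal(0.0, 0.15)
    radius = config.base_radius_um * rng.lognormal(0.0, 0.10)
    het = config.heterogeneity

    def week_drift() -> tuple[float, float, float, float]:
        # week-level microstructural wander, both classes (nuisance)
        return (
            rng.lognormal(0.0, 0.04),  # density
            rng.lognormal(0.0, 0.05),  # reflectivity spread
            rng.lognormal(0.0, 0.04),  # radius
            float(np.clip(het + rng.normal(0.0, 0.06), 0.0, 0.9)),  # clustering
        )

    e = config.effect_sizes
    d0, a0, r0, h0 = week_drift()
    week0 = _patient_scan(
        rng, config, density * d0, amp_std * a0, radius * r0, h0, e.cluster_std_mm
    )
    d1, a1, r1, h1 = week_drift()
    if label == "R":
        week1 = _patient_scan(
            rng,
            config,
            density * d1,
            amp_std * a1 * e.amp_scale_factor,
            radius * r1 * e.radius_factor,
            min(0.95, h1 + e.cluster_fraction_increase),
            e.cluster_std_mm,
        )
    else:
        week1 = _patient_scan(
            rng, config, density * d1, amp_std * a1, radius * r1, h1, e.cluster_std_mm
        )

    g = config.geometry
    centre = (
        g.depth_mm / 2.0 + rng.uniform(-2.0, 2.0),
        g.width_mm / 2.0 + rng.uniform(-4.0, 4.0),
    )
    az = config.roi_semiaxes_mm[0] * rng.uniform(0.95, 1.15)
    ax = config.roi_semiaxes_mm[1] * rng.uniform(0.95, 1.15)
    masks = [_ellipse_mask(week0.frames[k], centre, (az, ax)) for k in range(g.n_frames)]
    return SyntheticPatient(
        patient_id=f"P{index:03d}",
        rf_week0=week0,
        rf_week1=week1,
        roi_masks=masks,
        true_label=label,
        attenuation=config.attenuation,
    )


def iter_cohort(config: SyntheticCohortConfig) -> Iterator[SyntheticPatient]:
    """Stream patients one at a time (memory-friendly for large cohorts)."""
    for i, label in enumerate(cohort_labels(config)):
        yield simulate_patient(config, i, label)


def simulate_cohort(config: SyntheticCohortConfig) -> list[SyntheticPatient]:
    """Materialise the whole cohort. Identical seed => bit-identical output."""
    return list(iter_cohort(config))


# ---------------------------------------------------------------------------
# Feature-level cohort (delta-feature tables without RF simulation)
# ---------------------------------------------------------------------------

def simulate_delta_table(
    n_patients: int,
    nonresponder_fraction: float,
    effects: dict[str, float] | None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Directly generate a 31-column week1-week0 delta-feature table.

    All features are i.i.d. Gaussian noise; responders additionally receive
    the shifts in ``effects`` (feature name -> mean shift).  Used for
    classifier and feature-selection tests where the RF stage is irrelevant.
    """
    from .texture import FEATURE_NAMES  # local import: no module cycle at import time

    effects = effects or {}
    unknown = set(effects) - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"unknown feature names in effects: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_nr = int(round(n_patients * nonresponder_fraction))
    labels = np.array(["NR"] * n_nr + ["R"] * (n_patients - n_nr))
    rng.shuffle(labels)
    data = rng.normal(0.0, noise_sd, (n_patients, len(FEATURE_NAMES)))
    df = pd.DataFrame(data, columns=FEATURE_NAMES)
    is_r = labels == "R"
    for name, shift in effects.items():
        df.loc[is_r, name] += shift
    df.index = [f"P{i:03d}" for i in range(n_patients)]
    df.index.name = "patient_id"
    return df, pd.Series(labels, index=df.index, name="true_label")
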