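"""Sliding-window power-spectrum estimation and reference-phantom normalization.

RF frames are analysed with overlapping axial/lateral windows; each window's
per-line tapered periodograms are averaged (Welch-style) before conversion to
dB.  Normalization against a reference phantom of known backscatter and
attenuation cancels the system transfer function.

Attenuation convention used throughout: ``alpha`` is the one-way amplitude
attenuation coefficient in dB/cm/MHz, so the round-trip *power* spectrum at
depth ``z`` cm is reduced by ``2 * alpha * f * z`` dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class DegenerateWindowError(ValueError):
    """Raised when a spectral window contains no signal (all-zero RF)."""


@dataclass(frozen=True)
class RFFrame:
    """One 2-D frame of raw RF echo data.

    Parameters
    ----------
    samples:
        Array of shape (axial samples, scan lines).
    sampling_rate:
        Axial sampling rate in MHz.
    sound_speed:
        Assumed propagation speed in m/s.
    line_pitch:
        Lateral distance between adjacent scan lines in mm.
    """

    samples: np.ndarray
    sampling_rate: float
    sound_speed: float = 1540.0
    line_pitch: float = 0.23

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2:
            raise ValueError("samples must be 2-D (axial x lines)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("RF samples must be finite")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_step_mm(self) -> float:
        """Axial pixel size in mm (pulse-echo: c/2 per unit time)."""
        c_mm_us = self.sound_speed / 1000.0
        return c_mm_us / (2.0 * self.sampling_rate)

    @property
    def depth_mm(self) -> float:
        return self.n_samples * self.axial_step_mm


@dataclass(frozen=True)
class SpectralConfig:
    """Geometry and FFT settings for the sliding-window analysis."""

    window_length_mm: float = 2.0
    window_width_mm: float = 2.0
    axial_overlap: float = 0.8
    lateral_overlap: float = 0.8
    taper: str = "hann"
    analysis_band: tuple[float, float] = (3.0, 8.5)
    nfft_min: int = 256

    def __post_init__(self) -> None:
        if not (0.0 <= self.axial_overlap < 1.0 and 0.0 <= self.lateral_overlap < 1.0):
            raise ValueError("overlaps must lie in [0, 1)")
        f_lo, f_hi = self.analysis_band
        if not f_lo < f_hi:
            raise ValueError("analysis_band must satisfy f_lo < f_hi")
        if self.taper.lower() != "hann":
            raise ValueError(f"unsupported taper {self.taper!r}")

    def window_samples(self, frame: RFFrame) -> int:
        return max(4, int(round(self.window_length_mm / frame.axial_step_mm)))

    def window_lines(self, frame: RFFrame) -> int:
        return max(1, int(round(self.window_width_mm / frame.line_pitch)))

    def axial_stride(self, frame: RFFrame) -> int:
        return max(1, int(round(self.window_samples(frame) * (1.0 - self.axial_overlap))))

    def lateral_stride(self, frame: RFFrame) -> int:
        return max(1, int(round(self.window_lines(frame) * (1.0 - self.lateral_overlap))))

    def nfft(self, frame: RFFrame) -> int:
        n = self.nfft_min
        target = 2 * self.window_samples(frame)
        while n < target:
            n *= 2
        return n


@dataclass(frozen=True)
class WindowSpectrum:
    """Averaged power spectrum of one analysis window, in dB re 1."""

    frequencies: np.ndarray  # MHz
    power: np.ndarray  # dB
    window_centre: tuple[float, float, int]  # (axial mm, lateral mm, frame index)

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if f.shape != p.shape:
            raise ValueError("frequency and power grids must match")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def depth_cm(self) -> float:
        return self.window_centre[0] / 10.0


@dataclass(frozen=True)
class NormalizedSpectrum:
    """Sample-minus-reference spectrum with backscatter and attenuation
    compensation applied; interpretable as the sample's backscatter (dB)."""

    frequencies: np.ndarray
    ns: np.ndarray  # dB
    window_centre: tuple[float, float, int]

    def band(self, f_lo: float, f_hi: float) -> tuple[np.ndarray, np.ndarray]:
        mask = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        return self.frequencies[mask], self.ns[mask]


def compute_power_spectrum(
    frame: RFFrame,
    axial_start: int,
    line_start: int,
    config: SpectralConfig,
    frame_index: int = 0,
) -> WindowSpectrum:
    """Welch-style power spectrum of a single window.

    The window spans ``config.window_samples`` axial samples from
    ``axial_start`` and ``config.window_lines`` lines from ``line_start``.
    Each line is Hann-tapered, FFT'd (zero-padded), and magnitude-squared;
    the per-line periodograms are averaged before conversion to dB.
    """
    nax = config.window_samples(frame)
    nlin = config.window_lines(frame)
    if axial_start < 0 or axial_start + nax > frame.n_samples:
        raise ValueError("window exceeds frame axially")
    if line_start < 0 or line_start + nlin > frame.n_lines:
        raise ValueError("window exceeds frame laterally")
    seg = frame.samples[axial_start : axial_start + nax, line_start : line_start + nlin]
    if not np.any(seg):
        raise DegenerateWindowError("degenerate window: all-zero RF data")
    taper = np.hanning(nax)
    nfft = config.nfft(frame)
    spec = np.fft.rfft(seg * taper[:, None], n=nfft, axis=0)
    power = np.mean(np.abs(spec) ** 2, axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame.sampling_rate)
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    centre = (
        (axial_start + nax / 2.0) * frame.axial_step_mm,
        (line_start + nlin / 2.0) * frame.line_pitch,
        frame_index,
    )
    return WindowSpectrum(frequencies=freqs, power=power_db, window_centre=centre)


def window_grid(
    frame: RFFrame, config: SpectralConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Global sliding-window grid of a frame: (axial starts, line starts)."""
    nax = config.window_samples(frame)
    nlin = config.window_lines(frame)
    if frame.n_samples < nax or frame.n_lines < nlin:
        raise ValueError("frame smaller than one analysis window")
    axial_starts = np.arange(0, frame.n_samples - nax + 1, config.axial_stride(frame))
    line_starts = np.arange(0, frame.n_lines - nlin + 1, config.lateral_stride(frame))
    return axial_starts, line_starts


def frame_spectra(
    frame: RFFrame,
    config: SpectralConfig,
    frame_index: int = 0,
    axial_indices: np.ndarray | None = None,
    line_indices: np.ndarray | None = None,
) -> "FrameSpectra":
    """Power spectra of sliding windows tiling the frame, vectorised.

    ``axial_indices``/``line_indices`` optionally restrict computation to a
    subset of the global window grid (e.g. an ROI bounding box) while keeping
    window centres consistent with the full grid.  Returns a
    :class:`FrameSpectra` holding an (n_axial, n_lateral, n_freq) dB power
    array plus the window-centre coordinate grids.
    """
    nax = config.window_samples(frame)
    nlin = config.window_lines(frame)
    axial_starts, line_starts = window_grid(frame, config)
    if axial_indices is not None:
        axial_starts = axial_starts[np.asarray(axial_indices)]
    if line_indices is not None:
        line_starts = line_starts[np.asarray(line_indices)]
    nfft = config.nfft(frame)
    taper = np.hanning(nax)

    # restrict the line dimension to the span actually needed
    line_lo = int(line_starts.min())
    line_hi = int(line_starts.max()) + nlin
    samples = frame.samples[:, line_lo:line_hi]

    # (n_axial_pos, n_lines, nax) tapered segments -> per-line periodograms
    windows = np.ascontiguousarray(
        sliding_window_view(samples, nax, axis=0)[axial_starts]
    )
    windows *= taper[None, None, :]
    spec = np.fft.rfft(windows, n=nfft, axis=2)
    per_line = np.abs(spec) ** 2  # (n_axial_pos, n_lines_span, n_freq)

    # lateral average over nlin consecutive lines via cumulative sums
    csum = np.cumsum(per_line, axis=1)
    pad = np.zeros_like(csum[:, :1, :])
    csum = np.concatenate([pad, csum], axis=1)
    rel = line_starts - line_lo
    power = (csum[:, rel + nlin, :] - csum[:, rel, :]) / nlin

    freqs = np.fft.rfftfreq(nfft, d=1.0 / frame.sampling_rate)
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    axial_centres = (axial_starts + nax / 2.0) * frame.axial_step_mm
    lateral_centres = (line_starts + nlin / 2.0) * frame.line_pitch
    return FrameSpectra(
        frequencies=freqs,
        power_db=power_db,
        axial_centres_mm=axial_centres,
        lateral_centres_mm=lateral_centres,
        frame_index=frame_index,
    )


@dataclass
class FrameSpectra:
    """All window spectra of a frame on a regular window-centre grid."""

    frequencies: np.ndarray  # (n_freq,)
    power_db: np.ndarray  # (n_axial, n_lateral, n_freq)
    axial_centres_mm: np.ndarray
    lateral_centres_mm: np.ndarray
    frame_index: int = 0

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.power_db.shape[:2]


def normalize_spectrum(
    sample: WindowSpectrum,
    reference: WindowSpectrum,
    phantom_bsc_db: Callable[[np.ndarray], np.ndarray],
    alpha_sample: float,
    alpha_reference: float,
    depth_cm: float | None = None,
) -> NormalizedSpectrum:
    """Reference-phantom normalization of one window spectrum.

    ``ns(f) = S_dB(f) - R_dB(f) + BSC_ref_dB(f) + 2 z f (alpha_s - alpha_r)``

    with z the window-centre depth in cm and f in MHz.  The system transfer
    function, common to sample and reference, cancels exactly.
    """
    if sample.frequencies.shape != reference.frequencies.shape or not np.allclose(
        sample.frequencies, reference.frequencies
    ):
        raise ValueError("sample and reference frequency grids differ")
    if depth_cm is None:
        depth_cm = sample.depth_cm
    if depth_cm < 0:
        raise ValueError("depth must be non-negative")
    f = sample.frequencies
    comp = 2.0 * depth_cm * f * (alpha_sample - alpha_reference)
    ns = sample.power - reference.power + np.asarray(phantom_bsc_db(f), dtype=float) + comp
    return NormalizedSpectrum(frequencies=f, ns=ns, window_centre=sample.window_centre)


def normalize_frame_spectra(
    sample: FrameSpectra,
    reference_power_db: np.ndarray,
    phantom_bsc_db: Callable[[np.ndarray], np.ndarray],
    alpha_sample: float,
    alpha_reference: float,
) -> np.ndarray:
    """Vectorised normalization of a whole frame's window spectra.

    ``reference_power_db`` has shape (n_axial, n_freq): the laterally averaged
    reference-phantom spectrum per axial window position (matching grids).
    Returns the normalized spectra, shape (n_axial, n_lateral, n_freq).
    """
    if reference_power_db.shape != (sample.power_db.shape[0], sample.power_db.shape[2]):
        raise ValueError("reference spectra grid does not match sample grid")
    f = sample.frequencies
    z_cm = sample.axial_centres_mm / 10.0
    comp = 2.0 * z_cm[:, None] * f[None, :] * (alpha_sample - alpha_reference)
    bsc = np.asarray(phantom_bsc_db(f), dtype=float)
    return (
        sample.power_db
        - reference_power_db[:, None, :]
        + bsc[None, None, :]
        + comp[:, None, :]
    )


def average_reference_spectra(frames: Sequence[FrameSpectra]) -> np.ndarray:
    """Average reference-phantom window spectra laterally and across frames.

    Averaging is done in linear power; returns dB array (n_axial, n_freq).
    """
    if not frames:
        raise ValueError("no reference frames given")
    linear = [np.mean(10.0 ** (fs.power_db / 10.0), axis=1) for fs in frames]
    return 10.0 * np.log10(np.mean(linear, axis=0))
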