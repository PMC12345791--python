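"""QUS parameter estimation from normalized spectra and parametric maps.

Six parameters are estimated per analysis window:

* MBF / SS / SI — ordinary least squares line fit to the normalized dB
  spectrum over the analysis band; MBF is the fit value at band centre.
* ASD / AAC — Gaussian form-factor backscatter model: regression of
  ``ns_dB(f) - 40 log10 f`` on ``f^2``; the slope maps to the effective
  radius through ``FF(f) = exp(-0.827 k^2 a^2)``, the intercept is the
  acoustic concentration in dB (relative units).
* SAS — dominant scatterer spacing from the autocorrelation of the
  detrended linear-power spectrum: a ripple of period ``df`` MHz maps to
  a spacing ``c / (2 df)``.

A scan-level attenuation coefficient is estimated by the spectral-difference
method (depth regression of window spectra).  ``build_parametric_maps``
assembles per-window estimates into ROI-masked maps on the window-centre
grid, one map per parameter per frame, plus per-scan means.

Note on naming: SAS is sometimes expanded as "spectral average slope" in
the clinical literature, but the quantity implemented here (and used in
this lineage) is the spacing-among-scatterers estimate in mm; the naming
discrepancy is documented rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import (
    FrameSpectra,
    NormalizedSpectrum,
    SpectralConfig,
    average_reference_spectra,
    frame_spectra,
    normalize_frame_spectra,
    window_grid,
)

logger = logging.getLogger(__name__)

_DB = 10.0 / np.log(10.0)
_FF_COEFF = 0.827


@dataclass(frozen=True)
class LinearFitResult:
    SS: float  # dB/MHz
    SI: float  # dB at 0 MHz
    MBF: float  # dB at band centre
    f_centre: float  # MHz

    def __post_init__(self) -> None:
        if not np.isclose(self.MBF, self.SI + self.SS * self.f_centre, atol=1e-9):
            raise ValueError("MBF must equal SI + SS * f_centre")


@dataclass(frozen=True)
class ScattererEstimate:
    ASD: float  # um, NaN when the fit is unphysical
    AAC: float  # dB, relative units
    valid: bool


@dataclass(frozen=True)
class SASEstimate:
    SAS: float | None  # mm, None when no significant spectral periodicity
    peak_correlation: float
    ripple_period_mhz: float | None


@dataclass(frozen=True)
class AttenuationEstimate:
    alpha: float  # dB/cm/MHz

    def __post_init__(self) -> None:
        if self.alpha < 0:
            object.__setattr__(self, "alpha", 0.0)


@dataclass
class ParametricMap:
    """Per-window parameter values over a frame's ROI (NaN outside)."""

    parameter_id: str
    values: np.ndarray  # 2-D (axial windows x lateral windows)
    pixel_spacing: tuple[float, float]  # mm (axial stride, lateral stride)
    roi_mask: np.ndarray  # boolean, same shape
    frame_index: int = 0

    def finite_mask(self) -> np.ndarray:
        return self.roi_mask & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.finite_mask()]


def fit_linear_spectrum(
    ns: NormalizedSpectrum, band: tuple[float, float] | None = None
) -> LinearFitResult:
    """OLS line fit of the normalized dB spectrum over the analysis band."""
    if band is None:
        band = (float(ns.frequencies[0]), float(ns.frequencies[-1]))
    f, y = ns.band(*band)
    if f.size < 3:
        raise ValueError("need at least 3 frequency points in the analysis band")
    slope, intercept = np.polyfit(f, y, 1)
    f_c = 0.5 * (band[0] + band[1])
    return LinearFitResult(
        SS=float(slope), SI=float(intercept), MBF=float(intercept + slope * f_c), f_centre=f_c
    )


def _asd_from_slope(slope: float, sound_speed: float) -> float:
    """Map the f^2 regression slope (dB/MHz^2) to effective diameter in um."""
    c_mm_us = sound_speed / 1000.0
    k_coeff = (2.0 * np.pi / c_mm_us) ** 2  # k^2 = k_coeff * f^2, f in MHz
    a2 = -slope / (_DB * _FF_COEFF * k_coeff)  # mm^2
    return 2.0 * np.sqrt(a2) * 1000.0


def estimate_asd_aac(
    ns: NormalizedSpectrum,
    sound_speed: float = 1540.0,
    band: tuple[float, float] | None = None,
) -> ScattererEstimate:
    """Gaussian form-factor fit: effective scatterer diameter + concentration."""
    if band is None:
        band = (float(ns.frequencies[0]), float(ns.frequencies[-1]))
    f, y = ns.band(*band)
    f = np.asarray(f, dtype=float)
    good = f > 0
    f, y = f[good], y[good]
    if f.size < 3:
        raise ValueError("need at least 3 positive-frequency points in band")
    resid = y - 40.0 * np.log10(f)
    slope, intercept = np.polyfit(f**2, resid, 1)
    aac = float(intercept)
    if slope > 1e-9:  # unphysical (growing) form factor
        return ScattererEstimate(ASD=float("nan"), AAC=aac, valid=False)
    slope = min(slope, 0.0)
    return ScattererEstimate(ASD=float(_asd_from_slope(slope, sound_speed)), AAC=aac, valid=True)


def _detrended_linear_power(y_db: np.ndarray) -> np.ndarray:
    """Linear power with a quadratic (in dB) baseline removed."""
    n = y_db.shape[-1]
    x = np.linspace(-1.0, 1.0, n)
    basis = np.vstack([np.ones(n), x, x**2]).T  # (n, 3)
    coef, *_ = np.linalg.lstsq(basis, np.moveaxis(y_db, -1, 0).reshape(n, -1), rcond=None)
    trend = (basis @ coef).reshape(n, *y_db.shape[:-1])
    trend = np.moveaxis(trend, 0, -1)
    p = 10.0 ** (y_db / 10.0)
    p_trend = 10.0 ** (trend / 10.0)
    return p - p_trend


def _autocorr(x: np.ndarray) -> np.ndarray:
    """Biased normalized autocorrelation along the last axis."""
    n = x.shape[-1]
    x = x - x.mean(axis=-1, keepdims=True)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    spec = np.fft.rfft(x, n=nfft, axis=-1)
    r = np.fft.irfft(np.abs(spec) ** 2, axis=-1)[..., :n]
    r0 = r[..., :1].copy()
    r0[r0 == 0] = 1.0
    return r / r0


def estimate_sas(
    ns: NormalizedSpectrum,
    sound_speed: float = 1540.0,
    band: tuple[float, float] | None = None,
    significance: float = 0.5,
    require_significance: bool = True,
) -> SASEstimate:
    """Dominant scatterer spacing from spectral-ripple autocorrelation.

    The linear-power spectrum over the band is detrended, autocorrelated
    over frequency lag, and the highest side peak located.  A ripple period
    ``df`` maps to SAS = c / (2 df).  When the peak correlation falls below
    ``significance`` (and ``require_significance`` is set) the spacing is
    reported as None — no significant periodicity.
    """
    if band is None:
        band = (float(ns.frequencies[0]), float(ns.frequencies[-1]))
    f, y = ns.band(*band)
    if f.size < 8:
        raise ValueError("unresolvable spacing: analysis band too narrow")
    df = float(f[1] - f[0])
    p = _detrended_linear_power(y)
    r = _autocorr(p)
    lag, peak = _dominant_lag(r[None, :], min_lag=2)
    lag, peak = int(lag[0]), float(peak[0])
    if lag <= 0 or (require_significance and peak < significance):
        return SASEstimate(SAS=None, peak_correlation=peak, ripple_period_mhz=None)
    ripple = lag * df
    sas_mm = (sound_speed / 1000.0) / (2.0 * ripple)
    return SASEstimate(SAS=float(sas_mm), peak_correlation=peak, ripple_period_mhz=ripple)


def _dominant_lag(r: np.ndarray, min_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Highest local maximum of each autocorrelation row beyond the mainlobe.

    The mainlobe is skipped by starting at the first local minimum of each
    row (at least ``min_lag``).  Returns (lag, value) arrays; lag 0 when no
    interior local maximum exists.
    """
    nwin, n = r.shape
    lags = np.zeros(nwin, dtype=int)
    peaks = np.full(nwin, -np.inf)
    interior = (r[:, 1:-1] >= r[:, :-2]) & (r[:, 1:-1] >= r[:, 2:])
    falling = np.cumsum(r[:, 1:-1] <= r[:, :-2], axis=1) > 0  # past first decline
    cand = interior & falling
    cand[:, : max(0, min_lag - 1)] = False
    for i in range(nwin):
        idx = np.nonzero(cand[i])[0]
        if idx.size:
            vals = r[i, idx + 1]
            j = int(np.argmax(vals))
            lags[i] = int(idx[j] + 1)
            peaks[i] = float(vals[j])
    return lags, peaks


def estimate_attenuation(
    spectra: Sequence[tuple[float, np.ndarray]] | None = None,
    frequencies: np.ndarray | None = None,
    band: tuple[float, float] = (3.0, 8.5),
) -> AttenuationEstimate:
    """Spectral-difference attenuation estimate from depth-stratified spectra.

    ``spectra`` is a sequence of (depth_cm, power_dB array) window spectra on
    a common frequency grid.  For each in-band frequency the dB power is
    regressed on depth; the per-frequency slopes ``m(f)`` are then regressed
    on ``f`` through the origin, giving ``m(f) = -2 alpha f`` and hence
    ``alpha`` in dB/cm/MHz.
    """
    if spectra is None or frequencies is None:
        raise ValueError("spectra and frequencies are required")
    depths = np.array([d for d, _ in spectra], dtype=float)
    if np.unique(np.round(depths, 6)).size < 3:
        raise ValueError("need windows at >= 3 distinct depths")
    y = np.stack([s for _, s in spectra])  # (n_win, n_freq)
    f = np.asarray(frequencies, dtype=float)
    sel = (f >= band[0]) & (f <= band[1])
    f = f[sel]
    y = y[:, sel]
    finite = np.all(np.isfinite(y), axis=1)  # empty (all-zero) windows excluded
    y, depths = y[finite], depths[finite]
    if np.unique(np.round(depths, 6)).size < 3:
        raise ValueError("need windows at >= 3 distinct depths")
    zc = depths - depths.mean()
    denom = float(np.sum(zc**2))
    slopes = (zc @ y) / denom  # dB/cm per frequency
    alpha = -float(np.sum(slopes * f) / np.sum(f**2)) / 2.0
    return AttenuationEstimate(alpha=max(alpha, 0.0))


# ---------------------------------------------------------------------------
# Vectorised per-frame estimation and map assembly
# ---------------------------------------------------------------------------

def _vectorised_fits(
    ns: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float],
    sound_speed: float,
    sas_significance: float,
    sas_require_significance: bool,
) -> dict[str, np.ndarray]:
    """Estimate all six parameters for a stack of normalized spectra.

    ``ns`` has shape (n_windows, n_freq); returns parameter arrays of
    length n_windows (NaN where invalid).
    """
    f = np.asarray(freqs, dtype=float)
    sel = (f >= band[0]) & (f <= band[1]) & (f > 0)
    fb = f[sel]
    y = ns[:, sel]  # (n_win, n_band)
    n_win = y.shape[0]
    f_c = 0.5 * (band[0] + band[1])

    # windows with empty/degenerate RF have non-finite spectra: estimate on a
    # placeholder and mark every parameter NaN afterwards
    bad = ~np.all(np.isfinite(y), axis=1)
    if bad.any():
        y = np.where(bad[:, None], 0.0, y)

    # MBF / SS / SI: one shared least-squares design
    design = np.vstack([np.ones_like(fb), fb]).T
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    si, ss = coef[0], coef[1]
    mbf = si + ss * f_c

    # ASD / AAC: regression of y - 40 log10 f on f^2
    resid = y - 40.0 * np.log10(fb)[None, :]
    design2 = np.vstack([np.ones_like(fb), fb**2]).T
    coef2, *_ = np.linalg.lstsq(design2, resid.T, rcond=None)
    aac, slope2 = coef2[0], coef2[1]
    c_mm_us = sound_speed / 1000.0
    k_coeff = (2.0 * np.pi / c_mm_us) ** 2
    a2 = -slope2 / (_DB * _FF_COEFF * k_coeff)
    asd = np.where(a2 > 0, 2.0 * np.sqrt(np.clip(a2, 0, None)) * 1000.0, np.nan)

    # SAS: autocorrelation of detrended linear power
    df = float(fb[1] - fb[0])
    p = _detrended_linear_power(y)
    r = _autocorr(p)
    lags, peaks = _dominant_lag(r, min_lag=2)
    sas = np.full(n_win, np.nan)
    ok = lags > 0
    if sas_require_significance:
        ok &= peaks >= sas_significance
    ripple = lags[ok] * df
    sas[ok] = c_mm_us / (2.0 * ripple)
    out = {"MBF": mbf, "SS": ss, "SI": si, "SAS": sas, "ASD": asd, "AAC": aac}
    if bad.any():
        for v in out.values():
            v[bad] = np.nan
    return out


def roi_window_mask(fs: FrameSpectra, roi: np.ndarray, frame_axial_step_mm: float, line_pitch_mm: float) -> np.ndarray:
    """Boolean (n_axial, n_lateral) grid: window centre lies inside the ROI."""
    ax_idx = np.clip(
        (fs.axial_centres_mm / frame_axial_step_mm).astype(int), 0, roi.shape[0] - 1
    )
    lat_idx = np.clip(
        (fs.lateral_centres_mm / line_pitch_mm).astype(int), 0, roi.shape[1] - 1
    )
    return roi[np.ix_(ax_idx, lat_idx)]


@dataclass
class PreparedReference:
    """Laterally/frame-averaged reference-phantom spectra on the window grid."""

    power_db: np.ndarray  # (n_axial_full, n_freq)
    frequencies: np.ndarray
    axial_centres_mm: np.ndarray
    known_bsc_db: object  # callable f -> dB
    attenuation: float


def prepare_reference(reference, config: SpectralConfig) -> PreparedReference:
    """Precompute the reference spectra once (reusable across scans)."""
    specs = [
        frame_spectra(fr, config, i) for i, fr in enumerate(reference.scan.frames)
    ]
    ref_db = average_reference_spectra(specs)
    return PreparedReference(
        power_db=ref_db,
        frequencies=specs[0].frequencies,
        axial_centres_mm=specs[0].axial_centres_mm,
        known_bsc_db=reference.known_bsc_db,
        attenuation=reference.attenuation,
    )


def build_parametric_maps(
    scan,
    roi_masks: Sequence[np.ndarray],
    config: SpectralConfig,
    reference,
    alpha_sample: float | None = None,
    sas_significance: float = 0.5,
    sas_require_significance: bool = False,
) -> tuple[list[ParametricMap], dict[str, float], AttenuationEstimate]:
    """Full per-scan estimation: maps for all parameters and frames.

    Parameters
    ----------
    scan:
        :class:`~qusr.rf_synth.RFScan` (or any object with ``frames``).
    roi_masks:
        Per-frame boolean masks at RF resolution.
    reference:
        :class:`~qusr.rf_synth.ReferencePhantom` providing the reference
        spectra, known backscatter and attenuation.
    alpha_sample:
        Sample attenuation in dB/cm/MHz; estimated from the scan's window
        spectra (spectral-difference method) when None.

    Returns (maps, per-scan parameter means, attenuation estimate).  Window
    estimates that fail to converge are NaN and excluded from the means;
    their fraction is logged.
    """
    frames = scan.frames
    if len(frames) != len(roi_masks):
        raise ValueError("one ROI mask per frame is required")
    if not any(np.any(m) for m in roi_masks):
        raise ValueError("ROI is empty")

    if not isinstance(reference, PreparedReference):
        reference = prepare_reference(reference, config)
    ref_db = reference.power_db

    band = config.analysis_band
    maps: list[ParametricMap] = []
    per_param_values: dict[str, list[np.ndarray]] = {}
    att_windows: list[tuple[float, np.ndarray]] = []
    att_freqs: np.ndarray | None = None
    n_windows = 0
    n_invalid = 0

    frame_data = []
    for k, (fr, roi) in enumerate(zip(frames, roi_masks)):
        axial_starts, line_starts = window_grid(fr, config)
        if axial_starts.size != ref_db.shape[0]:
            raise ValueError("reference phantom geometry does not match the scan")
        nax = config.window_samples(fr)
        nlin = config.window_lines(fr)
        ax_idx = np.clip(
            (axial_starts + nax // 2), 0, roi.shape[0] - 1
        )
        lat_idx = np.clip((line_starts + nlin // 2), 0, roi.shape[1] - 1)
        wmask_full = roi[np.ix_(ax_idx, lat_idx)]
        if not wmask_full.any():
            raise ValueError(f"ROI smaller than one analysis window in frame {k}")
        # restrict computation to the ROI bounding box on the window grid
        rows = np.nonzero(wmask_full.any(axis=1))[0]
        cols = np.nonzero(wmask_full.any(axis=0))[0]
        row_range = np.arange(rows[0], rows[-1] + 1)
        col_range = np.arange(cols[0], cols[-1] + 1)
        fs = frame_spectra(fr, config, k, axial_indices=row_range, line_indices=col_range)
        wmask = wmask_full[np.ix_(row_range, col_range)]
        # collect raw in-ROI spectra for attenuation estimation
        z_cm = np.repeat(fs.axial_centres_mm / 10.0, wmask.shape[1])[wmask.ravel()]
        raw = fs.power_db.reshape(-1, fs.power_db.shape[2])[wmask.ravel()]
        att_windows.extend(zip(z_cm, raw))
        att_freqs = fs.frequencies
        frame_data.append((fr, fs, wmask, row_range))

    if alpha_sample is None:
        try:
            alpha_est = estimate_attenuation(att_windows, att_freqs, band)
        except ValueError:
            logger.warning("attenuation estimation failed; assuming reference value")
            alpha_est = AttenuationEstimate(alpha=reference.attenuation)
    else:
        alpha_est = AttenuationEstimate(alpha=alpha_sample)

    for k, (fr, fs, wmask, row_range) in enumerate(frame_data):
        ns = normalize_frame_spectra(
            fs,
            ref_db[row_range],
            reference.known_bsc_db,
            alpha_est.alpha,
            reference.attenuation,
        )
        flat_ns = ns.reshape(-1, ns.shape[2])[wmask.ravel()]
        fits = _vectorised_fits(
            flat_ns,
            fs.frequencies,
            band,
            fr.sound_speed,
            sas_significance,
            sas_require_significance,
        )
        spacing = (
            config.axial_stride(fr) * fr.axial_step_mm,
            config.lateral_stride(fr) * fr.line_pitch,
        )
        for pid, vals in fits.items():
            grid = np.full(wmask.shape, np.nan)
            grid[wmask] = vals
            maps.append(
                ParametricMap(
                    parameter_id=pid,
                    values=grid,
                    pixel_spacing=spacing,
                    roi_mask=wmask.copy(),
                    frame_index=k,
                )
            )
            per_param_values.setdefault(pid, []).append(vals)
            n_windows += vals.size
            n_invalid += int(np.sum(~np.isfinite(vals)))

    if n_windows:
        logger.info(
            "parametric maps: %d windows, %.1f%% invalid estimates excluded",
            n_windows,
            100.0 * n_invalid / n_windows,
        )
    means = {
        pid: float(np.nanmean(np.concatenate(v))) if np.any(np.isfinite(np.concatenate(v))) else float("nan")
        for pid, v in per_param_values.items()
    }
    return maps, means, alpha_est
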