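import numpy as np
import pytest

from qusr.qus_params import (
    AttenuationEstimate,
    LinearFitResult,
    build_parametric_maps,
    estimate_asd_aac,
    estimate_attenuation,
    estimate_sas,
    fit_linear_spectrum,
    prepare_reference,
)
from qusr.rf_synth import (
    FORM_FACTOR_COEFF,
    PulseModel,
    RFScan,
    quasi_periodic_field,
    random_field,
    simulate_reference_phantom,
    simulate_rf_frame,
)
from qusr.spectra import NormalizedSpectrum, SpectralConfig

BAND = (3.0, 8.5)
C = 1540.0
C_MM_US = 1.54
DB = 10.0 / np.log(10.0)


def _ns(f, y, centre=(10.0, 5.0, 0)):
    return NormalizedSpectrum(np.asarray(f, float), np.asarray(y, float), centre)


def model_spectrum(f, asd_um, aac_db):
    """Forward Gaussian form-factor model used as the inverse-crime oracle."""
    a_mm = asd_um / 2000.0
    k = 2 * np.pi * f / C_MM_US
    return 40 * np.log10(f) + aac_db - DB * FORM_FACTOR_COEFF * (k * a_mm) ** 2


class TestLinearFit:
    def test_exact_line(self):
        f = np.linspace(3.0, 8.5, 56)
        r = fit_linear_spectrum(_ns(f, 2.0 * f + 3.0), BAND)
        assert r.SS == pytest.approx(2.0, abs=1e-10)
        assert r.SI == pytest.approx(3.0, abs=1e-9)
        assert r.MBF == pytest.approx(3.0 + 2.0 * 5.75, abs=1e-9)

    def test_flat_spectrum(self):
        f = np.linspace(3.0, 8.5, 30)
        r = fit_linear_spectrum(_ns(f, np.full_like(f, 7.0)), BAND)
        assert r.SS == pytest.approx(0.0, abs=1e-12)
        assert r.SI == pytest.approx(7.0)
        assert r.MBF == pytest.approx(7.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="3"):
            fit_linear_spectrum(_ns([4.0, 5.0], [1.0, 2.0]), BAND)

    def test_mbf_identity_enforced(self):
        with pytest.raises(ValueError, match="MBF"):
            LinearFitResult(SS=1.0, SI=0.0, MBF=99.0, f_centre=5.75)

    def test_slope_ci_coverage(self):
        """Monte-Carlo coverage oracle: the true slope lies inside its own
        95% least-squares CI in >= 93% of noisy replicates."""
        from scipy import stats

        f = np.linspace(3.0, 8.5, 50)
        X = np.vstack([np.ones_like(f), f]).T
        xtx_inv = np.linalg.inv(X.T @ X)
        tcrit = stats.t.ppf(0.975, 48)
        hits = 0
        n_rep = 1000
        rng = np.random.default_rng(7)
        for _ in range(n_rep):
            y = 1.5 * f - 4.0 + rng.normal(0, 1.0, f.size)
            r = fit_linear_spectrum(_ns(f, y), BAND)
            resid = y - (r.SI + r.SS * f)
            s2 = resid @ resid / 48
            se_slope = np.sqrt(s2 * xtx_inv[1, 1])
            if abs(r.SS - 1.5) <= tcrit * se_slope:
                hits += 1
        assert hits / n_rep >= 0.93


class TestASDAAC:
    def test_inverse_crime_recovery(self):
        """Spectrum generated from the estimation model itself: ASD recovered
        within 5%."""
        f = np.linspace(3.0, 8.5, 56)
        est = estimate_asd_aac(_ns(f, model_spectrum(f, 100.0, 5.0)), C, BAND)
        assert est.valid
        assert est.ASD == pytest.approx(100.0, rel=0.05)
        assert est.AAC == pytest.approx(5.0, abs=0.1)

    def test_point_scatterers_zero_diameter(self):
        f = np.linspace(3.0, 8.5, 56)
        est = estimate_asd_aac(_ns(f, model_spectrum(f, 0.0, 2.0)), C, BAND)
        assert est.ASD == pytest.approx(0.0, abs=1e-6)

    def test_positive_slope_flagged_invalid(self):
        f = np.linspace(3.0, 8.5, 56)
        y = 40 * np.log10(f) + 0.5 * f**2  # unphysical growth
        est = estimate_asd_aac(_ns(f, y), C, BAND)
        assert not est.valid
        assert np.isnan(est.ASD)
        assert np.isfinite(est.AAC)

    def test_concentration_doubling_model_level(self):
        """Doubling concentration shifts AAC by exactly 10 log10 2 in the
        model; the RF-level Monte-Carlo version lives in the acceptance
        suite."""
        f = np.linspace(3.0, 8.5, 56)
        e1 = estimate_asd_aac(_ns(f, model_spectrum(f, 80.0, 3.0)), C, BAND)
        e2 = estimate_asd_aac(_ns(f, model_spectrum(f, 80.0, 3.0 + 10 * np.log10(2))), C, BAND)
        assert e2.AAC - e1.AAC == pytest.approx(10 * np.log10(2), abs=1e-9)


def _sas_spectrum_config(pulse):
    # long gate for fine spectral resolution of the ripple
    return SpectralConfig(window_length_mm=12.0, window_width_mm=2.0, nfft_min=1024)


class TestSAS:
    @pytest.mark.parametrize("d_mm", [1.0, 0.5])
    def test_spacing_recovered(self, pulse, d_mm):
        """Forward simulation oracle: quasi-periodic scatterers at spacing d
        produce spectral ripple df = c/(2d); SAS recovers d within the
        spectral grid resolution."""
        from qusr.spectra import frame_spectra

        cfg = _sas_spectrum_config(pulse)
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fld = quasi_periodic_field(
                20.0, 16 * 0.23, 6.0, period_mm=d_mm, rng=rng, jitter_mm=0.01
            )
            fr = simulate_rf_frame(fld, pulse, n_lines=16, depth_mm=20.0)
            fs = frame_spectra(fr, cfg)
            # average the in-band spectra for a stable ripple estimate
            power = 10 * np.log10(np.mean(10 ** (fs.power_db / 10), axis=(0, 1)))
            ns = NormalizedSpectrum(fs.frequencies, power, (10.0, 2.0, 0))
            est = estimate_sas(ns, C, BAND, require_significance=False)
            df_grid = fs.frequencies[1] - fs.frequencies[0]
            ripple = C_MM_US / (2 * d_mm)
            tol = C_MM_US / 2 * (1 / (ripple - df_grid) - 1 / (ripple + df_grid))
            hits.append(est.SAS is not None and abs(est.SAS - d_mm) <= tol)
        assert sum(hits) >= 4

    def test_random_positions_null(self, pulse):
        """No periodicity: the spacing estimate is null in >= 90% of seeds."""
        from qusr.spectra import frame_spectra

        cfg = _sas_spectrum_config(pulse)
        nulls = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            fld = random_field(20.0, 16 * 0.23, 6.0, rng)
            fr = simulate_rf_frame(fld, pulse, n_lines=16, depth_mm=20.0)
            fs = frame_spectra(fr, cfg)
            power = 10 * np.log10(np.mean(10 ** (fs.power_db / 10), axis=(0, 1)))
            ns = NormalizedSpectrum(fs.frequencies, power, (10.0, 2.0, 0))
            est = estimate_sas(ns, C, BAND, require_significance=True)
            nulls += est.SAS is None
        assert nulls >= 0.9 * n_seeds

    def test_band_too_narrow(self):
        f = np.linspace(3.0, 8.5, 56)
        with pytest.raises(ValueError, match="unresolvable"):
            estimate_sas(_ns(f, np.zeros_like(f)), C, band=(5.0, 5.3))


class TestAttenuation:
    def _phantom_spectra(self, pulse, alpha, seed, depth_mm=35.0):
        from qusr.spectra import frame_spectra

        rng = np.random.default_rng(seed)
        fld = random_field(depth_mm, 48 * 0.23, 4.0, rng)
        fr = simulate_rf_frame(fld, pulse, alpha, n_lines=48, depth_mm=depth_mm)
        fs = frame_spectra(fr, SpectralConfig())
        lin = np.mean(10 ** (fs.power_db / 10), axis=1)
        windows = [
            (fs.axial_centres_mm[i] / 10, 10 * np.log10(lin[i]))
            for i in range(len(fs.axial_centres_mm))
        ]
        return windows, fs.frequencies

    def test_zero_attenuation(self, pulse):
        ests = []
        for seed in range(10):
            w, f = self._phantom_spectra(pulse, 0.0, seed)
            ests.append(estimate_attenuation(w, f, BAND).alpha)
        assert np.mean(ests) == pytest.approx(0.0, abs=0.1)

    def test_simulation_recovery(self, pulse):
        """alpha = 0.7 dB/cm/MHz recovered within 15% (mean over seeds)."""
        ests = []
        for seed in range(50):
            w, f = self._phantom_spectra(pulse, 0.7, seed)
            ests.append(estimate_attenuation(w, f, BAND).alpha)
        assert np.mean(ests) == pytest.approx(0.7, rel=0.15)

    def test_monotonic_doubling(self, pulse):
        means = []
        for alpha in (0.3, 0.6):
            ests = [
                estimate_attenuation(*self._phantom_spectra(pulse, alpha, s), BAND).alpha
                for s in range(15)
            ]
            means.append(np.mean(ests))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.3)

    def test_requires_three_strata(self):
        f = np.linspace(0, 20, 50)
        w = [(1.0, np.zeros(50)), (1.0, np.zeros(50)), (2.0, np.zeros(50))]
        with pytest.raises(ValueError, match="3 distinct depths"):
            estimate_attenuation(w, f, BAND)

    def test_negative_clamped(self):
        assert AttenuationEstimate(alpha=-0.2).alpha == 0.0


@pytest.fixture(scope="module")
def phantom_setup(pulse):
    ref = simulate_reference_phantom(
        pulse, 0.3, seed=5, depth_mm=25.0, n_lines=96, n_frames=2
    )
    cfg = SpectralConfig()
    prep = prepare_reference(ref, cfg)
    return ref, prep, cfg


class TestParametricMaps:
    def _scan(self, pulse, seed, density=4.0, amp_std=1.0, alpha=0.3, n_frames=1):
        rng = np.random.default_rng(seed)
        frames = []
        for _ in range(n_frames):
            fld = random_field(25.0, 96 * 0.23, density, rng, amp_std)
            frames.append(
                simulate_rf_frame(fld, pulse, alpha, n_lines=96, depth_mm=25.0)
            )
        return RFScan(frames)

    def _roi(self, scan):
        fr = scan.frames[0]
        m = np.zeros((fr.n_samples, fr.n_lines), dtype=bool)
        m[fr.n_samples // 4 : 3 * fr.n_samples // 4, 10:86] = True
        return [m] * len(scan.frames)

    def test_homogeneous_phantom_map_uniformity(self, pulse, phantom_setup):
        """Homogeneous medium: MBF map spread stays within the speckle bound."""
        _, prep, cfg = phantom_setup
        scan = self._scan(pulse, seed=8)
        maps, means, alpha = build_parametric_maps(
            scan, self._roi(scan), cfg, prep, alpha_sample=0.3
        )
        mbf = next(m for m in maps if m.parameter_id == "MBF")
        vals = mbf.valid_values()
        assert vals.size > 100
        assert np.std(vals) < 3.0  # dB, speckle bound for ~9-line windows

    def test_two_region_contrast_recovered(self, pulse, phantom_setup):
        """Scans differing by 2x concentration: MBF means differ by ~3 dB."""
        _, prep, cfg = phantom_setup
        diffs = []
        for seed in range(5):
            m = []
            for dens in (4.0, 8.0):
                scan = self._scan(pulse, seed=100 + seed, density=dens)
                _, means, _ = build_parametric_maps(
                    scan, self._roi(scan), cfg, prep, alpha_sample=0.3
                )
                m.append(means["MBF"])
            diffs.append(m[1] - m[0])
        assert np.mean(diffs) == pytest.approx(10 * np.log10(2), abs=0.75)

    def test_empty_mask_error(self, pulse, phantom_setup):
        _, prep, cfg = phantom_setup
        scan = self._scan(pulse, seed=9)
        fr = scan.frames[0]
        empty = [np.zeros((fr.n_samples, fr.n_lines), dtype=bool)]
        with pytest.raises(ValueError, match="ROI"):
            build_parametric_maps(scan, empty, cfg, prep)

    def test_mbf_identity_across_maps(self, pulse, phantom_setup):
        """MBF == SI + SS * f_c for every window, to machine precision."""
        _, prep, cfg = phantom_setup
        scan = self._scan(pulse, seed=10)
        maps, _, _ = build_parametric_maps(scan, self._roi(scan), cfg, prep, alpha_sample=0.3)
        by_id = {m.parameter_id: m for m in maps}
        f_c = 0.5 * (cfg.analysis_band[0] + cfg.analysis_band[1])
        lhs = by_id["MBF"].values
        rhs = by_id["SI"].values + by_id["SS"].values * f_c
        ok = np.isfinite(lhs)
        assert np.allclose(lhs[ok], rhs[ok], atol=1e-9)

    def test_attenuation_estimated_when_not_given(self, pulse, phantom_setup):
        _, prep, cfg = phantom_setup
        scan = self._scan(pulse, seed=11, alpha=0.5)
        _, _, est = build_parametric_maps(scan, self._roi(scan), cfg, prep)
        assert 0.0 <= est.alpha <= 1.5

    def test_reference_system_invariance_of_maps(self, spectral_config):
        """Parameter maps computed under two system responses agree within
        tolerance (reference-phantom invariance propagates)."""
        pulses = [
            PulseModel(centre_frequency=6.0, fractional_bandwidth=0.9),
            PulseModel(centre_frequency=7.0, fractional_bandwidth=0.7),
        ]
        rng = np.random.default_rng(3)
        tissue = random_field(25.0, 96 * 0.23, 4.0, rng, amp_std=1.3)
        ref_field = random_field(25.0, 96 * 0.23, 4.0, rng)
        mbf_means = []
        for pulse in pulses:
            fr = simulate_rf_frame(tissue, pulse, 0.3, n_lines=96, depth_mm=25.0)
            ref_fr = simulate_rf_frame(ref_field, pulse, 0.3, n_lines=96, depth_mm=25.0)

            class _Ref:
                scan = RFScan([ref_fr])
                attenuation = 0.3

                @staticmethod
                def known_bsc_db(f):
                    with np.errstate(divide="ignore"):
                        return 40.0 * np.log10(f / 6.5) + 10.0 * np.log10(4.0)

            scan = RFScan([fr])
            roi = np.zeros_like(fr.samples, dtype=bool)
            roi[fr.n_samples // 4 : 3 * fr.n_samples // 4, 10:86] = True
            _, means, _ = build_parametric_maps(
                scan, [roi], spectral_config, _Ref(), alpha_sample=0.3
            )
            mbf_means.append(means["MBF"])
        assert abs(mbf_means[0] - mbf_means[1]) <= 0.5
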