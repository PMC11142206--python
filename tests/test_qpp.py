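"""Sliding-template QPP detection: STC, iteration, events, summaries."""
import dataclasses

import numpy as np
import pytest

from qppdyn.core import InvalidConfigError
from qppdyn.qpp import (
    QppParams,
    compute_stc,
    cingulate_qpp_range,
    detect_qpp,
    fraction_above_threshold,
    regress_global_signal,
    stc_histogram,
)
from qppdyn.synthetic import SimulationConfig, generate_parcellated


def _params(**kw):
    base = dict(window_frames=8, regress_gs_first=False, start_seed=0)
    base.update(kw)
    return QppParams(**base)


class TestComputeStc:
    def test_template_from_scan_has_unit_peak(self, rng):
        data = rng.standard_normal((6, 40))
        tpl = data[:, 12:17].copy()
        stc = compute_stc(tpl, data)
        assert stc[12] == pytest.approx(1.0, abs=1e-12)

    def test_negated_window_gives_minus_one(self, rng):
        data = rng.standard_normal((6, 40))
        stc = compute_stc(-data[:, 20:25], data)
        assert stc[20] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_per_lag_pearson_oracle(self, rng):
        data = rng.standard_normal((6, 40))
        tpl = rng.standard_normal((6, 5))
        stc = compute_stc(tpl, data)
        for t in range(40 - 5 + 1):
            expected = np.corrcoef(tpl.ravel(), data[:, t : t + 5].ravel())[0, 1]
            assert abs(stc[t] - expected) <= 1e-10

    def test_zero_variance_template_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            stc = compute_stc(np.ones((3, 5)), np.random.default_rng(0)
                              .standard_normal((3, 20)))
        assert np.all(stc == 0)

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((5, 60))
        tpl = rng.standard_normal((5, 6))
        np.testing.assert_allclose(
            compute_stc(tpl, data), compute_stc(tpl, 3.7 * data), atol=1e-10
        )


class TestDetectQpp:
    def test_noise_free_recovery(self, noise_free_qpp_config):
        scan, truth = generate_parcellated(noise_free_qpp_config)
        res = detect_qpp([scan], _params())
        assert res.converged
        np.testing.assert_array_equal(res.event_onsets, truth.event_onsets)
        best = max(
            np.corrcoef(np.roll(truth.planted_template, lag, axis=1).ravel(),
                        res.template.ravel())[0, 1]
            for lag in range(-7, 8)
        )
        assert best >= 0.99

    def test_duplication_invariance(self, noise_free_qpp_config):
        """Running on a scan concatenated with itself yields the same
        template as the single scan (after lag alignment)."""
        scan, _ = generate_parcellated(noise_free_qpp_config)
        res1 = detect_qpp([scan], _params())
        res2 = detect_qpp([scan, scan], _params())
        assert res1.converged and res2.converged
        best = max(
            np.corrcoef(np.roll(res1.template, lag, axis=1).ravel(),
                        res2.template.ravel())[0, 1]
            for lag in range(-7, 8)
        )
        assert best >= 1.0 - 1e-6
        assert res2.event_onsets.size == 2 * res1.event_onsets.size

    def test_boundary_windows_masked(self, noise_free_qpp_config):
        scan, _ = generate_parcellated(noise_free_qpp_config)
        res = detect_qpp([scan, scan], _params())
        T, W = scan.n_frames, res.window_frames
        straddle = np.arange(T - W + 1, T)
        assert not res.boundary_mask[straddle].any()
        assert not np.isin(res.event_onsets, straddle).any()

    def test_template_scales_with_input(self, noise_free_qpp_config):
        scan, _ = generate_parcellated(noise_free_qpp_config)
        res1 = detect_qpp([scan], _params())
        res2 = detect_qpp([scan.with_values(4.0 * scan.values)], _params())
        np.testing.assert_allclose(res2.template, 4.0 * res1.template, atol=1e-8)
        np.testing.assert_allclose(res2.stc, res1.stc, atol=1e-10)

    def test_no_pattern_result_on_tiny_threshold_miss(self):
        """All-zero data cannot produce supra-threshold peaks: the detector
        reports an explicit no-pattern result instead of failing."""
        flat = np.zeros((5, 100))
        res = detect_qpp([flat], _params(n_starts=3))
        assert not res.converged
        assert res.event_onsets.size == 0
        assert res.template is None

    def test_detection_rate_monotone_in_amplitude(self):
        """Planted-event recovery rate is non-decreasing in the
        pattern-to-noise amplitude ratio (20 seeds per ratio)."""
        ratios = [0.5, 1.0, 2.0, 4.0]
        rates = []
        for ratio in ratios:
            hits = total = 0
            for seed in range(20):
                cfg = SimulationConfig(
                    seed=seed, gs_amplitude=0.0, noise_sd=1.0,
                    qpp_amplitude=ratio, interval_jitter_frames=4.0,
                )
                scan, truth = generate_parcellated(cfg)
                res = detect_qpp([scan], _params(n_starts=8))
                total += truth.event_onsets.size
                if res.converged:
                    for t in truth.event_onsets:
                        if np.any(np.abs(res.event_onsets - t) <= 2):
                            hits += 1
            rates.append(hits / total)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] >= 0.9  # strong patterns are essentially always found

    def test_white_noise_stc_matches_phase_randomized_surrogates(self):
        """On structure-free data the fraction of |STC| > 0.2 is consistent
        with the same statistic on phase-randomized surrogates (which
        preserve each region's power spectrum but destroy any repeating
        pattern): the pooled observed-vs-surrogate difference stays within
        2 standard errors. Pooling over several noise realizations accounts
        for the sampling variability of the observed statistic itself."""
        params = _params(n_starts=6)

        def frac(mat):
            res = detect_qpp([mat], params)
            if not res.converged:
                return np.nan
            return fraction_above_threshold(res.stc, 0.2, "absolute",
                                            valid=res.boundary_mask)

        observed, surrogate = [], []
        rng = np.random.default_rng(99)
        for seed in range(6):
            base = np.random.default_rng(seed).standard_normal((20, 480))
            observed.append(frac(base))
            for _ in range(12):
                spec = np.fft.rfft(base, axis=1)
                phases = np.exp(2j * np.pi * rng.random(spec.shape))
                phases[:, 0] = 1.0
                sur = np.fft.irfft(spec * phases, n=base.shape[1], axis=1)
                surrogate.append(frac(sur))
        observed = np.asarray(observed)
        surrogate = np.asarray(surrogate)
        assert np.all(np.isfinite(observed))
        surrogate = surrogate[np.isfinite(surrogate)]
        sd = surrogate.std(ddof=1)
        se = sd * np.sqrt(1.0 / observed.size + 1.0 / surrogate.size)
        assert abs(observed.mean() - surrogate.mean()) <= 2.0 * se


class TestSummaries:
    def test_fraction_above_threshold_modes(self):
        stc = np.array([0.1, 0.25, -0.3, 0.05])
        assert fraction_above_threshold(stc, 0.2, "signed") == 0.25
        assert fraction_above_threshold(stc, 0.2, "absolute") == 0.5
        zeros = np.zeros(10)
        assert fraction_above_threshold(zeros, 0.2, "signed") == 0.0
        assert fraction_above_threshold(zeros, 0.2, "absolute") == 0.0

    def test_histogram_example(self):
        edges, counts = stc_histogram(np.array([0.15, 0.15, -0.85]), 0.1)
        bin_of = lambda x: int(np.searchsorted(edges, x, side="right")) - 1
        assert counts[bin_of(0.15)] == 2
        assert counts[bin_of(-0.85)] == 1
        assert counts.sum() == 3

    def test_histogram_conserves_counts(self, rng):
        stc = np.clip(rng.standard_normal(500) * 0.3, -1, 1)
        _, counts = stc_histogram(stc, 0.05)
        assert counts.sum() == 500

    def test_histogram_with_all_masked_rejected(self):
        with pytest.raises(InvalidConfigError):
            stc_histogram(np.array([0.1, 0.2]), 0.1, valid=np.array([False, False]))


class TestCingulateRange:
    def test_planted_waveform_range_recovered(self, noise_free_qpp_config):
        cfg = noise_free_qpp_config
        scan, truth = generate_parcellated(cfg)
        res = detect_qpp([scan], _params())
        got = cingulate_qpp_range(res, 0, cfg.cingulate_region_ids)
        cing = truth.planted_template[list(cfg.cingulate_region_ids)].mean(axis=0)
        assert got == pytest.approx(cing.max() - cing.min(), abs=1e-6)

    def test_single_symmetric_event_range(self):
        """One event whose cingulate segment sweeps −a..+a has range 2a."""
        W, T, a = 6, 60, 1.5
        data = np.zeros((4, T))
        seg = np.linspace(-a, a, W)
        data[:2, 20:26] = seg  # cingulate rows
        data[2:, 20:26] = np.array([1, -1, 1, -1, 1, -1]) * a  # keep rank up
        params = _params(window_frames=W, n_starts=10)
        res = detect_qpp([data], params)
        assert res.converged
        got = cingulate_qpp_range(res, 0, (0, 1))
        assert got == pytest.approx(2 * a, abs=1e-8)

    def test_zero_events_gives_nan(self, noise_free_qpp_config):
        scan, _ = generate_parcellated(noise_free_qpp_config)
        flat = scan.with_values(np.zeros_like(scan.values))
        res = detect_qpp([scan, flat], _params())
        assert res.converged
        assert np.isnan(cingulate_qpp_range(res, 1, (0, 1, 2)))
        assert res.events_for_scan(1).size == 0


class TestGsr:
    def test_residuals_orthogonal_to_removed_gs(self, rng):
        mat = rng.standard_normal((12, 300))
        g = mat.mean(axis=0)
        g = (g - g.mean()) / g.std(ddof=1)
        resid = regress_global_signal(mat)
        for r in range(12):
            rc = resid[r] - resid[r].mean()
            assert abs(np.dot(rc, g) / (np.linalg.norm(rc) * np.linalg.norm(g))) \
                <= 1e-10

    def test_residual_mean_trace_vanishes(self, rng):
        """Removing the unweighted mean from every region makes the
        recomputed mean trace identically zero (up to roundoff)."""
        mat = rng.standard_normal((12, 300))
        resid = regress_global_signal(mat)
        assert np.abs(resid.mean(axis=0)).max() <= 1e-12
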