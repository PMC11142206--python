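"""Complex PCA: analytic signal, decomposition, incidence, phase patterns."""
import dataclasses

import numpy as np
import pytest

from qppdyn.core import InvalidConfigError
from qppdyn.cpca import (
    CpcaResult,
    analytic_signal,
    complex_pca,
    component_incidence,
    reconstruct_component_pattern,
)
from qppdyn.synthetic import SimulationConfig, generate_cohort


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher–Lee circular correlation between two angle vectors."""
    am = np.angle(np.mean(np.exp(1j * a)))
    bm = np.angle(np.mean(np.exp(1j * b)))
    num = np.sum(np.sin(a - am) * np.sin(b - bm))
    den = np.sqrt(np.sum(np.sin(a - am) ** 2) * np.sum(np.sin(b - bm) ** 2))
    return float(num / den)


def traveling_wave(n_regions=30, n_frames=480, tr=1.25, f=0.05, span=0.8):
    """cos(2πft − φ_r) with a linear phase ramp φ_r across regions."""
    t = np.arange(n_frames) * tr
    phi = np.linspace(0.0, 2.0 * np.pi * span, n_regions)
    return np.cos(2 * np.pi * f * t[None, :] - phi[:, None]), phi


class TestAnalyticSignal:
    def test_analytic_identity_on_sinusoid(self):
        t = np.arange(480) * 1.25
        x = np.cos(2 * np.pi * 0.05 * t)
        z = analytic_signal(x[None, :], normalize=False)[0]
        interior = slice(24, -24)
        assert np.allclose(np.abs(z)[interior], 1.0, atol=0.02)
        assert np.allclose(z.imag[interior], np.sin(2 * np.pi * 0.05 * t)[interior],
                           atol=0.02)

    def test_real_part_equals_input_exactly(self, rng):
        x = rng.standard_normal((5, 100))
        z = analytic_signal(x, normalize=False)
        np.testing.assert_array_equal(z.real, x)

    def test_normalized_real_part_is_zscore(self, rng):
        x = rng.standard_normal((5, 100)) * 3.0 + 1.0
        z = analytic_signal(x)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        np.testing.assert_allclose(z.real, (x - x.mean(axis=1, keepdims=True)) / sd,
                                   atol=1e-12)

    def test_matches_quadrature_filter_oracle(self, rng):
        """Frequency-domain oracle: zero the negative frequencies, double
        the positive ones, keep DC (and Nyquist for even length)."""
        x = rng.standard_normal(128)
        spec = np.fft.fft(x)
        h = np.zeros(128)
        h[0] = 1.0
        h[1:64] = 2.0
        h[64] = 1.0  # Nyquist bin for even length
        expected = np.fft.ifft(spec * h)
        z = analytic_signal(x[None, :], normalize=False)[0]
        np.testing.assert_allclose(z, expected, atol=1e-10)

    def test_constant_row_flagged_and_zeroed(self, rng):
        x = np.vstack([rng.standard_normal(50), np.full(50, 4.0)])
        with pytest.warns(UserWarning, match="constant"):
            z = analytic_signal(x)
        assert np.all(z[1] == 0)


class TestComplexPca:
    def test_rank_one_data_concentrates_variance(self, rng):
        a = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        b = rng.standard_normal(12) + 1j * rng.standard_normal(12)
        Z = np.outer(b, a)  # region × time, rank 1
        with pytest.warns(UserWarning, match="rank"):
            res = complex_pca(Z, K=3)
        assert res.variance_fraction[0] >= 1.0 - 1e-10

    def test_full_rank_reconstruction(self, rng):
        Z = rng.standard_normal((20, 100)) + 1j * rng.standard_normal((20, 100))
        res = complex_pca(Z, K=20)
        err = np.linalg.norm(res.reconstruct() - Z.T) / np.linalg.norm(Z)
        assert err <= 1e-8

    def test_traveling_wave_phase_ramp_recovered(self):
        X, phi = traveling_wave()
        res = complex_pca(analytic_signal(X), K=3)
        rho = circular_correlation(np.angle(res.loadings[:, 0]), phi)
        assert rho >= 0.95

    def test_eigenvalue_sum_equals_total_variance(self, rng):
        Z = rng.standard_normal((10, 80)) + 1j * rng.standard_normal((10, 80))
        res = complex_pca(Z, K=10)
        assert np.sum(res.eigenvalues) == pytest.approx(
            res.total_variance, rel=1e-8
        )
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        for k in range(res.n_components):
            assert np.linalg.norm(res.loadings[:, k]) == pytest.approx(1.0,
                                                                       abs=1e-10)

    def test_global_phase_invariance(self, rng):
        Z = rng.standard_normal((8, 120)) + 1j * rng.standard_normal((8, 120))
        res1 = complex_pca(Z, K=3)
        alpha = 0.9
        res2 = complex_pca(np.exp(1j * alpha) * Z, K=3)
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, rtol=1e-10)
        # loadings rotate by the conjugate phasor, up to the per-component
        # phase freedom of the decomposition
        for k in range(3):
            overlap = np.vdot(res2.loadings[:, k],
                              np.exp(-1j * alpha) * res1.loadings[:, k])
            assert abs(overlap) == pytest.approx(1.0, abs=1e-8)
        inc1 = component_incidence(res1, K=3)
        inc2 = component_incidence(res2, K=3)
        np.testing.assert_allclose(
            inc1.drop(columns="scan_id").to_numpy(),
            inc2.drop(columns="scan_id").to_numpy(), atol=1e-12,
        )

    def test_k_beyond_shape_rejected(self, rng):
        Z = rng.standard_normal((4, 30)) + 0j
        with pytest.raises(InvalidConfigError):
            complex_pca(Z, K=5)


class TestIncidence:
    def test_rank_one_data_fully_dominated_by_component_one(self, rng):
        a = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        b = rng.standard_normal(12) + 1j * rng.standard_normal(12)
        with pytest.warns(UserWarning, match="rank"):
            res = complex_pca(np.outer(b, a), K=3)
        inc = component_incidence(res, K=3)
        assert inc["component_1"].iloc[0] == 1.0

    def test_two_orthogonal_epochs_split_incidence(self, rng):
        """Pattern A active on the first half, an equal-power orthogonal
        pattern B on the second half: incidence ≈ {0.5, 0.5, 0}."""
        T, R = 480, 20
        t = np.arange(T) * 1.25
        uA = np.zeros(R)
        uA[:10] = 1.0
        uB = np.zeros(R)
        uB[10:] = 1.0  # disjoint support ⇒ orthogonal
        X = np.zeros((R, T))
        X += np.outer(uA, np.sin(2 * np.pi * 0.05 * t) * (t < t[T // 2]))
        X += np.outer(uB, np.sin(2 * np.pi * 0.05 * t) * (t >= t[T // 2]))
        X += 1e-3 * rng.standard_normal((R, T))  # keep the rank above 2
        res = complex_pca(analytic_signal(X, normalize=False), K=3)
        inc = component_incidence(res, K=3)
        fracs = sorted(
            [inc["component_1"].iloc[0], inc["component_2"].iloc[0],
             inc["component_3"].iloc[0]], reverse=True,
        )
        assert fracs[0] == pytest.approx(0.5, abs=0.05)
        assert fracs[1] == pytest.approx(0.5, abs=0.05)
        assert fracs[2] == pytest.approx(0.0, abs=0.05)

    def test_fractions_partition_unity(self, rng):
        mats = [rng.standard_normal((10, 100)) + 1j * rng.standard_normal((10, 100))
                for _ in range(3)]
        res = complex_pca(mats, K=3)
        inc = component_incidence(res, K=3)
        sums = inc[["component_1", "component_2", "component_3"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_gs_dominant_cohort_favors_component_one(self):
        """When the shared global fluctuation dwarfs the planted pattern,
        component 1 dominates more frames than component 2 in every scan
        (20 seeds)."""
        counts = {("mCherry", "baseline"): 2, ("ChR2", "baseline"): 2,
                  ("mCherry", "5Hz"): 2, ("ChR2", "5Hz"): 2}
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, gs_amplitude=3.0,
                                   qpp_amplitude=0.3, noise_sd=0.5)
            scans = generate_cohort(cfg, counts)
            analytic = [analytic_signal(s) for s in scans]
            res = complex_pca(analytic, K=3)
            inc = component_incidence(res, K=3)
            assert np.all(inc["component_1"] > inc["component_2"])


class TestPatternReconstruction:
    def test_traveling_wave_bins_are_shifted_copies(self):
        R = 24
        X, phi = traveling_wave(n_regions=R, span=1.0)  # 2π ramp over 24 regions
        res = complex_pca(analytic_signal(X), K=1)
        pat = reconstruct_component_pattern(res, 1, n_phase_bins=8)
        # one phase bin = 2π/8 ⇒ a shift of 24/8 = 3 regions along the ramp
        shifts = []
        for j in range(7):
            xc = [np.dot(np.roll(pat[:, j], s), pat[:, j + 1]) for s in range(R)]
            shifts.append(int(np.argmax(xc)))
        assert all(s in (3, R - 3) for s in shifts)
        assert len(set(shifts)) == 1  # consistent direction

    def test_single_bin_is_phase_zero_snapshot(self, rng):
        Z = rng.standard_normal((6, 50)) + 1j * rng.standard_normal((6, 50))
        res = complex_pca(Z, K=2)
        pat = reconstruct_component_pattern(res, 1, n_phase_bins=1)
        amp = np.sqrt(np.mean(np.abs(res.scores[:, 0]) ** 2))
        np.testing.assert_allclose(
            pat[:, 0], np.real(amp * np.conj(res.loadings[:, 0])), atol=1e-12
        )

    def test_zero_component_gives_zero_pattern(self):
        res = CpcaResult(
            loadings=np.zeros((5, 1), complex), scores=np.zeros((20, 1), complex),
            eigenvalues=np.zeros(1), variance_fraction=np.zeros(1),
            total_variance=0.0, scan_offsets=np.array([0, 20]),
            scan_ids=["s"],
        )
        pat = reconstruct_component_pattern(res, 1, n_phase_bins=4)
        assert np.all(pat == 0)
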