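import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfmflow import (RateProfile, build_matrix, check_sensitivity_bound,
                     densities_from_eigenvector, perron, sensitivities_fd,
                     sensitivities_spectral, steady_state_cf,
                     translation_rate_spectral)

from conftest import random_profile

rate_lists = st.lists(st.floats(0.1, 10.0), min_size=2, max_size=20)


class TestMatrix:
    def test_offdiagonal_entries(self):
        diag, off = build_matrix(RateProfile([4.0, 1.0, 0.25]))
        assert np.array_equal(diag, np.zeros(4))
        assert off == pytest.approx([0.5, 1.0, 2.0])

    def test_single_site_eigenvalues(self):
        spec = perron(build_matrix(RateProfile([1.0, 1.0])),
                      full_spectrum=True)
        assert spec.eigenvalues == pytest.approx(
            [-np.sqrt(2), 0.0, np.sqrt(2)], abs=1e-14)


class TestPerron:
    def test_single_site_pair(self):
        spec = perron(build_matrix(RateProfile([1.0, 1.0])))
        assert spec.zeta == pytest.approx(np.sqrt(2), rel=1e-14)
        v_expected = np.array([1.0, np.sqrt(2), 1.0])
        assert spec.v == pytest.approx(v_expected / np.linalg.norm(v_expected),
                                       rel=1e-12)

    def test_homogeneous_toeplitz_pair(self):
        # constant rates: the matrix is a scaled Toeplitz with known pair
        n, lam_c = 12, 2.5
        spec = perron(build_matrix(RateProfile(np.full(n + 1, lam_c))))
        theta = np.pi / (n + 3)
        assert spec.zeta == pytest.approx(
            2.0 * lam_c ** -0.5 * np.cos(theta), rel=1e-13)
        j = np.arange(1, n + 3)
        v = np.sin(j * theta)
        assert spec.v == pytest.approx(v / np.linalg.norm(v), rel=1e-10)

    def test_spectrum_symmetric_and_distinct(self, rng):
        prof = random_profile(rng, 6)
        spec = perron(build_matrix(prof), full_spectrum=True)
        w = spec.eigenvalues
        assert np.max(np.abs(w + w[::-1])) < 1e-12 * spec.zeta
        assert np.min(np.diff(w)) > 0.0
        assert w[-1] == pytest.approx(spec.zeta)

    def test_perron_root_lower_bound(self, rng):
        # monotonicity against the all-(max rate) Toeplitz comparison matrix
        for n in (1, 5, 30):
            prof = random_profile(rng, n)
            spec = perron(build_matrix(prof))
            bound = 2.0 * np.cos(np.pi / (n + 3)) * prof.rates.max() ** -0.5
            assert spec.zeta >= bound - 1e-14


class TestTranslationRate:
    def test_single_site(self):
        assert translation_rate_spectral(RateProfile([1.0, 1.0])).R \
            == pytest.approx(0.5, rel=1e-14)

    def test_two_site_closed_form(self):
        ss = translation_rate_spectral(RateProfile([1.0, 1.0, 1.0]))
        assert ss.R == pytest.approx(1.0 / (4 * np.cos(np.pi / 5) ** 2),
                                     rel=1e-14)
        assert ss.method == "spectral"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rate_lists, st.floats(0.2, 5.0))
    def test_positive_homogeneity(self, rates, c):
        """Scaling every rate by c scales R by c (degree-1 homogeneity)."""
        base = translation_rate_spectral(RateProfile(rates)).R
        scaled = translation_rate_spectral(RateProfile(c * np.asarray(rates))).R
        assert scaled == pytest.approx(c * base, rel=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rate_lists)
    def test_matches_continued_fraction(self, rates):
        prof = RateProfile(rates)
        Rs = translation_rate_spectral(prof).R
        Rc = steady_state_cf(prof, with_densities=False).R
        assert abs(Rs - Rc) / Rs < 1e-10

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rate_lists)
    def test_reversal_leaves_rate_invariant(self, rates):
        """Flipping the rate order is a permutation similarity of the
        matrix, so R is unchanged and sensitivities reverse."""
        prof = RateProfile(rates)
        Rf = translation_rate_spectral(prof).R
        Rb = translation_rate_spectral(prof.reversed()).R
        assert Rb == pytest.approx(Rf, rel=1e-12)
        sf = sensitivities_spectral(prof).s
        sb = sensitivities_spectral(prof.reversed()).s
        assert sb[::-1] == pytest.approx(sf, rel=1e-8, abs=1e-15)


class TestDensities:
    def test_single_site(self):
        prof = RateProfile([1.0, 1.0])
        e = densities_from_eigenvector(prof, perron(build_matrix(prof)))
        assert e == pytest.approx([0.5], rel=1e-12)

    def test_two_site(self):
        prof = RateProfile([1.0, 1.0, 1.0])
        e = densities_from_eigenvector(prof, perron(build_matrix(prof)))
        assert e == pytest.approx([0.6180339887, 0.3819660113], rel=1e-9)

    def test_exit_flux_consistency(self, rng):
        for n in (1, 4, 15, 40):
            prof = random_profile(rng, n)
            spec = perron(build_matrix(prof))
            e = densities_from_eigenvector(prof, spec)
            assert prof.rates[-1] * e[-1] == pytest.approx(
                spec.zeta ** -2, rel=1e-12)

    def test_matches_cf_densities(self, rng):
        prof = random_profile(rng, 12)
        spec = perron(build_matrix(prof))
        e_spec = densities_from_eigenvector(prof, spec)
        e_cf = steady_state_cf(prof).e
        assert e_spec == pytest.approx(e_cf, rel=1e-8)


class TestSensitivities:
    def test_single_site_analytic(self):
        # d/d lambda_i of R = l0 l1/(l0 + l1) at (1, 1) is 1/4 each
        s = sensitivities_spectral(RateProfile([1.0, 1.0])).s
        assert s == pytest.approx([0.25, 0.25], rel=1e-13)

    def test_bottleneck_interior(self):
        # implicit differentiation of R = l1 (1 - 2R)^2 at R = 1/4
        s = sensitivities_spectral(RateProfile([0.5, 1.0, 0.5])).s
        assert s[1] == pytest.approx(1.0 / 12.0, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rate_lists)
    def test_euler_identity_and_positivity(self, rates):
        """Degree-1 homogeneity of R implies sum_i lambda_i s_i = R."""
        prof = RateProfile(rates)
        s = sensitivities_spectral(prof).s
        R = translation_rate_spectral(prof).R
        assert np.all(s > 0.0)
        assert abs(np.dot(prof.rates, s) - R) < 1e-10 * R

    def test_fd_single_site(self):
        s = sensitivities_fd(RateProfile([1.0, 1.0]), rel_step=1e-6).s
        assert s == pytest.approx([0.25, 0.25], abs=1e-9)

    def test_fd_matches_spectral_entrywise(self, rng):
        # moderate dynamic range so FD can resolve every entry
        prof = RateProfile(rng.uniform(0.5, 2.0, 11))
        ss = sensitivities_spectral(prof).s
        sf = sensitivities_fd(prof, rel_step=1e-6).s
        assert np.max(np.abs(ss - sf) / ss) < 1e-5

    def test_fd_second_order_convergence(self):
        prof = RateProfile([0.5, 1.3, 0.8, 2.0])
        exact = sensitivities_spectral(prof).s
        e1 = np.max(np.abs(sensitivities_fd(prof, 2e-3).s - exact))
        e2 = np.max(np.abs(sensitivities_fd(prof, 1e-3).s - exact))
        assert 2.5 < e1 / e2 < 6.0

    def test_fd_bad_step(self):
        with pytest.raises(ValueError):
            sensitivities_fd(RateProfile([1.0, 1.0]), rel_step=1.5)


class TestSensitivityBound:
    def test_slow_initiation_approaches_one(self):
        # analytic: s_0 = (l1/(l0+l1))^2 -> 1 as l0 -> 0
        s = sensitivities_spectral(RateProfile([1e-6, 1.0]))
        report = check_sensitivity_bound(s)
        assert report["ok"]
        assert 0.99 < report["max_sensitivity"] < 1.0

    def test_random_sweep(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 41))
            report = check_sensitivity_bound(
                sensitivities_spectral(random_profile(rng, n)))
            assert report["ok"] and report["max_sensitivity"] < 1.0

    def test_homogeneous_peak_at_center(self):
        prof = RateProfile(np.ones(201))
        report = check_sensitivity_bound(sensitivities_spectral(prof))
        assert report["argmax"] == 100

    def test_rejects_coupled_mode(self):
        from rfmflow import SensitivityProfile
        sp = SensitivityProfile(s=np.array([0.4, -0.4]),
                                mode="coupled_boundary")
        with pytest.raises(ValueError):
            check_sensitivity_bound(sp)
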