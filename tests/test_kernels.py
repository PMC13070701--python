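"""Forward kernels: Bloch-McConnell propagation, analytical R1rho, B1 averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cestfit.exceptions import ValidationError
from cestfit.model import Acquisition, angular_frequencies, make_model
from cestfit.kernels import (Propagator, apply_b1_inhomogeneity,
                             build_bm_matrix, gaussian_b1_grid,
                             profile_baldwin, profile_matrix, profile_noex,
                             propagate, r1rho_baldwin)

A1 = dict(k_ex=300.0, p_B=0.05, delta_A=118.0, delta_delta=-5.0,
          R1_A=1.5, R2_A=10.0, R2_B=10.0)


@pytest.fixture
def a1_model():
    return make_model(**A1)


class TestBmMatrix:
    def test_shape_and_zero_first_row(self, a1_model):
        prop = build_bm_matrix(a1_model, 100.0, -200.0, 62.8)
        assert prop.generator.shape == (7, 7)
        assert np.all(prop.generator[0] == 0.0)

    def test_decoupled_eigenvalues_without_exchange_or_rf(self):
        """With k = omega1 = Omega = 0 the spectrum is the relaxation rates."""
        m = make_model(k_ex=0.0, p_B=0.05, delta_A=118.0, delta_delta=-5.0,
                       R1_A=1.3, R2_A=9.0, R2_B=17.0, R1_B=2.1)
        prop = build_bm_matrix(m, 0.0, 0.0, 0.0)
        eig = np.sort(np.linalg.eigvals(prop.generator).real)
        expected = np.sort([0.0, -9.0, -9.0, -1.3, -17.0, -17.0, -2.1])
        np.testing.assert_allclose(eig, expected, atol=1e-10)

    def test_pure_exchange_conserves_total_z(self, a1_model):
        """Without relaxation or RF, d(Mz_A + Mz_B)/dt = 0."""
        m = make_model(k_ex=300.0, p_B=0.05, delta_A=118.0, delta_delta=-5.0,
                       R1_A=0.0, R2_A=0.0, R2_B=0.0, R1_B=0.0)
        gen = build_bm_matrix(m, 0.0, 0.0, 0.0).generator
        # rows 3 (Mz_A) and 6 (Mz_B); their z-columns must cancel
        z_block = gen[np.ix_([3, 6], [3, 6])]
        np.testing.assert_allclose(z_block.sum(axis=0), 0.0, atol=1e-12)

    def test_nonfinite_rejected(self, a1_model):
        with pytest.raises(ValidationError):
            build_bm_matrix(a1_model, float("inf"), 0.0, 62.8)

    def test_propagator_validates(self):
        bad = np.ones((7, 7))
        with pytest.raises(ValidationError):
            Propagator(bad)


class TestPropagate:
    def test_zero_time_is_identity(self, a1_model):
        prop = build_bm_matrix(a1_model, 300.0, -2200.0, 62.8)
        M0 = np.array([1.0, 0.1, -0.2, 0.9, 0.0, 0.05, 0.04])
        np.testing.assert_array_equal(propagate(prop, M0, 0.0), M0)

    def test_equilibrium_is_fixed_point_without_rf(self, a1_model):
        """Detailed balance + recovery keep the equilibrium state static."""
        prop = build_bm_matrix(a1_model, 500.0, -1500.0, 0.0)
        M0 = np.array([1.0, 0.0, 0.0, a1_model.p_A, 0.0, 0.0, a1_model.p_B])
        out = propagate(prop, M0, 2.0)
        np.testing.assert_allclose(out, M0, atol=1e-12)

    def test_constant_element_preserved(self, a1_model):
        prop = build_bm_matrix(a1_model, 300.0, -2200.0, 628.0)
        out = propagate(prop, [1.0, 0, 0, a1_model.p_A, 0, 0, a1_model.p_B],
                        0.4)
        assert out[0] == pytest.approx(1.0, abs=1e-10)

    def test_negative_time_rejected(self, a1_model):
        prop = build_bm_matrix(a1_model, 0.0, 0.0, 62.8)
        with pytest.raises(ValidationError):
            propagate(prop, [1, 0, 0, 0.95, 0, 0, 0.05], -0.1)

    def test_matches_rk4_oracle(self, a1_model, oracles):
        """Matrix exponential vs independent fine-step RK4, max-abs 1e-7."""
        rng = np.random.default_rng(42)
        m = make_model(k_ex=float(rng.uniform(50, 800)),
                       p_B=float(rng.uniform(0.01, 0.1)),
                       delta_A=118.0, delta_delta=float(rng.uniform(-6, 6)),
                       R1_A=1.2, R2_A=12.0, R2_B=25.0)
        prop = build_bm_matrix(m, 900.0, -1100.0, 2 * np.pi * 25.0)
        M0 = np.array([1.0, 0, 0, m.p_A, 0, 0, m.p_B])
        exact = propagate(prop, M0, 0.4)
        ref = oracles["rk4"](prop.generator[None], M0[None], 0.4,
                             dt=1e-5)[0]
        np.testing.assert_allclose(exact, ref, atol=1e-7)


class TestMatrixKernel:
    def test_vanishing_minor_state_matches_noex(self, paper_acq):
        m = make_model(k_ex=300.0, p_B=1e-12, delta_A=118.0,
                       delta_delta=-5.0)
        offs = np.arange(113.0, 123.0, 0.5)
        pm = profile_matrix(m, paper_acq, 10.0, offs)
        pn = profile_noex(1.5, 10.0, 118.0, paper_acq, 10.0, offs)
        np.testing.assert_allclose(pm, pn, atol=1e-6)

    def test_no_exchange_matches_noex_tightly(self, paper_acq):
        m = make_model(k_ex=0.0, p_B=1e-12, delta_A=118.0, delta_delta=-5.0)
        offs = np.arange(113.0, 123.0, 0.5)
        pm = profile_matrix(m, paper_acq, 10.0, offs)
        pn = profile_noex(1.5, 10.0, 118.0, paper_acq, 10.0, offs)
        np.testing.assert_allclose(pm, pn, atol=1e-8)

    def test_far_off_resonance_baseline(self, a1_model, paper_acq):
        val = profile_matrix(a1_model, paper_acq, 10.0, [1118.0])[0]
        assert 0.999 <= val <= 1.0

    def test_two_dips_at_expected_shifts(self, a1_model, paper_acq):
        """A1 shows dips at 118.0 (ground) and 113.0 (minor), deeper at 118."""
        import scipy.signal
        grid = np.arange(104.0, 130.0 + 1e-9, 0.25)
        prof = profile_matrix(a1_model, paper_acq, 10.0, grid)
        idx, _ = scipy.signal.find_peaks(-prof, prominence=0.05)
        positions = sorted(grid[idx])
        assert len(positions) == 2
        assert abs(positions[0] - 113.0) <= 0.25
        assert abs(positions[1] - 118.0) <= 0.25
        assert prof[np.searchsorted(grid, positions[1])] < \
            prof[np.searchsorted(grid, positions[0])]

    def test_swap_symmetry(self, a1_model, paper_acq):
        """Relabeling A<->B and observing B reproduces the profile."""
        offs = np.arange(104.0, 130.0, 0.5)
        direct = profile_matrix(a1_model, paper_acq, 10.0, offs, observe="A")
        swapped = make_model(
            k_ex=a1_model.k_ex, p_B=a1_model.p_A,
            delta_A=a1_model.delta_B, delta_delta=-a1_model.delta_delta,
            R1_A=a1_model.R1_B, R1_B=a1_model.R1_A,
            R2_A=a1_model.R2_B, R2_B=a1_model.R2_A)
        mirrored = profile_matrix(swapped, paper_acq, 10.0, offs,
                                  observe="B")
        np.testing.assert_allclose(direct, mirrored, atol=1e-8)

    def test_singular_generator_fallback(self, paper_acq):
        """No relaxation and no RF: magnetization stays at equilibrium."""
        m = make_model(k_ex=300.0, p_B=0.05, delta_A=118.0, delta_delta=-5.0,
                       R1_A=0.0, R2_A=0.0, R2_B=0.0, R1_B=0.0)
        offs = np.array([110.0, 118.0, 126.0])
        out = profile_matrix(m, paper_acq, 1e-12, offs)
        np.testing.assert_allclose(out, 1.0, atol=1e-6)


class TestR1rho:
    def test_no_exchange_closed_form(self, paper_acq):
        m = make_model(k_ex=0.0, p_B=0.05, delta_A=118.0, delta_delta=-5.0,
                       R1_A=1.5, R2_A=10.0)
        oA = np.array([50.0, 200.0, -800.0])
        o1 = 2 * np.pi * 25.0
        got = r1rho_baldwin(m, oA, oA, o1)
        cos2 = oA ** 2 / (oA ** 2 + o1 ** 2)
        np.testing.assert_allclose(got, 1.5 * cos2 + 10.0 * (1 - cos2),
                                   rtol=1e-12)

    def test_far_off_resonance_approaches_r1(self, a1_model):
        got = r1rho_baldwin(a1_model, np.array([1e7]), np.array([1e7]),
                            2 * np.pi * 25.0)[0]
        assert got == pytest.approx(a1_model.R1_A, rel=1e-3)

    def test_positive_and_finite_on_grid(self, a1_model, paper_acq):
        offs = np.arange(104.0, 130.0, 0.25)
        for nu1 in (10.0, 100.0):
            oA, oB, o1 = angular_frequencies(a1_model, paper_acq, offs, nu1)
            r = r1rho_baldwin(a1_model, oA, oB, o1)
            assert np.all(np.isfinite(r)) and np.all(r > 0)

    def test_matches_trott_palmer_in_slow_exchange(self, paper_acq, oracles):
        """Agreement with the literature closed form in its validity domain."""
        m = make_model(k_ex=100.0, p_B=0.01, delta_A=118.0, delta_delta=-5.0,
                       R1_A=1.5, R2_A=10.0, R2_B=10.0)
        offs = np.array([112.0, 112.5, 113.0, 113.5, 114.0, 116.0, 120.0,
                         124.0])
        oA, oB, o1 = angular_frequencies(m, paper_acq, offs, 25.0)
        mine = r1rho_baldwin(m, oA, oB, o1)
        ref = oracles["trott_palmer"](m, oA, oB, o1)
        np.testing.assert_allclose(mine, ref, rtol=0.02)

    def test_zero_rf_rejected(self, a1_model):
        with pytest.raises(ValidationError):
            r1rho_baldwin(a1_model, np.array([100.0]), np.array([0.0]), 0.0)


class TestBaldwinKernel:
    def test_zero_saturation_time_returns_equilibrium(self, a1_model):
        acq0 = Acquisition(larmor_MHz=80.12, T_sat=0.0, b1_fields=(10.0,))
        out = profile_baldwin(a1_model, acq0, 10.0,
                              [104.0, 113.0, 118.0, 130.0])
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_ground_state_resonance_saturates(self, a1_model, paper_acq):
        assert profile_baldwin(a1_model, paper_acq, 10.0, [118.0])[0] < 0.02

    def test_far_off_resonance_baseline(self, a1_model, paper_acq):
        val = profile_baldwin(a1_model, paper_acq, 10.0, [1118.0])[0]
        assert 0.999 <= val <= 1.0

    def test_close_to_matrix_kernel(self, a1_model, paper_acq):
        offs = np.arange(104.0, 130.0 + 1e-9, 0.25)
        for nu1 in (10.0, 100.0):
            pm = profile_matrix(a1_model, paper_acq, nu1, offs)
            pb = profile_baldwin(a1_model, paper_acq, nu1, offs)
            assert np.max(np.abs(pm - pb)) < 0.01


class TestNoexKernel:
    def test_far_off_resonance_baseline(self, paper_acq):
        assert profile_noex(1.5, 10.0, 118.0, paper_acq, 10.0,
                            [1118.0])[0] >= 0.999

    def test_dip_halfwidth_grows_with_rf(self, paper_acq):
        """Saturation width increases monotonically with the RF amplitude."""
        grid = np.arange(114.0, 122.0, 0.01)
        widths = []
        for nu1 in (10.0, 25.0, 50.0, 100.0):
            prof = profile_noex(1.5, 10.0, 118.0, paper_acq, nu1, grid)
            depth = 1.0 - prof.min()
            below = grid[prof < 1.0 - depth / 2.0]
            widths.append(below.max() - below.min())
        assert all(b > a for a, b in zip(widths, widths[1:]))


class TestB1Inhomogeneity:
    def test_degenerate_distribution_is_identity(self, a1_model, paper_acq):
        offs = np.arange(110.0, 126.0, 0.5)
        fn = lambda nu1, o: profile_baldwin(a1_model, paper_acq, nu1, o)
        nominal = fn(10.0, offs)
        for kwargs in (dict(frac_sigma=0.0, n_points=11),
                       dict(frac_sigma=0.1, n_points=1)):
            out = apply_b1_inhomogeneity(fn, 10.0, offsets_ppm=offs, **kwargs)
            np.testing.assert_array_equal(out, nominal)

    @pytest.mark.parametrize("frac_sigma,n_points",
                             [(0.05, 3), (0.1, 11), (0.2, 101), (0.5, 7)])
    def test_weights_normalized(self, frac_sigma, n_points):
        _, weights = gaussian_b1_grid(100.0, frac_sigma, n_points)
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_quadrature_converged_at_11_points(self, a1_model, paper_acq):
        offs = np.arange(104.0, 130.0, 0.25)
        fn = lambda nu1, o: profile_baldwin(a1_model, paper_acq, nu1, o)
        coarse = apply_b1_inhomogeneity(fn, 100.0, 0.1, 11, offs)
        fine = apply_b1_inhomogeneity(fn, 100.0, 0.1, 101, offs)
        assert np.max(np.abs(coarse - fine)) < 1e-3

    def test_unphysical_width_rejected(self):
        with pytest.raises(ValidationError, match="frac_sigma"):
            gaussian_b1_grid(100.0, 0.6, 11)

    @pytest.mark.parametrize("n", [0, 2, 10])
    def test_even_or_zero_points_rejected(self, n):
        with pytest.raises(ValidationError, match="n_points"):
            gaussian_b1_grid(100.0, 0.1, n)


@given(k_ex=st.floats(1.0, 2000.0), p_B=st.floats(1e-3, 0.3),
       delta_delta=st.floats(-8.0, 8.0), r2b=st.floats(0.5, 100.0))
@settings(max_examples=15, deadline=None, derandomize=True)
def test_all_kernels_bounded(k_ex, p_B, delta_delta, r2b, paper_acq):
    """Intensities stay in [-1, 1]; the far baseline stays at 1."""
    m = make_model(k_ex=k_ex, p_B=p_B, delta_A=118.0,
                   delta_delta=delta_delta, R1_A=1.5, R2_A=10.0, R2_B=r2b)
    offs = np.arange(106.0, 130.0, 1.0)
    for prof in (profile_matrix(m, paper_acq, 25.0, offs),
                 profile_baldwin(m, paper_acq, 25.0, offs),
                 profile_noex(m.R1_A, m.R2_A, m.delta_A, paper_acq, 25.0,
                              offs)):
        assert np.all(prof >= -1.0 - 1e-9) and np.all(prof <= 1.0 + 1e-9)
    far = profile_matrix(m, paper_acq, 25.0, [1118.0])[0]
    assert 0.999 <= far <= 1.0 + 1e-12
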