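"""Density criterion, plateau / fractional-density selection, AIC/BIC, CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from climenet import (
    CovarianceMatrix,
    DensProfile,
    LambdaGrid,
    aic_bic_select,
    dens,
    dens_profile,
    kcv_select,
    make_lambda_grid,
    sample_covariance,
    select_lambda_p,
    select_lambda_platu,
)
from conftest import random_spd


class TestDens:
    def test_identity_and_zero_and_hand_case(self):
        assert dens(np.eye(10)) == 10.0
        assert dens(np.zeros((4, 4))) == 0.0
        assert dens(np.array([[2.0, -1.0], [-1.0, 2.0]])) == 6.0


class TestLambdaGrid:
    def test_default_grid_bounds_and_monotonicity(self):
        g = make_lambda_grid()
        assert len(g) == 30
        assert g.values[0] == pytest.approx(0.4)
        assert g.values[-1] == pytest.approx(1e-10)
        assert np.all(np.diff(g.values) < 0)

    @pytest.mark.parametrize("bad", [[0.5, 0.5], [0.2, 0.5], [1.2, 0.1], [0.1, -0.5]])
    def test_invalid_grids_rejected(self, bad):
        with pytest.raises(ValueError):
            LambdaGrid(np.array(bad))


class TestDensProfile:
    def test_identity_covariance_closed_form(self):
        sigma = CovarianceMatrix(np.eye(6), n_obs=100)
        grid = make_lambda_grid(0.5, 0.01, 8)
        prof = dens_profile(sigma, grid)
        np.testing.assert_allclose(prof.dens, 6 * (1 - grid.values), atol=1e-6)

    def test_profile_nondecreasing_as_lambda_falls(self, toy_sigma):
        prof = dens_profile(toy_sigma, make_lambda_grid(0.4, 1e-8, 15))
        assert np.all(np.diff(prof.dens) >= -1e-6)

    def test_small_lambda_end_approaches_inverse_density(self, toy_sigma):
        prof = dens_profile(toy_sigma, make_lambda_grid(0.4, 1e-10, 20))
        target = np.abs(np.linalg.inv(toy_sigma.values)).sum()
        assert prof.dens[-1] == pytest.approx(target, rel=0.01)

    def test_early_stopping_matches_full_profile_selection(self, toy_sigma):
        grid = make_lambda_grid(0.4, 1e-10, 20)
        full = dens_profile(toy_sigma, grid)
        early = dens_profile(toy_sigma, grid, stop_early=True)
        assert (select_lambda_platu(early).lam_selected
                == select_lambda_platu(full).lam_selected)


def _profile_from_dens(dens_values, lambdas=None):
    d = np.asarray(dens_values, dtype=float)
    if lambdas is None:
        lambdas = np.logspace(-1, -5, d.size)
    return DensProfile(LambdaGrid(np.asarray(lambdas)), d)


class TestPlateauSelection:
    def test_constant_profile_selects_largest_lambda(self):
        prof = _profile_from_dens([5.0, 5.0, 5.0, 5.0])
        assert select_lambda_platu(prof).index == 0

    def test_plateau_onset_found(self):
        # relative gaps 0.9, 0.5, 0.009, 0.005, 0 -> plateau starts at index 2
        prof = _profile_from_dens(np.array([0.1, 0.5, 0.991, 0.995, 1.0]) * 8.0)
        assert select_lambda_platu(prof, epsilon=0.01).index == 2

    def test_flattening_profile_shape(self):
        # steep improvement then flattening: the rule picks the flattening point
        lambdas = np.logspace(np.log10(0.4), -6, 25)
        d = 100 * (1 - 1 / (1 + (4e-4 / lambdas) ** 0.8))
        prof = _profile_from_dens(d, lambdas)
        sel = select_lambda_platu(prof, epsilon=0.01)
        dmax = d.max()
        assert np.all(np.abs(d[sel.index:] - dmax) / dmax <= 0.01)
        if sel.index > 0:
            assert abs(d[sel.index - 1] - dmax) / dmax > 0.01
        assert sel.lam_selected < 4e-4  # on the flat tail, not the steep rise

    def test_no_plateau_returns_smallest_with_warning(self):
        # non-monotone profile whose tail falls away from the maximum:
        # no grid point satisfies the plateau condition
        prof = _profile_from_dens([1.0, 8.0, 4.0])
        sel = select_lambda_platu(prof, epsilon=0.001)
        assert sel.index == 2
        assert sel.warning is not None


class TestFractionalDensitySelection:
    def test_constant_profile_tie_breaks_to_largest_lambda(self):
        prof = _profile_from_dens([3.0, 3.0, 3.0])
        assert select_lambda_p(prof, 0.5).index == 0

    def test_equidistant_tie_prefers_sparser(self):
        # dens 1..10, target 4.5: dens 4 and 5 tie; larger lambda (dens 4) wins
        prof = _profile_from_dens(np.arange(1.0, 11.0))
        assert select_lambda_p(prof, 0.45).index == 3

    def test_linear_profile_picks_nearest(self):
        prof = _profile_from_dens(np.arange(1.0, 11.0))
        sel = select_lambda_p(prof, 0.75)  # target 7.5: dens 7 vs 8 tie -> dens 7
        assert sel.index == 6

    def test_p_limits(self):
        prof = _profile_from_dens([1.0, 4.0, 9.0, 10.0])
        assert select_lambda_p(prof, 0.999).index == 3
        assert select_lambda_p(prof, 0.01).index == 0

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_p_rejected(self, p):
        prof = _profile_from_dens([1.0, 2.0])
        with pytest.raises(ValueError):
            select_lambda_p(prof, p)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6), st.floats(0.05, 0.95))
def test_fractional_selection_minimizes_distance(seed, p):
    d = np.sort(np.random.default_rng(seed).uniform(0.1, 10.0, size=12))
    prof = _profile_from_dens(d)
    sel = select_lambda_p(prof, p)
    dist = np.abs(d - p * d.max())
    assert dist[sel.index] == dist.min()
    assert sel.lam_selected in prof.grid.values


def test_platu_never_below_argmax_lambda():
    rng = np.random.default_rng(7)
    for _ in range(20):
        d = np.cumsum(rng.uniform(0, 1, size=10))  # non-decreasing profile
        prof = _profile_from_dens(d)
        sel = select_lambda_platu(prof)
        argmax_lam = prof.grid.values[int(np.argmax(d))]
        assert sel.lam_selected >= argmax_lam


class TestInformationCriteria:
    def test_identity_covariance_prefers_small_lambda(self):
        # estimate is (1-lam) I: fit improves as lam -> 0 at constant df
        sigma = CovarianceMatrix(np.eye(5), n_obs=100)
        grid = LambdaGrid(np.array([0.5, 0.1, 0.01]))
        for crit in ("aic", "bic"):
            sel = aic_bic_select(sigma, grid, criterion=crit)
            assert sel.lam_selected == pytest.approx(0.01)

    def test_single_point_grid(self, toy_sigma):
        sel = aic_bic_select(toy_sigma, LambdaGrid(np.array([0.05])), "aic")
        assert sel.lam_selected == pytest.approx(0.05)

    def test_scores_and_df_recorded_per_grid_point(self, toy_sigma):
        grid = make_lambda_grid(0.4, 1e-4, 6)
        sel = aic_bic_select(toy_sigma, grid, "bic")
        assert sel.score_trace.shape == (6,)
        assert np.all(np.diff(sel.df) >= 0)  # denser as lambda falls


class TestCrossValidation:
    def test_identical_halves_reduce_to_in_sample_loss(self):
        rng = np.random.default_rng(5)
        half = rng.standard_normal((20, 4))
        ts = np.vstack([half, half])
        grid = make_lambda_grid(0.4, 1e-3, 5)
        sel = kcv_select(ts, grid, loss="neg_loglik", k=2)
        # train block == validation block, so the CV loss is the in-sample
        # loss of each half; check the curve is finite and selection in grid
        assert np.all(np.isfinite(sel.score_trace))
        assert sel.lam_selected in grid.values

    def test_single_lambda_grid(self):
        ts = np.random.default_rng(6).standard_normal((40, 3))
        sel = kcv_select(ts, LambdaGrid(np.array([0.05])), loss="trace_l2")
        assert sel.lam_selected == pytest.approx(0.05)

    def test_too_few_timepoints_rejected(self):
        ts = np.random.default_rng(0).standard_normal((8, 3))
        with pytest.raises(ValueError, match="T >= 2k"):
            kcv_select(ts, k=5)

    def test_deterministic_given_inputs(self):
        ts = np.random.default_rng(9).standard_normal((50, 5))
        grid = make_lambda_grid(0.4, 1e-4, 6)
        a = kcv_select(ts, grid, loss="neg_loglik")
        b = kcv_select(ts, grid, loss="neg_loglik")
        assert a.lam_selected == b.lam_selected
        np.testing.assert_array_equal(a.score_trace, b.score_trace)
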