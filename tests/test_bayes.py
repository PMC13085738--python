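"""Hierarchical model, directional tests, ICC and convergence checks."""

import numpy as np
import pandas as pd
import pytest

from cleanstation.bayes import (
    FitDiagnostics,
    ModelSpec,
    PosteriorDraws,
    bin_surface_area,
    cell_mean_test,
    diagnostics,
    fit_hierarchical,
    icc,
    icc_category,
    one_sided_test,
    transform_policy,
)

LEVELS = ("before", "first", "second", "after")


def _draws_from_beta(beta_flat, levels=("a", "b")):
    """Minimal two-level PosteriorDraws with a prescribed contrast vector."""
    beta = np.asarray(beta_flat, dtype=float).reshape(2, -1, 1)
    c, d = beta.shape[:2]
    z = np.zeros((c, d))
    o = np.ones((c, d))
    return PosteriorDraws(
        levels=levels, mu=z, beta=beta, sigma_station=o, sigma_area=o,
        sigma_resid=o, u=np.zeros((c, d, 1)), v=np.zeros((c, d, 1)),
        fitted_var=o,
    )


class TestDirectionalSummaries:
    def test_er_is_one_at_even_odds(self):
        draws = _draws_from_beta([1.0, -1.0] * 10)
        res = one_sided_test(draws, ("b", "a"), ">")
        assert res.pp == pytest.approx(0.5)
        assert res.er == pytest.approx(1.0)

    def test_nineteen_of_twenty_draws(self):
        draws = _draws_from_beta([1.0] * 19 + [-1.0])
        res = one_sided_test(draws, ("b", "a"), ">")
        assert res.pp == pytest.approx(0.95)
        assert res.er == pytest.approx(19.0)

    def test_er_formula_matches_largest_printed_values(self):
        # PP = 0.999875 over 8000 draws -> ER = 7999
        draws = _draws_from_beta([1.0] * 7999 + [-1.0])
        res = one_sided_test(draws, ("b", "a"), ">")
        assert res.pp == pytest.approx(0.999875)
        assert res.er == pytest.approx(7999.0)

    def test_unanimous_draws_hit_finite_cap(self):
        draws = _draws_from_beta([1.0] * 2000)
        res = one_sided_test(draws, ("b", "a"), ">")
        assert res.pp == 1.0
        assert res.er == pytest.approx((2000 - 0.5) / 0.5)

    def test_opposite_directions_sum_to_one(self):
        rng = np.random.default_rng(0)
        draws = _draws_from_beta(rng.normal(0.3, 1.0, 2000))
        a = one_sided_test(draws, ("b", "a"), ">")
        b = one_sided_test(draws, ("a", "b"), ">")
        assert a.pp + b.pp == pytest.approx(1.0)

    def test_credible_intervals_nested_and_percentile_based(self):
        rng = np.random.default_rng(1)
        vec = rng.normal(2.0, 1.0, 4000)
        draws = _draws_from_beta(vec)
        res = one_sided_test(draws, ("b", "a"), ">")
        lo95, hi95 = np.percentile(vec, [2.5, 97.5])
        assert res.ci95 == pytest.approx((lo95, hi95))
        assert res.ci95[0] <= res.ci75[0] <= res.ci75[1] <= res.ci95[1]
        assert res.estimate == pytest.approx(vec.mean())

    def test_cell_mean_test_directions(self):
        rng = np.random.default_rng(2)
        vec = rng.normal(-1.0, 0.5, 2000)  # cell mean below zero
        draws = _draws_from_beta(vec)
        below = cell_mean_test(draws, "b", "<")
        above = cell_mean_test(draws, "b", ">")
        assert below.pp + above.pp == pytest.approx(1.0)
        assert below.pp > 0.9
        assert below.estimate == pytest.approx(vec.mean())


class TestICC:
    def test_zero_station_variance_is_minimal(self):
        d = _draws_from_beta([1.0] * 10)
        d.sigma_station = np.zeros_like(d.sigma_station)
        out = icc(d)
        assert out["station"] == (0.0, "minimal")

    def test_equal_station_and_residual_variance(self):
        d = _draws_from_beta([1.0] * 10)
        d.sigma_area = np.zeros_like(d.sigma_area)
        val, cat = icc(d)["station"]
        assert val == pytest.approx(0.5)
        assert cat == "strong"

    def test_fixed_draws_match_direct_arithmetic(self):
        d = _draws_from_beta([1.0] * 4)
        d.sigma_station = np.full_like(d.sigma_station, 2.0)  # var 4
        d.sigma_area = np.full_like(d.sigma_area, 1.0)  # var 1
        d.sigma_resid = np.full_like(d.sigma_resid, np.sqrt(5.0))  # var 5
        out = icc(d)
        assert out["station"][0] == pytest.approx(0.4)
        assert out["area_group"][0] == pytest.approx(0.1)
        assert out["total"][0] == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "value,category",
        [(0.01, "minimal"), (0.05, "meaningful"), (0.12, "meaningful"), (0.3, "strong")],
    )
    def test_category_rule(self, value, category):
        assert icc_category(value) == category


class TestTransformPolicy:
    def test_skewed_rates_get_sqrt(self):
        for v in ("cleaning_rate", "mean_clean_duration_s", "posing_rate"):
            assert transform_policy(v) == "sqrt"

    def test_signed_variables_stay_identity(self):
        assert transform_policy("responsiveness_cm") == "identity"
        assert transform_policy("selectivity") == "identity"

    def test_override(self):
        assert transform_policy("cleaning_rate", overrides={"cleaning_rate": "identity"}) == "identity"

    def test_sqrt_of_negative_named_rows(self, mixed_model_data):
        df = mixed_model_data(0)
        df.loc[3, "y"] = -1.0
        spec = ModelSpec.fast("y", LEVELS, transform="sqrt")
        with pytest.raises(ValueError, match="negative values at rows"):
            fit_hierarchical(df, spec, 0)


class TestModelSpec:
    def test_chain_and_iteration_invariants(self):
        with pytest.raises(ValueError, match="2 chains"):
            ModelSpec("y", LEVELS, chains=1)
        with pytest.raises(ValueError, match="exceed warmup"):
            ModelSpec("y", LEVELS, iterations=100, warmup=100)

    def test_default_matches_reported_sampler_settings(self):
        spec = ModelSpec("y", LEVELS)
        assert (spec.chains, spec.iterations, spec.warmup) == (4, 15_000, 5_000)


class TestFitHierarchical:
    def test_null_data_recovers_no_effect(self, mixed_model_data):
        df = mixed_model_data(3, beta_second=0.0, station_sd=0.0)
        draws = fit_hierarchical(df, ModelSpec.fast("y", LEVELS), 1)
        for lev in LEVELS[1:]:
            b = draws.level_effect(lev)
            assert abs(b.mean()) < 3 * b.std()

    def test_reproducible_for_fixed_seed(self, mixed_model_data):
        df = mixed_model_data(4)
        d1 = fit_hierarchical(df, ModelSpec.fast("y", LEVELS), 7)
        d2 = fit_hierarchical(df, ModelSpec.fast("y", LEVELS), 7)
        assert np.array_equal(d1.beta, d2.beta)

    def test_collapsed_grouping_matches_least_squares(self, mixed_model_data):
        """With no station or area variance the fixed effects shrink to the
        ordinary least-squares cell estimates."""
        df = mixed_model_data(5, beta_second=-1.5, station_sd=0.0, resid_sd=0.2)
        df["area_group"] = "all"
        spec = ModelSpec.fast("y", LEVELS)
        draws = fit_hierarchical(df, spec, 2)
        # closed-form OLS for a one-way layout: cell means
        cell = df.groupby("replicate")["y"].mean()
        ref = cell["before"]
        for lev in LEVELS[1:]:
            post = draws.level_effect(lev)
            assert post.mean() == pytest.approx(cell[lev] - ref, abs=4 * post.std())

    def test_missing_responses_dropped(self, mixed_model_data):
        df = mixed_model_data(6)
        df.loc[df["replicate"] == "after", "y"] = np.nan
        draws = fit_hierarchical(df, ModelSpec.fast("y", LEVELS), 3)
        assert draws.levels == ("before", "first", "second")

    def test_single_station_rejected(self, mixed_model_data):
        df = mixed_model_data(7)
        df = df[df["station_id"] == "S00"]
        with pytest.raises(ValueError, match="2 stations"):
            fit_hierarchical(df, ModelSpec.fast("y", LEVELS), 0)


class TestDiagnostics:
    def _iid_draws(self, chains=4, n=1000, offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.normal(0, 1, (chains, n))
        mu[0] += offset
        o = np.abs(rng.normal(1, 0.1, (chains, n)))
        return PosteriorDraws(
            levels=("a", "b"), mu=mu, beta=rng.normal(0, 1, (chains, n, 1)),
            sigma_station=o, sigma_area=o.copy(), sigma_resid=o.copy(),
            u=np.zeros((chains, n, 1)), v=np.zeros((chains, n, 1)),
            fitted_var=o.copy(),
        )

    def test_iid_chains_pass_rhat(self):
        diag = diagnostics(self._iid_draws())
        assert diag.max_rhat < 1.01
        assert diag.converged

    def test_offset_chain_flagged(self):
        diag = diagnostics(self._iid_draws(offset=10.0))
        assert diag.rhat["mu"] > 1.01
        assert not diag.converged

    def test_duplicated_chains_bound_ess(self):
        d = self._iid_draws(chains=2, n=500)
        d.mu[1] = d.mu[0]  # identical chains
        diag = diagnostics(d)
        assert diag.ess_bulk["mu"] <= 2 * 500

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            diagnostics(self._iid_draws(chains=1))


class TestBinSurfaceArea:
    def test_quartile_bins(self):
        areas = pd.Series(np.arange(1.0, 21.0), index=[f"S{i}" for i in range(20)])
        bins = bin_surface_area(areas, 4)
        assert bins.nunique() == 4
        assert (bins.value_counts() == 5).all()

    def test_verbatim_one_level_per_value(self):
        areas = pd.Series([1.2, 3.4, 3.4, 9.9])
        assert bin_surface_area(areas, 0).nunique() == 3
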