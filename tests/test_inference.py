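"""Tests for the grid screen, greedy chains and derived fit quantities."""

import numpy as np
import pandas as pd
import pytest

from ratchetscan import ScanParameters, exact_recognition_probabilities, solo_layout
from ratchetscan.inference import (
    ChainConfig,
    fit_context_leakage,
    grid_screen,
    load_observations,
    observed_vector,
    predict_nmd_null,
    predicted_expression,
    rss,
    run_chain,
    run_chains,
    summarize_chains,
)
from ratchetscan.synthetic_data import generate_gfp_table


@pytest.fixture(scope="module")
def small_geometry():
    """A reduced reporter window keeping chain tests fast."""
    from ratchetscan import duo_layout

    up, down = 25, 25
    solo = solo_layout(up, down)
    duos = [duo_layout(p, up, down) for p in (8, 9, 11, 12, 14, 15)]
    return solo, duos


class TestRss:
    def test_identical_vectors_give_zero(self):
        assert rss(np.ones(4), np.ones(4)) == 0.0

    def test_hand_computed_values(self):
        assert rss(np.array([1.0, 1.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)
        assert rss(np.array([0.5, 0.9]), np.array([0.6, 0.7])) == pytest.approx(0.05)

    def test_length_mismatch_and_nan_rejected(self):
        with pytest.raises(ValueError):
            rss(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            rss(np.array([np.nan]), np.array([1.0]))


class TestPredictedExpression:
    def test_oracle_and_simulation_agree(self, small_geometry, rng):
        solo, duos = small_geometry
        params = ScanParameters(0.005, 0.6, 0.5)
        oracle = predicted_expression(solo, duos, params, use_oracle=True)
        sim = predicted_expression(solo, duos, params, sims_per_variant=8000, rng=rng)
        assert np.allclose(oracle, sim, atol=0.05)

    def test_scale_equivariance_of_the_objective(self, small_geometry):
        """Solo normalisation makes the RSS invariant to raw-intensity units."""
        solo, duos = small_geometry
        params = ScanParameters(0.005, 0.6, 0.5)
        norm = predicted_expression(solo, duos, params, use_oracle=True)
        raw_solo = exact_recognition_probabilities(solo, params).expression * 37.5
        raw = np.array(
            [exact_recognition_probabilities(d, params).expression * 37.5 for d in duos]
        )
        assert np.allclose(raw / raw_solo, norm)


class TestGridScreen:
    def test_single_value_grid_returns_that_set(self, small_geometry):
        solo, duos = small_geometry
        params = ScanParameters(0.005, 0.6, 0.5)
        observed = predicted_expression(solo, duos, params, use_oracle=True)
        grid = {"p_pawl": [0.005], "p_leakage": [0.6], "p_nmd": [0.5]}
        result = grid_screen(observed, solo, duos, grid=grid, use_oracle=True)
        assert result.start == params
        assert result.top_sets == [params]
        assert result.table["rss"].iloc[0] == pytest.approx(0.0)

    def test_generating_grid_point_ranks_first_without_noise(self, small_geometry):
        solo, duos = small_geometry
        truth = ScanParameters(0.01, 0.6, 0.5)
        observed = predicted_expression(solo, duos, truth, use_oracle=True)
        grid = {"p_pawl": [0.001, 0.01, 0.1], "p_leakage": [0.3, 0.6, 0.8], "p_nmd": [0.2, 0.5, 0.8]}
        result = grid_screen(observed, solo, duos, grid=grid, use_oracle=True, top_k=5)
        assert truth in result.top_sets
        best = result.table.iloc[0]
        assert ScanParameters(best.p_pawl, best.p_leakage, best.p_nmd) == truth

    def test_empty_observations_rejected(self, small_geometry):
        solo, duos = small_geometry
        with pytest.raises(ValueError):
            grid_screen(np.array([]), solo, duos, use_oracle=True)


class TestChains:
    def test_running_minimum_rss_non_increasing(self, small_geometry, rng):
        solo, duos = small_geometry
        truth = ScanParameters(0.005, 0.6, 0.5)
        observed = predicted_expression(solo, duos, truth, use_oracle=True)
        config = ChainConfig(n_iterations=30, use_oracle=True)
        result = run_chain(observed, solo, duos, ScanParameters(0.01, 0.4, 0.3), config, rng)
        running = result.trace["rss"].cummin()
        assert (result.trace["rss"].values == running.values).all()  # incumbent RSS only falls
        assert result.best_rss == pytest.approx(result.trace["rss"].min())

    def test_accepted_iterations_strictly_decrease_rss(self, small_geometry, rng):
        solo, duos = small_geometry
        truth = ScanParameters(0.005, 0.6, 0.5)
        observed = predicted_expression(solo, duos, truth, use_oracle=True)
        config = ChainConfig(n_iterations=40, use_oracle=True)
        result = run_chain(observed, solo, duos, ScanParameters(0.02, 0.3, 0.8), config, rng)
        accepted = result.trace[result.trace["accepted"]]
        diffs = accepted["rss"].diff().dropna()
        assert (diffs < 0).all()

    def test_one_parameter_changes_per_iteration_in_cyclic_order(self, small_geometry, rng):
        solo, duos = small_geometry
        observed = predicted_expression(solo, duos, ScanParameters(0.005, 0.6, 0.5), use_oracle=True)
        config = ChainConfig(n_iterations=9, use_oracle=True)
        result = run_chain(observed, solo, duos, ScanParameters(0.01, 0.4, 0.3), config, rng)
        trace = result.trace
        order = ("p_pawl", "p_leakage", "p_nmd")
        for it in range(1, 10):
            updated = order[(it - 1) % 3]
            for name in order:
                if name == updated:
                    continue
                if trace.loc[it, "accepted"]:
                    assert trace.loc[it, name] == trace.loc[it - 1, name]

    def test_fixed_parameters_never_move(self, rng):
        solo = solo_layout(25, 25)
        ref = ScanParameters(0.005, 0.6, 0.5)
        observed = np.array([1.1])
        config = ChainConfig(n_iterations=20, fixed=("p_pawl", "p_nmd"), use_oracle=True)
        result = run_chain(observed, solo, [solo_layout(25, 25, leakage_override=None)],
                           ref, config, rng)
        assert (result.trace["p_pawl"] == ref.p_pawl).all()
        assert (result.trace["p_nmd"] == ref.p_nmd).all()

    def test_summarize_chains(self, small_geometry, rng):
        solo, duos = small_geometry
        observed = predicted_expression(solo, duos, ScanParameters(0.005, 0.6, 0.5), use_oracle=True)
        config = ChainConfig(n_iterations=5, use_oracle=True)
        results = run_chains(observed, solo, duos, ScanParameters(0.01, 0.5, 0.5), config, 3, 11)
        summary = summarize_chains(results)
        best = [r.best_params for r in results]
        assert summary.loc["p_nmd", "mean"] == pytest.approx(np.mean([p.p_nmd for p in best]))
        with pytest.raises(ValueError):
            summarize_chains(results[:1])

    def test_identical_chains_have_zero_se(self, small_geometry):
        solo, duos = small_geometry
        observed = predicted_expression(solo, duos, ScanParameters(0.005, 0.6, 0.5), use_oracle=True)
        config = ChainConfig(n_iterations=5, use_oracle=True)
        r = run_chain(observed, solo, duos, ScanParameters(0.01, 0.5, 0.5), config,
                      np.random.default_rng(4))
        summary = summarize_chains([r, r])
        assert (summary["se"] == 0).all()


class TestContextLeakage:
    def test_recovery_and_ordering(self):
        """Per-context leakage fits recover planted context strengths A<G<C<T."""
        solo = solo_layout(25, 25)
        p_pawl, p_nmd, ref_leak = 0.005, 0.5, 0.6
        planted = {"A": 0.40, "G": 0.55, "C": 0.70, "T": 0.85}
        ref_expr = exact_recognition_probabilities(
            solo, ScanParameters(p_pawl, ref_leak, p_nmd)
        ).expression
        observed = {
            ctx: exact_recognition_probabilities(
                solo, ScanParameters(p_pawl, leak, p_nmd)
            ).expression / ref_expr
            for ctx, leak in planted.items()
        }
        config = ChainConfig(n_iterations=40, fixed=("p_pawl", "p_nmd"), use_oracle=True)
        fits = fit_context_leakage(
            observed, p_pawl, p_nmd, ref_leak, solo=solo, config=config, n_chains=3, seed=5
        )
        for ctx, leak in planted.items():
            assert fits.loc[ctx, "p_leakage_mean"] == pytest.approx(leak, abs=0.1)
        ordered = fits.loc[["A", "G", "C", "T"], "p_leakage_mean"]
        assert ordered.is_monotonic_increasing
        assert fits.loc[["A", "G", "C", "T"], "net_leakage"].is_monotonic_increasing


class TestNmdNull:
    def test_mrna_one_and_expression_not_below_nmd_fit(self, small_geometry):
        solo, duos = small_geometry
        params = ScanParameters(0.005, 0.6, 0.5)
        null = predict_nmd_null(solo, duos, params)
        assert np.allclose(null["mrna"], 1.0)
        for layout, row in zip([solo, *duos], null.itertuples()):
            res_null = exact_recognition_probabilities(layout, params.replace(p_nmd=0.0))
            functional_fraction = float(res_null.p_init[layout.functional_mask()].sum())
            assert row.expression == pytest.approx(functional_fraction)
            with_nmd = exact_recognition_probabilities(layout, params).expression
            assert row.expression >= with_nmd - 1e-12


class TestObservationIO:
    def test_tsv_round_trip_and_position_means(self, tmp_path, fit_layouts):
        solo, duos = fit_layouts
        params = ScanParameters(0.001, 0.77, 0.62)
        table, _ = generate_gfp_table(solo, duos, params, noise_sd=0.0)
        path = tmp_path / "obs.tsv"
        table.to_csv(path, sep="\t", index=False)
        loaded = load_observations(path)
        oof = [d for d in duos if not d.sites[1].functional]
        positions = [d.sites[1].position - d.upstream_len for d in oof]
        observed = observed_vector(loaded, positions)
        oracle = predicted_expression(solo, oof, params, use_oracle=True)
        assert np.allclose(observed, oracle)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"label": ["x"], "gfp_norm": [1.0]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            load_observations(path)
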