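"""Tornado (one-way DSA) and probabilistic sensitivity analysis behavior."""

import numpy as np
import pandas as pd
import pytest

from netcea import (
    ceac,
    incremental_scatter,
    net_monetary_benefit,
    one_way_dsa,
    sample_psa,
    tornado,
    uncertain_parameters,
)
from netcea.sensitivity import (
    PSASamples,
    _incremental_nmb,
    get_parameter,
    set_parameter,
)


class TestParameterRegistry:
    def test_get_set_roundtrip(self, config):
        for name in ("prevalence", "PET/CT.sensitivity", "costs.biopsy",
                     "utilities.clinically_relevant_treated",
                     "transitions.p_progression"):
            base = get_parameter(config, name)
            bumped = set_parameter(config, name, base / 2)
            assert get_parameter(bumped, name) == base / 2
            assert get_parameter(config, name) == base  # original untouched

    def test_unknown_name_rejected(self, config):
        with pytest.raises(KeyError):
            get_parameter(config, "MRI.sensitivity")
        with pytest.raises(KeyError):
            set_parameter(config, "costs.nope", 1.0)

    def test_families_follow_published_distribution_column(self, config):
        ups = uncertain_parameters(config)
        assert ups["prevalence"].family == "beta"
        assert ups["PET/CT.sensitivity"].family == "beta"
        assert ups["costs.timely_treatment"].family == "gamma"
        assert ups["transitions.p_death_untreated"].family == "beta"
        # boundary means degenerate to point masses
        assert ups["utilities.no_burden"].family == "fixed"
        assert ups["costs.true_negative_acute"].family == "fixed"
        assert ups["transitions.p_untreated_to_treated"].family == "fixed"


class TestDeterministicSA:
    def test_zero_width_range_reproduces_base_case(self, config, life_table):
        base = get_parameter(config, "PET/CT.sensitivity")
        bar = one_way_dsa(config, life_table, "PET/CT.sensitivity", base, base)
        assert bar.width == 0.0
        assert bar.nmb_low == bar.nmb_high == _incremental_nmb(config, life_table, "PET/CT")

    def test_incremental_nmb_monotone_in_own_sensitivity(self, config, life_table):
        grid = np.linspace(0.73, 0.91, 5)
        values = [
            _incremental_nmb(
                set_parameter(config, "PET/CT.sensitivity", s), life_table, "PET/CT"
            )
            for s in grid
        ]
        assert all(a <= b + 1e-9 for a, b in zip(values, values[1:]))

    def test_default_tornado_sorted_descending(self, config, life_table):
        df = tornado(config, life_table)
        assert len(df) == 10
        assert list(df["width"]) == sorted(df["width"], reverse=True)

    def test_empty_parameter_list_gives_empty_tornado(self, config, life_table):
        df = tornado(config, life_table, params=[])
        assert df.empty
        assert "width" in df.columns

    def test_unknown_parameter_rejected(self, config, life_table):
        with pytest.raises(KeyError):
            one_way_dsa(config, life_table, "bogus.param")

    def test_inverted_range_rejected(self, config, life_table):
        with pytest.raises(ValueError):
            one_way_dsa(config, life_table, "costs.biopsy", 2000.0, 1000.0)


@pytest.fixture(scope="module")
def psa_small(model):
    return model.psa(n=400, seed=11)


class TestPSA:
    def test_same_seed_reproduces_samples(self, config, life_table):
        a = sample_psa(config, life_table, n=50, seed=5)
        b = sample_psa(config, life_table, n=50, seed=5)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        for s in a.strategies:
            assert np.array_equal(a.costs[s], b.costs[s])
            assert np.array_equal(a.qalys[s], b.qalys[s])

    def test_sample_means_recover_base_values(self, config, life_table):
        samples = sample_psa(config, life_table, n=30_000, seed=2)
        for name in samples.draws.columns:
            draws = samples.draws[name].to_numpy()
            se = draws.std(ddof=1) / np.sqrt(draws.size)
            assert abs(draws.mean() - get_parameter(config, name)) < 3 * se

    def test_sampled_draws_respect_domains(self, psa_small):
        for name in psa_small.draws.columns:
            col = psa_small.draws[name]
            assert (col >= 0.0).all()
            if not name.endswith("cost") and "." in name and not name.startswith("costs"):
                assert (col <= 1.0).all()

    def test_vanishing_spreads_converge_to_base_case(self, config, life_table, base_results):
        tight = config.replace(psa_ess=1e9, psa_cv=1e-5)
        samples = sample_psa(tight, life_table, n=200, seed=3)
        for res in base_results.results:
            assert samples.costs[res.strategy].mean() == pytest.approx(res.cost, rel=1e-3)
            assert samples.qalys[res.strategy].mean() == pytest.approx(res.qaly, rel=1e-3)

    def test_psa_matches_scalar_engine_at_point_mass(self, config, life_table, base_results):
        """The vectorized PSA engine and the trace-level cohort engine agree."""
        tight = config.replace(psa_ess=1e12, psa_cv=1e-7)
        samples = sample_psa(tight, life_table, n=3, seed=4)
        for res in base_results.results:
            assert samples.costs[res.strategy] == pytest.approx(res.cost, rel=1e-4)
            assert samples.qalys[res.strategy] == pytest.approx(res.qaly, rel=1e-4)


class TestCEAC:
    def test_single_sample_gives_indicator_curve(self, config, life_table):
        samples = sample_psa(config, life_table, n=1, seed=9)
        curve = ceac(samples, [0.0, 50_000.0, 100_000.0])
        values = curve[list(samples.strategies)].to_numpy()
        assert set(np.unique(values)) <= {0.0, 1.0}

    def test_probabilities_partition_unity(self, psa_small):
        curve = ceac(psa_small, np.arange(0, 200_001, 5_000))
        total = curve[list(psa_small.strategies)].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_zero_wtp_matches_cheapest_fraction(self, psa_small):
        curve = ceac(psa_small, [0.0])
        costs = np.stack([psa_small.costs[s] for s in psa_small.strategies])
        cheapest = costs.argmin(axis=0)
        for i, s in enumerate(psa_small.strategies):
            assert curve[s].iloc[0] == pytest.approx(np.mean(cheapest == i), abs=1e-9)

    def test_point_estimate_nmb_ordering_matches_ceac_winner(self, config, life_table, base_results):
        tight = config.replace(psa_ess=1e12, psa_cv=1e-7)
        samples = sample_psa(tight, life_table, n=5, seed=6)
        curve = ceac(samples, [config.wtp])
        winner = curve[list(samples.strategies)].iloc[0].idxmax()
        by_nmb = max(base_results.results, key=lambda r: net_monetary_benefit(r, config.wtp))
        assert winner == by_nmb.strategy

    def test_empty_or_negative_grid_rejected(self, psa_small):
        with pytest.raises(ValueError):
            ceac(psa_small, [])
        with pytest.raises(ValueError):
            ceac(psa_small, [-5.0])


class TestScatter:
    def test_one_point_per_draw(self, psa_small):
        df = incremental_scatter(psa_small, "PET/CT", "CT")
        assert len(df) == psa_small.n

    def test_identical_strategies_collapse_to_origin(self, psa_small):
        clone = PSASamples(
            seed=0,
            draws=psa_small.draws,
            costs={"A": psa_small.costs["CT"], "B": psa_small.costs["CT"]},
            qalys={"A": psa_small.qalys["CT"], "B": psa_small.qalys["CT"]},
        )
        df = incremental_scatter(clone, "A", "B")
        assert (df["delta_cost"] == 0.0).all()
        assert (df["delta_effect"] == 0.0).all()

    def test_unknown_strategy_rejected(self, psa_small):
        with pytest.raises(KeyError):
            incremental_scatter(psa_small, "PET/CT", "MRI")

    def test_mean_point_consistent_with_base_case_quadrant(self, model, base_results):
        samples = model.psa(n=4000, seed=13)
        df = incremental_scatter(samples, "PET/CT", "CT")
        pet = base_results.result("PET/CT")
        ct = base_results.result("CT")
        se_e = df["delta_effect"].std(ddof=1) / np.sqrt(len(df))
        se_c = df["delta_cost"].std(ddof=1) / np.sqrt(len(df))
        assert abs(df["delta_effect"].mean() - (pet.qaly - ct.qaly)) < 3 * se_e + 1e-3
        assert abs(df["delta_cost"].mean() - (pet.cost - ct.cost)) < 3 * se_c + 50.0
        assert df["delta_effect"].mean() > 0.0  # QALY gain side of the CE plane
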