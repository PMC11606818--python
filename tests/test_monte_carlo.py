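"""Monte Carlo engine: sampling, propagation, and distribution read-outs."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import tearisk as tr
from tearisk import monte_carlo as mc
from tearisk.tea_data import Metal, Origin


def rng(seed=0):
    return np.random.default_rng(seed)


class TestDistributionSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            mc.DistributionSpec("gamma", {"shape": 1.0})

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            mc.DistributionSpec("normal", {"mean": 0.0})

    @pytest.mark.parametrize(
        "family, params",
        [
            ("normal", {"mean": 0.0, "sd": -1.0}),
            ("uniform", {"low": 1.0, "high": 0.0}),
            ("triangular", {"low": 0.0, "mode": 2.0, "high": 1.0}),
            ("empirical", {"values": ()}),
        ],
    )
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(ValueError):
            mc.DistributionSpec(family, params)

    def test_bad_truncation_rejected(self):
        with pytest.raises(ValueError, match="truncation"):
            mc.DistributionSpec("normal", {"mean": 0.0, "sd": 1.0}, truncation=(1.0, 1.0))


class TestSampleDistribution:
    def test_point_mass_is_constant(self):
        draws = mc.sample_distribution(mc.DistributionSpec.point(3.38), 5, rng())
        assert np.all(draws == 3.38)

    def test_uniform_mean_within_standard_error(self):
        n = 10_000
        draws = mc.sample_distribution(
            mc.DistributionSpec("uniform", {"low": 0.0, "high": 1.0}), n, rng(1)
        )
        se = 1 / math.sqrt(12 * n)
        assert abs(draws.mean() - 0.5) < 5 * se

    def test_truncation_bounds_enforced(self):
        spec = mc.DistributionSpec(
            "lognormal", {"meanlog": 0.0, "sdlog": 1.0}, truncation=(0.0, 1.0)
        )
        draws = mc.sample_distribution(spec, 5000, rng(2))
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_impossible_truncation_errors(self):
        spec = mc.DistributionSpec(
            "uniform", {"low": 0.0, "high": 1.0}, truncation=(5.0, 6.0)
        )
        with pytest.raises(RuntimeError, match="mass"):
            mc.sample_distribution(spec, 10, rng())

    def test_empirical_support(self):
        spec = mc.DistributionSpec("empirical", {"values": (1.0, 2.0, 3.0)})
        draws = mc.sample_distribution(spec, 1000, rng(3))
        assert set(np.unique(draws)) <= {1.0, 2.0, 3.0}


class TestFitSpec:
    def test_normal_moment_match(self, fixture_records):
        spec = mc.fit_spec_from_records(
            fixture_records, Origin.FOREIGN, Metal.LEAD, family="normal"
        )
        assert spec.params["mean"] == pytest.approx(2.83, abs=0.005)
        assert spec.params["sd"] == pytest.approx(1.12, abs=0.005)

    def test_lognormal_analytic_mean_matches_sample_mean(self, fixture_records):
        spec = mc.fit_spec_from_records(fixture_records, Origin.FOREIGN, Metal.LEAD)
        values = [
            r.infusion_conc
            for r in fixture_records
            if r.origin is Origin.FOREIGN and r.metal is Metal.LEAD
        ]
        assert spec.analytic_mean() == pytest.approx(np.mean(values), abs=1e-9)

    def test_empirical_support_is_observed_values(self, fixture_records):
        spec = mc.fit_spec_from_records(
            fixture_records, Origin.IRANIAN, Metal.ARSENIC, family="empirical"
        )
        observed = sorted(
            r.infusion_conc
            for r in fixture_records
            if r.origin is Origin.IRANIAN and r.metal is Metal.ARSENIC
        )
        assert sorted(spec.params["values"]) == observed

    def test_all_zero_lognormal_directed_to_alternatives(self):
        records = [
            tr.ConcentrationRecord(str(i), Origin.IRANIAN, Metal.ARSENIC, 1.0, 0.0)
            for i in range(4)
        ]
        with pytest.raises(ValueError, match="empirical"):
            mc.fit_spec_from_records(records, Origin.IRANIAN, Metal.ARSENIC)


def _point_config(fixture_records, populations, toxicology, origin, n_iter=200, seed=0):
    conc = {
        metal: mc.DistributionSpec.point(
            tr.group_summary(fixture_records, origin, metal, "infusion").mean
        )
        for metal in Metal
    }
    dc = {name: mc.DistributionSpec.point(p.dc) for name, p in populations.items()}
    bw = {name: mc.DistributionSpec.point(p.bw) for name, p in populations.items()}
    return mc.SimulationConfig(
        concentration=conc, dc=dc, bw=bw, toxicology=toxicology, n_iter=n_iter, seed=seed
    )


class TestRunSimulation:
    def test_degenerate_collapse_to_deterministic(
        self, fixture_records, populations, toxicology
    ):
        # all point distributions -> every iteration equals the point pipeline
        report = tr.point_risk_pipeline(fixture_records, toxicology, populations)
        for origin in Origin:
            config = _point_config(fixture_records, populations, toxicology, origin)
            result = mc.run_simulation(config)
            sub = report.risk[report.risk.origin == origin.value]
            for _, row in sub.iterrows():
                key = (row.group, Metal(row.metal))
                assert np.all(result.edi[key] == row.edi_ug_per_kg_bw_day)
                assert np.all(result.hq[key] == row.hq)
                if not np.isnan(row.ilcr):
                    assert np.all(result.ilcr[key] == row.ilcr)
            hi = report.hazard_index[report.hazard_index.origin == origin.value]
            for _, row in hi.iterrows():
                assert np.all(result.hi[row.group] == pytest.approx(row.hi))

    def test_seed_determinism(self, fixture_records):
        config = mc.config_from_records(fixture_records, Origin.FOREIGN, n_iter=500, seed=1)
        a = mc.run_simulation(config)
        b = mc.run_simulation(config)
        for group in a.hi:
            assert np.array_equal(a.hi[group], b.hi[group])

    def test_different_seeds_agree_within_mc_error(self, fixture_records):
        means = []
        for seed in (1, 2):
            config = mc.config_from_records(
                fixture_records, Origin.FOREIGN, n_iter=4000, seed=seed
            )
            result = mc.run_simulation(config)
            means.append(result.hi["adults"].mean())
        a, _ = means
        config = mc.config_from_records(fixture_records, Origin.FOREIGN, n_iter=4000, seed=1)
        sd = mc.run_simulation(config).hi["adults"].std(ddof=1)
        assert abs(means[0] - means[1]) < 6 * sd / math.sqrt(4000)

    def test_hi_is_samplewise_sum_of_hqs(self, fixture_records):
        config = mc.config_from_records(fixture_records, Origin.IRANIAN, n_iter=300, seed=7)
        result = mc.run_simulation(config)
        for group, hi_vec in result.hi.items():
            total = sum(vec for (g, _), vec in result.hq.items() if g == group)
            assert np.allclose(hi_vec, total, rtol=0, atol=0)

    def test_vector_lengths_equal_n_iter(self, fixture_records):
        config = mc.config_from_records(fixture_records, Origin.FOREIGN, n_iter=123, seed=0)
        result = mc.run_simulation(config)
        assert all(v.size == 123 for v in result.samples.values())
        assert all(v.size == 123 for v in result.hi.values())

    def test_lognormal_mc_mean_matches_deterministic_within_3se(
        self, fixture_records, populations, toxicology
    ):
        # only Cm varies and HQ is linear in Cm, so E[HQ] = HQ(E[Cm])
        n = 10_000
        config = mc.config_from_records(
            fixture_records, Origin.FOREIGN, populations, toxicology, n_iter=n, seed=11
        )
        result = mc.run_simulation(config)
        lead_mean = tr.group_summary(
            fixture_records, Origin.FOREIGN, Metal.LEAD, "infusion"
        ).mean
        pop = populations["adults"]
        expected = tr.hazard_quotient(
            tr.estimate_edi(pop.dc, lead_mean, pop.bw), toxicology[Metal.LEAD].rfd
        )
        vec = result.hq[("adults", Metal.LEAD)]
        se = vec.std(ddof=1) / math.sqrt(n)
        assert abs(vec.mean() - expected) < 3 * se

    def test_missing_spec_without_records_is_config_error(self, populations, toxicology):
        dc = {name: mc.DistributionSpec.point(p.dc) for name, p in populations.items()}
        bw = {name: mc.DistributionSpec.point(p.bw) for name, p in populations.items()}
        config = mc.SimulationConfig(
            concentration={}, dc=dc, bw=bw, toxicology=toxicology, n_iter=10, seed=0
        )
        with pytest.raises(ValueError, match="concentration spec"):
            mc.run_simulation(config)


class TestPercentile:
    def test_linear_interpolation_convention(self):
        assert mc.percentile(np.arange(1, 101), 0.5) == pytest.approx(50.5)

    def test_constant_vector(self):
        assert mc.percentile(np.full(10, 3.3), 0.73) == 3.3

    def test_extremes(self):
        values = np.array([5.0, 1.0, 9.0])
        assert mc.percentile(values, 1.0) == 9.0
        assert mc.percentile(values, 0.0) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mc.percentile([], 0.5)


class TestFrequencyTable:
    @given(
        values=st.lists(st.floats(-100, 100), min_size=2, max_size=200),
        n_bins=st.integers(1, 30),
    )
    def test_invariants(self, values, n_bins):
        table = mc.cumulative_frequency(np.array(values), n_bins)
        assert table.cumulative[0] == 0.0
        assert table.cumulative[-1] == pytest.approx(1.0)
        assert np.all(np.diff(table.cumulative) >= 0)
        assert np.allclose(table.reverse + table.cumulative, 1.0)
        assert np.all(np.diff(table.edges) >= 0)

    def test_uniform_bin_fractions(self):
        n = 10_000
        draws = rng(5).uniform(0, 1, n)
        table = mc.cumulative_frequency(draws, 10)
        fractions = np.diff(table.cumulative)
        assert np.all(np.abs(fractions - 0.1) < 0.015)  # ~5 binomial SEs


class TestExceedance:
    def test_all_below(self):
        res = mc.exceedance_fraction([1.0, 2.0], 5.0)
        assert res.fraction_above == 0.0 and res.fraction_at_or_below == 1.0

    def test_hand_count_strictly_above(self):
        assert mc.exceedance_fraction([1, 2, 3, 4], 2.0).fraction_above == 0.5

    def test_point_mass_above_who_cutoff(self):
        draws = np.full(100, 7.5e-5)
        assert mc.exceedance_fraction(draws, 1e-5).fraction_above == 1.0

    @given(t=st.lists(st.floats(0, 10), min_size=2, max_size=6))
    def test_monotone_in_threshold(self, t):
        values = np.linspace(0, 10, 101)
        fractions = [mc.exceedance_fraction(values, x).fraction_above for x in sorted(t)]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
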