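"""Batch-fermentation accounting: yields, off-gas back-calculation,
carbon distribution, growth kinetics, energy charge."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from zymoflux import (
    AdenylatePools,
    BatchTimeSeries,
    OffgasSample,
    carbon_distribution,
    carbon_distribution_from_fluxes,
    energy_charge,
    fit_yield,
    growth_rate,
    make_scenario,
    od_to_cdw,
    offgas_concentration,
    read_batch_series,
    run_scenario,
    specific_glucose_uptake,
    total_acetaldehyde,
    write_batch_series,
)
from zymoflux.batch import with_total_acetaldehyde
from zymoflux.synthetic import SyntheticBatchConfig, simulate_batch

NO_NOISE = {k: 0.0 for k in
            ("glucose", "ethanol", "acetaldehyde", "acetate", "acetoin", "od600")}


def linear_series(yield_=1.7, s0=100.0, n=8, t_scale=1.0, conc_scale=1.0):
    """Exact linear product coupling P = yield * (S0 - S), no noise."""
    t = np.arange(n, dtype=float) * t_scale
    glucose = np.linspace(s0, 0.2 * s0, n)
    product = yield_ * (glucose[0] - glucose)
    return BatchTimeSeries(
        times=t,
        od600=0.25 * np.exp(0.3 * t),
        concentrations={
            "glucose": glucose * conc_scale,
            "acetaldehyde_liquid": product * conc_scale,
        },
    )


class TestFitYield:
    def test_exact_linear_input(self):
        est = fit_yield(linear_series(1.7), "acetaldehyde_liquid")
        assert est.yield_mol_mol == pytest.approx(1.70)
        assert est.r_squared == pytest.approx(1.0)
        assert est.intercept_mm == pytest.approx(0.0, abs=1e-9)

    def test_constant_zero_product(self):
        series = linear_series()
        series.concentrations["acetaldehyde_liquid"][:] = 0.0
        est = fit_yield(series, "acetaldehyde_liquid")
        assert est.yield_mol_mol == 0.0

    def test_recovers_generator_yield_within_two_se(self):
        cfg = SyntheticBatchConfig(
            seed=20240917, n_points=10, strip_rate=0.0,
            yields={"ethanol": 0.49, "acetaldehyde": 1.3,
                    "acetate": 0.07, "acetoin": 0.06},
            noise_sd={**NO_NOISE, "glucose": 1.0, "acetaldehyde": 0.5},
        )
        series, _ = simulate_batch(cfg)
        est = fit_yield(series, "acetaldehyde_liquid")
        assert abs(est.yield_mol_mol - 1.3) <= 2 * est.std_error

    def test_too_few_points_rejected(self):
        series = linear_series(n=8)
        # only two points remain above the 5% glucose floor
        series.concentrations["glucose"][2:] = 0.0
        with pytest.raises(ValueError, match=">= 3 points"):
            fit_yield(series, "acetaldehyde_liquid")

    def test_flat_glucose_rejected(self):
        series = linear_series()
        series.concentrations["glucose"][:] = 100.0
        with pytest.raises(ValueError, match="variance"):
            fit_yield(series, "acetaldehyde_liquid")

    def test_invariant_under_affine_retiming(self):
        # yield depends on the S-P relation, not on the clock
        fast = fit_yield(linear_series(t_scale=1.0), "acetaldehyde_liquid")
        slow = fit_yield(linear_series(t_scale=7.3), "acetaldehyde_liquid")
        assert fast.yield_mol_mol == pytest.approx(slow.yield_mol_mol)

    def test_unit_coherence_mm_vs_m(self):
        in_mm = fit_yield(linear_series(conc_scale=1.0), "acetaldehyde_liquid")
        in_m = fit_yield(linear_series(conc_scale=1e-3), "acetaldehyde_liquid")
        assert in_m.yield_mol_mol == pytest.approx(in_mm.yield_mol_mol)


class TestOdToCdw:
    @pytest.mark.parametrize("od,expected", [(1.0, 0.24), (0.0, 0.0), (2.5, 0.60)])
    def test_calibration_factor(self, od, expected):
        assert od_to_cdw(od) == pytest.approx(expected)

    def test_negative_od_rejected(self):
        with pytest.raises(ValueError):
            od_to_cdw(-0.1)


class TestOffgas:
    def test_trap_back_calculation(self):
        # 1 µmol trapped from 24 l/h sampled over 6 s = 0.04 l of gas
        assert offgas_concentration(1.0, 24.0, 6.0) == pytest.approx(25.0)

    def test_doubling_duration_halves_concentration(self):
        one = offgas_concentration(1.0, 24.0, 6.0)
        two = offgas_concentration(1.0, 24.0, 12.0)
        assert two == pytest.approx(one / 2)

    def test_zero_trapped_gives_zero(self):
        assert offgas_concentration(0.0, 24.0, 6.0) == 0.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            offgas_concentration(1.0, 0.0, 6.0)
        with pytest.raises(ValueError):
            offgas_concentration(1.0, 24.0, -1.0)


class TestTotalAcetaldehyde:
    def test_no_offgas_samples_returns_liquid(self):
        series = linear_series()
        total = total_acetaldehyde(series, 0.4)
        np.testing.assert_allclose(
            total, series.concentrations["acetaldehyde_liquid"]
        )

    def test_constant_gas_concentration_closed_form(self):
        # constant c µmol/l at flow f: stripped(t) = f*c*t/V (in mmol/l)
        series = linear_series(n=5, t_scale=1.0)
        flow, c, dur, vol = 24.0, 25.0, 6.0, 0.4
        trapped = c * flow * dur / 3600.0
        series.offgas = [
            OffgasSample(t, trapped, flow, dur) for t in series.times[1:]
        ]
        total = total_acetaldehyde(series, vol)
        stripped = total - series.concentrations["acetaldehyde_liquid"]
        expected = flow * c * series.times / 1000.0 / vol
        np.testing.assert_allclose(stripped, expected, rtol=1e-9)

    def test_recovers_produced_curve_from_stripped_run(self):
        cfg = SyntheticBatchConfig(seed=5, strip_rate=0.4, noise_sd=NO_NOISE,
                                   n_points=25)
        series, truth = simulate_batch(cfg)
        total = total_acetaldehyde(series, cfg.liquid_volume)
        produced = truth.produced["acetaldehyde"]
        mask = produced > 0
        rel = np.abs(total[mask] - produced[mask]) / produced[mask]
        assert rel.max() <= 0.05

    def test_stripped_term_monotone(self):
        cfg = SyntheticBatchConfig(seed=6, strip_rate=0.4, noise_sd=NO_NOISE)
        series, _ = simulate_batch(cfg)
        stripped = (total_acetaldehyde(series, cfg.liquid_volume)
                    - series.concentrations["acetaldehyde_liquid"])
        assert np.all(np.diff(stripped) >= -1e-12)

    def test_missing_volume_rejected(self):
        with pytest.raises(ValueError):
            total_acetaldehyde(linear_series(), 0.0)


class TestCarbonDistribution:
    def test_best_strain_acetaldehyde_fraction(self):
        dist = carbon_distribution({"acetaldehyde": 1.3})
        assert dist.fractions["acetaldehyde"] == pytest.approx(0.433, abs=5e-4)

    def test_all_zero(self):
        dist = carbon_distribution(
            {p: 0.0 for p in ("ethanol", "acetaldehyde", "acetate", "acetoin")}
        )
        assert all(f == 0 for f in dist.fractions.values())
        assert dist.closure == 0.0

    def test_biomass_fraction_uses_carbon_content(self):
        # 10 g cdw/mol at 0.48 gC/g = 4.8 gC per 72.066 gC of glucose
        dist = carbon_distribution({}, biomass_yield_g_per_mol=10.0)
        assert dist.fractions["biomass"] == pytest.approx(4.8 / (6 * 12.011))

    def test_model_fluxes_close_exactly(self, model):
        sol = run_scenario(model, make_scenario("B"), audit=False)
        dist = carbon_distribution_from_fluxes(model, sol)
        assert dist.closure == pytest.approx(1.0, abs=1e-6)
        assert dist.fractions["acetaldehyde"] == pytest.approx(2 * 1.86 / 6, abs=1e-3)

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            carbon_distribution({"ethanol": -0.1})


class TestGrowthKinetics:
    def test_doubling_every_two_hours(self):
        t = np.arange(8, dtype=float) * 2.0
        series = BatchTimeSeries(
            times=t, od600=0.2 * 2 ** (t / 2.0),
            concentrations={"glucose": np.linspace(100, 50, 8)},
        )
        assert growth_rate(series) == pytest.approx(np.log(2) / 2, abs=1e-9)

    def test_constant_od_gives_zero_rate(self):
        series = BatchTimeSeries(
            times=np.arange(5.0), od600=np.full(5, 0.8),
            concentrations={"glucose": np.linspace(100, 60, 5)},
        )
        assert growth_rate(series) == 0.0

    def test_recovers_generator_mu(self):
        cfg = SyntheticBatchConfig(seed=11)
        series, _ = simulate_batch(cfg)
        assert abs(growth_rate(series) - cfg.mu) <= 0.02

    def test_explicit_window(self):
        t = np.arange(10, dtype=float)
        od = 0.2 * np.exp(0.5 * t)
        od[7:] = od[6]  # stationary tail
        series = BatchTimeSeries(
            times=t, od600=od,
            concentrations={"glucose": np.linspace(100, 0, 10)},
        )
        assert growth_rate(series, window=(0, 6)) == pytest.approx(0.5)

    def test_nonpositive_od_in_window_rejected(self):
        series = BatchTimeSeries(
            times=np.arange(4.0), od600=np.array([0.2, 0.0, 0.4, 0.8]),
            concentrations={},
        )
        with pytest.raises(ValueError):
            growth_rate(series, window=(0, 3))

    def test_specific_uptake_near_generator_value(self):
        cfg = SyntheticBatchConfig(seed=13)
        series, _ = simulate_batch(cfg)
        q = specific_glucose_uptake(series)
        assert q == pytest.approx(cfg.q_glc, rel=0.1)


class TestEnergyCharge:
    @pytest.mark.parametrize("pools,expected", [
        ((1, 0, 0), 1.0),
        ((1, 1, 1), 0.5),
        ((2, 2, 1), 0.6),
        ((0, 0, 1), 0.0),
    ])
    def test_known_pool_ratios(self, pools, expected):
        assert energy_charge(AdenylatePools(*pools)) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            energy_charge(AdenylatePools(0, 0, 0))

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError):
            AdenylatePools(1, -1, 1)

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, k):
        base = energy_charge(AdenylatePools(2.0, 1.0, 0.5))
        scaled = energy_charge(AdenylatePools(2.0 * k, 1.0 * k, 0.5 * k))
        assert scaled == pytest.approx(base)


class TestSeriesIO:
    def test_long_format_round_trip(self, tmp_path):
        cfg = SyntheticBatchConfig(seed=3)
        series, _ = simulate_batch(cfg)
        p = tmp_path / "run.tsv"
        og = tmp_path / "run.offgas.tsv"
        write_batch_series(series, p, og)
        back = read_batch_series(p, og)
        np.testing.assert_allclose(back.times, series.times)
        np.testing.assert_allclose(back.od600, series.od600)
        for key, values in series.concentrations.items():
            np.testing.assert_allclose(back.concentrations[key], values)
        assert len(back.offgas) == len(series.offgas)
        for a, b in zip(back.offgas, series.offgas):
            assert a.time_h == pytest.approx(b.time_h)
            assert a.trapped_umol == pytest.approx(b.trapped_umol)
            assert (a.gas_flow_l_h, a.duration_s) == (
                b.gas_flow_l_h, b.duration_s
            )

    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            BatchTimeSeries(
                times=np.array([0.0, 2.0, 1.0]),
                od600=np.ones(3),
                concentrations={},
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            BatchTimeSeries(
                times=np.arange(3.0), od600=np.ones(3),
                concentrations={"glucose": np.array([1.0, -0.5, 0.0])},
            )
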