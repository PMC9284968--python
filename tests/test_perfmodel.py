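import math

import numpy as np
import pytest

from loopamp.perfmodel import (
    AmplificationCurve,
    NoFeasibleAmplificationError,
    SequencerModel,
    optimal_amplification,
    sequencing_time,
)

from .oracles import grid_argmin_total_time


def steady_model(**kwargs):
    defaults = dict(active_pores=100.0, per_pore_read_rate=1 / 60)
    defaults.update(kwargs)
    return SequencerModel(**defaults)


class TestSequencingTime:
    def test_100_calls_per_minute_reaches_250_in_150s(self):
        # 100 pores * 1 read/min/pore * fraction 1 => 100 useful calls/min
        model = steady_model()
        assert sequencing_time(model, 1.0, support=250) == pytest.approx(150.0)

    def test_doubling_fraction_halves_time(self):
        model = steady_model()
        assert sequencing_time(model, 0.5, 250) == pytest.approx(
            2 * sequencing_time(model, 1.0, 250)
        )

    def test_zero_fraction_is_infinite(self):
        assert math.isinf(sequencing_time(steady_model(), 0.0, 250))

    def test_strictly_decreasing_in_each_rate_factor(self):
        base = sequencing_time(steady_model(), 0.4, 250)
        assert sequencing_time(steady_model(), 0.5, 250) < base
        assert sequencing_time(steady_model(active_pores=150), 0.4, 250) < base
        assert (
            sequencing_time(steady_model(per_pore_read_rate=1 / 30), 0.4, 250) < base
        )
        assert sequencing_time(steady_model(barcode_loss=0.2), 0.4, 250) > base
        assert sequencing_time(steady_model(call_yield=0.8), 0.4, 250) > base

    def test_ramp_integrates_piecewise(self):
        # during the ramp the rate averages (r0 + steady)/2
        model = steady_model(
            participation=1.0, ramp_initial=0.5, ramp_duration=100.0
        )
        base_rate = 100 / 60  # calls per second at participation 1
        ramp_calls = base_rate * 100 * 0.75
        # support below the ramp budget: solve the quadratic branch
        t = sequencing_time(model, 1.0, support=int(ramp_calls // 2))
        assert 0 < t < 100
        # support beyond the ramp: linear continuation
        support = int(ramp_calls + base_rate * 50)
        t2 = sequencing_time(model, 1.0, support=support)
        assert t2 == pytest.approx(150.0, rel=0.01)

    def test_ramp_accumulation_matches_numeric_integration(self):
        model = steady_model(
            participation=0.8, ramp_initial=0.3, ramp_duration=120.0
        )
        support = 100
        t = sequencing_time(model, 0.7, support=support)
        # numeric check: integrate the instantaneous rate up to t
        ts = np.linspace(0, t, 200_001)
        part = np.where(
            ts < 120, 0.3 + (0.8 - 0.3) * ts / 120, 0.8
        )
        rate = 100 * (1 / 60) * 0.7 * part
        accumulated = np.trapezoid(rate, ts)
        assert accumulated == pytest.approx(support, rel=1e-4)

    def test_prediction_matches_simulated_runs_within_20pct(self):
        """Thinned-Poisson simulation vs model, 20 seeded replicates."""
        rng = np.random.default_rng(5)
        lam, f, support = 30.0, 0.4, 250
        model = SequencerModel(active_pores=lam, per_pore_read_rate=1.0)
        predicted = sequencing_time(model, f, support)
        for _ in range(20):
            times = np.cumsum(rng.exponential(1 / lam, size=5000))
            supported = times[rng.random(5000) < f]
            observed = supported[support - 1]
            assert abs(observed - predicted) / predicted < 0.20


class TestOptimalAmplification:
    def _logistic_curve(self):
        amounts = tuple(float(t) for t in range(0, 21))
        fractions = tuple(1 / (1 + math.exp(-(t - 10))) for t in amounts)
        return AmplificationCurve(amounts=amounts, fractions=fractions)

    def test_matches_dense_grid_oracle(self):
        curve = self._logistic_curve()
        model = steady_model()
        per_unit, overhead = 60.0, 300.0
        opt = optimal_amplification(
            curve, model, per_unit_amp_time=per_unit, fixed_overhead=overhead
        )
        oracle_a, oracle_t = grid_argmin_total_time(
            curve.amounts, curve.fractions,
            lambda f: sequencing_time(model, f, 250),
            per_unit, overhead,
        )
        grid_step = (curve.amounts[-1] - curve.amounts[0]) / 2000
        assert abs(opt.amount - oracle_a) <= grid_step
        assert opt.total_time == pytest.approx(oracle_t, rel=1e-3)

    def test_constant_fraction_prefers_minimal_amplification(self):
        curve = AmplificationCurve(amounts=(0.0, 5.0, 10.0), fractions=(0.4, 0.4, 0.4))
        opt = optimal_amplification(curve, steady_model(), per_unit_amp_time=60.0)
        assert opt.amount == curve.amounts[0]

    def test_overamplification_penalty_smaller_than_under(self):
        curve = self._logistic_curve()
        model = steady_model()
        opt = optimal_amplification(
            curve, model, per_unit_amp_time=60.0, fixed_overhead=300.0
        )
        delta = 2.0

        def total(a):
            f = curve.fraction_at(a)
            return a * 60.0 + 300.0 + sequencing_time(model, f, 250)

        over = total(opt.amount + delta) - opt.total_time
        under = total(opt.amount - delta) - opt.total_time
        assert over >= 0 and under >= 0
        assert over < under

    def test_units_audit_cycles_vs_seconds(self):
        # a cycles-mode curve and its seconds-mode equivalent agree
        amounts_cycles = (20.0, 24.0, 28.0, 30.0)
        fractions = (0.05, 0.30, 0.60, 0.65)
        seconds_per_cycle = 55.0
        c_cycles = AmplificationCurve(amounts=amounts_cycles, fractions=fractions)
        c_seconds = AmplificationCurve(
            amounts=tuple(a * seconds_per_cycle for a in amounts_cycles),
            fractions=fractions,
        )
        model = steady_model()
        opt_c = optimal_amplification(c_cycles, model, per_unit_amp_time=seconds_per_cycle)
        opt_s = optimal_amplification(c_seconds, model, per_unit_amp_time=1.0)
        assert opt_c.total_time == pytest.approx(opt_s.total_time, rel=1e-6)
        assert opt_c.amount * seconds_per_cycle == pytest.approx(
            opt_s.amount, rel=1e-6
        )

    def test_all_zero_fractions_infeasible(self):
        curve = AmplificationCurve(amounts=(1.0, 2.0), fractions=(0.0, 0.0))
        with pytest.raises(NoFeasibleAmplificationError):
            optimal_amplification(curve, steady_model())

    def test_table_covers_full_curve(self):
        curve = self._logistic_curve()
        opt = optimal_amplification(curve, steady_model(), per_unit_amp_time=60.0)
        amounts = [row[0] for row in opt.table]
        assert amounts[0] == curve.amounts[0]
        assert amounts[-1] == curve.amounts[-1]
        assert min(row[4] for row in opt.table) == opt.total_time


class TestValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SequencerModel(active_pores=10, per_pore_read_rate=1, participation=1.5)
        with pytest.raises(ValueError):
            SequencerModel(active_pores=0, per_pore_read_rate=1)

    def test_curve_must_increase(self):
        with pytest.raises(ValueError):
            AmplificationCurve(amounts=(2.0, 1.0), fractions=(0.1, 0.2))

    def test_curve_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "curve.tsv"
        path.write_text("# amount\tfraction\n20\t0.05\n24\t0.3\n28\t0.6\n")
        curve = AmplificationCurve.from_tsv(path)
        assert curve.amounts == (20.0, 24.0, 28.0)
        assert curve.fraction_at(26.0) == pytest.approx(0.45)
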