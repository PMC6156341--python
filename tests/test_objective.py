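"""Scoring machinery: sum of squares, static penalties, trajectory constraints, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qqfit.objective import (Constraint, DifferenceObservable, EmptyWindowError,
                             Observable, QuantPoint, Trajectory, make_objective,
                             oscillation_penalty, qual_objective, quant_objective,
                             read_constraints_csv, read_quant_csv, total_objective,
                             violation, write_constraints_csv, write_quant_csv)


class DictAdapter:
    """Minimal adapter: outputs looked up from a table keyed by condition 'c'."""

    def __init__(self, table, output_names=("y",)):
        self.table = table
        self.output_names = tuple(output_names)

    def evaluate(self, params, condition):
        return self.table[condition["c"]]


def scalar_constraint(kind, threshold=0.0, tolerance=0.0, weight=1.0, c=0):
    return Constraint(id=f"{kind}_{c}", observable=Observable("y", {"c": c}),
                      kind=kind, threshold=threshold, tolerance=tolerance, weight=weight)


class TestQuantObjective:
    def test_perfect_fit_is_zero(self):
        ad = DictAdapter({0: {"y": 1.0}, 1: {"y": 2.0}})
        pts = [QuantPoint({"c": 0}, "y", 1.0), QuantPoint({"c": 1}, "y", 2.0)]
        assert quant_objective(ad, {}, pts) == 0.0

    def test_sum_of_squared_residuals(self):
        ad = DictAdapter({0: {"y": 1.0}, 1: {"y": 2.0}})
        pts = [QuantPoint({"c": 0}, "y", 0.0), QuantPoint({"c": 1}, "y", 0.0)]
        assert quant_objective(ad, {}, pts) == pytest.approx(5.0)

    def test_noiseless_self_consistency(self, raf_adapter, truth_constants):
        from qqfit.synth import gen_raf_quant
        pts = gen_raf_quant(truth_constants, noise_sd=0.0)
        truth = {"K3": 4000.0, "K5": 0.1}
        assert quant_objective(raf_adapter, truth, pts) < 1e-12

    def test_missing_output_raises(self):
        ad = DictAdapter({0: {"y": 1.0}})
        with pytest.raises(ValueError, match="output"):
            quant_objective(ad, {}, [QuantPoint({"c": 0}, "z", 1.0)])


class TestViolation:
    def test_less_than(self):
        c = scalar_constraint("less_than", threshold=15.24)
        assert violation(c, 17.24) == pytest.approx(2.0)

    def test_band_boundary_scores_zero(self):
        c = scalar_constraint("within_band", threshold=0.0, tolerance=1.5)
        assert violation(c, 1.5) == 0.0
        assert violation(c, -1.5) == 0.0
        assert violation(c, 2.0) == pytest.approx(0.5)

    def test_never_reach_satisfied(self):
        t = np.linspace(0, 10, 51)
        traj = Trajectory(t, 7.2 * (1 - np.abs(t - 5) / 5))  # peaks at exactly 7.2
        c = Constraint(id="v", observable=Observable("V"), kind="never_reach", threshold=8.0)
        assert violation(c, traj) == pytest.approx(-0.8)

    def test_must_reach(self):
        traj = Trajectory(np.linspace(0, 1, 20), np.linspace(0, 0.6, 20))
        c = Constraint(id="spn", observable=Observable("SPN"), kind="must_reach",
                       threshold=1.0)
        assert violation(c, traj) == pytest.approx(0.4)

    def test_time_window_restricts_evaluation(self):
        t = np.linspace(0, 10, 101)
        traj = Trajectory(t, t)  # ramps to 10
        c = Constraint(id="w", observable=Observable("V"), kind="never_reach",
                       threshold=8.0, window=(0.0, 5.0))
        assert violation(c, traj) == pytest.approx(-3.0)  # max over window is 5

    def test_value_triggered_window(self):
        """Constraint enforced only until the trigger output reaches its level."""
        t = np.linspace(0, 10, 101)
        ori = Trajectory(t, t / 2)       # constrained output
        vol = Trajectory(t, t)           # trigger: V reaches 8 at t = 8
        c = Constraint(id="ori", observable=Observable("ORI"), kind="never_reach",
                       threshold=1.0, window_trigger=("V", 8.0))
        # max of ORI over t <= 8 is 4 -> violation 3
        assert violation(c, ori, trigger_trajectory=vol) == pytest.approx(3.0)

    def test_empty_window_raises(self):
        traj = Trajectory(np.linspace(0, 1, 10), np.zeros(10))
        c = Constraint(id="w", observable=Observable("V"), kind="never_reach",
                       threshold=1.0, window=(5.0, 6.0))
        with pytest.raises(EmptyWindowError):
            violation(c, traj)


class TestQualObjective:
    def test_all_satisfied_is_exactly_zero(self):
        ad = DictAdapter({0: {"y": 1.0}})
        cons = [scalar_constraint("less_than", threshold=2.0, weight=5.0)]
        assert qual_objective(ad, {}, cons) == 0.0

    def test_penalty_arithmetic(self):
        """A violation of 2 at weight 0.03 costs exactly 0.06."""
        ad = DictAdapter({0: {"y": 17.24}})
        cons = [scalar_constraint("less_than", threshold=15.24, weight=0.03)]
        assert qual_objective(ad, {}, cons) == pytest.approx(0.06)

    def test_negative_g_contributes_nothing(self):
        ad = DictAdapter({0: {"y": 1.0}, 1: {"y": -5.0}})
        cons = [scalar_constraint("less_than", threshold=0.0, weight=2.0, c=0),
                scalar_constraint("less_than", threshold=0.0, weight=2.0, c=1)]
        assert qual_objective(ad, {}, cons) == pytest.approx(2.0)

    def test_linear_not_squared(self):
        """Doubling one violation doubles its contribution exactly."""
        ad1 = DictAdapter({0: {"y": 3.0}})
        ad2 = DictAdapter({0: {"y": 6.0}})
        cons = [scalar_constraint("less_than", threshold=0.0, weight=0.7)]
        assert qual_objective(ad2, {}, cons) == pytest.approx(2 * qual_objective(ad1, {}, cons))

    def test_weight_scaling_is_exact(self):
        ad = DictAdapter({0: {"y": 3.0}, 1: {"y": 0.5}})
        cons = [scalar_constraint("less_than", c=0), scalar_constraint("less_than", c=1)]
        lam = 3.5
        scaled = [Constraint(id=c.id, observable=c.observable, kind=c.kind,
                             threshold=c.threshold, weight=lam * c.weight)
                  for c in cons]
        assert qual_objective(ad, {}, scaled) == pytest.approx(
            lam * qual_objective(ad, {}, cons), rel=1e-15)

    def test_breakdown_reports_each_constraint(self):
        ad = DictAdapter({0: {"y": 3.0}, 1: {"y": -1.0}})
        cons = [scalar_constraint("less_than", c=0), scalar_constraint("less_than", c=1)]
        total, breakdown = qual_objective(ad, {}, cons, return_breakdown=True)
        assert breakdown["less_than_0"] == pytest.approx(3.0)
        assert breakdown["less_than_1"] == 0.0
        assert total == pytest.approx(sum(breakdown.values()))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(-10, 10), min_size=1, max_size=6),
           bump=st.floats(0.1, 5.0), idx=st.integers(0, 5))
    def test_inflating_a_violation_never_decreases_total(self, values, bump, idx):
        idx = idx % len(values)
        table = {i: {"y": v} for i, v in enumerate(values)}
        cons = [scalar_constraint("less_than", weight=0.5, c=i) for i in range(len(values))]
        before = qual_objective(DictAdapter(table), {}, cons)
        table2 = {**table, idx: {"y": values[idx] + bump}}
        after = qual_objective(DictAdapter(table2), {}, cons)
        assert after >= before - 1e-12


def test_total_is_exact_sum_of_parts(raf_adapter, raf_quant_seeded, raf_constraints):
    params = {"K3": 900.0, "K5": 0.01}
    f_quant = quant_objective(raf_adapter, params, raf_quant_seeded)
    f_qual = qual_objective(raf_adapter, params, raf_constraints)
    f_tot = total_objective(raf_adapter, params, raf_quant_seeded, raf_constraints)
    assert f_tot == f_quant + f_qual  # bit-identical


def test_difference_observable_uses_model_reference(raf_adapter):
    """A(I) − A(0) is recomputed from the model, not hard-coded."""
    obs = DifferenceObservable("activity", {"I": 0.0}, {"I": 0.0})
    c = Constraint(id="self", observable=obs, kind="within_band", tolerance=1.5,
                   weight=1.0)
    assert qual_objective(raf_adapter, {"K3": 123.0, "K5": 0.5}, [c]) == 0.0


class TestOscillationPenalty:
    def test_monotone_trajectory_unpenalized(self):
        t = np.linspace(0, 1, 100)
        assert oscillation_penalty(Trajectory(t, t**2)) == 0.0

    def test_sine_peak_count_against_brute_force(self):
        t = np.linspace(0, 25 * 2 * np.pi, 4001)
        v = np.sin(t)
        n_peaks = sum(1 for i in range(1, len(v) - 1)
                      if v[i] > v[i - 1] and v[i] > v[i + 1])
        assert n_peaks == 25
        assert oscillation_penalty(Trajectory(t, v), max_peaks=20, weight=1.0) == 5

    def test_boundary_count_unpenalized(self):
        t = np.linspace(0, 20 * 2 * np.pi, 3001)
        assert oscillation_penalty(Trajectory(t, np.sin(t)), max_peaks=20) == 0.0


class TestTrajectoryType:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros(3))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0]), np.zeros(3))


class TestRoundTrips:
    def test_quant_csv(self, tmp_path, truth_constants):
        from qqfit.synth import gen_raf_quant
        pts = gen_raf_quant(truth_constants, seed=7)
        path = tmp_path / "quant.csv"
        write_quant_csv(pts, path)
        back = read_quant_csv(path)
        assert back == pts

    def test_constraints_csv(self, tmp_path, raf_constraints):
        path = tmp_path / "cons.csv"
        write_constraints_csv(raf_constraints, path)
        back = read_constraints_csv(path)
        assert back == raf_constraints
        # writing what we read is content-equivalent
        path2 = tmp_path / "cons2.csv"
        write_constraints_csv(back, path2)
        assert path.read_text() == path2.read_text()


def test_make_objective_flavors_agree(raf_adapter, raf_quant_seeded, raf_constraints):
    params = {"K3": 50.0, "K5": 2.0}
    f_q = make_objective(raf_adapter, raf_quant_seeded, raf_constraints, "quant")
    f_c = make_objective(raf_adapter, raf_quant_seeded, raf_constraints, "qual")
    f_t = make_objective(raf_adapter, raf_quant_seeded, raf_constraints, "total")
    assert f_t(params) == f_q(params) + f_c(params)
    with pytest.raises(ValueError):
        make_objective(raf_adapter, [], [], "bogus")
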