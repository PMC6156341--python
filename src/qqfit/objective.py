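"""Objective assembly for combined quantitative + qualitative fitting.

The total objective is

    f_tot(x) = f_quant(x) + f_qual(x)

where ``f_quant`` is an unweighted sum of squares over quantitative data
points and ``f_qual`` is a static penalty function over inequality
constraints: each qualitative observation is rendered as g_i(x) < 0 and
contributes C_i · max(0, g_i(x)).  The penalty is linear (not squared) in
the violation, so a single badly violated constraint cannot dominate the
objective, and a satisfied constraint contributes exactly zero.

Constraints may be scalar (on a named model output, or on the difference of
one output under two conditions) or trajectory-flavored (``must_reach`` /
``never_reach`` over a time course, optionally restricted to a window).
Windows are closed intervals on the simulator's native time grid; a window
end may also be value-triggered (first sample where a trigger output
reaches a threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence, Union, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "QuantPoint",
    "Observable",
    "DifferenceObservable",
    "Constraint",
    "ConfigurationError",
    "EmptyWindowError",
    "quant_objective",
    "violation",
    "qual_objective",
    "total_objective",
    "oscillation_penalty",
    "make_objective",
    "read_quant_csv",
    "write_quant_csv",
    "read_constraints_csv",
    "write_constraints_csv",
]

SCALAR_KINDS = ("less_than", "greater_than", "within_band")
TRAJECTORY_KINDS = ("must_reach", "never_reach")


class ConfigurationError(ValueError):
    """A data point or constraint references something the model does not provide."""


class EmptyWindowError(ValueError):
    """A constraint window selects no samples of the trajectory."""


@runtime_checkable
class ModelAdapter(Protocol):
    """Contract between models and the scoring machinery.

    ``evaluate(params, condition)`` maps a parameter mapping and a condition
    record to ``{output name: scalar or Trajectory}``; it must be
    deterministic and declare stable ``output_names``.  An optional
    ``evaluate_batch(params, conditions)`` returning arrays enables
    vectorized scoring for cheap closed-form models.
    """

    output_names: Sequence[str]

    def evaluate(self, params: Mapping[str, float], condition: Mapping[str, float]
                 ) -> Mapping[str, object]: ...


@dataclass(frozen=True)
class Trajectory:
    """A sampled time course with strictly increasing times."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be equal-length 1-D sequences")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class QuantPoint:
    """One quantitative observation: output measured under a condition."""

    condition: Mapping[str, float]
    output: str
    value: float


@dataclass(frozen=True)
class Observable:
    """A named model output evaluated under one condition."""

    output: str
    condition: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DifferenceObservable:
    """output(condition) − output(ref_condition); e.g. A(I) − A(0).

    The reference value is recomputed from the model for every parameter
    vector, never cached across vectors — it may depend on fitted parameters.
    """

    output: str
    condition: Mapping[str, float]
    ref_condition: Mapping[str, float]


ObservableSpec = Union[Observable, DifferenceObservable]


@dataclass(frozen=True)
class Constraint:
    """One qualitative observation as an inequality g(x) < 0 with weight C.

    kinds (g definitions; value = observable under this parameter vector):
      less_than     g = value − threshold
      greater_than  g = threshold − value
      within_band   g = |value − threshold_reference| − tolerance
                    (for difference observables the reference is 0, so
                    ``threshold`` is usually 0 and tolerance is ε)
      never_reach   g = max over (windowed) trajectory − threshold
      must_reach    g = threshold − max over (windowed) trajectory
    """

    id: str
    observable: ObservableSpec
    kind: str
    threshold: float = 0.0
    tolerance: float = 0.0
    weight: float = 1.0
    window: tuple[float, float] | None = None
    # value-triggered window end: (trigger output name, trigger threshold);
    # window closes at the first sample where trigger >= threshold.
    window_trigger: tuple[str, float] | None = None

    def __post_init__(self):
        if self.kind not in SCALAR_KINDS + TRAJECTORY_KINDS:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if not self.weight > 0:
            raise ValueError("constraint weight must be positive")
        if self.kind == "within_band" and not self.tolerance > 0:
            raise ValueError("within_band requires tolerance > 0")
        if (self.window is not None or self.window_trigger is not None) \
                and self.kind not in TRAJECTORY_KINDS:
            raise ValueError("windows are only valid for trajectory constraints")


# ---------------------------------------------------------------------------
# evaluation helpers

def _adapter_outputs(adapter, params, condition):
    out = adapter.evaluate(params, condition)
    return out


def _observable_value(adapter, params, spec: ObservableSpec):
    if isinstance(spec, DifferenceObservable):
        a = _lookup(adapter, params, spec.condition, spec.output)
        b = _lookup(adapter, params, spec.ref_condition, spec.output)
        return a - b
    return _lookup(adapter, params, spec.condition, spec.output)


def _lookup(adapter, params, condition, output):
    outs = _adapter_outputs(adapter, params, condition)
    if output not in outs:
        raise ConfigurationError(
            f"model does not provide output {output!r}; available: {sorted(outs)}")
    return outs[output]


def _windowed_values(traj: Trajectory, constraint: Constraint,
                     trigger_traj: Trajectory | None = None) -> np.ndarray:
    mask = np.ones(len(traj.times), dtype=bool)
    if constraint.window is not None:
        t0, t1 = constraint.window
        mask &= (traj.times >= t0) & (traj.times <= t1)
    if constraint.window_trigger is not None:
        if trigger_traj is None:
            raise ConfigurationError(
                f"constraint {constraint.id!r} has a value-triggered window but no "
                f"trigger trajectory was provided")
        hit = np.nonzero(trigger_traj.values >= constraint.window_trigger[1])[0]
        if len(hit):
            # window closes at the first sample where the trigger output
            # reaches its threshold (e.g. "enforced until V(τ) = 8")
            mask &= traj.times <= trigger_traj.times[hit[0]]
    vals = traj.values[mask]
    if len(vals) == 0:
        raise EmptyWindowError(
            f"constraint {constraint.id!r}: window selects no samples "
            f"(trajectory spans [{traj.times[0]}, {traj.times[-1]}])")
    return vals


# ---------------------------------------------------------------------------
# the three objective terms

def quant_objective(adapter, params: Mapping[str, float],
                    points: Sequence[QuantPoint]) -> float:
    """Sum of squared residuals Σ_j (y_model − y_data)² (unweighted)."""
    points = list(points)
    if not points:
        return 0.0
    if hasattr(adapter, "evaluate_batch"):
        outs = adapter.evaluate_batch(params, [p.condition for p in points])
        resid = np.empty(len(points))
        for j, p in enumerate(points):
            if p.output not in outs:
                raise ConfigurationError(f"model does not provide output {p.output!r}")
            resid[j] = outs[p.output][j] - p.value
        return float(np.dot(resid, resid))
    total = 0.0
    for p in points:
        y = _lookup(adapter, params, p.condition, p.output)
        total += (float(y) - p.value) ** 2
    return total


def violation(constraint: Constraint, value, trigger_trajectory: Trajectory | None = None
              ) -> float:
    """The signed constraint function g for a computed observable value.

    ``value`` is a scalar for scalar kinds, a :class:`Trajectory` (or an
    already-windowed array of samples) for trajectory kinds.  g < 0 means
    satisfied; only max(0, g) is penalized.  For a value-triggered window,
    ``trigger_trajectory`` supplies the trigger output's time course.
    """
    kind = constraint.kind
    if kind in TRAJECTORY_KINDS:
        if isinstance(value, Trajectory):
            vals = _windowed_values(value, constraint, trigger_trajectory)
        else:
            vals = np.asarray(value, dtype=float)
            if vals.size == 0:
                raise EmptyWindowError(f"constraint {constraint.id!r}: empty trajectory")
        peak = float(np.max(vals))
        return peak - constraint.threshold if kind == "never_reach" \
            else constraint.threshold - peak
    value = float(value)
    if kind == "less_than":
        return value - constraint.threshold
    if kind == "greater_than":
        return constraint.threshold - value
    # within_band: boundary |Δ| == tolerance scores exactly zero penalty
    return abs(value - constraint.threshold) - constraint.tolerance


def _constraint_value(adapter, params, c: Constraint):
    return _observable_value(adapter, params, c.observable)


def qual_objective(adapter, params: Mapping[str, float],
                   constraints: Sequence[Constraint],
                   return_breakdown: bool = False):
    """Static penalty Σ_i C_i·max(0, g_i); optionally the per-constraint terms.

    With ``return_breakdown=True`` returns ``(total, {id: penalty})`` so a
    report can show which constraints are violated and by how much.
    """
    constraints = list(constraints)
    breakdown: dict[str, float] = {}
    # batch path: all scalar plain-Observable constraints in one model call
    values: dict[int, object] = {}
    if hasattr(adapter, "evaluate_batch") and constraints:
        conds, idx = [], []
        for i, c in enumerate(constraints):
            if isinstance(c.observable, DifferenceObservable):
                conds.extend([c.observable.condition, c.observable.ref_condition])
                idx.append((i, True))
            elif isinstance(c.observable, Observable) and c.kind in SCALAR_KINDS:
                conds.append(c.observable.condition)
                idx.append((i, False))
        if conds:
            outs = adapter.evaluate_batch(params, conds)
            pos = 0
            for i, is_diff in idx:
                name = constraints[i].observable.output
                if name not in outs:
                    raise ConfigurationError(f"model does not provide output {name!r}")
                if is_diff:
                    values[i] = outs[name][pos] - outs[name][pos + 1]
                    pos += 2
                else:
                    values[i] = outs[name][pos]
                    pos += 1
    total = 0.0
    for i, c in enumerate(constraints):
        v = values.get(i)
        if v is None:
            v = _constraint_value(adapter, params, c)
        trigger = None
        if c.window_trigger is not None and isinstance(c.observable, Observable):
            trigger = _lookup(adapter, params, c.observable.condition,
                              c.window_trigger[0])
        g = violation(c, v, trigger)
        pen = c.weight * max(0.0, g)
        breakdown[c.id] = pen
        total += pen
    if return_breakdown:
        return total, breakdown
    return total


def total_objective(adapter, params: Mapping[str, float],
                    points: Sequence[QuantPoint],
                    constraints: Sequence[Constraint]) -> float:
    """f_tot = f_quant + f_qual, exactly (same floating-point sum of the parts)."""
    return quant_objective(adapter, params, points) \
        + qual_objective(adapter, params, constraints)


def oscillation_penalty(traj: Trajectory, max_peaks: int = 20,
                        weight: float = 1.0) -> float:
    """Penalize rapidly oscillating time courses: weight·max(0, #peaks − max_peaks).

    A peak is a strict interior local maximum (greater than both neighbors).
    Exactly ``max_peaks`` peaks incurs no penalty.
    """
    v = traj.values
    if len(v) < 3:
        return 0.0
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    n_peaks = int(np.count_nonzero(interior))
    return weight * max(0, n_peaks - max_peaks)


def make_objective(adapter, points: Sequence[QuantPoint],
                   constraints: Sequence[Constraint],
                   which: str = "total") -> Callable[[Mapping[str, float]], float]:
    """A callable over parameter mappings for the optimizers.

    ``which``: "total", "quant" or "qual".
    """
    points = list(points)
    constraints = list(constraints)
    if which == "quant":
        return lambda params: quant_objective(adapter, params, points)
    if which == "qual":
        return lambda params: qual_objective(adapter, params, constraints)
    if which == "total":
        return lambda params: total_objective(adapter, params, constraints=constraints,
                                              points=points)
    raise ValueError(f"unknown objective flavor {which!r}")


# ---------------------------------------------------------------------------
# file dialects
#
# Quantitative data: CSV with one condition column per condition key plus
# columns ``output`` and ``value``.  Constraints: CSV with header
#   id,output,condition,ref_condition,kind,threshold,tolerance,weight,
#   window_start,window_end
# where condition records are encoded as "key=val;key=val" and an empty
# ref_condition marks a plain (non-difference) observable.

def write_quant_csv(points: Sequence[QuantPoint], path) -> None:
    rows = [{**dict(p.condition), "output": p.output, "value": p.value} for p in points]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_quant_csv(path) -> list[QuantPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    cond_cols = [c for c in df.columns if c not in ("output", "value")]
    return [
        QuantPoint(condition={k: float(row[k]) for k in cond_cols},
                   output=str(row["output"]), value=float(row["value"]))
        for _, row in df.iterrows()
    ]


def _encode_cond(cond: Mapping[str, float]) -> str:
    return ";".join(f"{k}={v!r}" for k, v in sorted(cond.items()))


def _decode_cond(s: str) -> dict[str, float]:
    if not s or (isinstance(s, float) and math.isnan(s)):
        return {}
    out = {}
    for part in str(s).split(";"):
        k, v = part.split("=")
        out[k] = float(v)
    return out


def write_constraints_csv(constraints: Sequence[Constraint], path) -> None:
    rows = []
    for c in constraints:
        obs = c.observable
        rows.append({
            "id": c.id,
            "output": obs.output,
            "condition": _encode_cond(obs.condition),
            "ref_condition": _encode_cond(obs.ref_condition)
            if isinstance(obs, DifferenceObservable) else "",
            "kind": c.kind,
            "threshold": c.threshold,
            "tolerance": c.tolerance,
            "weight": c.weight,
            "window_start": "" if c.window is None else c.window[0],
            "window_end": "" if c.window is None else c.window[1],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_constraints_csv(path) -> list[Constraint]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    out = []
    for _, row in df.iterrows():
        cond = _decode_cond(row["condition"])
        ref = _decode_cond(row["ref_condition"])
        if row["ref_condition"]:
            obs: ObservableSpec = DifferenceObservable(str(row["output"]), cond, ref)
        else:
            obs = Observable(str(row["output"]), cond)
        window = None
        if str(row.get("window_start", "")) != "":
            window = (float(row["window_start"]), float(row["window_end"]))
        out.append(Constraint(
            id=str(row["id"]), observable=obs, kind=str(row["kind"]),
            threshold=float(row["threshold"]), tolerance=float(row["tolerance"]),
            weight=float(row["weight"]), window=window,
        ))
    return out
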