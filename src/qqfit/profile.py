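"""Profile-likelihood uncertainty quantification.

One parameter is held fixed at each value of a grid while the remaining
parameters are re-optimized; the resulting minimum objective, normalized to
zero by subtracting the curve's minimum, plays the role of a relative
negative log-likelihood.  The range of parameter values whose relative
objective stays at or below a chosen threshold is reported as a confidence
interval.  The objective here is not a likelihood in the rigorous sense —
the threshold is illustrative, not a χ² quantile — but lower values mean
better consistency with the data, and combining datasets can only sharpen
the curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .objective import make_objective
from .optimize import OptimizerResult, SearchSpace, de_fit

__all__ = [
    "ProfileCurve",
    "ConfidenceInterval",
    "EmptyIntervalError",
    "compute_profile",
    "interval_at_threshold",
    "profile_suite",
    "plot_profiles",
    "suite_table",
]

logger = logging.getLogger(__name__)


class EmptyIntervalError(ValueError):
    """The entire profile lies above the requested threshold."""


@dataclass(frozen=True)
class ProfileCurve:
    """Minimized objective along a grid of fixed values of one parameter."""

    parameter: str
    grid: np.ndarray          # strictly increasing fixed values (natural units)
    raw: np.ndarray           # minimum objective at each grid value (NaN = failed)
    scale: str = "linear"     # "linear" or "log10": how the grid was laid out
    replicates: int = 1

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        r = np.asarray(self.raw, dtype=float)
        if len(g) != len(r):
            raise ValueError("grid and raw must have equal length")
        if not np.all(np.diff(g) > 0):
            raise ValueError("grid must be strictly increasing")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "raw", r)

    @property
    def normalized(self) -> np.ndarray:
        """raw − min(raw): the relative objective, zero at the curve minimum."""
        return self.raw - np.nanmin(self.raw)

    def scaled_grid(self) -> np.ndarray:
        return np.log10(self.grid) if self.scale == "log10" else self.grid


@dataclass(frozen=True)
class ConfidenceInterval:
    """Outermost threshold crossings of a normalized profile.

    ``lower``/``upper`` are in the parameter's natural units.  A censored
    side means the curve was still at or below the threshold at that grid
    end, so only a one-sided bound is known (reported like "<−0.1" when the
    upper end is interior but the lower is censored).
    """

    lower: float
    upper: float
    threshold: float
    lower_censored: bool = False
    upper_censored: bool = False

    def width_decades(self) -> float:
        """log10(upper) − log10(lower); censored ends use the grid boundary."""
        return float(np.log10(self.upper) - np.log10(self.lower))


def compute_profile(objective: Callable[[Mapping[str, float]], float],
                    space: SearchSpace, parameter: str,
                    grid: Sequence[float], *, scale: str = "linear",
                    inner_optimizer: Callable[..., OptimizerResult] | None = None,
                    replicates: int = 1, seed: int | None = None) -> ProfileCurve:
    """Profile ``parameter`` over ``grid``, re-optimizing all other parameters.

    ``inner_optimizer(objective, space, seed=...)`` runs the nested
    minimization (default: :func:`de_fit` with its defaults).  With
    ``replicates > 1`` each grid point keeps the best of the replicate
    minima.  If no free parameters remain after fixing, the objective is
    simply evaluated.  An inner-optimizer failure at a grid point is
    recorded as NaN rather than aborting the profile.
    """
    if parameter not in space.bounds:
        raise ValueError(f"{parameter!r} is not a parameter of the search space")
    inner = inner_optimizer or de_fit
    ss = np.random.SeedSequence(seed)
    raw = np.empty(len(grid))
    for gi, value in enumerate(grid):
        sub = space.with_fixed(**{parameter: float(value)})
        best = np.inf
        for rep_seed in ss.generate_state(replicates):
            rep_seed = int(rep_seed % (2**31))
            try:
                if sub.ndim == 0:
                    val = float(objective(sub.to_params(np.empty(0))))
                else:
                    val = inner(objective, sub, seed=rep_seed).objective
            except Exception:  # noqa: BLE001 - record and continue
                logger.exception("inner optimization failed at %s=%g", parameter, value)
                val = np.nan
            if not np.isnan(val):
                best = min(best, val)
        raw[gi] = best if np.isfinite(best) else np.nan
    return ProfileCurve(parameter=parameter, grid=np.asarray(grid, dtype=float),
                        raw=raw, scale=scale, replicates=replicates)


def interval_at_threshold(curve: ProfileCurve, threshold: float) -> ConfidenceInterval:
    """Smallest/largest parameter values with normalized objective <= threshold.

    Endpoints are linearly interpolated (on the grid's scale) between the
    grid points straddling the outermost crossings; a side still below the
    threshold at a grid end is censored there.  Interior excursions above
    the threshold between the outermost crossings trigger a warning — the
    confidence region is then disconnected and the interval is its hull.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    x = curve.scaled_grid()
    y = curve.normalized
    ok = ~np.isnan(y)
    x, y = x[ok], y[ok]
    below = y <= threshold
    if not below.any():
        raise EmptyIntervalError(
            f"entire profile of {curve.parameter} lies above threshold {threshold}")
    idx = np.nonzero(below)[0]
    first, last = idx[0], idx[-1]

    def cross(i_out, i_in):
        # linear interpolation between (x[i_out], y[i_out]) above and
        # (x[i_in], y[i_in]) at/below the threshold
        frac = (y[i_out] - threshold) / (y[i_out] - y[i_in])
        return x[i_out] + frac * (x[i_in] - x[i_out])

    lower_censored = first == 0
    upper_censored = last == len(x) - 1
    lo = x[0] if lower_censored else cross(first - 1, first)
    hi = x[-1] if upper_censored else cross(last + 1, last)
    if not np.all(below[first:last + 1]):
        warnings.warn(
            f"profile of {curve.parameter}: confidence region at threshold "
            f"{threshold} is disconnected; reporting its hull", stacklevel=2)
    if curve.scale == "log10":
        lo, hi = 10.0 ** lo, 10.0 ** hi
    return ConfidenceInterval(lower=float(lo), upper=float(hi), threshold=threshold,
                              lower_censored=bool(lower_censored),
                              upper_censored=bool(upper_censored))


FLAVORS = ("quant", "qual", "total")


def profile_suite(adapter, points, constraints, space: SearchSpace,
                  grids: Mapping[str, Sequence[float]], *,
                  scales: Mapping[str, str] | None = None,
                  threshold: float = 0.15,
                  inner_optimizer=None, replicates: int = 1,
                  seed: int | None = None) -> dict[str, dict[str, dict]]:
    """Profiles and intervals for every parameter × objective flavor.

    For each parameter in ``grids`` and each of the three objective flavors
    (quantitative-only, qualitative-only, combined) this computes a
    :class:`ProfileCurve` and, where possible, the threshold interval.
    Returns ``{parameter: {flavor: {"curve": ..., "interval": ...}}}``; the
    interval is ``None`` when the whole curve exceeds the threshold.
    """
    scales = dict(scales or {})
    ss = np.random.SeedSequence(seed)
    out: dict[str, dict[str, dict]] = {}
    for pname, grid in grids.items():
        out[pname] = {}
        for flavor, fseed in zip(FLAVORS, ss.generate_state(len(FLAVORS))):
            objective = make_objective(adapter, points, constraints, which=flavor)
            curve = compute_profile(
                objective, space, pname, grid,
                scale=scales.get(pname, "linear"),
                inner_optimizer=inner_optimizer, replicates=replicates,
                seed=int(fseed % (2**31)))
            try:
                interval = interval_at_threshold(curve, threshold)
            except EmptyIntervalError:
                interval = None
            out[pname][flavor] = {"curve": curve, "interval": interval}
    return out


def _fmt_interval(iv: ConfidenceInterval | None, log10: bool) -> str:
    if iv is None:
        return "(empty)"
    f = (lambda v: np.log10(v)) if log10 else (lambda v: v)
    if iv.lower_censored and iv.upper_censored:
        return "unbounded"
    if iv.lower_censored:
        return f"<{f(iv.upper):.1f}"
    if iv.upper_censored:
        return f">{f(iv.lower):.1f}"
    return f"{f(iv.lower):.1f}–{f(iv.upper):.1f}"


def plot_profiles(suite: Mapping[str, Mapping[str, dict]], threshold: float = 0.15,
                  path=None):
    """Relative-objective profiles per parameter (log10 axis for log grids).

    Requires matplotlib (the ``plot`` extra).  Returns the figure; saves to
    ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = list(suite)
    fig, axes = plt.subplots(1, len(params), figsize=(4.2 * len(params), 3.4),
                             squeeze=False)
    styles = {"quant": ("--", "tab:blue"), "qual": ("-.", "tab:orange"),
              "total": ("-", "tab:purple")}
    for ax, pname in zip(axes[0], params):
        for flavor, d in suite[pname].items():
            curve = d["curve"]
            ls, color = styles[flavor]
            label = {"total": "combined"}.get(flavor, flavor)
            ax.plot(curve.scaled_grid(), curve.normalized, ls, color=color,
                    label=label)
        ax.axhline(threshold, color="gray", lw=0.8)
        log10 = suite[pname]["total"]["curve"].scale == "log10"
        ax.set_xlabel(f"log10({pname})" if log10 else pname)
        ax.set_ylabel("relative objective")
        ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def suite_table(suite: Mapping[str, Mapping[str, dict]],
                ground_truth: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Per-parameter bounds table: ground truth vs quant / qual / combined.

    log10-profiled parameters are reported on the log10 scale, matching how
    dose–response constants are conventionally tabulated.
    """
    rows = []
    for pname, flavors in suite.items():
        log10 = flavors["total"]["curve"].scale == "log10"
        row = {"parameter": f"log10({pname})" if log10 else pname}
        if ground_truth is not None and pname in ground_truth:
            gt = ground_truth[pname]
            row["ground_truth"] = round(float(np.log10(gt)) if log10 else gt, 4)
        row["quant"] = _fmt_interval(flavors["quant"]["interval"], log10)
        row["qual"] = _fmt_interval(flavors["qual"]["interval"], log10)
        row["combined"] = _fmt_interval(flavors["total"]["interval"], log10)
        rows.append(row)
    return pd.DataFrame(rows)
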