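"""Global minimization drivers: differential evolution and scatter search.

Both drivers minimize a scalar objective (a callable over named-parameter
mappings) inside a box :class:`SearchSpace`.  Differential evolution
delegates to :func:`scipy.optimize.differential_evolution`; scatter search
is implemented here: a small elite reference set updated each iteration by
one pairwise-combination child per ordered parent pair, with boundary
clipping, replace-parent-if-strictly-better acceptance, and
stagnation-triggered diversification from a Latin-hypercube queue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import differential_evolution
from scipy.stats import qmc

__all__ = [
    "SearchSpace",
    "OptimizerResult",
    "de_fit",
    "scatter_search_fit",
    "combine_pair",
    "latin_hypercube_queue",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchSpace:
    """Named box bounds with optional per-parameter log10 scaling.

    ``scales[name]`` is ``"linear"`` (default) or ``"log10"``; internally the
    optimizers work in scaled coordinates, so a log10 parameter is searched
    uniformly in its exponent.  ``fixed`` holds parameters clamped to a value
    (used by profile likelihood); they are excluded from the optimized
    dimensions but always present in the parameter mappings handed to the
    objective.
    """

    bounds: dict[str, tuple[float, float]]
    scales: dict[str, str] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
            if self.scales.get(name, "linear") == "log10" and lo <= 0:
                raise ValueError(f"{name}: log10 scale requires positive bounds")

    @property
    def free_names(self) -> list[str]:
        return [n for n in self.bounds if n not in self.fixed]

    @property
    def ndim(self) -> int:
        return len(self.free_names)

    def with_fixed(self, **values: float) -> "SearchSpace":
        return replace(self, fixed={**self.fixed, **values})

    def _scale(self, name: str, value: float) -> float:
        return np.log10(value) if self.scales.get(name, "linear") == "log10" else value

    def _unscale(self, name: str, value: float) -> float:
        return 10.0 ** value if self.scales.get(name, "linear") == "log10" else value

    def scaled_bounds(self) -> list[tuple[float, float]]:
        return [(self._scale(n, self.bounds[n][0]), self._scale(n, self.bounds[n][1]))
                for n in self.free_names]

    def to_params(self, x: np.ndarray) -> dict[str, float]:
        """Scaled free-coordinate array -> full named parameter mapping."""
        params = {n: self._unscale(n, float(v)) for n, v in zip(self.free_names, x)}
        params.update(self.fixed)
        return params

    def to_array(self, params) -> np.ndarray:
        return np.array([self._scale(n, params[n]) for n in self.free_names])

    def clip(self, x: np.ndarray) -> np.ndarray:
        """Reset out-of-range coordinates to the boundary of the range."""
        b = np.asarray(self.scaled_bounds())
        return np.clip(x, b[:, 0], b[:, 1])


@dataclass
class OptimizerResult:
    params: dict[str, float]
    objective: float
    n_evaluations: int
    trace: np.ndarray  # per-iteration best objective, non-increasing
    seed: int | None


def _wrap(objective, space: SearchSpace):
    """Array-coordinate objective with an evaluation counter."""
    count = [0]

    def f(x):
        count[0] += 1
        return float(objective(space.to_params(np.asarray(x, dtype=float))))

    return f, count


def de_fit(objective, space: SearchSpace, *, max_iterations: int = 1000,
           strategy: str = "best1exp", seed: int | None = None,
           popsize: int = 15, tol: float = 0.01, polish: bool = True,
           init: str = "latinhypercube") -> OptimizerResult:
    """Differential evolution inside the search space (deterministic per seed)."""
    f, count = _wrap(objective, space)
    trace: list[float] = []

    def cb(intermediate_result):
        trace.append(float(intermediate_result.fun))

    res = differential_evolution(
        f, bounds=space.scaled_bounds(), maxiter=max_iterations,
        strategy=strategy, rng=seed, popsize=popsize, tol=tol,
        polish=polish, init=init, callback=cb,
    )
    trace.append(float(res.fun))
    return OptimizerResult(
        params=space.to_params(res.x), objective=float(res.fun),
        n_evaluations=count[0], trace=np.minimum.accumulate(np.asarray(trace)),
        seed=seed,
    )


def latin_hypercube_queue(space: SearchSpace, n: int, seed: int | None = None
                          ) -> np.ndarray:
    """n Latin-hypercube points in scaled coordinates (one per stratum per axis)."""
    if n < 1:
        raise ValueError("queue size must be >= 1")
    sampler = qmc.LatinHypercube(d=space.ndim, rng=np.random.default_rng(seed))
    unit = sampler.random(n)
    b = np.asarray(space.scaled_bounds())
    return b[:, 0] + unit * (b[:, 1] - b[:, 0])


def combine_pair(parent_better: np.ndarray, parent_other: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Child sampled uniformly from the box centered on the better parent.

    Per-coordinate half-width equals the parent separation, so children land
    near the better parent but can explore past it; identical parents give an
    identical child.  Coordinates are in the space's scaled units and are not
    clipped here.
    """
    w = np.abs(parent_other - parent_better)
    return rng.uniform(parent_better - w, parent_better + w)


def scatter_search_fit(objective, space: SearchSpace, *, refset_size: int = 12,
                       stagnation_limit: int = 5, queue_size: int | None = None,
                       iterations: int = 100, seed: int | None = None
                       ) -> OptimizerResult:
    """Scatter search with an elite reference set and an LHS diversification queue.

    Each iteration proposes one child per ordered pair of refset members
    (refset_size × (refset_size − 1) proposals), clips children to the box,
    and replaces a parent by the best of its children iff strictly better
    (children are compared against the parent's pre-iteration objective, so
    the result is independent of pair enumeration order).  A member that goes
    ``stagnation_limit`` iterations without improvement is replaced by the
    next queue entry (drawn without replacement; the queue is refilled with a
    fresh seeded Latin-hypercube batch if exhausted).  The current refset
    best is exempt from stagnation replacement so the best objective in the
    refset is monotone non-increasing.
    """
    if queue_size is None:
        queue_size = max(1000, 100 * space.ndim)
    if queue_size < refset_size:
        raise ValueError("queue_size must be >= refset_size")
    f, count = _wrap(objective, space)
    rng = np.random.default_rng(seed)
    queue_seed = rng.integers(2**31)
    queue = list(latin_hypercube_queue(space, queue_size, seed=int(queue_seed)))

    def next_from_queue():
        nonlocal queue
        if not queue:
            refill = int(rng.integers(2**31))
            logger.info("LHS queue exhausted; refilling %d entries (seed %d)",
                        queue_size, refill)
            queue = list(latin_hypercube_queue(space, queue_size, seed=refill))
        return queue.pop(0)

    # initial refset: the first refset_size queue entries
    members = [next_from_queue() for _ in range(refset_size)]
    objectives = np.array([f(x) for x in members])
    if not np.any(np.isfinite(objectives)):
        raise RuntimeError("objective non-finite at every initial refset member")
    stagnation = np.zeros(refset_size, dtype=int)
    trace = []
    for _ in range(iterations):
        pre = objectives.copy()
        best_child = [None] * refset_size
        best_child_obj = np.full(refset_size, np.inf)
        for i in range(refset_size):
            for j in range(refset_size):
                if i == j:
                    continue
                if pre[i] <= pre[j]:
                    better, other = members[i], members[j]
                else:
                    better, other = members[j], members[i]
                child = space.clip(combine_pair(better, other, rng))
                obj = f(child)
                if obj < best_child_obj[i]:
                    best_child_obj[i] = obj
                    best_child[i] = child
        for i in range(refset_size):
            if best_child[i] is not None and best_child_obj[i] < pre[i]:
                members[i] = best_child[i]
                objectives[i] = best_child_obj[i]
                stagnation[i] = 0
            else:
                stagnation[i] += 1
        incumbent = int(np.argmin(objectives))
        for i in range(refset_size):
            if i != incumbent and stagnation[i] >= stagnation_limit:
                members[i] = np.asarray(next_from_queue())
                objectives[i] = f(members[i])
                stagnation[i] = 0
        trace.append(float(objectives.min()))
    best = int(np.argmin(objectives))
    trace = np.minimum.accumulate(np.asarray(trace)) if trace \
        else np.array([float(objectives.min())])
    return OptimizerResult(
        params=space.to_params(members[best]), objective=float(objectives[best]),
        n_evaluations=count[0], trace=trace, seed=seed,
    )
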