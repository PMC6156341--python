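"""Polynomial coefficient identification from sparse points plus sign data.

The demonstration problem: recover the five positive coefficients of a
parabola y₁ = a·x² − b·x + c and a line y₂ = d·x + e from three quantitative
anchor points (two on the parabola, one on the line) — which alone leave the
system underdetermined — plus qualitative labels telling, at grid points on
[0, 10], whether the line is above (+) or below (−) the parabola.

The sign pattern brackets the two intersection roots x₁ < x₂ of y₁ − y₂.
If the roots were known exactly, Vieta's formulas

    x₁ + x₂ = (b + d)/a        x₁·x₂ = (c − e)/a

together with the three anchors close a 5×5 linear system with a unique
solution.  Sampling candidate (x₁, x₂) pairs inside the sign-change
brackets and keeping only all-positive solutions yields interval bounds on
every coefficient that tighten as the label grid densifies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import POLY_ANCHORS, POLY_GROUND_TRUTH, QualLabel, gen_poly_signs

__all__ = [
    "RootBounds",
    "InconsistentSignsError",
    "DegenerateConfigurationError",
    "EmptyFeasibleSetError",
    "sign_change_intervals",
    "solve_vieta",
    "coefficient_bounds",
    "bounds_vs_npoints",
]

COEFF_NAMES = ("a", "b", "c", "d", "e")


class InconsistentSignsError(ValueError):
    """The label pattern does not bracket exactly two intersection roots."""


class DegenerateConfigurationError(ValueError):
    """The (x1, x2, anchors) configuration yields a singular linear system."""


class EmptyFeasibleSetError(ValueError):
    """No sampled (x1, x2) pair gives an all-positive coefficient solution."""


@dataclass(frozen=True)
class RootBounds:
    """Open intervals bracketing the two roots; zero width pins a root exactly."""

    x1: tuple[float, float]
    x2: tuple[float, float]

    def __post_init__(self):
        if not (self.x1[0] <= self.x1[1] and self.x2[0] <= self.x2[1]):
            raise ValueError("interval endpoints out of order")
        if not self.x1[1] <= self.x2[0]:
            raise ValueError("x1 interval must lie entirely left of x2 interval")


def sign_change_intervals(labels: Sequence[QualLabel]) -> RootBounds:
    """Locate the two roots from the label sequence.

    A root lies in any grid interval whose endpoints carry opposite signs,
    and exactly at any grid point labelled '0' (the noiseless generator
    reports an exact tie there, which pins the intersection).  Anything
    other than exactly two located roots raises
    :class:`InconsistentSignsError`.
    """
    labels = sorted(labels, key=lambda l: l.x)
    roots: list[tuple[float, float]] = []
    for lab in labels:
        if lab.label == "0":
            roots.append((lab.x, lab.x))
    for left, right in zip(labels, labels[1:]):
        if {left.label, right.label} == {"+", "-"}:
            roots.append((left.x, right.x))
    roots.sort()
    if len(roots) != 2:
        raise InconsistentSignsError(
            f"expected evidence for exactly 2 intersection roots, found {len(roots)}")
    return RootBounds(x1=roots[0], x2=roots[1])


def _system(x1: float, x2: float, anchors: Mapping[str, Sequence[tuple[float, float]]]):
    """The 5×5 system in (a, b, c, d, e): anchors + the two Vieta relations."""
    (px1, py1), (px2, py2) = anchors["parabola"]
    (lx, ly), = anchors["line"]
    A = np.array([
        [px1**2, -px1, 1.0, 0.0, 0.0],
        [px2**2, -px2, 1.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, lx, 1.0],
        [x1 + x2, -1.0, 0.0, -1.0, 0.0],
        [x1 * x2, 0.0, -1.0, 0.0, 1.0],
    ])
    y = np.array([py1, py2, ly, 0.0, 0.0])
    return A, y


def solve_vieta(x1: float, x2: float,
                anchors: Mapping[str, Sequence[tuple[float, float]]] = POLY_ANCHORS
                ) -> np.ndarray:
    """Solve for (a, b, c, d, e) given exact roots and the three anchors."""
    if x1 == x2:
        raise DegenerateConfigurationError("x1 and x2 must be distinct")
    A, y = _system(x1, x2, anchors)
    try:
        sol = np.linalg.solve(A, y)
    except np.linalg.LinAlgError as err:
        raise DegenerateConfigurationError(str(err)) from err
    if not np.all(np.isfinite(sol)):
        raise DegenerateConfigurationError("singular configuration")
    return sol


def _interior_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """n candidate values strictly inside (lo, hi): midpoints of n equal bins.

    A zero-width interval (an exactly pinned root) collapses to its point.
    """
    if hi == lo:
        return np.array([lo])
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def coefficient_bounds(bounds: RootBounds,
                       anchors: Mapping[str, Sequence[tuple[float, float]]] = POLY_ANCHORS,
                       grid_n: int = 100) -> dict[str, tuple[float, float]]:
    """Per-coefficient (min, max) over sampled root pairs with all-positive fits.

    A ``grid_n × grid_n`` grid of (x₁, x₂) candidates is sampled inside the
    open root brackets; for each pair the 5×5 system is solved and solutions
    with any non-positive coefficient are discarded.
    """
    g1 = _interior_grid(*bounds.x1, grid_n)
    g2 = _interior_grid(*bounds.x2, grid_n)
    X1, X2 = np.meshgrid(g1, g2, indexing="ij")
    x1 = X1.ravel()
    x2 = X2.ravel()
    # batched 5x5 solves: only the two Vieta rows depend on (x1, x2)
    n = len(x1)
    A = np.zeros((n, 5, 5))
    base, y = _system(0.0, 1.0, anchors)  # placeholder roots; rows 3-4 overwritten
    A[:] = base
    A[:, 3, 0] = x1 + x2
    A[:, 4, 0] = x1 * x2
    try:
        sols = np.linalg.solve(A, np.broadcast_to(y[:, None], (n, 5, 1)))[..., 0]
    except np.linalg.LinAlgError:
        # isolated singular pairs: solve one by one, mark them infeasible
        sols = np.full((n, 5), np.nan)
        for i in range(n):
            try:
                sols[i] = np.linalg.solve(A[i], y)
            except np.linalg.LinAlgError:
                pass
    keep = np.all(np.isfinite(sols), axis=1)
    keep[keep] = np.all(sols[keep] > 0, axis=1)
    if not keep.any():
        raise EmptyFeasibleSetError("no sampled root pair yields all-positive coefficients")
    survivors = sols[keep]
    return {name: (float(survivors[:, i].min()), float(survivors[:, i].max()))
            for i, name in enumerate(COEFF_NAMES)}


def bounds_vs_npoints(coeffs: Sequence[float] = POLY_GROUND_TRUTH,
                      anchors: Mapping[str, Sequence[tuple[float, float]]] = POLY_ANCHORS,
                      n_list: Sequence[int] = (4, 8, 16, 32, 64, 128),
                      grid_n: int = 100) -> pd.DataFrame:
    """Coefficient ranges as a function of label count: the convergence table.

    One row per n (number of equal intervals, so n+1 labels) with min/max of
    each coefficient.  For nested grids (n doubling) the ranges shrink
    weakly with n, converging to the ground truth as the brackets tighten.
    """
    rows = []
    for n in n_list:
        if n < 4:
            raise ValueError("need n >= 4 intervals to bracket both roots")
        labels = gen_poly_signs(coeffs, n_intervals=n)
        ranges = coefficient_bounds(sign_change_intervals(labels), anchors, grid_n)
        row: dict[str, float] = {"n_intervals": n}
        for name in COEFF_NAMES:
            row[f"{name}_min"], row[f"{name}_max"] = ranges[name]
        rows.append(row)
    return pd.DataFrame(rows)
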