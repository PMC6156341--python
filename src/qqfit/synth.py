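"""Seeded generators for the two built-in case studies' synthetic datasets.

* Raf binding curve: receptor occupancy Ȳ at a grid of free-inhibitor
  concentrations, perturbed by additive Gaussian noise (sd 0.1).  Values are
  deliberately not clipped to [0, 1] — the noise model is additive on the
  measured fraction.
* Raf activity labels: noiseless qualitative calls comparing A(I) = RR + RIR
  to the basal activity A(0); within ±ε counts as "0", otherwise "+"/"−".
* Polynomial sign labels: at equally spaced x the sign of y₂ − y₁ for the
  parabola/line pair, with exact equality reported as a tie ("0").

All generators are pure functions of their arguments (and seed); the label
generators draw no random numbers at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .objective import Constraint, DifferenceObservable, QuantPoint
from .raf import DEFAULT_R_TOT, EquilibriumConstants, RafEquilibriumAdapter

__all__ = [
    "QualLabel",
    "default_quant_grid",
    "default_qual_grid",
    "gen_raf_quant",
    "gen_raf_qual",
    "raf_constraints_from_labels",
    "gen_poly_signs",
    "POLY_GROUND_TRUTH",
    "POLY_ANCHORS",
]

#: Polynomial demo ground truth (a, b, c, d, e) for y1 = a x² − b x + c, y2 = d x + e.
POLY_GROUND_TRUTH = (0.5, 3.0, 5.0, 1.0, 1.5)

#: Quantitative anchors: two points on the parabola, one on the line.
POLY_ANCHORS = {"parabola": [(2.0, 1.0), (8.0, 13.0)], "line": [(3.5, 5.0)]}

#: Default qualitative-band tolerance on Raf activity, μM.
RAF_EPSILON = 1.5

#: Default penalty weight C_i for the Raf activity constraints.
RAF_WEIGHT = 0.03


@dataclass(frozen=True)
class QualLabel:
    """A qualitative call at one condition value: '+', '−' or '0' (within error)."""

    x: float
    label: str

    def __post_init__(self):
        if self.label not in ("+", "-", "0"):
            raise ValueError(f"label must be one of '+', '-', '0'; got {self.label!r}")


def default_quant_grid() -> np.ndarray:
    """15 log-spaced inhibitor concentrations over [1e-5, 1e2] μM.

    The range spans the full occupancy transition of the ground-truth system
    (Ȳ ≈ 0.01 at 1e-5 μM to ≈ 0.97 at 1e2 μM) — the natural design for a
    binding-curve experiment.
    """
    return np.logspace(-5, 2, 15)


def default_qual_grid() -> np.ndarray:
    """20 log-spaced inhibitor concentrations over [1e-5, 1e2] μM.

    Same axis as the quantitative grid; under the ground truth the labels
    read 0…0 / +…+ / 0 / −…− along increasing I, i.e. basal, paradoxically
    activated, crossover, inhibited.
    """
    return np.logspace(-5, 2, 20)


def gen_raf_quant(constants: EquilibriumConstants, R_tot: float = DEFAULT_R_TOT,
                  I_grid: Sequence[float] | None = None, noise_sd: float = 0.1,
                  seed: int | None = None) -> list[QuantPoint]:
    """Noisy occupancy measurements Ȳ(I) + N(0, noise_sd²) on the I grid."""
    I_grid = default_quant_grid() if I_grid is None else np.asarray(I_grid, dtype=float)
    if np.any(I_grid < 0):
        raise ValueError("inhibitor concentrations must be non-negative")
    adapter = RafEquilibriumAdapter(
        {"K1": constants.K1, "K2": constants.K2, "K3": constants.K3,
         "K5": constants.K5}, R_tot=R_tot)
    clean = adapter.evaluate_batch({}, [{"I": float(I)} for I in I_grid])["occupancy"]
    noise = np.zeros_like(clean) if noise_sd == 0 else \
        np.random.default_rng(seed).normal(0.0, noise_sd, size=len(clean))
    return [QuantPoint(condition={"I": float(I)}, output="occupancy",
                       value=float(y + n))
            for I, y, n in zip(I_grid, clean, noise)]


def gen_raf_qual(constants: EquilibriumConstants, R_tot: float = DEFAULT_R_TOT,
                 I_grid: Sequence[float] | None = None,
                 epsilon: float = RAF_EPSILON) -> list[QualLabel]:
    """Noiseless activity labels vs the basal activity A(0), with tolerance ε."""
    I_grid = default_qual_grid() if I_grid is None else np.asarray(I_grid, dtype=float)
    if np.any(I_grid < 0):
        raise ValueError("inhibitor concentrations must be non-negative")
    adapter = RafEquilibriumAdapter(
        {"K1": constants.K1, "K2": constants.K2, "K3": constants.K3,
         "K5": constants.K5}, R_tot=R_tot)
    A = adapter.evaluate_batch({}, [{"I": float(I)} for I in I_grid])["activity"]
    A0 = adapter.evaluate({}, {"I": 0.0})["activity"]
    labels = []
    for I, a in zip(I_grid, A):
        d = a - A0
        labels.append(QualLabel(x=float(I),
                                label="0" if abs(d) < epsilon else ("+" if d > 0 else "-")))
    return labels


def raf_constraints_from_labels(labels: Sequence[QualLabel],
                                epsilon: float = RAF_EPSILON,
                                weight: float = RAF_WEIGHT,
                                R_tot: float = DEFAULT_R_TOT) -> list[Constraint]:
    """Render activity labels as inequality constraints on A(I) − A(0).

    "+" → A(I) − A(0) > 0, "−" → A(I) − A(0) < 0, "0" → |A(I) − A(0)| < ε.
    A(0) is a model output recomputed per parameter vector (it depends only
    on K1 here, but the framework does not assume that).
    """
    out = []
    for i, lab in enumerate(labels):
        obs = DifferenceObservable("activity", condition={"I": lab.x},
                                   ref_condition={"I": 0.0})
        if lab.label == "0":
            out.append(Constraint(id=f"qual_{i}", observable=obs, kind="within_band",
                                  threshold=0.0, tolerance=epsilon, weight=weight))
        elif lab.label == "+":
            out.append(Constraint(id=f"qual_{i}", observable=obs, kind="greater_than",
                                  threshold=0.0, weight=weight))
        else:
            out.append(Constraint(id=f"qual_{i}", observable=obs, kind="less_than",
                                  threshold=0.0, weight=weight))
    return out


# tie detection tolerance for the polynomial sign labels: an observation with
# |y1 - y2| below this is reported as an exact tie ("0"), which pins the
# intersection to that grid point.
_POLY_TIE_TOL = 1e-9


def gen_poly_signs(coeffs: Sequence[float] = POLY_GROUND_TRUTH,
                   n_intervals: int = 4,
                   domain: tuple[float, float] = (0.0, 10.0)) -> list[QualLabel]:
    """Sign of y₂ − y₁ at n_intervals + 1 equally spaced points of the domain.

    '+' where the line lies above the parabola, '−' where below, '0' at an
    exact intersection on the grid (|y₁ − y₂| ≤ 1e−9).
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    a, b, c, d, e = coeffs
    x = np.linspace(domain[0], domain[1], n_intervals + 1)
    diff = (d * x + e) - (a * x**2 - b * x + c)  # y2 - y1
    labels = []
    for xi, di in zip(x, diff):
        if abs(di) <= _POLY_TIE_TOL:
            lab = "0"
        else:
            lab = "+" if di > 0 else "-"
        labels.append(QualLabel(x=float(xi), label=lab))
    return labels
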