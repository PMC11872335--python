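"""Restricted-cubic and B-spline bases on ICE-anchored timescales.

Time variables (cycle number, time-to-event, time-to-death) enter the
imputation and weight models through flexible spline expansions so that a
nonlinear course of quality of life — e.g. a drop in the final cycles
before death — can be captured.  Restricted cubic splines (natural splines,
linear beyond the boundary knots) are the preferred basis; B-splines are the
fallback when near-collinearity of the truncated-power basis obstructs
model convergence.

For time-distance variables the knots are anchored to the event: 1, 4, 9
and 20 cycles before the ICE (i.e. on the ``t``/``s`` scale).  For forward
time (cycle number) no anchored placement exists and quantile-based knots
are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "rcs_basis", "bspline_basis", "ice_knots", "ICE_TIME_KNOTS"]

#: Knot locations (cycles before the ICE) for all time-distance splines.
ICE_TIME_KNOTS: tuple[float, ...] = (1.0, 4.0, 9.0, 20.0)


def ice_knots(ice_kind: str) -> tuple[float, ...]:
    """Knot vector for a time-distance variable, on the ``t``/``s`` scale.

    ``pd``/``td``/``death`` all use distances of 1, 4, 9 and 20 cycles
    before the event.  For forward time (``cycle``) there is no anchored
    choice; returns ``None`` to request quantile placement.
    """
    if ice_kind in ("pd", "td", "death", "s"):
        return ICE_TIME_KNOTS
    if ice_kind in ("cycle", "j", "forward"):
        return None
    raise ValueError(f"unknown ice_kind {ice_kind!r}")


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    With knots ``t_1 < ... < t_k`` returns ``k - 1`` columns: the identity
    ``x`` followed by ``k - 2`` truncated-cubic combinations that are linear
    beyond the boundary knots (Harrell's parameterisation, normalised by
    ``(t_k - t_1)^2``).  Deterministic given ``(x, knots)``.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = knots.size
    tk, tk1 = knots[-1], knots[-2]
    norm = (knots[-1] - knots[0]) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def bspline_basis(x, knots, degree: int = 3) -> np.ndarray:
    """Clamped B-spline basis with ``len(knots) + degree - 1`` columns.

    ``knots`` are the distinct breakpoints (boundary included); the knot
    vector is clamped by repeating the boundary knots ``degree`` times, so
    rows sum to one inside the span.  Outside the span each basis function
    is extended linearly from its boundary value and slope (linear-tail
    rule), mirroring the natural-spline behaviour of the preferred basis.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if knots.ndim != 1 or knots.size < 2 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be a strictly increasing vector of length >= 2")
    t = np.r_[[knots[0]] * degree, knots, [knots[-1]] * degree]
    n_basis = knots.size + degree - 1
    out = np.zeros((x.size, n_basis))
    lo, hi = knots[0], knots[-1]
    inside = (x >= lo) & (x <= hi)
    if inside.any():
        out[inside] = BSpline.design_matrix(x[inside], t, degree).toarray()
    for mask, x0 in (((x < lo), lo), ((x > hi), hi)):
        if mask.any():
            val = BSpline.design_matrix(np.array([x0]), t, degree).toarray()[0]
            slope = np.array(
                [BSpline(t, np.eye(n_basis)[i], degree).derivative()(x0) for i in range(n_basis)]
            )
            out[mask] = val[None, :] + np.outer(x[mask] - x0, slope)
    return out


@dataclass(frozen=True)
class SplineBasis:
    """A concrete basis: kind, knots and (for B-splines) degree."""

    kind: str  # "rcs" | "bspline"
    knots: tuple[float, ...]
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("rcs", "bspline"):
            raise ValueError(f"unknown spline kind {self.kind!r}")
        kn = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", kn)
        if np.any(np.diff(kn) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.kind == "rcs" and len(kn) < 3:
            raise ValueError("rcs needs >= 3 knots")

    @property
    def n_basis(self) -> int:
        if self.kind == "rcs":
            return len(self.knots) - 1  # identity column + (k-2) nonlinear
        return len(self.knots) + self.degree - 1

    def evaluate(self, x) -> np.ndarray:
        if self.kind == "rcs":
            return rcs_basis(x, self.knots)
        return bspline_basis(x, self.knots, self.degree)

    def column_names(self, var: str) -> list[str]:
        if self.kind == "rcs":
            return [var] + [f"rcs({var}){i}" for i in range(1, len(self.knots) - 1)]
        return [f"bs({var}){i}" for i in range(self.n_basis)]
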