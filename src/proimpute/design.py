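"""Declarative model specifications and design-matrix construction.

A :class:`ModelSpec` lists the fixed-effect terms of an imputation or
missingness model: plain variables, categorical expansions, spline
transforms of the time variables, and interactions of any of these with a
0/1 indicator (e.g. ``rcs(s) x death_ind`` so that the shape of the
quality-of-life course near the end of follow-up differs between patients
whose survival time is a death versus a censoring time).

:func:`default_model_spec` returns the bundled model variants:

* ``model2`` — B-spline mixed model used with predictive mean matching
  (two-level PMM);
* ``model3`` — restricted-cubic-spline mixed model with a random patient
  intercept, used for normal conditional draws;
* ``model45`` — fixed-effects additive model used with the clustered
  bootstrap (normal draws = model 4, PMM = model 5);
* ``naive`` — random intercept + spline of cycle + baseline covariates
  only, no ICE information (the benchmark a careless analysis would use).

The builder resolves quantile knots, expands categorical levels, detects
rank deficiency via a pivoted QR and drops dependent columns (recorded in
the diagnostics), and can be re-applied to new rows with the bases and
drops frozen from the fitting data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .splines import ICE_TIME_KNOTS, SplineBasis

__all__ = ["Term", "ModelSpec", "default_model_spec", "DesignBuilder", "MODEL_VARIANTS"]

MODEL_VARIANTS = ("model2", "model3", "model45", "naive")

CATEGORICAL_VARS = ("sex", "ecog")


@dataclass(frozen=True)
class Term:
    """One fixed-effect term: ``transform(var)``, optionally ``: by``.

    ``transform`` is ``identity``, ``categorical``, ``rcs`` or ``bspline``;
    ``by`` names a numeric (usually 0/1) column the expansion is multiplied
    with, yielding an interaction block.  ``knots=None`` requests quantile
    placement at fit time.
    """

    var: str
    transform: str = "identity"
    knots: tuple[float, ...] | None = None
    by: str | None = None

    def label(self) -> str:
        base = self.var if self.transform == "identity" else f"{self.transform}({self.var})"
        return f"{base}:{self.by}" if self.by else base


@dataclass(frozen=True)
class ModelSpec:
    """Imputation/weight model specification (response, terms, intercept)."""

    terms: tuple[Term, ...]
    response: str = "qol"
    random_intercept: bool = True
    name: str = "custom"

    def validate(self, columns) -> None:
        cols = set(columns)
        missing = sorted(
            {t.var for t in self.terms if t.var not in cols}
            | {t.by for t in self.terms if t.by and t.by not in cols}
        )
        if missing:
            raise ValueError(f"model terms reference unknown columns: {missing}")
        # note: interaction-only time terms (no main effect) are deliberate
        # in some model variants, so no orphan check here
        if any(t.var == self.response or t.by == self.response for t in self.terms):
            raise ValueError(f"response {self.response!r} may not appear among predictors")

    def with_spline_kind(self, kind: str) -> "ModelSpec":
        """Swap every spline transform to ``kind`` (rcs <-> bspline fallback)."""
        new = tuple(
            replace(t, transform=kind) if t.transform in ("rcs", "bspline") else t
            for t in self.terms
        )
        return replace(self, terms=new, name=f"{self.name}[{kind}]")

    def drop_interaction(self) -> "ModelSpec | None":
        """Drop the highest-order interaction block (widest expansion first)."""
        inter = [t for t in self.terms if t.by is not None]
        if not inter:
            return None
        order = {"identity": 0, "categorical": 1, "rcs": 2, "bspline": 2}
        worst = max(inter, key=lambda t: order.get(t.transform, 0))
        new = tuple(t for t in self.terms if t is not worst)
        return replace(self, terms=new, name=f"{self.name}-{worst.label()}")


_COVARIATES = (
    Term("age"),
    Term("sex", "categorical"),
    Term("ecog", "categorical"),
)


def default_model_spec(variant: str) -> ModelSpec:
    """Return one of the bundled imputation model specifications."""
    K = ICE_TIME_KNOTS
    if variant == "model3":
        terms = (
            Term("cycle", "rcs"),
            Term("t_pd", "rcs", K),
            Term("t_td", "rcs", K),
            Term("s", "rcs", K),
            Term("s", "rcs", K, by="death_ind"),
            Term("death_ind"),
            Term("e_pd_now"),
            Term("e_pd_now", by="pd_ind"),
            Term("e_td_now"),
            # the t_pd x pd_ind interaction is deliberately absent: with the
            # event-anchored caps it over-parameterises the model
        ) + _COVARIATES
        return ModelSpec(terms, random_intercept=True, name="model3")
    if variant == "model2":
        terms = (
            Term("cycle", "bspline"),
            Term("t_pd", "bspline", K, by="pd_ind"),
            Term("pd_ind"),
            Term("t_td", "bspline", K),
            Term("s", "bspline", K, by="death_ind"),
            Term("death_ind"),
            Term("e_pd_now", by="pd_ind"),
            Term("e_td_now"),
        ) + _COVARIATES
        return ModelSpec(terms, random_intercept=True, name="model2")
    if variant == "model45":
        terms = (
            Term("cycle", "rcs"),
            Term("t_pd", "rcs", K),
            Term("t_pd", "rcs", K, by="pd_ind"),
            Term("pd_ind"),
            Term("t_td", "rcs", K),
            Term("s", "rcs", K),
            Term("s", "rcs", K, by="death_ind"),
            Term("death_ind"),
            Term("e_pd_now"),
            Term("e_pd_now", by="pd_ind"),
            Term("e_td_now"),
        ) + _COVARIATES
        return ModelSpec(terms, random_intercept=False, name="model45")
    if variant == "naive":
        terms = (Term("cycle", "rcs"),) + _COVARIATES
        return ModelSpec(terms, random_intercept=True, name="naive")
    raise ValueError(f"unknown model variant {variant!r}; expected one of {MODEL_VARIANTS}")


_QUANTILES_BY_COUNT = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def _quantile_knots(x: np.ndarray, n_knots: int = 5) -> tuple[float, ...]:
    """Quantile knot placement for forward-time variables (max 5 knots)."""
    x = np.asarray(x, dtype=float)
    for k in range(n_knots, 2, -1):
        q = np.quantile(x, _QUANTILES_BY_COUNT[k])
        q = tuple(np.unique(q))
        if len(q) == k:
            return q
    return tuple(np.unique(x))  # degenerate data; caller falls back to identity


class DesignBuilder:
    """Materialise a :class:`ModelSpec` into a numeric design matrix.

    ``fit(df)`` freezes quantile knots, B-spline boundary knots and
    categorical levels from the fitting rows and determines which columns
    to drop for rank (pivoted QR); ``transform(df)`` re-applies the frozen
    design to any rows.
    """

    def __init__(self, spec: ModelSpec, rank_tol: float = 1e-9):
        self.spec = spec
        self.rank_tol = rank_tol
        self._bases: dict[int, SplineBasis | None] = {}
        self._levels: dict[str, list] = {}
        self.columns_: list[str] | None = None
        self.dropped_: list[str] = []
        self.condition_number_: float | None = None

    # -- internal ---------------------------------------------------------
    def _resolve_basis(self, idx: int, term: Term, x: np.ndarray) -> SplineBasis | None:
        knots = term.knots
        if knots is None:
            knots = _quantile_knots(x)
        lo, hi = float(np.min(x)), float(np.max(x))
        if not hi > lo:
            return None  # constant variable: fall back to linear (then dropped)
        if term.transform == "bspline":
            # data range as boundary knots, anchored knots interior
            interior = [k for k in knots if lo < k < hi]
            return SplineBasis("bspline", tuple([lo] + interior + [hi]))
        # rcs keeps anchored knots inside the observed range; tails are linear
        kn = [k for k in knots if lo <= k <= hi]
        if len(kn) < 3:
            return None
        return SplineBasis("rcs", tuple(kn))

    def _term_block(self, term: Term, idx: int, df: pd.DataFrame, fitting: bool):
        x = df[term.var].to_numpy()
        if term.transform == "identity":
            cols, names = np.asarray(x, dtype=float)[:, None], [term.var]
        elif term.transform == "categorical":
            if fitting:
                self._levels[term.var] = sorted(pd.unique(pd.Series(x).astype(str)))
            levels = self._levels[term.var]
            sx = pd.Series(x).astype(str)
            cols = np.column_stack([(sx == lv).to_numpy(dtype=float) for lv in levels[1:]]) \
                if len(levels) > 1 else np.empty((len(df), 0))
            names = [f"{term.var}[{lv}]" for lv in levels[1:]]
        elif term.transform in ("rcs", "bspline"):
            x = np.asarray(x, dtype=float)
            if fitting:
                self._bases[idx] = self._resolve_basis(idx, term, x)
            basis = self._bases[idx]
            if basis is None:  # too few distinct values: fall back to linear
                cols, names = x[:, None], [term.var]
            else:
                cols = basis.evaluate(x)
                names = basis.column_names(term.var)
        else:
            raise ValueError(f"unknown transform {term.transform!r}")
        if term.by is not None:
            by = df[term.by].to_numpy(dtype=float)[:, None]
            cols = cols * by
            names = [f"{n}:{term.by}" for n in names]
        return cols, names

    def _assemble(self, df: pd.DataFrame, fitting: bool):
        blocks = [np.ones((len(df), 1))]
        names = ["intercept"]
        owners = [-1]
        for idx, term in enumerate(self.spec.terms):
            cols, nm = self._term_block(term, idx, df, fitting)
            blocks.append(cols)
            names.extend(nm)
            owners.extend([idx] * len(nm))
        X = np.hstack(blocks)
        # de-duplicate names (same column may arise from different terms)
        seen: dict[str, int] = {}
        uniq = []
        for n in names:
            k = seen.get(n, 0)
            seen[n] = k + 1
            uniq.append(n if k == 0 else f"{n}#{k}")
        return X, uniq, owners

    # -- public -----------------------------------------------------------
    def fit(self, df: pd.DataFrame) -> "DesignBuilder":
        self.spec.validate(df.columns)
        X, names, owners = self._assemble(df, fitting=True)
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        keep_mask = np.zeros(X.shape[1], dtype=bool)
        tol = self.rank_tol * max(diag[0], 1.0)
        rank = int(np.sum(diag > tol))
        keep_mask[piv[:rank]] = True
        self.columns_ = [n for n, k in zip(names, keep_mask) if k]
        self.dropped_ = [n for n, k in zip(names, keep_mask) if not k]
        # exact duplicate columns between two *different* main-effect terms
        # signal a user-level specification error and are refused by the
        # model fitters; any other rank deficiency (interaction aliasing,
        # sparse data regions) is resolved by dropping, with diagnostics
        self.duplicate_main_columns_ = []
        seen: dict[bytes, tuple[int, str]] = {}
        for ci, (name, owner) in enumerate(zip(names, owners)):
            if owner < 0 or self.spec.terms[owner].by is not None:
                continue
            key = X[:, ci].tobytes()
            if key in seen and seen[key][0] != owner:
                self.duplicate_main_columns_.append((seen[key][1], name))
            else:
                seen.setdefault(key, (owner, name))
        self._keep_idx = np.nonzero(keep_mask)[0]
        Xk = X[:, self._keep_idx]
        self.condition_number_ = float(np.linalg.cond(Xk))
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("DesignBuilder must be fit before transform")
        X, _, _ = self._assemble(df, fitting=False)
        return X[:, self._keep_idx]

    def fit_transform(self, df: pd.DataFrame) -> np.ndarray:
        return self.fit(df).transform(df)
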