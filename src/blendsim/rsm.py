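"""Box-Behnken design and response-surface modelling on coded factors.

A three-factor Box-Behnken design places runs at the midpoints of the
edges of the factor cube (coded levels in {-1, 0, +1}, exactly one zero
per edge run) plus replicated centre points.  Responses are modelled by
ordinary least squares on the coded scale

    y = b0 + sum_i bi xi + sum_{i<j} bij xi xj + sum_i bii xi^2 (+ noise)

with the caller choosing the term subset.  :class:`ResponseSurfaceModel`
follows the statsmodels convention: build the model from a design table
and a response, ``fit()`` returns an :class:`RsmResults` carrying the
coefficients, the ANOVA decomposition (including PRESS-based predicted
R-squared), prediction with t-based confidence intervals, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorDef",
    "SpecLimits",
    "code_factors",
    "decode_factors",
    "build_bbd",
    "ResponseSurfaceModel",
    "RsmResults",
    "fit_rsm",
    "design_space",
    "optimize",
    "TERMS",
]

#: Canonical term vocabulary for three coded factors.
TERMS = (
    "x1", "x2", "x3",
    "x1x2", "x1x3", "x2x3",
    "x1^2", "x2^2", "x3^2",
)

# Edge-midpoint block of the canonical 3-factor Box-Behnken design.
_BBD3 = np.array(
    [
        [-1, -1, 0], [1, -1, 0], [-1, 1, 0], [1, 1, 0],
        [-1, 0, -1], [1, 0, -1], [-1, 0, 1], [1, 0, 1],
        [0, -1, -1], [0, 1, -1], [0, -1, 1], [0, 1, 1],
    ],
    dtype=float,
)


class SingularDesignError(ValueError):
    """Model matrix is rank deficient (aliased terms)."""


@dataclass(frozen=True)
class FactorDef:
    """A process factor with its low/high natural-unit levels.

    The coded value is ``(natural - center) / half_width`` with
    ``center = (low + high)/2`` and ``half_width = (high - low)/2``, so
    low maps to -1, the centre to 0 and high to +1.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name}: low must be < high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.high - self.low)

    def code(self, natural):
        return (np.asarray(natural, dtype=float) - self.center) / self.half_width

    def decode(self, coded):
        return self.center + np.asarray(coded, dtype=float) * self.half_width


@dataclass(frozen=True)
class SpecLimits:
    """Acceptance limits for one response (either bound may be None)."""

    response: str
    lower: float | None = None
    upper: float | None = None
    target: str = "inside"  # informational: maximize / minimize / inside

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None:
            if not self.lower < self.upper:
                raise ValueError(
                    f"{self.response}: lower {self.lower} must be < upper {self.upper}"
                )

    def satisfied(self, value) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        ok = np.ones(value.shape, dtype=bool)
        if self.lower is not None:
            ok &= value >= self.lower
        if self.upper is not None:
            ok &= value <= self.upper
        return ok


def code_factors(settings, factors: Sequence[FactorDef]) -> np.ndarray:
    """Code natural-unit settings; values outside [-1, 1] are allowed."""
    settings = np.atleast_2d(np.asarray(settings, dtype=float))
    if settings.shape[-1] != len(factors):
        raise ValueError(
            f"expected {len(factors)} factor columns, got {settings.shape[-1]}"
        )
    return np.column_stack([f.code(settings[:, i]) for i, f in enumerate(factors)])


def decode_factors(coded, factors: Sequence[FactorDef]) -> np.ndarray:
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    return np.column_stack([f.decode(coded[:, i]) for i, f in enumerate(factors)])


def build_bbd(
    factors: Sequence[FactorDef],
    center_runs: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Three-factor Box-Behnken design table in natural and coded units.

    Returns 12 edge-midpoint runs plus ``center_runs`` centre replicates,
    with run order shuffled by ``seed`` (None keeps canonical order).
    """
    if len(factors) != 3:
        raise ValueError("Box-Behnken construction here supports exactly 3 factors")
    coded = _BBD3
    if center_runs:
        coded = np.vstack([coded, np.zeros((center_runs, 3))])
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(coded))
        coded = coded[order]
    natural = decode_factors(coded, factors)
    df = pd.DataFrame(natural, columns=[f.name for f in factors])
    for i, f in enumerate(factors):
        df[f"coded_{f.name}"] = coded[:, i]
    df.insert(0, "run", np.arange(1, len(df) + 1))
    return df


def _term_column(term: str, coded: np.ndarray) -> np.ndarray:
    """Evaluate one model term on coded columns x1..x3."""
    if term == "intercept":
        return np.ones(len(coded))
    if term.endswith("^2"):
        i = int(term[1]) - 1
        return coded[:, i] ** 2
    if len(term) == 4:  # e.g. x1x2
        i, j = int(term[1]) - 1, int(term[3]) - 1
        return coded[:, i] * coded[:, j]
    i = int(term[1]) - 1
    return coded[:, i]


def _model_matrix(terms: Sequence[str], coded: np.ndarray) -> np.ndarray:
    return np.column_stack([_term_column(t, coded) for t in ("intercept", *terms)])


class ResponseSurfaceModel:
    """OLS response-surface model on coded factors.

    Parameters
    ----------
    coded : (n, k) array of coded factor settings.
    response : length-n response vector.
    terms : model terms beyond the intercept (subset of :data:`TERMS`).
    factors : optional FactorDefs enabling natural-unit prediction.
    response_name : label used in summaries.
    """

    def __init__(self, coded, response, terms: Sequence[str],
                 factors: Sequence[FactorDef] | None = None,
                 response_name: str = "y"):
        self.coded = np.atleast_2d(np.asarray(coded, dtype=float))
        self.response = np.asarray(response, dtype=float)
        if len(self.coded) != len(self.response):
            raise ValueError("design and response lengths differ")
        if np.any(~np.isfinite(self.response)):
            raise ValueError("response contains missing/non-finite values")
        unknown = [t for t in terms if t not in TERMS]
        if unknown:
            raise ValueError(f"unknown terms: {unknown}")
        if len(self.response) < len(terms) + 1:
            raise ValueError("fewer runs than model terms")
        self.terms = tuple(terms)
        self.factors = tuple(factors) if factors is not None else None
        self.response_name = response_name

    @classmethod
    def from_dataframe(cls, runs: pd.DataFrame, response: str,
                       factors: Sequence[FactorDef],
                       terms: Sequence[str]) -> "ResponseSurfaceModel":
        """Build from a natural-unit run table (one factor column per FactorDef)."""
        natural = runs[[f.name for f in factors]].to_numpy(dtype=float)
        coded = code_factors(natural, factors)
        return cls(coded, runs[response].to_numpy(dtype=float), terms,
                   factors=factors, response_name=response)

    def fit(self) -> "RsmResults":
        X = _model_matrix(self.terms, self.coded)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the aliased columns for the error message
            _, r = np.linalg.qr(X)
            aliased = [("intercept", *self.terms)[i]
                       for i in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
            raise SingularDesignError(f"rank-deficient design; aliased terms: {aliased}")
        params, *_ = np.linalg.lstsq(X, self.response, rcond=None)
        return RsmResults(self, X, params)


class RsmResults:
    """Fit results: coefficients, ANOVA, prediction, summary."""

    def __init__(self, model: ResponseSurfaceModel, X: np.ndarray,
                 params: np.ndarray):
        self.model = model
        self.exog = X
        self.params = pd.Series(params, index=("intercept", *model.terms))
        self.fittedvalues = X @ params
        self.resid = model.response - self.fittedvalues
        self.nobs = len(model.response)
        self.df_model = len(model.terms)
        self.df_resid = self.nobs - self.df_model - 1
        y = model.response
        self.ss_total = float(np.sum((y - y.mean()) ** 2))
        self.ss_resid = float(np.sum(self.resid**2))
        self.ss_model = self.ss_total - self.ss_resid
        self.xtx_inv = np.linalg.inv(X.T @ X)
        self.leverage = np.einsum("ij,jk,ik->i", X, self.xtx_inv, X)
        self.press = float(np.sum((self.resid / (1.0 - self.leverage)) ** 2))

    # ----- goodness of fit -------------------------------------------------
    @property
    def rsquared(self) -> float:
        return self.ss_model / self.ss_total

    @property
    def rsquared_adj(self) -> float:
        return 1.0 - (1.0 - self.rsquared) * (self.nobs - 1) / self.df_resid

    @property
    def rsquared_pred(self) -> float:
        """Predicted R-squared, 1 - PRESS/SS_total (leave-one-out)."""
        return 1.0 - self.press / self.ss_total

    @property
    def mse_resid(self) -> float:
        return self.ss_resid / self.df_resid if self.df_resid > 0 else np.nan

    @property
    def resid_sd(self) -> float:
        return float(np.sqrt(self.mse_resid))

    @property
    def fvalue(self) -> float:
        if self.df_resid <= 0:
            return np.nan
        return (self.ss_model / self.df_model) / self.mse_resid

    @property
    def f_pvalue(self) -> float:
        if self.df_resid <= 0:
            return np.nan
        return float(stats.f.sf(self.fvalue, self.df_model, self.df_resid))

    def bse(self) -> pd.Series:
        """Coefficient standard errors."""
        se = np.sqrt(np.diag(self.xtx_inv) * self.mse_resid)
        return pd.Series(se, index=self.params.index)

    # ----- ANOVA -----------------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """ANOVA table: per-term SS (type III; equals sequential on the
        orthogonal Box-Behnken design), model, residual and total rows."""
        rows = []
        msr = self.mse_resid
        rows.append(dict(source="model", ss=self.ss_model, df=self.df_model,
                         ms=self.ss_model / self.df_model, F=self.fvalue,
                         p=self.f_pvalue))
        bse = self.bse()
        for term in self.model.terms:
            # type-III SS from the partial t statistic: SS = b^2 / [(X'X)^-1]_jj
            j = list(self.params.index).index(term)
            ss = self.params[term] ** 2 / self.xtx_inv[j, j]
            F = ss / msr if self.df_resid > 0 else np.nan
            p = float(stats.f.sf(F, 1, self.df_resid)) if self.df_resid > 0 else np.nan
            rows.append(dict(source=term, ss=ss, df=1, ms=ss, F=F, p=p))
        rows.append(dict(source="residual", ss=self.ss_resid, df=self.df_resid,
                         ms=msr, F=np.nan, p=np.nan))
        rows.append(dict(source="total", ss=self.ss_total, df=self.nobs - 1,
                         ms=np.nan, F=np.nan, p=np.nan))
        df = pd.DataFrame(rows)
        df.attrs.update(
            rsquared=self.rsquared, rsquared_adj=self.rsquared_adj,
            rsquared_pred=self.rsquared_pred, press=self.press,
        )
        return df

    # ----- prediction ------------------------------------------------------
    def _design_point(self, settings, coded: bool) -> np.ndarray:
        settings = np.atleast_2d(np.asarray(settings, dtype=float))
        if not coded:
            if self.model.factors is None:
                raise ValueError("model has no factor definitions; pass coded=True")
            settings = code_factors(settings, self.model.factors)
        return _model_matrix(self.model.terms, settings)

    def predict(self, settings, coded: bool = False, ci: bool = False,
                alpha: float = 0.05):
        """Evaluate the polynomial at natural-unit (or coded) settings.

        With ``ci=True`` also returns the (lower, upper) t-based confidence
        band for the mean response.
        """
        X0 = self._design_point(settings, coded)
        pred = X0 @ self.params.to_numpy()
        out = pred if pred.size > 1 else float(pred[0])
        if not ci:
            return out
        se = np.sqrt(np.einsum("ij,jk,ik->i", X0, self.xtx_inv, X0) * self.mse_resid)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid)
        lo, hi = pred - tcrit * se, pred + tcrit * se
        if pred.size == 1:
            return out, (float(lo[0]), float(hi[0]))
        return out, (lo, hi)

    def eliminate_backward(self, alpha: float = 0.05) -> "RsmResults":
        """Drop the least-significant term while its p exceeds ``alpha``."""
        res = self
        while True:
            an = res.anova().set_index("source")
            term_p = an.loc[list(res.model.terms), "p"]
            worst = term_p.idxmax()
            if term_p[worst] <= alpha or len(res.model.terms) == 1:
                return res
            remaining = tuple(t for t in res.model.terms if t != worst)
            res = ResponseSurfaceModel(
                res.model.coded, res.model.response, remaining,
                factors=res.model.factors,
                response_name=res.model.response_name,
            ).fit()

    def summary(self) -> str:
        lines = [
            f"Response surface fit: {self.model.response_name}",
            f"  n = {self.nobs}, model df = {self.df_model}, residual df = {self.df_resid}",
            f"  R2 = {self.rsquared:.4f}  adj R2 = {self.rsquared_adj:.4f}  "
            f"pred R2 = {self.rsquared_pred:.4f}",
            f"  F = {self.fvalue:.2f}  (p = {self.f_pvalue:.4g})",
            "  term         coef        SE",
        ]
        bse = self.bse()
        for term, b in self.params.items():
            lines.append(f"  {term:<10} {b:>9.4f} {bse[term]:>9.4f}")
        return "\n".join(lines)


def fit_rsm(runs: pd.DataFrame, response: str, factors: Sequence[FactorDef],
            terms: Sequence[str]) -> RsmResults:
    """Convenience wrapper: fit a coded OLS model to a natural-unit run table."""
    return ResponseSurfaceModel.from_dataframe(runs, response, factors, terms).fit()


# ---------------------------------------------------------------------------
# design-space mapping and optimisation
# ---------------------------------------------------------------------------

def _grid_points(grid: Mapping[str, np.ndarray],
                 factors: Sequence[FactorDef],
                 fixed: Mapping[str, float] | None) -> tuple[np.ndarray, list[str]]:
    fixed = dict(fixed or {})
    axes, free = [], []
    for f in factors:
        if f.name in fixed:
            axes.append(np.array([fixed[f.name]], dtype=float))
        else:
            if f.name not in grid:
                raise ValueError(f"no grid for factor {f.name!r} and not pinned")
            axes.append(np.asarray(grid[f.name], dtype=float))
            free.append(f.name)
    if any(len(a) == 0 for a in axes):
        raise ValueError("empty grid axis")
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    return pts, free


def design_space(fits: Mapping[str, RsmResults], specs: Sequence[SpecLimits],
                 grid: Mapping[str, np.ndarray],
                 factors: Sequence[FactorDef],
                 fixed: Mapping[str, float] | None = None,
                 use_ci: bool = False, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean acceptability map over a factor grid.

    A grid cell is acceptable iff every response's point prediction (or,
    with ``use_ci=True``, its 95% confidence bound on the unfavourable
    side) satisfies that response's limits.
    """
    pts, _ = _grid_points(grid, factors, fixed)
    df = pd.DataFrame(pts, columns=[f.name for f in factors])
    ok = np.ones(len(pts), dtype=bool)
    for spec in specs:
        fit = fits[spec.response]
        if use_ci:
            pred, (lo, hi) = fit.predict(pts, ci=True, alpha=alpha)
            pred = np.atleast_1d(pred)
            lo, hi = np.atleast_1d(lo), np.atleast_1d(hi)
            good = np.ones(len(pts), dtype=bool)
            if spec.lower is not None:
                good &= lo >= spec.lower
            if spec.upper is not None:
                good &= hi <= spec.upper
        else:
            pred = np.atleast_1d(fit.predict(pts))
            good = spec.satisfied(pred)
        df[f"pred_{spec.response}"] = pred
        ok &= good
    df["acceptable"] = ok
    return df


def optimize(fits: Mapping[str, RsmResults], specs: Sequence[SpecLimits],
             grid: Mapping[str, np.ndarray], factors: Sequence[FactorDef],
             objectives: Mapping[str, str],
             fixed: Mapping[str, float] | None = None,
             top: int = 5) -> pd.DataFrame:
    """Ranked feasible settings from a grid search.

    ``objectives`` maps response name to 'maximize'/'minimize'.  Feasible
    cells are scored by the mean of per-response desirabilities (linear
    rescaling over the feasible set); ties prefer lower filling level
    (first factor) then higher speed (second factor).
    """
    space = design_space(fits, specs, grid, factors, fixed)
    feas = space[space["acceptable"]].copy()
    if feas.empty:
        feas.attrs["diagnostic"] = "no grid point satisfies all specifications"
        return feas
    score = np.zeros(len(feas))
    for resp, sense in objectives.items():
        v = feas[f"pred_{resp}"].to_numpy()
        span = v.max() - v.min()
        d = np.ones_like(v) if span == 0 else (v - v.min()) / span
        if sense == "minimize":
            d = 1.0 - d
        score += d
    feas["desirability"] = score / max(len(objectives), 1)
    names = [f.name for f in factors]
    feas = feas.sort_values(
        ["desirability", names[0], names[1]],
        ascending=[False, True, False], kind="stable",
    )
    return feas.head(top).reset_index(drop=True)
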