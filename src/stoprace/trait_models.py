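"""Mixed-effects trait regressions for stop-task outcomes.

Log-transformed SST outcomes (SSRT, GoRT, GoRTSD) are regressed on sex, ADHD
trait score (reversed SWAN, so +54 is maximal ADHD traits) and age, with a
family-level random intercept to absorb sibling resemblance.  Main effects
enter by forward stepwise selection; the higher-order terms age^2, age x sex
and age^2 x sex are assessed once the main effects are in.  Fitted models
yield predicted-value grids at covariate extremes (back-transformed to ms)
and Cohen-style effect sizes between grid cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "TraitModelFit",
    "PredictionCell",
    "reverse_swan",
    "fit_trait_model",
    "predict_grid",
    "effect_size",
    "cell_difference",
]

SWAN_TOTAL_RANGE = (-54, 54)

MAIN_TERMS = ("male", "trait", "age")
HIGHER_ORDER_TERMS = ("age2", "age_male", "age2_male")

# Term name -> function of a frame with primitive columns male/trait/age/gort.
_BUILDERS = {
    "male": lambda d: d["male"],
    "trait": lambda d: d["trait"],
    "age": lambda d: d["age"],
    "age2": lambda d: d["age"] ** 2,
    "age_male": lambda d: d["age"] * d["male"],
    "age2_male": lambda d: d["age"] ** 2 * d["male"],
    "gort": lambda d: d["gort"],
}


class SingularFitError(ValueError):
    """Design matrix is rank-deficient; names the collinear terms."""


def reverse_swan(raw_total: float, limit: float = 54.0) -> float:
    """Reverse a SWAN score so that positive values mean higher ADHD traits.

    The SWAN rates strengths positively (+3 far above average), so raw totals
    run from +54 (greatest strength) to -54; analyses use the negated score.
    """
    arr = np.asarray(raw_total, dtype=float)
    if np.any(np.abs(arr) > limit):
        raise ValueError(f"SWAN total outside [-{limit:g}, +{limit:g}]")
    out = -arr
    return float(out) if np.isscalar(raw_total) else out


@dataclass
class TraitModelFit:
    response_name: str
    included_terms: list[str]
    fixed_effects: dict[str, tuple[float, float, float]]  # term -> (est, se, p)
    family_variance: float
    residual_variance: float
    scale: str = "log"
    covariate_means: dict[str, float] = field(default_factory=dict)
    fitted_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    _result: object = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.fixed_effects[t][0] for t in self.included_terms])


def _primitives(cohort: pd.DataFrame, trait_col: str) -> pd.DataFrame:
    d = pd.DataFrame(index=cohort.index)
    if "male" in cohort.columns:
        d["male"] = cohort["male"].astype(float)
    else:
        d["male"] = (cohort["sex"].astype(str).str.lower() == "male").astype(float)
    d["trait"] = cohort[trait_col].astype(float)
    d["age"] = cohort["age"].astype(float)
    if "gort_mean" in cohort.columns:
        d["gort"] = cohort["gort_mean"].astype(float)
    return d


def _design(prims: pd.DataFrame, terms: list[str]) -> np.ndarray:
    cols = [np.ones(len(prims))]
    for t in terms:
        cols.append(np.asarray(_BUILDERS[t](prims), dtype=float))
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # Identify columns that are linear combinations of the preceding ones.
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(terms[j - 1])
        raise SingularFitError(f"collinear terms: {bad}")


class _OLSSurrogate:
    """Stand-in when the mixed fit degenerates (family variance at the zero
    boundary makes the information matrix singular); equivalent to the
    mixed model at that boundary."""

    def __init__(self, y: np.ndarray, X: np.ndarray):
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        self.fe_params = beta
        self.resid = resid
        self.fittedvalues = X @ beta
        self.scale = sigma2
        self.cov_re = np.array([[0.0]])
        XtX = X.T @ X
        try:
            self._cov = sigma2 * np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            self._cov = np.full((X.shape[1], X.shape[1]), np.nan)

    def cov_params(self) -> np.ndarray:
        return self._cov


def _fit_mixed(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                return model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                continue
        return _OLSSurrogate(y, X)


def _term_pvalue(result, idx: int) -> float:
    est = result.fe_params[idx]
    se = np.sqrt(result.cov_params()[idx, idx])
    if se <= 0 or not np.isfinite(se):
        return 1.0
    return float(2 * stats.norm.sf(abs(est / se)))


def fit_trait_model(
    cohort: pd.DataFrame,
    response: str = "ssrt",
    candidate_terms: tuple[str, ...] = MAIN_TERMS,
    entry_alpha: float = 0.05,
    higher_order_terms: tuple[str, ...] = HIGHER_ORDER_TERMS,
    forced_terms: tuple[str, ...] = (),
    trait_col: str = "swan_total",
    assess_higher_order: bool = True,
) -> TraitModelFit:
    """Forward-stepwise mixed model for ``log(response)`` with a family
    random intercept.

    ``forced_terms`` are entered unconditionally (used to control GoRT in
    models of GoRTSD).  Higher-order terms are assessed only after all main
    effects have entered.  Selection uses Wald p-values of the entering
    coefficient at ``entry_alpha``; the final model is refit by ML on the
    selected term set.
    """
    y = cohort[response].astype(float)
    if (y <= 0).any():
        raise ValueError(f"{response} must be positive for the log transform")
    logy = np.log(y.to_numpy())
    prims = _primitives(cohort, trait_col)
    groups = cohort["family_id"].to_numpy()

    included: list[str] = list(forced_terms)
    X0 = _design(prims, included)
    _check_rank(X0, included)

    def stepwise(pool: list[str]) -> None:
        remaining = list(pool)
        while remaining:
            best_term, best_p = None, np.inf
            for term in remaining:
                trial_terms = included + [term]
                X = _design(prims, trial_terms)
                if np.linalg.matrix_rank(X) < X.shape[1]:
                    continue
                res = _fit_mixed(logy, X, groups)
                p = _term_pvalue(res, len(trial_terms))  # col 0 is intercept
                if p < best_p:
                    best_term, best_p = term, p
            if best_term is None or best_p >= entry_alpha:
                break
            included.append(best_term)
            remaining.remove(best_term)

    stepwise([t for t in candidate_terms if t not in included])
    mains_in = all(t in included for t in candidate_terms)
    if assess_higher_order and mains_in and higher_order_terms:
        stepwise([t for t in higher_order_terms if t not in included])

    X = _design(prims, included)
    _check_rank(X, included)
    result = _fit_mixed(logy, X, groups)

    names = ["intercept"] + included
    fe: dict[str, tuple[float, float, float]] = {}
    cov = result.cov_params()
    for j, name in enumerate(names):
        est = float(result.fe_params[j])
        se = float(np.sqrt(cov[j, j]))
        p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan
        fe[name] = (est, se, p)

    fit = TraitModelFit(
        response_name=response,
        included_terms=names,
        fixed_effects=fe,
        family_variance=float(np.asarray(result.cov_re)[0, 0]),
        residual_variance=float(result.scale),
        covariate_means={"gort": float(prims["gort"].mean()) if "gort" in prims else np.nan},
        fitted_ranges={
            "age": (float(prims["age"].min()), float(prims["age"].max())),
            "trait": (float(prims["trait"].min()), float(prims["trait"].max())),
        },
        _result=result,
    )
    return fit


@dataclass(frozen=True)
class PredictionCell:
    age: float
    sex: str
    trait: float
    predicted: float
    ci_low: float
    ci_high: float
    pred_sd: float


def predict_grid(
    fit: TraitModelFit,
    ages=(6, 18),
    sexes=("female", "male"),
    traits=(-54, 54),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Population-level predictions (random effect at zero) back-transformed
    to ms, with normal-theory CIs on the linear predictor and the SD of a
    single new observation (family + residual variance, delta method)."""
    result = fit._result
    cov = result.cov_params()[: len(fit.included_terms), : len(fit.included_terms)]
    beta = np.array([fit.fixed_effects[t][0] for t in fit.included_terms])
    z = stats.norm.ppf(1 - alpha / 2)
    s_new2 = fit.family_variance + fit.residual_variance

    rows = []
    for age, sex, trait in itertools.product(ages, sexes, traits):
        lo, hi = fit.fitted_ranges.get("age", (-np.inf, np.inf))
        if not lo <= age <= hi:
            warnings.warn(f"age {age} outside fitted range [{lo:g}, {hi:g}]")
        lo, hi = fit.fitted_ranges.get("trait", (-np.inf, np.inf))
        if not lo <= trait <= hi:
            warnings.warn(f"trait {trait} outside fitted range [{lo:g}, {hi:g}]")
        prim = pd.DataFrame(
            {
                "male": [1.0 if str(sex).lower() == "male" else 0.0],
                "trait": [float(trait)],
                "age": [float(age)],
                "gort": [fit.covariate_means.get("gort", np.nan)],
            }
        )
        x = _design(prim, fit.included_terms[1:])[0]
        lp = float(x @ beta)
        se_lp = float(np.sqrt(x @ cov @ x))
        pred = np.exp(lp)
        rows.append(
            {
                "response": fit.response_name,
                "sex": sex,
                "age": age,
                "trait": trait,
                "predicted": pred,
                "ci_low": np.exp(lp - z * se_lp),
                "ci_high": np.exp(lp + z * se_lp),
                # SD of one new observation on the ms scale (delta method).
                "pred_sd": pred * np.sqrt(se_lp**2 + s_new2),
            }
        )
    return pd.DataFrame(rows)


def effect_size(
    pred1: float, pred2: float, sd1: float, sd2: float, mode: str = "pooled"
) -> float:
    """Cohen-style standardized difference between two predicted cells.

    ``pooled`` (default) divides by ``sqrt((sd1^2 + sd2^2)/2)``.  ``printed``
    reproduces the as-printed approximation with the difference of squared
    SDs under the root; it is degenerate when the two cells have equal
    dispersion and is kept for fidelity only.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("cell SDs must be positive")
    if mode == "pooled":
        denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    elif mode == "printed":
        diff = abs(sd1**2 - sd2**2)
        if diff == 0:
            raise ZeroDivisionError(
                "printed-mode denominator is zero when cell SDs are equal; "
                "use mode='pooled'"
            )
        denom = np.sqrt(diff)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float((pred1 - pred2) / denom)


def _select(grid: pd.DataFrame, selector: dict) -> pd.Series:
    mask = np.ones(len(grid), dtype=bool)
    for key, val in selector.items():
        mask &= grid[key] == val
    sub = grid[mask]
    if len(sub) != 1:
        raise KeyError(f"selector {selector} matched {len(sub)} cells, need exactly 1")
    return sub.iloc[0]


def cell_difference(
    grid: pd.DataFrame, cell_a: dict, cell_b: dict, ndigits: int | None = None
) -> float:
    """``predicted(a) - predicted(b)`` between two grid cells."""
    diff = float(_select(grid, cell_a)["predicted"] - _select(grid, cell_b)["predicted"])
    return round(diff, ndigits) if ndigits is not None else diff
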