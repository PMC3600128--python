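"""Variance-components heritability for sibling family data.

Implements maximum-likelihood polygenic variance decomposition for cohorts of
full-sibling families (unrelated across families).  The phenotype, after
removal of covariate effects (mean model X*beta), is modelled per family as
multivariate normal with covariance

    sigma_A^2 * K + sigma_E^2 * I,

where K is the expected additive-genetic relationship matrix (1 on the
diagonal, 0.5 between full siblings).  Heritability is
h^2 = sigma_A^2 / (sigma_A^2 + sigma_E^2), tested against zero with a
likelihood-ratio test using the 1/2 chi2_0 + 1/2 chi2_1 boundary mixture.

Because K for a sibship is compound symmetric, the correlation matrix at a
given h^2 is ``(1 - h^2/2) I + (h^2/2) J`` and its inverse and determinant
have closed forms per family size, so the profile likelihood over h^2 (with
beta by GLS and the total variance in closed form) is a fast one-dimensional
optimization even at several thousand families.

Bivariate fits stack both traits per family, with cross-trait covariance
``rhog * sigma_A1 * sigma_A2`` (same person and, halved, between siblings)
plus ``rhoe * sigma_E1 * sigma_E2`` within person, partitioning the
phenotypic correlation into genetic (rhog) and environmental (rhoe) parts:

    rhop = rhog * sqrt(h1^2 * h2^2) + rhoe * sqrt((1 - h1^2) * (1 - h2^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Pedigree",
    "HeritabilityEstimate",
    "BivariateEstimate",
    "univariate_h2",
    "h2_confidence_interval",
    "bivariate_fit",
    "decompose_rhop",
]

_H2_EPS = 1e-6
_RHO_BOUND = 1.0 - 1e-6


class UnidentifiableError(ValueError):
    """The requested component cannot be estimated from this pedigree."""


@dataclass(frozen=True)
class Pedigree:
    """Full-sibling families; members of a family are siblings (expected
    relationship 0.5), members of different families unrelated."""

    families: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a table with ``individual_id`` and ``family_id``."""
        ids = frame["individual_id"].astype(str)
        if ids.duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        fams = []
        for fid, sub in frame.groupby("family_id", sort=True):
            fams.append((str(fid), tuple(sub["individual_id"].astype(str))))
        return cls(families=tuple(fams))

    @property
    def individuals(self) -> list[str]:
        return [m for _, members in self.families for m in members]

    @property
    def n_individuals(self) -> int:
        return sum(len(m) for _, m in self.families)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_sizes(self) -> list[int]:
        return [len(m) for _, m in self.families]


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    p_value: float
    ci: tuple[float, float]
    total_variance: float
    loglik: float
    covariate_effects: dict[str, float]
    n_individuals: int
    n_families: int


@dataclass
class BivariateEstimate:
    h2_1: float
    h2_2: float
    rhog: float
    rhog_se: float
    rhoe: float
    rhop: float
    p_rhog_zero: float
    loglik: float
    n_individuals: int
    boundary: bool = False


# ---------------------------------------------------------------------------
# data marshalling


def _as_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    """Covariates -> design matrix with intercept, plus column names."""
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = ["intercept"] + [str(c) for c in covariates.columns]
        X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = ["intercept"] + [f"x{j}" for j in range(arr.shape[1])]
        X = np.column_stack([np.ones(n), arr])
    return X, names


def _size_groups(pedigree: Pedigree, keep: np.ndarray) -> dict[int, np.ndarray]:
    """Map family size -> (F, n) array of row indices, after dropping rows
    where ``keep`` is False (families shrink, empty families vanish)."""
    groups: dict[int, list[list[int]]] = {}
    pos = 0
    for _, members in pedigree.families:
        idx = [pos + j for j in range(len(members)) if keep[pos + j]]
        pos += len(members)
        if idx:
            groups.setdefault(len(idx), []).append(idx)
    return {n: np.array(rows, dtype=int) for n, rows in groups.items()}


def _align_trait(trait, pedigree: Pedigree) -> np.ndarray:
    inds = pedigree.individuals
    if isinstance(trait, pd.Series) and trait.index.inferred_type in ("string", "mixed"):
        return trait.reindex(inds).to_numpy(dtype=float)  # keyed by individual id
    arr = np.asarray(trait, dtype=float)
    if arr.shape[0] != len(inds):
        raise ValueError("trait length does not match pedigree")
    return arr


# ---------------------------------------------------------------------------
# univariate


def _cs_coeffs(h2: float, n: int) -> tuple[float, float, float]:
    """Inverse/logdet coefficients of C = a I + b J for a sibship of size n:
    C^-1 = (1/a)(I - c J), with the log-determinant returned last."""
    a = 1.0 - 0.5 * h2
    b = 0.5 * h2
    c = b / (a + n * b)
    logdet = (n - 1) * np.log(a) + np.log(a + n * b)
    return a, c, logdet


def _profile_terms(h2, y, X, groups):
    """GLS accumulators at a given h2: X'C^-1X, X'C^-1y, y'C^-1y, sum logdet."""
    p = X.shape[1]
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    q = 0.0
    logdet = 0.0
    for n, idx in groups.items():
        a, c, ld = _cs_coeffs(h2, n)
        Xf = X[idx]  # (F, n, p)
        yf = y[idx]  # (F, n)
        sX = Xf.sum(axis=1)  # (F, p)
        sy = yf.sum(axis=1)  # (F,)
        A += (np.einsum("fni,fnj->ij", Xf, Xf) - c * sX.T @ sX) / a
        bvec += (np.einsum("fni,fn->i", Xf, yf) - c * sX.T @ sy) / a
        q += (np.einsum("fn,fn->", yf, yf) - c * sy @ sy) / a
        logdet += idx.shape[0] * ld
    return A, bvec, q, logdet


def _profile_nll(h2, y, X, groups, N):
    """Negative log-likelihood profiled over beta (GLS) and total variance."""
    A, bvec, q, logdet = _profile_terms(h2, y, X, groups)
    beta = np.linalg.solve(A, bvec)
    Q = q - beta @ bvec
    sig = Q / N
    nll = 0.5 * (N * np.log(sig) + logdet + N + N * np.log(2 * np.pi))
    return nll, beta, sig


def _nll_full(h2, sig, y, X, groups, N):
    """Negative log-likelihood at explicit (h2, total variance), beta by GLS
    (used for the observed-information SE of h2)."""
    A, bvec, q, logdet = _profile_terms(h2, y, X, groups)
    beta = np.linalg.solve(A, bvec)
    Q = q - beta @ bvec
    return 0.5 * (N * np.log(sig) + logdet + Q / sig + N * np.log(2 * np.pi))


def univariate_h2(
    trait,
    pedigree: Pedigree,
    covariates=None,
    alpha: float = 0.05,
) -> HeritabilityEstimate:
    """Maximum-likelihood narrow-sense heritability from sibling resemblance.

    ``trait`` is aligned to ``pedigree.individuals`` (array) or keyed by
    individual id (Series); rows with missing trait or covariates are
    dropped.  Singleton families are retained — they inform the mean model
    and the total variance even though they carry no kinship signal.
    """
    y_all = _align_trait(trait, pedigree)
    X_all, names = _as_matrix(covariates, len(y_all))
    keep = np.isfinite(y_all) & np.all(np.isfinite(X_all), axis=1)
    groups = _size_groups(pedigree, keep)
    if not any(n >= 2 for n in groups):
        raise UnidentifiableError(
            "heritability requires at least one family with 2+ phenotyped siblings"
        )
    N = int(sum(n * idx.shape[0] for n, idx in groups.items()))
    y, X = y_all, X_all  # indexed through groups, unkept rows never touched

    grid = np.linspace(0.0, 1.0, 41)
    vals = [_profile_nll(h, y, X, groups, N)[0] for h in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda h: _profile_nll(h, y, X, groups, N)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2_hat = float(np.clip(res.x, 0.0, 1.0))
    nll_hat, beta, sig = _profile_nll(h2_hat, y, X, groups, N)

    # Observed information in (h2, total variance), central differences with
    # the evaluation stencil kept inside the parameter space.
    step_h, step_s = 1e-4, sig * 1e-4
    hc = float(np.clip(h2_hat, step_h, 1.0 - step_h))
    H = np.zeros((2, 2))
    f = lambda h, s: _nll_full(h, s, y, X, groups, N)
    f0 = f(hc, sig)
    H[0, 0] = (f(hc + step_h, sig) - 2 * f0 + f(hc - step_h, sig)) / step_h**2
    H[1, 1] = (f(hc, sig + step_s) - 2 * f0 + f(hc, sig - step_s)) / step_s**2
    H[0, 1] = H[1, 0] = (
        f(hc + step_h, sig + step_s)
        - f(hc + step_h, sig - step_s)
        - f(hc - step_h, sig + step_s)
        + f(hc - step_h, sig - step_s)
    ) / (4 * step_h * step_s)
    try:
        var_h2 = float(np.linalg.inv(H)[0, 0])
    except np.linalg.LinAlgError:
        var_h2 = np.nan
    se = float(np.sqrt(var_h2)) if var_h2 > 0 else np.nan

    nll0, _, _ = _profile_nll(0.0, y, X, groups, N)
    lr = 2.0 * (nll0 - nll_hat)
    p = 1.0 if lr <= 0 else 0.5 * float(stats.chi2.sf(lr, df=1))

    ci = h2_confidence_interval(h2_hat, se, alpha) if np.isfinite(se) else (np.nan, np.nan)
    return HeritabilityEstimate(
        h2=h2_hat,
        se=se,
        p_value=p,
        ci=ci,
        total_variance=float(sig),
        loglik=float(-nll_hat),
        covariate_effects=dict(zip(names, beta.tolist())),
        n_individuals=N,
        n_families=int(sum(idx.shape[0] for idx in groups.values())),
    )


def h2_confidence_interval(h2: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Asymptotic-normal interval ``h2 -/+ Z(alpha/2) * SE`` clamped to [0, 1]."""
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return (max(h2 - z * se, 0.0), min(h2 + z * se, 1.0))


# ---------------------------------------------------------------------------
# bivariate


def decompose_rhop(h2_1: float, h2_2: float, rhog: float, rhoe: float) -> float:
    """Phenotypic correlation implied by the genetic/environmental
    decomposition."""
    return rhog * np.sqrt(h2_1 * h2_2) + rhoe * np.sqrt((1.0 - h2_1) * (1.0 - h2_2))


def _biv_sigma(theta: np.ndarray, n: int) -> np.ndarray:
    """Stacked 2n x 2n family covariance; vector order is (trait1 members,
    trait2 members)."""
    h1, h2, ls1, ls2, rg, re = theta
    s1, s2 = np.exp(ls1), np.exp(ls2)
    sa = np.array(
        [
            [h1 * s1, rg * np.sqrt(h1 * s1 * h2 * s2)],
            [rg * np.sqrt(h1 * s1 * h2 * s2), h2 * s2],
        ]
    )
    se_ = np.array(
        [
            [(1 - h1) * s1, re * np.sqrt((1 - h1) * s1 * (1 - h2) * s2)],
            [re * np.sqrt((1 - h1) * s1 * (1 - h2) * s2), (1 - h2) * s2],
        ]
    )
    K = 0.5 * np.eye(n) + 0.5 * np.ones((n, n))
    return np.kron(sa, K) + np.kron(se_, np.eye(n))


def _biv_nll(theta, Y_by_size, X2_by_size, Ntot):
    """Negative log-likelihood with both mean vectors profiled by joint GLS."""
    p2 = next(iter(X2_by_size.values())).shape[2]
    A = np.zeros((p2, p2))
    bvec = np.zeros(p2)
    q = 0.0
    logdet = 0.0
    for n, Yf in Y_by_size.items():
        sigma = _biv_sigma(theta, n)
        sign, ld = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf, None
        try:
            siginv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return np.inf, None
        X2 = X2_by_size[n]
        A += np.einsum("fai,ab,fbj->ij", X2, siginv, X2, optimize=True)
        bvec += np.einsum("fai,ab,fb->i", X2, siginv, Yf, optimize=True)
        q += float(np.einsum("fa,ab,fb->", Yf, siginv, Yf, optimize=True))
        logdet += Yf.shape[0] * ld
    try:
        beta = np.linalg.solve(A, bvec)
    except np.linalg.LinAlgError:
        return np.inf, None
    Q = q - beta @ bvec
    nll = 0.5 * (logdet + Q + Ntot * np.log(2 * np.pi))
    return nll, beta


def _biv_minimize(nll_fn, theta0, bounds, fixed: dict[int, float] | None = None):
    """L-BFGS-B over the free coordinates of theta."""
    fixed = fixed or {}
    free = [i for i in range(len(theta0)) if i not in fixed]

    def expand(x):
        theta = np.empty(len(theta0))
        for k, i in enumerate(free):
            theta[i] = x[k]
        for i, v in fixed.items():
            theta[i] = v
        return theta

    res = optimize.minimize(
        lambda x: nll_fn(expand(x)),
        x0=np.array([theta0[i] for i in free]),
        bounds=[bounds[i] for i in free],
        method="L-BFGS-B",
    )
    return expand(res.x), float(res.fun)


def bivariate_fit(
    trait1,
    trait2,
    pedigree: Pedigree,
    covariates=None,
    n_starts: int = 3,
    seed: int = 0,
) -> BivariateEstimate:
    """Joint maximum-likelihood fit of two traits' variance components and
    their genetic (rhog) and environmental (rhoe) correlations.

    Individuals missing either trait or any covariate are dropped.  Uses
    multiple optimizer starts to guard against local optima; the rhog = 0
    null for the pleiotropy test is refit with rhog fixed.
    """
    y1 = _align_trait(trait1, pedigree)
    y2 = _align_trait(trait2, pedigree)
    X_all, _ = _as_matrix(covariates, len(y1))
    keep = (
        np.isfinite(y1) & np.isfinite(y2) & np.all(np.isfinite(X_all), axis=1)
    )
    groups = _size_groups(pedigree, keep)
    if not any(n >= 2 for n in groups):
        raise UnidentifiableError("bivariate fit requires multi-sibling families")

    p = X_all.shape[1]
    Y_by_size: dict[int, np.ndarray] = {}
    X2_by_size: dict[int, np.ndarray] = {}
    for n, idx in groups.items():
        Yf = np.concatenate([y1[idx], y2[idx]], axis=1)  # (F, 2n)
        Xf = X_all[idx]  # (F, n, p)
        F = idx.shape[0]
        X2 = np.zeros((F, 2 * n, 2 * p))
        X2[:, :n, :p] = Xf
        X2[:, n:, p:] = Xf
        Y_by_size[n] = Yf
        X2_by_size[n] = X2
    Ntot = int(sum(Y.shape[0] * Y.shape[1] for Y in Y_by_size.values()))

    # Univariate fits seed the per-trait parameters.
    uni1 = univariate_h2(y1, pedigree, covariates=covariates)
    uni2 = univariate_h2(y2, pedigree, covariates=covariates)
    if uni1.h2 < 1e-4 or uni2.h2 < 1e-4:
        raise UnidentifiableError(
            "genetic correlation unidentifiable with a trait at the h2 = 0 boundary"
        )
    r_ph = float(np.corrcoef(y1[keep], y2[keep])[0, 1])
    r_ph = float(np.clip(r_ph, -0.9, 0.9))

    bounds = [
        (_H2_EPS, 1.0 - _H2_EPS),
        (_H2_EPS, 1.0 - _H2_EPS),
        (None, None),
        (None, None),
        (-_RHO_BOUND, _RHO_BOUND),
        (-_RHO_BOUND, _RHO_BOUND),
    ]
    base = [
        float(np.clip(uni1.h2, 0.02, 0.98)),
        float(np.clip(uni2.h2, 0.02, 0.98)),
        float(np.log(uni1.total_variance)),
        float(np.log(uni2.total_variance)),
    ]
    rho_starts = [(r_ph, r_ph), (0.9, 0.0), (-0.9, 0.0)][: max(n_starts, 1)]

    def nll_fn(theta):
        return _biv_nll(theta, Y_by_size, X2_by_size, Ntot)[0]

    best_theta, best_nll = None, np.inf
    for rg0, re0 in rho_starts:
        theta0 = np.array(base + [rg0, re0])
        theta, val = _biv_minimize(nll_fn, theta0, bounds)
        if val < best_nll:
            best_theta, best_nll = theta, val
    h1, h2_, _, _, rg, re = best_theta
    boundary = abs(rg) >= _RHO_BOUND - 1e-4

    # rhog SE from the observed information over all six parameters.
    rhog_se = np.nan
    if not boundary:
        k = len(best_theta)
        steps = np.full(k, 1e-4)
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = steps[i]
                ej = np.zeros(k); ej[j] = steps[j]
                fpp = nll_fn(best_theta + ei + ej)
                fpm = nll_fn(best_theta + ei - ej)
                fmp = nll_fn(best_theta - ei + ej)
                fmm = nll_fn(best_theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
        try:
            var_rg = float(np.linalg.inv(H)[4, 4])
            rhog_se = float(np.sqrt(var_rg)) if var_rg > 0 else np.nan
        except np.linalg.LinAlgError:
            pass

    theta_null0 = best_theta.copy()
    theta_null, nll_null = _biv_minimize(nll_fn, theta_null0, bounds, fixed={4: 0.0})
    lr = 2.0 * (nll_null - best_nll)
    p_rg = float(stats.chi2.sf(max(lr, 0.0), df=1))

    return BivariateEstimate(
        h2_1=float(h1),
        h2_2=float(h2_),
        rhog=float(rg),
        rhog_se=rhog_se,
        rhoe=float(re),
        rhop=float(decompose_rhop(h1, h2_, rg, re)),
        p_rhog_zero=p_rg,
        loglik=float(-best_nll),
        n_individuals=Ntot // 2,
        boundary=boundary,
    )
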