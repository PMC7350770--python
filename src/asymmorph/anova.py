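"""Phylogenetic ANOVA: GLS with a Pagel's-lambda correlation structure and
Benjamini-Hochberg control across scenario tests.

The working covariance is V(lambda) = lambda * C + (1 - lambda) * diag(C),
i.e. the off-diagonal of the phylogenetic covariance scaled by lambda in
[0, 1]. lambda is profiled by a grid search followed by golden-section
refinement; factor coefficients and the residual scale are then GLS
closed-form at the chosen lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trees import Phylogeny, covariance, safe_cholesky


class AnovaError(ValueError):
    pass


@dataclass
class GlsFit:
    coefficients: dict[str, float]
    lam: float
    loglik: float
    sigma2: float
    rss_whitened: float
    n: int
    p: int  # design columns
    levels: list[str]
    at_boundary: bool
    design: np.ndarray
    response: np.ndarray
    cov_base: np.ndarray  # unit-lambda phylogenetic covariance C


def _design(factor: dict[str, str], tips: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Reference-level (treatment) coding; first sorted level is the baseline."""
    missing = [t for t in tips if t not in factor]
    if missing:
        raise AnovaError(f"factor missing for tips: {missing}")
    levels = sorted({factor[t] for t in tips})
    X = np.ones((len(tips), len(levels)))
    names = ["(intercept)"]
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = [1.0 if factor[t] == lev else 0.0 for t in tips]
        names.append(f"[{lev}]")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        counts = {lev: sum(1 for t in tips if factor[t] == lev) for lev in levels}
        empty = [lev for lev, c in counts.items() if c == 0]
        raise AnovaError(f"rank-deficient design; aliased levels: {empty or levels}")
    return X, names, levels


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    V[np.diag_indices_from(V)] = np.diag(C)
    return V


def _profile_loglik(y: np.ndarray, X: np.ndarray, C: np.ndarray, lam: float):
    n = len(y)
    V = _lambda_cov(C.copy(), lam)
    L, _ = safe_cholesky(V)
    Ly = np.linalg.solve(L, y)
    LX = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(LX, Ly, rcond=None)
    resid = Ly - LX @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return float(ll), beta, sigma2, rss


def _golden_section(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Maximise f on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


def fit_gls_lambda(
    trait: dict[str, float],
    factor: dict[str, str] | None,
    tree: Phylogeny,
    lam: float | None = None,
    grid_points: int = 21,
    tol: float = 1e-6,
) -> GlsFit:
    """GLS fit of trait ~ factor with Pagel's-lambda correlation.

    ``factor=None`` fits the intercept-only (null) model. ``lam`` fixes
    lambda instead of estimating it.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in trait]
    if missing:
        raise AnovaError(f"trait missing for tips: {missing}")
    y = np.array([float(trait[t]) for t in tips])
    if factor is None:
        X, names, levels = np.ones((len(tips), 1)), ["(intercept)"], []
    else:
        X, names, levels = _design(factor, tips)
        if len(levels) >= 2:
            counts = {lev: sum(1 for t in tips if factor[t] == lev) for lev in levels}
            empty = [lev for lev, c in counts.items() if c == 0]
            if empty:
                raise AnovaError(f"factor levels without tips: {empty}")
    C = covariance(tree).matrix

    if lam is None:
        grid = np.linspace(0.0, 1.0, grid_points)
        lls = [_profile_loglik(y, X, C, g)[0] for g in grid]
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid_points - 1)]
        lam_hat = _golden_section(lambda g: _profile_loglik(y, X, C, g)[0], lo, hi, tol=tol)
        # keep the grid point if refinement did not improve (flat likelihood)
        if _profile_loglik(y, X, C, grid[i])[0] > _profile_loglik(y, X, C, lam_hat)[0]:
            lam_hat = float(grid[i])
    else:
        if not 0.0 <= lam <= 1.0:
            raise AnovaError("lambda must be in [0, 1]")
        lam_hat = float(lam)

    ll, beta, sigma2, rss = _profile_loglik(y, X, C, lam_hat)
    return GlsFit(
        coefficients=dict(zip(names, beta.tolist())),
        lam=float(lam_hat),
        loglik=ll,
        sigma2=sigma2,
        rss_whitened=rss,
        n=len(y),
        p=X.shape[1],
        levels=list(levels),
        at_boundary=lam is None and (lam_hat <= tol or lam_hat >= 1 - tol),
        design=X,
        response=y,
        cov_base=C,
    )


@dataclass
class AnovaResult:
    scenario: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    lam: float


def anova_f(fit: GlsFit, null: GlsFit, scenario: str = "") -> AnovaResult:
    """F test of the factor from whitened residual sums of squares.

    Both models are evaluated at the alternative model's fitted lambda
    (the null is re-whitened, not re-fitted).
    """
    if fit.n != null.n:
        raise AnovaError("fits are on different tip sets")
    if null.p >= fit.p:
        if null.p == fit.p:
            # factor adds nothing (single level): F = 0, p = 1 by convention
            return AnovaResult(scenario, 0.0, 0, fit.n - fit.p, 1.0, fit.lam)
        raise AnovaError("null model must be nested in the alternative")
    # null design columns must be a subspace of the alternative's
    coef, *_ = np.linalg.lstsq(fit.design, null.design, rcond=None)
    proj = fit.design @ coef
    if not np.allclose(proj, null.design, atol=1e-8):
        raise AnovaError("designs are not nested")

    _, _, _, rss_null = _profile_loglik(null.response, null.design, null.cov_base, fit.lam)
    _, _, _, rss_full = _profile_loglik(fit.response, fit.design, fit.cov_base, fit.lam)
    df_num = fit.p - null.p
    df_den = fit.n - fit.p
    if df_den <= 0:
        raise AnovaError("no residual degrees of freedom")
    F = max((rss_null - rss_full) / df_num, 0.0) / (rss_full / df_den)
    p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(scenario, float(F), df_num, df_den, p, fit.lam)


def phylo_anova(
    trait: dict[str, float], factor: dict[str, str], tree: Phylogeny, scenario: str = ""
) -> AnovaResult:
    """Convenience wrapper: fit full and null GLS-lambda models and F-test."""
    fit = fit_gls_lambda(trait, factor, tree)
    null = fit_gls_lambda(trait, None, tree, lam=fit.lam)
    return anova_f(fit, null, scenario=scenario)


def bh_adjust(pvalues: list[float], labels: list[str] | None = None) -> pd.DataFrame:
    """Benjamini-Hochberg step-up adjustment.

    adjusted p_(i) = min over j >= i of p_(j) * m / j, capped at 1; ties keep
    their input order (stable sort).
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise AnovaError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return pd.DataFrame(
        {
            "scenario": labels if labels is not None else [str(i) for i in range(m)],
            "p": p,
            "p_bh": adjusted,
        }
    )
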