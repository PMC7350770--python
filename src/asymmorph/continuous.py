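"""ML fitting and AIC ranking of BM/OU continuous-trait models on (painted) trees.

Model classes
-------------
BM     single-rate Brownian motion
BMtr   BM with a directional trend (mean drifts with tip depth)
BMsm   BM with separate phylogenetic means per terminal regime state
BMM    multi-rate BM: one rate per painted regime
BMMtr  BMM plus a shared trend
BMMsm  BMM plus separate means per terminal regime state
OU     single-optimum Ornstein-Uhlenbeck, free root state
OUM    multi-optimum OU over a regime painting, shared attraction alpha

All likelihoods are multivariate normal; mean-structure coefficients and the
overall scale sigma^2 are profiled analytically (GLS), alpha / trend /
relative rates are found by bounded multi-start quasi-Newton search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .trees import Phylogeny, RegimePainting, covariance, safe_cholesky


class ModelError(ValueError):
    pass


MODEL_CLASSES = ("BM", "BMtr", "BMsm", "BMM", "BMMtr", "BMMsm", "OU", "OUM")
MULTI_REGIME = ("BMsm", "BMM", "BMMtr", "BMMsm", "OUM")


@dataclass(frozen=True)
class ContinuousModelSpec:
    model_class: str
    scenario: str = ""

    def __post_init__(self) -> None:
        if self.model_class not in MODEL_CLASSES:
            raise ModelError(f"unknown model class {self.model_class!r}")

    @property
    def name(self) -> str:
        return f"{self.model_class}-{self.scenario}" if self.scenario else self.model_class

    @property
    def needs_painting(self) -> bool:
        return self.model_class in MULTI_REGIME


@dataclass
class ContinuousFit:
    spec: ContinuousModelSpec
    params: dict
    loglik: float
    k: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


def _trait_vector(tree: Phylogeny, trait) -> np.ndarray:
    if isinstance(trait, dict):
        missing = [t for t in tree.tip_labels if t not in trait]
        if missing:
            raise ModelError(f"trait missing for tips: {missing}")
        y = np.array([float(trait[t]) for t in tree.tip_labels])
    else:
        y = np.asarray(trait, dtype=float)
        if y.shape != (len(tree.tips),):
            raise ModelError("trait vector length must equal tip count")
    if not np.isfinite(y).all():
        raise ModelError("trait contains non-finite values")
    return y


# ---------------------------------------------------------------------------
# covariance / mean building blocks


def _mrca_depths(tree: Phylogeny) -> np.ndarray:
    d = tree.tip_depths()
    dist = tree.patristic_distances()
    return (d[:, None] + d[None, :] - dist) / 2.0


def _ou_cov_unit(tree: Phylogeny, alpha: float) -> np.ndarray:
    """OU covariance for sigma^2 = 1, deterministic root (non-stationary start)."""
    d = tree.tip_depths()
    ta = _mrca_depths(tree)
    if alpha <= 0:
        return ta.copy()
    # -expm1 avoids catastrophic cancellation in the BM limit alpha -> 0
    return (
        np.exp(-alpha * (d[:, None] + d[None, :] - 2 * ta))
        * -np.expm1(-2.0 * alpha * ta)
        / (2.0 * alpha)
    )


def _root_paths(tree: Phylogeny, painting: RegimePainting):
    """Per tip: ordered (start_depth, end_depth, state) segments, root to tip."""
    depths = tree.depths()
    paths = {}
    for tip in tree.tips:
        segs = []
        node = tip
        chain = []
        while node.parent is not None:
            chain.append(node)
            node = node.parent
        for node in reversed(chain):
            start = depths[node.parent.id]
            t = start
            for seg_len, st in painting.segments[node.id]:
                segs.append((t, t + seg_len, st))
                t += seg_len
        paths[tip.label] = segs
    return paths


def _oum_design(tree: Phylogeny, painting: RegimePainting, alpha: float) -> tuple[np.ndarray, list[str]]:
    """Columns: root weight e^{-alpha d_i}, then one attraction weight per state.

    Lineage-wise integration of regime occupancy with exponential attraction
    weighting; columns sum to 1 for every tip.
    """
    states = list(painting.states)
    d = tree.tip_depths()
    paths = _root_paths(tree, painting)
    n = len(tree.tips)
    X = np.zeros((n, 1 + len(states)))
    X[:, 0] = np.exp(-alpha * d)
    for i, label in enumerate(tree.tip_labels):
        for start, end, st in paths[label]:
            j = 1 + states.index(st)
            X[i, j] += np.exp(-alpha * (d[i] - end)) - np.exp(-alpha * (d[i] - start))
    return X, states


def _gls_profile(y: np.ndarray, X: np.ndarray, V0: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Profile GLS: returns (beta_hat, sigma2_hat, loglik) for V = sigma2 * V0."""
    n = len(y)
    L, _ = safe_cholesky(V0)
    Ly = np.linalg.solve(L, y)
    LX = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(LX, Ly, rcond=None)
    resid = Ly - LX @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) - 0.5 * logdet
    return beta, sigma2, float(ll)


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    L, _ = safe_cholesky(V)
    r = np.linalg.solve(L, y - mean)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    n = len(y)
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + r @ r))


# ---------------------------------------------------------------------------
# explicit-parameter likelihood


def model_loglik(
    spec: ContinuousModelSpec,
    params: dict,
    tree: Phylogeny,
    trait,
    painting: RegimePainting | None = None,
) -> float:
    """Log-likelihood at explicitly supplied parameters.

    Recognised parameter keys: ``sigma2`` (BM/OU rate), ``root``, ``mu``
    (trend per My), ``alpha``, ``theta`` (OU optimum), ``optima`` (state ->
    optimum for OUM), ``rates`` (state -> sigma2 for BMM-type),
    ``measurement_error`` (variance added to the diagonal).
    """
    if spec.needs_painting and painting is None:
        raise ModelError(f"{spec.model_class} requires a painting")
    y = _trait_vector(tree, trait)
    d = tree.tip_depths()
    n = len(y)
    me = float(params.get("measurement_error", 0.0))
    cls = spec.model_class

    if cls in ("BM", "BMtr", "BMsm"):
        V = float(params["sigma2"]) * covariance(tree).matrix
    elif cls in ("BMM", "BMMtr", "BMMsm"):
        comps = covariance(tree, painting).components
        V = np.zeros((n, n))
        for st, C in comps.items():
            V += float(params["rates"][st]) * C
    elif cls == "OU":
        V = float(params["sigma2"]) * _ou_cov_unit(tree, float(params["alpha"]))
    elif cls == "OUM":
        V = float(params["sigma2"]) * _ou_cov_unit(tree, float(params["alpha"]))
    V = V + me * np.eye(n)

    if cls in ("BM", "BMM"):
        mean = np.full(n, float(params["root"]))
    elif cls in ("BMtr", "BMMtr"):
        mean = float(params["root"]) + float(params["mu"]) * d
    elif cls in ("BMsm", "BMMsm"):
        means = params["means"]
        mean = np.array([float(means[painting.tip_states[t]]) for t in tree.tip_labels])
    elif cls == "OU":
        a = float(params["alpha"])
        w = np.exp(-a * d)
        mean = float(params["root"]) * w + float(params["theta"]) * (1.0 - w)
    elif cls == "OUM":
        a = float(params["alpha"])
        X, states = _oum_design(tree, painting, a)
        beta = np.array([float(params["root"])] + [float(params["optima"][s]) for s in states])
        mean = X @ beta

    return _mvn_loglik(y, mean, V)


# ---------------------------------------------------------------------------
# fitting


def _design_for(
    cls: str,
    tree: Phylogeny,
    painting: RegimePainting | None,
    alpha: float | None,
    notes: list[str],
) -> tuple[np.ndarray, list[str]]:
    """(design matrix, coefficient names) for the mean structure of a class."""
    n = len(tree.tips)
    d = tree.tip_depths()
    if cls in ("BM", "BMM"):
        return np.ones((n, 1)), ["root"]
    if cls in ("BMtr", "BMMtr"):
        if np.ptp(d) <= 1e-10 * max(d.max(), 1e-300):
            if "trend-unidentifiable" not in notes:
                notes.append("trend-unidentifiable")
                warnings.warn(
                    "ultrametric tree: trend mu unidentifiable, fixed to 0", stacklevel=3
                )
            return np.ones((n, 1)), ["root"]
        return np.column_stack([np.ones(n), d]), ["root", "mu"]
    if cls in ("BMsm", "BMMsm"):
        states = list(painting.states)
        X = np.zeros((n, len(states)))
        for i, t in enumerate(tree.tip_labels):
            X[i, states.index(painting.tip_states[t])] = 1.0
        return X, [f"mean[{s}]" for s in states]
    if cls == "OU":
        w = np.exp(-alpha * d)
        return np.column_stack([w, 1.0 - w]), ["root", "theta"]
    if cls == "OUM":
        X, states = _oum_design(tree, painting, alpha)
        return X, ["root"] + [f"optimum[{s}]" for s in states]
    raise ModelError(cls)


def _param_count(cls: str, n_states: int, trend_free: bool) -> int:
    # sigma2 + mean parameters (+ alpha, trend, extra regime rates)
    if cls == "BM":
        return 2
    if cls == "BMtr":
        return 2 + (1 if trend_free else 0)
    if cls == "BMsm":
        return 1 + n_states
    if cls == "BMM":
        return n_states + 1
    if cls == "BMMtr":
        return n_states + 1 + (1 if trend_free else 0)
    if cls == "BMMsm":
        return 2 * n_states
    if cls == "OU":
        return 4
    if cls == "OUM":
        return 3 + n_states
    raise ModelError(cls)


def fit_model(
    spec: ContinuousModelSpec,
    tree: Phylogeny,
    trait,
    painting: RegimePainting | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> ContinuousFit:
    """Maximum-likelihood fit of one model class.

    sigma^2 and all mean coefficients are profiled analytically; alpha (OU
    classes) and relative regime rates (BMM classes) are optimised numerically
    with multiple starts.
    """
    if spec.needs_painting and painting is None:
        raise ModelError(f"{spec.model_class} requires a painting")
    y = _trait_vector(tree, trait)
    cls = spec.model_class
    notes: list[str] = []
    depth = float(tree.tip_depths().max())
    states = list(painting.states) if painting is not None else []

    C_total = covariance(tree).matrix
    comps = covariance(tree, painting).components if painting is not None else None

    def bm_family_cov(rel_log: np.ndarray) -> np.ndarray:
        # first state has relative rate 1; the profiled sigma2 is its rate
        V0 = comps[states[0]].copy()
        for j, st in enumerate(states[1:]):
            V0 += np.exp(rel_log[j]) * comps[st]
        return V0

    if cls in ("BM", "BMtr", "BMsm"):
        X, names = _design_for(cls, tree, painting, None, notes)
        beta, sigma2, ll = _gls_profile(y, X, C_total)
        params = dict(zip(names, beta.tolist()))
        params["sigma2"] = sigma2
        if cls == "BMtr" and "mu" not in params:
            params["mu"] = 0.0
        if cls in ("BMsm",):
            params["means"] = {s: params.pop(f"mean[{s}]") for s in states}
        k = _param_count(cls, len(states), trend_free="trend-unidentifiable" not in notes)
        return ContinuousFit(spec, params, ll, k, notes=notes)

    rng = np.random.default_rng(seed)

    if cls in ("BMM", "BMMtr", "BMMsm"):
        m = len(states)
        X, names = _design_for(cls, tree, painting, None, notes)

        def neg(rel_log: np.ndarray) -> float:
            V0 = bm_family_cov(rel_log)
            try:
                _, _, ll = _gls_profile(y, X, V0)
            except Exception:
                return 1e10
            return -ll

        bounds = [(-20.0, 20.0)] * (m - 1)
        starts = [np.zeros(m - 1)]
        starts += [rng.normal(0, 2, size=m - 1) for _ in range(n_starts - 1)]
        best = None
        for x0 in starts:
            res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-12})
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise ModelError(f"{spec.name}: optimisation failed")
        V0 = bm_family_cov(best.x)
        beta, sigma2, ll = _gls_profile(y, X, V0)
        rel = np.concatenate([[1.0], np.exp(best.x)])
        params = dict(zip(names, beta.tolist()))
        params["rates"] = {st: sigma2 * rel[j] for j, st in enumerate(states)}
        if cls == "BMMtr" and "mu" not in params:
            params["mu"] = 0.0
        if cls == "BMMsm":
            params["means"] = {s: params.pop(f"mean[{s}]") for s in states}
        k = _param_count(cls, m, trend_free="trend-unidentifiable" not in notes)
        return ContinuousFit(spec, params, ll, k, notes=notes)

    # OU / OUM: profile everything but alpha
    def neg_alpha(log_alpha: np.ndarray) -> float:
        a = float(np.exp(log_alpha[0]))
        V0 = _ou_cov_unit(tree, a)
        X, _ = _design_for(cls, tree, painting, a, notes)
        try:
            _, _, ll = _gls_profile(y, X, V0)
        except Exception:
            return 1e10
        return -ll

    lo, hi = np.log(1e-9), np.log(1e4 / max(depth, 1e-6))
    starts = [np.array([np.log(s / depth)]) for s in (0.01, 0.1, 1.0, 3.0, 10.0)][:n_starts]
    best = None
    for x0 in starts:
        res = minimize(
            neg_alpha, x0, method="L-BFGS-B", bounds=[(lo, hi)], options={"ftol": 1e-12}
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise ModelError(f"{spec.name}: optimisation failed")
    alpha = float(np.exp(best.x[0]))
    V0 = _ou_cov_unit(tree, alpha)
    X, names = _design_for(cls, tree, painting, alpha, notes)
    beta, sigma2, ll = _gls_profile(y, X, V0)
    params = dict(zip(names, beta.tolist()))
    params["sigma2"] = sigma2
    params["alpha"] = alpha
    if cls == "OUM":
        params["optima"] = {s: params.pop(f"optimum[{s}]") for s in states}
    k = _param_count(cls, len(states), trend_free=True)
    return ContinuousFit(spec, params, ll, k, notes=notes)


def rank_models(fits: list[ContinuousFit]) -> pd.DataFrame:
    """Ascending-AIC ranking table with a delta-AIC column."""
    if not fits:
        raise ModelError("rank_models needs at least one fit")
    rows = [
        {
            "model": f.spec.name,
            "class": f.spec.model_class,
            "scenario": f.spec.scenario,
            "loglik": f.loglik,
            "k": f.k,
            "AIC": f.aic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values(["AIC", "model"], kind="stable").reset_index(drop=True)
    df["dAIC"] = df["AIC"] - df["AIC"].iloc[0]
    df.index = np.arange(1, len(df) + 1)
    df.index.name = "rank"
    return df
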