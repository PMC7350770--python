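"""Mk discrete-character likelihoods and ML fitting (ER / SYM / ARD)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .trees import Phylogeny


class MkError(ValueError):
    pass


STRUCTURES = ("ER", "SYM", "ARD")


def n_free_rates(structure: str, n_states: int) -> int:
    if structure == "ER":
        return 1
    if structure == "SYM":
        return n_states * (n_states - 1) // 2
    if structure == "ARD":
        return n_states * (n_states - 1)
    raise MkError(f"unknown structure {structure!r}")


@dataclass
class MkModel:
    """Continuous-time Markov model on a discrete state set.

    ``rates`` fills the off-diagonal of Q: ER one value; SYM the upper
    triangle row-wise (mirrored); ARD row-wise all off-diagonals.
    """

    states: tuple[str, ...]
    structure: str
    rates: np.ndarray
    root_prior: str = "uniform"  # or "stationary"

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        k = n_free_rates(self.structure, len(self.states))
        if self.rates.shape != (k,):
            raise MkError(
                f"{self.structure} with {len(self.states)} states needs {k} rates, "
                f"got {self.rates.shape}"
            )
        if (self.rates < 0).any():
            raise MkError("rates must be >= 0")

    @property
    def Q(self) -> np.ndarray:
        s = len(self.states)
        Q = np.zeros((s, s))
        if self.structure == "ER":
            Q[:] = self.rates[0]
        elif self.structure == "SYM":
            iu = np.triu_indices(s, k=1)
            Q[iu] = self.rates
            Q[(iu[1], iu[0])] = self.rates
        else:  # ARD
            pos = 0
            for i in range(s):
                for j in range(s):
                    if i != j:
                        Q[i, j] = self.rates[pos]
                        pos += 1
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def root_distribution(self) -> np.ndarray:
        s = len(self.states)
        if self.root_prior == "uniform":
            return np.full(s, 1.0 / s)
        if self.root_prior == "stationary":
            Q = self.Q
            # left null vector of Q
            w, v = np.linalg.eig(Q.T)
            i = int(np.argmin(np.abs(w)))
            pi = np.real(v[:, i])
            pi = np.abs(pi)
            return pi / pi.sum()
        raise MkError(f"unknown root prior {self.root_prior!r}")


def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for each branch length, via eigendecomposition with expm fallback."""
    try:
        w, v = np.linalg.eig(Q)
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) > 1e10:
            raise np.linalg.LinAlgError
        P = np.real(
            np.einsum("ij,tj,jk->tik", v, np.exp(np.outer(lengths, w)), vinv)
        )
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=2, keepdims=True)
    except np.linalg.LinAlgError:
        return np.array([expm(Q * t) for t in lengths])


def mk_loglik(tree: Phylogeny, tip_states: dict[str, str], model: MkModel) -> float:
    """Felsenstein pruning log-likelihood of tip states under the Mk model."""
    states = model.states
    s = len(states)
    index = {st: i for i, st in enumerate(states)}
    for label in tree.tip_labels:
        if label not in tip_states:
            raise MkError(f"tip {label!r} has no state")
        if tip_states[label] not in index:
            raise MkError(
                f"tip {label!r}: state {tip_states[label]!r} not in vocabulary {states}"
            )

    branches = tree.branches
    lengths = np.array([b.length for b in branches])
    P = _transition_matrices(model.Q, lengths)
    P_of = {b.id: P[i] for i, b in enumerate(branches)}

    partial: dict[int, np.ndarray] = {}
    scale_log = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(s)
            vec[index[tip_states[node.label]]] = 1.0
        else:
            vec = np.ones(s)
            for c in node.children:
                vec = vec * (P_of[c.id] @ partial[c.id])
        m = vec.max()
        if m <= 0:
            return -np.inf
        partial[node.id] = vec / m
        scale_log += np.log(m)
    root_vec = partial[tree.root.id]
    return float(np.log(root_vec @ model.root_distribution()) + scale_log)


@dataclass
class MkFit:
    model: MkModel
    loglik: float
    k: int

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


def fit_mk(
    tree: Phylogeny,
    tip_states: dict[str, str],
    structure: str = "ER",
    states: tuple[str, ...] | None = None,
    root_prior: str = "uniform",
    n_starts: int = 5,
    seed: int = 0,
    rate_bounds: tuple[float, float] = (1e-8, 1e3),
) -> MkFit:
    """ML fit of the Mk model by multi-start bounded optimisation on log rates."""
    if structure not in STRUCTURES:
        raise MkError(f"unknown structure {structure!r}")
    if states is None:
        states = tuple(sorted(set(tip_states.values())))
    k = n_free_rates(structure, len(states))

    def neg_loglik(log_rates: np.ndarray) -> float:
        model = MkModel(states, structure, np.exp(log_rates), root_prior=root_prior)
        ll = mk_loglik(tree, tip_states, model)
        return -ll if np.isfinite(ll) else 1e10

    lo, hi = np.log(rate_bounds[0]), np.log(rate_bounds[1])
    # coarse scan over a shared log rate locates the basin; the likelihood is
    # flat at very high rates, where quasi-Newton steps stall on a plateau
    grid = np.linspace(max(lo, np.log(1e-6)), min(hi, np.log(1e2)), 21)
    grid_vals = [neg_loglik(np.full(k, g)) for g in grid]
    base = grid[int(np.argmin(grid_vals))]

    rng = np.random.default_rng(seed)
    starts = [np.full(k, base)]
    starts += [np.clip(base + rng.normal(0, 1.0, size=k), lo, hi) for _ in range(n_starts - 1)]

    best_x, best_fun = np.full(k, base), float(np.min(grid_vals))
    for x0 in starts:
        res = minimize(
            neg_loglik, x0, method="L-BFGS-B", bounds=[(lo, hi)] * k,
            options={"ftol": 1e-9, "gtol": 1e-9},
        )
        if res.fun < best_fun:
            best_x, best_fun = np.clip(res.x, lo, hi), float(res.fun)
    # quasi-Newton can stall on the flat high-rate plateau: polish the winner
    res = minimize(
        neg_loglik, best_x, method="Nelder-Mead", bounds=[(lo, hi)] * k,
        options={"xatol": 1e-7, "fatol": 1e-10},
    )
    if res.fun < best_fun:
        best_x, best_fun = np.clip(res.x, lo, hi), float(res.fun)
    if not np.isfinite(best_fun):
        raise MkError("Mk optimisation failed to find a finite likelihood")
    model = MkModel(states, structure, np.exp(best_x), root_prior=root_prior)
    return MkFit(model=model, loglik=-best_fun, k=k)
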