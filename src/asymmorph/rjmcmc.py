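"""Reversible-jump MCMC over relaxed Brownian motion with rate shifts, and the
combined model with trait jumps; posterior summaries and chain diagnostics.

Model
-----
Each branch carries a Brownian rate: the base rate rescaled by the scalar of
the nearest ancestral shift (nested-clade override). A shift placed on a
branch therefore governs that branch and all descendants until a deeper shift
overrides it. In the ``jump-rbm`` class, jumps add independent normal trait
displacements (shared variance) inherited by all descendants of their branch.
The trait likelihood is multivariate normal with

    V_ij = sum_b rate_b * length_b  [b on the shared root path of i, j]
         + jump_var * (shared jump count)
         + measurement_error * delta_ij .

Priors follow the configured :class:`PriorConfig`: Poisson(log 2) on the
number of shifts, Half-Cauchy(25) on the base rate, the shift rate scalars and
the measurement-error variance, Poisson on the number of jumps, and
Half-Cauchy on the jump variance. Shift locations are uniform over branch
subsets; jumps are assigned to branches uniformly and independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trees import Phylogeny


class McmcError(ValueError):
    pass


LOG2 = math.log(2.0)


@dataclass(frozen=True)
class PriorConfig:
    shift_count_mean: float = LOG2
    rate_scale: float = 25.0
    error_scale: float = 25.0
    jump_count_mean: float = LOG2
    jump_var_scale: float = 25.0

    def __post_init__(self) -> None:
        for name in ("shift_count_mean", "rate_scale", "error_scale", "jump_count_mean", "jump_var_scale"):
            if getattr(self, name) <= 0:
                raise McmcError(f"prior parameter {name} must be > 0")


def half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((x / scale) ** 2)


def half_cauchy_sample(rng: np.random.Generator, scale: float) -> float:
    return abs(scale * math.tan(math.pi * (rng.random() - 0.5)))


def poisson_logpmf(k: int, mean: float) -> float:
    return k * math.log(mean) - mean - math.lgamma(k + 1)


@dataclass
class ChainState:
    shifts: dict[int, float]  # branch id -> rate scalar
    base_rate: float
    root: float
    error_var: float
    jumps: dict[int, int]  # branch id -> jump count (jump-rbm only)
    jump_var: float
    loglik: float = 0.0
    logprior: float = 0.0
    generation: int = 0

    @property
    def log_posterior(self) -> float:
        return self.loglik + self.logprior

    def copy(self) -> "ChainState":
        return replace(self, shifts=dict(self.shifts), jumps=dict(self.jumps))


@dataclass
class PosteriorTrace:
    samples: list[ChainState]
    model: str  # "rbm" | "jump-rbm"
    seed: int
    n_generations: int
    thin: int
    branch_ids: list[int]
    acceptance: dict[str, float]
    tree: Phylogeny | None = None


MOVE_WEIGHTS = {
    "rate": 0.4,
    "shift_birth_death": 0.2,
    "shift_relocate": 0.1,
    "root_error": 0.1,
    "jump": 0.2,
}

JUMP_CAP = 5


class _Sampler:
    def __init__(
        self,
        tree: Phylogeny,
        trait: np.ndarray,
        prior: PriorConfig,
        model: str,
        rng: np.random.Generator,
        prior_only: bool = False,
    ):
        self.tree = tree
        self.y = trait
        self.prior = prior
        self.model = model
        self.rng = rng
        self.prior_only = prior_only

        self.branches = tree.branches
        self.branch_ids = [b.id for b in self.branches]
        self.n_branches = len(self.branches)
        self.lengths = np.array([b.length for b in self.branches])
        mask = tree.tip_mask_below()
        self.masks = mask[[b.id for b in self.branches]].astype(float)  # (B, n_tips)
        self.pos = {b.id: i for i, b in enumerate(self.branches)}
        self.n = len(tree.tips)

        names = ["rate", "shift_birth_death", "shift_relocate", "root_error"]
        if model == "jump-rbm":
            names.append("jump")
        w = np.array([MOVE_WEIGHTS[m] for m in names])
        self.move_names = names
        self.move_probs = w / w.sum()

        self.accepted: dict[str, int] = {m: 0 for m in names}
        self.proposed: dict[str, int] = {m: 0 for m in names}

    # -- model evaluation --------------------------------------------------

    def branch_rates(self, state: ChainState) -> np.ndarray:
        """Effective per-branch rate under nested-clade shift semantics."""
        scal = np.empty(len(self.tree.nodes))
        scal[self.tree.root.id] = 1.0
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            inherited = scal[node.parent.id]
            scal[node.id] = state.shifts.get(node.id, inherited)
        out = np.array([scal[b.id] for b in self.branches])
        return state.base_rate * out

    def loglik(self, state: ChainState) -> float:
        if self.prior_only:
            return 0.0
        w = self.branch_rates(state) * self.lengths
        if self.model == "jump-rbm" and state.jumps:
            jw = np.zeros(self.n_branches)
            for bid, cnt in state.jumps.items():
                jw[self.pos[bid]] = cnt * state.jump_var
            w = w + jw
        V = (self.masks.T * w) @ self.masks
        V[np.diag_indices_from(V)] += state.error_var
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            V[np.diag_indices_from(V)] += 1e-10 * np.mean(np.diag(V))
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -np.inf
        r = np.linalg.solve(L, self.y - state.root)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        return float(-0.5 * (self.n * math.log(2 * math.pi) + logdet + r @ r))

    def logprior(self, state: ChainState) -> float:
        p = self.prior
        k = len(state.shifts)
        lp = poisson_logpmf(k, p.shift_count_mean)
        lp -= math.lgamma(self.n_branches + 1) - math.lgamma(k + 1) - math.lgamma(
            self.n_branches - k + 1
        )  # -log C(B, k): shift locations uniform over subsets
        for s in state.shifts.values():
            lp += half_cauchy_logpdf(s, p.rate_scale)
        lp += half_cauchy_logpdf(state.base_rate, p.rate_scale)
        lp += half_cauchy_logpdf(state.error_var, p.error_scale)
        if self.model == "jump-rbm":
            N = sum(state.jumps.values())
            lp += -p.jump_count_mean + N * math.log(
                p.jump_count_mean / self.n_branches
            )
            for cnt in state.jumps.values():
                lp -= math.lgamma(cnt + 1)
            lp += half_cauchy_logpdf(state.jump_var, p.jump_var_scale)
        return lp

    def evaluate(self, state: ChainState) -> ChainState:
        state.loglik = self.loglik(state)
        state.logprior = self.logprior(state)
        return state

    # -- moves -------------------------------------------------------------

    def _accept(self, old: ChainState, new: ChainState, log_q_correction: float) -> bool:
        self.evaluate(new)
        if not np.isfinite(new.log_posterior):
            return False
        delta = new.log_posterior - old.log_posterior + log_q_correction
        return math.log(self.rng.random()) < delta

    def move_rate(self, state: ChainState) -> tuple[ChainState, float]:
        new = state.copy()
        targets = ["base"] + list(new.shifts)
        pick = targets[self.rng.integers(len(targets))]
        eps = self.rng.normal(0.0, 0.6)
        if pick == "base":
            new.base_rate = state.base_rate * math.exp(eps)
        else:
            new.shifts[pick] = state.shifts[pick] * math.exp(eps)
        return new, eps  # log Hastings for multiplicative lognormal = log(x'/x)

    def _birth_prob(self, k: int) -> float:
        if k == 0:
            return 1.0
        if k >= self.n_branches:
            return 0.0
        return 0.5

    def move_shift_birth_death(self, state: ChainState) -> tuple[ChainState, float]:
        k = len(state.shifts)
        pb = self._birth_prob(k)
        new = state.copy()
        if self.rng.random() < pb:  # birth
            free = [b for b in self.branch_ids if b not in state.shifts]
            bid = free[self.rng.integers(len(free))]
            s = half_cauchy_sample(self.rng, self.prior.rate_scale)
            new.shifts[bid] = s
            log_q_fwd = (
                math.log(pb)
                - math.log(len(free))
                + half_cauchy_logpdf(s, self.prior.rate_scale)
            )
            pd_rev = 1.0 - self._birth_prob(k + 1)
            log_q_rev = math.log(pd_rev) - math.log(k + 1)
        else:  # death
            bids = list(state.shifts)
            bid = bids[self.rng.integers(len(bids))]
            s = new.shifts.pop(bid)
            log_q_fwd = math.log(1.0 - pb) - math.log(k)
            pb_rev = self._birth_prob(k - 1)
            n_free_rev = self.n_branches - (k - 1)
            log_q_rev = (
                math.log(pb_rev)
                - math.log(n_free_rev)
                + half_cauchy_logpdf(s, self.prior.rate_scale)
            )
        return new, log_q_rev - log_q_fwd

    def _free_neighbours(self, bid: int, shifts: dict[int, float]) -> list[int]:
        node = self.tree.nodes[bid]
        out = []
        if node.parent is not None and node.parent is not self.tree.root:
            if node.parent.id not in shifts:
                out.append(node.parent.id)
        for c in node.children:
            if c.id not in shifts:
                out.append(c.id)
        return out

    def move_shift_relocate(self, state: ChainState) -> tuple[ChainState, float]:
        if not state.shifts:
            return state.copy(), -np.inf  # no-op, rejected
        new = state.copy()
        bids = list(state.shifts)
        src = bids[self.rng.integers(len(bids))]
        if self.rng.random() < 0.5:
            # global relocation: uniform over free branches (symmetric)
            free = [b for b in self.branch_ids if b not in state.shifts]
            if not free:
                return state.copy(), -np.inf
            dst = free[self.rng.integers(len(free))]
            new.shifts[dst] = new.shifts.pop(src)
            return new, 0.0
        # local slide: move to a free parent/child branch
        nbrs = self._free_neighbours(src, state.shifts)
        if not nbrs:
            return state.copy(), -np.inf
        dst = nbrs[self.rng.integers(len(nbrs))]
        new.shifts[dst] = new.shifts.pop(src)
        n_rev = len(self._free_neighbours(dst, new.shifts))
        if n_rev == 0:
            return state.copy(), -np.inf
        return new, math.log(len(nbrs)) - math.log(n_rev)

    def move_root_error(self, state: ChainState) -> tuple[ChainState, float]:
        new = state.copy()
        if self.rng.random() < 0.5:
            scale = max(abs(self.y).max(), 1.0) * 0.1 if not self.prior_only else 1.0
            new.root = state.root + self.rng.normal(0.0, scale)
            return new, 0.0
        eps = self.rng.normal(0.0, 0.6)
        new.error_var = state.error_var * math.exp(eps)
        return new, eps

    def move_jump(self, state: ChainState) -> tuple[ChainState, float]:
        new = state.copy()
        u = self.rng.random()
        N = sum(state.jumps.values())
        if u < 0.3:  # jump-variance update
            eps = self.rng.normal(0.0, 0.6)
            new.jump_var = state.jump_var * math.exp(eps)
            return new, eps
        if u < 0.65:  # birth / death
            pb = 1.0 if N == 0 else 0.5
            if self.rng.random() < pb:  # birth
                bid = self.branch_ids[self.rng.integers(self.n_branches)]
                if state.jumps.get(bid, 0) >= JUMP_CAP:
                    return state.copy(), -np.inf
                new.jumps[bid] = new.jumps.get(bid, 0) + 1
                log_q_fwd = math.log(pb) - math.log(self.n_branches)
                pd_rev = 0.5
                log_q_rev = (
                    math.log(pd_rev)
                    + math.log(new.jumps[bid])
                    - math.log(N + 1)
                )
            else:  # death: remove one jump uniformly at random
                bids = [b for b, c in state.jumps.items() for _ in range(c)]
                bid = bids[self.rng.integers(len(bids))]
                cnt = new.jumps[bid]
                if cnt == 1:
                    del new.jumps[bid]
                else:
                    new.jumps[bid] = cnt - 1
                log_q_fwd = math.log(0.5) + math.log(cnt) - math.log(N)
                pb_rev = 1.0 if N == 1 else 0.5
                log_q_rev = math.log(pb_rev) - math.log(self.n_branches)
            return new, log_q_rev - log_q_fwd
        # relocation: move one jump to a uniformly chosen branch
        if N == 0:
            return state.copy(), -np.inf
        bids = [b for b, c in state.jumps.items() for _ in range(c)]
        src = bids[self.rng.integers(len(bids))]
        dst = self.branch_ids[self.rng.integers(self.n_branches)]
        if dst != src and state.jumps.get(dst, 0) >= JUMP_CAP:
            return state.copy(), -np.inf
        if new.jumps[src] == 1:
            del new.jumps[src]
        else:
            new.jumps[src] -= 1
        new.jumps[dst] = new.jumps.get(dst, 0) + 1
        n_src = state.jumps[src]
        n_dst_new = new.jumps[dst]
        log_q_fwd = math.log(n_src / N)
        log_q_rev = math.log(n_dst_new / N)
        return new, log_q_rev - log_q_fwd

    def step(self, state: ChainState) -> ChainState:
        move = self.move_names[
            self.rng.choice(len(self.move_names), p=self.move_probs)
        ]
        fn = getattr(self, f"move_{move}")
        new, log_q = fn(state)
        self.proposed[move] += 1
        if np.isfinite(log_q) and self._accept(state, new, log_q):
            self.accepted[move] += 1
            return new
        return state


def run_rjmcmc(
    tree: Phylogeny,
    trait,
    prior: PriorConfig | None = None,
    n_generations: int = 1_000_000,
    thin: int = 10_000,
    model: str = "jump-rbm",
    seed: int = 0,
    prior_only: bool = False,
) -> PosteriorTrace:
    """Run one rjMCMC chain and return the thinned posterior trace.

    ``prior_only`` disables the likelihood (prior-predictive sampling), used
    for calibration checks of the shift-count and rate-scalar priors.
    """
    if model not in ("rbm", "jump-rbm"):
        raise McmcError(f"unknown model {model!r}")
    if prior is None:
        prior = PriorConfig()
    if n_generations < thin:
        raise McmcError("n_generations must be >= thin")
    if not tree.is_binary():
        raise McmcError("tree must be binary (resolve polytomies first)")

    if prior_only:
        y = np.zeros(len(tree.tips))
    else:
        if isinstance(trait, dict):
            y = np.array([float(trait[t]) for t in tree.tip_labels])
        else:
            y = np.asarray(trait, dtype=float)
        if y.shape != (len(tree.tips),):
            raise McmcError("trait length must equal tip count")

    rng = np.random.default_rng(seed)
    sampler = _Sampler(tree, y, prior, model, rng, prior_only=prior_only)

    depth = max(float(tree.tip_depths().mean()), 1e-8)
    var = float(np.var(y)) if not prior_only else 1.0
    state = ChainState(
        shifts={},
        base_rate=max(var / depth, 1e-6),
        root=float(np.mean(y)),
        error_var=max(var * 0.01, 1e-8),
        jumps={},
        jump_var=max(var * 0.1, 1e-6),
    )
    sampler.evaluate(state)
    tries = 0
    while not np.isfinite(state.log_posterior):
        tries += 1
        if tries > 10:
            raise McmcError("non-finite posterior at initial state after 10 retries")
        state.base_rate = float(half_cauchy_sample(rng, prior.rate_scale))
        state.error_var = float(half_cauchy_sample(rng, prior.error_scale))
        sampler.evaluate(state)

    samples: list[ChainState] = []
    for gen in range(1, n_generations + 1):
        state = sampler.step(state)
        if gen % thin == 0:
            snap = state.copy()
            snap.generation = gen
            samples.append(snap)

    acceptance = {
        m: (sampler.accepted[m] / sampler.proposed[m]) if sampler.proposed[m] else 0.0
        for m in sampler.move_names
    }
    return PosteriorTrace(
        samples=samples,
        model=model,
        seed=seed,
        n_generations=n_generations,
        thin=thin,
        branch_ids=sampler.branch_ids,
        acceptance=acceptance,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# summaries


def _retained(trace: PosteriorTrace, burnin_fraction: float) -> list[ChainState]:
    if not trace.samples:
        raise McmcError("empty trace")
    start = int(len(trace.samples) * burnin_fraction)
    kept = trace.samples[start:]
    if not kept:
        raise McmcError("burn-in leaves no samples")
    return kept


@dataclass
class ShiftSummary:
    table: pd.DataFrame  # branch, probability, direction, mean_relative_rate
    n_retained: int


def summarize_shifts(trace: PosteriorTrace, burnin_fraction: float = 0.25) -> ShiftSummary:
    """Per-branch shift probability, direction, and posterior mean relative rate."""
    kept = _retained(trace, burnin_fraction)
    tree = trace.tree
    sampler = _Sampler(
        tree,
        np.zeros(len(tree.tips)),
        PriorConfig(),
        trace.model,
        np.random.default_rng(0),
        prior_only=True,
    )
    n_branches = len(trace.branch_ids)
    prob = np.zeros(n_branches)
    direction_acc = np.zeros(n_branches)
    rel_rate = np.zeros(n_branches)
    pos = {bid: i for i, bid in enumerate(trace.branch_ids)}
    for s in kept:
        rates = sampler.branch_rates(s) / s.base_rate
        rel_rate += rates
        for bid, scalar in s.shifts.items():
            i = pos[bid]
            prob[i] += 1
            # direction relative to what the branch would inherit
            node = tree.nodes[bid]
            parent_scalar = 1.0
            p = node.parent
            while p is not None and p is not tree.root:
                if p.id in s.shifts:
                    parent_scalar = s.shifts[p.id]
                    break
                p = p.parent
            direction_acc[i] += 1.0 if scalar > parent_scalar else -1.0
    n = len(kept)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.where(prob > 0, direction_acc / np.maximum(prob, 1), 0.0)
    table = pd.DataFrame(
        {
            "branch": trace.branch_ids,
            "probability": prob / n,
            "direction": np.where(direction >= 0, "forward", "backward"),
            "direction_score": direction,
            "mean_relative_rate": rel_rate / n,
        }
    )
    table.loc[table["probability"] == 0, "direction"] = ""
    return ShiftSummary(table=table, n_retained=n)


@dataclass
class JumpSummary:
    table: pd.DataFrame  # branch, probability, mean_count
    n_retained: int
    status: str = "ok"


def summarize_jumps(trace: PosteriorTrace, burnin_fraction: float = 0.25) -> JumpSummary:
    if trace.model != "jump-rbm":
        return JumpSummary(
            table=pd.DataFrame(columns=["branch", "probability", "mean_count"]),
            n_retained=0,
            status="model class 'rbm' has no jumps",
        )
    kept = _retained(trace, burnin_fraction)
    pos = {bid: i for i, bid in enumerate(trace.branch_ids)}
    prob = np.zeros(len(trace.branch_ids))
    mean_count = np.zeros(len(trace.branch_ids))
    for s in kept:
        for bid, cnt in s.jumps.items():
            prob[pos[bid]] += 1
            mean_count[pos[bid]] += cnt
    n = len(kept)
    return JumpSummary(
        table=pd.DataFrame(
            {
                "branch": trace.branch_ids,
                "probability": prob / n,
                "mean_count": mean_count / n,
            }
        ),
        n_retained=n,
    )


# ---------------------------------------------------------------------------
# diagnostics


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the autocorrelation time (Geyer initial positive sequence)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    # autocovariance via FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # sum consecutive pairs until a pair sum goes non-positive
    tau = 1.0
    for t in range(1, n - 1, 2):
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
    return float(n / tau)


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """PSRF = sqrt(1 + B / (n W)); equals 1 exactly for identical chains."""
    if len(chains) < 2:
        raise McmcError("PSRF requires >= 2 chains")
    arrs = [np.asarray(c, dtype=float) for c in chains]
    n = min(len(a) for a in arrs)
    arrs = [a[:n] for a in arrs]
    means = np.array([a.mean() for a in arrs])
    variances = np.array([a.var(ddof=1) for a in arrs])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(math.sqrt(1.0 + B / (n * W)))


@dataclass
class Diagnostics:
    ess: dict[str, float]
    psrf: dict[str, float] | None
    n_samples: int
    flags: list[str] = field(default_factory=list)


def _scalar_series(trace: PosteriorTrace) -> dict[str, np.ndarray]:
    out = {
        "base_rate": np.array([s.base_rate for s in trace.samples]),
        "root": np.array([s.root for s in trace.samples]),
        "error_var": np.array([s.error_var for s in trace.samples]),
        "n_shifts": np.array([len(s.shifts) for s in trace.samples], dtype=float),
        "log_posterior": np.array([s.log_posterior for s in trace.samples]),
    }
    if trace.model == "jump-rbm":
        out["n_jumps"] = np.array(
            [sum(s.jumps.values()) for s in trace.samples], dtype=float
        )
        out["jump_var"] = np.array([s.jump_var for s in trace.samples])
    return out


def diagnostics(
    traces: list[PosteriorTrace],
    ess_threshold: float = 200.0,
    psrf_threshold: float = 1.1,
) -> Diagnostics:
    """ESS per scalar parameter (pooled first chain) and PSRF across chains."""
    if not traces:
        raise McmcError("no traces")
    series = _scalar_series(traces[0])
    ess = {k: effective_sample_size(v) for k, v in series.items()}
    psrf = None
    if len(traces) >= 2:
        per_chain = [_scalar_series(t) for t in traces]
        psrf = {
            k: gelman_rubin([pc[k] for pc in per_chain]) for k in series
        }
    flags = [f"low ESS: {k} ({v:.0f})" for k, v in ess.items() if v < ess_threshold]
    if psrf:
        flags += [f"high PSRF: {k} ({v:.3f})" for k, v in psrf.items() if v > psrf_threshold]
    return Diagnostics(ess=ess, psrf=psrf, n_samples=len(traces[0].samples), flags=flags)
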