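import numpy as np
import pytest
from scipy import stats

from asymmorph import (
    ContinuousModelSpec,
    PriorConfig,
    diagnostics,
    model_loglik,
    run_rjmcmc,
    summarize_jumps,
    summarize_shifts,
)
from asymmorph.rjmcmc import (
    McmcError,
    effective_sample_size,
    gelman_rubin,
    half_cauchy_logpdf,
    _Sampler,
)
from asymmorph.synthetic import SimTraitSpec, painting_from_shifts, simulate_trait, simulate_tree
from asymmorph.trees import resolve_polytomies


@pytest.fixture(scope="module")
def tree20():
    return resolve_polytomies(simulate_tree(20, seed=1))


@pytest.fixture(scope="module")
def prior_trace(tree20):
    """Prior-predictive trace: likelihood disabled, 10^4 retained samples."""
    return run_rjmcmc(
        tree20, None, n_generations=200_000, thin=20, model="jump-rbm",
        seed=7, prior_only=True,
    )


class TestPriors:
    def test_invalid_prior_rejected(self):
        with pytest.raises(McmcError):
            PriorConfig(rate_scale=-1.0)

    def test_half_cauchy_logpdf_normalised(self):
        from scipy.integrate import quad

        val, _ = quad(lambda x: np.exp(half_cauchy_logpdf(x, 25.0)), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_zero_shift_prior_mass(self, prior_trace):
        counts = np.array([len(s.shifts) for s in prior_trace.samples])
        assert (counts == 0).mean() == pytest.approx(0.5, abs=0.02)

    def test_shift_count_poisson_chisquare(self, prior_trace):
        from conftest import poisson_gof_pvalue

        counts = np.array([len(s.shifts) for s in prior_trace.samples])
        assert poisson_gof_pvalue(counts, np.log(2)) > 0.01

    def test_rate_scalars_half_cauchy_ks(self, prior_trace):
        scalars = np.array([v for s in prior_trace.samples for v in s.shifts.values()])
        cdf = lambda x: 2 * np.arctan(np.asarray(x) / 25.0) / np.pi
        assert stats.kstest(scalars[::3], cdf).pvalue > 0.01

    def test_jump_count_poisson(self, prior_trace):
        counts = np.array([sum(s.jumps.values()) for s in prior_trace.samples])
        assert (counts == 0).mean() == pytest.approx(0.5, abs=0.02)
        assert counts.mean() == pytest.approx(np.log(2), abs=0.05)


class TestRun:
    def test_determinism(self, tree20):
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=2))
        t1 = run_rjmcmc(tree20, y, n_generations=2000, thin=10, model="jump-rbm", seed=5)
        t2 = run_rjmcmc(tree20, y, n_generations=2000, thin=10, model="jump-rbm", seed=5)
        for a, b in zip(t1.samples, t2.samples):
            assert a.shifts == b.shifts
            assert a.jumps == b.jumps
            assert a.base_rate == b.base_rate
            assert a.root == b.root
            assert a.loglik == b.loglik

    def test_trace_length_and_order(self, tree20):
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=2))
        trace = run_rjmcmc(tree20, y, n_generations=3000, thin=30, model="rbm", seed=1)
        assert len(trace.samples) == 100
        gens = [s.generation for s in trace.samples]
        assert gens == sorted(gens)
        assert all(g % 30 == 0 for g in gens)

    def test_bad_inputs(self, tree20):
        with pytest.raises(McmcError, match="model"):
            run_rjmcmc(tree20, None, model="bogus", prior_only=True)
        with pytest.raises(McmcError, match="thin"):
            run_rjmcmc(tree20, None, n_generations=5, thin=10, prior_only=True)

    def test_no_spurious_shifts_under_bm(self):
        """Posterior shift count stays near the prior mean on single-rate data."""
        tree = resolve_polytomies(simulate_tree(60, seed=30))
        y = simulate_trait(tree, SimTraitSpec(sigma2=0.05, seed=31))
        trace = run_rjmcmc(tree, y, n_generations=20_000, thin=20, model="rbm", seed=32)
        counts = [len(s.shifts) for s in trace.samples[len(trace.samples) // 4:]]
        assert np.mean(counts) <= np.log(2) + 0.5

    def test_fixed_configuration_matches_bmm_likelihood(self, tree20):
        """Sampler likelihood at a fixed shift state equals the BMM likelihood."""
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=9))
        yv = np.array([y[l] for l in tree20.tip_labels])
        sampler = _Sampler(
            tree20, yv, PriorConfig(), "rbm", np.random.default_rng(0)
        )
        bid = tree20.branches[4].id
        from asymmorph.rjmcmc import ChainState

        state = ChainState(
            shifts={bid: 3.0}, base_rate=0.1, root=0.2, error_var=0.0,
            jumps={}, jump_var=0.0,
        )
        ll = sampler.loglik(state)
        painting = painting_from_shifts(tree20, {bid: 3.0})
        params = {
            "rates": {"base": 0.1, f"shift{bid}": 0.3},
            "root": 0.2,
        }
        oracle = model_loglik(
            ContinuousModelSpec("BMM"), params, tree20, y, painting=painting
        )
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestSummaries:
    def test_no_shift_trace_all_zero(self, tree20):
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=2))
        trace = run_rjmcmc(tree20, y, n_generations=1000, thin=10, model="rbm", seed=3)
        for s in trace.samples:
            s.shifts = {}
        summ = summarize_shifts(trace)
        assert (summ.table["probability"] == 0).all()

    def test_probabilities_thinning_invariant(self, prior_trace):
        import copy

        full = summarize_shifts(prior_trace, burnin_fraction=0.0)
        half = copy.copy(prior_trace)
        half.samples = prior_trace.samples[::2]
        thinned = summarize_shifts(half, burnin_fraction=0.0)
        # same prior marginals: per-branch probabilities agree statistically
        assert np.abs(
            full.table["probability"].mean() - thinned.table["probability"].mean()
        ) < 0.01

    def test_burnin_leaves_no_samples(self, tree20):
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=2))
        trace = run_rjmcmc(tree20, y, n_generations=100, thin=100, model="rbm", seed=3)
        with pytest.raises(McmcError):
            summarize_shifts(trace, burnin_fraction=1.0)

    def test_rbm_trace_jump_summary_empty(self, tree20):
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=2))
        trace = run_rjmcmc(tree20, y, n_generations=1000, thin=10, model="rbm", seed=3)
        summ = summarize_jumps(trace)
        assert summ.table.empty
        assert "rbm" in summ.status

    def test_jump_counts_nonnegative_and_consistent(self, prior_trace):
        summ = summarize_jumps(prior_trace)
        tbl = summ.table
        assert (tbl["mean_count"] >= 0).all()
        assert (tbl.loc[tbl["probability"] == 0, "mean_count"] == 0).all()

    def test_planted_jump_recovered(self):
        """A 5-SD jump on a known branch attains the top jump probability.

        Scaled down to 8 replicates / 4x10^4 generations for the CPU budget;
        pass mark is the stated 70%.
        """
        successes = 0
        n_rep = 8
        for rep in range(n_rep):
            tree = resolve_polytomies(simulate_tree(50, seed=5000 + rep))
            mask = tree.tip_mask_below()
            cands = [b.id for b in tree.branches if 5 <= mask[b.id].sum() <= 15]
            bid = cands[rep % len(cands)]
            base = simulate_trait(tree, SimTraitSpec(sigma2=0.01, seed=6000 + rep))
            sd = float(np.std(list(base.values())))
            y = simulate_trait(
                tree,
                SimTraitSpec(sigma2=0.01, jump_branches={bid: 5 * sd}, seed=6000 + rep),
            )
            trace = run_rjmcmc(
                tree, y, n_generations=40_000, thin=40, model="jump-rbm",
                seed=7000 + rep,
            )
            table = summarize_jumps(trace).table.sort_values(
                "probability", ascending=False
            )
            successes += int(table.iloc[0]["branch"]) == bid
        assert successes >= 0.7 * n_rep, f"{successes}/{n_rep}"

    def test_retained_count_reported(self, prior_trace):
        summ = summarize_shifts(prior_trace, burnin_fraction=0.25)
        assert summ.n_retained == len(prior_trace.samples) - len(prior_trace.samples) // 4


class TestDiagnostics:
    def test_white_noise_ess(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        ess = effective_sample_size(x)
        assert abs(ess - 5000) / 5000 < 0.10

    def test_ar1_ess_analytic(self):
        rng = np.random.default_rng(1)
        n = 20_000
        phi = 0.5
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert abs(effective_sample_size(x) - expected) / expected < 0.15

    def test_identical_chains_psrf_one(self):
        x = np.random.default_rng(2).normal(size=1000)
        assert gelman_rubin([x, x.copy()]) == pytest.approx(1.0, abs=1e-6)

    def test_psrf_detects_divergent_means(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 1000)
        b = rng.normal(5, 1, 1000)
        assert gelman_rubin([a, b]) > 2.0

    def test_psrf_requires_two_chains(self):
        with pytest.raises(McmcError):
            gelman_rubin([np.zeros(10)])

    def test_diagnostics_bundle(self, tree20):
        y = simulate_trait(tree20, SimTraitSpec(sigma2=0.1, seed=2))
        traces = [
            run_rjmcmc(tree20, y, n_generations=5000, thin=10, model="rbm", seed=s)
            for s in (1, 2)
        ]
        diag = diagnostics(traces)
        assert set(diag.ess) >= {"base_rate", "root", "n_shifts"}
        assert all(v <= len(traces[0].samples) * 1.01 for v in diag.ess.values())
        assert diag.psrf is not None
        assert all(v >= 1.0 - 1e-9 for v in diag.psrf.values())
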