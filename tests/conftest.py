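import numpy as np
import pytest

from asymmorph import (
    AsymmetrySpec,
    SkullTemplateParams,
    make_dataset,
    make_template,
    parse_newick,
)
from asymmorph.synthetic import simulate_tree
from asymmorph.trees import resolve_polytomies


@pytest.fixture(scope="session")
def template_and_scheme():
    return make_template(SkullTemplateParams())


@pytest.fixture(scope="session")
def template(template_and_scheme):
    return template_and_scheme[0]


@pytest.fixture(scope="session")
def scheme(template_and_scheme):
    return template_and_scheme[1]


@pytest.fixture()
def tiny_scheme():
    """1 pair + 1 midline point: the smallest valid scheme shape x3."""
    from asymmorph import LandmarkScheme

    return LandmarkScheme(
        n_total=3, pairs=((0, 2),), midline=(1,), regions={0: "other", 1: "other", 2: "other"}
    )


@pytest.fixture(scope="session")
def asym_dataset():
    """Six specimens with 2 mm planted right-nasal displacement."""
    return make_dataset(6, asymmetry=AsymmetrySpec(magnitude=2.0), seed=11)


@pytest.fixture(scope="session")
def four_tip_tree():
    return parse_newick("((A:1.0,B:1.0):0.5,(C:0.8,D:0.8):0.7);")


@pytest.fixture(scope="session")
def bd_tree_50():
    return resolve_polytomies(simulate_tree(50, seed=42))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)


def poisson_gof_pvalue(counts: np.ndarray, mean: float) -> float:
    """Chi-square goodness-of-fit p for integer counts vs Poisson(mean).

    Bins with expected count < 5 are pooled into a single tail bin.
    """
    from scipy import stats

    counts = np.asarray(counts, dtype=int)
    maxk = int(counts.max())
    obs = np.bincount(counts, minlength=maxk + 1).astype(float)
    ks = np.arange(maxk + 1)
    exp = stats.poisson.pmf(ks, mean) * len(counts)
    keep = exp >= 5
    obs_main, exp_main = obs[keep], exp[keep]
    # tail bin: everything beyond the kept range (including unobserved mass)
    tail_exp = len(counts) - exp_main.sum()
    tail_obs = len(counts) - obs_main.sum()
    if tail_exp > 1e-9:
        obs_main = np.append(obs_main, tail_obs)
        exp_main = np.append(exp_main, tail_exp)
    chi2 = float(((obs_main - exp_main) ** 2 / exp_main).sum())
    return float(stats.chi2.sf(chi2, len(obs_main) - 1))
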