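"""Synthetic skulls, trees, and traits for exercising the full pipeline.

The landmark template is a stylised skull — an elongated rostrum, paired
lateral arcs, and a dorsal midline ridge — exactly symmetric about the y = 0
plane, so every downstream asymmetry statistic has a known zero baseline.
Generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import (
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    SpecimenMetadata,
)
from .trees import Node, Phylogeny, RegimePainting


class SyntheticError(ValueError):
    pass


# fraction of bilateral pairs allotted to each region, in landmark order
# (anterior to posterior); midline points get their own anterior-to-posterior
# region sequence. Reconstructed region semantics, not an anatomical atlas.
_PAIR_REGION_LAYOUT = (
    ("rostrum", 0.24),
    ("premaxilla", 0.14),
    ("nasal", 0.12),
    ("maxilla", 0.15),
    ("orbit", 0.09),
    ("jugal", 0.08),
    ("squamosal", 0.09),
    ("posterior", 0.09),
    ("other", 1.0),  # remainder
)
_MIDLINE_REGION_LAYOUT = ("rostrum", "rostrum", "nasal", "nasal", "other", "other", "posterior", "posterior", "posterior")


@dataclass(frozen=True)
class SkullTemplateParams:
    n_pairs: int = 57
    n_midline: int = 9
    centroid_size: float = 500.0
    seed: int = 0


def _region_for_pair(i: int, n_pairs: int) -> str:
    cum = 0.0
    for region, frac in _PAIR_REGION_LAYOUT:
        cum = min(cum + frac, 1.0)
        if (i + 1) / n_pairs <= cum + 1e-12:
            return region
    return "other"


def make_template(params: SkullTemplateParams | None = None) -> tuple[LandmarkConfiguration, LandmarkScheme]:
    """Deterministic, exactly bilaterally symmetric skull template.

    Landmark order: left 1..P, midline P+1..P+M, right P+M+1..2P+M
    (pair i pairs landmark i with landmark P+M+i), mirroring the convention
    of a 57+9+57 = 123 scheme with reference set 1..66.
    """
    if params is None:
        params = SkullTemplateParams()
    P, M = params.n_pairs, params.n_midline
    if P < 1 or M < 1:
        raise SyntheticError("need at least one pair and one midline landmark")
    rng = np.random.default_rng(params.seed)

    # left-side landmarks on two lateral arcs along an elongated axis
    t = np.linspace(0.05, 0.95, P)
    x = 10.0 * t
    width = 1.2 + 2.2 * np.sin(np.pi * t) ** 2 + 1.8 * t**2  # widens posteriorly
    y = width
    z = 0.8 * np.sin(2 * np.pi * t) * (0.3 + t) + rng.normal(0, 0.15, P)
    left = np.column_stack([x, y, z])

    tm = np.linspace(0.0, 1.0, M)
    mid = np.column_stack(
        [10.0 * tm, np.zeros(M), 1.2 * np.cos(np.pi * tm) * 0.5 + rng.normal(0, 0.1, M)]
    )

    right = left.copy()
    right[:, 1] *= -1.0

    coords = np.vstack([left, mid, right])
    coords = coords - coords.mean(axis=0)
    size = float(np.sqrt((coords**2).sum()))
    coords = coords * (params.centroid_size / size)

    pairs = tuple((i, P + M + i) for i in range(P))
    midline = tuple(range(P, P + M))
    regions: dict[int, str] = {}
    for i in range(P):
        reg = _region_for_pair(i, P)
        regions[i] = reg
        regions[P + M + i] = reg
    for j in range(M):
        if M == len(_MIDLINE_REGION_LAYOUT):
            regions[P + j] = _MIDLINE_REGION_LAYOUT[j]
        else:
            regions[P + j] = _MIDLINE_REGION_LAYOUT[
                min(int(j / M * len(_MIDLINE_REGION_LAYOUT)), len(_MIDLINE_REGION_LAYOUT) - 1)
            ]

    scheme = LandmarkScheme(n_total=2 * P + M, pairs=pairs, midline=midline, regions=regions)
    config = LandmarkConfiguration(
        specimen_id="template",
        coords=coords,
        missing=np.zeros(2 * P + M, dtype=bool),
    )
    return config, scheme


@dataclass(frozen=True)
class AsymmetrySpec:
    """Planted directional displacement: ``regions`` landmarks on ``side``
    shifted by ``magnitude`` mm along ``direction``."""

    regions: tuple[str, ...] = ("nasal",)
    direction: tuple[float, float, float] = (0.0, 1.0, 0.0)  # leftward
    magnitude: float = 2.0
    side: str = "right"  # left | right | both | midline

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise SyntheticError("magnitude must be >= 0")
        if self.side not in ("left", "right", "both", "midline"):
            raise SyntheticError(f"bad side {self.side!r}")


def affected_landmarks(spec: AsymmetrySpec, scheme: LandmarkScheme) -> list[int]:
    idx = set()
    for region in spec.regions:
        idx |= set(scheme.region_indices(region))
    if spec.side == "left":
        side_idx = set(scheme.left_indices)
    elif spec.side == "right":
        side_idx = set(scheme.right_indices)
    elif spec.side == "midline":
        side_idx = set(scheme.midline)
    else:
        side_idx = set(scheme.left_indices) | set(scheme.right_indices) | set(scheme.midline)
    return sorted(idx & side_idx)


def apply_asymmetry(
    config: LandmarkConfiguration, spec: AsymmetrySpec, scheme: LandmarkScheme
) -> LandmarkConfiguration:
    """Translate the affected landmarks by magnitude * unit(direction)."""
    affected = affected_landmarks(spec, scheme)
    if not affected:
        raise SyntheticError(
            f"no landmarks in regions {spec.regions} on side {spec.side!r}"
        )
    d = np.asarray(spec.direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise SyntheticError("direction must be non-zero")
    out = config.copy()
    out.coords[affected] += spec.magnitude * d / norm
    return out


def make_dataset(
    n_specimens: int,
    params: SkullTemplateParams | None = None,
    asymmetry: AsymmetrySpec | None = None,
    magnitudes: list[float] | None = None,
    seed: int = 0,
    groups: list[str] | None = None,
) -> LandmarkDataset:
    """Bundle of perturbed template copies with simple metadata.

    ``magnitudes`` gives each specimen its own planted displacement magnitude
    (recycled); without an asymmetry spec all specimens are symmetric.
    """
    template, scheme = make_template(params)
    configs = []
    meta = []
    for i in range(n_specimens):
        cfg = template.copy()
        cfg.specimen_id = f"spec{i + 1:03d}"
        if asymmetry is not None:
            mag = asymmetry.magnitude if magnitudes is None else magnitudes[i % len(magnitudes)]
            spec_i = AsymmetrySpec(
                regions=asymmetry.regions,
                direction=asymmetry.direction,
                magnitude=mag,
                side=asymmetry.side,
            )
            cfg = apply_asymmetry(cfg, spec_i, scheme)
            cfg.specimen_id = f"spec{i + 1:03d}"
        group = groups[i % len(groups)] if groups else "odontocete"
        meta.append(
            SpecimenMetadata(
                specimen_id=cfg.specimen_id, species=f"sp{i + 1:03d}", group=group
            )
        )
        configs.append(cfg)
    return LandmarkDataset(scheme=scheme, configurations=configs, metadata=meta)


DEFAULT_FRAGILE_REGIONS = ("jugal", "squamosal", "rostrum")


def degrade(
    dataset: LandmarkDataset,
    specimen_missing_fraction: float = 0.39,
    landmark_missing_rate: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    fragile_regions: tuple[str, ...] = DEFAULT_FRAGILE_REGIONS,
    fragile_weight: float = 3.0,
) -> LandmarkDataset:
    """Plant missingness (biased to fragile regions) and Gaussian noise."""
    for name, rate in (
        ("specimen_missing_fraction", specimen_missing_fraction),
        ("landmark_missing_rate", landmark_missing_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise SyntheticError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scheme = dataset.scheme
    fragile = set()
    known_regions = set(scheme.regions.values())
    for region in fragile_regions:
        if region in known_regions:
            fragile |= set(scheme.region_indices(region))
    weights = np.ones(scheme.n_total)
    weights[sorted(fragile)] = fragile_weight
    probs = np.clip(landmark_missing_rate * weights, 0.0, 1.0)

    new_configs = []
    for cfg in dataset.configurations:
        out = cfg.copy()
        if noise_sd > 0:
            out.coords = out.coords + rng.normal(0.0, noise_sd, out.coords.shape)
        if specimen_missing_fraction > 0 and rng.random() < specimen_missing_fraction:
            miss = rng.random(scheme.n_total) < probs
            if not miss.any():
                miss[rng.choice(np.flatnonzero(weights == weights.max()))] = True
            out.missing = out.missing | miss
            out.coords[out.missing] = np.nan
        new_configs.append(out)
    return LandmarkDataset(
        scheme=scheme, configurations=new_configs, metadata=list(dataset.metadata)
    )


# ---------------------------------------------------------------------------
# trees


def simulate_tree(
    n_tips: int,
    model: str = "birth-death",
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    fossil_tips: int = 0,
    seed: int = 0,
) -> Phylogeny:
    """Random rooted tree with positive branch lengths.

    ``birth-death`` grows forward in time until n_tips extant lineages exist
    (extinct lineages pruned); ``coalescent`` merges n_tips lineages backward.
    ``fossil_tips`` truncates that many randomly chosen tips at a random
    fraction of their terminal branch, making the tree non-ultrametric.
    """
    if n_tips < 2:
        raise SyntheticError("need >= 2 tips")
    rng = np.random.default_rng(seed)

    if model == "coalescent":
        lineages = [Node(label=f"t{i + 1}") for i in range(n_tips)]
        heights = {id(n): 0.0 for n in lineages}
        now = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            now += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            parent = Node()
            a.length = now - heights[id(a)]
            b.length = now - heights[id(b)]
            parent.add_child(a)
            parent.add_child(b)
            heights[id(parent)] = now
            lineages = [n for n in lineages if n not in (a, b)] + [parent]
        root = lineages[0]
        root.length = 0.0
        tree = Phylogeny(root)
    elif model == "birth-death":
        for attempt in range(1000):
            tree = _birth_death_attempt(n_tips, birth_rate, death_rate, rng)
            if tree is not None:
                break
        else:
            raise SyntheticError("birth-death simulation failed to survive")
    else:
        raise SyntheticError(f"unknown tree model {model!r}")

    if fossil_tips > 0:
        tips = list(tree.tips)
        chosen = rng.choice(len(tips), size=min(fossil_tips, len(tips)), replace=False)
        for i in chosen:
            tips[i].length *= rng.uniform(0.1, 0.9)
        tree = Phylogeny(tree.root)
    return tree


def _birth_death_attempt(n_tips, birth, death, rng) -> Phylogeny | None:
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    alive = [a, b]
    pending = {id(a): 0.0, id(b): 0.0}  # elapsed time on open branch

    while len(alive) < n_tips:
        total = len(alive) * (birth + death)
        dt = rng.exponential(1.0 / total)
        for n in alive:
            pending[id(n)] += dt
        i = rng.integers(len(alive))
        node = alive[i]
        is_birth = death == 0 or rng.random() < birth / (birth + death)
        if is_birth:
            node.length = pending.pop(id(node))
            c1, c2 = Node(), Node()
            node.add_child(c1)
            node.add_child(c2)
            pending[id(c1)] = 0.0
            pending[id(c2)] = 0.0
            alive = alive[:i] + alive[i + 1 :] + [c1, c2]
        else:
            node.length = pending.pop(id(node))
            alive = alive[:i] + alive[i + 1 :]
            if len(alive) < 2:
                return None

    # close open branches with one more waiting time to the present
    dt = rng.exponential(1.0 / (len(alive) * birth))
    for n in alive:
        n.length = pending[id(n)] + dt

    # prune extinct lineages (leaves that were closed without a label)
    for idx, n in enumerate(alive):
        n.label = f"t{idx + 1}"

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.label else None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        node.children = []
        for k in kept:
            node.add_child(k)
        return node

    pruned = prune(root)
    if pruned is None or pruned.is_leaf:
        return None
    pruned.length = 0.0
    tree = Phylogeny(pruned)
    return tree if len(tree.tips) == n_tips else None


# ---------------------------------------------------------------------------
# traits


@dataclass(frozen=True)
class SimTraitSpec:
    """Continuous-trait simulation settings with planted shifts and jumps.

    ``shift_branches`` maps branch id -> rate multiplier applied to that
    branch and its descendants (nested overrides, matching the rjMCMC shift
    semantics); ``jump_branches`` maps branch id -> displacement SD of one
    normal jump added on that branch.
    """

    model: str = "BM"  # BM | OU
    sigma2: float = 1.0
    root: float = 0.0
    alpha: float = 0.0
    optimum: float = 0.0
    trend: float = 0.0
    shift_branches: dict = field(default_factory=dict)
    jump_branches: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise SyntheticError("sigma2 must be > 0")
        if self.alpha < 0:
            raise SyntheticError("alpha must be >= 0")


def simulate_trait(tree: Phylogeny, spec: SimTraitSpec) -> dict[str, float]:
    """Root-to-tip recursive simulation; returns tip label -> value.

    Branch diffusion noise and jump displacements come from independent
    child streams of the seed, so adding a jump leaves the diffusion draws
    of every branch untouched.
    """
    rng = np.random.default_rng([spec.seed, 0])
    jump_rng = np.random.default_rng([spec.seed, 1])
    values: dict[int, float] = {tree.root.id: spec.root}
    multiplier: dict[int, float] = {tree.root.id: 1.0}
    for node in tree.preorder():
        if node is tree.root:
            continue
        mult = spec.shift_branches.get(node.id, multiplier[node.parent.id])
        multiplier[node.id] = mult
        s2 = spec.sigma2 * mult
        t = node.length
        parent_val = values[node.parent.id]
        if spec.model == "OU" and spec.alpha > 0:
            a = spec.alpha
            mean = parent_val * np.exp(-a * t) + spec.optimum * (1 - np.exp(-a * t))
            var = s2 / (2 * a) * (1 - np.exp(-2 * a * t))
        else:
            mean = parent_val + spec.trend * t
            var = s2 * t
        val = mean + float(rng.standard_normal()) * float(np.sqrt(max(var, 0.0)))
        if node.id in spec.jump_branches:
            val += float(jump_rng.normal(0.0, spec.jump_branches[node.id]))
        values[node.id] = val
    return {t.label: values[t.id] for t in tree.tips}


def simulate_discrete(
    tree: Phylogeny,
    Q: np.ndarray,
    states: tuple[str, ...],
    seed: int = 0,
    root_state: str | None = None,
) -> dict[str, str]:
    """CTMC simulation of a discrete character along the tree."""
    Q = np.asarray(Q, dtype=float)
    s = len(states)
    if Q.shape != (s, s):
        raise SyntheticError("Q shape must match states")
    rng = np.random.default_rng(seed)
    from scipy.linalg import expm

    lengths = sorted({b.length for b in tree.branches})
    P_of = {t: expm(Q * t) for t in lengths}
    root_idx = states.index(root_state) if root_state is not None else rng.integers(s)
    state_at: dict[int, int] = {tree.root.id: int(root_idx)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        P = P_of[node.length]
        p = np.clip(P[state_at[node.parent.id]], 0, None)
        p = p / p.sum()
        state_at[node.id] = int(rng.choice(s, p=p))
    return {t.label: states[state_at[t.id]] for t in tree.tips}


def painting_from_shifts(tree: Phylogeny, shift_branches: dict) -> RegimePainting:
    """Regime painting matching planted shift semantics (for BMM cross-checks)."""
    state_of: dict[int, str] = {tree.root.id: "base"}
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.id in shift_branches:
            state_of[node.id] = f"shift{node.id}"
        else:
            state_of[node.id] = state_of[node.parent.id]
    states = tuple(sorted(set(state_of.values())))
    return RegimePainting(
        segments={b.id: [(b.length, state_of[b.id])] for b in tree.branches},
        tip_states={t.label: state_of[t.id] for t in tree.tips},
        states=states,
    )
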