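"""Rooted time-tree handling: I/O, polytomy resolution, pruning, regime
painting, and phylogenetic covariance construction.

Trees are stored in a small explicit node structure; dendropy handles the
Newick/NEXUS serialisation. Branches are identified by the id of the node
they subtend (the child node); the root has no branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("id", "label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.id: int = -1
        self.label = label
        self.length = float(length)
        self.parent: "Node | None" = None
        self.children: list["Node"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Phylogeny:
    """Rooted phylogeny with branch lengths in My; tip labels unique."""

    def __init__(self, root: Node):
        self.root = root
        self._index()

    def _index(self) -> None:
        self.nodes: list[Node] = []
        for i, node in enumerate(self.preorder()):
            node.id = i
            self.nodes.append(node)
        self.tips = [n for n in self.nodes if n.is_leaf]
        labels = [t.label for t in self.tips]
        if None in labels:
            raise TreeError("unlabelled tip")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        for n in self.nodes:
            if n is not self.root and n.length < 0:
                raise TreeError(f"negative branch length at node {n.id}")

    # -- traversal ---------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]

    @property
    def branches(self) -> list[Node]:
        """Non-root nodes; each identifies the branch above it."""
        return [n for n in self.nodes if n is not self.root]

    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths."""
        d = {self.root.id: 0.0}
        for n in self.preorder():
            if n is not self.root:
                d[n.id] = d[n.parent.id] + n.length
        return d

    def tip_depths(self) -> np.ndarray:
        d = self.depths()
        return np.array([d[t.id] for t in self.tips])

    def total_length(self) -> float:
        return sum(n.length for n in self.branches)

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.nodes)

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def mrca_id(self, labels: list[str]) -> int:
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise TreeError(f"unknown tips: {sorted(missing)}")
        below: dict[int, set[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[n.id] = {n.label}
            else:
                below[n.id] = set().union(*(below[c.id] for c in n.children))
        best = self.root
        for n in self.preorder():
            if want.issubset(below[n.id]):
                best = n
        return best.id

    def clade_node_ids(self, node_id: int) -> list[int]:
        node = self.nodes[node_id]
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            out.append(n.id)
            stack.extend(n.children)
        return out

    def tip_mask_below(self) -> np.ndarray:
        """(n_nodes, n_tips) boolean: tip j descends from (or is) node i."""
        n_tips = len(self.tips)
        tip_pos = {t.id: j for j, t in enumerate(self.tips)}
        mask = np.zeros((len(self.nodes), n_tips), dtype=bool)
        for n in self.postorder():
            if n.is_leaf:
                mask[n.id, tip_pos[n.id]] = True
            else:
                for c in n.children:
                    mask[n.id] |= mask[c.id]
        return mask

    def copy(self) -> "Phylogeny":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Phylogeny(clone(self.root))

    # -- distances ---------------------------------------------------------

    def patristic_distances(self) -> np.ndarray:
        """Tip-to-tip path length matrix, tips in ``tip_labels`` order."""
        depths = self.depths()
        mask = self.tip_mask_below()
        n = len(self.tips)
        mrca_depth = np.zeros((n, n))
        # deepest node having both tips below = MRCA; preorder visits shallow
        # first so later (deeper) nodes overwrite
        for node in self.preorder():
            m = mask[node.id]
            idx = np.where(m)[0]
            if len(idx) >= 1:
                mrca_depth[np.ix_(idx, idx)] = depths[node.id]
        tip_depth = self.tip_depths()
        return tip_depth[:, None] + tip_depth[None, :] - 2 * mrca_depth

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.label.replace(" ", "_")
                return f"{label}:{node.length:.17g}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.length:.17g}"

        return fmt(self.root)[: -len(f":{self.root.length:.17g}")] + ";"

    def write(self, path, schema: str = "newick") -> None:
        dt = _to_dendropy(self)
        dt.write(path=str(path), schema=schema, suppress_rooting=False)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    def convert(dnode) -> Node:
        label = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        length = dnode.edge.length
        node = Node(label=label, length=0.0 if length is None else float(length))
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    for edge in dtree.preorder_edge_iter():
        if edge.head_node is not dtree.seed_node and edge.length is None:
            raise TreeError("tree has branches without lengths")
    return Phylogeny(convert(dtree.seed_node))


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: Node, dnode):
        dnode.edge.length = node.length
        if node.is_leaf:
            dnode.taxon = taxa.require_taxon(label=node.label)
        for c in node.children:
            build(c, dnode.new_child())

    build(tree.root, dtree.seed_node)
    dtree.is_rooted = True
    return dtree


def read_tree(path, schema: str | None = None) -> Phylogeny:
    """Read a rooted tree from Newick or NEXUS (auto-detected if not given)."""
    if schema is None:
        with open(path) as fh:
            head = fh.read(512).lstrip()
        schema = "nexus" if head.upper().startswith("#NEXUS") else "newick"
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except Exception as e:  # dendropy raises many parse error types
        raise TreeError(f"cannot parse {path} as {schema}: {e}") from e
    return _from_dendropy(dtree)


def parse_newick(text: str) -> Phylogeny:
    dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return _from_dendropy(dtree)


# ---------------------------------------------------------------------------
# topology operations


def resolve_polytomies(tree: Phylogeny, seed: int | None = None) -> Phylogeny:
    """Make the tree strictly binary by inserting zero-length branches.

    Deterministic ladderised order by default; with a seed, child order is
    shuffled before laddering. Patristic distances are unchanged either way.
    """
    out = tree.copy()
    rng = np.random.default_rng(seed) if seed is not None else None
    stack = [out.root]
    while stack:
        node = stack.pop()
        children = list(node.children)
        if rng is not None and len(children) > 2:
            rng.shuffle(children)
        while len(children) > 2:
            a = children.pop()
            b = children.pop()
            joint = Node(length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            children.append(joint)
        node.children = []
        for c in children:
            node.add_child(c)
        stack.extend(c for c in children if c.children)
    return Phylogeny(out.root)


def prune_to_taxa(tree: Phylogeny, names: list[str]) -> Phylogeny:
    """Induced subtree on ``names``; degree-2 nodes suppressed, lengths summed."""
    unknown = sorted(set(names) - set(tree.tip_labels))
    if unknown:
        raise TreeError(f"unknown taxa: {unknown}")
    keep = set(names)

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return Node(node.label, node.length) if node.label in keep else None
        kept = [p for p in (prune(c) for c in node.children) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        new = Node(node.label, node.length)
        for k in kept:
            new.add_child(k)
        return new

    root = prune(tree.root)
    if root is None:
        raise TreeError("pruning removed every tip")
    root.length = 0.0
    return Phylogeny(root)


# ---------------------------------------------------------------------------
# regime painting


@dataclass
class RegimePainting:
    """Branch-segment -> state map over a tree.

    ``segments[branch_id]`` is an ordered (rootward-first) list of
    (length, state); lengths on a branch sum to the branch length.
    """

    segments: dict[int, list[tuple[float, str]]]
    tip_states: dict[str, str]
    states: tuple[str, ...]

    def validate(self, tree: Phylogeny) -> None:
        for b in tree.branches:
            segs = self.segments.get(b.id)
            if segs is None:
                raise TreeError(f"branch {b.id} not painted")
            if abs(sum(s for s, _ in segs) - b.length) > 1e-9 * max(b.length, 1.0):
                raise TreeError(f"branch {b.id}: segment lengths do not sum to length")
            for _, st in segs:
                if st not in self.states:
                    raise TreeError(f"branch {b.id}: state {st!r} not in vocabulary")

    def branch_state(self, branch_id: int) -> str:
        """State of the tipward end of a branch."""
        return self.segments[branch_id][-1][1]


def paint_regimes(
    tree: Phylogeny,
    tip_states: dict[str, str] | None = None,
    clades: list[tuple[list[str], str]] | None = None,
    base_state: str | None = None,
    include_stem: bool = True,
) -> RegimePainting:
    """Paint regime states onto every branch.

    Two specification routes (combinable):

    * ``clades``: list of (tip-name list, state); the MRCA clade of each list
      is painted with that state (stem branch included unless
      ``include_stem=False``). Unpainted branches take ``base_state``.
      Larger clades are painted first so nested clades override.
    * ``tip_states`` alone: branch states are propagated from unanimous
      descendant tip states bottom-up; non-unanimous nodes inherit the parent
      state top-down (root falls back to the majority tip state).
    """
    if clades is None and tip_states is None:
        raise TreeError("need tip_states or clades")

    state_of: dict[int, str] = {}

    if clades is not None:
        if base_state is None:
            raise TreeError("clade painting requires base_state")
        for b in tree.nodes:
            state_of[b.id] = base_state
        mrcas: dict[int, str] = {}
        resolved = sorted(
            ((tree.mrca_id(tips), st, tips) for tips, st in clades),
            key=lambda t: -len(tree.clade_node_ids(t[0])),
        )
        for node_id, st, tips in resolved:
            if node_id in mrcas and mrcas[node_id] != st:
                raise TreeError(
                    f"conflicting clade assignments at node {node_id}: "
                    f"{mrcas[node_id]!r} vs {st!r}"
                )
            mrcas[node_id] = st
            ids = tree.clade_node_ids(node_id)
            for i in ids:
                state_of[i] = st
            if not include_stem and node_id != tree.root.id:
                state_of[node_id] = state_of.get(tree.nodes[node_id].parent.id, base_state)
        # stem handling: the clade MRCA's own branch carries the clade state
        # when include_stem, which the loop above already did.
        states = tuple(sorted({base_state} | {st for _, st in clades}))
    else:
        missing = sorted(set(tree.tip_labels) - set(tip_states))
        if missing:
            raise TreeError(f"tips without a state: {missing}")
        below: dict[int, str | None] = {}
        for n in tree.postorder():
            if n.is_leaf:
                below[n.id] = tip_states[n.label]
            else:
                child_states = {below[c.id] for c in n.children}
                below[n.id] = child_states.pop() if len(child_states) == 1 else None
        vals = [tip_states[t] for t in tree.tip_labels]
        majority = max(sorted(set(vals)), key=vals.count)
        for n in tree.preorder():
            if below[n.id] is not None:
                state_of[n.id] = below[n.id]
            elif n is tree.root:
                state_of[n.id] = majority
            else:
                state_of[n.id] = state_of[n.parent.id]
        states = tuple(sorted(set(vals)))

    segments = {
        b.id: [(b.length, state_of[b.id])] for b in tree.branches
    }
    painting = RegimePainting(
        segments=segments,
        tip_states={t.label: state_of[t.id] for t in tree.tips},
        states=states,
    )
    painting.validate(tree)
    return painting


# ---------------------------------------------------------------------------
# covariance


@dataclass
class PhyloCovariance:
    labels: list[str]
    matrix: np.ndarray
    components: dict[str, np.ndarray] | None = None  # per painted state


def covariance(tree: Phylogeny, painting: RegimePainting | None = None) -> PhyloCovariance:
    """Tip x tip shared root-to-MRCA path lengths (BM covariance, unit rate).

    With a painting, per-state component matrices accumulate only segments in
    that state; components sum to the total matrix.
    """
    mask = tree.tip_mask_below()
    n = len(tree.tips)
    total = np.zeros((n, n))
    comps = (
        {st: np.zeros((n, n)) for st in painting.states} if painting is not None else None
    )
    for b in tree.branches:
        m = mask[b.id].astype(float)
        outer = np.outer(m, m)
        total += b.length * outer
        if comps is not None:
            for seg_len, st in painting.segments[b.id]:
                comps[st] += seg_len * outer
    return PhyloCovariance(labels=tree.tip_labels, matrix=total, components=comps)


def safe_cholesky(V: np.ndarray, mean_depth: float | None = None):
    """Cholesky with a logged ridge fallback for near-singular covariances.

    Zero-length branches (polytomy resolution) duplicate covariance rows; a
    ridge of 1e-8 x mean root-to-tip depth restores positive definiteness.
    """
    try:
        return np.linalg.cholesky(V), 0.0
    except np.linalg.LinAlgError:
        pass
    if mean_depth is None:
        mean_depth = float(np.mean(np.diag(V)))
    ridge = 1e-8 * max(mean_depth, 1e-12)
    for _ in range(8):
        try:
            L = np.linalg.cholesky(V + ridge * np.eye(len(V)))
            warnings.warn(f"covariance singular; ridge {ridge:.3g} applied", stacklevel=2)
            return L, ridge
        except np.linalg.LinAlgError:
            ridge *= 10
    raise TreeError("covariance matrix singular even after ridge fallback")
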