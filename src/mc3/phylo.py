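"""A self-contained Bayesian phylogenetic target for exercising the sampler.

The model is deliberately minimal: a rooted ultrametric binary tree with
node heights in coalescent units, a Jukes-Cantor (JC69) substitution
likelihood computed by Felsenstein pruning, and a constant-size Kingman
coalescent prior on the genealogy with a log-normal prior on the
population size Ne.  Data are produced by the package's own simulators
(coalescent genealogy + JC69 site evolution), so the testbed has a known
ground truth and needs no external data.

Trees are stored as flat arrays: nodes ``0..n-1`` are tips (in taxa
order, height 0), nodes ``n..2n-2`` are internal; the root can be any
internal index after topology moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .targets import Proposal, Target

__all__ = [
    "Tree",
    "Alignment",
    "PhyloState",
    "PhyloTarget",
    "jc69_log_likelihood",
    "coalescent_log_density",
    "simulate_coalescent_tree",
    "simulate_jc69_alignment",
    "NNIProposal",
    "TreeScaleProposal",
    "NodeHeightProposal",
    "PopSizeScaleProposal",
]

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}


class Tree:
    """Rooted binary ultrametric tree with node heights (tips at 0)."""

    __slots__ = ("taxa", "parent", "children", "heights", "root")

    def __init__(self, taxa, parent, children, heights, root):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)  # (2n-1, 2); -1 for tips
        self.heights = np.asarray(heights, dtype=float)
        self.root = int(root)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_taxa - 1

    def copy(self) -> "Tree":
        return Tree(self.taxa, self.parent.copy(), self.children.copy(),
                    self.heights.copy(), self.root)

    def postorder(self) -> list[int]:
        """Children-before-parents node ordering."""
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            if self.children[node, 0] >= 0:
                stack.extend(self.children[node])
        order.reverse()
        return order

    def validate(self) -> None:
        """Raise ValueError on any violated tree invariant."""
        n = self.n_taxa
        if n < 2:
            raise ValueError("a tree needs at least two taxa")
        seen = np.zeros(self.n_nodes, dtype=bool)
        for node in self.postorder():
            if seen[node]:
                raise ValueError("cycle detected")
            seen[node] = True
            c1, c2 = self.children[node]
            if (c1 >= 0) != (c2 >= 0):
                raise ValueError(f"node {node} has exactly one child")
            if c1 >= 0:
                for c in (c1, c2):
                    if self.parent[c] != node:
                        raise ValueError("parent/child arrays disagree")
                    if self.heights[node] <= self.heights[c]:
                        raise ValueError("internal node not above its children")
            elif self.heights[node] != 0.0:
                raise ValueError("tips must sit at height 0")
        if not seen.all():
            raise ValueError("tree is not connected")
        if self.parent[self.root] != -1:
            raise ValueError("root must have no parent")

    def clades(self) -> set[frozenset]:
        """Descendant-taxon sets of all internal nodes (rooted clades)."""
        below: dict[int, frozenset] = {}
        out = set()
        for node in self.postorder():
            if self.children[node, 0] < 0:
                below[node] = frozenset((self.taxa[node],))
            else:
                c1, c2 = self.children[node]
                below[node] = below[c1] | below[c2]
                out.add(below[node])
        return out

    # -- text formats ----------------------------------------------------

    def newick(self, labels: dict | None = None) -> str:
        """Newick string; branch lengths derived from node heights.

        ``labels`` optionally remaps taxon names (used by the NEXUS
        translate block, which writes numeric tip ids).
        """
        def fmt(node: int) -> str:
            h_parent = self.heights[self.parent[node]] if self.parent[node] >= 0 else self.heights[node]
            length = float(h_parent - self.heights[node])
            if self.children[node, 0] < 0:
                name = self.taxa[node] if labels is None else labels[self.taxa[node]]
                return f"{name}:{length!r}"
            c1, c2 = self.children[node]
            return f"({fmt(c1)},{fmt(c2)}):{length!r}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, taxa: Sequence[str] | None = None) -> "Tree":
        """Parse a Newick string (via dendropy) into the array layout.

        Node heights are recovered from root-to-node path lengths under
        the ultrametric assumption (tips at height 0).
        """
        import dendropy

        try:
            dtree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:  # dendropy's reader errors are not ValueErrors
            raise ValueError(f"cannot parse newick: {exc}") from exc
        return _from_dendropy(cls, dtree, taxa)

    def to_data(self) -> dict:
        return {
            "taxa": list(self.taxa),
            "parent": [int(v) for v in self.parent],
            "children": [[int(a), int(b)] for a, b in self.children],
            "heights": [float(h) for h in self.heights],
            "root": self.root,
        }

    @classmethod
    def from_data(cls, data: dict) -> "Tree":
        return cls(data["taxa"], data["parent"], data["children"],
                   data["heights"], data["root"])


def _from_dendropy(cls, dtree, taxa=None) -> Tree:
    leaves = [lf for lf in dtree.leaf_node_iter()]
    labels = [lf.taxon.label.replace(" ", "_") for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxa in tree")
    if taxa is None:
        taxa = sorted(labels)
    elif set(taxa) != set(labels):
        raise ValueError("tree taxa do not match the expected taxon set")
    tip_index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    heights = np.zeros(n_nodes)

    # depths from root, then heights = max_depth - depth (tips clamp to 0)
    depth = {}
    for node in dtree.preorder_node_iter():
        edge = node.edge.length or 0.0
        depth[node] = (depth[node.parent_node] + edge) if node.parent_node else 0.0
    max_depth = max(depth[lf] for lf in leaves)

    next_internal = n
    index = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            idx = tip_index[node.taxon.label.replace(" ", "_")]
            heights[idx] = 0.0
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ValueError("only rooted binary trees are supported")
            idx = next_internal
            next_internal += 1
            heights[idx] = max_depth - depth[node]
            for k in kids:
                children[idx][0 if children[idx][0] < 0 else 1] = index[k]
                parent[index[k]] = idx
        index[node] = idx
    root = index[dtree.seed_node]
    tree = cls(list(taxa), parent, children, heights, root)
    tree.validate()
    return tree


@dataclass(frozen=True)
class Alignment:
    """Rectangular nucleotide matrix (taxa x sites), bases coded 0..3."""

    taxa: tuple[str, ...]
    codes: np.ndarray

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], sequences: Sequence[str]) -> "Alignment":
        if len(taxa) != len(sequences):
            raise ValueError("one sequence per taxon required")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxa")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError("alignment must be rectangular")
        codes = np.zeros((len(taxa), lengths.pop()), dtype=np.uint8)
        for i, seq in enumerate(sequences):
            for j, base in enumerate(seq.upper()):
                try:
                    codes[i, j] = _BASE_TO_CODE[base]
                except KeyError:
                    raise ValueError(f"unsupported symbol {base!r} in sequence {taxa[i]}")
        return cls(tuple(taxa), codes)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.codes[self.taxa.index(taxon)]
        return "".join(_BASES[c] for c in row)


@dataclass
class PhyloState:
    """The sampled state: genealogy plus coalescent population size."""

    tree: Tree
    pop_size: float


# ---------------------------------------------------------------------------
# likelihood and prior


def _jc69_probs(t: float, rate: float) -> tuple[float, float]:
    e = math.exp(-4.0 * rate * t / 3.0)
    return 0.25 + 0.75 * e, 0.25 - 0.25 * e


def jc69_log_likelihood(tree: Tree, alignment: Alignment, rate: float = 1.0) -> float:
    """Felsenstein pruning under JC69 with uniform root frequencies."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if alignment.n_sites == 0:
        raise ValueError("empty alignment")
    if set(alignment.taxa) != set(tree.taxa):
        raise ValueError("alignment taxa do not match tree taxa")
    patterns, weights = np.unique(alignment.codes, axis=1, return_counts=True)
    row_of = {t: i for i, t in enumerate(alignment.taxa)}
    return _pruning_loglik(tree, patterns, weights, row_of, rate)


def _pruning_loglik(tree, patterns, weights, row_of, rate) -> float:
    """Pruning over pre-compressed site patterns (hot path)."""
    n_pat = patterns.shape[1]
    partials = np.empty((tree.n_nodes, n_pat, 4))
    log_scale = 0.0
    for node in tree.postorder():
        c1, c2 = tree.children[node]
        if c1 < 0:
            obs = patterns[row_of[tree.taxa[node]]]
            p = np.zeros((n_pat, 4))
            p[np.arange(n_pat), obs] = 1.0
            partials[node] = p
            continue
        acc = np.ones((n_pat, 4))
        for child in (c1, c2):
            t = tree.heights[node] - tree.heights[child]
            ps, pd = _jc69_probs(t, rate)
            child_p = partials[child]
            acc *= (ps - pd) * child_p + pd * child_p.sum(axis=1, keepdims=True)
        # rescale to dodge underflow on deeper trees
        m = acc.max(axis=1, keepdims=True)
        log_scale += float(weights @ np.log(m[:, 0]))
        partials[node] = acc / m
    site_lik = 0.25 * partials[tree.root].sum(axis=1)
    return float(weights @ np.log(site_lik)) + log_scale


def coalescent_log_density(tree: Tree, pop_size: float) -> float:
    """Constant-size Kingman coalescent log density of an ultrametric tree.

    Each inter-event interval of duration ``tau`` with ``k`` extant
    lineages contributes ``-k(k-1) tau / (2 Ne)``; each of the ``n - 1``
    coalescent events contributes ``-log Ne``.
    """
    if pop_size <= 0:
        raise ValueError("pop_size must be positive")
    n = tree.n_taxa
    if np.any(tree.heights[:n] != 0.0):
        raise ValueError("tree must be ultrametric with tips at height 0")
    event_heights = np.sort(tree.heights[n:])
    log_p = -(n - 1) * math.log(pop_size)
    prev = 0.0
    k = n
    for h in event_heights:
        log_p -= k * (k - 1) * (h - prev) / (2.0 * pop_size)
        prev = h
        k -= 1
    return log_p


# ---------------------------------------------------------------------------
# simulators


def simulate_coalescent_tree(
    n_taxa: int,
    pop_size: float,
    rng: np.random.Generator,
    taxa: Sequence[str] | None = None,
) -> Tree:
    """Draw a genealogy from the constant-size Kingman coalescent."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if pop_size <= 0:
        raise ValueError("pop_size must be positive")
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n_taxa)]
    elif len(taxa) != n_taxa:
        raise ValueError("taxa labels must match n_taxa")
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    heights = np.zeros(n_nodes)

    active = list(range(n_taxa))
    t = 0.0
    nxt = n_taxa
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 * pop_size / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        heights[nxt] = t
        children[nxt] = (a, b)
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(taxa, parent, children, heights, nxt - 1)


def simulate_jc69_alignment(
    tree: Tree,
    n_sites: int,
    rate: float,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve iid-uniform root states down the tree under JC69."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    states = np.empty((tree.n_nodes, n_sites), dtype=np.uint8)
    order = tree.postorder()[::-1]  # parents before children
    states[tree.root] = rng.integers(0, 4, size=n_sites)
    for node in order:
        for child in tree.children[node]:
            if child < 0:
                continue
            t = tree.heights[node] - tree.heights[child]
            ps, _ = _jc69_probs(t, rate) if rate > 0 else (1.0, 0.0)
            keep = rng.random(n_sites) < (ps - (1 - ps) / 3)
            # with prob 4/3*(1-ps) draw uniformly among all four bases
            uniform = rng.integers(0, 4, size=n_sites)
            states[child] = np.where(keep, states[node], uniform)
    seqs = states[: tree.n_taxa]
    return Alignment(tuple(tree.taxa), seqs.copy())


# ---------------------------------------------------------------------------
# proposals on PhyloState


class NNIProposal(Proposal):
    """Nearest-neighbour interchange on a random internal edge.

    The move swaps the sibling of an internal node with one of its
    children; if the incoming sibling is not below the node's height the
    geometry is invalid and the move returns the rejection sentinel.
    Forward and reverse picks are equiprobable, so log-Hastings is 0.
    """

    name = "nni"

    def propose(self, state: PhyloState, rng, scale=None):
        tree = state.tree
        n = tree.n_taxa
        candidates = [v for v in range(n, tree.n_nodes) if v != tree.root]
        if not candidates:
            return None, 0.0
        c = candidates[int(rng.integers(len(candidates)))]
        p = tree.parent[c]
        c1, c2 = tree.children[p]
        s = c2 if c1 == c else c1  # sibling moves down
        g = tree.children[c][int(rng.integers(2))]  # grandchild moves up
        if tree.heights[s] >= tree.heights[c]:
            return None, 0.0
        new = tree.copy()
        pc = new.children[p]
        pc[0 if pc[0] == s else 1] = g
        cc = new.children[c]
        cc[0 if cc[0] == g else 1] = s
        new.parent[s] = c
        new.parent[g] = p
        return PhyloState(new, state.pop_size), 0.0


class TreeScaleProposal(Proposal):
    """Scale all internal node heights by m = exp(scale * (u - 1/2)).

    log-Hastings (including the Jacobian of scaling the ``n - 1``
    internal heights) is ``(n - 1) * log m`` for the log-uniform
    multiplier used here.
    """

    name = "tree_scale"

    def __init__(self, scale: float = 0.5):
        self.default_scale = scale

    def propose(self, state: PhyloState, rng, scale):
        tree = state.tree
        m = math.exp(scale * (rng.random() - 0.5))
        new = tree.copy()
        n = tree.n_taxa
        new.heights[n:] *= m
        return PhyloState(new, state.pop_size), (n - 1) * math.log(m)


class NodeHeightProposal(Proposal):
    """Uniform re-draw of one non-root internal node height within its
    bracket (max child height, parent height); symmetric."""

    name = "node_height"

    def propose(self, state: PhyloState, rng, scale=None):
        tree = state.tree
        n = tree.n_taxa
        candidates = [v for v in range(n, tree.n_nodes) if v != tree.root]
        if not candidates:
            return None, 0.0
        v = candidates[int(rng.integers(len(candidates)))]
        lo = float(tree.heights[tree.children[v]].max())
        hi = float(tree.heights[tree.parent[v]])
        if hi <= lo:
            return None, 0.0
        new = tree.copy()
        new.heights[v] = lo + (hi - lo) * rng.random()
        return PhyloState(new, state.pop_size), 0.0


class PopSizeScaleProposal(Proposal):
    """Multiplicative random walk on Ne; log-Hastings is log m."""

    name = "popsize_scale"

    def __init__(self, scale: float = 0.7):
        self.default_scale = scale

    def propose(self, state: PhyloState, rng, scale):
        m = math.exp(scale * (rng.random() - 0.5))
        return PhyloState(state.tree, state.pop_size * m), math.log(m)


# ---------------------------------------------------------------------------
# the target


class PhyloTarget(Target):
    """JC69 likelihood + Kingman coalescent prior + log-normal Ne prior.

    With ``alignment=None`` the likelihood is identically zero and the
    sampler explores the prior — the standard validation mode in which
    MCMC and MC3 marginals must both reproduce direct simulation.
    """

    def __init__(
        self,
        alignment: Alignment | None = None,
        taxa: Sequence[str] | None = None,
        rate: float = 1.0,
        ne_log_mean: float = 0.0,
        ne_log_sd: float = 1.0,
    ):
        if alignment is None and taxa is None:
            raise ValueError("either an alignment or a taxon set is required")
        self.alignment = alignment
        self.taxa = tuple(taxa) if taxa is not None else tuple(alignment.taxa)
        if alignment is not None and set(self.taxa) != set(alignment.taxa):
            raise ValueError("taxa and alignment disagree")
        self.rate = rate
        self.ne_log_mean = ne_log_mean
        self.ne_log_sd = ne_log_sd
        self.param_names = ("pop_size", "tree_height")
        if alignment is not None:
            # site-pattern compression once, not per likelihood call
            self._patterns, self._weights = np.unique(
                alignment.codes, axis=1, return_counts=True
            )
            self._row_of = {t: i for i, t in enumerate(alignment.taxa)}

    def initial_state(self, rng):
        pop_size = float(np.exp(self.ne_log_mean + self.ne_log_sd * rng.standard_normal()))
        tree = simulate_coalescent_tree(len(self.taxa), pop_size, rng, self.taxa)
        return PhyloState(tree, pop_size)

    def log_likelihood(self, state):
        if self.alignment is None:
            return 0.0
        return _pruning_loglik(state.tree, self._patterns, self._weights,
                               self._row_of, self.rate)

    def log_prior(self, state):
        ne = state.pop_size
        if ne <= 0:
            return -math.inf
        z = (math.log(ne) - self.ne_log_mean) / self.ne_log_sd
        log_ne_prior = -0.5 * z * z - math.log(ne * self.ne_log_sd * math.sqrt(2 * math.pi))
        return coalescent_log_density(state.tree, ne) + log_ne_prior

    def param_values(self, state):
        return (state.pop_size, float(state.tree.heights[state.tree.root]))

    def snapshot(self, state):
        return state.tree.copy()

    def default_proposals(self):
        return [
            (NNIProposal(), 1.0),
            (TreeScaleProposal(), 1.0),
            (NodeHeightProposal(), 2.0),
            (PopSizeScaleProposal(), 1.0),
        ]

    def state_to_data(self, state):
        return {"tree": state.tree.to_data(), "pop_size": state.pop_size}

    def state_from_data(self, data):
        return PhyloState(Tree.from_data(data["tree"]), float(data["pop_size"]))
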