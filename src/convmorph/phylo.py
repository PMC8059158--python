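"""Tree handling and Brownian-motion machinery.

The ``Phylogeny`` container is an array-based rooted tree (tips first,
then internal nodes in postorder-compatible indexing) built from Newick
via dendropy.  On top of it: the phylogenetic covariance matrix C,
maximum-likelihood (GLS / weighted squared-change) ancestral state
reconstruction, Brownian-motion rate estimation, and multivariate BM
simulation — the ingredients every downstream comparative statistic and
both convergence nulls share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np


@dataclass
class BMModel:
    """Multivariate Brownian motion: per-unit-time trait covariance R and root state."""

    rate_matrix: np.ndarray  # p x p, symmetric PSD
    root_state: np.ndarray  # length p
    rank: int | None = None

    def __post_init__(self) -> None:
        self.rate_matrix = np.atleast_2d(np.asarray(self.rate_matrix, float))
        self.root_state = np.atleast_1d(np.asarray(self.root_state, float))
        if not np.allclose(self.rate_matrix, self.rate_matrix.T):
            raise ValueError("rate matrix must be symmetric")

    @property
    def p(self) -> int:
        return self.rate_matrix.shape[0]


class Phylogeny:
    """Rooted tree with branch lengths (time units, e.g. My).

    Nodes ``0 .. n_tips-1`` are the tips in input order; internal nodes
    follow; ``parent[root] == -1``.  Polytomies are allowed; zero-length
    branches are replaced by ``1e-8 x tree depth`` with a warning.
    """

    def __init__(self, tip_labels, parent, blen, node_labels=None, child_order=None):
        self.tip_labels: list[str] = list(tip_labels)
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.n_tips = len(self.tip_labels)
        self.n_nodes = len(self.parent)
        self.node_labels = node_labels or [
            self.tip_labels[i] if i < self.n_tips else f"node{i}"
            for i in range(self.n_nodes)
        ]
        roots = np.where(self.parent < 0)[0]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        if len(set(self.tip_labels)) != self.n_tips:
            dupes = {t for t in self.tip_labels if self.tip_labels.count(t) > 1}
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
        if np.any(self.blen[np.arange(self.n_nodes) != self.root] < 0):
            raise ValueError("negative branch length")
        if child_order is not None:
            self.children: list[list[int]] = child_order
        else:
            self.children = [[] for _ in range(self.n_nodes)]
            for i in range(self.n_nodes):
                if i != self.root:
                    self.children[self.parent[i]].append(i)
        depth = self.depths()
        eps = 1e-8 * depth.max() if depth.max() > 0 else 1e-8
        zero = (self.blen == 0) & (np.arange(self.n_nodes) != self.root)
        if zero.any():
            warnings.warn(
                f"{zero.sum()} zero-length branch(es) replaced by {eps:.2e}"
            )
            self.blen = np.where(zero, eps, self.blen)

    # -- traversal helpers ---------------------------------------------------

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.blen[v]
        return d

    def ancestors(self, node: int) -> list[int]:
        """Node, its ancestors, up to and including the root."""
        path = [node]
        while path[-1] != self.root:
            path.append(int(self.parent[path[-1]]))
        return path

    def mrca(self, i: int, j: int) -> int:
        ai = self.ancestors(i)
        aj = set(self.ancestors(j))
        for v in ai:
            if v in aj:
                return v
        raise RuntimeError("disconnected tree")  # pragma: no cover

    def path_to_mrca(self, tip: int, mrca: int) -> list[int]:
        """Nodes from ``tip`` up to and including ``mrca``."""
        path = []
        v = tip
        while v != mrca:
            path.append(v)
            v = int(self.parent[v])
        path.append(mrca)
        return path

    def clade_nodes(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"tip {label!r} not in tree") from None

    # -- Newick I/O ----------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str, from_file: bool = False) -> "Phylogeny":
        kwargs = {"path": source} if from_file else {"data": source}
        try:
            dtree = dendropy.Tree.get(schema="newick", **kwargs)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
            raise ValueError(f"duplicate tip labels in Newick: {e}") from None
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        # preorder keeps the file's tip order (leaf_node_iter does not)
        leaves = [nd for nd in dtree.preorder_node_iter() if nd.is_leaf()]
        labels = []
        for lf in leaves:
            if lf.taxon is None or lf.taxon.label is None:
                raise ValueError("unlabeled tip in Newick")
            labels.append(lf.taxon.label)
        internals = [nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()]
        index = {id(nd): i for i, nd in enumerate(leaves)}
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        node_labels = [None] * n
        child_order: list[list[int]] = [[] for _ in range(n)]
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            node_labels[i] = (
                nd.taxon.label if nd.taxon else (nd.label or f"node{i}")
            )
            child_order[i] = [index[id(c)] for c in nd.child_nodes()]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise ValueError(
                        f"missing branch length on node {node_labels[i]!r}"
                    )
                blen[i] = nd.edge.length
        return cls(labels, parent, blen, node_labels=node_labels, child_order=child_order)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                s = self.tip_labels[v]
            else:
                s = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return s
            return f"{s}:{self.blen[v]:.10g}"

        return rec(self.root) + ";"


def read_newick(path) -> Phylogeny:
    """Parse a rooted Newick tree with branch lengths; tip order = file order."""
    return Phylogeny.from_newick(str(path), from_file=True)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Phylogenetic covariance


def phylo_covariance(tree: Phylogeny) -> np.ndarray:
    """n x n matrix of shared root-to-MRCA path lengths; diagonal = tip depths."""
    depth = tree.depths()
    n = tree.n_tips
    c = np.zeros((n, n))
    anc_sets = [dict.fromkeys(tree.ancestors(i)) for i in range(n)]
    for i in range(n):
        c[i, i] = depth[i]
        path_i = list(anc_sets[i])
        for j in range(i + 1, n):
            aj = anc_sets[j]
            mrca = next(v for v in path_i if v in aj)
            c[i, j] = c[j, i] = depth[mrca]
    return c


# ---------------------------------------------------------------------------
# Ancestral states (GLS / BM maximum likelihood)


def ancestral_operator(tree: Phylogeny) -> np.ndarray:
    """Linear map A (n_internal x n_tips) with internal states = A @ tip values.

    The BM maximum-likelihood (equivalently GLS, equivalently
    branch-length-weighted squared-change parsimony) reconstruction is the
    solution of the weighted tree Laplacian system; precomputing A lets
    simulation nulls reconstruct thousands of datasets with one matmul.
    """
    n, m = tree.n_tips, tree.n_nodes
    internal = [v for v in range(m) if v >= n]
    pos = {v: i for i, v in enumerate(internal)}
    lmat = np.zeros((len(internal), len(internal)))
    bmat = np.zeros((len(internal), n))
    for v in internal:
        i = pos[v]
        w_total = 0.0
        if v != tree.root:
            w = 1.0 / tree.blen[v]
            w_total += w
            lmat[i, pos[tree.parent[v]]] -= w
        for c in tree.children[v]:
            w = 1.0 / tree.blen[c]
            w_total += w
            if c < n:
                bmat[i, c] += w
            else:
                lmat[i, pos[c]] -= w
        lmat[i, i] += w_total
    return np.linalg.solve(lmat, bmat)


def ancestral_states(tree: Phylogeny, tip_values: np.ndarray) -> np.ndarray:
    """ML Brownian-motion states at every node; returns (n_nodes, p).

    Rows 0..n_tips-1 are the input tip values (tree tip order); the rest
    are reconstructed internal states.
    """
    x = np.atleast_2d(np.asarray(tip_values, float))
    if x.shape[0] != tree.n_tips:
        if x.shape[1] == tree.n_tips:
            x = x.T
        else:
            raise ValueError("tip_values rows must match tree tips")
    a = ancestral_operator(tree)
    out = np.empty((tree.n_nodes, x.shape[1]))
    out[: tree.n_tips] = x
    out[tree.n_tips :] = a @ x
    return out


# ---------------------------------------------------------------------------
# BM rate estimation and simulation


def estimate_bm_rate(tree: Phylogeny, tip_values: np.ndarray) -> BMModel:
    """Evolutionary rate matrix R and GLS root state from tip data.

    R = (X - 1 a')' C^{-1} (X - 1 a') / (n - 1), the multivariate GLS
    estimator, which equals the average outer product of phylogenetically
    independent contrasts on binary trees and handles polytomies natively.
    ``rank`` flags rank deficiency (p may exceed n - 1).
    """
    x = np.atleast_2d(np.asarray(tip_values, float))
    if x.ndim == 2 and x.shape[0] != tree.n_tips and x.shape[1] == tree.n_tips:
        x = x.T
    n = tree.n_tips
    if n < 3:
        raise ValueError("rate estimation needs at least 3 tips")
    c = phylo_covariance(tree)
    cinv = np.linalg.inv(c)
    one = np.ones(n)
    denom = one @ cinv @ one
    root = (one @ cinv @ x) / denom
    resid = x - root
    r = resid.T @ cinv @ resid / (n - 1)
    r = (r + r.T) / 2.0
    return BMModel(rate_matrix=r, root_state=root, rank=int(np.linalg.matrix_rank(r)))


def _rate_factor(rate_matrix: np.ndarray) -> np.ndarray:
    """Matrix square-root factor L with L L' = R; errors on non-PSD input."""
    evals, evecs = np.linalg.eigh(rate_matrix)
    tol = -1e-10 * max(evals.max(), 1.0)
    if evals.min() < tol:
        raise ValueError("rate matrix is not positive semidefinite")
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_bm(
    tree: Phylogeny,
    model: BMModel,
    n_sims: int,
    seed: int | np.random.SeedSequence | None = None,
    return_nodes: bool = False,
) -> np.ndarray:
    """Simulate multivariate BM along the tree.

    Returns tip values of shape (n_sims, n_tips, p); with
    ``return_nodes`` the full (n_sims, n_nodes, p) array.  Per-simulation
    random streams are spawned deterministically from the seed, so any
    prefix of the simulations is reproducible.
    """
    lfac = _rate_factor(model.rate_matrix)
    p = model.p
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    order = tree.preorder()
    out = np.empty((n_sims, tree.n_nodes, p))
    sqrt_bl = np.sqrt(tree.blen)
    for s in range(n_sims):
        rng = np.random.default_rng(children[s])
        z = rng.standard_normal((tree.n_nodes, p))
        states = out[s]
        states[tree.root] = model.root_state
        for v in order:
            if v != tree.root:
                states[v] = states[tree.parent[v]] + sqrt_bl[v] * (z[v] @ lfac.T)
    if return_nodes:
        return out
    return out[:, : tree.n_tips, :]
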