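"""Ordination of aligned shapes: PCA, variance bookkeeping, phylomorphospace.

PCA here is the ordinary (unweighted) eigendecomposition of the
covariance of vectorized Procrustes coordinates; the phylogeny is only
projected in afterwards, by placing internal nodes at their
reconstructed ancestral scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from convmorph.landmarks import AlignedShapes, species_mean_shapes
from convmorph.phylo import Phylogeny, ancestral_states


@dataclass
class ShapeSpace:
    """Principal-component ordination of a set of shapes."""

    scores: np.ndarray  # N x m
    eigenvalues: np.ndarray  # length m
    pct_variance: np.ndarray  # length m, sums to 100 over non-null axes
    loadings: np.ndarray  # m x D basis rows
    reference_mean: np.ndarray  # the centred-data mean (K x 3 for shapes)
    ids: list[str]
    level: str = "specimen"

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def pca_matrix(x: np.ndarray, ids=None, level: str = "specimen", mean_shape_dims=None) -> ShapeSpace:
    """PCA of a plain N x D data matrix (rows = observations)."""
    x = np.asarray(x, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 observations")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    keep = s**2 > max(s.max() ** 2 * 1e-12, 1e-300)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic sign: largest-magnitude loading of each axis is positive
    for a in range(len(s)):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] = -vt[a]
            u[:, a] = -u[:, a]
    eigenvalues = s**2 / (n - 1)
    pct = 100.0 * eigenvalues / eigenvalues.sum()
    ref = mean if mean_shape_dims is None else mean.reshape(mean_shape_dims)
    return ShapeSpace(
        scores=u * s,
        eigenvalues=eigenvalues,
        pct_variance=pct,
        loadings=vt,
        reference_mean=ref,
        ids=list(ids) if ids is not None else [str(i) for i in range(n)],
        level=level,
    )


def pca(aligned: AlignedShapes, level: str = "specimen", tree: Phylogeny | None = None) -> ShapeSpace:
    """Principal components of vectorized Procrustes coordinates.

    ``level="specimen"`` ordinates individual configurations;
    ``level="species_mean"`` first averages Procrustes coordinates per
    species (tree tip order when a tree is given) and ordinates the means.
    """
    if level == "specimen":
        x = aligned.flat()
        ids = list(aligned.specimen_ids)
    elif level == "species_mean":
        ids, means = species_mean_shapes(aligned, tree=tree)
        x = means.reshape(len(ids), -1)
    else:
        raise ValueError(f"unknown PCA level {level!r}")
    k = aligned.n_landmarks
    return pca_matrix(x, ids=ids, level=level, mean_shape_dims=(k, 3))


def select_pcs(space_or_pct, threshold_pct: float) -> list[int]:
    """Indices (0-based, in axis order) of PCs explaining strictly more
    than ``threshold_pct`` percent of the variance."""
    if not 0 < threshold_pct < 100:
        raise ValueError("threshold must be in (0, 100)")
    pct = space_or_pct.pct_variance if isinstance(space_or_pct, ShapeSpace) else np.asarray(space_or_pct, float)
    return [i for i, v in enumerate(pct) if v > threshold_pct]


def phylomorphospace_coords(
    space: ShapeSpace, tree: Phylogeny, axes: tuple[int, ...] = (0, 1)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node coordinates for projecting the phylogeny into a PC scatter.

    Tips sit at their species-mean scores; internal nodes at the ML
    ancestral reconstruction of those scores.  Returns ``(nodes, edges)``
    tables ready for plotting.
    """
    if space.level != "species_mean":
        raise ValueError("phylomorphospace needs species-mean scores")
    missing = [t for t in tree.tip_labels if t not in space.ids]
    extra = [s for s in space.ids if s not in tree.tip_labels]
    if missing or extra:
        raise ValueError(
            f"score/tree tip mismatch: missing from scores {missing}, "
            f"absent from tree {extra}"
        )
    order = [space.ids.index(t) for t in tree.tip_labels]
    tip_scores = space.scores[order][:, list(axes)]
    node_states = ancestral_states(tree, tip_scores)
    nodes = pd.DataFrame(
        {
            "node": tree.node_labels,
            "is_tip": [i < tree.n_tips for i in range(tree.n_nodes)],
            **{f"PC{a + 1}": node_states[:, k] for k, a in enumerate(axes)},
        }
    )
    edges = pd.DataFrame(
        {
            "parent": [tree.node_labels[tree.parent[v]] for v in range(tree.n_nodes) if v != tree.root],
            "child": [tree.node_labels[v] for v in range(tree.n_nodes) if v != tree.root],
        }
    )
    return nodes, edges


def scores_table(space: ShapeSpace) -> pd.DataFrame:
    df = pd.DataFrame(
        space.scores, columns=[f"PC{i + 1}" for i in range(space.n_axes)]
    )
    df.insert(0, "id", space.ids)
    return df
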