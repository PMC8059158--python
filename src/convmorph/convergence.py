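"""Convergence testing: UPGMA candidates, C1-C4 metrics, phenotypic angles.

Two complementary tests are implemented.  The distance-based C1-C4
family compares the realized phenotypic distance between two tips
(D_tip) with the maximal distance between any two nodes on their
lineages since divergence (D_max): C1 = 1 - D_tip/D_max is the
proportion of the maximal lineage distance closed by evolution, C2 the
raw magnitude D_max - D_tip, and C3/C4 scale C2 by the total phenotypic
change along the two lineages / the whole clade descending from the
MRCA.  Significance comes from re-measuring the metrics on Brownian
motion simulations parameterized by the rate matrix estimated from the
data.  The angle test measures theta between the two species'
tip-minus-MRCA phenotypic vectors and compares it against angles from
random reassignments of the convergent "state" across the tips (small
angles = convergence, one-sided).

The module also houses the Benjamini-Hochberg step-up FDR procedure and
the maximal-convergence decision rule that combines both tests across
the total / facial / neurocranial datasets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from convmorph.phylo import (
    Phylogeny,
    ancestral_operator,
    ancestral_states,
    estimate_bm_rate,
    simulate_bm,
)

DATASETS = ("total", "facial", "neurocranial")


# ---------------------------------------------------------------------------
# UPGMA candidate selection


@dataclass
class CandidateSet:
    focal: str
    cluster: list[str]  # members of the focal cluster, focal included
    linkage_matrix: np.ndarray
    merge_heights: np.ndarray

    @property
    def candidates(self) -> list[str]:
        return [s for s in self.cluster if s != self.focal]


def upgma_candidates(
    scores: np.ndarray,
    species: list[str],
    focal: str,
    cut: str | float = "gap",
) -> CandidateSet:
    """Candidate convergent species from average-linkage clustering.

    Euclidean distances on the supplied (species x selected-PC) scores
    are agglomerated by UPGMA; the candidate set is the phenogram
    cluster containing the focal species at a cut chosen by ``cut``:

    * ``"gap"`` (default) — cut just below the largest jump in merge
      height along the focal cluster's merge path, the classic
      dendrogram-gap heuristic; the candidate set is the focal cluster
      as it stood before that jump, i.e. the tightest phenotypically
      coherent group around the focal species.
    * ``"penultimate"`` — the focal species' second-to-last merge (its
      side of the final split of the phenogram).
    * a number — an explicit merge-height cut.

    Equal-distance ties follow the input index order (scipy's
    deterministic agglomeration).
    """
    if focal not in species:
        raise ValueError(f"focal species {focal!r} not among the scored species")
    if len(species) < 3:
        raise ValueError("need at least 3 species to cluster")
    z = linkage(np.asarray(scores, float), method="average", metric="euclidean")
    members: dict[int, list[int]] = {i: [i] for i in range(len(species))}
    focal_idx = species.index(focal)
    focal_cluster = focal_idx
    cut_height = cut if isinstance(cut, (int, float)) else None
    focal_history: list[list[int]] = [[focal_idx]]
    focal_heights: list[float] = []
    for t, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        new = len(species) + t
        members[new] = members[a] + members[b]
        if cut_height is not None and h > cut_height:
            break
        if focal_cluster in (a, b):
            focal_cluster = new
            focal_history.append(members[new])
            focal_heights.append(float(h))
    if cut_height is not None:
        cluster_idx = focal_history[-1]
    elif cut == "penultimate":
        cluster_idx = focal_history[-2] if len(focal_history) >= 2 else focal_history[-1]
    elif cut == "gap":
        if len(focal_heights) < 2:
            cluster_idx = focal_history[-1]
        else:
            h = np.asarray(focal_heights)
            gaps = np.diff(np.log(h + 1e-12 * h.max()))  # scale-free gap
            # a candidate set is a group: only cuts leaving the focal with
            # at least two companions are eligible (fall back to the last)
            eligible = [
                k for k in range(1, len(focal_history) - 1)
                if len(focal_history[k]) >= 3
            ]
            if not eligible:
                cluster_idx = focal_history[-2]
            else:
                best = max(eligible, key=lambda k: gaps[k - 1])
                cluster_idx = focal_history[best]
    else:
        raise ValueError(f"unknown cut rule {cut!r}")
    return CandidateSet(
        focal=focal,
        cluster=[species[i] for i in sorted(cluster_idx)],
        linkage_matrix=z,
        merge_heights=z[:, 2].copy(),
    )


def dendrogram_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Ultrametric Newick string of a linkage matrix (heights halved, as node depths)."""
    from scipy.cluster.hierarchy import to_tree

    root = to_tree(linkage_matrix)

    def rec(node, parent_height):
        height = node.dist / 2.0
        bl = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        left = rec(node.left, height)
        right = rec(node.right, height)
        return f"({left},{right}):{bl:.10g}"

    h = root.dist / 2.0
    return f"({rec(root.left, h)},{rec(root.right, h)});"


# ---------------------------------------------------------------------------
# C1-C4 distance metrics


@dataclass
class CMetrics:
    c1: float
    c2: float
    c3: float
    c4: float
    d_tip: float
    d_max: float
    l_tot_lineage: float
    l_tot_clade: float


def _pair_geometry(tree: Phylogeny, i: int, j: int):
    mrca = tree.mrca(i, j)
    path_i = tree.path_to_mrca(i, mrca)
    path_j = tree.path_to_mrca(j, mrca)
    lineage_edges = path_i[:-1] + path_j[:-1]  # child nodes of branches on both paths
    clade_edges = [v for v in tree.clade_nodes(mrca) if v != mrca]
    return mrca, path_i, path_j, lineage_edges, clade_edges


def _c_from_states(states, i, j, path_i, path_j, lineage_edges, clade_edges, parent):
    """Compute the C metrics from node-state arrays; ``states`` is (..., n_nodes, p)."""
    d_tip = np.linalg.norm(states[..., i, :] - states[..., j, :], axis=-1)
    a = states[..., path_i, :]
    b = states[..., path_j, :]
    cross = np.linalg.norm(a[..., :, None, :] - b[..., None, :, :], axis=-1)
    d_max = cross.max(axis=(-1, -2))
    edge_len = lambda edges: np.linalg.norm(
        states[..., edges, :] - states[..., [parent[v] for v in edges], :], axis=-1
    ).sum(axis=-1)
    l_lin = edge_len(lineage_edges)
    l_clade = edge_len(clade_edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = np.where(d_max > 0, 1.0 - d_tip / d_max, 0.0)
        c2 = d_max - d_tip
        c3 = np.where(l_lin > 0, c2 / l_lin, 0.0)
        c4 = np.where(l_clade > 0, c2 / l_clade, 0.0)
    return c1, c2, c3, c4, d_tip, d_max, l_lin, l_clade


def c_metrics(
    tree: Phylogeny,
    tip_values: np.ndarray,
    pair: tuple[str, str],
    node_states: np.ndarray | None = None,
) -> CMetrics:
    """Distance-based convergence metrics C1-C4 for one species pair.

    Ancestral states are the BM maximum-likelihood reconstruction unless
    ``node_states`` (n_nodes x p, tips first in tree order) injects them
    directly.  D_max searches all node pairs (u, v) with u on the
    MRCA->tip1 path and v on the MRCA->tip2 path, tips and MRCA included.
    """
    i, j = (tree.tip_index(s) for s in pair)
    if i == j:
        raise ValueError("convergence metrics need two distinct species")
    if node_states is None:
        node_states = ancestral_states(tree, tip_values)
    else:
        node_states = np.asarray(node_states, float)
        if node_states.shape[0] != tree.n_nodes:
            raise ValueError("injected node_states must cover every node")
    mrca, path_i, path_j, lineage_edges, clade_edges = _pair_geometry(tree, i, j)
    vals = _c_from_states(
        node_states, i, j, path_i, path_j, lineage_edges, clade_edges, tree.parent
    )
    return CMetrics(*(float(v) for v in vals))


def c_significance_many(
    tree: Phylogeny,
    tip_values: np.ndarray,
    pairs: list[tuple[str, str]],
    n_sims: int = 1000,
    seed=None,
) -> dict:
    """Simulation p-values for C1-C4 for many pairs against one shared null.

    The rate matrix is estimated once from the tip data; ``n_sims`` BM
    datasets are simulated on the tree and their ancestral states
    reconstructed once, then every pair's metrics are measured on the
    same simulated datasets: p = (#{sim metric >= observed} + 1) /
    (n_sims + 1).
    """
    if n_sims < 100:
        raise ValueError("need at least 100 simulations")
    x = np.atleast_2d(np.asarray(tip_values, float))
    model = estimate_bm_rate(tree, x)
    if not np.any(model.rate_matrix):
        raise ValueError("degenerate (all-zero) rate matrix; no variation to simulate")
    sims = simulate_bm(tree, model, n_sims, seed=seed)  # (S, n, p)
    aop = ancestral_operator(tree)
    anc = np.einsum("ij,sjp->sip", aop, sims)
    states = np.concatenate([sims, anc], axis=1)
    results = {}
    for pair in pairs:
        obs = c_metrics(tree, x, pair)
        i, j = (tree.tip_index(s) for s in pair)
        _, path_i, path_j, lineage_edges, clade_edges = _pair_geometry(tree, i, j)
        c1, c2, c3, c4, *_ = _c_from_states(
            states, i, j, path_i, path_j, lineage_edges, clade_edges, tree.parent
        )
        out = {"observed": obs, "n_sims": n_sims}
        for name, sim_vals, obs_val in (
            ("c1", c1, obs.c1),
            ("c2", c2, obs.c2),
            ("c3", c3, obs.c3),
            ("c4", c4, obs.c4),
        ):
            out[f"p_{name}"] = float((np.sum(sim_vals >= obs_val) + 1) / (n_sims + 1))
        results[pair] = out
    return results


def c_significance(
    tree: Phylogeny,
    tip_values: np.ndarray,
    pair: tuple[str, str],
    n_sims: int = 1000,
    seed=None,
) -> dict:
    """Simulation p-values for C1-C4 under a Brownian-motion null (one pair)."""
    return c_significance_many(tree, tip_values, [pair], n_sims=n_sims, seed=seed)[pair]


# ---------------------------------------------------------------------------
# Phenotypic vector angle test


def theta_tables(tree: Phylogeny, tip_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise phenotypic angles for every tip pair.

    Returns symmetric (n_tips x n_tips) matrices of theta (degrees) and
    theta/time; each pair's vectors run from the reconstructed MRCA
    phenotype to the two tips.  Degenerate pairs (a tip coinciding with
    its MRCA reconstruction) are NaN.  Computing the full table once
    makes the shuffle null for any state group a pure lookup.
    """
    states = ancestral_states(tree, tip_values)
    depth = tree.depths()
    n = tree.n_tips
    tmat = np.full((n, n), np.nan)
    ttime = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            mrca = tree.mrca(i, j)
            vi = states[i] - states[mrca]
            vj = states[j] - states[mrca]
            ni, nj = np.linalg.norm(vi), np.linalg.norm(vj)
            if ni < 1e-12 or nj < 1e-12:
                continue
            cosang = np.clip(vi @ vj / (ni * nj), -1.0, 1.0)
            theta = float(np.degrees(np.arccos(cosang)))
            elapsed = (depth[i] - depth[mrca]) + (depth[j] - depth[mrca])
            tmat[i, j] = tmat[j, i] = theta
            ttime[i, j] = ttime[j, i] = theta / elapsed
    return tmat, ttime


def theta_convergence(
    tree: Phylogeny,
    tip_values: np.ndarray,
    group: list[str],
    n_shuffles: int = 1000,
    seed=None,
    tables: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Phenotypic-vector angle test for a convergent state group.

    Each species' phenotypic vector runs from the reconstructed MRCA
    phenotype to its tip; theta is the angle between the two vectors
    (mean over pairs for groups larger than two), and theta_time divides
    it by the patristic path length between the species through their
    MRCA — the adjustment that makes angles comparable across divergence
    depths (under Brownian motion close relatives have small angles by
    inheritance alone).  The null shuffles the state labels across the
    tips ``n_shuffles`` times; p is the one-sided (+1-corrected)
    fraction of shuffled mean time-adjusted angles <= the observed one,
    small angles for the elapsed time indicating convergence.
    """
    if len(group) < 2:
        raise ValueError("state group needs at least 2 species")
    idx = [tree.tip_index(s) for s in group]
    if tables is None:
        tables = theta_tables(tree, tip_values)
    tmat, ttime = tables
    combos = list(itertools.combinations(range(len(idx)), 2))
    obs_t = np.array([tmat[idx[a], idx[b]] for a, b in combos])
    obs_tt = np.array([ttime[idx[a], idx[b]] for a, b in combos])
    if np.isnan(obs_t).any():
        raise ValueError(
            "zero-length phenotypic vector (tip equals its MRCA reconstruction)"
        )
    theta = float(obs_t.mean())
    theta_time = float(obs_tt.mean())
    rng = np.random.default_rng(seed)
    g = len(idx)
    # random g-subsets of tips, vectorized: top-g of random keys per shuffle
    draws = np.argsort(rng.random((n_shuffles, tree.n_tips)), axis=1)[:, :g]
    null = np.stack(
        [ttime[draws[:, a], draws[:, b]] for a, b in combos], axis=1
    ).mean(axis=1)
    n_le = int(np.sum(null <= theta_time))  # NaN rows compare False
    p = (n_le + 1) / (n_shuffles + 1)
    return {"theta": theta, "theta_time": theta_time, "p_theta": float(p)}


# ---------------------------------------------------------------------------
# Multiple testing and the decision rule


def bh_fdr(p_values, alpha: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(significant_flags, adjusted_p)``; adjusted p-values are
    the usual step-up minima capped at 1, and a result is flagged when
    its adjusted p is <= alpha.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted <= alpha, adjusted


def maximal_convergence_call(
    results: pd.DataFrame, alpha: float = 0.10, family: str = "dataset_method"
) -> pd.DataFrame:
    """Apply FDR control and the maximal-convergence decision rule.

    ``results`` is a long table with columns ``species``, ``dataset``
    (total / facial / neurocranial), ``p_c1`` and ``p_theta`` (raw
    simulation / shuffle p-values), plus optional ``c1`` and ``theta``
    columns carried through.  BH adjustment is applied within families
    given by ``family``: ``"dataset_method"`` (one family per dataset x
    test, the default), ``"dataset"`` (both tests pooled per dataset) or
    ``"global"``.  A species is maximally convergent when it is
    significant under BOTH tests in the total dataset AND under both
    tests in at least one patch dataset.  Species missing any dataset are
    excluded with a warning.
    """
    df = results.copy()
    need = {"species", "dataset", "p_c1", "p_theta"}
    if not need <= set(df.columns):
        raise ValueError(f"results table must have columns {sorted(need)}")
    counts = df.groupby("species")["dataset"].apply(lambda s: set(s))
    incomplete = [sp for sp, ds in counts.items() if not set(DATASETS) <= ds]
    if incomplete:
        warnings.warn(
            f"species missing datasets excluded from the call: {incomplete}"
        )
        df = df[~df["species"].isin(incomplete)]
    for col in ("p_c1", "p_theta"):
        df["sig_" + col[2:]] = False
        df["adj_" + col[2:]] = np.nan
        if family == "dataset_method":
            groups = [df["dataset"] == ds for ds in DATASETS]
        elif family == "dataset":
            groups = [df["dataset"] == ds for ds in DATASETS]
        elif family == "global":
            groups = [pd.Series(True, index=df.index)]
        else:
            raise ValueError(f"unknown BH family {family!r}")
        if family == "dataset":
            # pool both methods within a dataset: adjust the concatenation
            for mask in groups:
                pooled = pd.concat([df.loc[mask, "p_c1"], df.loc[mask, "p_theta"]])
                flags, adj = bh_fdr(pooled.to_numpy(), alpha)
                half = mask.sum()
                which = 0 if col == "p_c1" else 1
                df.loc[mask, "sig_" + col[2:]] = flags[which * half : (which + 1) * half]
                df.loc[mask, "adj_" + col[2:]] = adj[which * half : (which + 1) * half]
        else:
            for mask in groups:
                if mask.sum() == 0:
                    continue
                flags, adj = bh_fdr(df.loc[mask, col].to_numpy(), alpha)
                df.loc[mask, "sig_" + col[2:]] = flags
                df.loc[mask, "adj_" + col[2:]] = adj
    rows = []
    for sp, sub in df.groupby("species", sort=False):
        by_ds = {r["dataset"]: r for _, r in sub.iterrows()}
        both = {ds: bool(by_ds[ds]["sig_c1"] and by_ds[ds]["sig_theta"]) for ds in DATASETS}
        row = {"species": sp}
        for ds in DATASETS:
            for k in ("c1", "theta"):
                if k in sub.columns:
                    row[f"{k}_{ds}"] = by_ds[ds][k]
            row[f"sig_c1_{ds}"] = bool(by_ds[ds]["sig_c1"])
            row[f"sig_theta_{ds}"] = bool(by_ds[ds]["sig_theta"])
        row["maximal_convergent"] = both["total"] and (both["facial"] or both["neurocranial"])
        rows.append(row)
    return pd.DataFrame(rows)
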