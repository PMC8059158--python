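"""UPGMA candidates, C1-C4 metrics, phenotypic angle test, FDR, decision rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from convmorph.convergence import (
    bh_fdr,
    c_metrics,
    c_significance,
    dendrogram_newick,
    maximal_convergence_call,
    theta_convergence,
    upgma_candidates,
)
from convmorph.phylo import Phylogeny, ancestral_states

from conftest import random_yule


# ---------------------------------------------------------------------------
# UPGMA


def test_upgma_hand_worked_example():
    """Four collinear points at 0, 2, 5, 10: agglomeration worked by hand.

    d(a,b)=2 -> merge at 2; d({ab},c) = (5+3)/2 = 4 < d(c,d)=5 -> merge at 4;
    final height = (10+8+5)/3 = 23/3.
    """
    scores = np.array([[0.0], [2.0], [5.0], [10.0]])
    cs = upgma_candidates(scores, ["a", "b", "c", "d"], focal="a", cut="penultimate")
    np.testing.assert_allclose(cs.merge_heights, [2.0, 4.0, 23.0 / 3.0], atol=1e-12)
    assert cs.cluster == ["a", "b", "c"]  # focal side of the final merge
    assert cs.candidates == ["b", "c"]


def test_upgma_coincident_species_merge_first():
    scores = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0], [9.0, 0.0]])
    cs = upgma_candidates(scores, ["a", "b", "c", "d"], focal="a")
    assert cs.merge_heights[0] == 0.0
    assert set(cs.cluster) >= {"a", "b"}


def test_upgma_tie_case_deterministic():
    # equilateral simplex: all pairwise distances equal
    scores = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    a = upgma_candidates(scores, ["x", "y", "z"], focal="y")
    b = upgma_candidates(scores, ["x", "y", "z"], focal="y")
    np.testing.assert_array_equal(a.linkage_matrix, b.linkage_matrix)
    assert a.cluster == b.cluster
    assert np.isclose(a.merge_heights[0], a.merge_heights[-1], atol=1e-9) or (
        a.merge_heights[-1] >= a.merge_heights[0]
    )


def test_upgma_focal_required():
    with pytest.raises(ValueError, match="nope"):
        upgma_candidates(np.eye(3), ["a", "b", "c"], focal="nope")


def test_dendrogram_newick_roundtrip():
    rng = np.random.default_rng(2)
    scores = rng.standard_normal((6, 3))
    labels = [f"s{i}" for i in range(6)]
    cs = upgma_candidates(scores, labels, focal="s0")
    tree = Phylogeny.from_newick(dendrogram_newick(cs.linkage_matrix, labels))
    assert sorted(tree.tip_labels) == labels
    depths = tree.depths()[: tree.n_tips]
    np.testing.assert_allclose(depths, depths[0], atol=1e-6)  # ultrametric


# ---------------------------------------------------------------------------
# C metrics


def _inject_states(tree, rng, p=3):
    return rng.standard_normal((tree.n_nodes, p))


def _brute_force_c(tree, states, i, j):
    """Independent enumeration of the C-metric ingredients."""
    anc_i = {i}
    v = i
    while v != tree.root:
        v = int(tree.parent[v])
        anc_i.add(v)
    v = j
    mrca = j if j in anc_i else None
    while mrca is None:
        v = int(tree.parent[v])
        if v in anc_i:
            mrca = v
    path = lambda tip: [tip] + list(
        itertools.takewhile(lambda u: True, _walk(tree, tip, mrca))
    )
    pi = _walk_list(tree, i, mrca)
    pj = _walk_list(tree, j, mrca)
    d_tip = np.linalg.norm(states[i] - states[j])
    d_max = max(
        np.linalg.norm(states[u] - states[v]) for u in pi for v in pj
    )
    lineage = [u for u in pi if u != mrca] + [u for u in pj if u != mrca]
    l_lin = sum(np.linalg.norm(states[u] - states[tree.parent[u]]) for u in lineage)
    clade = []
    stack = [mrca]
    while stack:
        u = stack.pop()
        clade.append(u)
        stack.extend(tree.children[u])
    l_clade = sum(
        np.linalg.norm(states[u] - states[tree.parent[u]]) for u in clade if u != mrca
    )
    return d_tip, d_max, l_lin, l_clade


def _walk(tree, tip, mrca):
    v = tip
    while v != mrca:
        v = int(tree.parent[v])
        yield v


def _walk_list(tree, tip, mrca):
    return [tip] + list(_walk(tree, tip, mrca))


@pytest.mark.parametrize("seed", range(100))
def test_c_metrics_against_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    tree = random_yule(6, seed)
    states = _inject_states(tree, rng)
    i, j = rng.choice(6, size=2, replace=False)
    pair = (tree.tip_labels[i], tree.tip_labels[j])
    res = c_metrics(tree, states[: tree.n_tips], pair, node_states=states)
    d_tip, d_max, l_lin, l_clade = _brute_force_c(tree, states, i, j)
    assert res.d_tip == pytest.approx(d_tip, abs=1e-12)
    assert res.d_max == pytest.approx(d_max, abs=1e-12)
    assert res.l_tot_lineage == pytest.approx(l_lin, abs=1e-12)
    assert res.l_tot_clade == pytest.approx(l_clade, abs=1e-12)
    assert res.c1 == pytest.approx(1 - d_tip / d_max, abs=1e-12)
    assert res.c2 == pytest.approx(d_max - d_tip, abs=1e-12)
    assert res.c3 == pytest.approx((d_max - d_tip) / l_lin, abs=1e-12)
    assert res.c4 == pytest.approx((d_max - d_tip) / l_clade, abs=1e-12)
    assert 0.0 <= res.c1 <= 1.0
    assert res.c2 >= 0.0


def test_c_metrics_same_species_error(three_tip_tree):
    with pytest.raises(ValueError, match="distinct"):
        c_metrics(three_tip_tree, np.eye(3), ("A", "A"))


def test_c_metrics_uses_ml_reconstruction_by_default(three_tip_tree):
    x = np.array([[1.0, 0.0], [0.0, 1.0], [3.0, -1.0]])
    implicit = c_metrics(three_tip_tree, x, ("A", "C"))
    states = ancestral_states(three_tip_tree, x)
    explicit = c_metrics(three_tip_tree, x, ("A", "C"), node_states=states)
    assert implicit == explicit


def test_c_significance_null_and_determinism(three_tip_tree):
    tree = random_yule(8, 5)
    rng = np.random.default_rng(1)
    x = rng.standard_normal((8, 3))
    pair = (tree.tip_labels[0], tree.tip_labels[4])
    a = c_significance(tree, x, pair, n_sims=120, seed=7)
    b = c_significance(tree, x, pair, n_sims=120, seed=7)
    assert a["p_c1"] == b["p_c1"]
    assert 0 < a["p_c1"] <= 1
    with pytest.raises(ValueError, match="at least 100"):
        c_significance(tree, x, pair, n_sims=10, seed=0)
    with pytest.raises(ValueError, match="degenerate"):
        c_significance(tree, np.ones((8, 2)), pair, n_sims=120, seed=0)


def test_c1_extreme_p_when_not_convergent():
    """Observed C1 = 0 (tips maximally distant) cannot beat the null."""
    tree = random_yule(6, 3)
    rng = np.random.default_rng(0)
    x = rng.standard_normal((6, 2)) * 0.1
    i, j = 0, 5
    x[i] = [10.0, 0.0]
    x[j] = [-10.0, 0.0]
    pair = (tree.tip_labels[i], tree.tip_labels[j])
    obs = c_metrics(tree, x, pair)
    assert obs.c1 == pytest.approx(0.0, abs=1e-9)
    res = c_significance(tree, x, pair, n_sims=150, seed=2)
    assert res["p_c1"] > 0.5


# ---------------------------------------------------------------------------
# Theta


def _star4(values):
    tree = Phylogeny.from_newick("(A:1,B:1,C:1,D:1);")
    return tree, np.asarray(values, float)


@pytest.mark.parametrize(
    "vb, expected",
    [
        ([2.0, 0.0], 0.0),  # parallel
        ([0.0, 1.0], 90.0),  # orthogonal: phenotypic dissimilarity
        ([1.0, 1.0], 45.0),
    ],
)
def test_theta_analytic_angles(vb, expected):
    # root reconstruction sits at the origin by symmetry, so tip values ARE
    # the phenotypic vectors
    va = [1.0, 0.0]
    tree, x = _star4([va, vb, [-va[0], -va[1]], [-vb[0], -vb[1]]])
    res = theta_convergence(tree, x, ["A", "B"], n_shuffles=20, seed=0)
    assert res["theta"] == pytest.approx(expected, abs=1e-8)
    assert res["theta_time"] == pytest.approx(expected / 2.0, abs=1e-8)


def test_theta_rotation_invariance():
    tree = random_yule(10, 8)
    rng = np.random.default_rng(4)
    x = rng.standard_normal((10, 4))
    q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
    group = [tree.tip_labels[1], tree.tip_labels[6]]
    a = theta_convergence(tree, x, group, n_shuffles=99, seed=5)
    b = theta_convergence(tree, x @ q, group, n_shuffles=99, seed=5)
    assert a["theta"] == pytest.approx(b["theta"], abs=1e-8)
    assert a["p_theta"] == b["p_theta"]


def test_theta_group_of_three():
    tree = random_yule(12, 13)
    rng = np.random.default_rng(3)
    x = rng.standard_normal((12, 3))
    group = [tree.tip_labels[i] for i in (0, 5, 9)]
    res = theta_convergence(tree, x, group, n_shuffles=99, seed=1)
    assert 0.0 <= res["theta"] <= 180.0
    with pytest.raises(ValueError, match="at least 2"):
        theta_convergence(tree, x, group[:1], n_shuffles=9, seed=0)


def test_theta_zero_vector_error():
    # tip A sits exactly at the root reconstruction (the tip mean): zero vector
    tree, x = _star4([[0.0, 0], [2.0, 0], [-1.0, 0], [-1.0, 0]])
    with pytest.raises(ValueError, match="zero-length"):
        theta_convergence(tree, x, ["A", "B"], n_shuffles=9, seed=0)


# ---------------------------------------------------------------------------
# BH and the decision rule


def test_bh_fdr_step_up_by_hand():
    flags, adj = bh_fdr([0.01, 0.02, 0.03, 0.5], alpha=0.10)
    # adjusted: min over k'>=k of p_(k') * m / k' -> (0.04, 0.04, 0.04, 0.5)
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5], atol=1e-12)
    np.testing.assert_array_equal(flags, [True, True, True, False])


def test_bh_fdr_edges():
    flags, adj = bh_fdr([], alpha=0.10)
    assert len(flags) == 0
    flags, _ = bh_fdr([1.0, 1.0, 1.0], alpha=0.10)
    assert not flags.any()
    flags, _ = bh_fdr([0.05], alpha=0.10)
    assert flags[0]
    with pytest.raises(ValueError):
        bh_fdr([1.5], alpha=0.10)


def _calls_table(rows):
    return pd.DataFrame(rows, columns=["species", "dataset", "p_c1", "p_theta"])


def test_maximal_call_trivial_cases():
    all_one = _calls_table(
        [(s, d, 1.0, 1.0) for s in ("x", "y") for d in ("total", "facial", "neurocranial")]
    )
    out = maximal_convergence_call(all_one, alpha=0.10)
    assert not out["maximal_convergent"].any()

    one_hot = _calls_table(
        [("x", d, 0.001, 0.001) for d in ("total", "facial", "neurocranial")]
        + [("y", d, 0.9, 0.9) for d in ("total", "facial", "neurocranial")]
    )
    out = maximal_convergence_call(one_hot, alpha=0.10).set_index("species")
    assert out.loc["x", "maximal_convergent"]
    assert not out.loc["y", "maximal_convergent"]


def test_maximal_call_requires_total_and_one_patch():
    rows = [
        ("x", "total", 0.001, 0.001),
        ("x", "facial", 0.9, 0.9),
        ("x", "neurocranial", 0.9, 0.9),
    ]
    out = maximal_convergence_call(_calls_table(rows), alpha=0.10)
    assert not out["maximal_convergent"].iloc[0]


def test_maximal_call_monotone_in_p(rng):
    """Lowering any p-value never removes a species from the maximal set."""
    datasets = ("total", "facial", "neurocranial")
    rows = [
        (f"s{k}", d, rng.uniform(0, 0.3), rng.uniform(0, 0.3))
        for k in range(6)
        for d in datasets
    ]
    base = _calls_table(rows)
    out0 = maximal_convergence_call(base, alpha=0.10)
    before = set(out0.loc[out0.maximal_convergent, "species"])
    lowered = base.copy()
    i = rng.integers(len(lowered))
    lowered.loc[i, "p_c1"] = lowered.loc[i, "p_c1"] / 10
    out1 = maximal_convergence_call(lowered, alpha=0.10)
    after = set(out1.loc[out1.maximal_convergent, "species"])
    assert before <= after


def test_maximal_call_incomplete_species_excluded():
    rows = [
        ("x", "total", 0.001, 0.001),
        ("x", "facial", 0.001, 0.001),
        # x lacks neurocranial
        ("y", "total", 0.001, 0.001),
        ("y", "facial", 0.001, 0.001),
        ("y", "neurocranial", 0.001, 0.001),
    ]
    with pytest.warns(UserWarning, match="missing datasets"):
        out = maximal_convergence_call(_calls_table(rows), alpha=0.10)
    assert list(out["species"]) == ["y"]
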