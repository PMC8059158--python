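"""Phylogenetically informed inference on shape.

Two workhorses: the multivariate phylogenetic-signal statistic K_mult
(the multivariate generalization of Blomberg's K — the ratio of observed
to Brownian-expected phylogenetic structuring, ~1 under BM) with a
tip-permutation null, and distance-based phylogenetic generalized least
squares (PGLS) with residual-randomization permutation inference, used
for allometry, clade, diet and prey-ratio models on multivariate
Procrustes coordinates or on log centroid size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from convmorph.convergence import bh_fdr
from convmorph.phylo import Phylogeny, phylo_covariance


@dataclass
class PhyloSignalResult:
    k_mult: float
    p: float
    n_perm: int


@dataclass
class PGLSResult:
    r2: float
    f: float
    z: float
    p: float
    df: tuple[int, int]
    n: int


def _inv_sqrt(c: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(c)
    if evals.min() <= 1e-12 * evals.max():
        raise ValueError(
            "singular phylogenetic covariance matrix; check for zero branch lengths"
        )
    return (evecs / np.sqrt(evals)) @ evecs.T


def k_mult(
    tree: Phylogeny,
    tip_values: np.ndarray,
    n_perm: int = 1000,
    seed=None,
) -> PhyloSignalResult:
    """Multivariate phylogenetic signal with a permutation p-value.

    K_mult = (num/den) / E[num/den | BM], where num is the summed squared
    Euclidean distance of tip data to the phylogenetically weighted (GLS)
    mean, den the same after whitening by C^(-1/2), and the Brownian
    expectation is the analytic (tr C - n / sum C^-1) / (n - 1).  The
    p-value permutes tip rows across the tree: p = (#{K_perm >= K_obs} +
    1) / (n_perm + 1).
    """
    x = np.atleast_2d(np.asarray(tip_values, float))
    if x.shape[0] != tree.n_tips:
        if x.shape[1] == tree.n_tips:
            x = x.T
        else:
            raise ValueError("tip_values rows must match tree tips")
    n = tree.n_tips
    if n < 4:
        raise ValueError("phylogenetic signal needs at least 4 tips")
    c = phylo_covariance(tree)
    cinv = np.linalg.inv(c)
    pmat = _inv_sqrt(c)
    one = np.ones(n)
    w = cinv @ one / (one @ cinv @ one)
    expected = (np.trace(c) - n / (one @ cinv @ one)) / (n - 1)

    def stat(data: np.ndarray) -> float:
        a = w @ data
        resid = data - a
        num = float((resid**2).sum())
        den = float(((pmat @ resid) ** 2).sum())
        return (num / den) / expected

    k_obs = stat(x)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(x[perm]) >= k_obs:
            n_ge += 1
    return PhyloSignalResult(
        k_mult=float(k_obs), p=float((n_ge + 1) / (n_perm + 1)), n_perm=n_perm
    )


def _design_matrix(predictor, species: list[str]) -> np.ndarray:
    """Build a design (without intercept) from a Series / DataFrame / array.

    Categorical predictors are dummy-coded with the first level dropped;
    every factor level must keep at least 2 species.
    """
    if isinstance(predictor, pd.Series):
        values = predictor.reindex(species)
        if values.isna().any():
            missing = [s for s in species if pd.isna(predictor.get(s, np.nan))]
            raise ValueError(f"predictor undefined for species {missing}")
        if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype):
            counts = values.value_counts()
            thin = counts[counts < 2]
            if len(thin):
                raise ValueError(
                    f"factor level(s) with fewer than 2 species: {list(thin.index)}"
                )
            return pd.get_dummies(values, drop_first=True, dtype=float).to_numpy()
        return values.to_numpy(float)[:, None]
    if isinstance(predictor, pd.DataFrame):
        return predictor.reindex(species).to_numpy(float)
    arr = np.asarray(predictor)
    if arr.dtype.kind in "OUS":
        return _design_matrix(pd.Series(arr, index=species), species)
    arr = arr.astype(float)
    return arr[:, None] if arr.ndim == 1 else arr


def pgls_fit(
    tree: Phylogeny,
    response: np.ndarray,
    predictor,
    species: list[str] | None = None,
    n_perm: int = 1000,
    seed=None,
    exclude: tuple[str, ...] = (),
) -> PGLSResult:
    """Distance-based PGLS with residual-randomization inference.

    Response rows follow ``species`` (default: tree tip order).  Both
    sides are whitened by C^(-1/2); sums of squares in the whitened space
    give R^2 and the pseudo-F; the null distribution permutes
    reduced-model (intercept-only) residuals (RRPP), and Z is the effect
    size (F_obs - mean F_null) / sd F_null.  ``exclude`` drops species
    (e.g. a focal unknown) before fitting — the covariance submatrix of
    the remaining tips is their exact phylogenetic covariance.
    """
    species = list(species) if species is not None else list(tree.tip_labels)
    y = np.atleast_2d(np.asarray(response, float))
    if y.shape[0] != len(species):
        raise ValueError("response rows must match the species list")
    keep = [i for i, s in enumerate(species) if s not in set(exclude)]
    if len(keep) < 3:
        raise ValueError("too few species left after exclusion")
    kept_species = [species[i] for i in keep]
    tip_idx = [tree.tip_index(s) for s in kept_species]
    c = phylo_covariance(tree)[np.ix_(tip_idx, tip_idx)]
    pmat = _inv_sqrt(c)
    n = len(keep)
    d = _design_matrix(predictor, kept_species)
    x_full = pmat @ np.hstack([np.ones((n, 1)), d])
    x_red = pmat @ np.ones((n, 1))
    yt = pmat @ y[keep]

    def hat(xmat: np.ndarray) -> np.ndarray:
        return xmat @ np.linalg.pinv(xmat.T @ xmat) @ xmat.T

    h_full, h_red = hat(x_full), hat(x_red)
    rank_full = np.linalg.matrix_rank(x_full)
    df_model = rank_full - 1
    df_resid = n - rank_full
    if df_resid < 1 or df_model < 1:
        raise ValueError("degenerate design (no residual or model df)")

    def f_stat(ymat: np.ndarray) -> float:
        rss_red = float(((ymat - h_red @ ymat) ** 2).sum())
        rss_full = float(((ymat - h_full @ ymat) ** 2).sum())
        ss_model = rss_red - rss_full
        return (ss_model / df_model) / (rss_full / df_resid)

    rss_red_obs = float(((yt - h_red @ yt) ** 2).sum())
    rss_full_obs = float(((yt - h_full @ yt) ** 2).sum())
    ss_model_obs = rss_red_obs - rss_full_obs
    r2 = ss_model_obs / rss_red_obs if rss_red_obs > 0 else 0.0
    f_obs = (ss_model_obs / df_model) / (rss_full_obs / df_resid)

    fitted_red = h_red @ yt
    resid_red = yt - fitted_red
    rng = np.random.default_rng(seed)
    f_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        f_null[b] = f_stat(fitted_red + resid_red[perm])
    p = float((np.sum(f_null >= f_obs) + 1) / (n_perm + 1))
    sd = f_null.std()
    z = float((f_obs - f_null.mean()) / sd) if sd > 0 else 0.0
    return PGLSResult(
        r2=float(r2), f=float(f_obs), z=z, p=p, df=(df_model, df_resid), n=n
    )


def adjust_pgls_table(p_values, alpha: float = 0.10):
    """BH-FDR flags for a table of PGLS / signal p-values.

    Thin delegation to the shared Benjamini-Hochberg implementation so
    regression tables and convergence tables use the identical procedure.
    """
    return bh_fdr(p_values, alpha)
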