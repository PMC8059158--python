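"""Prey-size ecology: mass ratios, diet classes, CVA discrimination, screens.

The ecology table derives, per species, the prey/predator mass ratio
(mean prey mass divided by pack size for social hunters, over predator
body mass), its natural log, fine (10-level) and coarse (3-level) diet
categories from percentage-biomass diet fractions, and the binary
prey-size class split at the 45% ratio threshold.  Canonical variates
analysis on selected PC scores discriminates the two prey-size classes
with leave-one-out jackknife validation and assigns unknown specimens
with equal-prior Mahalanobis posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: prey-size class boundary: "large" prey are heavier than this fraction of
#: predator body mass (per-capita for pack hunters).  Single source of truth.
PREY_RATIO_CUT = 0.45

# diet fraction column -> base category name
_DIET_BASE = {
    "vertebrates": "carnivore",
    "invertebrates": "insectivore",
    "fruit": "frugivore",
    "plants": "herbivore",
    "hard": "durophage",
}


def _diet_labels(fracs: dict[str, float]) -> tuple[str | None, str | None]:
    """(fine, coarse) diet labels from percentage-biomass fractions."""
    if any(pd.isna(v) for v in fracs.values()):
        return None, None
    if any(not 0 <= v <= 1 for v in fracs.values()):
        raise ValueError(f"diet fractions must lie in [0, 1], got {fracs}")
    items = sorted(fracs.items(), key=lambda kv: -kv[1])
    main, main_frac = items[0]
    if main_frac > 0.5:
        fine = _DIET_BASE[main]
        if len(items) > 1:
            sec, sec_frac = items[1]
            if 0.2 <= sec_frac < 0.5:
                fine = f"{_DIET_BASE[main]}/{_DIET_BASE[sec]}"
    else:
        fine = "generalist"
    if fracs.get("vertebrates", 0) >= 0.5:
        coarse = "carnivorous"
    elif fracs.get("invertebrates", 0) >= 0.5:
        coarse = "insectivorous"
    else:
        coarse = "generalist"
    return fine, coarse


def build_ecology(raw, prey_ratio_cut: float = PREY_RATIO_CUT) -> pd.DataFrame:
    """Build the per-species ecology table from raw masses and diet fractions.

    ``raw`` is a DataFrame or CSV path with columns ``species``,
    ``body_mass_kg``, ``mean_prey_mass_kg``, ``pack_size`` and any of the
    diet-fraction columns ``diet_vertebrates``, ``diet_invertebrates``,
    ``diet_fruit``, ``diet_plants``, ``diet_hard`` (proportions of diet
    biomass).  Output adds ``prey_ratio`` (per-capita prey mass over
    predator mass), ``ln_prey_ratio``, ``size_class`` (small/large at the
    ratio cut), ``diet_fine`` and ``diet_coarse``; rows with missing diet
    fractions keep null labels and are flagged.
    """
    df = raw.copy() if isinstance(raw, pd.DataFrame) else pd.read_csv(raw)
    for col in ("body_mass_kg", "mean_prey_mass_kg"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "species"].tolist()
            raise ValueError(f"non-positive {col} for species {bad}")
    if "pack_size" not in df.columns:
        df["pack_size"] = 1
    if (df["pack_size"] < 1).any():
        raise ValueError("pack_size must be >= 1")
    frac_cols = {c[5:]: c for c in df.columns if c.startswith("diet_")}
    fine, coarse, flagged = [], [], []
    for _, row in df.iterrows():
        fracs = {k: row[c] for k, c in frac_cols.items()}
        f, c = _diet_labels(fracs) if fracs else (None, None)
        fine.append(f)
        coarse.append(c)
        flagged.append(f is None)
    out = df.copy()
    out["prey_ratio"] = (
        df["mean_prey_mass_kg"] / df["pack_size"] / df["body_mass_kg"]
    )
    out["ln_prey_ratio"] = np.log(out["prey_ratio"])
    out["size_class"] = np.where(out["prey_ratio"] > prey_ratio_cut, "large", "small")
    out["diet_fine"] = fine
    out["diet_coarse"] = coarse
    out["diet_missing"] = flagged
    return out


# ---------------------------------------------------------------------------
# Canonical variates (two-group) discrimination


@dataclass
class CVAResult:
    canonical_axis: np.ndarray  # weight vector over the selected PCs
    group_means: dict[str, np.ndarray]
    classes: list[str]  # the two class labels, order fixed
    scores: np.ndarray  # per-specimen canonical scores (knowns + unknowns)
    assignments: list[str]  # per specimen (jackknifed for knowns, full-fit for unknowns)
    posteriors: np.ndarray  # N x 2, equal-prior Mahalanobis posteriors
    confusion: pd.DataFrame  # jackknife confusion matrix (true x assigned)
    pct_correct: float  # jackknifed
    resub_pct_correct: float  # resubstitution (full-fit) accuracy, for comparison
    pct_correct_by: dict[str, float]
    is_unknown: np.ndarray


def _lda_fit(x: np.ndarray, y: np.ndarray, classes: list[str]):
    """Pooled within-group covariance, its inverse, and group means."""
    means = {c: x[y == c].mean(axis=0) for c in classes}
    resid = np.vstack([x[y == c] - means[c] for c in classes])
    sw = resid.T @ resid / (len(x) - len(classes))
    try:
        sw_inv = np.linalg.inv(sw)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular within-group scatter; use fewer PC axes than specimens per group"
        ) from None
    return means, sw_inv


def _classify(x: np.ndarray, means, sw_inv, classes):
    d2 = np.stack(
        [np.einsum("ij,jk,ik->i", x - means[c], sw_inv, x - means[c]) for c in classes],
        axis=1,
    )
    like = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / 2.0)
    post = like / like.sum(axis=1, keepdims=True)
    return np.asarray(classes, dtype=object)[np.argmin(d2, axis=1)], post


def cva_discriminate(
    scores: np.ndarray,
    classes,
    unknown: np.ndarray | None = None,
    groups=None,
) -> CVAResult:
    """Two-group canonical variates analysis with jackknife validation.

    ``scores`` is N x m (selected PC axes per specimen); ``classes`` the
    per-specimen size-class labels (ignored for rows flagged in the
    boolean mask ``unknown``).  The canonical axis is the (single)
    eigenvector of within^-1 x between scatter; assignment uses
    Mahalanobis distance to the group means with equal priors, posterior
    probabilities as normalized Gaussian likelihoods.  Known specimens
    are classified leave-one-out (refit excluding each in turn); unknowns
    are scored against the full known fit.  ``groups`` (e.g. infraclass
    labels) yields per-group percent-correct breakdowns.
    """
    x = np.asarray(scores, float)
    y = np.asarray(classes, dtype=object)
    unknown = (
        np.zeros(len(x), dtype=bool) if unknown is None else np.asarray(unknown, bool)
    )
    known = ~unknown
    class_names = sorted(set(y[known]))
    if len(class_names) != 2:
        raise ValueError(f"need exactly 2 known classes, got {class_names}")
    for c in class_names:
        if (y[known] == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 known specimens")
    xk, yk = x[known], y[known]
    means, sw_inv = _lda_fit(xk, yk, class_names)
    axis = sw_inv @ (means[class_names[1]] - means[class_names[0]])
    axis = axis / np.linalg.norm(axis)
    canon_scores = x @ axis

    assignments = np.empty(len(x), dtype=object)
    posteriors = np.empty((len(x), 2))
    # leave-one-out jackknife over the knowns
    known_idx = np.where(known)[0]
    for pos, i in enumerate(known_idx):
        mask = np.ones(len(known_idx), dtype=bool)
        mask[pos] = False
        m_i, swi_i = _lda_fit(xk[mask], yk[mask], class_names)
        a, p = _classify(x[i : i + 1], m_i, swi_i, class_names)
        assignments[i] = a[0]
        posteriors[i] = p[0]
    if unknown.any():
        a, p = _classify(x[unknown], means, sw_inv, class_names)
        assignments[unknown] = a
        posteriors[unknown] = p

    true_k = y[known]
    pred_k = assignments[known]
    resub_pred, _ = _classify(xk, means, sw_inv, class_names)
    resub_pct = 100.0 * float((resub_pred == yk).mean())
    confusion = pd.crosstab(
        pd.Series(true_k, name="true"), pd.Series(pred_k, name="assigned")
    ).reindex(index=class_names, columns=class_names, fill_value=0)
    pct = 100.0 * np.trace(confusion.to_numpy()) / confusion.to_numpy().sum()
    pct_by = {}
    if groups is not None:
        g = np.asarray(groups, dtype=object)[known]
        for name in pd.unique(g):
            sel = g == name
            pct_by[str(name)] = 100.0 * float((pred_k[sel] == true_k[sel]).mean())
    return CVAResult(
        canonical_axis=axis,
        group_means=means,
        classes=class_names,
        scores=canon_scores,
        assignments=list(assignments),
        posteriors=posteriors,
        confusion=confusion,
        pct_correct=float(pct),
        resub_pct_correct=resub_pct,
        pct_correct_by=pct_by,
        is_unknown=unknown,
    )


# ---------------------------------------------------------------------------
# Per-PC nonparametric screens


def _rank_test_ok(cls: pd.Series, labels) -> bool:
    """Rank-sum tests need at least 4 species per size class; warn and skip otherwise."""
    import warnings

    sizes = [(cls == lab).sum() for lab in labels]
    if min(sizes) < 4:
        warnings.warn(
            f"rank-sum screen skipped: size classes too thin ({dict(zip(labels, sizes))})"
        )
        return False
    return True


def pc_ecology_screen(
    scores: pd.DataFrame,
    ln_ratio: pd.Series,
    classes: pd.Series,
    species_filter: list[str] | None = None,
) -> pd.DataFrame:
    """Per-PC Wilcoxon rank-sum (between size classes) and Spearman screens.

    ``scores`` is a species x PC frame (index = species); ``ln_ratio``
    and ``classes`` are species-indexed.  Rank-sum p uses exact
    enumeration for small tie-free samples and the tie-corrected normal
    approximation otherwise; Spearman's rho is tested against
    ``ln_ratio``.  ``species_filter`` restricts to a subgroup (e.g.
    placentals only).  Constant PCs yield null p-values and a flag.
    """
    sp = list(scores.index)
    if species_filter is not None:
        sp = [s for s in sp if s in set(species_filter)]
    sub = scores.loc[sp]
    ratio = ln_ratio.reindex(sp)
    cls = classes.reindex(sp)
    labels = sorted(cls.dropna().unique())
    rows = []
    for pc in sub.columns:
        v = sub[pc].to_numpy(float)
        row: dict = {"pc": pc, "constant": bool(np.ptp(v) == 0)}
        if row["constant"]:
            row.update(wilcoxon_p=np.nan, spearman_rs=np.nan, spearman_p=np.nan)
            rows.append(row)
            continue
        if len(labels) == 2 and _rank_test_ok(cls, labels):
            a = v[(cls == labels[0]).to_numpy()]
            b = v[(cls == labels[1]).to_numpy()]
            method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
            try:
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            except ValueError:  # ties make the exact method unavailable
                res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            row["wilcoxon_p"] = float(res.pvalue)
        else:
            row["wilcoxon_p"] = np.nan
        rho, p = stats.spearmanr(v, ratio.to_numpy(float))
        row["spearman_rs"] = float(rho)
        row["spearman_p"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
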