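"""Synthetic study generator.

Produces complete fake landmark studies — a unit-depth pure-birth tree,
species-mean latent phenotypes evolving by multivariate Brownian motion
(optionally with a convergent regime blending a focal tip set toward a
shared target phenotype), specimen-level landmark configurations built
from a template plus a linear latent-to-landmark deformation basis,
centroid-size allometry, and an ecology table whose log prey/predator
mass ratio is driven by the first latent axis — so that every stage of
the pipeline can be exercised and calibrated without any external data.

Because the latent-to-landmark map is linear and the basis rows are
orthonormal, shape-space analyses of the generated data see exactly the
simulated latent covariance structure (up to Procrustes projection and
specimen noise).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from convmorph.landmarks import (
    LandmarkConfiguration,
    write_landmarks,
    write_subset_map,
)
from convmorph.phylo import BMModel, Phylogeny, simulate_bm, write_newick
from convmorph.prey_size import PREY_RATIO_CUT


@dataclass
class SyntheticScenario:
    """Parameters of one simulated study.

    Defaults mirror the emulated study's sampling design: 57 species on
    a unit-depth pure-birth tree, 4 specimens per species (two of each
    sex), 36 landmarks standing in for the full digitizing template, 4
    latent shape axes with geometrically decaying Brownian rates
    (leading-axis dominance as in real cranial data), mild allometry and
    an ecology effect tying the log prey/predator ratio to latent
    axis 1.  ``convergence_weight`` w blends the focal species' latent
    means toward a shared drawn target: w=0 is pure BM, w=1 complete
    convergence.
    """

    n_species: int = 57
    n_specimens_per_species: int = 4
    n_landmarks: int = 36
    p_latent: int = 4
    rates: np.ndarray | None = None  # diagonal of R; default 0.004 * 2^-k
    focal_set: list[str] | None = None
    n_focal: int = 3
    convergence_weight: float = 0.0
    specimen_noise_sd: float = 0.002  # per-coordinate, shape units
    allometry_slope: float = 0.15  # b: ln centroid size per sd of latent 1
    ecology_effect: float = 1.0  # a: ln prey ratio per sd of latent 1
    ratio_noise_sd: float = 0.4
    base_size_mm: float = 100.0
    seed: int = 0

    def rate_matrix(self) -> np.ndarray:
        if self.rates is not None:
            r = np.asarray(self.rates, float)
        else:
            r = 0.004 * 0.5 ** np.arange(self.p_latent)
        return np.diag(r)

    def __post_init__(self) -> None:
        if not 0.0 <= self.convergence_weight <= 1.0:
            raise ValueError("convergence_weight must lie in [0, 1]")


@dataclass
class SyntheticStudy:
    scenario: SyntheticScenario
    tree: Phylogeny
    configs: list[LandmarkConfiguration]
    ecology: pd.DataFrame  # raw table in the build_ecology input schema
    template: np.ndarray
    basis: np.ndarray
    subsets: np.ndarray
    roles: np.ndarray
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        """Write tree / landmarks / ecology / subset map / truth to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": out / "tree.nwk",
            "landmarks": out / "landmarks.tps",
            "ecology": out / "ecology.csv",
            "subset_map": out / "subset_map.csv",
            "truth": out / "truth.csv",
        }
        write_newick(self.tree, paths["tree"])
        write_landmarks(self.configs, paths["landmarks"], format="tps")
        self.ecology.to_csv(paths["ecology"], index=False)
        write_subset_map(self.subsets, self.roles, paths["subset_map"])
        pd.DataFrame(self.truth["latent_means"], index=self.tree.tip_labels).to_csv(
            paths["truth"]
        )
        return paths


# ---------------------------------------------------------------------------
# Tree simulation


def yule_tree(n_tips: int, rng: np.random.Generator, labels=None) -> Phylogeny:
    """Pure-birth tree with ``n_tips`` extant tips, rescaled to unit depth."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    labels = labels or [f"sp{i + 1:02d}" for i in range(n_tips)]
    parent_of: dict[int, int] = {}
    blen_of: dict[int, float] = {}
    counter = [0]

    def new_node() -> int:
        counter[0] += 1
        return counter[0] - 1

    root = new_node()
    t = 0.0
    active = [(new_node(), root, 0.0), (new_node(), root, 0.0)]  # (id, parent, start)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node, par, start = active.pop(k)
        parent_of[node], blen_of[node] = par, t - start
        active.append((new_node(), node, t))
        active.append((new_node(), node, t))
    t += rng.exponential(1.0 / n_tips)
    tip_records = active
    for node, par, start in tip_records:
        parent_of[node], blen_of[node] = par, t - start
    # linearize: tips first (in creation order of the final active set), internals after
    tip_ids = [node for node, _, _ in tip_records]
    internal_ids = [root] + [
        v for v in range(counter[0]) if v not in set(tip_ids) and v != root
    ]
    index = {v: i for i, v in enumerate(tip_ids)}
    for j, v in enumerate(internal_ids):
        index[v] = n_tips + j
    n_nodes = counter[0]
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    for v in range(n_nodes):
        if v != root:
            parent[index[v]] = index[parent_of[v]]
            blen[index[v]] = blen_of[v] / t  # rescale to unit depth
    return Phylogeny(labels, parent, blen)


# ---------------------------------------------------------------------------
# Template geometry


def _template(n_landmarks: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Skull-shaped stand-in template: points on a stretched ellipsoid.

    Returns (coords with unit centroid size, subset labels, role labels).
    The anterior third (largest x) is the facial patch, the posterior
    third the neurocranial patch.  Points follow a Fibonacci spiral so
    consecutive indices are spatial neighbours (curve sliding assumes
    index-contiguous curves).
    """
    k = n_landmarks
    i = np.arange(k, dtype=float)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / k
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    pts = np.column_stack([1.6 * z, 1.0 * r * np.cos(phi), 0.8 * r * np.sin(phi)])
    pts -= pts.mean(axis=0)
    pts /= np.sqrt((pts**2).sum())
    third = k // 3
    order = np.argsort(-pts[:, 0])  # descending x: anterior first
    subsets = np.full(k, "other", dtype=object)
    subsets[order[:third]] = "facial"
    subsets[order[-third:]] = "neurocranial"
    roles = np.full(k, "patch_semilandmark", dtype=object)
    n_fixed = max(4, k // 8)
    roles[::3] = "curve_semilandmark"
    roles[:n_fixed] = "fixed"
    return pts, subsets, roles


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Study simulation


def simulate_study(scenario: SyntheticScenario) -> SyntheticStudy:
    """Generate one complete study from the scenario (all randomness from its seed)."""
    ss = np.random.SeedSequence(scenario.seed)
    s_tree, s_bm, s_target, s_spec, s_eco, s_basis = ss.spawn(6)
    rng_tree = np.random.default_rng(s_tree)
    tree = yule_tree(scenario.n_species, rng_tree)

    rates = scenario.rate_matrix()
    model = BMModel(rate_matrix=rates, root_state=np.zeros(scenario.p_latent))
    latents = simulate_bm(tree, model, 1, seed=s_bm)[0]  # (n_species, p)
    latents_bm = latents.copy()

    rng_target = np.random.default_rng(s_target)
    w = scenario.convergence_weight
    focal = list(scenario.focal_set) if scenario.focal_set else []
    target = rng_target.standard_normal(scenario.p_latent) @ np.sqrt(rates)
    if w > 0:
        if not focal:
            focal = _distant_tip_set(tree, scenario.n_focal)
        for sp in focal:
            i = tree.tip_index(sp)
            latents[i] = (1 - w) * latents[i] + w * target

    # landmark embedding
    k = scenario.n_landmarks
    template, subsets, roles = _template(k)
    rng_basis = np.random.default_rng(s_basis)
    q, _ = np.linalg.qr(rng_basis.standard_normal((3 * k, scenario.p_latent)))
    basis = q.T  # p x 3K, orthonormal rows

    sd1 = np.sqrt(rates[0, 0])  # latent-1 sd at unit depth, for standardized effects
    z_std = latents[:, 0] / sd1
    rng_spec = np.random.default_rng(s_spec)
    configs: list[LandmarkConfiguration] = []
    for i, sp in enumerate(tree.tip_labels):
        shape_flat = template.reshape(-1) + latents[i] @ basis
        ln_size_sp = np.log(scenario.base_size_mm) + scenario.allometry_slope * z_std[i]
        for j in range(scenario.n_specimens_per_species):
            coords = shape_flat.reshape(k, 3) + rng_spec.normal(
                0.0, scenario.specimen_noise_sd, size=(k, 3)
            )
            size = np.exp(ln_size_sp + rng_spec.normal(0.0, 0.02))
            rot = _random_rotation(rng_spec)
            coords = (coords @ rot.T) * size + rng_spec.uniform(-50, 50, size=3)
            configs.append(
                LandmarkConfiguration(
                    specimen_id=f"{sp}_{j + 1}",
                    species_id=sp,
                    sex="f" if j % 2 == 0 else "m",
                    coords=coords,
                    roles=roles.copy(),
                    subsets=subsets.copy(),
                )
            )

    ecology = _simulate_ecology(tree, z_std, scenario, np.random.default_rng(s_eco))
    truth = {
        "latent_means": latents,
        "latent_means_bm": latents_bm,
        "target": target,
        "focal_set": focal,
        "z_std": z_std,
    }
    return SyntheticStudy(
        scenario=scenario,
        tree=tree,
        configs=configs,
        ecology=ecology,
        template=template,
        basis=basis,
        subsets=subsets,
        roles=roles,
        truth=truth,
    )


def _distant_tip_set(tree: Phylogeny, n_focal: int) -> list[str]:
    """Focal tips spanning distant lineages (greedy max-min patristic distance).

    Convergence between close relatives is confounded by inheritance —
    the emulated study design plants its convergent regime across
    distantly related species, as a cross-clade comparison would.
    """
    depth = tree.depths()
    n = tree.n_tips
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = tree.mrca(i, j)
            dist[i, j] = dist[j, i] = depth[i] + depth[j] - 2 * depth[m]
    chosen = list(np.unravel_index(np.argmax(dist), dist.shape))
    while len(chosen) < n_focal:
        rest = [i for i in range(n) if i not in chosen]
        chosen.append(max(rest, key=lambda i: dist[i, chosen].min()))
    return [tree.tip_labels[i] for i in sorted(chosen)]


def _clade_labels(tree: Phylogeny) -> dict[str, str]:
    """Three clade labels from the lineages present just after the second split."""
    internals = sorted(
        (v for v in range(tree.n_nodes) if tree.children[v]),
        key=lambda v: tree.depths()[v],
    )
    lineages: list[int] = list(tree.children[tree.root])
    if len(lineages) < 3 and len(internals) > 1:
        second = next(v for v in internals[1:] if v in lineages)
        lineages = [v for v in lineages if v != second] + list(tree.children[second])
    labels = {}
    for name, v in zip("ABCDEF", lineages):
        for node in tree.clade_nodes(v):
            if node < tree.n_tips:
                labels[tree.tip_labels[node]] = f"clade_{name}"
    return labels


def _simulate_ecology(
    tree: Phylogeny,
    z_std: np.ndarray,
    scenario: SyntheticScenario,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = scenario.n_species
    ln_ratio = (
        np.log(PREY_RATIO_CUT)
        + scenario.ecology_effect * z_std
        + rng.normal(0.0, scenario.ratio_noise_sd, size=n)
    )
    ratio = np.exp(ln_ratio)
    body = 10.0 * np.exp(3 * 0.05 * z_std + rng.normal(0.0, 0.3, size=n))
    pack = np.ones(n, dtype=int)
    pack_hunters = rng.choice(n, size=2, replace=False)
    pack[pack_hunters] = rng.integers(4, 11, size=2)
    prey = ratio * pack * body
    # coarse diet classes: mostly carnivores, with guaranteed minority classes
    coarse = np.array(["carnivorous"] * n, dtype=object)
    minority = rng.choice(n, size=6, replace=False)
    coarse[minority[:3]] = "insectivorous"
    coarse[minority[3:]] = "generalist"
    vert = np.empty(n)
    invert = np.empty(n)
    fruit = np.empty(n)
    for i in range(n):
        if coarse[i] == "carnivorous":
            vert[i] = rng.uniform(0.55, 0.9)
            invert[i] = (1 - vert[i]) * rng.uniform(0.4, 0.9)
        elif coarse[i] == "insectivorous":
            invert[i] = rng.uniform(0.55, 0.9)
            vert[i] = (1 - invert[i]) * rng.uniform(0.4, 0.9)
        else:
            vert[i] = rng.uniform(0.25, 0.45)
            invert[i] = rng.uniform(0.25, 0.45)
        fruit[i] = max(0.0, 1 - vert[i] - invert[i]) * rng.uniform(0.3, 1.0)
    clades = _clade_labels(tree)
    return pd.DataFrame(
        {
            "species": tree.tip_labels,
            "body_mass_kg": body,
            "mean_prey_mass_kg": prey,
            "pack_size": pack,
            "diet_vertebrates": np.round(vert, 3),
            "diet_invertebrates": np.round(invert, 3),
            "diet_fruit": np.round(fruit, 3),
            "clade": [clades.get(sp, "clade_A") for sp in tree.tip_labels],
        }
    )


def fixture_small(seed: int = 20240117) -> SyntheticStudy:
    """Deterministic miniature study: 8 species x 3 specimens x 20 landmarks."""
    scenario = SyntheticScenario(
        n_species=8,
        n_specimens_per_species=3,
        n_landmarks=20,
        p_latent=3,
        seed=seed,
    )
    return simulate_study(scenario)
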