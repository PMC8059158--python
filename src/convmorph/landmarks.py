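"""Landmark I/O and generalized Procrustes alignment (GPA).

Configurations are K x 3 coordinate matrices in mm, each point carrying a
role (``fixed``, ``curve_semilandmark``, ``patch_semilandmark``) and a
subset label (``facial``, ``neurocranial``, ``other``).  GPA removes
translation, scale and rotation, leaving dimensionless Procrustes
coordinates (Pcoords) plus centroid sizes; patch subsets can then be
carved out and re-superimposed as their own shape spaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ROLES = ("fixed", "curve_semilandmark", "patch_semilandmark")
SUBSETS = ("facial", "neurocranial", "other")


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark configuration.

    coords are K x 3, in mm; ``roles`` and ``subsets`` are length-K label
    arrays.  K must match across all specimens of a dataset.
    """

    specimen_id: str
    species_id: str
    coords: np.ndarray
    sex: str = "unknown"
    roles: np.ndarray | None = None
    subsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be K x 3, "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinate")
        k = self.coords.shape[0]
        if self.roles is None:
            self.roles = np.full(k, "fixed", dtype=object)
        else:
            self.roles = np.asarray(self.roles, dtype=object)
        if self.subsets is None:
            self.subsets = np.full(k, "other", dtype=object)
        else:
            self.subsets = np.asarray(self.subsets, dtype=object)
        if len(self.roles) != k or len(self.subsets) != k:
            raise ValueError(
                f"specimen {self.specimen_id!r}: role/subset labels must be length K={k}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass
class AlignedShapes:
    """Procrustes-aligned specimens.

    ``pcoords`` is N x K x 3 with every configuration centred at the
    origin and scaled to unit centroid size; ``csize`` holds the original
    centroid sizes in mm and ``ln_csize`` their natural logs (lnCS).
    """

    pcoords: np.ndarray
    csize: np.ndarray
    specimen_ids: list[str]
    species_ids: list[str]
    roles: np.ndarray
    subsets: np.ndarray
    mean_shape: np.ndarray
    n_iterations: int = 0
    ssq_history: list = None  # per-iteration summed squared distance to consensus

    @property
    def ln_csize(self) -> np.ndarray:
        return np.log(self.csize)

    @property
    def n_specimens(self) -> int:
        return self.pcoords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.pcoords.shape[1]

    def flat(self) -> np.ndarray:
        """Vectorized pcoords, N x 3K (landmark-major: x1,y1,z1,x2,...)."""
        return self.pcoords.reshape(self.n_specimens, -1)


# ---------------------------------------------------------------------------
# I/O


def _read_subset_map(subset_map) -> tuple[np.ndarray | None, np.ndarray | None]:
    """subset_map: path or DataFrame with 0-based landmark_index, subset[, role]."""
    if subset_map is None:
        return None, None
    df = subset_map if isinstance(subset_map, pd.DataFrame) else pd.read_csv(subset_map)
    idx = df["landmark_index"].to_numpy(dtype=int)
    k = idx.max() + 1
    subsets = np.full(k, "other", dtype=object)
    subsets[idx] = df["subset"].to_numpy(dtype=object)
    roles = None
    if "role" in df.columns:
        roles = np.full(k, "fixed", dtype=object)
        roles[idx] = df["role"].to_numpy(dtype=object)
    bad = set(subsets) - set(SUBSETS)
    if bad:
        raise ValueError(f"unknown subset labels {sorted(bad)}; expected {SUBSETS}")
    return subsets, roles


def read_landmarks(path, format: str = "tps", subset_map=None) -> list[LandmarkConfiguration]:
    """Read per-specimen landmark configurations from a TPS or wide-CSV file.

    TPS records use ``LM3=<K>`` followed by K whitespace-separated x y z
    lines, an ``ID=<specimen>`` line, and optionally
    ``COMMENT=<species>[,<sex>]``.  CSV is wide format with columns
    ``specimen, species[, sex], x0,y0,z0, x1,...`` (0-based landmark
    indices).  ``subset_map`` attaches subset (and optionally role)
    labels by 0-based landmark index.
    """
    subsets, roles = _read_subset_map(subset_map)
    if format == "tps":
        configs = _read_tps(path)
    elif format == "csv":
        configs = _read_wide_csv(path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    if not configs:
        raise ValueError(f"no specimens found in {path}")
    k0 = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k0:
            raise ValueError(
                f"specimen {c.specimen_id!r} has {c.n_landmarks} landmarks, "
                f"expected {k0} (as in {configs[0].specimen_id!r})"
            )
    if subsets is not None:
        if len(subsets) != k0:
            raise ValueError(
                f"subset map covers {len(subsets)} landmarks but data has {k0}"
            )
        for c in configs:
            c.subsets = subsets.copy()
            if roles is not None:
                c.roles = roles.copy()
    return configs


def _read_tps(path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    expect = 0
    spec_id, species, sex = None, "unknown", "unknown"

    def flush(lineno):
        nonlocal coords, expect, spec_id, species, sex
        if expect == 0:
            return
        if len(coords) != expect:
            raise ValueError(
                f"{path}: specimen {spec_id!r} declares LM3={expect} but has "
                f"{len(coords)} coordinate lines (near line {lineno})"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id or f"specimen_{len(configs)}",
                species_id=species,
                sex=sex,
                coords=np.array(coords),
            )
        )
        coords, expect, spec_id, species, sex = [], 0, None, "unknown", "unknown"

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                flush(lineno)
                expect = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                spec_id = line.split("=", 1)[1].strip()
            elif upper.startswith("COMMENT="):
                parts = line.split("=", 1)[1].split(",")
                species = parts[0].strip()
                if len(parts) > 1:
                    sex = parts[1].strip()
            elif "=" in line and not _is_numeric_row(line):
                continue  # unrecognised TPS keys (SCALE=, IMAGE=) are skipped
            else:
                vals = line.split()
                if len(vals) != 3 or not _is_numeric_row(line):
                    raise ValueError(
                        f"{path}: line {lineno}: expected 3 numeric coordinates, "
                        f"got {line!r}"
                    )
                coords.append([float(v) for v in vals])
    flush(lineno="EOF")
    return configs


def _is_numeric_row(line: str) -> bool:
    try:
        [float(v) for v in line.split()]
        return True
    except ValueError:
        return False


def _read_wide_csv(path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, float_precision="round_trip")
    coord_cols = [c for c in df.columns if c[0] in "xyz" and c[1:].isdigit()]
    ks = sorted({int(c[1:]) for c in coord_cols})
    configs = []
    for row_i, row in df.iterrows():
        coords = np.empty((len(ks), 3))
        for j, k in enumerate(ks):
            for d, ax in enumerate("xyz"):
                col = f"{ax}{k}"
                if col not in df.columns or pd.isna(row[col]):
                    raise ValueError(
                        f"{path}: row {row_i} (specimen {row.get('specimen')!r}): "
                        f"missing or non-numeric cell {col}"
                    )
                coords[j, d] = float(row[col])
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen"]),
                species_id=str(row["species"]),
                sex=str(row["sex"]) if "sex" in df.columns else "unknown",
                coords=coords,
            )
        )
    return configs


def write_landmarks(configs: list[LandmarkConfiguration], path, format: str = "tps") -> None:
    """Write configurations in the same TPS / wide-CSV dialects read_landmarks reads."""
    if format == "tps":
        with open(path, "w") as fh:
            for c in configs:
                fh.write(f"LM3={c.n_landmarks}\n")
                for x, y, z in c.coords:
                    fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
                fh.write(f"ID={c.specimen_id}\n")
                fh.write(f"COMMENT={c.species_id},{c.sex}\n")
    elif format == "csv":
        rows = []
        for c in configs:
            row = {"specimen": c.specimen_id, "species": c.species_id, "sex": c.sex}
            for j, (x, y, z) in enumerate(c.coords):
                row[f"x{j}"], row[f"y{j}"], row[f"z{j}"] = x, y, z
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown landmark format {format!r}")


def write_subset_map(subsets, roles, path) -> None:
    pd.DataFrame(
        {
            "landmark_index": np.arange(len(subsets)),
            "subset": subsets,
            "role": roles,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geometry


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid (mm)."""
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincide (centroid size 0)")
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimizing ||source @ R - target||; reflections excluded."""
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def gpa_align(
    configs: list[LandmarkConfiguration],
    slide_semilandmarks: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapes:
    """Generalized Procrustes alignment of a specimen set.

    Each configuration is centred, scaled to unit centroid size, and
    rotated to the running consensus by the orthogonal (det +1,
    reflection-free) least-squares rotation; the consensus is re-estimated
    until it changes by less than ``tol`` (RMS over coordinates).  With
    ``slide_semilandmarks``, curve and patch points slide against the
    consensus to minimize thin-plate-spline bending energy before each
    rotation round (curve points along their index-neighbour tangent,
    patch points in a locally estimated tangent plane).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 specimens")
    k = configs[0].n_landmarks
    for c in configs:
        if c.n_landmarks != k:
            raise ValueError(f"specimen {c.specimen_id!r}: landmark count mismatch")
    csize = np.array([centroid_size(c) for c in configs])
    if np.any(csize == 0):
        raise ValueError("cannot align a zero-size configuration")
    shapes = np.stack([(c.coords - c.coords.mean(0)) / s for c, s in zip(configs, csize)])

    roles = configs[0].roles
    consensus = shapes[0].copy()
    n_iter = 0
    ssq_history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        if slide_semilandmarks and n_iter > 1:
            shapes = _slide_all(shapes, consensus, roles)
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        ssq_history.append(float(((shapes - shapes.mean(axis=0)) ** 2).sum()))
        new_consensus = shapes.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last consensus "
            f"change {change:.3e} > tol {tol:.1e})"
        )
    # re-centre/scale guards against drift introduced by sliding
    shapes -= shapes.mean(axis=1, keepdims=True)
    shapes /= np.sqrt((shapes**2).sum(axis=(1, 2), keepdims=True))
    return AlignedShapes(
        pcoords=shapes,
        csize=csize,
        specimen_ids=[c.specimen_id for c in configs],
        species_ids=[c.species_id for c in configs],
        roles=np.asarray(roles, dtype=object),
        subsets=np.asarray(configs[0].subsets, dtype=object),
        mean_shape=shapes.mean(axis=0),
        n_iterations=n_iter,
        ssq_history=ssq_history,
    )


def _bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """TPS bending-energy matrix of a 3D reference configuration (K x K)."""
    k = ref.shape[0]
    r = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    s = r  # 3D TPS kernel U(r) = r
    q = np.hstack([np.ones((k, 1)), ref])
    lmat = np.zeros((k + 4, k + 4))
    lmat[:k, :k] = s + 1e-10 * np.eye(k)
    lmat[:k, k:] = q
    lmat[k:, :k] = q.T
    linv = np.linalg.inv(lmat)
    return linv[:k, :k]


def _tangent_directions(consensus: np.ndarray, roles: np.ndarray) -> dict[int, np.ndarray]:
    """Sliding directions per semilandmark, estimated on the consensus.

    Curve semilandmarks get one direction (index-neighbour chord; curves
    are assumed index-contiguous); patch semilandmarks get two directions
    spanning the local tangent plane of their 6 nearest consensus points.
    """
    k = consensus.shape[0]
    dirs: dict[int, np.ndarray] = {}
    for j in range(k):
        if roles[j] == "curve_semilandmark":
            lo, hi = max(j - 1, 0), min(j + 1, k - 1)
            t = consensus[hi] - consensus[lo]
            norm = np.linalg.norm(t)
            if norm > 0:
                dirs[j] = (t / norm)[None, :]
        elif roles[j] == "patch_semilandmark":
            d = np.linalg.norm(consensus - consensus[j], axis=1)
            nbrs = consensus[np.argsort(d)[1:7]] - consensus[j]
            _, _, vt = np.linalg.svd(nbrs, full_matrices=False)
            dirs[j] = vt[:2]
    return dirs


def _slide_all(shapes: np.ndarray, consensus: np.ndarray, roles: np.ndarray) -> np.ndarray:
    """Slide semilandmarks of every specimen against the consensus."""
    be = _bending_energy_matrix(consensus)
    dirs = _tangent_directions(consensus, np.asarray(roles, dtype=object))
    if not dirs:
        return shapes
    cols = []  # (landmark j, unit direction) pairs -> one slide parameter each
    for j, mat in dirs.items():
        for row in mat:
            cols.append((j, row))
    n_par = len(cols)
    out = shapes.copy()
    # quadratic form per coordinate axis: E = sum_d (y_d - c_d)' BE (y_d - c_d)
    for i in range(shapes.shape[0]):
        diff = shapes[i] - consensus
        # gradient g_t = 2 * u_t' BE_row(j_t) applied per axis; assemble normal eqs
        amat = np.zeros((n_par, n_par))
        bvec = np.zeros(n_par)
        bed = {j: be[j] for j, _ in cols}
        for a, (ja, ua) in enumerate(cols):
            for b, (jb, ub) in enumerate(cols):
                amat[a, b] = float(np.dot(ua, ub)) * be[ja, jb]
            bvec[a] = -float(ua @ (bed[ja] @ diff))
        try:
            t = np.linalg.solve(amat + 1e-10 * np.eye(n_par), bvec)
        except np.linalg.LinAlgError:
            continue
        for a, (ja, ua) in enumerate(cols):
            out[i, ja] += t[a] * ua
        out[i] -= out[i].mean(axis=0)
        out[i] /= np.sqrt((out[i] ** 2).sum())
    return out


def subset_shapes(aligned: AlignedShapes, subset: str, realign: bool = True) -> AlignedShapes:
    """Extract one landmark subset (``total``/``facial``/``neurocranial``/``other``).

    With ``realign`` (the default) the subset is re-superimposed as its
    own shape space; its centroid sizes are the sizes of the subset
    landmarks in the original mm-scale configurations.
    """
    if subset == "total":
        return aligned
    mask = aligned.subsets == subset
    if not mask.any():
        raise ValueError(f"subset {subset!r} selects no landmarks")
    sub = aligned.pcoords[:, mask, :]
    # raw (mm) subset coords = pcoords * full csize (alignment is rigid + scale)
    raw = sub * aligned.csize[:, None, None]
    configs = [
        LandmarkConfiguration(
            specimen_id=sid,
            species_id=spid,
            coords=raw[i],
            roles=aligned.roles[mask],
            subsets=aligned.subsets[mask],
        )
        for i, (sid, spid) in enumerate(zip(aligned.specimen_ids, aligned.species_ids))
    ]
    if realign:
        return gpa_align(configs)
    csize = np.array([centroid_size(c) for c in configs])
    centred = sub - sub.mean(axis=1, keepdims=True)
    return AlignedShapes(
        pcoords=centred,
        csize=csize,
        specimen_ids=list(aligned.specimen_ids),
        species_ids=list(aligned.species_ids),
        roles=aligned.roles[mask],
        subsets=aligned.subsets[mask],
        mean_shape=centred.mean(axis=0),
    )


def species_mean_shapes(
    aligned: AlignedShapes, species_map: dict[str, str] | None = None, tree=None
) -> tuple[list[str], np.ndarray]:
    """Coordinate-wise mean Procrustes shape per species.

    Returns ``(species_ids, means)`` with means of shape S x K x 3.  When a
    tree is supplied the rows follow its tip order; species with no
    specimens are dropped with a warning.
    """
    species = [
        species_map.get(sid, sp) if species_map else sp
        for sid, sp in zip(aligned.specimen_ids, aligned.species_ids)
    ]
    order: list[str] = []
    for sp in species:
        if sp not in order:
            order.append(sp)
    if tree is not None:
        present = set(order)
        missing = [t for t in tree.tip_labels if t not in present]
        if missing:
            warnings.warn(f"tree tips with no specimens dropped: {missing}")
        order = [t for t in tree.tip_labels if t in present]
    means = np.stack(
        [
            aligned.pcoords[[i for i, sp in enumerate(species) if sp == name]].mean(axis=0)
            for name in order
        ]
    )
    return order, means


def write_aligned(aligned: AlignedShapes, path) -> None:
    """Aligned coordinates + centroid sizes as wide CSV."""
    rows = []
    for i, sid in enumerate(aligned.specimen_ids):
        row = {
            "specimen": sid,
            "species": aligned.species_ids[i],
            "csize": aligned.csize[i],
            "ln_csize": aligned.ln_csize[i],
        }
        for j, (x, y, z) in enumerate(aligned.pcoords[i]):
            row[f"x{j}"], row[f"y{j}"], row[f"z{j}"] = x, y, z
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
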