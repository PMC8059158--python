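"""Landmark I/O, centroid size, and generalized Procrustes alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import convmorph as cm
from convmorph.landmarks import (
    LandmarkConfiguration,
    centroid_size,
    gpa_align,
    read_landmarks,
    species_mean_shapes,
    subset_shapes,
    write_landmarks,
    write_subset_map,
)


def _random_configs(rng, n=4, k=12, scale=1.0):
    base = rng.standard_normal((k, 3))
    out = []
    for i in range(n):
        coords = base + 0.05 * rng.standard_normal((k, 3))
        out.append(
            LandmarkConfiguration(
                specimen_id=f"s{i}", species_id=f"sp{i % 2}", coords=scale * coords
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def test_tps_roundtrip_bit_identical(tmp_path, rng):
    configs = _random_configs(rng, n=8, k=60)
    path = tmp_path / "lm.tps"
    write_landmarks(configs, path, format="tps")
    back = read_landmarks(path, format="tps")
    assert len(back) == 8
    for a, b in zip(configs, back):
        assert a.specimen_id == b.specimen_id
        assert a.species_id == b.species_id
        assert np.array_equal(a.coords, b.coords)  # %.17g round-trips float64


def test_csv_roundtrip_and_subset_map(tmp_path, small_study):
    path = tmp_path / "lm.csv"
    write_landmarks(small_study.configs, path, format="csv")
    smap = tmp_path / "subsets.csv"
    write_subset_map(small_study.subsets, small_study.roles, smap)
    back = read_landmarks(path, format="csv", subset_map=smap)
    assert len(back) == len(small_study.configs)
    assert np.array_equal(back[0].subsets, small_study.subsets)
    assert np.array_equal(back[0].roles, small_study.roles)
    np.testing.assert_array_equal(back[3].coords, small_study.configs[3].coords)


def test_tps_record_counts(tmp_path):
    path = tmp_path / "two.tps"
    path.write_text(
        "LM3=5\n" + "0 0 0\n1 0 0\n0 1 0\n0 0 1\n1 1 1\nID=a\nCOMMENT=spA\n"
        "LM3=5\n" + "0 0 0\n2 0 0\n0 2 0\n0 0 2\n2 2 2\nID=b\nCOMMENT=spB\n"
    )
    configs = read_landmarks(path, format="tps")
    assert len(configs) == 2
    assert all(c.n_landmarks == 5 for c in configs)
    assert [c.specimen_id for c in configs] == ["a", "b"]


def test_malformed_inputs_raise(tmp_path):
    bad_tps = tmp_path / "bad.tps"
    bad_tps.write_text("LM3=2\n0 0 0\n1 1\nID=a\n")
    with pytest.raises(ValueError, match="line 3"):
        read_landmarks(bad_tps, format="tps")

    bad_csv = tmp_path / "bad.csv"
    bad_csv.write_text("specimen,species,x0,y0,z0,x1,y1,z1\na,spA,0,0,0,1,1,\n")
    with pytest.raises(ValueError, match="z1"):
        read_landmarks(bad_csv, format="csv")

    mismatch = tmp_path / "mismatch.tps"
    mismatch.write_text(
        "LM3=2\n0 0 0\n1 1 1\nID=a\nLM3=3\n0 0 0\n1 1 1\n2 2 2\nID=b\n"
    )
    with pytest.raises(ValueError, match="b"):
        read_landmarks(mismatch, format="tps")


# ---------------------------------------------------------------------------
# Centroid size


def test_centroid_size_analytic():
    coords = np.array([[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]])
    assert centroid_size(coords) == pytest.approx(np.sqrt(2.0), abs=1e-12)


def test_centroid_size_brute_force(rng):
    coords = rng.standard_normal((20, 3)) * 7 + 3
    centroid = coords.mean(axis=0)
    expected = np.sqrt(sum(np.sum((p - centroid) ** 2) for p in coords))
    assert centroid_size(coords) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(c=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 100))
def test_centroid_size_homogeneous(c, seed):
    coords = np.random.default_rng(seed).standard_normal((9, 3))
    assert centroid_size(c * coords) == pytest.approx(c * centroid_size(coords), rel=1e-9)


def test_degenerate_configuration_warns():
    coords = np.ones((5, 3))
    with pytest.warns(UserWarning, match="coincide"):
        assert centroid_size(coords) == 0.0


# ---------------------------------------------------------------------------
# GPA


def _rigid_copy(config, rng, scale=2.5):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    coords = scale * config.coords @ q.T + rng.uniform(-10, 10, 3)
    return LandmarkConfiguration("copy", config.species_id, coords)


def test_gpa_identical_configs_zero_distance(rng):
    a = _random_configs(rng, n=1)[0]
    b = LandmarkConfiguration("b", a.species_id, a.coords.copy())
    aligned = gpa_align([a, b])
    assert np.linalg.norm(aligned.pcoords[0] - aligned.pcoords[1]) < 1e-10


def test_gpa_rigid_invariance(rng):
    a = _random_configs(rng, n=1, k=15)[0]
    b = _rigid_copy(a, rng)
    aligned = gpa_align([a, b])
    rms = np.sqrt(((aligned.pcoords[0] - aligned.pcoords[1]) ** 2).mean())
    assert rms < 1e-8


def test_gpa_output_invariant_under_input_transform(rng):
    configs = _random_configs(rng, n=5, k=10)
    ref = gpa_align(configs)
    transformed = configs[:2] + [_rigid_copy(configs[2], rng, scale=0.3)] + configs[3:]
    transformed[2].specimen_id = configs[2].specimen_id
    out = gpa_align(transformed)
    assert np.allclose(ref.pcoords, out.pcoords, atol=1e-8)


def test_gpa_pair_matches_closed_form_opa():
    """2-specimen GPA equals ordinary Procrustes: hand-derived 2D rotation."""
    a = np.array([[0.0, 0.0, 0], [4.0, 0.0, 0], [0.0, 3.0, 0]])
    b0 = np.array([[0.0, 0.0, 0], [4.4, 0.3, 0], [-0.4, 3.1, 0]])
    # closed-form 2D OPA angle between centered, unit-scaled configs:
    # theta* = atan2(sum(x_i cross y_i), sum(x_i dot y_i))
    ac = (a - a.mean(0)) / centroid_size(a)
    bc = (b0 - b0.mean(0)) / centroid_size(b0)
    cross = np.sum(bc[:, 0] * ac[:, 1] - bc[:, 1] * ac[:, 0])
    dot = np.sum(bc[:, 0] * ac[:, 0] + bc[:, 1] * ac[:, 1])
    th = np.arctan2(cross, dot)
    rot = np.array([[np.cos(th), np.sin(th), 0], [-np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    b_opa = bc @ rot
    d_opa = np.linalg.norm(ac - b_opa)

    aligned = gpa_align(
        [
            LandmarkConfiguration("a", "spA", a),
            LandmarkConfiguration("b", "spB", b0),
        ]
    )
    d_gpa = np.linalg.norm(aligned.pcoords[0] - aligned.pcoords[1])
    assert d_gpa == pytest.approx(d_opa, abs=1e-10)


def test_gpa_invariants(aligned_small):
    sizes = np.sqrt((aligned_small.pcoords**2).sum(axis=(1, 2)))
    assert np.allclose(sizes, 1.0, atol=1e-9)
    centroids = aligned_small.pcoords.mean(axis=1)
    assert np.abs(centroids).max() < 1e-9
    assert np.allclose(
        aligned_small.mean_shape, aligned_small.pcoords.mean(axis=0), atol=1e-12
    )
    # monotone descent of summed squared distance to the consensus
    ssq = aligned_small.ssq_history
    assert all(b <= a + 1e-10 for a, b in zip(ssq, ssq[1:]))


def test_gpa_no_reflection(rng):
    configs = _random_configs(rng, n=3, k=8)
    aligned = gpa_align(configs)
    for i, c in enumerate(configs):
        centred = (c.coords - c.coords.mean(0)) / centroid_size(c)
        r, *_ = np.linalg.lstsq(centred, aligned.pcoords[i], rcond=None)
        assert np.linalg.det(r) > 0


def test_gpa_sliding_smoke(small_study):
    slid = gpa_align(small_study.configs, slide_semilandmarks=True)
    sizes = np.sqrt((slid.pcoords**2).sum(axis=(1, 2)))
    assert np.allclose(sizes, 1.0, atol=1e-9)
    assert slid.n_iterations <= 100


# ---------------------------------------------------------------------------
# Subsets and species means


def test_subset_partition_and_realignment(aligned_small):
    labels = aligned_small.subsets
    counts = {s: int((labels == s).sum()) for s in ("facial", "neurocranial", "other")}
    assert sum(counts.values()) == aligned_small.n_landmarks
    assert subset_shapes(aligned_small, "total") is aligned_small
    fac = subset_shapes(aligned_small, "facial", realign=True)
    assert fac.n_landmarks == counts["facial"]
    sizes = np.sqrt((fac.pcoords**2).sum(axis=(1, 2)))
    assert np.allclose(sizes, 1.0, atol=1e-9)
    with pytest.raises(ValueError, match="no landmarks"):
        al = cm.AlignedShapes(
            pcoords=aligned_small.pcoords,
            csize=aligned_small.csize,
            specimen_ids=aligned_small.specimen_ids,
            species_ids=aligned_small.species_ids,
            roles=aligned_small.roles,
            subsets=np.full(aligned_small.n_landmarks, "facial", dtype=object),
            mean_shape=aligned_small.mean_shape,
        )
        subset_shapes(al, "neurocranial")


def test_species_means(aligned_small, small_study):
    ids, means = species_mean_shapes(aligned_small, tree=small_study.tree)
    assert ids == small_study.tree.tip_labels
    # brute-force mean for one species
    target = ids[0]
    rows = [i for i, sp in enumerate(aligned_small.species_ids) if sp == target]
    assert len(rows) == 3
    brute = sum(aligned_small.pcoords[i] for i in rows) / len(rows)
    np.testing.assert_allclose(means[0], brute, atol=1e-14)


def test_species_means_mirror_symmetry(rng):
    base = rng.standard_normal((6, 3))
    delta = 0.01 * rng.standard_normal((6, 3))
    al = cm.AlignedShapes(
        pcoords=np.stack([base + delta, base - delta]),
        csize=np.ones(2),
        specimen_ids=["x1", "x2"],
        species_ids=["sp", "sp"],
        roles=np.full(6, "fixed", dtype=object),
        subsets=np.full(6, "other", dtype=object),
        mean_shape=base,
    )
    ids, means = species_mean_shapes(al)
    np.testing.assert_allclose(means[0], base, atol=1e-15)
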