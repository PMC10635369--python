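import numpy as np
import pytest

from helixcontact.contact_map import ResiduePair, candidate_pairs
from helixcontact.features import (
    CF_LENGTH,
    SDF_LENGTH,
    WINDOW_OFFSETS,
    FeatureMatrix,
    HelixAxis,
    IncompleteNeighborhoodError,
    apply_scaler,
    cf_vector,
    extract_features,
    fit_scaler,
    helix_axis,
    interhelical_tilt,
    pair_distance_features,
    read_feature_matrix,
    relative_residue_angle,
    residue_plane_normal,
    sdf_vector,
    write_feature_matrix,
)
from helixcontact.structure_io import AtomRecord, ChainStructure, Residue, StructureError
from helixcontact.synthetic import BundleSpec, helix_bundle, ideal_helix

from conftest import make_residue, random_rotation, transform_chain


def angle_between(u, v):
    return np.degrees(np.arccos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)))


class TestHelixAxis:
    def test_recovers_generator_axis(self, helix12):
        chain, true_axis = helix12
        est = helix_axis(chain, (0, 11))
        assert angle_between(est.direction, true_axis) < 5.0

    def test_agrees_with_ca_line_fit(self, helix12):
        # secondary oracle: principal direction of the CA point cloud
        chain, _ = helix12
        ca = np.array([r.coords_of("CA") for r in chain.residues])
        centered = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        principal = vt[0] * np.sign(vt[0] @ (ca[-1] - ca[0]))
        est = helix_axis(chain, (0, 11))
        assert angle_between(est.direction, principal) < 5.0

    def test_equivariant_under_rotation(self, helix12, rng):
        chain, _ = helix12
        rot = random_rotation(rng)
        moved = transform_chain(chain, rot, np.zeros(3))
        base = helix_axis(chain, (0, 11)).direction
        np.testing.assert_allclose(
            helix_axis(moved, (0, 11)).direction, rot @ base, atol=1e-6
        )

    def test_too_short_segment(self, helix12):
        chain, _ = helix12
        with pytest.raises(StructureError, match="too short"):
            helix_axis(chain, (0, 3))

    def test_missing_backbone_atom_named(self, helix12):
        chain, _ = helix12
        broken = transform_chain(chain, np.eye(3), np.zeros(3))
        res = broken.residues[2]
        res.atoms = [a for a in res.atoms if a.name != "O"]
        with pytest.raises(StructureError, match="O in residue 2"):
            helix_axis(broken, (0, 11))

    def test_unit_invariant(self):
        with pytest.raises(StructureError):
            HelixAxis(direction=np.array([0.0, 0.0, 2.0]), segment=(0, 5))


class TestInterhelicalTilt:
    def test_parallel_zero(self):
        a = HelixAxis(direction=np.array([0.0, 0.0, 1.0]), segment=(0, 5))
        b = HelixAxis(direction=np.array([0.0, 0.0, 1.0]), segment=(10, 15))
        assert interhelical_tilt(a, b) == pytest.approx(0.0)

    def test_orthogonal_ninety(self):
        a = HelixAxis(direction=np.array([0.0, 0.0, 1.0]), segment=(0, 5))
        b = HelixAxis(direction=np.array([1.0, 0.0, 0.0]), segment=(10, 15))
        assert interhelical_tilt(a, b) == pytest.approx(90.0)

    def test_antiparallel_one_eighty(self):
        a = HelixAxis(direction=np.array([0.0, 0.0, 1.0]), segment=(0, 5))
        b = HelixAxis(direction=np.array([0.0, 0.0, -1.0]), segment=(10, 15))
        assert interhelical_tilt(a, b) == pytest.approx(180.0)

    def test_symmetric(self, rng):
        u = rng.normal(size=3)
        v = rng.normal(size=3)
        a = HelixAxis(direction=u / np.linalg.norm(u), segment=(0, 5))
        b = HelixAxis(direction=v / np.linalg.norm(v), segment=(10, 15))
        assert interhelical_tilt(a, b) == pytest.approx(interhelical_tilt(b, a))


class TestPairDistanceFeatures:
    def test_degenerate_single_atoms(self):
        a = make_residue(0, [(0.0, 0.0, 0.0)], names=["CA"])
        b = make_residue(1, [(7.0, 0.0, 0.0)], names=["CA"])
        d1, sd, da = pair_distance_features(a, b)
        assert d1 == pytest.approx(7.0)
        assert sd == pytest.approx(0.0)
        assert da == pytest.approx(7.0)

    def test_rigid_invariance(self, rng):
        coords_a = rng.normal(size=(4, 3))
        coords_b = rng.normal(size=(4, 3)) + 5
        a = make_residue(0, coords_a, names=["N", "CA", "C", "O"])
        b = make_residue(1, coords_b, names=["N", "CA", "C", "O"])
        rot, shift = random_rotation(rng), rng.normal(scale=10, size=3)
        a2 = make_residue(0, coords_a @ rot.T + shift, names=["N", "CA", "C", "O"])
        b2 = make_residue(1, coords_b @ rot.T + shift, names=["N", "CA", "C", "O"])
        np.testing.assert_allclose(
            pair_distance_features(a, b), pair_distance_features(a2, b2), atol=1e-9
        )

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            ca = rng.normal(scale=4, size=(4, 3))
            cb = rng.normal(scale=4, size=(4, 3))
            a = make_residue(0, ca, names=["N", "CA", "C", "O"])
            b = make_residue(1, cb, names=["N", "CA", "C", "O"])
            dists = [
                float(np.linalg.norm(x - y)) for x in ca for y in cb
            ]
            mean = sum(dists) / len(dists)
            var = sum((d - mean) ** 2 for d in dists) / len(dists)  # divisor MN
            d1, sd, da = pair_distance_features(a, b)
            assert d1 == pytest.approx(mean, abs=1e-8)
            assert sd == pytest.approx(var ** 0.5, abs=1e-8)
            assert da == pytest.approx(float(np.linalg.norm(ca[1] - cb[1])), abs=1e-8)

    def test_sd_mean_identity(self, rng):
        # population identity: sd^2 + mean^2 == mean of squared distances
        ca = rng.normal(scale=4, size=(5, 3))
        cb = rng.normal(scale=4, size=(6, 3))
        a = make_residue(0, ca, names=["N", "CA", "C", "O", "CB"])
        b = make_residue(1, cb, names=["N", "CA", "C", "O", "CB", "CG"])
        d1, sd, _ = pair_distance_features(a, b)
        sq = np.mean([np.linalg.norm(x - y) ** 2 for x in ca for y in cb])
        assert sd ** 2 + d1 ** 2 == pytest.approx(sq, abs=1e-8)

    def test_missing_ca(self):
        a = make_residue(0, [(0.0, 0.0, 0.0)], names=["N"])
        b = make_residue(1, [(7.0, 0.0, 0.0)], names=["CA"])
        with pytest.raises(StructureError, match="alpha carbon"):
            pair_distance_features(a, b)


class TestResiduePlane:
    def test_unit_cross_product(self):
        r = make_residue(0, [(1, 0, 0), (0, 0, 0), (0, 1, 0)], names=["N", "CA", "C"])
        np.testing.assert_allclose(residue_plane_normal(r), [0, 0, 1], atol=1e-12)

    def test_equivariance(self, rng):
        coords = rng.normal(size=(3, 3))
        r = make_residue(0, coords, names=["N", "CA", "C"])
        rot = random_rotation(rng)
        r2 = make_residue(0, coords @ rot.T, names=["N", "CA", "C"])
        np.testing.assert_allclose(
            residue_plane_normal(r2), rot @ residue_plane_normal(r), atol=1e-9
        )

    def test_collinear_degenerate(self):
        r = make_residue(0, [(1, 0, 0), (0, 0, 0), (-1, 0, 0)], names=["N", "CA", "C"])
        with pytest.raises(StructureError, match="degenerate"):
            residue_plane_normal(r)

    def test_relative_angle_translated_copy_zero(self, rng):
        coords = rng.normal(size=(3, 3))
        a = make_residue(0, coords, names=["N", "CA", "C"])
        b = make_residue(1, coords + 7, names=["N", "CA", "C"])
        assert relative_residue_angle(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_relative_angle_self_zero(self, rng):
        coords = rng.normal(size=(3, 3))
        a = make_residue(0, coords, names=["N", "CA", "C"])
        assert relative_residue_angle(a, a) == pytest.approx(0.0, abs=1e-9)

    def test_relative_angle_second_implementation(self, rng):
        # independent oracle: angle via explicit normalized cross products
        for _ in range(20):
            ca_, cb_ = rng.normal(size=(3, 3)), rng.normal(size=(3, 3))
            a = make_residue(0, ca_, names=["N", "CA", "C"])
            b = make_residue(1, cb_, names=["N", "CA", "C"])

            def normal(c):
                v = np.cross(c[0] - c[1], c[2] - c[1])
                return v / np.linalg.norm(v)

            expect = np.degrees(
                np.arccos(np.clip(np.dot(normal(ca_), normal(cb_)), -1, 1))
            )
            assert relative_residue_angle(a, b) == pytest.approx(expect, abs=1e-8)


@pytest.fixture(scope="module")
def bundle_and_pair():
    chain, ann = helix_bundle(BundleSpec(n_helices=2, residues_per_helix=15,
                                         inter_axial_distance=8.0, seed=3))
    pairs = candidate_pairs(chain, ann)
    # an interior pair whose window stays on both helices
    pair = next(
        p for p in pairs
        if ann.segment_of(p.i - 1) == ann.segment_of(p.i + 1) == p.helix_i
        and ann.segment_of(p.j - 1) == ann.segment_of(p.j + 1) == p.helix_j
    )
    return chain, ann, pair


class TestSdfVector:
    def test_length_40(self, bundle_and_pair):
        chain, ann, pair = bundle_and_pair
        assert sdf_vector(chain, ann, pair).shape == (SDF_LENGTH,)

    def test_rigid_motion_invariance(self, bundle_and_pair, rng):
        chain, ann, pair = bundle_and_pair
        base = sdf_vector(chain, ann, pair)
        for _ in range(5):
            rot = random_rotation(rng)
            moved = transform_chain(chain, rot, rng.normal(scale=20, size=3))
            np.testing.assert_allclose(sdf_vector(moved, ann, pair), base, atol=1e-6)

    def test_theta_slots_constant(self, bundle_and_pair):
        chain, ann, pair = bundle_and_pair
        vec = sdf_vector(chain, ann, pair)
        thetas = vec[0::5]
        assert np.all(thetas == thetas[0])

    def test_window_order_matches_neighbors(self, bundle_and_pair):
        chain, ann, pair = bundle_and_pair
        from helixcontact.features import pair_distance_features as pdf
        vec = sdf_vector(chain, ann, pair)
        for w, (di, dj) in enumerate(WINDOW_OFFSETS):
            d1, sd, da = pdf(chain[pair.i + di], chain[pair.j + dj])
            assert vec[5 * w + 1] == pytest.approx(d1)
            assert vec[5 * w + 3] == pytest.approx(da)

    def test_incomplete_window_raises(self, bundle_and_pair):
        chain, ann, _ = bundle_and_pair
        edge = ResiduePair(i=0, j=ann.segments[1][0] + 2,
                           helix_i=0, helix_j=1)
        with pytest.raises(IncompleteNeighborhoodError):
            sdf_vector(chain, ann, edge)

    def test_neighbor_theta_mode_differs(self, bundle_and_pair):
        chain, ann, pair = bundle_and_pair
        center = sdf_vector(chain, ann, pair, theta_mode="center")
        neighbor = sdf_vector(chain, ann, pair, theta_mode="neighbor")
        # same geometry features, same theta set (all neighbors on the same
        # two helices here)
        np.testing.assert_allclose(neighbor, center, atol=1e-9)


class TestCfVector:
    def test_length_192(self, bundle_and_pair):
        chain, _, pair = bundle_and_pair
        assert cf_vector(chain, pair).shape == (CF_LENGTH,)

    def test_translation_moves_every_x(self, bundle_and_pair):
        chain, _, pair = bundle_and_pair
        base = cf_vector(chain, pair)
        moved = transform_chain(chain, np.eye(3), np.array([10.0, 0.0, 0.0]))
        shifted = cf_vector(moved, pair)
        np.testing.assert_allclose(shifted[0::3], base[0::3] + 10.0, atol=1e-9)
        np.testing.assert_allclose(shifted[1::3], base[1::3], atol=1e-9)
        np.testing.assert_allclose(shifted[2::3], base[2::3], atol=1e-9)

    def test_glycine_cb_falls_back_to_ca(self):
        chain, ann = helix_bundle(BundleSpec(n_helices=2, residues_per_helix=15,
                                             inter_axial_distance=8.0, seed=3))
        pairs = candidate_pairs(chain, ann)
        pair = next(p for p in pairs if 0 < p.i and p.j < len(chain) - 1)
        target = chain[pair.i]
        target.atoms = [a for a in target.atoms if a.name != "CB"]
        target.aa_code = "G"
        vec = cf_vector(chain, pair)
        # window position (0,-1) holds residue i at block offset 3*24
        block = vec[3 * 24: 3 * 24 + 12]
        np.testing.assert_array_equal(block[9:12], block[3:6])  # CB == CA


class TestScaling:
    def _matrix(self, columns):
        n = len(columns[0])
        vectors = np.zeros((n, SDF_LENGTH))
        for k, col in enumerate(columns):
            vectors[:, k] = col
        pairs = [ResiduePair(i=k, j=k + 10, helix_i=0, helix_j=1) for k in range(n)]
        return FeatureMatrix(kind="SDF", vectors=vectors, pair_index=pairs,
                             sequence_ids=["s"] * n)

    def test_formula(self):
        m = self._matrix([[2.0, 4.0, 6.0]])
        scaled = apply_scaler(fit_scaler(m), m)
        np.testing.assert_allclose(scaled.vectors[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        m = self._matrix([[3.0, 3.0, 3.0]])
        scaled = apply_scaler(fit_scaler(m), m)
        np.testing.assert_array_equal(scaled.vectors[:, 0], [0.0, 0.0, 0.0])

    def test_test_values_not_clipped(self):
        train = self._matrix([[2.0, 4.0, 6.0]])
        params = fit_scaler(train)
        test = self._matrix([[0.0, 8.0, 4.0]])
        scaled = apply_scaler(params, test)
        assert scaled.vectors[0, 0] < -1.0
        assert scaled.vectors[1, 0] > 1.0

    def test_train_extremes_hit_bounds(self, rng):
        vectors = rng.normal(size=(20, SDF_LENGTH))
        m = FeatureMatrix(
            kind="SDF", vectors=vectors,
            pair_index=[ResiduePair(i=k, j=k + 10, helix_i=0, helix_j=1) for k in range(20)],
            sequence_ids=["s"] * 20,
        )
        scaled = apply_scaler(fit_scaler(m), m)
        np.testing.assert_allclose(scaled.vectors.min(axis=0), -1.0, atol=1e-12)
        np.testing.assert_allclose(scaled.vectors.max(axis=0), 1.0, atol=1e-12)

    def test_fit_apply_idempotent_on_scaled_frame(self, rng):
        vectors = rng.normal(size=(20, SDF_LENGTH))
        m = FeatureMatrix(
            kind="SDF", vectors=vectors,
            pair_index=[ResiduePair(i=k, j=k + 10, helix_i=0, helix_j=1) for k in range(20)],
            sequence_ids=["s"] * 20,
        )
        once = apply_scaler(fit_scaler(m), m)
        twice = apply_scaler(fit_scaler(once), once)
        np.testing.assert_allclose(twice.vectors, once.vectors, atol=1e-12)


class TestExtractFeatures:
    def test_skips_and_keeps_consistently(self, tight_bundle, tight_bundle_pairs):
        chain, ann = tight_bundle
        matrix, kept, skipped = extract_features(
            chain, ann, tight_bundle_pairs, "SDF", "seq0"
        )
        assert len(matrix) == len(kept)
        assert len(kept) + skipped == len(tight_bundle_pairs)
        assert skipped > 0  # terminal windows leave the helix ends

    def test_serialization_round_trip(self, tight_bundle, tight_bundle_pairs):
        chain, ann = tight_bundle
        matrix, _, _ = extract_features(chain, ann, tight_bundle_pairs, "SDF", "seq0")
        back = read_feature_matrix(write_feature_matrix(matrix), "SDF")
        np.testing.assert_allclose(back.vectors, matrix.vectors, rtol=1e-9)
        assert back.sequence_ids == matrix.sequence_ids
        assert [(p.i, p.j) for p in back.pair_index] == [
            (p.i, p.j) for p in matrix.pair_index
        ]
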