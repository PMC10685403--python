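"""Graph topology and node/edge feature channels."""

import numpy as np
import pytest

from graphmqa.decoys import build_backbone
from graphmqa.features import (
    backbone_dihedrals,
    build_graph,
    dihedral_sincos,
    featurize,
    pair_geometry,
    rbf_expand,
    relative_position_encoding,
    residue_frames,
    secondary_structure,
)
from graphmqa.structure import RigidTransform, apply_transform

from conftest import make_structure_from_ca, random_structure


class TestBuildGraph:
    def test_k_capped_at_n_minus_one(self, collinear3):
        knn = build_graph(collinear3, 30)
        assert knn.shape == (3, 2)

    def test_chain_neighbors_first(self):
        ca = np.zeros((8, 3))
        ca[:, 0] = 3.8 * np.arange(8)
        s = make_structure_from_ca(ca)
        knn = build_graph(s, 3)
        for i in range(1, 7):
            assert set(knn[i, :2]) == {i - 1, i + 1}

    @pytest.mark.parametrize("n", [5, 40, 100])
    def test_agrees_with_bruteforce_sort(self, rng, n):
        s = random_structure(rng, n)
        k = 10
        knn = build_graph(s, k)
        ca = s.ca
        for i in range(n):
            d = np.linalg.norm(ca - ca[i], axis=1)
            d[i] = np.inf
            expected = np.lexsort((np.arange(n), d))[: min(k, n - 1)]
            np.testing.assert_array_equal(knn[i], expected)


class TestPositionalEncoding:
    def test_zero_offset_alternates_zero_one(self):
        enc = relative_position_encoding(5, 5, 16)
        np.testing.assert_allclose(enc[0::2], 0.0)
        np.testing.assert_allclose(enc[1::2], 1.0)

    def test_antisymmetric_sine_channels(self):
        fwd = relative_position_encoding(10, 3, 16)
        bwd = relative_position_encoding(3, 10, 16)
        np.testing.assert_allclose(fwd[0::2], -bwd[0::2], atol=1e-12)
        np.testing.assert_allclose(fwd[1::2], bwd[1::2], atol=1e-12)

    def test_clipping_beyond_window(self):
        far = relative_position_encoding(120, 0, 16)
        at_clip = relative_position_encoding(32, 0, 16)
        np.testing.assert_array_equal(far, at_clip)


class TestDihedrals:
    def test_roundtrip_through_builder(self):
        n = 15
        phi = np.linspace(-150, -50, n)
        psi = np.linspace(-60, 140, n)
        s = build_backbone("A" * n, phi, psi)
        ang = np.degrees(backbone_dihedrals(s))
        np.testing.assert_allclose(ang[1:, 0], phi[1:], atol=1e-6)
        np.testing.assert_allclose(ang[:-1, 1], psi[:-1], atol=1e-6)

    def test_terminal_angles_undefined(self, helix20):
        ang = backbone_dihedrals(helix20)
        assert np.isnan(ang[0, 0]) and np.isnan(ang[0, 2])
        assert np.isnan(ang[-1, 1])
        enc = dihedral_sincos(ang)
        assert enc[0, 0] == 0.0 and enc[0, 1] == 0.0

    def test_rigid_invariance(self, rng, toy30):
        # compare on sin/cos to avoid the +-pi wrap of trans omega angles
        base = dihedral_sincos(backbone_dihedrals(toy30))
        t = RigidTransform.random(rng)
        moved = dihedral_sincos(backbone_dihedrals(apply_transform(toy30, t)))
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_mirror_negates(self, toy30):
        import dataclasses

        mirrored = dataclasses.replace(toy30, coords=toy30.coords * [1, 1, -1])
        base = backbone_dihedrals(toy30)
        flipped = backbone_dihedrals(mirrored)
        defined = ~np.isnan(base)
        np.testing.assert_allclose(flipped[defined], -base[defined], atol=1e-9)


class TestSecondaryStructure:
    def test_helix_interior(self, helix20):
        states = secondary_structure(helix20)
        assert set(states[1:-1]) == {"H"}

    def test_strand_interior(self):
        n = 15
        s = build_backbone("A" * n, np.full(n, -120.0), np.full(n, 120.0))
        states = secondary_structure(s)
        assert set(states[1:-1]) == {"E"}

    def test_terminals_coil(self, helix20):
        states = secondary_structure(helix20)
        assert states[0] == "C" and states[-1] == "C"


class TestPairGeometry:
    def test_self_pair_identity(self, toy30):
        frames = residue_frames(toy30)
        s_ij, q = pair_geometry(frames, toy30.ca, 4, 4)
        np.testing.assert_allclose(s_ij, 0.0, atol=1e-12)
        np.testing.assert_allclose(q, [1, 0, 0, 0], atol=1e-12)

    def test_invariance_under_global_transform(self, rng, toy30):
        frames = residue_frames(toy30)
        base_s, base_q = pair_geometry(frames, toy30.ca, 2, 17)
        for _ in range(10):
            t = RigidTransform.random(rng)
            moved = apply_transform(toy30, t)
            mf = residue_frames(moved)
            s_ij, q = pair_geometry(mf, moved.ca, 2, 17)
            np.testing.assert_allclose(s_ij, base_s, atol=1e-9)
            np.testing.assert_allclose(q, base_q, atol=1e-9)

    def test_local_vector_norm_is_ca_distance(self, toy30):
        frames = residue_frames(toy30)
        s_ij, _ = pair_geometry(frames, toy30.ca, 3, 21)
        d = np.linalg.norm(toy30.ca[21] - toy30.ca[3])
        assert np.linalg.norm(s_ij) == pytest.approx(d, abs=1e-9)


class TestRbf:
    def test_peak_at_center(self):
        centers = np.linspace(0, 20, 16)
        out = rbf_expand(np.array(centers[5]), centers, 1.0)
        assert out[5] == pytest.approx(1.0)

    def test_midpoint_symmetry(self):
        centers = np.linspace(0, 20, 16)
        mid = 0.5 * (centers[3] + centers[4])
        out = rbf_expand(np.array(mid), centers, 1.3)
        assert out[3] == pytest.approx(out[4])

    def test_range(self, rng):
        centers = np.linspace(0, 20, 16)
        out = rbf_expand(rng.uniform(0, 25, size=50), centers, 1.3)
        assert (out > 0).all() and (out <= 1).all()


class TestFeatureBundle:
    def test_no_nan_and_reproducible(self, toy30):
        a = featurize(toy30, k=10)
        b = featurize(toy30, k=10)
        assert np.isfinite(a.node_features).all()
        assert np.isfinite(a.edge_features).all()
        np.testing.assert_array_equal(a.node_features, b.node_features)
        np.testing.assert_array_equal(a.edge_features, b.edge_features)
        assert a.layout_hash == b.layout_hash

    def test_invariant_channels_under_rigid_transforms(self, rng, toy30):
        base = featurize(toy30, k=10)
        inv = base.node_invariant_mask()
        for _ in range(5):
            t = RigidTransform.random(rng)
            moved = featurize(apply_transform(toy30, t), k=10)
            np.testing.assert_allclose(
                moved.node_features[:, inv], base.node_features[:, inv], atol=1e-6
            )
            np.testing.assert_allclose(
                moved.edge_features, base.edge_features, atol=1e-6
            )

    def test_pose_channels_can_be_excluded(self, rng, toy30):
        base = featurize(toy30, k=10, include_pose_channels=False)
        t = RigidTransform.random(rng)
        moved = featurize(apply_transform(toy30, t), k=10,
                          include_pose_channels=False)
        np.testing.assert_allclose(moved.node_features, base.node_features,
                                   atol=1e-6)

    def test_energy_provider_hook(self, toy30):
        n = len(toy30)
        bundle = featurize(toy30, k=5,
                           energy_provider=lambda s: np.full((n, n, 1), 2.5))
        off, size = bundle.layout["edge_channels"]["pair_energy"]
        assert size == 1
        assert (bundle.edge_features[:, :, off] == 2.5).all()
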