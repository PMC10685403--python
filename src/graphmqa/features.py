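"""Residue-graph construction and node/edge feature assembly.

Node channels combine sequence-level information (sinusoidal position
encoding, Meiler physicochemical descriptors, BLOSUM62 substitution profile),
local geometry (phi/psi/omega dihedrals, 3-state secondary structure from a
dihedral-region rule) and topology descriptors (triangular location, residue
contact order, a pose-invariant voxel grid of the backbone neighbourhood).

Edge channels describe each residue pair by Gaussian radial-basis expansions
of the five backbone-atom distances, the inter-residue displacement expressed
in the source residue's local frame, the relative rotation between the two
local frames (as a quaternion), pair contact order, and a sinusoidal encoding
of the (clipped) sequence separation.  A physicochemical energy channel is
present in the schema but zero-filled unless an external provider supplies it.

All channels except the triangular-location Euler angles are invariant under
global rigid motion; the layout metadata marks those pose-sensitive columns
so callers can drop them when strict invariance is required.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ContractError, DegenerateInputError
from .structure import BackboneStructure
from .topology import contact_order, local_frame, triangular_location, voxelize

RELPOS_CLIP = 32

# Meiler (2001) 7-parameter amino-acid descriptors.
MEILER = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94, 0.32, 0.42),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
}
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def _blosum62_rows() -> dict[str, np.ndarray]:
    from biotite.sequence.align import SubstitutionMatrix

    mat = SubstitutionMatrix.std_protein_matrix()
    alph = mat.get_alphabet1()
    rows = {}
    for a in AA_ORDER:
        ia = alph.encode(a)
        rows[a] = np.array(
            [mat.score_matrix()[ia, alph.encode(b)] for b in AA_ORDER], dtype=float
        )
    return rows


_BLOSUM_ROWS = _blosum62_rows()
_BLOSUM_FALLBACK = np.zeros(20)


def positional_encoding(index: float, d_model: int) -> np.ndarray:
    """Interleaved (sin, cos) sinusoidal encoding of a scalar index."""
    if d_model % 2:
        raise ContractError("d_model must be even")
    k = np.arange(d_model // 2)
    freqs = index / (10000.0 ** (2 * k / d_model))
    out = np.empty(d_model)
    out[0::2] = np.sin(freqs)
    out[1::2] = np.cos(freqs)
    return out


def relative_position_encoding(i: int, j: int, d_model: int = 16) -> np.ndarray:
    """Sinusoidal encoding of the clipped sequence separation ``i - j``."""
    rel = int(np.clip(i - j, -RELPOS_CLIP, RELPOS_CLIP))
    return positional_encoding(rel, d_model)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def backbone_dihedrals(s: BackboneStructure) -> np.ndarray:
    """Per-residue (phi, psi, omega) in radians; NaN where undefined.

    phi_i uses C(i-1); psi_i uses N(i+1); omega_i is the torsion of the
    peptide bond *preceding* residue i.  Angles across chain breaks are
    undefined.
    """
    n = len(s)
    if n < 2:
        raise DegenerateInputError("need >= 2 residues for dihedrals")
    N, CA, C = s.coords[:, 0], s.coords[:, 1], s.coords[:, 2]
    out = np.full((n, 3), np.nan)
    for i in range(n):
        prev_ok = i > 0 and s.chain_ids[i - 1] == s.chain_ids[i]
        next_ok = i + 1 < n and s.chain_ids[i + 1] == s.chain_ids[i]
        if prev_ok:
            out[i, 0] = _dihedral(C[i - 1], N[i], CA[i], C[i])
            out[i, 2] = _dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
        if next_ok:
            out[i, 1] = _dihedral(N[i], CA[i], C[i], N[i + 1])
    return out


def dihedral_sincos(angles: np.ndarray) -> np.ndarray:
    """(N, 3) angles -> (N, 6) interleaved sin/cos; undefined -> (0, 0)."""
    out = np.zeros((angles.shape[0], 6))
    defined = ~np.isnan(angles)
    out[:, 0::2][defined] = np.sin(angles[defined])
    out[:, 1::2][defined] = np.cos(angles[defined])
    return out


# Dihedral-region secondary-structure rule (degrees).
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-180.0, -80.0)
_STRAND_PSI_A = (80.0, 180.0)
_STRAND_PSI_B = (-180.0, -170.0)


def secondary_structure(s: BackboneStructure) -> np.ndarray:
    """3-state (H/E/C) assignment from a self-contained phi/psi-region rule.

    A pluggable stand-in for hydrogen-bond-pattern assignment: residues
    whose (phi, psi) fall in the canonical alpha region are H, those in the
    beta region are E, everything else (including residues with undefined
    dihedrals) is C.
    """
    if len(s) < 3:
        raise DegenerateInputError("need >= 3 residues for secondary structure")
    ang = np.degrees(backbone_dihedrals(s))
    states = np.full(len(s), "C", dtype="<U1")
    for i, (phi, psi, _) in enumerate(ang):
        if np.isnan(phi) or np.isnan(psi):
            continue
        if _HELIX_PHI[0] <= phi <= _HELIX_PHI[1] and _HELIX_PSI[0] <= psi <= _HELIX_PSI[1]:
            states[i] = "H"
        elif _STRAND_PHI[0] <= phi <= _STRAND_PHI[1] and (
            _STRAND_PSI_A[0] <= psi <= _STRAND_PSI_A[1]
            or _STRAND_PSI_B[0] <= psi <= _STRAND_PSI_B[1]
        ):
            states[i] = "E"
    return states


def ss_onehot(states: np.ndarray) -> np.ndarray:
    onehot = np.zeros((len(states), 3))
    for i, st in enumerate(states):
        onehot[i, "HEC".index(st)] = 1.0
    return onehot


def build_graph(s: BackboneStructure, k: int) -> np.ndarray:
    """K-nearest-neighbour indices by CA distance, ascending, ties by index."""
    n = len(s)
    if n < 2:
        raise DegenerateInputError("need >= 2 residues to build a graph")
    ca = s.ca
    diff = ca[:, None, :] - ca[None, :, :]
    d = np.sqrt((diff * diff).sum(-1))
    np.fill_diagonal(d, np.inf)
    k_eff = min(k, n - 1)
    idx = np.arange(n)
    knn = np.empty((n, k_eff), dtype=int)
    for i in range(n):
        order = np.lexsort((idx, d[i]))
        knn[i] = order[:k_eff]
    return knn


def residue_frames(s: BackboneStructure) -> np.ndarray:
    """(N, 3, 3) local frames (columns = axes) from N/CA/C Gram-Schmidt."""
    return np.stack(
        [local_frame(s.coords[i, 0], s.coords[i, 1], s.coords[i, 2]) for i in range(len(s))]
    )


def pair_geometry(
    frames: np.ndarray, ca: np.ndarray, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-relative displacement ``s_ij`` and rotation quaternion ``Q_ij``.

    ``s_ij = R_i^T (CA_j - CA_i)``; ``Q_ij`` is the scalar-first quaternion of
    ``R_i^T R_j`` with its sign fixed to a non-negative scalar part.  Both are
    invariant under a global rigid transform of the structure.
    """
    s_ij = frames[i].T @ (ca[j] - ca[i])
    rel = frames[i].T @ frames[j]
    q = Rotation.from_matrix(rel).as_quat()  # (x, y, z, w)
    q = np.array([q[3], q[0], q[1], q[2]])
    if q[0] < 0 or (q[0] == 0 and (q[np.nonzero(q)[0][0]] < 0 if q.any() else False)):
        q = -q
    return s_ij, q


def rbf_expand(d, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian radial-basis expansion of distances (broadcasts over ``d``)."""
    if sigma <= 0:
        raise ContractError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    return np.exp(-((d[..., None] - centers) ** 2) / (2.0 * sigma**2))


def default_rbf_centers(n_centers: int = 16, d_max: float = 20.0) -> tuple[np.ndarray, float]:
    centers = np.linspace(0.0, d_max, n_centers)
    return centers, float(centers[1] - centers[0])


@dataclass
class FeatureBundle:
    """Everything the network consumes, plus layout metadata."""

    node_features: np.ndarray  # (N, Dn)
    edge_features: np.ndarray  # (N, N, De)
    knn_indices: np.ndarray    # (N, K)
    frames: np.ndarray         # (N, 3, 3)
    coords: np.ndarray         # (N, 3) CA positions
    layout: dict = field(default_factory=dict)

    @property
    def layout_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.layout, sort_keys=True).encode()
        ).hexdigest()[:16]

    def node_invariant_mask(self) -> np.ndarray:
        """Boolean mask over node columns that are pose-invariant."""
        mask = np.ones(self.node_features.shape[1], dtype=bool)
        for name, (off, size) in self.layout["node_channels"].items():
            if name in self.layout["pose_sensitive"]:
                mask[off : off + size] = False
        return mask


def featurize(
    s: BackboneStructure,
    k: int = 30,
    d_pos: int = 16,
    n_rbf: int = 16,
    rbf_max: float = 20.0,
    voxel_grid: int = 8,
    voxel_extent: float = 16.0,
    energy_provider=None,
    include_pose_channels: bool = True,
) -> FeatureBundle:
    """Assemble the full :class:`FeatureBundle` for one structure.

    ``energy_provider``, when given, must map the structure to an
    ``(N, N, 1)`` inter-residue energy array; by default the channel is
    zero-filled.  ``include_pose_channels=False`` zeroes the triangular-
    location Euler columns so every emitted value is pose-invariant.
    """
    n = len(s)
    if n < 3:
        raise DegenerateInputError("featurization needs >= 3 residues")
    ca = s.ca
    frames = residue_frames(s)
    knn = build_graph(s, k)
    centers, sigma = default_rbf_centers(n_rbf, rbf_max)

    # --- node features ---
    tri = [triangular_location(s, i) for i in range(n)]
    co = contact_order(s)
    dihed = backbone_dihedrals(s)
    parts = {
        "position_encoding": np.stack([positional_encoding(i, d_pos) for i in range(n)]),
        "meiler": np.stack([np.array(MEILER.get(a, np.zeros(7))) for a in s.sequence]),
        "blosum62": np.stack(
            [_BLOSUM_ROWS.get(a, _BLOSUM_FALLBACK) for a in s.sequence]
        ),
        "secondary_structure": ss_onehot(secondary_structure(s)),
        "dihedrals": dihedral_sincos(dihed),
        "tri_sides": np.stack([t.side_lengths for t in tri]),
        "tri_avg_dist": np.stack([t.avg_distances for t in tri]),
        "tri_euler": np.stack(
            [dihedral_sincos(t.euler_angles[None, :])[0] for t in tri]
        ),
        "contact_order": co.node_order[:, None],
        "voxels": np.stack(
            [voxelize(s, i, voxel_grid, voxel_extent).ravel() for i in range(n)]
        ),
    }
    if not include_pose_channels:
        parts["tri_euler"] = np.zeros_like(parts["tri_euler"])
    node_layout, off = {}, 0
    for name, arr in parts.items():
        node_layout[name] = (off, arr.shape[1])
        off += arr.shape[1]
    node = np.concatenate(list(parts.values()), axis=1)

    # --- edge features (dense N x N) ---
    atom_dists = np.stack(
        [
            np.linalg.norm(s.coords[:, None, a, :] - s.coords[None, :, a, :], axis=-1)
            for a in range(5)
        ],
        axis=-1,
    )  # (N, N, 5) for N, CA, C, O, CB
    rbf = rbf_expand(atom_dists, centers, sigma).reshape(n, n, 5 * len(centers))

    s_ij = np.empty((n, n, 3))
    q_ij = np.empty((n, n, 4))
    for i in range(n):
        rel_ca = (ca - ca[i]) @ frames[i]
        s_ij[i] = rel_ca
        rel_rot = np.einsum("ab,jbc->jac", frames[i].T, frames)
        quat = Rotation.from_matrix(rel_rot).as_quat()
        quat = np.concatenate([quat[:, 3:4], quat[:, :3]], axis=1)
        flip = quat[:, 0] < 0
        quat[flip] = -quat[flip]
        q_ij[i] = quat

    rel_idx = np.arange(n)[:, None] - np.arange(n)[None, :]
    relpos = np.stack(
        [
            positional_encoding(int(np.clip(r, -RELPOS_CLIP, RELPOS_CLIP)), d_pos)
            for r in rel_idx.ravel()
        ]
    ).reshape(n, n, d_pos)

    energy = (
        np.asarray(energy_provider(s), dtype=float)
        if energy_provider is not None
        else np.zeros((n, n, 1))
    )

    eparts = {
        "rbf_distances": rbf,
        "local_vector": s_ij,
        "frame_quaternion": q_ij,
        "pair_contact_order": co.pair_order[:, :, None],
        "relative_position": relpos,
        "pair_energy": energy,
    }
    edge_layout, off = {}, 0
    for name, arr in eparts.items():
        edge_layout[name] = (off, arr.shape[2])
        off += arr.shape[2]
    edge = np.concatenate(list(eparts.values()), axis=2)

    layout = {
        "node_channels": node_layout,
        "edge_channels": edge_layout,
        "pose_sensitive": ["tri_euler"],
        "k_requested": k,
        "d_pos": d_pos,
        "rbf_centers": centers.tolist(),
        "rbf_sigma": sigma,
        "voxel_grid": voxel_grid,
        "voxel_extent": voxel_extent,
    }
    if not (np.isfinite(node).all() and np.isfinite(edge).all()):
        raise ContractError("non-finite feature values")
    return FeatureBundle(
        node_features=node,
        edge_features=edge,
        knn_indices=knn,
        frames=frames,
        coords=ca.copy(),
        layout=layout,
    )


def save_features(bundle: FeatureBundle, path, sidecar_path=None) -> None:
    np.savez_compressed(
        path,
        node_features=bundle.node_features,
        edge_features=bundle.edge_features,
        knn_indices=bundle.knn_indices,
        frames=bundle.frames,
        coords=bundle.coords,
    )
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump({"layout": bundle.layout, "layout_hash": bundle.layout_hash}, fh, indent=2)
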