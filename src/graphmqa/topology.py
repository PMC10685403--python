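"""Topology descriptors: triangular location, residue contact order, voxels.

Three residue-level descriptors tie each residue's local environment to the
global fold:

* **Triangular location** -- for residue ``i`` (point ``P1``), find the CA
  farthest from it (``P2``) and the CA farthest from ``P2`` excluding both
  (``P3``).  The triangle's side lengths, the mean distance of all residues
  to each vertex, and the Euler angles of a local frame anchored at ``P1``
  describe where the residue sits relative to the protein's extremes.  The
  distances are pose-invariant; the Euler angles rotate with the structure.
* **Contact order** -- classical topological complexity, extended to a
  per-residue form ``O_i`` (mean sequence separation of spatial neighbours
  within 15 A, normalised by neighbour count and chain length) and a
  per-pair form ``O_ij = |i-j| / d_ij``.
* **Voxelization** -- occupancy counts of backbone atoms on a cubic grid
  expressed in the residue's own N/CA/C frame, which makes the counts
  invariant to global pose.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateInputError, GeometryError
from .structure import BackboneStructure

logger = logging.getLogger(__name__)

CONTACT_RADIUS = 15.0


@dataclass
class TriangularLocation:
    """Triangle anchored at one residue against the fold's extreme points."""

    side_lengths: np.ndarray   # (D12, D13, D23)
    avg_distances: np.ndarray  # mean distance of all CA to P1, P2, P3
    euler_angles: np.ndarray   # intrinsic ZYX angles of the local frame
    vertices: tuple            # residue indices (i, p2, p3)
    degenerate: bool


@dataclass
class ContactOrderFeatures:
    node_order: np.ndarray  # (N,)
    pair_order: np.ndarray  # (N, N), symmetric, zero diagonal


def _argmax_lowest_index(values: np.ndarray, exclude: set[int]) -> int:
    """Index of the maximum, excluding some indices; ties -> lowest index."""
    best, best_val = -1, -np.inf
    for j, v in enumerate(values):
        if j in exclude:
            continue
        if v > best_val + 1e-12:
            best, best_val = j, v
    return best


def triangular_location(s: BackboneStructure, i: int) -> TriangularLocation:
    """Triangular-location descriptor of residue ``i``."""
    n = len(s)
    if n < 3:
        raise DegenerateInputError("triangular location needs >= 3 residues")
    ca = s.ca
    p1 = ca[i]
    d_from_p1 = np.linalg.norm(ca - p1, axis=1)
    i2 = _argmax_lowest_index(d_from_p1, {i})
    p2 = ca[i2]
    d_from_p2 = np.linalg.norm(ca - p2, axis=1)
    i3 = _argmax_lowest_index(d_from_p2, {i, i2})
    p3 = ca[i3]

    sides = np.array([
        np.linalg.norm(p2 - p1),
        np.linalg.norm(p3 - p1),
        np.linalg.norm(p3 - p2),
    ])
    avgs = np.array([
        np.linalg.norm(ca - p, axis=1).mean() for p in (p1, p2, p3)
    ])

    ex = p3 - p1
    nex = np.linalg.norm(ex)
    if nex < 1e-8:
        raise DegenerateInputError("P3 coincides with P1")
    ex = ex / nex
    v = p2 - p1
    v_ex = (v @ ex) * ex
    rej = v - v_ex
    nrej = np.linalg.norm(rej)
    degenerate = nrej < 1e-8
    if degenerate:
        # collinear triangle: any unit vector orthogonal to ex
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ ex) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        ey = np.cross(ex, trial)
        ey /= np.linalg.norm(ey)
    else:
        ey = rej / nrej
    ez = np.cross(ex, ey)
    frame = np.stack([ex, ey, ez], axis=1)  # columns are the axes
    euler = Rotation.from_matrix(frame).as_euler("ZYX")
    return TriangularLocation(
        side_lengths=sides,
        avg_distances=avgs,
        euler_angles=euler,
        vertices=(i, i2, i3),
        degenerate=degenerate,
    )


def contact_order(s: BackboneStructure) -> ContactOrderFeatures:
    """Per-residue and per-pair contact order on CA distances."""
    n = len(s)
    if n < 2:
        raise DegenerateInputError("contact order needs >= 2 residues")
    ca = s.ca
    diff = ca[:, None, :] - ca[None, :, :]
    d = np.sqrt((diff * diff).sum(-1))
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)

    within = (d <= CONTACT_RADIUS) & ~np.eye(n, dtype=bool)
    r = within.sum(axis=1)
    node = np.zeros(n)
    ok = r > 0
    node[ok] = (sep * within).sum(axis=1)[ok] / (r[ok] * n)

    pair = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    coincident = off & (d < 1e-9)
    if coincident.any():
        logger.warning("coincident CA atoms: %d pairs skipped in pair contact order",
                       int(coincident.sum()) // 2)
    valid = off & ~coincident
    pair[valid] = sep[valid] / d[valid]
    return ContactOrderFeatures(node_order=node, pair_order=pair)


def local_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame from backbone atoms (Gram-Schmidt).

    The first axis points along CA->C, the second is the CA->N direction
    orthogonalised against it, the third their cross product.  Returns the
    3x3 matrix whose *columns* are the axes.
    """
    e1 = c - ca
    n1 = np.linalg.norm(e1)
    if n1 < 1e-8:
        raise GeometryError("C coincides with CA")
    e1 = e1 / n1
    u = n - ca
    u = u - (u @ e1) * e1
    n2 = np.linalg.norm(u)
    if n2 < 1e-8:
        raise GeometryError("collinear N, CA, C: frame undefined")
    e2 = u / n2
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=1)


def voxelize(s: BackboneStructure, i: int, grid: int = 8, extent: float = 16.0) -> np.ndarray:
    """Occupancy counts of backbone atoms around residue ``i``.

    All backbone atoms of the structure are expressed in residue ``i``'s
    local frame (origin at its CA) and binned on a ``grid**3`` lattice over
    the cube ``[-extent/2, extent/2)^3``.  Atoms outside the cube are
    discarded.  Imputed CB atoms participate like real ones.
    """
    frame = local_frame(s.coords[i, 0], s.coords[i, 1], s.coords[i, 2])
    atoms = s.coords.reshape(-1, 3)
    local = (atoms - s.ca[i]) @ frame  # project onto frame axes
    half = extent / 2.0
    width = extent / grid
    idx = np.floor((local + half) / width).astype(int)
    inside = ((idx >= 0) & (idx < grid)).all(axis=1)
    counts = np.zeros((grid, grid, grid))
    np.add.at(counts, tuple(idx[inside].T), 1.0)
    return counts
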