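"""Shared fixtures: small structures, random-structure factories, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from graphmqa.decoys import build_backbone, toy_reference
from graphmqa.structure import BackboneStructure, RigidTransform, impute_cbeta


def make_structure_from_ca(ca: np.ndarray, sequence: str | None = None,
                           chain_ids=None) -> BackboneStructure:
    """Build a full backbone around given CA positions.

    N and C are placed at fixed offsets from each CA (non-collinear), O and
    CB by the standard constructions, so geometry-only operations (lDDT,
    contact order, KNN) see exactly the requested CA geometry.
    """
    n = len(ca)
    sequence = sequence or "A" * n
    coords = np.zeros((n, 5, 3))
    n_off = np.array([-0.8, 1.1, 0.3])
    c_off = np.array([1.2, 0.7, -0.4])
    for i in range(n):
        coords[i, 1] = ca[i]
        coords[i, 0] = ca[i] + n_off
        coords[i, 2] = ca[i] + c_off
        coords[i, 3] = ca[i] + np.array([1.8, 1.4, -0.9])
        coords[i, 4] = impute_cbeta(coords[i, 0], coords[i, 1], coords[i, 2])
    return BackboneStructure(
        sequence=sequence,
        chain_ids=np.array(
            list(chain_ids) if chain_ids is not None else ["A"] * n, dtype=object
        ),
        residue_numbers=np.arange(1, n + 1),
        coords=coords,
        cb_present=np.ones(n, dtype=bool),
    )


def random_structure(rng: np.random.Generator, n: int) -> BackboneStructure:
    """Random self-avoiding-ish chain with ~3.8 A CA steps."""
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    ca = np.concatenate([[np.zeros(3)], np.cumsum(3.8 * steps, axis=0)])
    return make_structure_from_ca(ca)


def random_built_structure(rng: np.random.Generator, n: int) -> BackboneStructure:
    """Random idealized backbone from sampled dihedrals."""
    phi = rng.uniform(-150, -40, size=n)
    psi = rng.uniform(-70, 150, size=n)
    return build_backbone("A" * n, phi, psi)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy30() -> BackboneStructure:
    return toy_reference(30)


@pytest.fixture
def helix20() -> BackboneStructure:
    n = 20
    return build_backbone("A" * n, np.full(n, -57.0), np.full(n, -47.0))


@pytest.fixture
def collinear3() -> BackboneStructure:
    """Three CA atoms on the x axis at 0, 3.8, 7.6 A."""
    ca = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    return make_structure_from_ca(ca)


def random_transform(rng: np.random.Generator) -> RigidTransform:
    return RigidTransform.random(rng)


# ---------------------------------------------------------------------------
# independent oracles (deliberately written as plain double loops)
# ---------------------------------------------------------------------------
def lddt_oracle(model_ca: np.ndarray, ref_ca: np.ndarray,
                radius: float = 15.0,
                thresholds=(0.5, 1.0, 2.0, 4.0)) -> np.ndarray:
    """Brute-force per-residue lDDT, independent of the package code path."""
    n = len(ref_ca)
    out = np.ones(n)
    for i in range(n):
        kept = 0
        passed = 0
        for j in range(n):
            if j == i:
                continue
            d_ref = float(np.sqrt(((ref_ca[i] - ref_ca[j]) ** 2).sum()))
            if d_ref >= radius:
                continue
            kept += 1
            d_mod = float(np.sqrt(((model_ca[i] - model_ca[j]) ** 2).sum()))
            for s in thresholds:
                if abs(d_mod - d_ref) < s:
                    passed += 1
        if kept:
            out[i] = passed / (kept * len(thresholds))
    return out


def contact_order_oracle(ca: np.ndarray, radius: float = 15.0) -> np.ndarray:
    """Brute-force per-residue contact order."""
    n = len(ca)
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        count = 0
        for j in range(n):
            if j == i:
                continue
            if np.linalg.norm(ca[i] - ca[j]) <= radius:
                total += abs(i - j)
                count += 1
        if count:
            out[i] = total / (count * n)
    return out
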