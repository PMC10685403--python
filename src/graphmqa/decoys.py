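"""Synthetic reference structures and decoy ensembles.

References are idealized backbones grown residue-by-residue from dihedral
angles (NeRF-style sequential placement with ideal bond lengths and angles).
Decoys are produced by adding Gaussian noise to the phi/psi angles of a
random subset of residues and rebuilding the chain -- the dihedral-adjustment
strategy for decoy generation.  Because a small angular change near the
middle of the chain moves everything downstream, the resulting ensembles
span a broad range of per-residue lDDT, which is what a quality-assessment
network needs to see during training.

No relaxation is applied after perturbation: at the sigma values used here
the occasional steric clash is irrelevant for distance-based labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .lddt import LDDTLabels, compute_lddt
from .structure import BackboneStructure, impute_cbeta

# Ideal backbone parameters (angstrom / degrees) for trans peptides.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with given bond c-d, angle b-c-d and torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ContractError("collinear support atoms in chain construction")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray | None = None,
    chain_id: str = "A",
) -> BackboneStructure:
    """Grow an idealized backbone from per-residue dihedrals (degrees).

    ``phi[0]`` and ``omega[0]`` do not influence the geometry (the first
    residue has no preceding peptide bond); ``psi[-1]`` only orients the
    terminal carbonyl oxygen.  Two calls with identical inputs produce
    bitwise-identical coordinates.
    """
    L = len(sequence)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    omega = np.full(L, 180.0) if omega is None else np.asarray(omega, dtype=float)
    if not (len(phi) == len(psi) == len(omega) == L):
        raise ContractError("angle arrays must match sequence length")

    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    # CA->C makes the ideal N-CA-C angle with CA->N (which points along -x)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])

    for i in range(1, L):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega[i])
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi[i])

    O = np.zeros((L, 3))
    for i in range(L):
        O[i] = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)

    CB = np.zeros((L, 3))
    cb_present = np.zeros(L, dtype=bool)
    for i, aa in enumerate(sequence):
        CB[i] = impute_cbeta(N[i], CA[i], C[i])
        cb_present[i] = aa != "G"

    coords = np.stack([N, CA, C, O, CB], axis=1)
    return BackboneStructure(
        sequence=sequence,
        chain_ids=np.array([chain_id] * L, dtype=object),
        residue_numbers=np.arange(1, L + 1),
        coords=coords,
        cb_present=cb_present,
    )


#: 30-residue toy sequence used by the worked examples and the benchmarks.
TOY_SEQUENCE = "MKVLAEGDWTRFIENSAHLQYPGCKVDLIR"


def toy_dihedrals(length: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Helix / loop / strand dihedral template for a small toy protein."""
    phi = np.full(length, -57.0)
    psi = np.full(length, -47.0)
    third = length // 3
    # loop segment (kept clear of the secondary-structure region boundaries)
    phi[third : 2 * third] = [-70.0 if k % 2 else -60.0 for k in range(third)]
    psi[third : 2 * third] = [120.0 if k % 2 else -30.0 for k in range(third)]
    # extended segment
    phi[2 * third :] = -120.0
    psi[2 * third :] = 120.0
    return phi, psi


def toy_reference(length: int = 30) -> BackboneStructure:
    """Deterministic 30-residue (by default) reference structure."""
    seq = (TOY_SEQUENCE * (length // len(TOY_SEQUENCE) + 1))[:length]
    phi, psi = toy_dihedrals(length)
    return build_backbone(seq, phi, psi)


@dataclass
class DecoyEnsemble:
    """A reference plus dihedral-perturbed models with their labels."""

    reference: BackboneStructure
    decoys: list = field(default_factory=list)
    labels: list = field(default_factory=list)
    perturbation_sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    seed: int = 0

    def __len__(self) -> int:
        return len(self.decoys)


def _reference_dihedrals(reference: BackboneStructure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .features import backbone_dihedrals

    ang = np.degrees(backbone_dihedrals(reference))
    phi, psi, omega = ang[:, 0], ang[:, 1], ang[:, 2]
    phi = np.where(np.isnan(phi), -57.0, phi)
    psi = np.where(np.isnan(psi), -47.0, psi)
    omega = np.where(np.isnan(omega), 180.0, omega)
    return phi, psi, omega


def perturb_dihedrals(
    reference: BackboneStructure,
    sigma: float,
    n_decoys: int,
    seed: int,
    perturb_fraction: float = 0.3,
) -> DecoyEnsemble:
    """Generate ``n_decoys`` models by graded dihedral perturbation.

    Per decoy, Gaussian noise with standard deviation ``sigma`` (degrees) is
    added to phi and psi of a random ``perturb_fraction`` of residues, and
    the backbone is rebuilt with ideal covalent geometry.  ``sigma = 0``
    reproduces the (idealized) reference exactly, so every label is 1.
    """
    if sigma < 0:
        raise ContractError("sigma must be non-negative")
    phi0, psi0, omega0 = _reference_dihedrals(reference)
    L = len(reference)
    rng = np.random.default_rng([seed, int(round(sigma * 1000)) % (2**31)])
    n_perturb = max(1, int(round(perturb_fraction * L)))

    ens = DecoyEnsemble(reference=reference, seed=seed)
    sigmas = []
    for _ in range(n_decoys):
        phi, psi = phi0.copy(), psi0.copy()
        subset = rng.choice(L, size=n_perturb, replace=False)
        phi[subset] += rng.normal(0.0, sigma, size=n_perturb)
        psi[subset] += rng.normal(0.0, sigma, size=n_perturb)
        decoy = build_backbone(reference.sequence, phi, psi, omega0)
        ens.decoys.append(decoy)
        ens.labels.append(compute_lddt(decoy, reference))
        sigmas.append(sigma)
    ens.perturbation_sigma = np.array(sigmas)
    return ens


def decoy_grid(
    reference: BackboneStructure,
    sigmas,
    n_per_sigma: int,
    seed: int,
    perturb_fraction: float = 0.3,
) -> DecoyEnsemble:
    """Concatenate perturbation ensembles across a sigma grid."""
    combined = DecoyEnsemble(reference=reference, seed=seed)
    parts = []
    for sig in sigmas:
        ens = perturb_dihedrals(reference, sig, n_per_sigma, seed, perturb_fraction)
        combined.decoys.extend(ens.decoys)
        combined.labels.extend(ens.labels)
        parts.append(ens.perturbation_sigma)
    combined.perturbation_sigma = np.concatenate(parts) if parts else np.zeros(0)
    return combined


def filter_similar(ensemble: DecoyEnsemble, min_mutual_lddt_gap: float) -> DecoyEnsemble:
    """Greedy diversity filter on mutual global lDDT.

    A decoy is kept only if its global lDDT against every already-kept decoy
    is at most ``1 - min_mutual_lddt_gap``; a gap of 0 keeps everything.
    """
    kept = DecoyEnsemble(reference=ensemble.reference, seed=ensemble.seed)
    kept_sigmas = []
    for decoy, labels, sig in zip(
        ensemble.decoys, ensemble.labels, ensemble.perturbation_sigma
    ):
        ok = True
        for other in kept.decoys:
            mutual = compute_lddt(decoy, other).global_lddt
            if mutual > 1.0 - min_mutual_lddt_gap:
                ok = False
                break
        if ok:
            kept.decoys.append(decoy)
            kept.labels.append(labels)
            kept_sigmas.append(sig)
    kept.perturbation_sigma = np.array(kept_sigmas)
    return kept
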