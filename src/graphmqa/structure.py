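"""Backbone structure container, PDB I/O and rigid-transform utilities.

The package works on a reduced five-atom backbone representation per residue
(N, CA, C, O, CB).  Missing CB atoms (glycine, or incomplete models) are
imputed from ideal tetrahedral geometry; missing O atoms are rebuilt from the
peptide plane.  All coordinates are Cartesian angstroms exactly as found in
the input file -- no recentering is applied, so downstream features have to
establish their own pose invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bts
import biotite.structure.io.pdb as btspdb
from biotite.sequence import ProteinSequence

from .errors import EmptyStructureError, GeometryError, StructureIOError

logger = logging.getLogger(__name__)

#: Order of the backbone atoms along axis 1 of ``BackboneStructure.coords``.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

# Ideal backbone geometry (angstroms / degrees), standard values for
# trans peptides; used for imputation and by the synthetic backbone builder.
IDEAL_CA_CB = 1.521
IDEAL_C_O = 1.231
IDEAL_ANGLE_CA_C_O = 120.8

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class BackboneStructure:
    """Per-residue backbone of a (possibly multimeric) protein model.

    Attributes
    ----------
    sequence:
        One-letter amino-acid string, one character per residue.
    chain_ids:
        Per-residue chain label, shape ``(N,)``.
    residue_numbers:
        Author residue numbering, shape ``(N,)``.
    coords:
        ``(N, 5, 3)`` array of coordinates for (N, CA, C, O, CB) in angstrom.
    cb_present:
        ``(N,)`` bool; ``False`` where CB was imputed (glycine has none).
    """

    sequence: str
    chain_ids: np.ndarray
    residue_numbers: np.ndarray
    coords: np.ndarray
    cb_present: np.ndarray

    def __post_init__(self) -> None:
        self.chain_ids = np.asarray(self.chain_ids)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cb_present = np.asarray(self.cb_present, dtype=bool)
        n = len(self.sequence)
        if not (
            self.coords.shape == (n, 5, 3)
            and self.chain_ids.shape == (n,)
            and self.residue_numbers.shape == (n,)
            and self.cb_present.shape == (n,)
        ):
            raise ValueError("inconsistent BackboneStructure field lengths")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        self._warn_ca_spacing()

    def _warn_ca_spacing(self) -> None:
        ca = self.ca
        for k in range(len(self) - 1):
            if self.chain_ids[k] != self.chain_ids[k + 1]:
                continue
            d = float(np.linalg.norm(ca[k + 1] - ca[k]))
            if not (2.0 < d < 4.5):
                logger.warning(
                    "unusual consecutive CA-CA distance %.2f A between "
                    "residues %d and %d", d, k, k + 1,
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        """``(N, 3)`` CA coordinates."""
        return self.coords[:, 1]

    @property
    def n_chains(self) -> int:
        return len(dict.fromkeys(self.chain_ids.tolist()))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` of 3-space."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def random(rng: np.random.Generator, max_translation: float = 50.0) -> "RigidTransform":
        """Haar-ish random rotation plus uniform translation."""
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.uniform(-max_translation, max_translation, size=3)
        return RigidTransform(q, t)


def apply_transform(s: BackboneStructure, t: RigidTransform) -> BackboneStructure:
    """Return a copy of ``s`` with every atom mapped through ``t``."""
    new_coords = s.coords @ t.rotation.T + t.translation
    return replace(s, coords=new_coords)


def impute_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place an ideal CB given the residue's N, CA and C atoms.

    The CB direction is decomposed into the in-plane bisector of the N-CA and
    C-CA bonds and the plane normal, with coefficients chosen so that the
    N-CA-CB and C-CA-CB angles take their ideal tetrahedral-like value
    (~110.5 deg) and the handedness matches L-amino acids.  The construction
    uses only vectors between the three inputs, hence commutes with any
    rigid transform.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-8 or nv < 1e-8:
        raise GeometryError("coincident backbone atoms")
    u = u / nu
    v = v / nv
    w = np.cross(u, v)
    nw = np.linalg.norm(w)
    if nw < 1e-8:
        raise GeometryError("collinear N, CA, C: cannot place CB")
    w = w / nw
    bis = u + v
    bis = bis / np.linalg.norm(bis)
    # angle CB makes with each bond: 110.5 deg; cos(half N-CA-C angle) from u.v
    half_cos = float(bis @ u)
    alpha = -np.cos(np.deg2rad(110.5)) / half_cos
    alpha = min(alpha, 1.0)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    direction = -alpha * bis + beta * w
    direction = direction / np.linalg.norm(direction)
    return ca + IDEAL_CA_CB * direction


def impute_oxygen(ca: np.ndarray, c: np.ndarray, n_next: np.ndarray | None) -> np.ndarray:
    """Rebuild the carbonyl O from the peptide plane.

    With the next residue's N available, O lies in the CA-C-N(next) plane,
    anti to the bisector.  For chain-terminal residues the CA-C direction is
    used as a fallback (the exact O position is immaterial there).
    """
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    d1 = c - ca
    d1 = d1 / np.linalg.norm(d1)
    if n_next is None:
        # terminal fallback: any direction at ~120.8 deg from CA-C
        ref = np.array([1.0, 0.0, 0.0])
        if abs(d1 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = np.cross(d1, ref)
        perp /= np.linalg.norm(perp)
    else:
        d2 = c - np.asarray(n_next, dtype=float)
        d2 = d2 / np.linalg.norm(d2)
        perp = d1 + d2
        nn = np.linalg.norm(perp)
        if nn < 1e-8:
            raise GeometryError("degenerate peptide plane for O imputation")
        perp = perp / nn
    return c + IDEAL_C_O * perp


def sequence_from_three(resnames: list[str]) -> str:
    return "".join(_THREE_TO_ONE.get(r, "X") for r in resnames)


def read_pdb(path, model_index: int | None = None) -> BackboneStructure:
    """Read one model of a PDB file into a :class:`BackboneStructure`.

    Residues are ordered by (chain id, residue number, insertion code);
    altlocs are resolved to highest occupancy; HETATM records are ignored.
    Residues missing any of N/CA/C are dropped with a warning.
    """
    try:
        pdb = btspdb.PDBFile.read(str(path))
        arr = pdb.get_structure(model=1 if model_index is None else model_index,
                                altloc="occupancy")
    except Exception as exc:  # biotite raises assorted types
        if "0 models" in str(exc):
            raise EmptyStructureError(f"no ATOM records in {path!r}") from exc
        raise StructureIOError(f"cannot read PDB file {path!r}: {exc}") from exc
    arr = arr[~arr.hetero]
    arr = arr[np.isin(arr.element, ["H", "D"], invert=True)]
    if arr.array_length() == 0:
        raise EmptyStructureError(f"no ATOM records in {path!r}")

    # group atoms by residue
    keys = list(zip(arr.chain_id, arr.res_id, arr.ins_code))
    residues: dict[tuple, dict] = {}
    for idx, key in enumerate(keys):
        residues.setdefault(key, {"name": arr.res_name[idx], "atoms": {}})
        residues[key]["atoms"].setdefault(arr.atom_name[idx], arr.coord[idx])

    order = sorted(residues, key=lambda k: (str(k[0]), int(k[1]), str(k[2])))
    seq, chains, numbers, coords, cb_present = [], [], [], [], []
    for key in order:
        info = residues[key]
        atoms = info["atoms"]
        if not all(a in atoms for a in ("N", "CA", "C")):
            logger.warning("dropping residue %s %s%s: incomplete backbone",
                           info["name"], key[0], key[1])
            continue
        n, ca, c = atoms["N"], atoms["CA"], atoms["C"]
        if "O" in atoms:
            o = atoms["O"]
        else:
            logger.warning("imputing O for residue %s %s%s", info["name"], key[0], key[1])
            o = impute_oxygen(ca, c, None)
        if "CB" in atoms:
            cb = atoms["CB"]
            has_cb = True
        else:
            cb = impute_cbeta(n, ca, c)
            has_cb = False
        seq.append(_THREE_TO_ONE.get(info["name"], "X"))
        chains.append(str(key[0]))
        numbers.append(int(key[1]))
        coords.append(np.stack([n, ca, c, o, cb]))
        cb_present.append(has_cb)

    if not seq:
        raise EmptyStructureError(f"no complete backbone residues in {path!r}")
    return BackboneStructure(
        sequence="".join(seq),
        chain_ids=np.array(chains, dtype=object),
        residue_numbers=np.array(numbers, dtype=int),
        coords=np.asarray(coords, dtype=float),
        cb_present=np.array(cb_present, dtype=bool),
    )


def write_pdb(s: BackboneStructure, path, bfactor: np.ndarray | None = None) -> None:
    """Write the backbone to a fixed-column PDB file.

    ``bfactor`` is an optional per-residue value written into the B-factor
    column of every atom of that residue (pLDDT convention uses 0-100).
    """
    n_res = len(s)
    records = []
    for i in range(n_res):
        atom_names = ["N", "CA", "C", "O"]
        if s.cb_present[i]:
            atom_names.append("CB")
        for name in atom_names:
            records.append((i, name, BACKBONE_ATOMS.index(name)))
    n_atoms = len(records)
    arr = bts.AtomArray(n_atoms)
    for k, (i, name, slot) in enumerate(records):
        arr.coord[k] = s.coords[i, slot]
        arr.chain_id[k] = str(s.chain_ids[i])
        arr.res_id[k] = int(s.residue_numbers[i])
        arr.res_name[k] = _ONE_TO_THREE.get(s.sequence[i], "UNK")
        arr.atom_name[k] = name
        arr.element[k] = name[0]
        arr.hetero[k] = False
    arr.set_annotation("b_factor", np.zeros(n_atoms))
    if bfactor is not None:
        bfactor = np.asarray(bfactor, dtype=float)
        for k, (i, _, _) in enumerate(records):
            arr.b_factor[k] = bfactor[i]
    pdb = btspdb.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
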