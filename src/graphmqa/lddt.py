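"""Ground-truth quality labels: per-residue lDDT, error bins, threshold mask.

lDDT (local Distance Difference Test) scores each residue of a model by the
fraction of reference CA-CA distances under 15 A that it preserves within
tolerances of 0.5, 1, 2 and 4 A.  The same pairwise quantities, discretised,
serve as classification targets for the decoder heads: a five-class
distance-error bin per residue pair and a binary mask marking pairs inside
the 15 A inclusion radius of the reference.

Everything here is CA-only: the method assesses residue-level quality, so
side-chain (full-atom) lDDT is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, DegenerateInputError
from .structure import BackboneStructure

#: lDDT distance-difference tolerances in angstrom.
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
#: Inclusion radius on the reference structure, angstrom.
INCLUSION_RADIUS = 15.0
#: Half-open |Dd| bin edges for the 5-class error head: [0,.5),[.5,1),[1,2),[2,4),[4,inf).
ERROR_BIN_EDGES = (0.5, 1.0, 2.0, 4.0)


@dataclass
class LDDTLabels:
    """Training targets derived from a model/reference structure pair.

    Attributes
    ----------
    local_lddt:
        ``(N,)`` per-residue lDDT in [0, 1].
    global_lddt:
        Mean of ``local_lddt``.
    error_bins:
        ``(N, N)`` int class in {0..4}; symmetric; diagonal 0.
    threshold_mask:
        ``(N, N)`` binary; 1 iff the reference CA-CA distance is below the
        inclusion radius and i != j.
    undefined:
        ``(N,)`` bool; True where a residue had no in-radius partner (its
        lDDT is reported as 1 by convention).
    """

    local_lddt: np.ndarray
    global_lddt: float
    error_bins: np.ndarray
    threshold_mask: np.ndarray
    undefined: np.ndarray


def _check_pair(model: BackboneStructure, reference: BackboneStructure) -> int:
    if len(model) != len(reference):
        raise AlignmentError(
            f"model has {len(model)} residues, reference {len(reference)}"
        )
    if model.sequence != reference.sequence:
        raise AlignmentError("model and reference sequences differ")
    n = len(model)
    if n < 2:
        raise DegenerateInputError("need at least 2 residues for lDDT")
    return n


def _pairwise_ca(s: BackboneStructure) -> np.ndarray:
    ca = s.ca
    diff = ca[:, None, :] - ca[None, :, :]
    return np.sqrt((diff * diff).sum(-1))


def compute_lddt(model: BackboneStructure, reference: BackboneStructure) -> LDDTLabels:
    """Compute full :class:`LDDTLabels` for a model against its reference."""
    n = _check_pair(model, reference)
    d_ref = _pairwise_ca(reference)
    d_mod = _pairwise_ca(model)
    delta = np.abs(d_mod - d_ref)

    mask = (d_ref < INCLUSION_RADIUS) & ~np.eye(n, dtype=bool)
    counts = mask.sum(axis=1)

    local = np.ones(n)
    undefined = counts == 0
    ok = ~undefined
    passed = np.zeros(n, dtype=int)
    for s in LDDT_THRESHOLDS:
        passed += ((delta < s) & mask).sum(axis=1)
    local[ok] = passed[ok] / (counts[ok] * len(LDDT_THRESHOLDS))

    bins = np.digitize(delta, ERROR_BIN_EDGES)
    np.fill_diagonal(bins, 0)
    return LDDTLabels(
        local_lddt=local,
        global_lddt=float(local.mean()),
        error_bins=bins.astype(int),
        threshold_mask=mask.astype(int),
        undefined=undefined,
    )


def label_error_bins(
    model: BackboneStructure, reference: BackboneStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Return just the ``(error_bins, threshold_mask)`` pair of arrays."""
    labels = compute_lddt(model, reference)
    return labels.error_bins, labels.threshold_mask


def save_labels(labels: LDDTLabels, path) -> None:
    np.savez_compressed(
        path,
        local_lddt=labels.local_lddt,
        global_lddt=np.array(labels.global_lddt),
        error_bins=labels.error_bins,
        threshold_mask=labels.threshold_mask,
        undefined=labels.undefined,
    )


def load_labels(path) -> LDDTLabels:
    with np.load(path) as data:
        return LDDTLabels(
            local_lddt=data["local_lddt"],
            global_lddt=float(data["global_lddt"]),
            error_bins=data["error_bins"],
            threshold_mask=data["threshold_mask"],
            undefined=data["undefined"],
        )
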