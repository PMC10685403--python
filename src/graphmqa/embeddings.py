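"""Sequence / structure embedding providers.

The network consumes three kinds of language-model representations: a
per-residue sequence embedding (1280-dim in single-sequence mode, 768-dim in
MSA mode), a per-pair row-attention embedding (144-dim, MSA mode only) and a
per-residue structural embedding of the backbone coordinates (512-dim).

Providers implement a uniform interface so the heavyweight models can be
plugged in externally; the package ships a deterministic mock provider whose
output is a pure function of (sequence, seed), with the structural embedding
additionally modulated by a smooth function of the CA coordinates so that
different decoys of the same sequence receive different structure signals.

Sequences longer than the 1022-residue transformer window are split in two
halves, embedded separately and reassembled in order; sequences of 2044
residues or more are refused.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UnsupportedLengthError
from .structure import BackboneStructure

SEQ_DIM_SINGLE = 1280
SEQ_DIM_MSA = 768
PAIR_DIM_MSA = 144
STRUCT_DIM = 512
LENGTH_LIMIT = 1022


@dataclass
class EmbeddingBundle:
    """Per-residue (and optionally per-pair) embedding tensors."""

    seq_embedding: np.ndarray          # (N, 1280) or (N, 768)
    struct_embedding: np.ndarray       # (N, 512)
    pair_attention: np.ndarray | None  # (N, N, 144) in MSA mode, else None
    mode: str                          # "single" | "msa"


def split_for_embedding(sequence: str, limit: int = LENGTH_LIMIT):
    """Split an over-long sequence for the embedding window.

    Returns ``(segments, spans)`` where ``spans`` are ``(start, stop)`` index
    pairs into the original sequence; concatenating the per-segment
    embeddings in order reassembles the full-length embedding.  Sequences of
    ``2 * limit`` residues or more are refused.
    """
    L = len(sequence)
    if L == 0:
        raise ContractError("empty sequence")
    if L <= limit:
        return [sequence], [(0, L)]
    if L >= 2 * limit:
        raise UnsupportedLengthError(
            f"sequence length {L} >= {2 * limit} is not supported"
        )
    mid = L // 2
    return [sequence[:mid], sequence[mid:]], [(0, mid), (mid, L)]


def _seed_from(sequence: str, seed: int, tag: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{tag}|{sequence}".encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32).tolist()
    return np.random.default_rng([seed % (2**31), *words])


class EmbeddingProvider:
    """Interface for embedding providers.

    Real language-model providers plug in behind this interface (taking the
    last-layer representations); MSA-mode providers additionally accept a
    pre-built A3M alignment path.  Implementations must be deterministic
    given their construction arguments.
    """

    mode: str

    def __init__(self, mode: str = "single", a3m_path=None):
        self.mode = mode
        self.a3m_path = a3m_path

    def embed(self, structure: BackboneStructure) -> EmbeddingBundle:
        raise NotImplementedError


class MockEmbeddingProvider(EmbeddingProvider):
    """Deterministic stand-in provider with the real tensor shapes.

    Sequence and pair tensors depend only on (sequence, seed).  The
    structural embedding adds a smooth sinusoidal transform of the CA
    coordinates projected through a fixed random matrix, making it sensitive
    to conformation while remaining deterministic.
    """

    def __init__(self, mode: str = "single", seed: int = 0, a3m_path=None):
        if mode not in ("single", "msa"):
            raise ContractError(f"unknown embedding mode {mode!r}")
        super().__init__(mode=mode, a3m_path=a3m_path)
        self.seed = seed

    def embed(self, structure: BackboneStructure) -> EmbeddingBundle:
        seq = structure.sequence
        n = len(seq)
        segments, spans = split_for_embedding(seq)

        seq_dim = SEQ_DIM_SINGLE if self.mode == "single" else SEQ_DIM_MSA
        seq_parts = []
        for segment in segments:
            rng = _seed_from(segment, self.seed, "seq")
            seq_parts.append(rng.normal(0, 1, size=(len(segment), seq_dim)))
        seq_emb = np.concatenate(seq_parts, axis=0)

        pair = None
        if self.mode == "msa":
            rng = _seed_from(seq, self.seed, "pair")
            pair = rng.normal(0, 1, size=(n, n, PAIR_DIM_MSA))
            pair = 0.5 * (pair + pair.transpose(1, 0, 2))

        rng = _seed_from(seq, self.seed, "struct")
        base = rng.normal(0, 1, size=(n, STRUCT_DIM))
        proj = rng.normal(0, 1.0 / np.sqrt(n), size=(n, STRUCT_DIM))
        ca = structure.ca
        dists = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        # smooth, pose-invariant but conformation-sensitive modulation
        base = base + np.sin(0.3 * dists) @ proj
        return EmbeddingBundle(
            seq_embedding=seq_emb,
            struct_embedding=base,
            pair_attention=pair,
            mode=self.mode,
        )


def cache_key(sequence: str, mode: str, seed: int) -> str:
    return hashlib.sha256(f"{mode}|{seed}|{sequence}".encode()).hexdigest()[:24]


def save_embeddings(bundle: EmbeddingBundle, path) -> None:
    arrays = {
        "seq_embedding": bundle.seq_embedding,
        "struct_embedding": bundle.struct_embedding,
        "mode": np.array(bundle.mode),
    }
    if bundle.pair_attention is not None:
        arrays["pair_attention"] = bundle.pair_attention
    np.savez_compressed(path, **arrays)


def load_embeddings(path) -> EmbeddingBundle:
    with np.load(path) as data:
        return EmbeddingBundle(
            seq_embedding=data["seq_embedding"],
            struct_embedding=data["struct_embedding"],
            pair_attention=data["pair_attention"] if "pair_attention" in data else None,
            mode=str(data["mode"]),
        )
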