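"""Sequence encodings: one-hot, nucleotide chemical property (NCP), fusion.

A 200-bp sequence becomes a 7x200 binary matrix: four one-hot rows (A, C,
G, T order) stacked on three NCP rows.  The NCP code describes each base by
ring structure (purine A/G vs pyrimidine C/T), functional group (amino A/C
vs keto G/T) and hydrogen-bond strength (weak A/T vs strong C/G):

    A -> (1, 1, 1)   C -> (0, 1, 0)   G -> (1, 0, 0)   T -> (0, 0, 1)

Downstream the fused matrix is treated as a single-channel grey image of
height 7 and width 200.
"""

from __future__ import annotations

import numpy as np

from .seq_io import ALPHABET, DnaRecord, SequenceValidationError

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

# NCP rows: x (purine), y (amino), z (weak H-bond), in A,C,G,T column order
_NCP_TABLE = np.array(
    [
        [1, 0, 1, 0],  # x: A,G
        [1, 1, 0, 0],  # y: A,C
        [1, 0, 0, 1],  # z: A,T
    ],
    dtype=np.float32,
)

SCHEMES = ("onehot", "ncp", "onehot+ncp")

#: rows contributed by each scheme (grid height)
SCHEME_ROWS = {"onehot": 4, "ncp": 3, "onehot+ncp": 7}


def _indices(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceValidationError(f"invalid characters {sorted(bad)} in sequence")
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


def encode_one_hot(seq: str) -> np.ndarray:
    """4 x L indicator matrix; column i is the one-hot code of base i."""
    idx = _indices(seq)
    out = np.zeros((4, len(idx)), dtype=np.float32)
    out[idx, np.arange(len(idx))] = 1.0
    return out


def encode_ncp(seq: str) -> np.ndarray:
    """3 x L chemical-property matrix (rows: purine, amino, weak H-bond)."""
    return _NCP_TABLE[:, _indices(seq)].copy()


def fuse(seq: str, scheme: str = "onehot+ncp") -> np.ndarray:
    """Encode a sequence under one scheme; fused = one-hot stacked on NCP."""
    if scheme == "onehot":
        return encode_one_hot(seq)
    if scheme == "ncp":
        return encode_ncp(seq)
    if scheme == "onehot+ncp":
        return np.vstack([encode_one_hot(seq), encode_ncp(seq)])
    raise ValueError(f"unknown encoding scheme {scheme!r}; choose from {SCHEMES}")


def decode_one_hot(grid: np.ndarray) -> str:
    """Recover the sequence from rows 0-3 by per-column argmax."""
    return "".join(BASE_ORDER[i] for i in grid[0:4].argmax(axis=0))


def encode_dataset(records: list[DnaRecord] | list[str], scheme: str = "onehot+ncp") -> np.ndarray:
    """Encode records into an (N, 1, rows, L) float32 image batch."""
    seqs = [r.seq if isinstance(r, DnaRecord) else r for r in records]
    grids = np.stack([fuse(s, scheme) for s in seqs]) if seqs else np.zeros(
        (0, SCHEME_ROWS[scheme], 0), dtype=np.float32
    )
    return grids[:, None, :, :].astype(np.float32)
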