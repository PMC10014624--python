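"""FASTA input/output and the two-layer benchmark directory layout.

Enhancer benchmarks used here consist of fixed-length 200-bp DNA fragments
over the plain {A, C, G, T} alphabet, organised in two classification
layers: layer 1 separates enhancers from non-enhancers, layer 2 separates
strong from weak enhancers.  Each layer has disjoint train and test splits
stored as one FASTA file per class.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SEQ_LEN = 200
ALPHABET = frozenset("ACGT")

#: class-file naming convention per layer: (positive file, negative file)
LAYER_CLASS_FILES = {
    1: ("enhancer.fa", "non_enhancer.fa"),
    2: ("strong.fa", "weak.fa"),
}


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a record violates the 200-bp ACGT contract."""


@dataclass(frozen=True)
class DnaRecord:
    """One identifier plus a 200-bp ACGT sequence (uppercased on ingest)."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) != SEQ_LEN:
            raise SequenceValidationError(
                f"record {self.id!r}: length {len(self.seq)} != {SEQ_LEN}"
            )
        bad = set(self.seq) - ALPHABET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)} "
                "(only A/C/G/T are accepted; ambiguity codes are rejected)"
            )


@dataclass
class LabeledDataset:
    """Parallel records/labels for one layer and split.

    Label 1 is the positive class: enhancer (layer 1) or strong enhancer
    (layer 2).
    """

    records: list[DnaRecord]
    labels: list[int]
    layer: int = 1
    split: str = "train"

    def __post_init__(self):
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records vs {len(self.labels)} labels"
            )
        if any(l not in (0, 1) for l in self.labels):
            raise ValueError("labels must be 0/1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self.labels) - self.n_positive

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset(
            [self.records[i] for i in indices],
            [self.labels[i] for i in indices],
            layer=self.layer,
            split=self.split,
        )


def read_fasta(path) -> list[DnaRecord]:
    """Read and validate a FASTA file into DnaRecords (order preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
        else:
            return []  # empty file
    return [DnaRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path, width: int = 60) -> None:
    """Write DnaRecords as wrapped FASTA."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _split_dir(root: Path, layer: int, split: str) -> Path:
    return root / f"layer{layer}" / split


def load_split(root, layer: int, split: str) -> LabeledDataset:
    """Load one split of one layer from the benchmark directory layout."""
    root = Path(root)
    if layer not in LAYER_CLASS_FILES:
        raise ValueError(f"layer must be 1 or 2, got {layer}")
    pos_name, neg_name = LAYER_CLASS_FILES[layer]
    d = _split_dir(root, layer, split)
    pos_path, neg_path = d / pos_name, d / neg_name
    for p in (pos_path, neg_path):
        if not p.exists():
            raise FileNotFoundError(
                f"benchmark layer {layer} {split} split: missing class file {p}"
            )
    pos, neg = read_fasta(pos_path), read_fasta(neg_path)
    if len(pos) != len(neg):
        logger.warning(
            "layer %d %s split is imbalanced: %d positives vs %d negatives",
            layer, split, len(pos), len(neg),
        )
    return LabeledDataset(
        records=pos + neg,
        labels=[1] * len(pos) + [0] * len(neg),
        layer=layer,
        split=split,
    )


def load_benchmark(root, layer: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Load (train, test) for one layer; logs duplicated sequences across splits."""
    train = load_split(root, layer, "train")
    test = load_split(root, layer, "test")
    train_seqs = Counter(r.seq for r in train.records)
    dups = sum(1 for r in test.records if r.seq in train_seqs)
    if dups:
        logger.warning(
            "layer %d: %d test sequences also occur in the training split", layer, dups
        )
    return train, test
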