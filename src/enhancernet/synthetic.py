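"""Synthetic two-layer benchmarks with a planted, tunable motif signal.

The generator emulates the structure of the real enhancer benchmark -
balanced classes of 200-bp ACGT sequences with disjoint train/test splits -
so every pipeline stage is testable offline.  Positives carry a fixed
short motif implanted at a uniform random position with probability
``implant_rate``; all other bases are i.i.d. with a configurable G+C
fraction.  A JSON manifest records every implant position, enabling
white-box tests without re-scanning sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_io import (
    LAYER_CLASS_FILES,
    SEQ_LEN,
    DnaRecord,
    LabeledDataset,
    write_fasta,
)

#: Sp1-like GC-box default motif: strong enough for fast smoke-training,
#: weak enough that accuracy is not trivially 100%.
DEFAULT_MOTIF = "GGGCGGGGC"


@dataclass
class SyntheticSpec:
    """Parameters of a planted-motif benchmark.

    n_pos/n_neg are the per-class training counts; test_n_pos/test_n_neg
    the per-class test counts.  bg_gc is the background G+C fraction.
    """

    n_pos: int = 400
    n_neg: int = 400
    test_n_pos: int = 100
    test_n_neg: int = 100
    seq_len: int = SEQ_LEN
    motif: str = DEFAULT_MOTIF
    implant_rate: float = 0.9
    bg_gc: float = 0.5
    layer: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.implant_rate <= 1.0:
            raise ValueError(f"implant_rate {self.implant_rate} outside [0, 1]")
        if not 0.0 < self.bg_gc < 1.0:
            raise ValueError(f"bg_gc {self.bg_gc} outside (0, 1)")
        if len(self.motif) >= self.seq_len:
            raise ValueError("motif must be shorter than the sequence length")
        if set(self.motif.upper()) - set("ACGT"):
            raise ValueError("motif must be over A/C/G/T")
        if min(self.n_pos, self.n_neg, self.test_n_pos, self.test_n_neg) < 0:
            raise ValueError("counts must be non-negative")
        if self.layer not in (1, 2):
            raise ValueError("layer must be 1 or 2")


def _background(rng: np.random.Generator, n: int, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, T
    draws = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=(n, length), p=probs)
    return [b"".join(row).decode() for row in draws]


def _make_split(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    split: str,
    n_pos: int,
    n_neg: int,
    manifest: dict,
) -> LabeledDataset:
    motif = spec.motif.upper()
    records: list[DnaRecord] = []
    labels: list[int] = []
    for i, seq in enumerate(_background(rng, n_pos, spec.seq_len, spec.bg_gc)):
        rid = f"pos_{split}_{i:05d}"
        pos = None
        if rng.random() < spec.implant_rate:
            pos = int(rng.integers(0, spec.seq_len - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        manifest[rid] = pos
        records.append(DnaRecord(id=rid, seq=seq))
        labels.append(1)
    for i, seq in enumerate(_background(rng, n_neg, spec.seq_len, spec.bg_gc)):
        rid = f"neg_{split}_{i:05d}"
        manifest[rid] = None
        records.append(DnaRecord(id=rid, seq=seq))
        labels.append(0)
    return LabeledDataset(records, labels, layer=spec.layer, split=split)


def simulate(spec: SyntheticSpec) -> tuple[LabeledDataset, LabeledDataset, dict]:
    """Generate (train, test, manifest); fully reproducible from spec.seed.

    The manifest maps record id -> implant position (None for no implant).
    """
    rng = np.random.default_rng(spec.seed)
    manifest: dict = {}
    train = _make_split(spec, rng, "train", spec.n_pos, spec.n_neg, manifest)
    test = _make_split(spec, rng, "test", spec.test_n_pos, spec.test_n_neg, manifest)
    return train, test, manifest


def write_benchmark_layout(
    train: LabeledDataset,
    test: LabeledDataset,
    root,
    manifest: dict | None = None,
    force: bool = False,
) -> Path:
    """Write datasets in the directory/FASTA layout the loader expects."""
    root = Path(root)
    layer = train.layer
    pos_name, neg_name = LAYER_CLASS_FILES[layer]
    layer_dir = root / f"layer{layer}"
    if layer_dir.exists() and any(layer_dir.iterdir()) and not force:
        raise FileExistsError(f"{layer_dir} exists; pass force=True to overwrite")
    for ds in (train, test):
        d = layer_dir / ds.split
        pos = [r for r, l in zip(ds.records, ds.labels) if l == 1]
        neg = [r for r, l in zip(ds.records, ds.labels) if l == 0]
        write_fasta(pos, d / pos_name)
        write_fasta(neg, d / neg_name)
    if manifest is not None:
        with open(layer_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return root
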