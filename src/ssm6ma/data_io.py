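"""Reading, validating, encoding and splitting 41-bp 6mA benchmark data.

Datasets follow the common benchmark layout: one FASTA file of positive
windows (center adenine methylated) and one of negatives (center adenine
unmethylated). Labels are carried by file membership. Every window has the
same odd length L (default 41) with the candidate adenine at the center,
position (L+1)/2 in the 1-based coordinates used throughout user-facing
output (position 21 for a 41-mer).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ALPHABET",
    "BASE_TO_INDEX",
    "INDEX_TO_BASE",
    "ValidationError",
    "LabeledSequence",
    "LabeledDataset",
    "EncodedBatch",
    "read_fasta",
    "write_fasta",
    "build_dataset",
    "encode",
    "encode_sequences",
    "decode",
    "kfold_split",
]

ALPHABET = "ACGT"
BASE_TO_INDEX = {b: i for i, b in enumerate(ALPHABET)}
INDEX_TO_BASE = np.array(list(ALPHABET))
_READABLE = set("ACGTN")


class ValidationError(ValueError):
    """A sequence record violated a dataset invariant."""


@dataclass(frozen=True)
class LabeledSequence:
    """One fixed-length DNA window with a binary label for its center base."""

    id: str
    bases: str
    label: int

    def validate(self, window_length: int) -> None:
        if len(self.bases) != window_length:
            raise ValidationError(
                f"record {self.id!r}: length {len(self.bases)} != "
                f"expected window length {window_length}")
        bad = set(self.bases) - set(ALPHABET)
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}")
        center = self.bases[window_length // 2]
        if center != "A":
            raise ValidationError(
                f"record {self.id!r}: center base is {center!r}, expected 'A' "
                f"at position {window_length // 2 + 1}")


@dataclass
class LabeledDataset:
    """Ordered collection of labeled windows, all of one length."""

    sequences: list[LabeledSequence]
    species_tag: str = ""

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[LabeledSequence]:
        return iter(self.sequences)

    @property
    def window_length(self) -> int:
        return len(self.sequences[0].bases) if self.sequences else 0

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sequences], dtype=np.int64)

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) by actual label tally."""
        y = self.labels
        return int((y == 1).sum()), int((y == 0).sum())

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset([self.sequences[i] for i in idx],
                              self.species_tag)


@dataclass
class EncodedBatch:
    """Integer-encoded sequences (A,C,G,T -> 0,1,2,3) plus labels."""

    indices: np.ndarray  # (batch, L) int64
    labels: np.ndarray  # (batch,) int64
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.indices.shape[0] != self.labels.shape[0]:
            raise ValueError("indices and labels disagree on batch size")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, bases) pairs in file order.

    Sequence lines are concatenated and upper-cased. Characters outside
    A, C, G, T, N (either case) raise :class:`ValidationError` naming the
    offending record. A missing file raises ``FileNotFoundError``; an empty
    file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        bad = set(bases) - _READABLE
        if bad:
            raise ValidationError(
                f"record {rec.id!r}: characters {sorted(bad)} outside "
                "the DNA alphabet")
        records.append((rec.id, bases))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write (id, bases) pairs as FASTA, wrapping lines at ``width``."""
    seq_records = [SeqRecord(Seq(bases), id=rid, description="")
                   for rid, bases in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def build_dataset(pos_path: str | Path, neg_path: str | Path,
                  window_length: int = 41,
                  species_tag: str = "") -> LabeledDataset:
    """Assemble a labeled dataset from a positive/negative FASTA pair.

    Positives are labeled 1 and come first, then negatives labeled 0. Every
    sequence is validated (length, ACGT alphabet, center base A). Sequences
    containing N are rejected; the error reports how many. A class imbalance
    triggers a warning, not an error.
    """
    if window_length % 2 != 1:
        raise ValueError("window_length must be odd")
    sequences: list[LabeledSequence] = []
    n_with_n = 0
    for path, label in ((pos_path, 1), (neg_path, 0)):
        for rid, bases in read_fasta(path):
            if "N" in bases:
                n_with_n += 1
                continue
            seq = LabeledSequence(rid, bases, label)
            seq.validate(window_length)
            sequences.append(seq)
    if n_with_n:
        raise ValidationError(
            f"{n_with_n} sequence(s) contain N and were rejected; the "
            "model's alphabet is fixed at A,C,G,T")
    dataset = LabeledDataset(sequences, species_tag=species_tag)
    n_pos, n_neg = dataset.class_counts()
    if n_pos != n_neg:
        warnings.warn(
            f"unbalanced dataset: {n_pos} positives vs {n_neg} negatives",
            stacklevel=2)
    return dataset


def encode_sequences(bases_list: Sequence[str]) -> np.ndarray:
    """Map sequences to an (n, L) integer matrix with A,C,G,T -> 0,1,2,3."""
    arr = np.frombuffer("".join(bases_list).encode(), dtype=np.uint8)
    arr = arr.reshape(len(bases_list), -1)
    out = np.empty(arr.shape, dtype=np.int64)
    for base, idx in BASE_TO_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def encode(dataset: LabeledDataset, batch_size: int) -> list[EncodedBatch]:
    """Encode a dataset into fixed-size batches preserving dataset order.

    The final batch may be smaller. Decoding a batch reproduces the source
    bases exactly (the mapping is a bijection per position).
    """
    if not len(dataset):
        raise ValueError("cannot encode an empty dataset")
    if batch_size < 1:
        raise ValueError("batch_size must be positive")
    indices = encode_sequences([s.bases for s in dataset])
    labels = dataset.labels
    ids = [s.id for s in dataset]
    return [EncodedBatch(indices[i:i + batch_size], labels[i:i + batch_size],
                         ids[i:i + batch_size])
            for i in range(0, len(dataset), batch_size)]


def decode(indices: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_sequences`."""
    return ["".join(row) for row in INDEX_TO_BASE[np.asarray(indices)]]


def kfold_split(dataset: LabeledDataset, k: int,
                seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, shuffled k-fold partition of dataset indices.

    Returns k (train_idx, val_idx) pairs. Validation folds partition all
    indices; each fold's class ratio matches the dataset's within one
    sample. Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(dataset):
        raise ValueError(f"k={k} exceeds dataset size {len(dataset)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y = dataset.labels
    return [(train, val) for train, val in skf.split(np.zeros(len(y)), y)]
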