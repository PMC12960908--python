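"""Benchmark-shaped synthetic 6mA datasets with a planted, position-anchored
motif.

Real 6mA benchmarks are balanced sets of 41-bp windows centered on an
adenine; positives (methylated) are enriched for a GAG core around the site
— guanine immediately up- and downstream of the methylated adenine. The
generator emulates that shape: both classes share an i.i.d. background over
A,C,G,T with the center forced to A, and a short pattern (default GAG, one
base upstream of the center, i.e. anchor 20 of a 41-mer) is planted in
positives with probability ``plant_probability`` and in negatives with
probability ``decoy_probability``.

A second, position-scrambled mode plants the same pattern in negatives at a
uniformly random *other* anchor instead, so the two classes contain the
motif equally often and only its position distinguishes them — a signal
that position-aware layers can exploit but position-agnostic ones cannot
encode in their filters.

The generator does not model read-level noise or mislabeled negatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import ALPHABET, LabeledDataset, LabeledSequence, write_fasta

__all__ = ["MotifSpec", "GeneratorConfig", "generate_dataset",
           "write_dataset"]


@dataclass
class MotifSpec:
    """A short pattern planted at a fixed 1-based anchor position.

    ``plant_probability`` applies to positives, ``decoy_probability`` to
    negatives. If the pattern overlaps the window center, the overlapping
    base must be A (the center is always an adenine in both classes).
    """

    pattern: str = "GAG"
    anchor: int = 20
    plant_probability: float = 0.9
    decoy_probability: float = 0.1

    def validate(self, window_length: int) -> None:
        if not self.pattern or set(self.pattern) - set(ALPHABET):
            raise ValueError(f"pattern {self.pattern!r} must be non-empty "
                             "over A,C,G,T")
        if not 1 <= self.anchor:
            raise ValueError("anchor is 1-based and must be >= 1")
        if self.anchor + len(self.pattern) - 1 > window_length:
            raise ValueError(
                f"pattern at anchor {self.anchor} overruns window length "
                f"{window_length}")
        center = (window_length + 1) // 2  # 1-based
        offset = center - self.anchor
        if 0 <= offset < len(self.pattern) and self.pattern[offset] != "A":
            raise ValueError(
                "pattern overlaps the center position with base "
                f"{self.pattern[offset]!r}; the center must stay A")
        for p in (self.plant_probability, self.decoy_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    n_per_class: int = 2000
    window_length: int = 41
    background_frequencies: tuple[float, float, float, float] = \
        (0.25, 0.25, 0.25, 0.25)
    motif: MotifSpec = field(default_factory=MotifSpec)
    seed: int = 0
    mode: str = "fixed"  # or "scrambled": decoys at random other anchors

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.window_length % 2 != 1 or self.window_length < 3:
            raise ValueError("window_length must be odd and >= 3")
        bg = np.asarray(self.background_frequencies, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background_frequencies must be 4 nonnegative "
                             "values summing to 1")
        if self.mode not in ("fixed", "scrambled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.motif.validate(self.window_length)


def _valid_anchors(motif: MotifSpec, window_length: int) -> list[int]:
    """Anchors where the pattern fits and keeps the center base A."""
    center = (window_length + 1) // 2
    anchors = []
    for a in range(1, window_length - len(motif.pattern) + 2):
        offset = center - a
        if 0 <= offset < len(motif.pattern) and motif.pattern[offset] != "A":
            continue
        anchors.append(a)
    return anchors


def generate_dataset(config: GeneratorConfig) -> LabeledDataset:
    """Draw a balanced labeled dataset; deterministic given ``config.seed``.

    Positives come first (ids pos_0000...), then negatives. Every sequence
    has the center base A; non-motif positions are i.i.d. from the
    background. In ``fixed`` mode negatives receive the pattern at the same
    anchor with ``decoy_probability``; in ``scrambled`` mode they receive it
    with ``plant_probability`` at a uniformly random anchor other than the
    motif's, making the class signal purely positional.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L, n = config.window_length, config.n_per_class
    center0 = L // 2  # 0-based
    bg = np.asarray(config.background_frequencies, dtype=float)
    motif = config.motif
    pat_idx = np.array([ALPHABET.index(c) for c in motif.pattern])

    def draw_class(label: int) -> np.ndarray:
        mat = rng.choice(4, size=(n, L), p=bg)
        mat[:, center0] = 0  # A
        if label == 1:
            plant = rng.random(n) < motif.plant_probability
            a0 = motif.anchor - 1
            mat[plant, a0:a0 + len(pat_idx)] = pat_idx
        elif config.mode == "fixed":
            plant = rng.random(n) < motif.decoy_probability
            a0 = motif.anchor - 1
            mat[plant, a0:a0 + len(pat_idx)] = pat_idx
        else:  # scrambled decoys at random other anchors
            anchors = [a for a in _valid_anchors(motif, L)
                       if a != motif.anchor]
            plant = rng.random(n) < motif.plant_probability
            where = rng.choice(anchors, size=n)
            for i in np.nonzero(plant)[0]:
                a0 = where[i] - 1
                mat[i, a0:a0 + len(pat_idx)] = pat_idx
        mat[:, center0] = 0  # planting never overwrites the center A
        return mat

    sequences = []
    letters = np.array(list(ALPHABET))
    for label, tag in ((1, "pos"), (0, "neg")):
        mat = draw_class(label)
        for i, row in enumerate(letters[mat]):
            sequences.append(LabeledSequence(f"{tag}_{i:05d}",
                                             "".join(row), label))
    return LabeledDataset(sequences, species_tag="synthetic")


def write_dataset(dataset: LabeledDataset, config: GeneratorConfig,
                  out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write pos/neg FASTA files plus a JSON sidecar with the full config.

    Returns (pos_path, neg_path, sidecar_path). Byte-identical output for
    identical configs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = [(s.id, s.bases) for s in dataset if s.label == 1]
    neg = [(s.id, s.bases) for s in dataset if s.label == 0]
    pos_path = out_dir / "positives.fasta"
    neg_path = out_dir / "negatives.fasta"
    side_path = out_dir / "generator_config.json"
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    with open(side_path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)
        fh.write("\n")
    return pos_path, neg_path, side_path
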