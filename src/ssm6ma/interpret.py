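"""Model interpretation: position-wise feature intensity, penultimate-layer
embeddings for 2D projection, and per-position nucleotide enrichment.

The intensity profile averages the fused feature matrix Z (L x N) over the
feature axis for each sample, then over samples of each ground-truth class,
yielding one L-vector per class; a localized class contrast indicates which
window positions the model attends to. The penultimate embedding is the
ReLU output of the width-16 hidden layer, exported per sequence for
external 2D projection (UMAP, via umap-learn). The enrichment table is a
simple class-conditional log-odds per position and base with pseudocounts —
a lightweight in-repo statistic (deliberately not the pLogo
binomial-probability logo) for confirming planted or biological motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ALPHABET, LabeledDataset, encode_sequences
from .network import Model

__all__ = [
    "IntensityProfile",
    "feature_intensity",
    "extract_penultimate",
    "position_enrichment",
    "project_2d",
]


@dataclass
class IntensityProfile:
    """Class-mean position-wise feature intensity (1-based positions)."""

    positions: np.ndarray  # (L,) int, 1..L
    mean_intensity_positive: np.ndarray  # (L,)
    mean_intensity_negative: np.ndarray  # (L,)

    @property
    def contrast(self) -> np.ndarray:
        return self.mean_intensity_positive - self.mean_intensity_negative

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.positions,
            "mean_pos": self.mean_intensity_positive,
            "mean_neg": self.mean_intensity_negative,
            "contrast": self.contrast,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.6f")


def _intermediates(model: Model, dataset: LabeledDataset,
                   batch_size: int = 256):
    from . import autodiff as ad
    idxmat = encode_sequences([s.bases for s in dataset])
    zs, pens = [], []
    with ad.no_grad():
        for lo in range(0, len(idxmat), batch_size):
            _, inter = model.forward(idxmat[lo:lo + batch_size],
                                     return_intermediates=True)
            zs.append(inter["Z"])
            pens.append(inter["penultimate"])
    return np.concatenate(zs), np.concatenate(pens)


def feature_intensity(model: Model, dataset: LabeledDataset) -> IntensityProfile:
    """Class-mean intensity profile of the fused feature matrix.

    Each sample's Z (L x N) is reduced to an L-vector by the mean over the
    feature axis; samples are grouped by ground-truth label and averaged.
    Both classes must be present.
    """
    labels = dataset.labels
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValueError("feature_intensity needs both classes present")
    z, _ = _intermediates(model, dataset)
    per_sample = z.mean(axis=2)  # (n, L)
    return IntensityProfile(
        positions=np.arange(1, z.shape[1] + 1),
        mean_intensity_positive=per_sample[labels == 1].mean(axis=0),
        mean_intensity_negative=per_sample[labels == 0].mean(axis=0))


def extract_penultimate(model: Model, dataset: LabeledDataset) -> pd.DataFrame:
    """Per-sequence penultimate activations (width-16 hidden layer, post-ReLU).

    Returns a DataFrame with columns id, label, v1..v16 (dropout disabled),
    one row per sequence, suitable for external 2D projection.
    """
    _, pen = _intermediates(model, dataset)
    cols = {f"v{i + 1}": pen[:, i] for i in range(pen.shape[1])}
    return pd.DataFrame({"id": [s.id for s in dataset],
                         "label": dataset.labels, **cols})


def position_enrichment(dataset: LabeledDataset,
                        pseudocount: float = 0.5) -> pd.DataFrame:
    """Class-conditional base frequencies and log2 odds per position.

    For each 1-based position and base: freq = (count + pseudocount) /
    (n_class + 4 * pseudocount), so the four frequencies sum to 1 in each
    class; score = log2(freq_pos / freq_neg). Positive scores mark bases
    over-represented in the positive class. Antisymmetric under class swap.
    """
    labels = dataset.labels
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("position_enrichment needs both classes present")
    idxmat = encode_sequences([s.bases for s in dataset])
    L = idxmat.shape[1]
    rows = []
    for cls, n_cls in ((1, n_pos), (0, n_neg)):
        sub = idxmat[labels == cls]
        counts = np.stack([(sub == b).sum(axis=0) for b in range(4)], axis=1)
        freq = (counts + pseudocount) / (n_cls + 4 * pseudocount)
        rows.append(freq)  # (L, 4)
    freq_pos, freq_neg = rows
    out = []
    for i in range(L):
        for b, base in enumerate(ALPHABET):
            out.append({"position": i + 1, "base": base,
                        "freq_pos": freq_pos[i, b],
                        "freq_neg": freq_neg[i, b],
                        "log2_odds": float(np.log2(freq_pos[i, b]
                                                   / freq_neg[i, b]))})
    return pd.DataFrame(out)


def project_2d(vectors: np.ndarray, seed: int = 0,
               n_neighbors: int = 15) -> np.ndarray:
    """2D UMAP projection of penultimate embeddings (delegated to umap-learn)."""
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=n_neighbors)
    return reducer.fit_transform(np.asarray(vectors))
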