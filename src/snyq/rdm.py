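"""Representational dissimilarity matrices (RDMs).

A 6x6 symmetric nonnegative matrix with zero diagonal holding the pairwise
dissimilarity between the six stimulus conditions, for either the V1 model
or the EEG data at one time point.  The 15 unique off-diagonal entries are
what enters the model-EEG Spearman correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = ["RDM", "CONDITION_LABELS"]

CONDITION_LABELS = (
    "LVF-low", "LVF-med", "LVF-high", "RVF-low", "RVF-med", "RVF-high",
)


@dataclass
class RDM:
    """Pairwise dissimilarity matrix over stimulus conditions."""

    matrix: np.ndarray
    labels: tuple = CONDITION_LABELS
    source: str = "model"  # {"model", "eeg"}
    normalization: str = "none"  # {"none", "per_feature_count"}

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("labels must match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise ValueError("RDM diagonal must be zero")
        if np.any(m < -1e-10):
            raise ValueError("RDM entries must be nonnegative")
        self.matrix = (m + m.T) / 2.0
        np.fill_diagonal(self.matrix, 0.0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        """The unique upper-triangle entries (15 values for 6 conditions)."""
        return squareform(self.matrix, checks=False)

    def entry(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "RDM":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(matrix=df.to_numpy(), labels=tuple(df.columns), **kwargs)

    @classmethod
    def mean(cls, rdms: list) -> "RDM":
        """Element-wise mean of several RDMs over the same labels."""
        labels = rdms[0].labels
        if any(r.labels != labels for r in rdms):
            raise ValueError("RDMs must share labels")
        return cls(
            matrix=np.mean([r.matrix for r in rdms], axis=0),
            labels=labels,
            source=rdms[0].source,
        )
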