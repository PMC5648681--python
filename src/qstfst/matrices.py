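"""Labeled symmetric population-by-population distance matrices.

Both the microsatellite F_ST matrix and the per-trait Q_ST matrices are
carried in this container so that the permutation comparison can align
them by population label rather than by array position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise values with a fixed label order.

    Missing pairs (e.g. a degenerate pairwise model fit) are stored as NaN
    and excluded listwise by consumers.
    """

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {k} labels"
            )
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def pair_values(self) -> pd.DataFrame:
        """Lower-triangle pairs as a tidy frame (pop1, pop2, value)."""
        rows = []
        for i in range(self.n):
            for j in range(i):
                rows.append((self.labels[i], self.labels[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["pop1", "pop2", "value"])

    def reindex(self, labels: list[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns ordered by ``labels``."""
        missing = set(labels) - set(self.labels)
        if missing:
            raise KeyError(f"labels not in matrix: {sorted(missing)}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="population")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))
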