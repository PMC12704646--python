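"""Linkage-disequilibrium (r-squared) matrices for clumping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass
class LDMatrix:
    """Symmetric r-squared matrix over an ordered set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.variant_ids)
        if self.r2.shape != (n, n):
            raise ValidationError("LD matrix shape does not match variant_ids length")
        if not np.allclose(self.r2, self.r2.T):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix diagonal must be exactly 1")
        if self.r2.size and (np.nanmin(self.r2) < 0 or np.nanmax(self.r2) > 1 + 1e-12):
            raise ValidationError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, id1: str, id2: str) -> float:
        """Pairwise r2; variants absent from the matrix count as independent (0)."""
        i, j = self._index.get(id1), self._index.get(id2)
        if i is None or j is None:
            return 0.0
        return float(self.r2[i, j])

    @classmethod
    def from_square_file(cls, path) -> "LDMatrix":
        """Read a delimited square matrix with variant ids as header and index."""
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(list(frame.columns.astype(str)), frame.to_numpy(float))

    @classmethod
    def from_long_file(cls, path) -> "LDMatrix":
        """Read long-format triplets (id1, id2, r2); missing pairs default to 0."""
        frame = pd.read_csv(path, sep=None, engine="python", dtype={0: str, 1: str})
        frame.columns = [c.lower() for c in frame.columns]
        ids = sorted(set(frame["id1"]) | set(frame["id2"]))
        idx = {v: i for i, v in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(mat, 1.0)
        for row in frame.itertuples(index=False):
            i, j = idx[row.id1], idx[row.id2]
            mat[i, j] = mat[j, i] = float(row.r2)
        np.fill_diagonal(mat, 1.0)
        return cls(ids, mat)

    def to_long_frame(self) -> pd.DataFrame:
        """Upper-triangle long format (id1, id2, r2), nonzero entries only."""
        rows = []
        n = len(self.variant_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.r2[i, j] != 0.0:
                    rows.append({"id1": self.variant_ids[i], "id2": self.variant_ids[j],
                                 "r2": self.r2[i, j]})
        return pd.DataFrame(rows, columns=["id1", "id2", "r2"])
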