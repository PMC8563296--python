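"""Symmetric dyadic matrices keyed by individual identity.

A :class:`DyadMatrix` holds one value per unordered pair (dyad) of units —
microbiome similarity, an association index, a contact rate — stored as a
full symmetric matrix with labelled rows/columns. All downstream statistics
use only the off-diagonal dyads; the diagonal is a convention (1 for
similarity matrices, NaN for social networks) and never enters an analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DyadMatrix", "SimilarityMatrix"]


def _check_symmetric(values: np.ndarray, atol: float = 0.0) -> bool:
    """NaN-aware symmetry check: values and NaN pattern must both be symmetric."""
    nan = np.isnan(values)
    if not np.array_equal(nan, nan.T):
        return False
    a = np.where(nan, 0.0, values)
    if atol == 0.0:
        return np.array_equal(a, a.T)
    return np.allclose(a, a.T, atol=atol, rtol=0.0)


class DyadMatrix:
    """A labelled symmetric matrix over unordered pairs of units.

    Parameters
    ----------
    ids
        Ordered unit labels (bats or samples); must be unique.
    values
        Square ``(n, n)`` array, symmetric up to the NaN pattern. NaN marks
        an undefined dyad (e.g. a contact rate with zero co-present hours).
    """

    def __init__(self, ids, values, *, check: bool = True):
        self.ids: list[str] = [str(i) for i in ids]
        self.values: np.ndarray = np.array(values, dtype=float)
        if check:
            self._validate()
        self._index = {u: k for k, u in enumerate(self.ids)}

    def _validate(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            dup = sorted({u for u in self.ids if self.ids.count(u) > 1})
            raise ValueError(f"duplicate unit ids: {dup}")
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} ids"
            )
        if not _check_symmetric(self.values):
            raise ValueError("matrix is not symmetric")

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, unit: str) -> int:
        try:
            return self._index[str(unit)]
        except KeyError:
            raise KeyError(f"unknown unit id {unit!r}") from None

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.index_of(a), self.index_of(b)])

    def dyad_values(self) -> np.ndarray:
        """Values over unique unordered dyads (upper triangle, i < j)."""
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    # -- structural operations --------------------------------------------
    def _like(self, ids, values) -> "DyadMatrix":
        """Construct a same-type matrix; subclasses override to carry metadata."""
        return type(self)(ids, values)

    def reorder(self, new_ids) -> "DyadMatrix":
        idx = np.array([self.index_of(u) for u in new_ids])
        return self._like(list(new_ids), self.values[np.ix_(idx, idx)])

    def subset(self, keep_ids) -> "DyadMatrix":
        return self.reorder([u for u in keep_ids])

    # -- IO ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        """Square CSV with a header row and first column of unit ids."""
        self.to_frame().to_csv(path, index_label="id", float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "DyadMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column ids differ")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(n={self.n})"


class SimilarityMatrix(DyadMatrix):
    """Dyadic similarity in [0, 1]; the diagonal is 1 by definition.

    Tiny floating overshoots outside [0, 1] (from distance round-off) are
    clipped; genuine violations raise.
    """

    _TOL = 1e-9

    def __init__(self, ids, values, *, check: bool = True):
        values = np.array(values, dtype=float)
        finite = np.isfinite(values)
        if check:
            bad = finite & ((values < -self._TOL) | (values > 1 + self._TOL))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"similarity out of [0,1] at ({ids[i]!r}, {ids[j]!r}): "
                    f"{values[i, j]}"
                )
        values[finite] = np.clip(values[finite], 0.0, 1.0)
        np.fill_diagonal(values, 1.0)
        super().__init__(ids, values, check=check)
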