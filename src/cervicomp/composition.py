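"""Compositional substrate: zero replacement, CLR transform, Aitchison distances.

All log-ratio work uses the natural logarithm. The centred log-ratio (CLR) of
a strictly positive composition x is ln(x_k / g(x)) with g(x) the geometric
mean of the row; the Aitchison distance between two compositions is the
Euclidean distance between their CLR vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from cervicomp.io import AbundanceTable, DataError


@dataclass
class CLRMatrix:
    """Samples x genera matrix of centred log-ratios; each row sums to 0."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise DataError("CLR matrix contains non-finite entries")
        sums = values.sum(axis=1)
        if np.abs(sums).max(initial=0.0) > 1e-9 * max(1.0, np.abs(values).max(initial=1.0)):
            raise DataError("CLR rows must sum to 0")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genera(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distance matrix with zero diagonal."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1]:
            raise DataError("distance matrix must be square")
        if not np.allclose(values, values.T, atol=1e-9):
            raise DataError("distance matrix must be symmetric")
        if np.abs(np.diag(values)).max(initial=0.0) > 1e-9:
            raise DataError("distance matrix must have zero diagonal")
        if (values < -1e-12).any():
            raise DataError("distance matrix must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def submatrix(self, samples) -> "DistanceMatrix":
        samples = list(samples)
        return DistanceMatrix(self.data.loc[samples, samples])


def replace_zeros(table: AbundanceTable, pseudocount: float = 0.5,
                  delta: float = 1e-6) -> AbundanceTable:
    """Return a strictly positive proportions table suitable for CLR.

    Counts mode: add ``pseudocount`` to every count, then close rows to 1.
    Proportions mode: multiplicative replacement — zeros become ``delta`` and
    the non-zero parts of a row with z zeros are rescaled by (1 − z·delta).
    A row of all zeros cannot be made compositional and is an error.
    """
    values = table.data.to_numpy(dtype=float)
    zero_rows = values.sum(axis=1) == 0
    if zero_rows.any():
        raise DataError(
            f"sample {table.data.index[np.argmax(zero_rows)]!r} is all zeros"
        )
    if table.mode == "counts":
        if pseudocount <= 0:
            raise DataError("pseudocount must be positive")
        out = values + pseudocount
        out /= out.sum(axis=1, keepdims=True)
    else:
        if not 0 < delta < 1:
            raise DataError("delta must lie in (0, 1)")
        zeros = values == 0
        z = zeros.sum(axis=1, keepdims=True)
        out = values * (1.0 - z * delta)
        out[zeros] = delta
    return AbundanceTable(
        pd.DataFrame(out, index=table.data.index, columns=table.data.columns),
        mode="proportions",
    )


def clr_transform(table: AbundanceTable) -> CLRMatrix:
    """Centred log-ratio transform of a strictly positive proportions table."""
    if table.mode != "proportions":
        raise DataError("clr_transform expects a proportions-mode table "
                        "(apply replace_zeros first)")
    values = table.data.to_numpy(dtype=float)
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise DataError(
            f"non-positive entry at sample {table.data.index[i]!r}, "
            f"genus {table.data.columns[j]!r}; apply replace_zeros first"
        )
    logs = np.log(values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CLRMatrix(pd.DataFrame(clr, index=table.data.index, columns=table.data.columns))


def aitchison_distance(clr: CLRMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between CLR rows (Aitchison distance)."""
    d = squareform(pdist(clr.data.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(pd.DataFrame(d, index=clr.data.index, columns=clr.data.index))


def aitchison_from_table(table: AbundanceTable, pseudocount: float = 0.5,
                         delta: float = 1e-6) -> DistanceMatrix:
    """Convenience chain: zero replacement -> CLR -> Aitchison distances."""
    return aitchison_distance(clr_transform(replace_zeros(table, pseudocount, delta)))


def clr_subset_mean(clr: CLRMatrix, genera) -> pd.Series:
    """Per-sample mean CLR over a genus subset.

    Equals the log of the geometric mean of the raw parts divided by the
    whole-composition geometric mean — the building block of every log-ratio
    index in the package.
    """
    genera = list(genera)
    if not genera:
        raise DataError("genus subset must be non-empty")
    unknown = [g for g in genera if g not in clr.data.columns]
    if unknown:
        raise DataError(f"unknown genera in subset: {unknown}")
    return clr.data[genera].mean(axis=1)
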