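"""Tabular IO: abundance tables, sample metadata, alignment, provenance headers.

Abundance TSV layout: rows are samples, first column the sample identifier,
header row the genus names. Metadata TSV layout: ``sample_id``, ``diagnosis``,
then any number of host-factor columns. Result files written by the pipeline
carry ``#``-prefixed header comments recording seed, version and parameters;
all readers skip such lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Recognised histopathological diagnosis labels, ordered by disease severity.
DIAGNOSES = ("Normal", "LSIL", "HSIL", "CCU")


class DataError(ValueError):
    """Raised when an input table violates a format or content contract."""


@dataclass
class AbundanceTable:
    """Samples x genera non-negative abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by genus name.
    mode : {"counts", "proportions"}
        ``counts`` requires non-negative integers; ``proportions`` requires
        each row to sum to 1 within 1e-9.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "proportions"):
            raise DataError(f"unknown abundance mode: {self.mode!r}")
        df = self.data
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate sample identifier: {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise DataError(f"duplicate genus identifier: {dup!r}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at sample {df.index[i]!r}, genus {df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative value at sample {df.index[i]!r}, genus {df.columns[j]!r}"
            )
        if self.mode == "counts":
            if not np.allclose(values, np.round(values), atol=1e-9):
                i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise DataError(
                    "non-integer count at sample "
                    f"{df.index[i]!r}, genus {df.columns[j]!r}"
                )
            self.data = df.astype(np.int64)
        else:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise DataError(
                    f"proportions row {df.index[np.argmax(bad)]!r} sums to "
                    f"{sums[np.argmax(bad)]:.12g}, expected 1"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genera(self) -> list[str]:
        return list(self.data.columns)

    def to_proportions(self) -> "AbundanceTable":
        """Close each row to sum 1 (rows with zero total are rejected)."""
        if self.mode == "proportions":
            return self
        sums = self.data.sum(axis=1)
        if (sums == 0).any():
            raise DataError(
                f"sample {sums.index[sums.eq(0).argmax()]!r} has zero total abundance"
            )
        return AbundanceTable(self.data.div(sums, axis=0), mode="proportions")


@dataclass
class SampleMetadata:
    """Per-sample diagnosis plus optional host-factor columns."""

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.data
        if "diagnosis" not in df.columns:
            raise DataError("metadata must have a 'diagnosis' column")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate sample identifier: {dup!r}")
        missing = df["diagnosis"].isna() | (df["diagnosis"].astype(str).str.strip() == "")
        if missing.any():
            dropped = list(df.index[missing])
            logger.warning(
                "dropping %d sample(s) with missing diagnosis: %s", len(dropped), dropped
            )
            self.data = df = df.loc[~missing]
        unknown = ~df["diagnosis"].isin(DIAGNOSES)
        if unknown.any():
            raise DataError(
                f"unknown diagnosis label {df['diagnosis'][unknown].iloc[0]!r} "
                f"(expected one of {DIAGNOSES})"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def diagnosis(self) -> pd.Series:
        return self.data["diagnosis"]

    @property
    def factors(self) -> list[str]:
        return [c for c in self.data.columns if c != "diagnosis"]


def read_abundance(path, mode: str = "counts") -> AbundanceTable:
    """Read a samples x genera abundance TSV (see module docstring for layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, mode=mode)


def read_metadata(path) -> SampleMetadata:
    """Read a metadata TSV with ``sample_id`` and ``diagnosis`` columns.

    Missing host-factor values are encoded by an explicit empty field and kept
    as NaN; samples with a missing diagnosis are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise DataError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleMetadata(df)


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None,
              index_label: str | None = None, float_format: str = "%.12g") -> None:
    """Write a DataFrame as TSV with optional ``#`` provenance header lines."""
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index_label=index_label, float_format=float_format)


def write_abundance(table: AbundanceTable, path, provenance: dict | None = None) -> None:
    fmt = "%d" if table.mode == "counts" else "%.12g"
    write_tsv(table.data, path, provenance, index_label="sample_id", float_format=fmt)


def write_metadata(meta: SampleMetadata, path, provenance: dict | None = None) -> None:
    write_tsv(meta.data, path, provenance, index_label="sample_id")


def align(table: AbundanceTable, meta: SampleMetadata) -> tuple[AbundanceTable, SampleMetadata]:
    """Restrict both inputs to their common samples, in the table's order.

    Dropped identifiers are logged. An empty intersection is an error.
    """
    common = [s for s in table.samples if s in set(meta.samples)]
    if not common:
        raise DataError("abundance table and metadata share no sample identifiers")
    dropped = (set(table.samples) | set(meta.samples)) - set(common)
    if dropped:
        logger.warning("align: dropping %d unmatched sample(s): %s",
                       len(dropped), sorted(dropped))
    return (
        AbundanceTable(table.data.loc[common], mode=table.mode),
        SampleMetadata(meta.data.loc[common]),
    )
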