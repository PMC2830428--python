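"""Differential Expression Ratio (DER) from a tri-state call matrix.

The input is a gene x dataset matrix of differential-expression calls made
upstream (1 = called differentially expressed, 0 = measured but not called,
NA = the gene was not measured on that dataset's platform). A gene's DER is
the number of datasets in which it was called DE divided by the number of
datasets in which it was measured — its frequency of differential expression
across the expression compendium. Genes measured in too small a fraction of
datasets carry unstable ratios and are filtered out.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEMatrix",
    "DERRecord",
    "DEMatrixFormatError",
    "parse_de_matrix",
    "filter_measured",
    "compute_der",
]


class DEMatrixFormatError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class DERRecord:
    gene_id: str
    n_measured: int
    n_de: int

    @property
    def der(self) -> float:
        return self.n_de / self.n_measured


class DEMatrix:
    """Tri-state DE-call matrix.

    Stored as a float array: 1.0 = DE, 0.0 = measured not-DE, NaN = not
    measured. Row labels are gene ids, column labels dataset ids, both unique.
    """

    def __init__(self, calls: pd.DataFrame):
        if calls.index.has_duplicates:
            dupes = calls.index[calls.index.duplicated()].unique().tolist()
            raise DEMatrixFormatError(f"duplicate gene ids: {dupes[:5]}")
        if calls.columns.has_duplicates:
            raise DEMatrixFormatError("duplicate dataset ids")
        values = calls.to_numpy(dtype=float)
        ok = np.isnan(values) | (values == 0.0) | (values == 1.0)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise DEMatrixFormatError(
                f"invalid call value at gene {calls.index[bad[0]]!r}, "
                f"dataset {calls.columns[bad[1]]!r}"
            )
        self.calls = calls.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_datasets(self) -> int:
        return self.calls.shape[1]

    def n_measured(self) -> pd.Series:
        return self.calls.notna().sum(axis=1)

    def n_de(self) -> pd.Series:
        return (self.calls == 1.0).sum(axis=1)


def parse_de_matrix(stream: str | Iterable[str] | io.TextIOBase) -> DEMatrix:
    """Parse a TSV DE-call matrix: header of dataset ids, rows of gene id
    followed by values in {1, 0, NA}."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        df = pd.read_csv(stream, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise DEMatrixFormatError(f"ragged matrix: {exc}") from exc
    if df.isna().to_numpy().any():
        r = int(np.argwhere(df.isna().to_numpy().any(axis=1))[0][0])
        raise DEMatrixFormatError(f"ragged row for gene {df.index[r]!r}")
    mapping = {"1": 1.0, "0": 0.0, "NA": np.nan}
    unknown = ~df.isin(list(mapping)).to_numpy()
    if unknown.any():
        r, c = np.argwhere(unknown)[0]
        raise DEMatrixFormatError(
            f"unknown token {df.iat[r, c]!r} at gene {df.index[r]!r}, dataset {df.columns[c]!r}"
        )
    converted = df.apply(lambda col: col.map(mapping))
    return DEMatrix(converted)


def filter_measured(
    matrix: DEMatrix, min_fraction: float = 0.05, min_count: int | None = None
) -> set[str]:
    """Gene ids measured in at least ``min_fraction`` of all datasets.

    The count threshold is ceil(min_fraction x n_datasets) with >= comparison
    ("at least" semantics on an integer count); ``min_count`` overrides the
    computed threshold directly.
    """
    if matrix.calls.empty:
        raise ValueError("empty DE matrix")
    if min_count is None:
        if not 0 < min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        min_count = math.ceil(min_fraction * matrix.n_datasets)
    measured = matrix.n_measured()
    return set(measured.index[measured >= min_count])


def compute_der(matrix: DEMatrix) -> pd.DataFrame:
    """Per-gene DER table: ``gene_id  n_measured  n_de  der``.

    Genes measured in zero datasets have no defined ratio and are omitted.
    """
    n_measured = matrix.n_measured()
    n_de = matrix.n_de()
    scored = n_measured > 0
    out = pd.DataFrame(
        {
            "gene_id": matrix.calls.index[scored],
            "n_measured": n_measured[scored].astype(int).to_numpy(),
            "n_de": n_de[scored].astype(int).to_numpy(),
        }
    )
    out["der"] = out["n_de"] / out["n_measured"]
    return out.reset_index(drop=True)
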