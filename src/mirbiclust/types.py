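"""Domain containers shared across the pipeline.

All matrix-like types are thin wrappers around a :class:`pandas.DataFrame`
oriented miRNA (or family) rows x sample columns; identifiers live on the
frame's index/columns and are compared case-sensitively after whitespace
stripping (miRNA nomenclature is case-meaningful: miR-17 vs mir-17).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

#: Allowed values for ER / PR / Her2 receptor status.
STATUS_LEVELS = ("positive", "negative", "unknown")
#: Histology classes of the breast-cancer cohort the generator emulates.
HISTOLOGY_LEVELS = ("IDC", "DCIS", "Normal", "Metaplastic", "CellLine", "Other")
#: Molecular subtype calls; "NA" marks samples without a subtype assignment.
SUBTYPE_LEVELS = ("Basal", "LuminalA", "LuminalB", "Her2", "Normal", "NA")

METADATA_COLUMNS = (
    "er_status",
    "pr_status",
    "her2_status",
    "histology",
    "molecular_subtype",
)


def _check_ids(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what} identifiers: {dups}")
    if any((not isinstance(x, str)) or x != x.strip() or not x for x in ids):
        raise DataError(f"{what} identifiers must be non-empty stripped strings")


@dataclass(frozen=True)
class CountMatrix:
    """Raw non-negative miRNA x sample read counts."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        _check_ids(f.index, "miRNA")
        _check_ids(f.columns, "sample")
        vals = f.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise DataError("count matrix must hold integers")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise DataError(
                f"negative count at miRNA {f.index[i]!r}, sample {f.columns[j]!r}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def library_totals(self) -> pd.Series:
        """Total miRNA reads per sample library."""
        return self.frame.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.frame.equals(other.frame)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Relative-percent read frequencies; every column sums to 100."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        _check_ids(f.index, "row")
        _check_ids(f.columns, "sample")
        vals = f.to_numpy(dtype=float)
        if (vals < 0).any():
            raise DataError("read frequencies must be non-negative")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 100.0, rtol=1e-9, atol=1e-7):
            bad = f.columns[np.argmax(np.abs(sums - 100.0))]
            raise DataError(f"column {bad!r} does not sum to 100% (got {sums.max()})")

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape


@dataclass(frozen=True)
class FamilyMap:
    """miRNA id -> sequence-family id (families use the ``sf-`` prefix)."""

    mapping: Mapping[str, str]

    def families(self) -> dict[str, list[str]]:
        """Family id -> ordered member miRNA list."""
        out: dict[str, list[str]] = {}
        for mirna, fam in self.mapping.items():
            out.setdefault(fam, []).append(mirna)
        return out

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, mirna: str) -> str:
        return self.mapping[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.mapping


@dataclass(frozen=True)
class StandardizedPair:
    """Row- and column-standardized variants of the expression matrix.

    ``row_std`` has every row at mean 0 / SD 1 (population denominator);
    ``col_std`` every column.  Rows and columns dropped for zero variance
    are recorded so reports can mention them.
    """

    row_std: pd.DataFrame
    col_std: pd.DataFrame
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.row_std.index.equals(self.col_std.index):
            raise DataError("row_std and col_std must share row identifiers")
        if not self.row_std.columns.equals(self.col_std.columns):
            raise DataError("row_std and col_std must share column identifiers")

    @property
    def row_ids(self) -> list[str]:
        return list(self.row_std.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.row_std.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_std.shape


def _check_scores(scores: Mapping[str, float], what: str) -> None:
    if not scores:
        raise DataError(f"bicluster has an empty {what} support")
    vals = np.array(list(scores.values()), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError(f"non-finite {what} score")
    if np.abs(vals).max() > 1.0 + 1e-9:
        raise DataError(f"{what} scores must lie in [-1, +1]")
    if not math.isclose(np.abs(vals).max(), 1.0, rel_tol=1e-6):
        raise DataError(f"{what} scores must be scaled to unit max-norm")
    if (vals == 0).any():
        raise DataError(f"zero {what} score stored inside the support")


@dataclass(frozen=True)
class Bicluster:
    """A fixed point of the ISA iteration.

    Scores are signed soft memberships in [-1, +1], scaled so the largest
    absolute value on each side equals 1; the sign encodes correlation
    direction (anti-correlated members carry opposite signs).
    """

    row_scores: Mapping[str, float]
    col_scores: Mapping[str, float]
    iterations: int = 0
    basin_count: int = 1

    def __post_init__(self) -> None:
        _check_scores(self.row_scores, "row")
        _check_scores(self.col_scores, "column")

    @property
    def row_set(self) -> frozenset[str]:
        return frozenset(self.row_scores)

    @property
    def col_set(self) -> frozenset[str]:
        return frozenset(self.col_scores)

    def dense_row_scores(self, row_ids: list[str]) -> np.ndarray:
        return np.array([self.row_scores.get(r, 0.0) for r in row_ids])

    def dense_col_scores(self, col_ids: list[str]) -> np.ndarray:
        return np.array([self.col_scores.get(c, 0.0) for c in col_ids])


@dataclass(frozen=True)
class BiclusterSet:
    """An ordered collection of biclusters plus the parameters that produced it."""

    biclusters: tuple[Bicluster, ...]
    params: Mapping[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self) -> Iterator[Bicluster]:
        return iter(self.biclusters)

    def __getitem__(self, i: int) -> Bicluster:
        return self.biclusters[i]

    @property
    def all_row_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for bc in self.biclusters:
            for r in bc.row_scores:
                seen.setdefault(r)
        return list(seen)

    @property
    def all_col_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for bc in self.biclusters:
            for c in bc.col_scores:
                seen.setdefault(c)
        return list(seen)


@dataclass(frozen=True)
class MembershipMatrices:
    """Dense soft-membership matrices: rows/samples x biclusters, zero = non-member."""

    row_membership: pd.DataFrame
    col_membership: pd.DataFrame

    def __post_init__(self) -> None:
        for m in (self.row_membership, self.col_membership):
            vals = m.to_numpy(dtype=float)
            if vals.size and np.abs(vals).max() > 1.0 + 1e-9:
                raise DataError("membership values must lie in [-1, +1]")


@dataclass(frozen=True)
class CohortMetadata:
    """Per-sample clinical annotation: IHC markers, histology, molecular subtype."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        _check_ids(f.index, "sample")
        missing = [c for c in METADATA_COLUMNS if c not in f.columns]
        if missing:
            raise DataError(f"metadata missing columns: {missing}")
        for col, levels in (
            ("er_status", STATUS_LEVELS),
            ("pr_status", STATUS_LEVELS),
            ("her2_status", STATUS_LEVELS),
            ("histology", HISTOLOGY_LEVELS),
            ("molecular_subtype", SUBTYPE_LEVELS),
        ):
            bad = set(f[col]) - set(levels)
            if bad:
                raise DataError(f"invalid {col} values: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def is_tnbc(self) -> pd.Series:
        """Triple-negative flag; pandas NA where any marker is unknown."""
        f = self.frame
        known = ~(f[["er_status", "pr_status", "her2_status"]] == "unknown").any(axis=1)
        tnbc = (f[["er_status", "pr_status", "her2_status"]] == "negative").all(axis=1)
        return tnbc.where(known, other=pd.NA)
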