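"""Data preparation: library filtering, read frequencies, family condensation,
and the double standardization the Iterative Signature Algorithm expects.

The canonical order is filter -> read frequencies -> condense -> standardize;
:func:`run_preprocessing` wires the stages together and reports the row and
column counts at each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, EmptyResultError
from .types import CountMatrix, FamilyMap, FrequencyMatrix, StandardizedPair

logger = logging.getLogger(__name__)

#: Minimum total miRNA sequence reads for a library to enter the analysis.
DEFAULT_MIN_READS = 5000


def filter_libraries(cm: CountMatrix, min_reads: int = DEFAULT_MIN_READS) -> CountMatrix:
    """Keep sample libraries with total read count >= ``min_reads`` (inclusive).

    The row set is unchanged; dropped sample ids are logged.
    """
    totals = cm.library_totals()
    keep = totals >= min_reads
    dropped = list(totals.index[~keep])
    if dropped:
        logger.info("filter_libraries dropped %d libraries: %s", len(dropped), dropped)
    if not keep.any():
        raise EmptyResultError(
            f"all {len(totals)} libraries fall below {min_reads} total reads"
        )
    return CountMatrix(cm.frame.loc[:, keep])


def to_read_frequencies(cm: CountMatrix) -> FrequencyMatrix:
    """Convert counts to relative-percent read frequencies per library.

    entry(i, j) = 100 * count(i, j) / library_total(j); columns sum to 100.
    """
    totals = cm.library_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise DataError(f"zero-total libraries cannot be normalized: {list(zero)}")
    freq = 100.0 * cm.frame.astype(float).div(totals.astype(float), axis=1)
    return FrequencyMatrix(freq)


def condense_families(fm: FrequencyMatrix, family_map: FamilyMap) -> FrequencyMatrix:
    """Collapse miRNA rows into sequence families by summing member frequencies.

    Read frequencies are additive shares of a library, so summing preserves
    the per-column 100% total.  Every row id must be covered by the map.
    """
    missing = [r for r in fm.row_ids if r not in family_map]
    if missing:
        raise DataError(f"miRNAs missing from the family map: {missing}")
    families = pd.Index([family_map[r] for r in fm.row_ids], name=fm.frame.index.name)
    condensed = fm.frame.groupby(families, sort=False).sum()
    return FrequencyMatrix(condensed)


def _standardize_axis(frame: pd.DataFrame, axis: int) -> pd.DataFrame:
    vals = frame.to_numpy(dtype=float)
    mean = vals.mean(axis=axis, keepdims=True)
    sd = vals.std(axis=axis, keepdims=True)  # population denominator
    return pd.DataFrame((vals - mean) / sd, index=frame.index, columns=frame.columns)


def standardize(fm: FrequencyMatrix | pd.DataFrame) -> StandardizedPair:
    """Produce the row-standardized and column-standardized matrix pair.

    ``row_std`` standardizes each row of the input; ``col_std`` standardizes
    each column *of the row-standardized matrix* (prenormalization).  Read
    frequencies span orders of magnitude between families, so standardizing
    columns of the raw matrix would leave every column encoding the static
    family-abundance profile rather than sample-specific deviation; removing
    the family main effect first keeps both matrices informative.  Each
    retained row of ``row_std`` and column of ``col_std`` has mean 0 and
    population SD 1.

    Rows and columns with zero variance are removed from both matrices
    (their ids are recorded on the result); removal is iterated because
    dropping a row can make a column constant and vice versa.
    """
    frame = fm.frame if isinstance(fm, FrequencyMatrix) else fm
    frame = frame.astype(float)
    dropped_rows: list[str] = []
    dropped_cols: list[str] = []
    while frame.shape[0] >= 2 and frame.shape[1] >= 2:
        row_sd = frame.std(axis=1, ddof=0)
        col_sd = frame.std(axis=0, ddof=0)
        bad_rows = row_sd.index[row_sd == 0]
        bad_cols = col_sd.index[col_sd == 0]
        if not len(bad_rows) and not len(bad_cols):
            # a column constant in the row-standardized matrix (e.g. under
            # duplicated rows) would make the prenormalized step degenerate
            pre = _standardize_axis(frame, axis=1)
            pre_sd = pre.std(axis=0, ddof=0)
            bad_cols = pre_sd.index[pre_sd == 0]
            if not len(bad_cols):
                break
        dropped_rows += list(bad_rows)
        dropped_cols += list(bad_cols)
        frame = frame.drop(index=bad_rows, columns=bad_cols)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise DataError(
            "fewer than 2 non-degenerate rows or columns after removing "
            f"zero-variance entries (dropped rows {dropped_rows}, cols {dropped_cols})"
        )
    if dropped_rows or dropped_cols:
        logger.info(
            "standardize dropped zero-variance rows %s and columns %s",
            dropped_rows, dropped_cols,
        )
    row_std = _standardize_axis(frame, axis=1)
    return StandardizedPair(
        row_std=row_std,
        col_std=_standardize_axis(row_std, axis=0),
        dropped_rows=tuple(dropped_rows),
        dropped_cols=tuple(dropped_cols),
    )


@dataclass(frozen=True)
class PreprocessingResult:
    """Staged outputs of the full preparation pipeline, with stage shapes."""

    filtered: CountMatrix
    frequencies: FrequencyMatrix
    condensed: FrequencyMatrix | None
    standardized: StandardizedPair
    stage_shapes: dict = field(default_factory=dict)

    @property
    def n_mirnas(self) -> int:
        """Row count before family condensation."""
        return self.frequencies.shape[0]

    @property
    def n_families(self) -> int:
        """Row count after family condensation (equals n_mirnas when skipped)."""
        return (self.condensed or self.frequencies).shape[0]


def run_preprocessing(
    cm: CountMatrix,
    family_map: FamilyMap | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> PreprocessingResult:
    """filter -> read frequencies -> (condense) -> standardize."""
    filtered = filter_libraries(cm, min_reads=min_reads)
    freq = to_read_frequencies(filtered)
    condensed = condense_families(freq, family_map) if family_map is not None else None
    sp = standardize(condensed if condensed is not None else freq)
    shapes = {
        "input": cm.shape,
        "filtered": filtered.shape,
        "frequencies": freq.shape,
        "condensed": condensed.shape if condensed is not None else None,
        "standardized": sp.shape,
    }
    for stage, shape in shapes.items():
        logger.info("preprocess stage %-12s shape %s", stage, shape)
    return PreprocessingResult(filtered, freq, condensed, sp, shapes)
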