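"""Readers and writers for every external representation the pipeline touches.

All tabular formats are plain tab-separated text with one header row and a
leading identifier column, so inputs and outputs stay diff-able.  Biclusters
use a small structured-text dialect (one record per bicluster) that
round-trips identifiers, scores (12 significant digits) and run parameters;
the same dialect is the ingestion route for externally produced
biclusterings (e.g. SAMBA output re-expressed in this format).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ConflictError, DataError, FormatError
from .types import (
    Bicluster,
    BiclusterSet,
    CohortMetadata,
    CountMatrix,
    FamilyMap,
    METADATA_COLUMNS,
)

PathLike = Union[str, Path]

ROWS_ARE_MIRNAS = "rows-are-mirnas"
ROWS_ARE_SAMPLES = "rows-are-samples"

_BICLUSTER_MAGIC = "#mirbiclust-biclusters\tv1"


def _read_tsv(path: PathLike) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse TSV table: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def read_count_matrix(path: PathLike, orientation: str = ROWS_ARE_MIRNAS) -> CountMatrix:
    """Read a read-count table; ``orientation`` says what the on-disk rows are.

    The matrix is stored miRNA x sample internally regardless of orientation.
    """
    if orientation not in (ROWS_ARE_MIRNAS, ROWS_ARE_SAMPLES):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate identifiers in header or id column")
    out = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (row, cell) in enumerate(zip(df.index, df[col])):
            try:
                value = int(cell.strip())
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {row!r}, column {col!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}: negative count {value} at row {row!r}, column {col!r}"
                )
            out[i, j] = value
    frame = pd.DataFrame(out, index=df.index, columns=df.columns)
    if orientation == ROWS_ARE_SAMPLES:
        frame = frame.T
    return CountMatrix(frame)


def write_count_matrix(cm: CountMatrix, path: PathLike) -> None:
    cm.frame.to_csv(path, sep="\t")


def write_frequency_matrix(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", float_format="%.12g")


def read_frequency_table(path: PathLike) -> pd.DataFrame:
    """Read a float TSV (frequency/standardized/membership matrix)."""
    df = _read_tsv(path)
    try:
        return df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in float table: {exc}") from exc


def read_family_map(path: PathLike) -> FamilyMap:
    """Read the two-column miRNA -> sequence-family table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) != 2 or not all(parts):
                raise FormatError(
                    f"{path}:{lineno}: expected two tab-separated fields, got {line!r}"
                )
            mirna, family = parts
            if mirna in mapping and mapping[mirna] != family:
                raise ConflictError(
                    f"{path}:{lineno}: miRNA {mirna!r} mapped to both "
                    f"{mapping[mirna]!r} and {family!r}"
                )
            mapping[mirna] = family
    return FamilyMap(mapping)


def write_family_map(fm: FamilyMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for mirna, family in fm.mapping.items():
            fh.write(f"{mirna}\t{family}\n")


def read_metadata(path: PathLike) -> CohortMetadata:
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    return CohortMetadata(df[list(METADATA_COLUMNS)])


def write_metadata(meta: CohortMetadata, path: PathLike) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Bicluster dialect
# ---------------------------------------------------------------------------

def write_biclusters(bs: BiclusterSet, path: PathLike) -> None:
    """Serialize a BiclusterSet; ``read_biclusters`` is its exact inverse."""
    lines = [_BICLUSTER_MAGIC]
    for key, value in bs.params.items():
        lines.append(f"#param\t{key}\t{json.dumps(value)}")
    lines.append(f"#n_biclusters\t{len(bs)}")
    for k, bc in enumerate(bs, start=1):
        lines.append(
            f">bicluster\t{k}\titerations={bc.iterations}\tbasin_count={bc.basin_count}"
        )
        for rid, score in bc.row_scores.items():
            lines.append(f"R\t{rid}\t{score:.12g}")
        for cid, score in bc.col_scores.items():
            lines.append(f"C\t{cid}\t{score:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_score(raw: str, path: PathLike, lineno: int) -> float:
    try:
        score = float(raw)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
    if not np.isfinite(score) or abs(score) > 1.0:
        raise FormatError(f"{path}:{lineno}: score {score} outside [-1, +1]")
    return score


def read_biclusters(path: PathLike) -> BiclusterSet:
    text = Path(path).read_text().splitlines()
    if not text or text[0] != _BICLUSTER_MAGIC:
        raise FormatError(f"{path}:1: missing bicluster-file header")
    params: dict[str, object] = {}
    declared: int | None = None
    biclusters: list[Bicluster] = []
    current: dict[str, object] | None = None

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        try:
            biclusters.append(
                Bicluster(
                    row_scores=current["rows"],
                    col_scores=current["cols"],
                    iterations=current["iterations"],
                    basin_count=current["basin_count"],
                )
            )
        except DataError as exc:
            raise FormatError(f"{path}: bicluster {len(biclusters) + 1}: {exc}") from exc
        current = None

    for lineno, line in enumerate(text[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "#param":
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: malformed #param line")
            try:
                params[fields[1]] = json.loads(fields[2])
            except json.JSONDecodeError:
                params[fields[1]] = fields[2]
        elif tag == "#n_biclusters":
            declared = int(fields[1])
        elif tag == ">bicluster":
            flush()
            attrs = dict(f.split("=", 1) for f in fields[2:] if "=" in f)
            current = {
                "rows": {},
                "cols": {},
                "iterations": int(attrs.get("iterations", 0)),
                "basin_count": int(attrs.get("basin_count", 1)),
            }
        elif tag in ("R", "C"):
            if current is None:
                raise FormatError(f"{path}:{lineno}: score line before any >bicluster")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            ident = fields[1].strip()
            score = _parse_score(fields[2], path, lineno)
            side = "rows" if tag == "R" else "cols"
            if ident in current[side]:
                raise FormatError(f"{path}:{lineno}: duplicate id {ident!r}")
            current[side][ident] = score
        else:
            raise FormatError(f"{path}:{lineno}: unrecognized line {line!r}")
    flush()
    if declared is not None and declared != len(biclusters):
        raise FormatError(
            f"{path}: header declares {declared} biclusters, found {len(biclusters)}"
        )
    return BiclusterSet(tuple(biclusters), params)


# ---------------------------------------------------------------------------
# Membership heatmap
# ---------------------------------------------------------------------------

def export_membership_heatmap(
    sample_membership: pd.DataFrame, path: PathLike
) -> tuple[pd.DataFrame, Path]:
    """Render the samples x biclusters membership heatmap.

    Samples whose membership is zero in every bicluster are dropped before
    rendering (only members of at least one bicluster are shown).  A
    companion TSV with the exact plotted values is written next to the
    image so downstream checks never parse pixels.  Returns the plotted
    frame and the TSV path.
    """
    vals = sample_membership.to_numpy(dtype=float)
    if vals.size and np.abs(vals).max() > 1.0 + 1e-9:
        raise DataError("membership values must lie in [-1, +1]")
    keep = np.abs(vals).sum(axis=1) > 0
    plotted = sample_membership.loc[keep]
    if plotted.empty:
        warnings.warn("no sample belongs to any bicluster; emitting empty heatmap")

    from matplotlib.figure import Figure

    fig = Figure(figsize=(max(4.0, 0.45 * sample_membership.shape[1] + 2),
                          max(3.0, 0.12 * max(len(plotted), 1) + 1.5)))
    ax = fig.add_subplot(111)
    if plotted.empty:
        ax.text(0.5, 0.5, "no bicluster members", ha="center", va="center")
        ax.set_axis_off()
    else:
        mesh = ax.pcolormesh(
            plotted.to_numpy(dtype=float), cmap="RdBu_r", vmin=-1.0, vmax=1.0
        )
        ax.set_xticks(np.arange(plotted.shape[1]) + 0.5)
        ax.set_xticklabels(plotted.columns, rotation=90, fontsize=7)
        ax.set_yticks([])
        ax.set_ylabel(f"{len(plotted)} samples in >=1 bicluster")
        ax.invert_yaxis()
        fig.colorbar(mesh, ax=ax, label="membership")
    fig.tight_layout()
    fig.savefig(path, dpi=150)

    tsv_path = Path(path).with_suffix(".tsv")
    plotted.to_csv(tsv_path, sep="\t", float_format="%.12g")
    return plotted, tsv_path


# ---------------------------------------------------------------------------
# GEO convenience reader (local file only; no network access)
# ---------------------------------------------------------------------------

def read_geo_series_matrix(path: PathLike, orientation: str = ROWS_ARE_MIRNAS) -> CountMatrix:
    """Parse a locally saved GEO series-matrix text file into a CountMatrix.

    Only the table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; values must be integer counts.
    Provided as a convenience for users who have downloaded an expression
    series themselves; nothing in the package fetches data over the network.
    """
    rows: list[list[str]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.startswith("!series_matrix_table_end"):
                break
            if in_table and stripped:
                rows.append([f.strip().strip('"') for f in stripped.split("\t")])
    if not in_table or len(rows) < 2:
        raise FormatError(f"{path}: no series-matrix table found")
    header, *body = rows
    frame = pd.DataFrame(
        [[int(x) for x in r[1:]] for r in body],
        index=[r[0] for r in body],
        columns=header[1:],
        dtype=np.int64,
    )
    cm = CountMatrix(frame)
    if orientation == ROWS_ARE_SAMPLES:
        cm = CountMatrix(cm.frame.T)
    return cm
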