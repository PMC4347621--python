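"""Validation: cross-run stability, consensus with an external biclustering,
and bicluster-phenotype association tables.

Bicluster similarity is the Jaccard index on the union of row and column
supports (scores ignored), so ISA output can be compared with sign-free
external results such as SAMBA biclusters; row and column identifiers are
namespaced before taking the union so a gene and a sample sharing a name
cannot collide.  A score-weighted cosine similarity is available as an
option.  Association tables use the two-sided Fisher exact test with
Benjamini-Hochberg correction across all rows; the underlying study reports
no formal test, so output headers label the q-values as an extension.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import isa
from .errors import DataError
from .types import Bicluster, BiclusterSet, CohortMetadata, StandardizedPair

logger = logging.getLogger(__name__)

DEFAULT_STABILITY_THRESHOLD = 0.95


def _tagged_support(bc: Bicluster) -> frozenset[str]:
    return frozenset(f"r:{r}" for r in bc.row_set) | frozenset(
        f"c:{c}" for c in bc.col_set
    )


def bicluster_jaccard(a: Bicluster, b: Bicluster) -> float:
    """Jaccard index on the union of row and column supports."""
    sa, sb = _tagged_support(a), _tagged_support(b)
    return len(sa & sb) / len(sa | sb)


def bicluster_score_similarity(
    a: Bicluster, b: Bicluster, row_ids: list[str], col_ids: list[str]
) -> float:
    """Score-weighted similarity: mean cosine of dense row and column scores."""
    def cosine(u: np.ndarray, v: np.ndarray) -> float:
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return float(u @ v / (nu * nv)) if nu and nv else 0.0

    return 0.5 * (
        cosine(a.dense_row_scores(row_ids), b.dense_row_scores(row_ids))
        + cosine(a.dense_col_scores(col_ids), b.dense_col_scores(col_ids))
    )


@dataclass(frozen=True)
class MatchResult:
    """Pairwise Jaccard matrix plus a greedy one-to-one assignment.

    ``relevance`` is the mean best-match Jaccard of set A into B (how well
    every A module is represented in B); ``recovery`` the mean best-match
    of B into A.
    """

    jaccard: pd.DataFrame
    assignment: tuple[tuple[int, int, float], ...]
    relevance: float
    recovery: float


def match_biclusters(a: BiclusterSet, b: BiclusterSet) -> MatchResult:
    """Compare two bicluster sets over the same identifier universes."""
    if len(a) == 0 or len(b) == 0:
        warnings.warn("empty bicluster set in comparison; relevance/recovery = 0")
        J = pd.DataFrame(
            np.zeros((len(a), len(b))),
            index=[f"A{k+1}" for k in range(len(a))],
            columns=[f"B{k+1}" for k in range(len(b))],
        )
        return MatchResult(J, (), 0.0, 0.0)
    J = np.array([[bicluster_jaccard(x, y) for y in b] for x in a])
    # greedy one-to-one: repeatedly take the best remaining pair
    pairs: list[tuple[int, int, float]] = []
    free_a, free_b = set(range(len(a))), set(range(len(b)))
    order = sorted(
        itertools.product(range(len(a)), range(len(b))),
        key=lambda ij: (-J[ij], ij),
    )
    for i, j in order:
        if i in free_a and j in free_b:
            pairs.append((i, j, float(J[i, j])))
            free_a.remove(i)
            free_b.remove(j)
    frame = pd.DataFrame(
        J,
        index=[f"A{k+1}" for k in range(len(a))],
        columns=[f"B{k+1}" for k in range(len(b))],
    )
    return MatchResult(
        jaccard=frame,
        assignment=tuple(pairs),
        relevance=float(J.max(axis=1).mean()),
        recovery=float(J.max(axis=0).mean()),
    )


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of repeated ISA runs from different random initializations."""

    n_runs: int
    counts: tuple[int, ...]
    min_matched_jaccard: float
    mean_matched_jaccard: float
    threshold: float
    stable: bool
    run_seeds: tuple[int, ...] = ()

    def summary(self) -> str:
        return (
            f"{self.n_runs} runs -> bicluster counts {list(self.counts)}; "
            f"matched Jaccard min={self.min_matched_jaccard:.3f} "
            f"mean={self.mean_matched_jaccard:.3f}; "
            f"stable={'yes' if self.stable else 'no'} "
            f"(threshold {self.threshold})"
        )


def stability_analysis(
    sp: StandardizedPair,
    params: dict | None = None,
    n_runs: int = 10,
    master_seed: int = 0,
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
) -> StabilityReport:
    """Re-run ISA ``n_runs`` times with different seeds and compare the results.

    Per-run seeds derive deterministically from ``master_seed``.  Every run
    after the first is matched against the first with a greedy one-to-one
    assignment (comparison is order-invariant); the protocol is *stable*
    when all runs return the same number of biclusters and every matched
    pair reaches the Jaccard threshold.  A single run is trivially stable.
    """
    params = dict(params or {})
    params.pop("seed", None)
    params.pop("rng_seed", None)
    ss = np.random.SeedSequence(master_seed)
    run_seeds = tuple(int(s) % (2**31) for s in ss.generate_state(n_runs))
    runs = [isa.run_isa(sp, seed=s, **params) for s in run_seeds]
    counts = tuple(len(r) for r in runs)
    matched: list[float] = []
    stable = len(set(counts)) == 1
    for other in runs[1:]:
        res = match_biclusters(runs[0], other)
        if len(runs[0]) == 0 and len(other) == 0:
            continue
        js = [j for _, _, j in res.assignment]
        matched.extend(js)
        if len(res.assignment) < max(len(runs[0]), len(other)) or (
            js and min(js) < threshold
        ):
            stable = False
    return StabilityReport(
        n_runs=n_runs,
        counts=counts,
        min_matched_jaccard=float(min(matched)) if matched else 1.0,
        mean_matched_jaccard=float(np.mean(matched)) if matched else 1.0,
        threshold=threshold,
        stable=stable,
        run_seeds=run_seeds,
    )


# ---------------------------------------------------------------------------
# Phenotype association
# ---------------------------------------------------------------------------

_UNKNOWN = {"er_status": "unknown", "pr_status": "unknown",
            "her2_status": "unknown", "molecular_subtype": "NA"}

ASSOCIATION_COLUMNS = (
    "bicluster", "characteristic", "level",
    "in_with", "in_without", "out_with", "out_without",
    "odds_ratio", "fisher_p", "q_bh_extension", "continuity_corrected",
)


def _characteristic_levels(meta: CohortMetadata):
    """(characteristic, level, has-level boolean Series over annotated samples)."""
    f = meta.frame
    for col in ("er_status", "pr_status", "her2_status"):
        known = f[col] != "unknown"
        yield col, "positive", (f.loc[known, col] == "positive")
    tnbc = meta.is_tnbc()
    known = tnbc.notna()
    yield "ihc", "TNBC", tnbc[known].astype(bool)
    for col, na in (("histology", None), ("molecular_subtype", "NA")):
        known = f[col] != na if na else pd.Series(True, index=f.index)
        for level in sorted(f.loc[known, col].unique()):
            yield col, level, (f.loc[known, col] == level)


def annotation_association(
    bs: BiclusterSet, meta: CohortMetadata, alpha: float = 0.05
) -> pd.DataFrame:
    """Fisher-exact association between bicluster membership and annotations.

    One row per (bicluster, annotation level): the 2x2 table of sample
    membership versus annotation over samples with known status, the odds
    ratio (0.5 Haldane continuity correction when any cell is empty, then
    flagged), the two-sided Fisher exact p and a BH-adjusted q computed
    across all testable rows.  Biclusters with no annotated member samples
    get a row of NA statistics.
    """
    rows = []
    for k, bc in enumerate(bs, start=1):
        name = f"BC{k}"
        for characteristic, level, has_level in _characteristic_levels(meta):
            annotated = has_level.index
            in_bc = pd.Series(
                [s in bc.col_set for s in annotated], index=annotated, dtype=bool
            )
            if not in_bc.any():
                rows.append([name, characteristic, level] + [0, 0,
                            int((~in_bc & has_level).sum()),
                            int((~in_bc & ~has_level).sum())]
                            + [np.nan, np.nan, np.nan, False])
                continue
            a = int((in_bc & has_level).sum())
            b = int((in_bc & ~has_level).sum())
            c = int((~in_bc & has_level).sum())
            d = int((~in_bc & ~has_level).sum())
            corrected = 0 in (a, b, c, d)
            if corrected:
                oddsr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
            else:
                oddsr = a * d / (b * c)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append([name, characteristic, level, a, b, c, d,
                         float(oddsr), float(p), np.nan, corrected])
    table = pd.DataFrame(rows, columns=list(ASSOCIATION_COLUMNS))
    testable = table["fisher_p"].notna()
    if testable.any():
        table.loc[testable, "q_bh_extension"] = multipletests(
            table.loc[testable, "fisher_p"].to_numpy(), alpha=alpha, method="fdr_bh"
        )[1]
    return table


def fixed_point_check(
    sp: StandardizedPair, bc: Bicluster, th_r: float, th_c: float
) -> bool:
    """True when one further ISA iteration from the bicluster's scores
    reproduces its row and column supports exactly."""
    r = bc.dense_row_scores(sp.row_ids)
    try:
        c_new, r_new = isa.one_step(sp, r, th_r, th_c)
    except DataError:
        return False
    return (
        frozenset(np.array(sp.sample_ids)[np.flatnonzero(c_new)]) == bc.col_set
        and frozenset(np.array(sp.row_ids)[np.flatnonzero(r_new)]) == bc.row_set
    )
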