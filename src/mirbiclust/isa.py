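"""The Iterative Signature Algorithm (ISA).

ISA searches a standardized expression matrix for *transcription modules*:
subsets of rows (miRNA families) behaving coherently over subsets of columns
(samples).  From a random sparse 0/1 seed over the rows it alternates two
thresholded projections — sample scores from the row-standardized matrix,
row scores from the column-standardized matrix — until consecutive score
vectors agree (Pearson correlation within ``eps`` of 1 and identical
supports).  Each fixed point is a bicluster with signed soft memberships in
[-1, +1]; +1 and -1 both mean maximal association, with opposite correlation
direction.  Thresholding is two-sided on the z-score (|z| > th), which is
what makes the negative memberships possible.  Fixed points reached from
many seeds are deduplicated by score correlation, keeping track of how many
seeds fell into each basin.

The two thresholds ``th_r`` (rows) and ``th_c`` (columns) control bicluster
granularity: higher thresholds give smaller, tighter modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateVectorError
from .types import Bicluster, BiclusterSet, MembershipMatrices, StandardizedPair

logger = logging.getLogger(__name__)

#: Default z-score thresholds: tight on the family side, permissive on
#: the sample side, favouring small coherent modules over broad ones.
DEFAULT_TH_R = 3.5
DEFAULT_TH_C = 1.0
DEFAULT_N_SEEDS = 300
DEFAULT_SPARSITY = 2
DEFAULT_EPS = 0.01
DEFAULT_MAX_ITER = 100
DEFAULT_COR_MERGE = 0.9
DEFAULT_N_PERMUTATIONS = 3
DEFAULT_MIN_BASIN = 2
DEFAULT_ROBUSTNESS_MARGIN = 1.1


def generate_seeds(
    m: int, n_seeds: int, sparsity: int, rng: np.random.Generator
) -> np.ndarray:
    """Random sparse 0/1 seed vectors, one per row of the returned array.

    Each seed has exactly ``sparsity`` ones at positions drawn uniformly
    without replacement; fully determined by the generator state.
    """
    if not 1 <= sparsity <= m:
        raise DataError(f"seed sparsity {sparsity} outside [1, {m}]")
    if n_seeds < 1:
        raise DataError("need at least one seed")
    seeds = np.zeros((n_seeds, m), dtype=np.int8)
    for k in range(n_seeds):
        seeds[k, rng.choice(m, size=sparsity, replace=False)] = 1
    return seeds


def threshold_scores(v: np.ndarray, th: float) -> np.ndarray:
    """Z-score ``v`` and keep entries with |z| > th (signed), zero elsewhere.

    Thresholding is two-sided and strict; a zero-SD input raises
    :class:`DegenerateVectorError` (callers discard the seed).
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise DataError("score vector needs at least 2 entries")
    sd = v.std()  # population denominator
    if sd == 0:
        raise DegenerateVectorError("score vector has zero standard deviation")
    z = (v - v.mean()) / sd
    return np.where(np.abs(z) > th, z, 0.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with a guard for constant vectors."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _support(v: np.ndarray) -> np.ndarray:
    return v != 0


def one_step(
    sp: StandardizedPair, r: np.ndarray, th_r: float, th_c: float
) -> tuple[np.ndarray, np.ndarray]:
    """A single ISA iteration from a row vector: returns (c_new, r_new).

    Sample scores come from the row-standardized matrix, row scores from the
    column-standardized one; either may be all-zero if nothing passes its
    threshold.
    """
    E_rows = sp.row_std.to_numpy()
    E_cols = sp.col_std.to_numpy()
    c = threshold_scores(E_rows.T @ r, th_c)
    if not c.any():
        return c, np.zeros(E_rows.shape[0])
    r_new = threshold_scores(E_cols @ c, th_r)
    return c, r_new


def isa_iterate(
    sp: StandardizedPair,
    seed: np.ndarray,
    th_r: float = DEFAULT_TH_R,
    th_c: float = DEFAULT_TH_C,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Bicluster | None:
    """Iterate ISA from one seed; return the fixed point or None.

    Convergence requires Pearson(r_i, r_{i-1}) >= 1 - eps and likewise for
    the column vectors, plus unchanged supports on both sides, so a reported
    bicluster is stable under a further iteration.  An all-zero intermediate
    vector, a degenerate (zero-SD) product, or exceeding ``max_iter``
    all yield None.
    """
    seed = np.asarray(seed, dtype=float)
    if seed.shape != (sp.shape[0],):
        raise DataError(
            f"seed length {seed.shape} does not match row count {sp.shape[0]}"
        )
    r_prev = seed
    c_prev: np.ndarray | None = None
    for iteration in range(1, max_iter + 1):
        try:
            c, r = one_step(sp, r_prev, th_r, th_c)
        except DegenerateVectorError:
            return None
        if not c.any() or not r.any():
            return None
        if c_prev is not None:
            converged = (
                _pearson(r, r_prev) >= 1.0 - eps
                and _pearson(c, c_prev) >= 1.0 - eps
                and np.array_equal(_support(r), _support(r_prev))
                and np.array_equal(_support(c), _support(c_prev))
            )
            if converged:
                return _as_bicluster(sp, r, c, iteration)
        r_prev, c_prev = r, c
    return None


def _as_bicluster(
    sp: StandardizedPair, r: np.ndarray, c: np.ndarray, iterations: int
) -> Bicluster:
    # A global sign flip (r, c) -> (-r, -c) maps fixed points to fixed
    # points; canonicalize so the column (sample) scores sum positive,
    # making independent runs directly comparable.
    flip = c.sum() if c.sum() != 0 else r.sum()
    if flip < 0:
        r, c = -r, -c
    r = r / np.abs(r).max()
    c = c / np.abs(c).max()
    row_ids = sp.row_ids
    col_ids = sp.sample_ids
    return Bicluster(
        row_scores={row_ids[i]: float(r[i]) for i in np.flatnonzero(r)},
        col_scores={col_ids[j]: float(c[j]) for j in np.flatnonzero(c)},
        iterations=iterations,
        basin_count=1,
    )


def merge_fixed_points(
    candidates: list[Bicluster],
    cor_merge: float = DEFAULT_COR_MERGE,
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
    params: dict | None = None,
) -> BiclusterSet:
    """Collapse duplicate fixed points from different seeds.

    Two fixed points are duplicates when the Pearson correlation of their
    dense row-score vectors exceeds ``cor_merge`` AND likewise for their
    column scores, allowing for a global sign flip (both correlations
    below ``-cor_merge``), since (r, c) and (-r, -c) are the same module.
    Duplicates collapse to the member with the largest basin count (ties:
    first found); basin counts accumulate.
    """
    if row_ids is None:
        row_ids = BiclusterSet(tuple(candidates)).all_row_ids
    if col_ids is None:
        col_ids = BiclusterSet(tuple(candidates)).all_col_ids
    if not candidates:
        return BiclusterSet((), params or {})

    def corr_matrix(vectors: np.ndarray) -> np.ndarray:
        centered = vectors - vectors.mean(axis=1, keepdims=True)
        sd = centered.std(axis=1)
        ok = sd > 0
        normed = np.zeros_like(centered)
        normed[ok] = centered[ok] / (sd[ok, None] * np.sqrt(vectors.shape[1]))
        corr = normed @ normed.T
        if (~ok).any():  # constant score vectors: equal pairs correlate fully
            for i in np.flatnonzero(~ok):
                corr[i, :] = corr[:, i] = [
                    1.0 if np.allclose(vectors[i], vectors[j]) else 0.0
                    for j in range(len(vectors))
                ]
        return corr

    R = np.array([c.dense_row_scores(row_ids) for c in candidates])
    C = np.array([c.dense_col_scores(col_ids) for c in candidates])
    CR, CC = corr_matrix(R), corr_matrix(C)
    # the flip branch additionally requires overlapping supports: (r, c) and
    # (-r, -c) share their supports, whereas disjoint modules in a small id
    # universe can be perfectly anti-correlated without being the same module
    overlap = (((R != 0).astype(float) @ (R != 0).T.astype(float)) > 0) & (
        ((C != 0).astype(float) @ (C != 0).T.astype(float)) > 0
    )
    duplicate = ((CR > cor_merge) & (CC > cor_merge)) | (
        (CR < -cor_merge) & (CC < -cor_merge) & overlap
    )
    reps: list[Bicluster] = []
    rep_idx: list[int] = []
    for i, cand in enumerate(candidates):
        merged = False
        for k, j in enumerate(rep_idx):
            if duplicate[i, j]:
                rep = reps[k]
                if cand.basin_count > rep.basin_count:
                    rep, cand = cand, rep
                    rep_idx[k] = i
                reps[k] = Bicluster(
                    row_scores=rep.row_scores,
                    col_scores=rep.col_scores,
                    iterations=rep.iterations,
                    basin_count=rep.basin_count + cand.basin_count,
                )
                merged = True
                break
        if not merged:
            reps.append(cand)
            rep_idx.append(i)
    return BiclusterSet(tuple(reps), params or {})


def _iterate_batch(
    sp: StandardizedPair,
    seeds: np.ndarray,
    th_r: float,
    th_c: float,
    eps: float,
    max_iter: int,
) -> list[Bicluster | None]:
    """Run :func:`isa_iterate` for every seed at once via matrix products.

    Mathematically identical to the per-seed loop (seeds are independent);
    returns results in seed order, None for non-converged seeds.
    """
    Er = sp.row_std.to_numpy()
    Ec = sp.col_std.to_numpy()
    k = seeds.shape[0]
    R = seeds.T.astype(float)  # m x k
    C_prev = None
    R_prev = R
    results: list[Bicluster | None] = [None] * k
    active = np.arange(k)

    def col_zscore(M: np.ndarray, th: float) -> tuple[np.ndarray, np.ndarray]:
        mean = M.mean(axis=0)
        sd = M.std(axis=0)
        ok = sd > 0
        Z = np.zeros_like(M)
        Z[:, ok] = (M[:, ok] - mean[ok]) / sd[ok]
        Z[np.abs(Z) <= th] = 0.0
        return Z, ok & (np.abs(Z) > 0).any(axis=0)

    def col_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        sa, sb = A.std(axis=0), B.std(axis=0)
        cov = (A * B).mean(axis=0) - A.mean(axis=0) * B.mean(axis=0)
        out = np.zeros(A.shape[1])
        ok = (sa > 0) & (sb > 0)
        out[ok] = cov[ok] / (sa[ok] * sb[ok])
        degen = ~ok
        if degen.any():
            out[degen] = np.isclose(A[:, degen], B[:, degen]).all(axis=0)
        return out

    for iteration in range(1, max_iter + 1):
        if active.size == 0:
            break
        C, alive_c = col_zscore(Er.T @ R, th_c)
        Rn = np.zeros_like(R)
        Zr, alive_r = col_zscore(Ec @ C[:, alive_c], th_r) if alive_c.any() else (
            np.zeros((Er.shape[0], 0)), np.zeros(0, dtype=bool))
        Rn[:, alive_c] = Zr
        alive = alive_c.copy()
        alive[alive_c] &= alive_r
        if C_prev is not None:
            conv = (
                (col_pearson(Rn, R_prev) >= 1.0 - eps)
                & (col_pearson(C, C_prev) >= 1.0 - eps)
                & ((Rn != 0) == (R_prev != 0)).all(axis=0)
                & ((C != 0) == (C_prev != 0)).all(axis=0)
                & alive
            )
            for idx in np.flatnonzero(conv):
                results[active[idx]] = _as_bicluster(
                    sp, Rn[:, idx], C[:, idx], iteration
                )
            alive &= ~conv
        keep = np.flatnonzero(alive)
        active = active[keep]
        R_prev = Rn[:, keep]
        C_prev = C[:, keep]
        R = R_prev
    return results


def robustness(sp: StandardizedPair, bc: Bicluster) -> float:
    """Robustness score of a module: normalized bilinear signal strength.

    sqrt of the product of the two projections r' (E_cols c) and
    c' (E_rows' r), scaled by the score-vector norms.  Coherent modules
    score far above chance fixed points; used by :func:`filter_robust`.
    """
    r = bc.dense_row_scores(sp.row_ids)
    c = bc.dense_col_scores(sp.sample_ids)
    a = float(r @ (sp.col_std.to_numpy() @ c))
    b = float(c @ (sp.row_std.to_numpy().T @ r))
    return float(
        np.sqrt(max(a, 0.0) * max(b, 0.0))
        / (np.linalg.norm(r) * np.linalg.norm(c))
    )


def permute_pair(sp: StandardizedPair, rng: np.random.Generator) -> StandardizedPair:
    """Null model: shuffle each row independently, re-standardize columns.

    Preserves every row's marginal distribution while destroying any
    row-column module structure.
    """
    vals = sp.row_std.to_numpy().copy()
    for i in range(vals.shape[0]):
        rng.shuffle(vals[i])
    row_std = pd.DataFrame(vals, index=sp.row_std.index, columns=sp.row_std.columns)
    sd = row_std.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # permutation cannot realistically zero a column out
    col_std = (row_std - row_std.mean(axis=0)) / sd
    return StandardizedPair(row_std, col_std,
                            dropped_rows=sp.dropped_rows,
                            dropped_cols=sp.dropped_cols)


def run_isa(
    sp: StandardizedPair,
    th_r: float = DEFAULT_TH_R,
    th_c: float = DEFAULT_TH_C,
    n_seeds: int = DEFAULT_N_SEEDS,
    sparsity: int = DEFAULT_SPARSITY,
    eps: float = DEFAULT_EPS,
    max_iter: int = DEFAULT_MAX_ITER,
    cor_merge: float = DEFAULT_COR_MERGE,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    robustness_filter: bool = True,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    min_basin: int = DEFAULT_MIN_BASIN,
    robustness_margin: float = DEFAULT_ROBUSTNESS_MARGIN,
) -> BiclusterSet:
    """Full ISA run: seeds -> iteration -> deduplication -> filtering.

    Sparse random seeds converge to many low-signal chance fixed points;
    two filters separate them from genuine modules.  With
    ``robustness_filter`` on (the default), ISA is rerun with the same
    parameters on ``n_permutations`` row-permuted copies of the data and
    real modules are kept only when their robustness exceeds
    ``robustness_margin`` times the largest robustness any permuted-data
    module reaches; the margin covers the slight strengthening of chance
    fixed points on real relative-frequency data, whose compositional
    coupling between rows the row-permutation null does not preserve.  ``min_basin`` is a
    reproducibility requirement: a reported module must have been reached
    from at least that many independent seeds (set to 1 to disable).
    Deterministic given ``seed``; the returned set's ``params`` record
    every argument needed to reproduce the run.  Zero converged seeds give
    an empty set with a warning (not an error).
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    def one_pass(pair: StandardizedPair) -> list[Bicluster]:
        seeds = generate_seeds(pair.shape[0], n_seeds, sparsity, rng)
        return [
            bc
            for bc in _iterate_batch(pair, seeds, th_r, th_c, eps, max_iter)
            if bc is not None
        ]

    converged = one_pass(sp)
    params: dict[str, object] = {
        "th_r": th_r,
        "th_c": th_c,
        "n_seeds": n_seeds,
        "sparsity": sparsity,
        "eps": eps,
        "max_iter": max_iter,
        "cor_merge": cor_merge,
        "rng_seed": seed,
        "robustness_filter": robustness_filter,
        "n_permutations": n_permutations if robustness_filter else 0,
        "min_basin": min_basin,
        "robustness_margin": robustness_margin if robustness_filter else None,
        "n_converged_seeds": len(converged),
    }
    if not converged:
        logger.warning("no seed converged; returning an empty bicluster set")
        return BiclusterSet((), params)
    merged = merge_fixed_points(
        converged, cor_merge, row_ids=sp.row_ids, col_ids=sp.sample_ids
    )
    kept = [bc for bc in merged if bc.basin_count >= min_basin]
    if robustness_filter:
        threshold = 0.0
        for _ in range(n_permutations):
            null_sp = permute_pair(sp, rng)
            for bc in one_pass(null_sp):
                threshold = max(threshold, robustness(null_sp, bc))
        threshold *= robustness_margin
        params["robustness_threshold"] = threshold
        kept = [bc for bc in kept if robustness(sp, bc) > threshold]
        logger.info(
            "robustness filter: kept %d/%d modules (null threshold %.3f)",
            len(kept), len(merged), threshold,
        )
    logger.info(
        "run_isa: %d/%d seeds converged into %d biclusters",
        len(converged), n_seeds, len(kept),
    )
    return BiclusterSet(tuple(kept), params)


def membership_matrices(
    bs: BiclusterSet, all_row_ids: list[str], all_col_ids: list[str]
) -> MembershipMatrices:
    """Dense miRNA x bicluster and sample x bicluster soft-membership matrices."""
    universe_r, universe_c = set(all_row_ids), set(all_col_ids)
    for k, bc in enumerate(bs, start=1):
        unknown = (bc.row_set - universe_r) | (bc.col_set - universe_c)
        if unknown:
            raise DataError(f"bicluster {k} references unknown ids: {sorted(unknown)}")
    cols = [f"BC{k}" for k in range(1, len(bs) + 1)]
    row_m = pd.DataFrame(0.0, index=pd.Index(all_row_ids), columns=cols)
    col_m = pd.DataFrame(0.0, index=pd.Index(all_col_ids), columns=cols)
    for k, bc in enumerate(bs):
        for rid, score in bc.row_scores.items():
            row_m.iloc[row_m.index.get_loc(rid), k] = score
        for cid, score in bc.col_scores.items():
            col_m.iloc[col_m.index.get_loc(cid), k] = score
    return MembershipMatrices(row_membership=row_m, col_membership=col_m)
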