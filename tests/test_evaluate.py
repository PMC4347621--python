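import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirbiclust import evaluate, isa
from mirbiclust.types import Bicluster, BiclusterSet


def bc(rows, cols):
    return Bicluster({r: 1.0 for r in rows}, {c: 1.0 for c in cols})


class TestJaccard:
    def test_set_arithmetic(self):
        a = bc(["g1", "g2"], ["s1"])
        b = bc(["g2", "g3"], ["s1"])
        assert evaluate.bicluster_jaccard(a, b) == pytest.approx(0.5)

    def test_row_and_col_namespaces_do_not_collide(self):
        # identifier "x" as a gene in one set, as a sample in the other
        a = bc(["x"], ["s1"])
        b = bc(["g1"], ["x"])
        assert evaluate.bicluster_jaccard(a, b) == 0.0

    def test_identity(self):
        a = bc(["g1"], ["s1", "s2"])
        assert evaluate.bicluster_jaccard(a, a) == 1.0


class TestMatchBiclusters:
    def test_self_match_is_perfect(self):
        s = BiclusterSet((bc(["g1"], ["s1"]), bc(["g2", "g3"], ["s2"])))
        res = evaluate.match_biclusters(s, s)
        assert res.relevance == 1.0 and res.recovery == 1.0
        assert all(j == 1.0 for _, _, j in res.assignment)

    def test_disjoint_sets_score_zero(self):
        a = BiclusterSet((bc(["g1"], ["s1"]),))
        b = BiclusterSet((bc(["g2"], ["s2"]),))
        res = evaluate.match_biclusters(a, b)
        assert res.relevance == 0.0 and res.recovery == 0.0

    def test_empty_set_warns_and_scores_zero(self):
        a = BiclusterSet((bc(["g1"], ["s1"]),))
        with pytest.warns(UserWarning, match="empty"):
            res = evaluate.match_biclusters(a, BiclusterSet(()))
        assert res.relevance == 0.0 and res.recovery == 0.0

    def test_permutation_invariance(self):
        items = (bc(["g1"], ["s1"]), bc(["g2"], ["s2"]), bc(["g1", "g2"], ["s3"]))
        a = BiclusterSet(items)
        b = BiclusterSet((bc(["g1"], ["s1", "s3"]), bc(["g2", "g4"], ["s2"])))
        base = evaluate.match_biclusters(a, b)
        for perm in itertools.permutations(items):
            res = evaluate.match_biclusters(BiclusterSet(perm), b)
            assert res.relevance == pytest.approx(base.relevance)
            assert res.recovery == pytest.approx(base.recovery)

    def test_nested_sets(self):
        a = BiclusterSet((bc(["g1"], ["s1"]), bc(["g2"], ["s2"])))
        b = BiclusterSet(a.biclusters + (bc(["g9"], ["s9"]),))
        res = evaluate.match_biclusters(a, b)
        assert res.relevance == 1.0  # every A module still perfectly present
        assert res.recovery < 1.0  # the extra B module is unmatched


class TestStability:
    def test_single_run_trivially_stable(self, planted_instance):
        *_, sp = planted_instance
        rep = evaluate.stability_analysis(sp, params={"n_seeds": 60},
                                          n_runs=1, master_seed=0)
        assert rep.stable and rep.min_matched_jaccard == 1.0

    def test_planted_instance_stable_over_runs(self, planted_instance):
        *_, sp = planted_instance
        rep = evaluate.stability_analysis(sp, n_runs=4, master_seed=5)
        assert rep.stable
        assert rep.min_matched_jaccard >= 0.95
        assert len(set(rep.counts)) == 1

    def test_flag_computed_on_noise(self):
        """Pure noise with permissive thresholds: the flag is well-defined
        either way; only its existence and the report schema are asserted."""
        from mirbiclust import preprocess

        rng = np.random.default_rng(8)
        frame = pd.DataFrame(
            rng.lognormal(0, 1, (40, 30)),
            index=[f"g{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(30)],
        )
        sp = preprocess.standardize(frame)
        rep = evaluate.stability_analysis(
            sp, params={"n_seeds": 40, "th_r": 1.5, "th_c": 1.0},
            n_runs=2, master_seed=3,
        )
        assert isinstance(rep.stable, bool)
        assert len(rep.counts) == 2

    def test_summary_mentions_counts(self, planted_instance):
        *_, sp = planted_instance
        rep = evaluate.stability_analysis(sp, params={"n_seeds": 60},
                                          n_runs=2, master_seed=1)
        assert "stable=" in rep.summary()


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (
            math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(n, col1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisherOracle:
    def test_exhaustive_agreement_small_tables(self):
        """scipy's two-sided Fisher p equals hypergeometric enumeration for
        every 2x2 table with total n <= 12."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        _, p = stats.fisher_exact([[a, b], [c, d]])
                        oracle = fisher_two_sided_oracle(a, b, c, d)
                        assert p == pytest.approx(oracle, abs=1e-9), (a, b, c, d)


class TestAnnotationAssociation:
    def test_perfect_tnbc_bicluster_p_value(self, cohort):
        # bicluster = exactly the 5 TNBC samples of a 10-sample cohort
        bs = BiclusterSet((bc(["g1"], [f"S{i}" for i in range(1, 6)]),))
        table = evaluate.annotation_association(bs, cohort)
        row = table[(table["characteristic"] == "ihc") & (table["level"] == "TNBC")]
        assert row["in_with"].item() == 5 and row["out_without"].item() == 5
        assert row["fisher_p"].item() == pytest.approx(2 / 252, abs=1e-9)

    def test_unknown_status_excluded(self, cohort):
        meta = cohort.frame.copy()
        meta.loc["S1", "er_status"] = "unknown"
        from mirbiclust.types import CohortMetadata

        bs = BiclusterSet((bc(["g1"], ["S1", "S2"]),))
        table = evaluate.annotation_association(bs, CohortMetadata(meta))
        row = table[(table["characteristic"] == "er_status")]
        counts = row[["in_with", "in_without", "out_with", "out_without"]].sum(axis=1)
        assert counts.item() == 9  # S1 no longer annotated for ER

    def test_zero_cell_continuity_correction_flagged(self, cohort):
        bs = BiclusterSet((bc(["g1"], ["S1", "S2"]),))  # both ER-negative
        table = evaluate.annotation_association(bs, cohort)
        row = table[(table["characteristic"] == "er_status")].iloc[0]
        assert row["continuity_corrected"]
        assert np.isfinite(row["odds_ratio"])

    def test_no_annotated_members_gives_na_row(self, cohort):
        bs = BiclusterSet((bc(["g1"], ["SX"]),))  # sample not in the cohort
        table = evaluate.annotation_association(bs, cohort)
        assert table["fisher_p"].isna().all()

    def test_bh_column_within_01(self, cohort):
        bs = BiclusterSet((bc(["g1"], ["S1", "S3", "S7"]),))
        table = evaluate.annotation_association(bs, cohort)
        q = table["q_bh_extension"].dropna()
        assert ((q >= 0) & (q <= 1)).all()

    def test_null_odds_ratio_near_one(self):
        """Membership independent of annotation by construction -> OR ~ 1."""
        rng = np.random.default_rng(0)
        from mirbiclust.types import CohortMetadata

        n = 400
        frame = pd.DataFrame(
            {
                "er_status": rng.choice(["positive", "negative"], n),
                "pr_status": rng.choice(["positive", "negative"], n),
                "her2_status": rng.choice(["positive", "negative"], n),
                "histology": ["IDC"] * n,
                "molecular_subtype": ["Basal"] * n,
            },
            index=[f"S{i}" for i in range(n)],
        )
        meta = CohortMetadata(frame)
        members = rng.choice(frame.index, size=200, replace=False)
        bs = BiclusterSet((bc(["g1"], list(members)),))
        table = evaluate.annotation_association(bs, meta)
        ors = table[table["characteristic"] == "er_status"]["odds_ratio"]
        assert 0.5 < ors.item() < 2.0


class TestFixedPointCheck:
    def test_reported_modules_are_fixed_points(self, planted_instance):
        *_, sp = planted_instance
        bs = isa.run_isa(sp, seed=2)
        assert len(bs) > 0
        for bcluster in bs:
            assert evaluate.fixed_point_check(sp, bcluster, 3.5, 1.0)
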