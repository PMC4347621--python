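import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirbiclust import isa, preprocess
from mirbiclust.errors import DataError, DegenerateVectorError
from mirbiclust.types import Bicluster, StandardizedPair


def pair_from(matrix: np.ndarray) -> StandardizedPair:
    frame = pd.DataFrame(
        matrix,
        index=[f"g{i}" for i in range(matrix.shape[0])],
        columns=[f"s{j}" for j in range(matrix.shape[1])],
    )
    return preprocess.standardize(frame)


@pytest.fixture(scope="module")
def block_pair():
    """100x60 noise matrix with one planted 10x8 block of +5."""
    rng = np.random.default_rng(0)
    mat = rng.normal(0, 1, (100, 60))
    mat[:10, :8] += 5.0
    return pair_from(mat)


class TestGenerateSeeds:
    def test_full_sparsity_forces_all_ones(self):
        seeds = isa.generate_seeds(5, 3, 5, np.random.default_rng(0))
        assert (seeds == 1).all()

    def test_deterministic_given_seed(self):
        a = isa.generate_seeds(100, 20, 2, np.random.default_rng(7))
        b = isa.generate_seeds(100, 20, 2, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_exact_sparsity(self):
        seeds = isa.generate_seeds(100, 100, 2, np.random.default_rng(1))
        assert (seeds.sum(axis=1) == 2).all()

    def test_sparsity_beyond_m_is_error(self):
        with pytest.raises(DataError):
            isa.generate_seeds(3, 1, 4, np.random.default_rng(0))


class TestThresholdScores:
    def test_single_outlier_z_value(self):
        # v = (0,0,0,10): mean 2.5, population SD ~4.330, z4 ~ 1.732
        out = isa.threshold_scores(np.array([0.0, 0, 0, 10]), th=1.0)
        assert out[:3].tolist() == [0.0, 0.0, 0.0]
        assert out[3] == pytest.approx(np.sqrt(3), abs=1e-9)

    def test_zero_threshold_keeps_all_nonzero_z(self):
        out = isa.threshold_scores(np.array([1.0, 2.0, 3.0]), th=0.0)
        assert np.count_nonzero(out) == 2  # middle entry has z exactly 0

    def test_constant_vector_signals_degenerate(self):
        with pytest.raises(DegenerateVectorError):
            isa.threshold_scores(np.array([5.0, 5.0, 5.0]), th=1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        v=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
        th_lo=st.floats(0, 2),
        delta=st.floats(0.1, 3),
    )
    def test_support_shrinks_as_threshold_grows(self, v, th_lo, delta):
        vec = np.asarray(v)
        if vec.std() == 0:
            return
        lo = isa.threshold_scores(vec, th_lo)
        hi = isa.threshold_scores(vec, th_lo + delta)
        assert set(np.flatnonzero(hi)) <= set(np.flatnonzero(lo))


class TestIsaIterate:
    def test_planted_block_recovered_from_inside_seed(self, block_pair):
        seed = np.zeros(100)
        seed[[2, 7]] = 1  # inside the planted block
        bc = isa.isa_iterate(block_pair, seed, th_r=2.5, th_c=1.5)
        assert bc is not None
        assert bc.row_set == {f"g{i}" for i in range(10)}
        assert bc.col_set == {f"s{j}" for j in range(8)}

    def test_planted_supports_are_a_fixed_point(self, block_pair):
        r = np.zeros(100)
        r[:10] = 1.0
        c, r_new = isa.one_step(block_pair, r, th_r=2.5, th_c=1.5)
        assert set(np.flatnonzero(c)) == set(range(8))
        assert set(np.flatnonzero(r_new)) == set(range(10))

    def test_dimension_mismatch_is_error(self, block_pair):
        with pytest.raises(DataError, match="length"):
            isa.isa_iterate(block_pair, np.ones(99))

    def test_noise_seed_with_huge_threshold_fails_to_converge(self):
        rng = np.random.default_rng(5)
        sp = pair_from(rng.normal(0, 1, (50, 40)))
        seed = np.zeros(50)
        seed[[3, 30]] = 1
        assert isa.isa_iterate(sp, seed, th_r=6.0, th_c=1.0) is None

    def test_scores_at_unit_max_norm(self, block_pair):
        seed = np.zeros(100)
        seed[[0, 1]] = 1
        bc = isa.isa_iterate(block_pair, seed, th_r=2.5, th_c=1.5)
        assert max(abs(s) for s in bc.row_scores.values()) == pytest.approx(1.0)
        assert max(abs(s) for s in bc.col_scores.values()) == pytest.approx(1.0)


class TestBatchIteration:
    def test_batch_matches_per_seed_path(self, block_pair):
        rng = np.random.default_rng(11)
        seeds = isa.generate_seeds(100, 30, 2, rng)
        batch = isa._iterate_batch(block_pair, seeds, 3.5, 1.0, 0.01, 100)
        for seed, got in zip(seeds, batch):
            ref = isa.isa_iterate(block_pair, seed, 3.5, 1.0, 0.01, 100)
            assert (ref is None) == (got is None)
            if ref is not None:
                assert got.iterations == ref.iterations
                assert got.row_set == ref.row_set
                assert got.col_set == ref.col_set
                for k, v in ref.row_scores.items():
                    assert got.row_scores[k] == pytest.approx(v, abs=1e-12)


class TestMergeFixedPoints:
    def test_identical_fixed_points_collapse(self):
        bc = Bicluster({"g1": 1.0}, {"s1": 1.0})
        merged = isa.merge_fixed_points([bc, bc], 0.9,
                                        row_ids=["g1", "g2"], col_ids=["s1", "s2"])
        assert len(merged) == 1
        assert merged[0].basin_count == 2

    def test_disjoint_supports_retained(self):
        a = Bicluster({"g1": 1.0}, {"s1": 1.0})
        b = Bicluster({"g2": 1.0}, {"s2": 1.0})
        merged = isa.merge_fixed_points([a, b], 0.9,
                                        row_ids=["g1", "g2"], col_ids=["s1", "s2"])
        assert len(merged) == 2

    def test_sign_flipped_duplicates_collapse(self):
        a = Bicluster({"g1": 1.0, "g2": 0.5}, {"s1": 1.0, "s2": 0.25})
        b = Bicluster({"g1": -1.0, "g2": -0.5}, {"s1": -1.0, "s2": -0.25})
        merged = isa.merge_fixed_points(
            [a, b], 0.9, row_ids=["g1", "g2", "g3"], col_ids=["s1", "s2", "s3"]
        )
        assert len(merged) == 1 and merged[0].basin_count == 2

    def test_many_seeds_on_single_block_give_one_bicluster(self, block_pair):
        rng = np.random.default_rng(3)
        candidates = []
        for seed in isa.generate_seeds(100, 100, 2, rng):
            bc = isa.isa_iterate(block_pair, seed, th_r=2.5, th_c=1.5)
            if bc is not None and bc.row_set >= {"g0", "g1"}:
                candidates.append(bc)
        assert len(candidates) > 5
        merged = isa.merge_fixed_points(
            candidates, 0.9,
            row_ids=list(block_pair.row_ids), col_ids=list(block_pair.sample_ids),
        )
        assert len(merged) == 1
        assert merged[0].basin_count == len(candidates)


class TestRunIsa:
    def test_deterministic_given_seed(self, planted_instance):
        *_, sp = planted_instance
        a = isa.run_isa(sp, seed=123, n_seeds=60)
        b = isa.run_isa(sp, seed=123, n_seeds=60)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.row_scores == y.row_scores
            assert x.col_scores == y.col_scores

    def test_parameters_recorded(self, planted_instance):
        *_, sp = planted_instance
        bs = isa.run_isa(sp, seed=9, n_seeds=50)
        assert bs.params["th_r"] == 3.5 and bs.params["th_c"] == 1.0
        assert bs.params["rng_seed"] == 9
        assert "robustness_threshold" in bs.params

    def test_defaults_match_study_thresholds(self):
        assert isa.DEFAULT_TH_R == 3.5
        assert isa.DEFAULT_TH_C == 1.0

    def test_membership_bounded_and_unit_max(self, planted_instance):
        *_, sp = planted_instance
        bs = isa.run_isa(sp, seed=1)
        mm = isa.membership_matrices(bs, sp.row_ids, sp.sample_ids)
        assert len(bs) > 0
        for m in (mm.row_membership, mm.col_membership):
            vals = m.to_numpy()
            assert np.abs(vals).max() <= 1.0 + 1e-12
            np.testing.assert_allclose(np.abs(vals).max(axis=0), 1.0)


class TestMembershipMatrices:
    def test_empty_set_gives_zero_matrices(self):
        from mirbiclust.types import BiclusterSet

        mm = isa.membership_matrices(BiclusterSet(()), ["g1"], ["s1"])
        assert mm.row_membership.shape == (1, 0)

    def test_scores_embedded_at_right_cells(self):
        from mirbiclust.types import BiclusterSet

        bs = BiclusterSet((Bicluster({"g2": -1.0}, {"s1": 1.0}),))
        mm = isa.membership_matrices(bs, ["g1", "g2"], ["s1", "s2"])
        assert mm.row_membership.loc["g2", "BC1"] == -1.0
        assert mm.row_membership.loc["g1", "BC1"] == 0.0
        assert mm.col_membership.loc["s1", "BC1"] == 1.0

    def test_unknown_id_is_error(self):
        from mirbiclust.types import BiclusterSet

        bs = BiclusterSet((Bicluster({"gX": 1.0}, {"s1": 1.0}),))
        with pytest.raises(DataError, match="gX"):
            isa.membership_matrices(bs, ["g1"], ["s1"])


class TestSoftOverlap:
    def test_overlapping_planted_modules_share_members(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(0, 1, (120, 80))
        mat[:10, :12] += 5.0
        mat[6:16, 8:20] += 5.0  # overlaps rows 6-9 and cols 8-11
        sp = pair_from(mat)
        found = []
        for rows in ([0, 1], [12, 13]):
            seed = np.zeros(120)
            seed[rows] = 1
            bc = isa.isa_iterate(sp, seed, th_r=2.5, th_c=1.5)
            assert bc is not None
            found.append(bc)
        shared_rows = found[0].row_set & found[1].row_set
        assert shared_rows, "overlapping modules should share row members"
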