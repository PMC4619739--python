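import numpy as np
import pytest

from level2ppi import (
    GeneList,
    build_network,
    classify_and_rank,
    coincidence_profile,
    holdout_cv,
    score_all,
    set_overlap,
)
from level2ppi.prediction import CandidateRecord
from level2ppi.validation import _paired_test, eligible_seed_pool, write_cv_table


class TestHoldoutCV:
    def test_planted_network_level2_beats_level1(self, planted_truth):
        """Seeds sharing hubs: held-out disease genes score far above background."""
        res = holdout_cv(
            planted_truth.network,
            planted_truth.seed_genes.as_set(),
            k=5,
            n_reps=100,
            rng_seed=1,
        )
        assert res.mean_ratio_level2 > 1
        assert res.mean_ratio_level2 > res.mean_ratio_level1
        assert res.paired_p < 0.05
        assert res.paired_t_stat > 0

    def test_null_network_ratios_near_one(self, null_truth):
        """Uniform random graph with random seeds: no signal to recover."""
        res = holdout_cv(
            null_truth.network,
            null_truth.seed_genes.as_set(),
            k=5,
            n_reps=200,
            rng_seed=3,
        )
        assert 0.8 < res.mean_ratio_level1 < 1.2
        assert 0.8 < res.mean_ratio_level2 < 1.2

    def test_bit_reproducible_under_fixed_seed(self, planted_truth):
        kwargs = dict(k=5, n_reps=20, rng_seed=99)
        a = holdout_cv(planted_truth.network, planted_truth.seed_genes.as_set(), **kwargs)
        b = holdout_cv(planted_truth.network, planted_truth.seed_genes.as_set(), **kwargs)
        assert a.ratios_level1 == b.ratios_level1
        assert a.ratios_level2 == b.ratios_level2
        assert a.heldout_sets == b.heldout_sets

    def test_same_deletion_sets_drive_both_levels(self, planted_truth):
        res = holdout_cv(
            planted_truth.network, planted_truth.seed_genes.as_set(), k=5,
            n_reps=10, rng_seed=5,
        )
        assert len(res.heldout_sets) == res.n_replicates
        assert len(res.ratios_level1) == len(res.ratios_level2) == res.n_replicates

    def test_pool_too_small_errors(self, toy):
        net, seeds = toy
        with pytest.raises(ValueError, match="pool"):
            holdout_cv(net, seeds, k=5, n_reps=5, rng_seed=0)

    def test_zero_candidate_mean_exhausts_redraws(self):
        # seed triangle is fully eligible, but the only candidates (X, Y)
        # have no path to any seed, so every replicate's denominator is zero
        net = build_network(
            [("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y")]
        )
        with pytest.raises(RuntimeError, match="zero"):
            holdout_cv(net, {"A", "B", "C"}, k=1, n_reps=2, rng_seed=0)

    def test_remaining_seed_comparison_group(self, planted_truth):
        res = holdout_cv(
            planted_truth.network, planted_truth.seed_genes.as_set(), k=5,
            n_reps=10, rng_seed=5, comparison_group="remaining",
        )
        assert res.mean_ratio_level2 > 1

    def test_parameter_recovery_heldout_seeds_rank_in_top_decile(self, planted_truth):
        """Held-out planted seeds are recovered near the top of the ranking."""
        res = holdout_cv(
            planted_truth.network, planted_truth.seed_genes.as_set(), k=5,
            n_reps=100, rng_seed=1,
        )
        fracs = np.asarray(res.heldout_median_rank_frac)
        assert (fracs <= 0.1).mean() >= 0.9

    def test_cv_table_has_one_row_per_replicate(self, planted_truth, tmp_path):
        res = holdout_cv(
            planted_truth.network, planted_truth.seed_genes.as_set(), k=5,
            n_reps=10, rng_seed=2,
        )
        p = tmp_path / "cv.tsv"
        write_cv_table(res, p)
        lines = p.read_text().splitlines()
        assert len([l for l in lines if not l.startswith("#")]) == 11  # header + 10


class TestPairedTest:
    def test_identical_series_degenerates_to_no_effect(self):
        t, p = _paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_positive_shift_is_certain(self):
        t, p = _paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert t == float("inf") and p == 0.0

    def test_matches_scipy_on_generic_input(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(1.2, 0.3, 50), rng.normal(1.0, 0.3, 50)
        t, p = _paired_test(a, b)
        t2, p2 = stats.ttest_rel(a, b)
        assert t == pytest.approx(float(t2)) and p == pytest.approx(float(p2))


class TestEligiblePool:
    def test_toy_pool_is_empty(self, toy):
        net, seeds = toy
        assert eligible_seed_pool(net, seeds) == []

    def test_triangle_seeds_all_eligible(self):
        net = build_network([("A", "B"), ("B", "C"), ("C", "A")])
        assert eligible_seed_pool(net, {"A", "B", "C"}) == ["A", "B", "C"]


def make_records(genes):
    return [
        CandidateRecord(g, 0, 0, False, False, False, False, False, i + 1)
        for i, g in enumerate(genes)
    ]


class TestCoincidenceProfile:
    def test_six_of_top_14_in_reference(self):
        genes = [f"G{i:02d}" for i in range(20)]
        records = make_records(genes)
        reference = GeneList("ref", genes[:6])
        profile = coincidence_profile(records, reference, bin_edges=[14])
        top = profile.bins[0]
        assert (top.n_candidates, top.n_overlapping) == (14, 6)
        assert top.coincidence_ratio == pytest.approx(6 / 14)  # 42.9%

    def test_disjoint_reference_gives_zero_ratios(self):
        records = make_records([f"G{i}" for i in range(30)])
        profile = coincidence_profile(records, GeneList("ref", ["ZZZ"]))
        assert all(b.coincidence_ratio in (0.0, None) for b in profile.bins)

    def test_reference_covering_all_gives_unit_ratios(self):
        genes = [f"G{i}" for i in range(30)]
        profile = coincidence_profile(make_records(genes), GeneList("ref", genes))
        for b in profile.bins:
            assert b.coincidence_ratio in (1.0, None)

    def test_empty_bin_reports_undefined(self):
        profile = coincidence_profile(
            make_records(["G1", "G2"]), GeneList("ref", ["G1"]), bin_edges=[2, 10]
        )
        assert profile.bins[1].n_candidates == 0
        assert profile.bins[1].coincidence_ratio is None

    def test_non_increasing_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            coincidence_profile(make_records(["G1"]), GeneList("r", ["G1"]), bin_edges=[10, 5])


class TestSetOverlap:
    def test_simple_overlap(self):
        n, ratio = set_overlap(GeneList("a", ["X", "Y", "Z"]), GeneList("b", ["Y"]))
        assert (n, ratio) == (1, pytest.approx(1 / 3))

    def test_subset_gives_ratio_one(self):
        n, ratio = set_overlap(GeneList("a", ["X", "Y"]), GeneList("b", ["X", "Y", "Z"]))
        assert ratio == 1.0

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError):
            set_overlap(GeneList("a", []), GeneList("b", ["X"]))

    def test_matches_independent_recount(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = [f"G{i}" for i in rng.integers(0, 50, size=rng.integers(1, 30))]
            b = [f"G{i}" for i in rng.integers(0, 50, size=rng.integers(0, 30))]
            if not a:
                continue
            gl_a, gl_b = GeneList("a", a), GeneList("b", b)
            n, ratio = set_overlap(gl_a, gl_b)
            brute = len({x for x in gl_a.genes if x in gl_b.genes})
            assert n == brute and ratio == pytest.approx(brute / len(gl_a))
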