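import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from pansv.bubbles import SVRecord, sv_type
from pansv.consensus import (
    MatchConfig, match_sv_sets, records_match, score_agreement,
    shared_fractions,
)
from pansv.synthetic import SimConfig, emit_replicates, simulate_pangenome


def random_sv_set(rng, n, chrom="chr1", spacing=5000):
    recs = []
    pos = 100
    for _ in range(n):
        pos += int(rng.integers(spacing // 2, spacing))
        kind = rng.random()
        if kind < 0.5:
            ref, alt = int(rng.integers(50, 600)), 0
        else:
            ref, alt = 1, int(rng.integers(50, 600))
        recs.append(SVRecord(chrom, pos, pos + ref, ref, alt,
                             sv_type(ref, alt)))
    return recs


class TestMatching:
    def test_identical_lists_match_perfectly(self):
        rng = np.random.default_rng(1)
        svs = random_sv_set(rng, 30)
        pairs = match_sv_sets(svs, svs)
        assert pairs == [(i, i) for i in range(30)]

    def test_shift_beyond_tolerance_unmatched(self):
        cfg = MatchConfig(breakpoint_tolerance=100)
        a = SVRecord("chr1", 1000, 1300, 300, 0, "DEL")
        b = SVRecord("chr1", 1101, 1401, 300, 0, "DEL")
        assert not records_match(a, b, cfg)
        b_edge = SVRecord("chr1", 1100, 1400, 300, 0, "DEL")
        assert records_match(a, b_edge, cfg)

    def test_type_and_length_ratio_enforced(self):
        cfg = MatchConfig()
        a = SVRecord("chr1", 1000, 1300, 300, 0, "DEL")
        assert not records_match(a, SVRecord("chr1", 1000, 1001, 1, 300, "INS"), cfg)
        short = SVRecord("chr1", 1000, 1150, 150, 0, "DEL")
        assert not records_match(a, short, cfg)

    def test_unsorted_input_rejected(self):
        recs = [SVRecord("chr1", 500, 600, 100, 0, "DEL"),
                SVRecord("chr1", 100, 200, 100, 0, "DEL")]
        with pytest.raises(ValueError, match="sorted"):
            match_sv_sets(recs, [])

    def test_greedy_near_optimal_vs_bipartite_oracle(self):
        """Greedy matching cardinality equals maximum bipartite matching in
        >=99% of random trials."""
        rng = np.random.default_rng(101)
        cfg = MatchConfig()
        agree = 0
        trials = 500
        for _ in range(trials):
            truth = random_sv_set(rng, int(rng.integers(5, 31)), spacing=400)
            test = []
            for r in truth:
                if rng.random() < 0.8:
                    shift = int(rng.integers(-150, 151))
                    start = max(0, r.start + shift)
                    test.append(SVRecord(r.chrom, start, start + r.ref_len,
                                         r.ref_len, r.alt_len, r.svtype))
            test.sort(key=lambda r: (r.chrom, r.start))
            got = len(match_sv_sets(test, truth, cfg))
            rows, cols = [], []
            for i, t in enumerate(test):
                for j, u in enumerate(truth):
                    if records_match(t, u, cfg):
                        rows.append(i)
                        cols.append(j)
            if rows:
                m = csr_matrix((np.ones(len(rows)), (rows, cols)),
                               shape=(len(test), len(truth)))
                opt = int((maximum_bipartite_matching(m, "column") >= 0).sum())
            else:
                opt = 0
            assert got <= opt
            agree += got == opt
        assert agree / trials >= 0.99


class TestScore:
    def test_identical_sets_score_100(self):
        svs = random_sv_set(np.random.default_rng(2), 20)
        rep = score_agreement(svs, svs)
        assert (rep.precision, rep.recall, rep.f1) == (100.0, 100.0, 100.0)

    def test_two_of_three_hand_computed(self):
        truth = [SVRecord("chr1", 1000, 1100, 100, 0, "DEL"),
                 SVRecord("chr1", 9000, 9200, 200, 0, "DEL"),
                 SVRecord("chr1", 20000, 20300, 300, 0, "DEL")]
        test = [truth[0], truth[1],
                SVRecord("chr1", 50000, 50400, 400, 0, "DEL")]
        rep = score_agreement(test, truth)
        assert rep.precision == pytest.approx(66.7, abs=0.05)
        assert rep.recall == pytest.approx(66.7, abs=0.05)
        assert rep.f1 == pytest.approx(66.7, abs=0.05)

    def test_empty_test_convention(self):
        truth = random_sv_set(np.random.default_rng(3), 5)
        rep = score_agreement([], truth)
        assert (rep.precision, rep.recall, rep.f1) == (0.0, 0.0, 0.0)

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError, match="truth"):
            score_agreement(random_sv_set(np.random.default_rng(4), 3), [])

    def test_adding_matched_record_never_decreases_recall(self):
        rng = np.random.default_rng(5)
        truth = random_sv_set(rng, 20)
        test = truth[:10]
        r1 = score_agreement(test, truth).recall
        r2 = score_agreement(truth[:11], truth).recall
        assert r2 >= r1

    def test_f1_symmetry_iff_equal_sizes(self):
        rng = np.random.default_rng(6)
        truth = random_sv_set(rng, 15)
        test = truth[:15]  # same size
        a = score_agreement(test, truth)
        b = score_agreement(truth, test)
        assert a.f1 == pytest.approx(b.f1)


class TestSharedFractions:
    def test_identical_sets_all_common(self):
        svs = random_sv_set(np.random.default_rng(7), 25)
        sf = shared_fractions({"a": svs, "b": svs, "c": svs})
        assert sf.common_to_all == 1.0
        assert sf.n_sites == 25

    def test_disjoint_sets_all_unique(self):
        rng = np.random.default_rng(8)
        a = random_sv_set(rng, 10, chrom="chr1")
        b = random_sv_set(rng, 10, chrom="chr2")
        sf = shared_fractions({"a": a, "b": b})
        assert sf.common_to_all == 0.0
        assert sf.unique_to("a") == pytest.approx(0.5)
        assert sf.n_sites == 20

    def test_group_lifting(self):
        svs = random_sv_set(np.random.default_rng(9), 10)
        sf = shared_fractions({"h1": svs, "h2": svs, "s1": svs[:5]},
                              groups={"h1": "hifi", "h2": "hifi", "s1": "ont"})
        assert sf.group_counts[frozenset({"hifi", "ont"})] == 5
        assert sf.group_counts[frozenset({"hifi"})] == 5


class TestReplicateAgreement:
    def test_recall_tracks_one_minus_noise(self):
        """Replicate-vs-truth recall matches 1 - noise within 3 binomial
        standard errors, and mean F1 decreases with noise."""
        cfg = SimConfig(n_chroms=1, chrom_length=2_000_000, sv_rate=3e-6,
                        n_genes=5, cnv_length=50_000, seed=42)
        truth = simulate_pangenome(cfg)
        n = len(truth.sv_catalogue)
        mean_f1 = []
        for noise in (0.0, 0.05, 0.1, 0.2):
            reps = emit_replicates(truth, 20, noise, seed=99)
            recalls, f1s = [], []
            for rep in reps:
                r = score_agreement(rep.sv_catalogue, truth.sv_catalogue)
                recalls.append(r.recall / 100)
                f1s.append(r.f1)
            mr = np.mean(recalls)
            se = np.sqrt(noise * (1 - noise) / n / 20) if noise else 0.0
            assert abs(mr - (1 - noise)) <= max(3 * se, 1e-12)
            mean_f1.append(np.mean(f1s))
        assert all(a >= b for a, b in zip(mean_f1, mean_f1[1:]))

    def test_zero_noise_replicates_identical(self):
        cfg = SimConfig(n_chroms=1, chrom_length=500_000, sv_rate=3e-6,
                        n_genes=5, cnv_length=50_000, seed=1)
        truth = simulate_pangenome(cfg)
        reps = emit_replicates(truth, 3, 0.0, seed=5)
        for rep in reps:
            assert rep.sv_catalogue == truth.sv_catalogue
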