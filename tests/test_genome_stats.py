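import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orphanfit.genome_stats import (
    GenePairClass,
    binom_tail,
    class_enrichment,
    cofitness_matrix,
    mhg,
    mmhg_pair,
    pssm_enrichment,
    pssm_scores,
    region_effect_test,
    relative_ratio_curve,
    stratify_pairs,
)
from orphanfit.profiles import ProfileMatrix


class TestBinomTail:
    def test_boundary_values(self):
        assert binom_tail(48, 0.25, 0) == 1.0
        assert binom_tail(10, 0.3, 10) == pytest.approx(0.3**10)

    def test_monotone_decreasing_in_k(self):
        vals = [binom_tail(20, 0.4, k) for k in range(21)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            binom_tail(10, 0.0, 5)
        with pytest.raises(ValueError):
            binom_tail(10, 0.5, 11)

    def test_matches_direct_summation(self):
        # independent oracle: sum the pmf terms with exact binomial coefficients
        n, p, k = 30, 0.2, 11
        expected = sum(
            math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
        )
        assert binom_tail(n, p, k) == pytest.approx(expected, rel=1e-12)


class TestRegionEffectTest:
    def _matrices(self, per_kind_values, conds):
        out = {}
        for kind, rows in per_kind_values.items():
            df = pd.DataFrame(
                rows, index=[f"{kind}{i}" for i in range(len(rows))], columns=conds
            )
            out[kind] = ProfileMatrix(df)
        return out

    def test_focal_always_lowest(self):
        conds = [f"c{i}" for i in range(10)]
        mats = self._matrices(
            {
                "three_prime_utr": [[-5.0] * 10],
                "cds": [[0.0] * 10],
                "promoter": [[1.0] * 10],
                "five_prime_utr": [[2.0] * 10],
            },
            conds,
        )
        wins, used, p = region_effect_test(mats, "three_prime_utr")
        assert (wins, used) == (10, 10)
        assert p == pytest.approx(0.25**10)

    def test_null_probability_is_one_over_n_kinds(self):
        conds = ["c0", "c1"]
        mats = self._matrices(
            {f"k{i}": [[float(i), float(i)]] for i in range(7)} | {
                "promoter": [[-9.0, -9.0]]
            },
            conds,
        )
        # wait: kinds must come from the fixed vocabulary only for regions;
        # matrices are keyed freely here (8 kinds -> p = 1/8)
        wins, used, p = region_effect_test(mats, "promoter")
        assert p == pytest.approx(binom_tail(2, 1 / 8, 2))

    def test_wins_match_brute_force_argmin(self):
        rng = np.random.default_rng(12)
        conds = [f"c{i}" for i in range(15)]
        kinds = ["promoter", "cds", "five_prime_utr", "three_prime_utr"]
        mats = self._matrices(
            {k: rng.standard_normal((6, 15)).tolist() for k in kinds}, conds
        )
        wins, used, _ = region_effect_test(mats, "cds", statistic="median")
        expected = 0
        for c in conds:
            meds = {k: np.median(mats[k].values[c]) for k in kinds}
            if all(meds["cds"] < v for k, v in meds.items() if k != "cds"):
                expected += 1
        assert wins == expected and used == 15

    def test_condition_with_missing_kind_skipped(self):
        conds = ["c0", "c1"]
        mats = self._matrices(
            {"cds": [[-1.0, np.nan]], "promoter": [[0.0, 0.0]]}, conds
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            wins, used, _ = region_effect_test(mats, "cds")
        assert used == 1 and wins == 1


class TestCofitness:
    def test_identical_and_reversed_vectors(self):
        df = pd.DataFrame(
            [[1.0, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
            index=["a", "b", "c"], columns=list("wxyz"),
        )
        corr = cofitness_matrix(ProfileMatrix(df))
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            rng.standard_normal((8, 6)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"c{j}" for j in range(6)],
        )
        corr = cofitness_matrix(ProfileMatrix(df))
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            rng.standard_normal((8, 6)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"c{j}" for j in range(6)],
        )
        corr = cofitness_matrix(ProfileMatrix(df))
        for i in range(8):
            for j in range(i + 1, 8):
                ra = stats.rankdata(df.iloc[i])
                rb = stats.rankdata(df.iloc[j])
                expected = np.corrcoef(ra, rb)[0, 1]
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_is_missing(self):
        df = pd.DataFrame(
            [[1.0, 2, np.nan, np.nan], [np.nan, np.nan, 3, 4], [1, 2, 3, 4]],
            index=["a", "b", "c"], columns=list("wxyz"),
        )
        corr = cofitness_matrix(ProfileMatrix(df))
        assert np.isnan(corr.loc["a", "b"])


def _exact_ranksum_greater(x, y):
    """Exhaustive permutation distribution of the rank-sum statistic."""
    pooled = list(x) + list(y)
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    count = total = 0
    for subset in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if ranks[list(subset)].sum() >= obs - 1e-12:
            count += 1
    return count / total


class TestClassEnrichment:
    def test_null_behavior_is_uninformative(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(60)
        y = rng.standard_normal(400)
        p = class_enrichment(x, y)
        assert 0.05 < p < 0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_small_samples_match_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(4).tolist()
        y = rng.standard_normal(5).tolist()
        assert class_enrichment(x, y) == pytest.approx(
            _exact_ranksum_greater(x, y), abs=1e-12
        )

    def test_top_decile_class_is_strongly_enriched(self):
        rng = np.random.default_rng(16)
        bg = np.sort(rng.standard_normal(100))
        cls = bg[-6:]
        assert class_enrichment(cls, bg[:-6]) < 1e-3

    def test_shifted_class_detected_in_most_runs(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cls = rng.normal(0.6, 1.0, 100)
            bg = rng.normal(0.0, 1.0, 400)
            if class_enrichment(cls, bg) < 0.01:
                detected += 1
        assert detected >= 95

    def test_tiny_class_warns(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            class_enrichment([5.0, 6.0], [0.0, 1.0, 2.0])

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            class_enrichment([], [1.0])


class TestRelativeRatioCurve:
    def test_class_equal_background_gives_zeros(self):
        vals = [0.1, 0.5, -0.2, 0.9]
        curve = relative_ratio_curve(vals, vals)
        defined = curve[curve["defined"]]
        assert np.allclose(defined["log10_ratio"], 0.0)

    def test_threshold_below_all_values_gives_zero(self):
        curve = relative_ratio_curve([0.5, 0.9], [0.3, 0.8], xs=[-0.5])
        assert curve["log10_ratio"].iloc[0] == pytest.approx(0.0)

    def test_counting_oracle_at_half(self):
        rng = np.random.default_rng(17)
        cls = rng.uniform(-0.5, 1, 6)
        bg = rng.uniform(-0.5, 1, 20)
        curve = relative_ratio_curve(cls, bg, xs=[0.5])
        rho_c = np.mean(cls >= 0.5)
        rho_t = np.mean(bg >= 0.5)
        row = curve.iloc[0]
        if rho_c > 0 and rho_t > 0:
            assert row["log10_ratio"] == pytest.approx(np.log10(rho_c / rho_t))
        else:
            assert not row["defined"]

    def test_zero_class_fraction_flagged_missing(self):
        curve = relative_ratio_curve([0.0], [0.9, 0.95], xs=[0.5])
        assert not curve["defined"].iloc[0]
        assert np.isnan(curve["log10_ratio"].iloc[0])


class TestStratifyPairs:
    def _genes(self):
        return pd.DataFrame(
            {
                "start": [1000, 4500, 90_000, 1_000_000],
                "gc": [0.30, 0.52, 0.55, 0.70],
                "scaffold": ["chr", "chr", "chr", "chr"],
            },
            index=["gA", "gB", "gC", "gD"],
        )

    def test_close_pair_in_smallest_bin(self):
        classes = {c.name: c.pairs for c in stratify_pairs(self._genes(), gc_filter=False)}
        assert frozenset({"gA", "gB"}) in classes["distance_bin:5000"]
        assert frozenset({"gA", "gC"}) not in classes["distance_bin:5000"]
        assert frozenset({"gA", "gC"}) in classes["distance_bin:100000"]

    def test_same_gc_decile_pair_filtered(self):
        genes = self._genes()
        # gB and gC sit in adjacent quantile space; force same decile via few bins
        classes = {
            c.name: c.pairs
            for c in stratify_pairs(genes, gc_deciles=2, gc_filter=True)
        }
        # with 2 GC bins: gA|gB low, gC|gD high -> only cross-bin pairs remain
        for pairs in classes.values():
            for p in pairs:
                pass
        assert frozenset({"gA", "gB"}) not in classes["distance_bin:5000"]

    def test_membership_matches_brute_force_distance(self):
        rng = np.random.default_rng(18)
        genes = pd.DataFrame(
            {
                "start": rng.integers(0, 200_000, 12),
                "gc": rng.uniform(0.3, 0.7, 12),
            },
            index=[f"g{i}" for i in range(12)],
        )
        classes = {c.name: c.pairs for c in stratify_pairs(genes, gc_filter=False)}
        starts = genes["start"]
        for size in (5_000, 20_000, 100_000):
            expected = {
                frozenset({a, b})
                for a, b in itertools.combinations(genes.index, 2)
                if abs(starts[a] - starts[b]) <= size
            }
            assert classes[f"distance_bin:{size}"] == expected

    def test_self_pairs_rejected_by_class_type(self):
        with pytest.raises(ValueError):
            GenePairClass(name="bad", pairs={frozenset({"g1"})})


def _mhg_oracle(labels):
    """Exhaustive prefix enumeration with exact hypergeometric tails."""
    n_total = len(labels)
    b_total = sum(labels)
    if b_total == 0:
        return 1.0, 0, 0
    best = (np.inf, 0, 0)
    b = 0
    for n in range(1, n_total + 1):
        b += labels[n - 1]
        tail = sum(
            math.comb(b_total, i) * math.comb(n_total - b_total, n - i)
            for i in range(b, min(n, b_total) + 1)
        ) / math.comb(n_total, n)
        if tail < best[0] - 1e-12:
            best = (tail, n, b)
    return best


class TestMhg:
    def test_single_leading_one(self):
        score, n, b = mhg([1, 0, 0, 0])
        assert score == pytest.approx(0.25)
        assert (n, b) == (1, 1)

    def test_all_zeros_scores_one(self):
        assert mhg([0, 0, 0]) == (1.0, 0, 0)

    def test_matches_exhaustive_oracle_on_all_short_lists(self):
        for n in range(1, 11):
            for bits in itertools.product([0, 1], repeat=n):
                score, n_at, b_at = mhg(list(bits))
                o_score, o_n, o_b = _mhg_oracle(list(bits))
                assert score == pytest.approx(o_score, rel=1e-9)
                if sum(bits):
                    assert (n_at, b_at) == (o_n, o_b)

    def test_score_in_unit_interval(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            labels = (rng.random(20) < 0.3).astype(int).tolist()
            score, _, _ = mhg(labels)
            assert 0 < score <= 1

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            mhg([0, 2, 1])
        with pytest.raises(ValueError):
            mhg([])


def _mmhg_oracle(rank_a, rank_b):
    n = len(rank_a)
    pos = {e: i for i, e in enumerate(rank_a)}
    best = (1.0, 0, 0, 0)
    for b_thresh in range(1, n):
        labels = [1 if pos[e] < b_thresh else 0 for e in rank_b]
        s, n_at, b_at = _mhg_oracle(labels)
        if s < best[0]:
            best = (s, n_at, b_at, b_thresh)
    return best


class TestMmhg:
    def test_identical_vs_reversed_rankings(self):
        elements = [f"e{i}" for i in range(12)]
        same = mmhg_pair(elements, list(elements), rng=0)
        rev = mmhg_pair(elements, elements[::-1], rng=0)
        assert same["score"] < 0.01
        assert rev["score"] > same["score"]
        assert same["empirical_p"] <= 0.05

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(20)
        elements = [f"e{i}" for i in range(8)]
        for _ in range(10):
            a = list(elements)
            b = list(elements)
            rng.shuffle(a)
            rng.shuffle(b)
            got = mmhg_pair(a, b, n_shuffles=5, rng=1)
            o_score, o_n, o_b, o_B = _mmhg_oracle(a, b)
            assert got["score"] == pytest.approx(o_score, rel=1e-9)
            assert (got["n"], got["b"], got["B"]) == (o_n, o_b, o_B)

    def test_seeded_shuffles_reproducible(self):
        elements = [f"e{i}" for i in range(10)]
        a = mmhg_pair(elements, elements[::-1], rng=42)
        b = mmhg_pair(elements, elements[::-1], rng=42)
        assert a == b

    def test_mismatched_element_sets_rejected(self):
        with pytest.raises(ValueError):
            mmhg_pair(["a", "b"], ["a", "c"])


class TestPssm:
    MOTIF = np.array(
        [  # strongly prefers ACGT
            [0.97, 0.01, 0.01, 0.01],
            [0.01, 0.97, 0.01, 0.01],
            [0.01, 0.01, 0.97, 0.01],
            [0.01, 0.01, 0.01, 0.97],
        ]
    ).T

    def test_planted_motif_at_top_of_ranking_scores_small(self):
        rng = np.random.default_rng(21)
        def random_seq(k=30):
            return "".join(rng.choice(list("ACGT"), size=k))
        # motif planted in the 4 top-ranked promoters only
        ranked = [(f"p{i}", ("ACGT" if i < 4 else "AAAA") + random_seq())
                  for i in range(16)]
        hits, score = pssm_enrichment(ranked, self.MOTIF, hit_threshold=7.0)
        assert {f"p{i}" for i in range(4)} <= hits
        assert score < 0.05

    def test_threshold_above_all_scores_gives_no_hits(self):
        ranked = [("p1", "ACGTACGT"), ("p2", "TTTTTTTT")]
        hits, score = pssm_enrichment(ranked, self.MOTIF, hit_threshold=1e6)
        assert hits == set() and score == 1.0

    def test_single_column_pssm_is_direct_lookup(self):
        pssm = np.array([[0.97], [0.01], [0.01], [0.01]])  # prefers A
        scores = pssm_scores({"a": "A", "t": "T"}, pssm)
        # reverse strand of T is A, so both reach the A log-odds
        assert scores["a"] == pytest.approx(np.log2(0.97 / 0.25), abs=1e-6)
        assert scores["t"] == pytest.approx(scores["a"])

    def test_short_sequence_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            scores = pssm_scores({"short": "AC", "ok": "ACGTACGT"}, self.MOTIF)
        assert "short" not in scores

    def test_reverse_strand_match_found(self):
        # reverse complement of ACGT is ACGT; use an asymmetric motif AAAC
        pssm = np.zeros((4, 4)) + 0.01
        for i, base in enumerate("AAAC"):
            pssm["ACGT".index(base), i] = 0.97
        fwd = pssm_scores({"s": "TTAAACTT"}, pssm)["s"]
        rev = pssm_scores({"s": "AAGTTTAA"}, pssm)["s"]  # contains GTTT = rc(AAAC)
        assert fwd == pytest.approx(rev)
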