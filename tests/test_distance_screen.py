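import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coaldelim.distance_screen import (
    UndefinedDistanceError,
    between_population_summary,
    p_distance,
    pairwise_matrix,
    screen_candidates,
)
from coaldelim.io_formats import AlignedLocus, PopulationMap

from .conftest import random_locus

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected_d,expected_n",
        [
            ("ACGT", "ACGT", 0.0, 4),
            ("ACGT", "ACGA", 0.25, 4),
            ("AC-TN", "ACGTA", 0.0, 3),  # gap and N excluded pairwise
            ("RCGT", "ACGT", 0.0, 3),    # ambiguity code excluded
        ],
    )
    def test_known_values(self, a, b, expected_d, expected_n):
        d, n = p_distance(a, b)
        assert d == pytest.approx(expected_d)
        assert n == expected_n

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="length"):
            p_distance("ACGT", "ACGTA")

    def test_no_comparable_sites(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("NN--", "ACGT")

    @given(a=dna, b=dna)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_identity(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        d_ab = p_distance(a, b)
        assert d_ab == p_distance(b, a)
        assert p_distance(a, a) == (0.0, n)


class TestPairwiseMatrix:
    def test_identical_sequences(self):
        locus = AlignedLocus("x", ("s1", "s2"), ("ACGT", "ACGT"))
        m = pairwise_matrix(locus)
        assert np.all(m.values == 0)
        assert m.comparable_sites[0, 1] == 4

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            locus = random_locus(rng, n=6, length=60)
            m = pairwise_matrix(locus)
            for i, j in itertools.combinations(range(6), 2):
                d, c = p_distance(locus.sequences[i], locus.sequences[j])
                assert m.values[i, j] == pytest.approx(d)
                assert m.values[j, i] == pytest.approx(d)
                assert m.comparable_sites[i, j] == c
            assert np.all(np.diag(m.values) == 0)

    def test_single_sample_rejected(self):
        locus = AlignedLocus("x", ("s1",), ("ACGT",))
        with pytest.raises(ValueError):
            pairwise_matrix(locus)


class TestBetweenPopulationSummary:
    def test_single_cross_pair(self):
        locus = AlignedLocus(
            "x", ("s1", "s2"), ("A" * 100, "A" * 95 + "C" * 5)
        )
        pm = PopulationMap({"s1": "A", "s2": "B"})
        m = pairwise_matrix(locus)
        assert between_population_summary(m, pm, "A", "B") == pytest.approx(
            (5.0, 5.0, 5.0)
        )

    def test_two_cross_pairs_arithmetic(self):
        # distances 0.012 and 0.023 across the split -> 1.2/2.3/1.75 percent
        base = "A" * 1000
        s2 = "C" * 12 + "A" * 988
        locus = AlignedLocus("x", ("p", "q", "r"), (base, s2, base[:977] + "G" * 23))
        pm = PopulationMap({"p": "A", "q": "B", "r": "B"})
        m = pairwise_matrix(locus)
        d_min, d_max, d_mean = between_population_summary(m, pm, "A", "B")
        assert d_min == pytest.approx(1.2)
        assert d_max == pytest.approx(2.3)
        assert d_mean == pytest.approx(1.75)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(7)
        locus = random_locus(rng, n=6, length=80)
        pm = PopulationMap(
            {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        )
        m = pairwise_matrix(locus)
        cross = [
            p_distance(locus.sequences[i], locus.sequences[j])[0] * 100
            for i in range(3)
            for j in range(3, 6)
        ]
        got = between_population_summary(m, pm, "A", "B")
        assert got == pytest.approx((min(cross), max(cross), float(np.mean(cross))))

    def test_unknown_population(self, tiny_locus, tiny_popmap):
        m = pairwise_matrix(tiny_locus)
        with pytest.raises(KeyError):
            between_population_summary(m, tiny_popmap, "A", "Z")


def _locus_with_cross_distance(d_pct: float, length: int = 1000):
    """Two 1-sample populations at exactly d_pct percent divergence."""
    k = round(d_pct / 100 * length)
    a = "A" * length
    b = "C" * k + "A" * (length - k)
    return AlignedLocus("x", ("s1", "s2"), (a, b)), PopulationMap(
        {"s1": "P1", "s2": "P2"}
    )


class TestScreenCandidates:
    @pytest.mark.parametrize(
        "d_pct,conspecific,expected",
        [
            (2.2, False, "lump_candidate"),   # below 3% band, different species
            (6.0, True, "split_candidate"),   # above 5% band, same species
            (4.0, True, "grey_zone"),
            (4.0, False, "grey_zone"),
            (6.0, False, "none"),
            (2.2, True, "none"),
            (3.0, False, "grey_zone"),        # boundary inclusive for grey
            (5.0, True, "grey_zone"),
        ],
    )
    def test_categories(self, d_pct, conspecific, expected):
        locus, pm = _locus_with_cross_distance(d_pct)
        m = pairwise_matrix(locus)
        (cand,) = screen_candidates(
            m, pm, {("P1", "P2"): conspecific}
        )
        assert cand.category == expected
        assert cand.d_min == pytest.approx(d_pct)

    def test_range_spanning_band_is_grey(self):
        # conspecific populations spanning 0.7-3.6 percent -> grey zone
        length = 1000
        seqs = ("A" * length, "C" * 7 + "A" * 993, "C" * 36 + "A" * 964)
        locus = AlignedLocus("x", ("s1", "s2", "s3"), seqs)
        pm = PopulationMap({"s1": "P1", "s2": "P2", "s3": "P2"})
        m = pairwise_matrix(locus)
        (cand,) = screen_candidates(m, pm, {("P1", "P2"): True})
        assert (cand.d_min, cand.d_max) == pytest.approx((0.7, 3.6))
        assert cand.category == "grey_zone"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        locus = random_locus(rng, n=8, length=120)
        pm = PopulationMap(
            {f"s{i}": f"P{i // 2}" for i in range(8)}
        )
        tax = {
            (f"P{i}", f"P{j}"): (i + j) % 2 == 0
            for i in range(4)
            for j in range(i + 1, 4)
        }
        m = pairwise_matrix(locus)

        def counts(lower, upper):
            cands = screen_candidates(m, pm, tax, lower=lower, upper=upper)
            return (
                sum(c.category == "lump_candidate" for c in cands),
                sum(c.category == "split_candidate" for c in cands),
            )

        lumps5, splits5 = counts(3.0, 5.0)
        lumps_hi, splits_hi = counts(3.0, 10.0)
        assert splits_hi <= splits5  # raising upper never adds splits
        lumps_lo, _ = counts(1.0, 5.0)
        assert lumps_lo <= lumps5  # lowering lower never adds lumps

    def test_invalid_thresholds(self, tiny_locus, tiny_popmap):
        m = pairwise_matrix(tiny_locus)
        with pytest.raises(ValueError, match="lower < upper"):
            screen_candidates(m, tiny_popmap, {("A", "B"): True}, lower=5, upper=3)

    def test_missing_taxonomy_entry(self, tiny_locus, tiny_popmap):
        m = pairwise_matrix(tiny_locus)
        with pytest.raises(KeyError, match="taxonomy"):
            screen_candidates(m, tiny_popmap, {})
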