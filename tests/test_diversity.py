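"""Diversity indices, distance modes, and neutrality statistics."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplogeo.diversity import (
    DistanceMode,
    ewens_log_pmf,
    fus_fs,
    haplotype_diversity,
    mean_pairwise_differences,
    neutrality_pvalue,
    nucleotide_diversity,
    pairwise_distances,
    segregating_sites,
    sequence_distance,
    tajima_constants,
    tajimas_d,
)
from haplogeo.seqdata import collapse_haplotypes
from haplogeo.seqdata import AlignedSequence, Locus

PAIRS = st.integers(0, 4).map("ACGT-".__getitem__)


def seq_pair(draw_len=12):
    return st.tuples(
        st.text(alphabet="ACGT-N", min_size=draw_len, max_size=draw_len),
        st.text(alphabet="ACGT-N", min_size=draw_len, max_size=draw_len),
    )


class TestSequenceDistance:
    @pytest.mark.parametrize(
        "mode,expected",
        [
            (DistanceMode.PER_COLUMN_GAP, 2),
            (DistanceMode.INDEL_AS_EVENT, 1),
            (DistanceMode.SUBSTITUTIONS_ONLY, 0),
        ],
    )
    def test_indel_pair_modes(self, study_table, mode, expected):
        h1 = study_table.by_id("H1").sequence
        h3 = study_table.by_id("H3").sequence
        assert sequence_distance(h1, h3, mode) == expected

    def test_event_mode_range_over_study_haplotypes(self, study_table):
        dm = pairwise_distances(study_table, DistanceMode.INDEL_AS_EVENT)
        off = dm.offdiagonal()
        assert off.max() == 4 and off.min() == 1
        assert dm.value("H4", "H6") == 4 and dm.value("H5", "H6") == 4

    def test_identical_sequences_zero_in_all_modes(self):
        for mode in DistanceMode:
            assert sequence_distance("AC-GT", "AC-GT", mode) == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sequence_distance("AC", "AC", "HAMMING")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seq_pair())
    def test_mode_ordering_and_symmetry(self, pair):
        a, b = pair
        d = {m: sequence_distance(a, b, m) for m in DistanceMode}
        assert (
            d[DistanceMode.SUBSTITUTIONS_ONLY]
            <= d[DistanceMode.INDEL_AS_EVENT]
            <= d[DistanceMode.PER_COLUMN_GAP]
        )
        for m in DistanceMode:
            assert sequence_distance(b, a, m) == d[m]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.text(alphabet="ACGT-", min_size=8, max_size=8),
            min_size=3, max_size=6, unique=True,
        )
    )
    def test_matrix_triangle_inequality(self, rows):
        """Per-column and substitutions-only matrices are metric on fully
        called sequences (gap columns removed alignment-wide for the
        latter). Event-coded indel distances are not metric in general --
        a gap run spanning substitution-variable columns can shortcut
        them -- so that mode is checked on the study data instead."""
        table = _table_from_rows(rows)
        for m in (DistanceMode.PER_COLUMN_GAP, DistanceMode.SUBSTITUTIONS_ONLY):
            d = pairwise_distances(table, m).d
            h = len(rows)
            for i in range(h):
                for j in range(h):
                    for l in range(h):
                        assert d[i, j] <= d[i, l] + d[l, j] + 1e-12

    def test_event_mode_triangle_holds_on_study_haplotypes(self, study_table):
        d = pairwise_distances(study_table, DistanceMode.INDEL_AS_EVENT).d
        h = d.shape[0]
        for i in range(h):
            for j in range(h):
                for l in range(h):
                    assert d[i, j] <= d[i, l] + d[l, j]


class TestHaplotypeDiversity:
    def test_study_value_and_sd(self):
        hd, sd = haplotype_diversity((8, 52, 33, 3, 4, 1, 1), 102)
        assert round(hd, 4) == 0.6329
        assert round(sd, 4) == 0.0334

    def test_monomorphic_sample(self):
        assert haplotype_diversity((5,), 5)[0] == 0.0

    def test_two_distinct_sequences(self):
        assert haplotype_diversity((1, 1), 2)[0] == pytest.approx(1.0)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            haplotype_diversity((1,), 1)

    def test_invariant_to_relabelling_and_maximal_when_even(self):
        base = (10, 5, 3, 2)
        hd, _ = haplotype_diversity(base, 20)
        hd_perm, _ = haplotype_diversity((2, 10, 3, 5), 20)
        assert hd == pytest.approx(hd_perm)
        hd_even, _ = haplotype_diversity((5, 5, 5, 5), 20)
        assert hd_even > hd


def _table_from_rows(rows, offset=1):
    aln = [
        AlignedSequence(f"s{i}", Locus.CONCAT, r, offset)
        for i, r in enumerate(rows, 1)
    ]
    return collapse_haplotypes(aln)


def _naive_k(rows, mode):
    """Brute-force mean pairwise difference over all individual pairs."""
    total = sum(
        sequence_distance(a, b, mode) for a, b in combinations(rows, 2)
    )
    n = len(rows)
    return total / (n * (n - 1) / 2)


class TestMeanPairwiseDifferences:
    def test_study_fixture_per_column_gap(self, study_table):
        k, _ = mean_pairwise_differences(study_table, DistanceMode.PER_COLUMN_GAP)
        assert k == pytest.approx(8035 / 5151)
        # prints as the study's headline values
        assert round(k / 801, 5) == 0.00195

    def test_study_fixture_substitutions_only(self, study_table):
        k, _ = mean_pairwise_differences(
            study_table, DistanceMode.SUBSTITUTIONS_ONLY
        )
        assert k == pytest.approx(3411 / 5151)

    def test_matches_brute_force_all_pairs(self, fixture):
        """k from haplotype counts equals the naive all-pairs computation."""
        rng = np.random.default_rng(5)
        rows_all = [s.bases for s in fixture.alignment]
        for n in (10, 21, 30):
            rows = [rows_all[i] for i in rng.choice(102, size=n, replace=False)]
            table = _table_from_rows(rows)
            for mode in DistanceMode:
                k, _ = mean_pairwise_differences(table, mode)
                assert k == pytest.approx(_naive_k(rows, mode), abs=1e-12)

    def test_identical_sequences_give_zero(self):
        table = _table_from_rows(["ACGT", "ACGT"])
        for mode in DistanceMode:
            assert mean_pairwise_differences(table, mode)[0] == 0.0


class TestNucleotideDiversity:
    def test_division_and_edges(self):
        assert nucleotide_diversity(1.55, 800) == pytest.approx(0.0019375)
        assert nucleotide_diversity(0.0, 10) == 0.0
        assert nucleotide_diversity(10.0, 10) == 1.0
        with pytest.raises(ValueError):
            nucleotide_diversity(1.0, 0)


def _constants_oracle(n):
    """Tajima's normalising constants via exact rational arithmetic."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2, a1


class TestTajimasD:
    @pytest.mark.parametrize("n", [4, 10, 102])
    def test_constants_match_exact_rational_oracle(self, n):
        c = tajima_constants(n)
        e1, e2, a1 = _constants_oracle(n)
        assert c.a1 == pytest.approx(float(a1), rel=1e-12)
        assert c.e1 == pytest.approx(float(e1), rel=1e-12)
        assert c.e2 == pytest.approx(float(e2), rel=1e-12)
        assert c.e1 > 0 and c.e2 > 0

    def test_study_value(self, study_table):
        k, _ = mean_pairwise_differences(
            study_table, DistanceMode.SUBSTITUTIONS_ONLY
        )
        S = segregating_sites(study_table, exclude_gaps=True)
        assert S == 5
        assert tajimas_d(102, S, k) == pytest.approx(-0.66145, abs=1e-4)

    def test_zero_when_estimators_agree(self):
        c = tajima_constants(20)
        assert tajimas_d(20, 3, 3 / c.a1) == pytest.approx(0.0, abs=1e-14)

    def test_small_sample_singleton_against_direct_formula(self):
        # one singleton among 4 sequences: k = 0.5 substitutions
        e1, e2, a1 = _constants_oracle(4)
        expected = (0.5 - 1 / float(a1)) / math.sqrt(float(e1))
        assert tajimas_d(4, 1, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajimas_d(10, 0, 0.0))


def _ewens_pmf_oracle(n, theta):
    """Ewens allele-count pmf via exact integer Stirling triangle."""
    tri = [[1]]
    for m in range(1, n + 1):
        prev = tri[-1]
        row = [0] * (m + 1)
        for k in range(1, m + 1):
            row[k] = (m - 1) * (prev[k] if k < m else 0) + prev[k - 1]
        tri.append(row)
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    return [tri[n][k] * theta**k / rising for k in range(1, n + 1)]


class TestFusFs:
    def test_symmetric_point_is_exactly_zero(self):
        fs, model = fus_fs(2, 2, 1.0)
        assert fs == 0.0
        assert model.S_prime == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [5, 50, 200])
    def test_ewens_distribution_normalised(self, n):
        total = np.exp(ewens_log_pmf(n, 1.7)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_exact_stirling_oracle(self):
        n, K, theta = 10, 4, 2.0
        pmf = _ewens_pmf_oracle(n, theta)
        s_prime = sum(pmf[K - 1 :])
        expected = math.log(s_prime / (1 - s_prime))
        fs, model = fus_fs(n, K, theta)
        assert fs == pytest.approx(expected, rel=1e-10)
        assert model.S_prime == pytest.approx(s_prime, rel=1e-10)

    def test_study_value(self, study_table):
        k, _ = mean_pairwise_differences(study_table, DistanceMode.PER_COLUMN_GAP)
        fs, _ = fus_fs(102, 7, k)
        assert round(fs, 5) == 0.34125

    def test_certain_allele_count_flags_infinity(self):
        fs, _ = fus_fs(5, 1, 1.0)
        assert math.isinf(fs)


class TestNeutralityPValue:
    def test_same_seed_reproduces_exactly(self):
        a = neutrality_pvalue("tajimas_d", -0.5, 20, "FIXED_S", 4,
                              n_reps=300, seed=9)
        b = neutrality_pvalue("tajimas_d", -0.5, 20, "FIXED_S", 4,
                              n_reps=300, seed=9)
        assert a == b

    def test_median_observation_sits_near_half(self):
        probe = neutrality_pvalue("tajimas_d", 0.0, 30, "FIXED_S", 5,
                                  n_reps=500, seed=3)
        r = neutrality_pvalue("tajimas_d", probe.null_median, 30, "FIXED_S", 5,
                              n_reps=500, seed=3)
        assert 0.4 <= r.p <= 0.6

    def test_study_tajima_p_in_reported_neighbourhood(self, study_table):
        """Simulation p for D = -0.66 at n=102, S=5 (study reports 0.291)."""
        k, _ = mean_pairwise_differences(
            study_table, DistanceMode.SUBSTITUTIONS_ONLY
        )
        D = tajimas_d(102, 5, k)
        r = neutrality_pvalue("tajimas_d", D, 102, "FIXED_S", 5,
                              n_reps=2000, seed=42)
        assert r.tail == "lower"
        assert 0.18 <= r.p <= 0.42
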