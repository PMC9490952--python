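"""RepeatMasker parsing, Kimura distances (with brute-force oracle), landscapes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from curupira.mapping import TagHit
from curupira.preprocess import SequenceTag
from curupira.simdata import mutate_te_copy
from curupira.telandscape import (
    DivergenceDomainError,
    TEAnnotation,
    alignment_divergence,
    classify_pirna_te,
    compare_landscapes,
    kimura2p,
    landscape,
    landscape_from_annotations,
    parse_repeatmasker_out,
)

RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching  repeat        position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat    class/family  begin end (left)  ID\n"
    "\n"
)


def brute_force_divergence(copy, consensus):
    """Independent per-site classifier: purine/pyrimidine membership decides."""
    purines = {"A", "G"}
    n = ts = tv = 0
    for c, k in zip(copy, consensus):
        if c not in "ACGT" or k not in "ACGT":
            continue
        n += 1
        if c == k:
            continue
        if (c in purines) == (k in purines):
            ts += 1
        else:
            tv += 1
    return ts / n, tv / n, n


class TestParseRepeatMaskerOut:
    def test_columns_and_coordinates(self, tmp_path):
        out = tmp_path / "r.out"
        out.write_text(
            RM_HEADER
            + "  463  1.3  0.6  1.7  contig_1  1001  1500  (8500)  +  hAT-N1  DNA/hAT-Ac  1  500  (0)  1\n"
            + "  239 25.1  2.0  0.0  contig_1  2001  2300  (7700)  C  L2-cons  LINE/L2  (0)  300  1  2\n"
        )
        a, b = parse_repeatmasker_out(out)
        assert (a.start, a.end, a.strand, a.major_class) == (1000, 1500, "+", "DNA")
        assert (b.strand, b.major_class, b.divergence_pct) == ("-", "LINE", 25.1)

    def test_unknown_class_maps_to_other(self, tmp_path):
        out = tmp_path / "r.out"
        out.write_text(
            RM_HEADER
            + "  10  5.0  0.0  0.0  c  1  100  (0)  +  rep  Simple_repeat  1  100  (0)  1\n"
        )
        (a,) = parse_repeatmasker_out(out)
        assert a.major_class == "Other"

    def test_empty_after_headers(self, tmp_path):
        out = tmp_path / "r.out"
        out.write_text(RM_HEADER)
        assert parse_repeatmasker_out(out) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        out = tmp_path / "r.out"
        out.write_text(RM_HEADER + "only three cols\n")
        with pytest.raises(ValueError, match=":4"):
            parse_repeatmasker_out(out)


class TestKimura2p:
    def test_zero_divergence(self):
        assert kimura2p(0.0, 0.0) == 0.0

    def test_worked_value(self):
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert kimura2p(0.10, 0.05) == pytest.approx(expected, abs=1e-12)
        assert kimura2p(0.10, 0.05) == pytest.approx(0.1702, abs=5e-5)

    def test_outside_domain_raises(self):
        with pytest.raises(DivergenceDomainError, match="domain"):
            kimura2p(0.40, 0.30)

    @given(
        st.floats(0.0, 0.2),
        st.floats(0.0, 0.2),
        st.floats(1e-4, 0.01),
    )
    def test_monotone_increasing_in_p_and_q(self, p, q, eps):
        assert kimura2p(p + eps, q) > kimura2p(p, q)
        assert kimura2p(p, q + eps) > kimura2p(p, q)

    @given(st.floats(0.001, 0.025), st.floats(0.001, 0.025))
    def test_small_divergence_limit(self, p, q):
        k = kimura2p(p, q)
        assert abs(k - (p + q)) / (p + q) < 0.1


class TestAlignmentDivergence:
    def test_identical_sequences(self):
        est = alignment_divergence("A" * 100, "A" * 100)
        assert (est.p, est.q, est.K, est.n_sites) == (0.0, 0.0, 0.0, 100)

    def test_hand_counted_example(self):
        est = alignment_divergence("GAAAAAAAAT", "AAAAAAAAAA")
        assert (est.p, est.q) == (0.1, 0.1)
        assert est.K == pytest.approx(0.2341, abs=5e-5)

    def test_gap_columns_stripped(self):
        est = alignment_divergence("AC-GT", "ACG-T")
        assert est.n_sites == 3 and est.K == 0.0

    def test_ambiguous_bases_excluded(self):
        est = alignment_divergence("ACGTN", "ACGTA")
        assert est.n_sites == 4

    def test_cpg_exclusion(self):
        # consensus CG dinucleotide masks both positions
        est = alignment_divergence("AAGT", "ACGT", exclude_cpg=True)
        assert est.n_sites == 2 and est.K == 0.0 and est.cpg_excluded

    def test_zero_usable_sites_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            alignment_divergence("NN", "NN")

    def test_matches_brute_force_on_random_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            a = "".join(bases[rng.integers(0, 4, 100)])
            b = "".join(bases[rng.integers(0, 4, 100)])
            ts, tv, n = brute_force_divergence(a, b)
            try:
                est = alignment_divergence(a, b)
            except DivergenceDomainError:
                with pytest.raises(DivergenceDomainError):
                    kimura2p(ts, tv)
                continue
            assert (est.p, est.q, est.n_sites) == (ts, tv, n)

    def test_mutated_copy_round_trip(self):
        consensus = "ACGT" * 50
        for seed, (p, q) in enumerate([(0.10, 0.05), (0.02, 0.01), (0.2, 0.1)]):
            copy, rp, rq = mutate_te_copy(consensus, p, q, seed=seed)
            est = alignment_divergence(copy, consensus)
            assert (est.p, est.q) == (rp, rq)


class TestLandscape:
    def test_binning_rule(self):
        est = alignment_divergence("GAAAA" + "A" * 95, "A" * 100)  # p=0.01 -> K~0.0101
        df = landscape([("fam", est, 500)])
        assert df.to_dict("records") == [{"family": "fam", "bin": 1, "bp": 500}]

    def test_mass_conservation(self, rng):
        consensus = "ACGT" * 50
        entries = []
        for i in range(20):
            p, q = rng.uniform(0, 0.15), rng.uniform(0, 0.08)
            copy, *_ = mutate_te_copy(consensus, p, q, seed=100 + i)
            est = alignment_divergence(copy, consensus)
            entries.append(("fam", est, 200))
        df = landscape(entries)
        assert df["bp"].sum() == 20 * 200

    def test_planted_divergence_concentrates_near_truth(self):
        consensus = "ACGT" * 125
        entries = []
        for i in range(30):
            copy, *_ = mutate_te_copy(consensus, 0.035, 0.015, seed=200 + i)
            est = alignment_divergence(copy, consensus)
            entries.append(("fam", est, 500))
        df = landscape(entries)
        mass_in_4_6 = df.loc[df["bin"].between(4, 6), "bp"].sum()
        assert mass_in_4_6 / df["bp"].sum() >= 0.9

    def test_clamped_at_max_bin(self):
        # p=0.33, q=0.08 -> K ~ 0.72, far beyond the 50% display clamp
        est = alignment_divergence("G" * 33 + "C" * 8 + "A" * 59, "A" * 100)
        df = landscape([("fam", est, 100)], max_bin=50)
        assert df["bin"].tolist() == [50]

    def test_empty_input(self):
        assert landscape([]).empty

    def test_from_annotation_divergence_column(self):
        anns = [
            TEAnnotation("c", 0, 500, "+", "hAT-N1", "DNA/hAT-Ac", 5.3),
            TEAnnotation("c", 600, 700, "+", "hAT-N1", "DNA/hAT-Ac", 5.9),
        ]
        df = landscape_from_annotations(anns)
        assert df.to_dict("records") == [
            {"family": "DNA/hAT-Ac", "bin": 5, "bp": 600}
        ]


class TestCompareLandscapes:
    def test_identical_landscapes_nothing_flagged(self):
        anns = [TEAnnotation("c", 0, 500, "+", "x", "LINE/L2", 3.0)]
        l1 = landscape_from_annotations(anns)
        df = compare_landscapes(l1, l1.copy())
        assert (df["difference"] == 0).all() and not df["flagged"].any()

    def test_bplus_specific_amplification_flagged(self):
        shared = [TEAnnotation("c", 0, 2000, "+", "x", "LINE/L2", 20.0)]
        extra = [
            TEAnnotation("c", 3000, 3800, "+", "y", "DNA/hAT-Ac", 1.0),
        ]
        l_bm = landscape_from_annotations(shared)
        l_bp = landscape_from_annotations(shared + extra)
        df = compare_landscapes(l_bm, l_bp)
        flagged = df[df["flagged"]]
        assert set(flagged["family"]) == {"DNA/hAT-Ac"} and set(flagged["bin"]) == {1}


class TestClassifyPirnaTE:
    @staticmethod
    def _hit(contig, start, length=25, library="FB-", weight=1.0):
        tag = SequenceTag("T" * length, {library: 1})
        return TagHit(tag, contig, start, start + length, "+", 1, weight)

    def test_largest_overlap_wins(self):
        anns = [
            TEAnnotation("c", 0, 120, "+", "d", "DNA/hAT-Ac", 1.0),  # 20 bp overlap
            TEAnnotation("c", 115, 300, "+", "l", "LTR/Pao", 1.0),  # 10 bp overlap
        ]
        df = classify_pirna_te([self._hit("c", 100)], anns)
        assert df.to_dict("records") == [
            {"library": "FB-", "te_class": "DNA", "percent": 100.0}
        ]

    def test_no_overlap_is_non_te(self):
        anns = [TEAnnotation("c", 500, 600, "+", "d", "DNA/hAT-Ac", 1.0)]
        df = classify_pirna_te([self._hit("c", 0)], anns)
        assert df.iloc[0]["te_class"] == "non-TE"

    def test_percentages_sum_to_100_per_library(self):
        anns = [
            TEAnnotation("c", 0, 50, "+", "d", "DNA/hAT-Ac", 1.0),
            TEAnnotation("c", 200, 260, "+", "l", "LINE/L2", 1.0),
        ]
        hits = [self._hit("c", 10), self._hit("c", 210), self._hit("c", 400)]
        df = classify_pirna_te(hits, anns)
        assert df.groupby("library")["percent"].sum().iloc[0] == pytest.approx(100.0)
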