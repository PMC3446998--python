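import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import anova_f_oracle, duncan_letters_oracle
from prorank.annotation_stats import (
    AnnotationTable,
    anova_oneway,
    category_fraction,
    duncan_mrt,
    group_conservation_summary,
    location_crosstab,
    ratio_chisq,
    read_annotation_table,
    read_blast_tabular,
    write_annotation_table,
)
from prorank.network_io import EdgeTableFormatError
from prorank.ranking_analysis import RankGroups


def blast_line(query, subject, evalue, bits):
    return f"{query}\t{subject}\t90.0\t100\t5\t1\t1\t100\t1\t100\t{evalue}\t{bits}"


def make_annotations(rows):
    """rows: (protein, bits, length, labels, nuc, cyt, mem)"""
    return AnnotationTable.from_records(
        [
            {
                "protein_id": p,
                "blast_bits": bits,
                "evalue": 1e-30 if not math.isnan(bits) else float("nan"),
                "length_aa": length,
                "pathway_labels": frozenset(labels),
                "nucleus": nuc,
                "cytoplasm": cyt,
                "membrane": mem,
            }
            for p, bits, length, labels, nuc, cyt, mem in rows
        ]
    )


class TestReadBlastTabular:
    def test_keeps_maximal_bit_score(self):
        text = blast_line("P1", "S1", "1e-10", 100) + "\n" + blast_line("P1", "S2", "1e-50", 250)
        best = read_blast_tabular(io.StringIO(text))
        assert best["P1"] == (250.0, 1e-50)

    def test_empty_file_empty_map(self):
        assert read_blast_tabular(io.StringIO("")) == {}

    def test_random_rows_match_scan_oracle(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"Q{rng.integers(10)}", float(rng.uniform(20, 500)))
            for _ in range(50)
        ]
        text = "\n".join(blast_line(q, "S", "1e-5", b) for q, b in rows)
        best = read_blast_tabular(io.StringIO(text))
        expected = {}
        for q, b in rows:
            if q not in expected or b > expected[q]:
                expected[q] = b
        assert {q: bits for q, (bits, _) in best.items()} == expected

    def test_wrong_column_count_names_line(self):
        text = blast_line("P1", "S1", "1e-10", 100) + "\nP2\tS1\tbroken\n"
        with pytest.raises(EdgeTableFormatError, match="line 2"):
            read_blast_tabular(io.StringIO(text))


class TestAnovaOneway:
    def test_equal_groups_give_zero_f(self):
        f_stat, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f_stat == 0.0

    def test_hand_computed_f(self):
        # SSB = 13.5 (df 1), SSW = 4 (df 4) -> F = 13.5
        f_stat, p = anova_oneway([[1, 2, 3], [4, 5, 6]])
        assert f_stat == pytest.approx(13.5, abs=1e-12)
        assert 0 < p < 0.05

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(12)
        groups = [list(rng.normal(loc, 2.0, size=9)) for loc in (0.0, 0.5, 1.5)]
        f_stat, _ = anova_oneway(groups)
        assert f_stat == pytest.approx(anova_f_oracle(groups), rel=1e-12)

    def test_zero_within_variance_unequal_means(self):
        f_stat, p = anova_oneway([[1, 1, 1], [2, 2, 2]])
        assert f_stat == math.inf and p == 0.0

    def test_type_one_error_calibration_small(self):
        rng = np.random.default_rng(99)
        rejections = sum(
            anova_oneway([rng.normal(size=20) for _ in range(3)])[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rejections / 400 <= 0.09

    def test_validation(self):
        with pytest.raises(ValueError):
            anova_oneway([[1, 2, 3]])
        with pytest.raises(ValueError):
            anova_oneway([[1], [2, 3]])


class TestDuncanMrt:
    def test_identical_samples_share_letter(self):
        letters = duncan_mrt([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert letters == ["A", "A"]

    def test_widely_separated_groups_all_distinct(self):
        rng = np.random.default_rng(0)
        groups = [list(rng.normal(mu, 0.1, 10)) for mu in (0.0, 100.0, 200.0)]
        letters = duncan_mrt(groups)
        assert sorted(letters) == ["A", "B", "C"]
        assert letters[2] == "A"  # highest mean gets the first letter

    def test_five_group_layout_matches_oracle(self):
        rng = np.random.default_rng(31)
        means = (10.0, 10.5, 12.0, 12.3, 18.0)
        groups = [list(rng.normal(mu, 1.5, 8)) for mu in means]
        assert duncan_mrt(groups) == duncan_letters_oracle(groups)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_layouts_match_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = int(rng.integers(3, 6))
        groups = [
            list(rng.normal(rng.uniform(0, 6), 1.0, int(rng.integers(5, 12))))
            for _ in range(g)
        ]
        assert duncan_mrt(groups) == duncan_letters_oracle(groups)

    def test_shift_invariance(self):
        rng = np.random.default_rng(77)
        groups = [list(rng.normal(mu, 1.0, 10)) for mu in (0.0, 1.0, 3.0)]
        shifted = [[v + 1234.5 for v in g] for g in groups]
        assert duncan_mrt(groups) == duncan_mrt(shifted)

    def test_two_group_null_calibration(self):
        # For 2 groups Duncan reduces to an LSD-style test: same-letter
        # probability under the null is ~0.95 at alpha=0.05.
        rng = np.random.default_rng(123)
        same = sum(
            duncan_mrt([list(rng.normal(size=10)), list(rng.normal(size=10))])
            == ["A", "A"]
            for _ in range(1000)
        )
        assert 0.93 <= same / 1000 <= 0.97

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            duncan_mrt([[1.0], [2.0, 3.0]])


class TestGroupConservationSummary:
    def _groups(self):
        return RankGroups(
            top=("T1", "T2", "T3"), mid=("M1", "M2", "M3"), bottom=("B1", "B2", "B3"), k=3
        )

    def test_flat_annotations_single_letter(self):
        rows = [
            (p, 100.0, 500, {"signalling"}, True, False, False)
            for p in ("T1", "T2", "T3", "M1", "M2", "M3", "B1", "B2", "B3")
        ]
        summary = group_conservation_summary(self._groups(), make_annotations(rows))
        assert summary.bits.anova_F == 0.0
        assert set(summary.bits.letters.values()) == {"A"}
        assert summary.bits.means["top"] == 100.0

    def test_planted_gradient_separates_letters(self):
        rng = np.random.default_rng(1)
        rows = []
        for prefix, mu in (("T", 300.0), ("M", 200.0), ("B", 100.0)):
            for i in (1, 2, 3):
                rows.append((f"{prefix}{i}", float(mu + rng.normal(0, 5)), 500, set(), 0, 0, 0))
        summary = group_conservation_summary(self._groups(), make_annotations(rows))
        assert summary.bits.letters["top"] != summary.bits.letters["bottom"]

    def test_missing_hit_exclusion_bookkeeping(self):
        rows = [
            (p, float("nan") if p == "T3" else 200.0, 500, set(), 0, 0, 0)
            for p in ("T1", "T2", "T3", "M1", "M2", "M3", "B1", "B2", "B3")
        ]
        summary = group_conservation_summary(self._groups(), make_annotations(rows))
        assert summary.n_used["top"] == 2
        assert summary.n_excluded["top"] == 1
        assert summary.n_used["mid"] == 3

    def test_low_coverage_raises(self):
        rows = [(p, 100.0, 500, set(), 0, 0, 0) for p in ("T1", "M1", "M2", "M3", "B1", "B2", "B3")]
        with pytest.raises(ValueError, match="annotated"):
            group_conservation_summary(self._groups(), make_annotations(rows))


class TestCategoryFraction:
    def test_published_denominator_convention(self):
        # 50 members, 43 with pathway assignment, 37 signalling -> 86.0% of annotated
        rows = []
        for i in range(50):
            if i < 37:
                labels = {"known_pathway", "signalling"}
            elif i < 43:
                labels = {"known_pathway"}
            else:
                labels = set()
            rows.append((f"P{i:02d}", 100.0, 500, labels, 0, 0, 0))
        ann = make_annotations(rows)
        group = [f"P{i:02d}" for i in range(50)]
        count, pct_annotated, pct_all = category_fraction(group, ann, "signalling")
        assert count == 37
        assert pct_annotated == pytest.approx(86.0, abs=0.05)
        assert pct_all == pytest.approx(74.0)

    def test_no_members_with_label(self):
        ann = make_annotations([("P1", 10.0, 100, {"x"}, 0, 0, 0)])
        assert category_fraction(["P1"], ann, "signalling") == (0, 0.0, 0.0)

    def test_all_members_labelled(self):
        ann = make_annotations([(f"P{i}", 10.0, 100, {"signalling"}, 0, 0, 0) for i in range(4)])
        count, pct_ann, pct_all = category_fraction([f"P{i}" for i in range(4)], ann, "signalling")
        assert (count, pct_ann, pct_all) == (4, 100.0, 100.0)

    @given(n_labelled=st.integers(0, 10))
    @settings(max_examples=15, deadline=None)
    def test_percentages_bounded(self, n_labelled):
        rows = [
            (f"P{i}", 10.0, 100, {"signalling"} if i < n_labelled else set(), 0, 0, 0)
            for i in range(10)
        ]
        ann = make_annotations(rows)
        count, pct_ann, pct_all = category_fraction([f"P{i}" for i in range(10)], ann, "signalling")
        assert count <= 10 and 0 <= pct_ann <= 100 and 0 <= pct_all <= 100


class TestLocationCrosstab:
    def test_flag_arithmetic(self):
        ann = make_annotations([("P1", 10.0, 100, set(), True, False, True)])
        table = location_crosstab({"top": ["P1"]}, ann)
        assert table.at["top", "nucleus"] == 1
        assert table.at["top", "cytoplasm"] == 0
        assert table.at["top", "membrane"] == 1
        assert table.at["top", "nucleus_plus_other"] == 1

    def test_empty_group_all_zero(self):
        ann = make_annotations([("P1", 10.0, 100, set(), 1, 1, 1)])
        table = location_crosstab({"bottom": []}, ann)
        assert table.loc["bottom"].sum() == 0

    def test_random_flags_match_tally_oracle(self):
        rng = np.random.default_rng(8)
        rows = [
            (f"P{i:02d}", 10.0, 100, set(), bool(rng.integers(2)), bool(rng.integers(2)), bool(rng.integers(2)))
            for i in range(30)
        ]
        ann = make_annotations(rows)
        group = [r[0] for r in rows]
        table = location_crosstab({"g": group}, ann)
        assert table.at["g", "nucleus"] == sum(r[4] for r in rows)
        assert table.at["g", "cytoplasm"] == sum(r[5] for r in rows)
        assert table.at["g", "membrane"] == sum(r[6] for r in rows)
        assert table.at["g", "nucleus_plus_other"] == sum(
            1 for r in rows if r[4] and (r[5] or r[6])
        )


class TestRatioChisq:
    def test_balanced_observed_balanced_reference(self):
        chi2, p = ratio_chisq(25, 25, 1, 1)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_chi2(self):
        # expected (25, 25): chi2 = (15^2 + 15^2)/25 = 18
        chi2, p = ratio_chisq(40, 10, 1, 1)
        assert chi2 == pytest.approx(18.0, abs=1e-12)
        assert p < 0.001

    def test_proportional_observed_gives_zero(self):
        for k in (1, 2, 7):
            chi2, _ = ratio_chisq(3 * k, 11 * k, 3, 11)
            assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            ratio_chisq(5, 5, 0, 0)

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            ratio_chisq(5, 5, 0, 10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ratio_chisq(-1, 5, 1, 1)


class TestAnnotationTableIO:
    def test_round_trip(self):
        rows = [
            ("P1", 123.4, 500, {"signalling", "MAPK"}, True, False, True),
            ("P2", float("nan"), 200, set(), False, True, False),
        ]
        table = make_annotations(rows)
        buf = io.StringIO()
        write_annotation_table(table, buf)
        back = read_annotation_table(io.StringIO(buf.getvalue()))
        assert back.bits("P1") == pytest.approx(123.4)
        assert not back.has_hit("P2")
        assert back.labels("P1") == {"signalling", "MAPK"}
        assert back.location("P1", "membrane")

    def test_bad_header_rejected(self):
        with pytest.raises(EdgeTableFormatError):
            read_annotation_table(io.StringIO("a\tb\nx\ty\n"))
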