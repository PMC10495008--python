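"""Fragment merging, structural classification, and locus composition."""

import numpy as np
import pytest

from pirnakit.io import RepeatHit
from pirnakit.te import (
    MergeParams,
    TEFamily,
    UnknownFamilyError,
    classify_copies,
    classify_copy,
    composition_stats,
    merge_fragments,
    trap_model_report,
    window_enrichment,
)
from tests.conftest import make_copy


def hit(start, end, family, cons_b, cons_e, strand="+", div=5.0, contig="c"):
    return RepeatHit(contig, start, end, strand, family, cons_b, cons_e, div)


class TestMergeFragments:
    def test_single_full_span_hit_gives_completeness_one(self, small_library):
        (copy,) = merge_fragments([hit(0, 5429, "LIN1", 1, 5429)], small_library)
        assert copy.completeness == 1.0
        assert copy.family == "LIN1"

    def test_two_colinear_fragments_merge_and_union_consensus(self, small_library):
        fam = [TEFamily("LIN5K", "LINE", 5000)]
        hits = [
            hit(0, 2000, "LIN5K", 1, 2000),
            hit(2300, 4800, "LIN5K", 2500, 5000),
        ]
        (copy,) = merge_fragments(hits, fam)
        assert len(copy.fragments) == 2
        assert copy.completeness == pytest.approx((2000 + 2501) / 5000)

    def test_opposite_strand_fragments_stay_separate(self, small_library):
        fam = [TEFamily("LIN5K", "LINE", 5000)]
        hits = [
            hit(0, 2000, "LIN5K", 1, 2000, "+"),
            hit(2300, 4800, "LIN5K", 2500, 5000, "-"),
        ]
        assert len(merge_fragments(hits, fam)) == 2

    def test_gap_beyond_max_gap_splits_copies(self, small_library):
        fam = [TEFamily("LIN5K", "LINE", 5000)]
        hits = [
            hit(0, 2000, "LIN5K", 1, 2000),
            hit(2000 + 5001, 9500, "LIN5K", 2500, 5000),
        ]
        assert len(merge_fragments(hits, fam, MergeParams(max_gap=5000))) == 2

    def test_ltr_internal_ltr_rows_merge_into_one_full_copy(self, small_library):
        # GYP1: 5000 nt, 400 nt LTRs -> internal consensus of 4200
        hits = [
            hit(0, 400, "GYP1_LTR", 1, 400),
            hit(400, 4600, "GYP1_I", 1, 4200),
            hit(4600, 5000, "GYP1_LTR", 1, 400),
        ]
        (copy,) = merge_fragments(hits, small_library)
        assert copy.completeness == 1.0
        copy = classify_copy(copy, small_library[0])
        assert copy.category == "full_length"
        assert copy.has_5ltr and copy.has_3ltr and copy.has_internal

    def test_unknown_family_raises_listing_names(self, small_library):
        with pytest.raises(UnknownFamilyError, match="NOPE"):
            merge_fragments([hit(0, 100, "NOPE", 1, 100)], small_library)

    def test_unsorted_input_rejected(self, small_library):
        hits = [hit(500, 600, "LIN1", 1, 100), hit(0, 100, "LIN1", 200, 300)]
        with pytest.raises(ValueError, match="sorted"):
            merge_fragments(hits, small_library)

    def test_partition_every_hit_in_exactly_one_copy(self, small_library):
        rng = np.random.default_rng(0)
        hits = []
        pos = 0
        for _ in range(40):
            pos += int(rng.integers(50, 8000))
            fam = ["LIN1", "DNA1", "GYP1_LTR"][int(rng.integers(0, 3))]
            length = int(rng.integers(50, 400))
            b = int(rng.integers(1, 2000))
            hits.append(
                hit(pos, pos + length, fam, b, b + length - 1,
                    "+" if rng.random() < 0.5 else "-")
            )
            pos += length
        copies = merge_fragments(hits, small_library)
        emitted = [f for c in copies for f in c.fragments]
        assert sorted(id(f) for f in emitted) == sorted(id(h) for h in hits)

    def test_merging_is_idempotent(self, small_library):
        hits = [
            hit(0, 400, "GYP1_LTR", 1, 400),
            hit(400, 4600, "GYP1_I", 1, 4200),
            hit(4600, 5000, "GYP1_LTR", 1, 400),
            hit(20000, 22000, "LIN1", 1, 2000),
            hit(22100, 25000, "LIN1", 2300, 5200),
        ]
        copies = merge_fragments(hits, small_library)
        re_hits = sorted(
            (f for c in copies for f in c.fragments),
            key=lambda h: (h.contig, h.start),
        )
        re_copies = merge_fragments(re_hits, small_library)
        assert [(c.start, c.end, c.family, len(c.fragments)) for c in copies] == [
            (c.start, c.end, c.family, len(c.fragments)) for c in re_copies
        ]


class TestClassifyCopy:
    def _line_copy(self, completeness):
        c = make_copy("LIN1", completeness=completeness)
        c.cons_intervals = [(1, int(round(completeness * 5429)))]
        return c

    def test_seventy_percent_boundary_is_inclusive(self, small_library):
        lin1 = small_library[2]
        assert classify_copy(self._line_copy(0.70), lin1).category == "full_length"
        assert classify_copy(self._line_copy(0.699), lin1).category == "fragment"

    def test_ltr_full_length_needs_both_ltrs_and_internal(self, small_library):
        gyp = small_library[0]  # 5000 nt, ltr 400
        both = make_copy("GYP1", completeness=0.96)
        both.cons_intervals = [(1, 4810)]  # 5' LTR, internal, >half the 3' LTR
        assert classify_copy(both, gyp).category == "full_length"
        one_ltr = make_copy("GYP1", completeness=0.85)
        one_ltr.cons_intervals = [(450, 4700)]  # no 5' LTR coverage
        assert classify_copy(one_ltr, gyp).category == "fragment"

    def test_ltr_only_coverage_is_solo_ltr(self, small_library):
        gyp = small_library[0]
        solo = make_copy("GYP1", completeness=400 / 5000)
        solo.cons_intervals = [(1, 400)]
        assert classify_copy(solo, gyp).category == "solo_LTR"

    def test_completeness_always_within_unit_interval(self, small_library):
        fam = [TEFamily("LIN5K", "LINE", 5000)]
        hits = [hit(0, 2000, "LIN5K", 1, 2000), hit(2010, 4100, "LIN5K", 1950, 4040)]
        (copy,) = merge_fragments(hits, fam, MergeParams(max_overlap_cons=100))
        assert 0.0 <= copy.completeness <= 1.0


class TestComposition:
    def test_direct_arithmetic(self, small_library):
        copies = (
            [make_copy("GYP1", "-") for _ in range(4)]
            + [make_copy("LIN1", "-")]
            + [make_copy("DNA1", "+") for _ in range(5)]
        )
        st = composition_stats(copies, small_library, "+")
        assert st.pct_antisense == pytest.approx(50.0)
        assert st.pct_antisense_that_are_LTR == pytest.approx(80.0)

    def test_all_sense_reports_missing_ltr_percentage(self, small_library):
        copies = [make_copy("LIN1", "+") for _ in range(3)]
        st = composition_stats(copies, small_library, "+")
        assert st.pct_antisense == 0.0
        assert st.pct_antisense_that_are_LTR is None

    def test_empty_copy_list_is_an_error(self, small_library):
        with pytest.raises(ValueError):
            composition_stats([], small_library, "+")

    def test_per_family_counts_split_by_category(self, small_library):
        copies = [
            make_copy("GYP1", category="full_length"),
            make_copy("GYP1", category="solo_LTR"),
            make_copy("GYP1", category="fragment"),
        ]
        st = composition_stats(copies, small_library, "+")
        row = st.per_family.set_index("family").loc["GYP1"]
        assert (row["n_copies"], row["full_length"], row["solo_LTR"]) == (3, 1, 1)


class TestWindowEnrichment:
    def test_starts_assign_to_containing_window(self):
        items = [make_copy("G", start=s) for s in range(300_000, 400_000, 3400)]
        counts = window_enrichment(items, 1_000_000, window=100_000)
        assert counts[3] == len(items)
        assert counts.sum() == len(items)
        assert (np.delete(counts, 3) == 0).all()

    def test_empty_input_gives_all_zero_vector(self):
        counts = window_enrichment([], 1_000_000, window=100_000)
        assert len(counts) == 10 and counts.sum() == 0

    def test_boundary_start_falls_in_upper_window(self):
        counts = window_enrichment([make_copy("G", start=200_000)], 1_000_000,
                                   window=100_000)
        assert counts[2] == 1 and counts[1] == 0

    def test_family_filter_and_sum_conservation(self):
        items = [make_copy("A", start=10), make_copy("B", start=20)]
        counts = window_enrichment(items, 1000, family_filter={"A"}, window=100)
        assert counts.sum() == 1

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            window_enrichment([], 1000, window=0)


class TestTrapModel:
    def test_multicopy_antisense_family_detected(self):
        copies = [
            make_copy("mdg4", "-", category="full_length"),
            make_copy("mdg4", "-", start=200, category="full_length"),
        ]
        rep = trap_model_report(copies, "+")
        assert rep.multicopy_antisense == {"mdg4"}

    def test_recent_fragment_divergence_boundary_exclusive(self):
        def pair(div):
            return [
                make_copy("F", "+", category="full_length"),
                make_copy("F", "-", start=300, category="fragment", divergence=div),
            ]

        assert trap_model_report(pair(8.0), "+").recent_fragment == {"F"}
        assert trap_model_report(pair(12.0), "+").recent_fragment == set()
        assert trap_model_report(pair(10.0), "+").recent_fragment == set()

    def test_no_full_length_copies_gives_empty_sets(self):
        copies = [make_copy("F", "-", category="fragment", divergence=1.0)]
        rep = trap_model_report(copies, "+")
        assert rep.multicopy_antisense == set() and rep.recent_fragment == set()
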