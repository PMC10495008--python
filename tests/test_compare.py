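"""Synteny alignment of annotations, sharing spectra, HT calls, digests."""

import random
import warnings

import numpy as np
import pytest

from pirnakit.compare import (
    AlignParams,
    HTParams,
    InsertionColumn,
    _tokens_match,
    align_annotation_pair,
    build_panel,
    digest_fragments,
    ht_classify,
    percent_identity,
    sharing_spectrum,
)
from tests.conftest import make_copy


def brute_force_best(a, b, params):
    """Exhaustive maximum over all monotone pairings (oracle for the DP)."""
    best = float("-inf")
    stack = [(0, 0, 0.0)]
    while stack:
        i, j, score = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score)
            continue
        if i < len(a) and j < len(b):
            pair = (
                params.match_score
                if _tokens_match(a[i], b[j], params)
                else -params.mismatch_penalty
            )
            stack.append((i + 1, j + 1, score + pair))
        if i < len(a):
            stack.append((i + 1, j, score - params.gap_penalty))
        if j < len(b):
            stack.append((i, j + 1, score - params.gap_penalty))
    return best


class TestAlignAnnotationPair:
    def test_identical_lists_fully_matched(self):
        a = [make_copy(f, start=i * 200) for i, f in enumerate("WXYZ")]
        cols, score = align_annotation_pair(a, a)
        assert score == pytest.approx(0.2 * 4)
        assert cols == [(i, i) for i in range(4)]

    def test_deletion_costs_one_gap(self):
        a = [make_copy(f, start=i * 200) for i, f in enumerate("XYZ")]
        b = [make_copy(f, start=i * 200) for i, f in enumerate("XZ")]
        cols, score = align_annotation_pair(a, b)
        assert score == pytest.approx(0.2 * 2 - 0.09)
        assert cols == [(0, 0), (1, None), (2, 1)]

    def test_score_matches_brute_force_on_random_pairs(self):
        rnd = random.Random(0)
        params = AlignParams()
        for _ in range(200):
            a = [
                make_copy(rnd.choice("EFGH"), rnd.choice("+-"), start=i * 100)
                for i in range(rnd.randint(0, 8))
            ]
            b = [
                make_copy(rnd.choice("EFGH"), rnd.choice("+-"), start=i * 100)
                for i in range(rnd.randint(0, 8))
            ]
            _, score = align_annotation_pair(a, b, params)
            assert score == pytest.approx(brute_force_best(a, b, params))

    def test_unordered_input_rejected(self):
        a = [make_copy("X", start=500), make_copy("Y", start=100)]
        with pytest.raises(ValueError, match="ordered"):
            align_annotation_pair(a, [])

    def test_strand_requirement_controls_matching(self):
        a = [make_copy("X", "+")]
        b = [make_copy("X", "-")]
        _, strict = align_annotation_pair(a, b, AlignParams())
        _, loose = align_annotation_pair(
            a, b, AlignParams(require_same_strand=False)
        )
        assert strict == pytest.approx(-0.1)  # mismatch beats two gaps
        assert loose == pytest.approx(0.2)

    def test_family_equivalence_groups_merge_names(self):
        a = [make_copy("mdg4-3")]
        b = [make_copy("mdg4-5")]
        params = AlignParams(family_equivalence={"mdg4-3": "mdg4", "mdg4-5": "mdg4"})
        _, score = align_annotation_pair(a, b, params)
        assert score == pytest.approx(0.2)


class TestBuildPanel:
    def test_copy_shared_by_all_genotypes_forms_one_column(self):
        panel = {
            g: [make_copy("F", start=100)] for g in ("G1", "G2", "G3")
        }
        (col,) = build_panel(panel)
        assert col.n_present == 3

    def test_private_copy_gets_its_own_column(self):
        panel = {
            "G1": [make_copy("A", start=0), make_copy("B", start=500)],
            "G2": [make_copy("A", start=0), make_copy("P", start=200),
                   make_copy("B", start=500)],
        }
        cols = build_panel(panel)
        assert len(cols) == 3
        private = [c for c in cols if c.family == "P"]
        assert private and private[0].n_present == 1
        assert private[0].states["G2"] == "full_length"

    def test_every_copy_lands_in_exactly_one_column(self):
        rng = np.random.default_rng(9)
        panel = {}
        for g in ("G1", "G2", "G3", "G4"):
            n = int(rng.integers(3, 8))
            panel[g] = [
                make_copy(f"F{rng.integers(0, 12)}", start=i * 300) for i in range(n)
            ]
        cols = build_panel(panel)
        n_states = sum(c.n_present for c in cols)
        assert n_states == sum(len(v) for v in panel.values())


class TestSharingSpectrum:
    def _col(self, cid, states):
        return InsertionColumn(cid, "F", states,
                               sum(1 for s in states.values() if s != "absent"))

    def test_proportions_and_normalization(self):
        gts = [f"G{i}" for i in range(1, 8)]
        cols = []
        for i in range(4):
            states = {g: "absent" for g in gts}
            states["G1"] = "full_length"
            cols.append(self._col(f"p{i}", states))
        for i in range(6):
            cols.append(self._col(f"s{i}", {g: "full_length" for g in gts}))
        spec = sharing_spectrum(cols, 7)
        assert spec[1] == pytest.approx(0.4)
        assert spec[7] == pytest.approx(0.6)
        assert sum(spec.values()) == pytest.approx(1.0)

    def test_fragmented_elsewhere_still_counts_as_shared(self):
        gts = [f"G{i}" for i in range(1, 8)]
        states = {g: "absent" for g in gts}
        states["G1"] = "full_length"
        for g in ("G2", "G3", "G4"):
            states[g] = "fragment"
        spec = sharing_spectrum([self._col("x", states)], 7, full_length_only=True)
        assert spec[4] == pytest.approx(1.0)

    def test_full_length_only_drops_all_fragment_columns(self):
        gts = ["G1", "G2"]
        frag = self._col("f", {"G1": "fragment", "G2": "absent"})
        full = self._col("g", {"G1": "full_length", "G2": "full_length"})
        spec = sharing_spectrum([frag, full], 2, full_length_only=True)
        assert spec == {1: 0.0, 2: 1.0}

    def test_empty_columns_rejected(self):
        with pytest.raises(ValueError):
            sharing_spectrum([], 7)


class TestPercentIdentity:
    def test_identical_sequences(self):
        s = "ACGT" * 25
        assert percent_identity(s, s) == 1.0

    def test_single_substitution_in_hundred(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), 100))
        b = a[:50] + ("A" if a[50] != "A" else "C") + a[51:]
        assert percent_identity(a, b) == pytest.approx(0.99)

    def test_mutation_dial_recovered(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 2000))
        b = list(a)
        for i in range(len(b)):
            if rng.random() < 0.05:
                b[i] = rng.choice([c for c in "ACGT" if c != b[i]])
        ident = percent_identity(a, "".join(b))
        assert ident == pytest.approx(0.95, abs=0.01)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(rng.choice(list("ACGT"), 110))
        assert percent_identity(a, b) == percent_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACGT")


class TestHTClassify:
    @pytest.mark.parametrize(
        "identity,expected",
        [(0.99, "horizontal"), (0.98, "vertical"), (0.95, "vertical")],
    )
    def test_threshold_is_strict(self, identity, expected):
        assert ht_classify(identity) == expected

    def test_baseline_overlap_warns(self):
        with pytest.warns(UserWarning, match="baseline"):
            HTParams(ht_threshold=0.95, baseline_range=(0.93, 0.97))


class TestDigest:
    def test_single_site_gives_two_fragments(self):
        rng = np.random.default_rng(11)
        while True:
            s = "".join(rng.choice(list("ACGT"), 1000))
            s = s[:747] + "TACGTA" + s[753:]
            if digest_fragments(s) == [750, 250]:
                break
        assert digest_fragments(s) == [750, 250]

    def test_no_site_leaves_sequence_uncut(self):
        assert digest_fragments("A" * 1000) == [1000]

    @pytest.mark.parametrize(
        "site,cut", [("TACGTA", True), ("CACGTG", True), ("AACGTA", False)]
    )
    def test_iupac_degeneracy(self, site, cut):
        s = "TTTTT" + site + "TTTTT"
        frags = digest_fragments(s)
        assert (len(frags) == 2) is cut

    def test_length_conserved_and_case_invariant(self):
        rng = np.random.default_rng(12)
        s = "".join(rng.choice(list("ACGT"), 5000))
        frags = digest_fragments(s)
        assert sum(frags) == len(s)
        assert digest_fragments(s.lower()) == frags

    def test_invalid_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            digest_fragments("ACGT", motif="AXGT")
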