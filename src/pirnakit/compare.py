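"""Cross-genotype comparison of TE annotations and horizontal-transfer calls.

Homology between TE insertions in different assemblies of the same locus is
established by synteny, not sequence: the ordered lists of annotated copies
are aligned by global dynamic programming over annotation tokens, where two
tokens match when they belong to the same family group (and strand).  A
star-progressive panel around a reference genotype turns pairwise alignments
into presence/absence columns, from which shared/private sharing spectra are
computed.  Copies that are full length in one genotype but fragmented in
others still count as shared.

Horizontal transfer is called from cross-species percent identity against a
vertical-descent baseline: identities above the threshold (default 98%,
chosen above the 93–97% identity range of the strictly vertically transmitted
R1 element) are labelled horizontal.  Direction of transfer is never
inferred.

A small restriction-digest utility predicts fragment lengths for
IUPAC-degenerate recognition sites (e.g. BsaAI's YACGTR), used to validate
locus duplications by PCR-digest.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from pirnakit.te import TECopy

# BsaAI: YAC^GTR (blunt, cut at the center of the 6-mer)
BSAAI_SITE = "YACGTR"
BSAAI_CUT_OFFSET = 3

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class AlignParams:
    """Scores for the annotation-token alignment (maximization DP).

    Matched pairs gain ``match_score``; pairing tokens of different families
    costs ``mismatch_penalty``; leaving a token unpaired costs
    ``gap_penalty``.  ``family_equivalence`` maps near-identical family names
    (e.g. closely related consensus variants) onto one group label before
    comparison.
    """

    match_score: float = 0.2
    mismatch_penalty: float = 0.1
    gap_penalty: float = 0.09
    require_same_strand: bool = True
    family_equivalence: Optional[dict[str, str]] = None

    def __post_init__(self):
        if self.match_score <= 0:
            raise ValueError("match_score must be positive")
        if self.mismatch_penalty < 0 or self.gap_penalty < 0:
            raise ValueError("penalties must be non-negative")

    def group(self, family: str) -> str:
        if self.family_equivalence:
            return self.family_equivalence.get(family, family)
        return family


@dataclass
class InsertionColumn:
    """One homologous insertion site across a genotype panel."""

    column_id: str
    family: str
    states: dict[str, str]  # genotype -> full_length | fragment | solo_LTR | absent
    n_present: int

    def __post_init__(self):
        present = sum(1 for s in self.states.values() if s != "absent")
        if present != self.n_present:
            raise ValueError("n_present inconsistent with states")
        if not (1 <= self.n_present <= len(self.states)):
            raise ValueError("n_present out of range")


@dataclass
class HTParams:
    """Identity threshold for horizontal-transfer calls.

    ``baseline_range`` is the identity range expected under vertical descent
    (taken from a strictly vertically transmitted element); the threshold
    should sit above it.
    """

    ht_threshold: float = 0.98
    baseline_range: tuple[float, float] = (0.93, 0.97)

    def __post_init__(self):
        if self.ht_threshold <= self.baseline_range[1]:
            warnings.warn(
                "ht_threshold overlaps the vertical-descent baseline range; "
                "horizontal calls will not be separable from vertical descent",
                stacklevel=2,
            )


def _tokens_match(a: TECopy, b: TECopy, params: AlignParams) -> bool:
    if params.group(a.family) != params.group(b.family):
        return False
    if params.require_same_strand and a.strand != b.strand:
        return False
    return True


def _check_ordered(copies: Sequence[TECopy], label: str) -> None:
    starts = [c.start for c in copies]
    if starts != sorted(starts):
        raise ValueError(f"annotation list {label} not ordered by genomic start")


def align_annotation_pair(
    a: Sequence[TECopy], b: Sequence[TECopy], params: AlignParams = AlignParams()
) -> tuple[list[tuple[Optional[int], Optional[int]]], float]:
    """Globally align two ordered TE-annotation lists by synteny.

    Returns the alignment as a list of columns ``(i, j)`` — indices into
    ``a``/``b`` or None for a gap — plus the total score.  The DP maximizes
    match score minus mismatch and gap penalties over all monotone pairings;
    on score ties the traceback prefers match over mismatch over gap.
    """
    _check_ordered(a, "a")
    _check_ordered(b, "b")
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    # move codes: 0 diag-match, 1 diag-mismatch, 2 up (gap in b), 3 left (gap in a)
    back = [[0] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for i in range(1, n + 1):
        H[i][0] = -params.gap_penalty * i
        back[i][0] = 2
    for j in range(1, m + 1):
        H[0][j] = -params.gap_penalty * j
        back[0][j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            is_match = _tokens_match(a[i - 1], b[j - 1], params)
            diag = H[i - 1][j - 1] + (
                params.match_score if is_match else -params.mismatch_penalty
            )
            up = H[i - 1][j] - params.gap_penalty
            left = H[i][j - 1] - params.gap_penalty
            options = [
                (diag, 0 if is_match else 1),
                (up, 2),
                (left, 3),
            ]
            best = max(o[0] for o in options)
            # tie-break: match > mismatch > gap
            for score, code in sorted(options, key=lambda o: o[1]):
                if score == best:
                    H[i][j] = score
                    back[i][j] = code
                    break
    cols: list[tuple[Optional[int], Optional[int]]] = []
    i, j = n, m
    while i > 0 or j > 0:
        code = back[i][j]
        if code in (0, 1) and i > 0 and j > 0:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif code == 2 and i > 0:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return cols, H[n][m]


def build_panel(
    copies_by_genotype: dict[str, Sequence[TECopy]],
    reference: Optional[str] = None,
    params: AlignParams = AlignParams(),
) -> list[InsertionColumn]:
    """Build homologous insertion columns across a genotype panel.

    Star-progressive around ``reference`` (default: first genotype): every
    other genotype is aligned to the reference, truly matched tokens join the
    reference token's column, and unmatched tokens form new columns keyed by
    their left flanking matched reference token, family group, and ordinal —
    so private insertions of the same family at the same flank merge across
    genotypes in order of appearance.  Every input copy lands in exactly one
    column.
    """
    genotypes = list(copies_by_genotype)
    if reference is None:
        reference = genotypes[0]
    if reference not in copies_by_genotype:
        raise ValueError(f"reference genotype {reference!r} not in panel")
    ref_copies = list(copies_by_genotype[reference])

    # per-reference-token columns, in reference order
    ref_states: list[dict[str, str]] = [
        {g: "absent" for g in genotypes} for _ in ref_copies
    ]
    for i, c in enumerate(ref_copies):
        ref_states[i][reference] = c.category
    # inserted columns: (left_ref_index, family_group, ordinal) -> states
    inserted: dict[tuple[int, str, int], dict[str, str]] = {}

    for g in genotypes:
        if g == reference:
            continue
        g_copies = list(copies_by_genotype[g])
        cols, _ = align_annotation_pair(ref_copies, g_copies, params)
        matched_j: dict[int, int] = {}
        for i, j in cols:
            if i is not None and j is not None and _tokens_match(
                ref_copies[i], g_copies[j], params
            ):
                matched_j[j] = i
        last_ref = -1
        ordinals: dict[tuple[int, str], int] = {}
        for j, copy in enumerate(g_copies):
            if j in matched_j:
                i = matched_j[j]
                if ref_states[i][g] != "absent":
                    raise ValueError(
                        f"genotype {g} assigned twice to reference column {i}"
                    )
                ref_states[i][g] = copy.category
                last_ref = i
            else:
                group = params.group(copy.family)
                k = ordinals.get((last_ref, group), 0)
                ordinals[(last_ref, group)] = k + 1
                key = (last_ref, group, k)
                states = inserted.setdefault(
                    key, {gg: "absent" for gg in genotypes}
                )
                if states[g] != "absent":
                    raise ValueError(
                        f"genotype {g} merged twice into inserted column {key}"
                    )
                states[g] = copy.category

    columns: list[InsertionColumn] = []

    def _make(column_id: str, family: str, states: dict[str, str]) -> None:
        n_present = sum(1 for s in states.values() if s != "absent")
        columns.append(InsertionColumn(column_id, family, states, n_present))

    ins_by_flank: dict[int, list[tuple[tuple, dict]]] = {}
    for key in sorted(inserted):
        ins_by_flank.setdefault(key[0], []).append((key, inserted[key]))
    for key, states in ins_by_flank.get(-1, []):
        _make(f"ins_{key[0]}_{key[1]}_{key[2]}", key[1], states)
    for i, c in enumerate(ref_copies):
        _make(f"ref_{i}", params.group(c.family), ref_states[i])
        for key, states in ins_by_flank.get(i, []):
            _make(f"ins_{key[0]}_{key[1]}_{key[2]}", key[1], states)
    return columns


def sharing_spectrum(
    columns: Sequence[InsertionColumn],
    panel_size: int,
    full_length_only: bool = False,
) -> dict[int, float]:
    """Proportion of insertion columns shared by exactly k of the genotypes.

    With ``full_length_only``, only columns where at least one genotype
    carries a full-length copy are counted — but their sharing count still
    includes genotypes where the copy is fragmented (degraded copies of a
    once-full-length insertion are shared, not private).
    """
    if panel_size < 2:
        raise ValueError("panel_size must be >= 2")
    kept = [
        c
        for c in columns
        if not full_length_only
        or any(s == "full_length" for s in c.states.values())
    ]
    if not kept:
        raise ValueError("no columns to build a spectrum from")
    spectrum = {k: 0 for k in range(1, panel_size + 1)}
    for c in kept:
        if c.n_present not in spectrum:
            raise ValueError(
                f"column {c.column_id} present in {c.n_present} genotypes, "
                f"panel size {panel_size}"
            )
        spectrum[c.n_present] += 1
    total = len(kept)
    return {k: v / total for k, v in spectrum.items()}


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of two sequences under global alignment.

    Unit match/mismatch/gap scores; identity is matches over alignment
    columns where both sequences have a base (gap columns excluded from the
    denominator).  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    a, b = sorted((seq_a.upper(), seq_b.upper()))  # canonical order => symmetry
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    aln = aligner.align(a, b)[0]
    matches = 0
    aligned_cols = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned_cols += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    if aligned_cols == 0:
        return 0.0
    return matches / aligned_cols


def ht_classify(identity: float, params: HTParams = HTParams()) -> str:
    """Label a cross-species TE identity as horizontal or vertical transfer.

    Strictly above the threshold means horizontal; the threshold itself is
    vertical (the baseline is an upper bound on vertical-descent identity,
    not a confidence bound).
    """
    if not (0.0 <= identity <= 1.0):
        raise ValueError("identity must be in [0, 1]")
    return "horizontal" if identity > params.ht_threshold else "vertical"


def digest_fragments(
    seq: str, motif: str = BSAAI_SITE, cut_offset: int = BSAAI_CUT_OFFSET
) -> list[int]:
    """Fragment lengths after cutting a sequence at every motif match.

    The motif may contain IUPAC degenerate codes; matching is on the forward
    strand of the given sequence, case-insensitive, including overlapping
    matches.  The cut is placed ``cut_offset`` bases into each match;
    fragment lengths are returned 5'->3' and always sum to the sequence
    length.
    """
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError("cut_offset must be within the motif")
    motif_u = motif.upper()
    bad = set(motif_u) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC characters in motif: {sorted(bad)}")
    pattern = "(?=" + "".join(
        f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch] for ch in motif_u
    ) + ")"
    s = seq.upper()
    cuts = sorted(
        {
            m.start() + cut_offset
            for m in re.finditer(pattern, s)
            if 0 < m.start() + cut_offset < len(s)
        }
    )
    bounds = [0] + cuts + [len(s)]
    return [e - b for b, e in zip(bounds, bounds[1:])]
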