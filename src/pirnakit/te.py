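"""Merging repeat fragments into TE copies and classifying their structure.

RepeatMasker reports one row per aligned fragment, so a single degraded
insertion — and every full-length LTR element, whose LTRs and internal region
are annotated against separate consensus entries — appears as several rows.
This module chains fragments into copies by genomic proximity and consensus
colinearity, measures how much of the family consensus each copy preserves,
and classifies copies as full-length, solo-LTR or fragment.  Locus-level
summaries (antisense composition, windowed family enrichment, transposon-trap
reports) are built on the classified copies.

Coordinate conventions follow :mod:`pirnakit.io`: genomic intervals 0-based
half-open, consensus intervals 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from pirnakit.io import RepeatHit

# suffixes by which RepeatMasker libraries split an LTR element into its
# long-terminal-repeat and internal consensus entries
_LTR_SUFFIX = re.compile(r"([_-](LTR|ltr))$")
_INT_SUFFIX = re.compile(r"([_-](I|int|INT|in))$")


@dataclass
class TEFamily:
    """One entry of the TE consensus library.

    ``ltr_len`` is the length of each terminal repeat for LTR-class families
    (0 otherwise); ``consensus_len`` is the full element length including both
    LTRs.
    """

    name: str
    te_class: str  # LTR, LINE, DNA, other
    consensus_len: int
    ltr_len: int = 0
    consensus_seq: Optional[str] = None

    def __post_init__(self):
        if self.consensus_len < 1:
            raise ValueError("consensus_len must be >= 1")
        if self.te_class == "LTR":
            if not (0 < self.ltr_len < self.consensus_len / 2):
                raise ValueError(
                    f"{self.name}: ltr_len must be in (0, consensus_len/2) "
                    "for LTR class"
                )
        elif self.ltr_len != 0:
            raise ValueError(f"{self.name}: ltr_len must be 0 for non-LTR class")


@dataclass
class MergeParams:
    """Tunables for fragment merging and structural classification.

    max_gap
        Largest genomic distance (nt) allowed between consecutive fragments of
        one copy.
    max_overlap_cons
        Tolerated overlap (nt) between consecutive consensus intervals before
        colinearity is considered violated.
    full_len_threshold
        Minimum fraction of the consensus a copy must cover to be full-length.
    ltr_region_cov_min
        Fraction of an LTR (or internal) sub-interval that must be covered for
        that feature to count as present.
    """

    max_gap: int = 5000
    max_overlap_cons: int = 30
    full_len_threshold: float = 0.70
    ltr_region_cov_min: float = 0.50

    def __post_init__(self):
        if self.max_gap < 0 or self.max_overlap_cons < 0:
            raise ValueError("gap/overlap tolerances must be non-negative")
        if not (0 < self.full_len_threshold <= 1):
            raise ValueError("full_len_threshold must be in (0, 1]")


@dataclass
class TECopy:
    """A merged TE insertion spanning one or more repeat fragments."""

    family: str
    contig: str
    start: int
    end: int
    strand: str
    fragments: list[RepeatHit]
    cons_intervals: list[tuple[int, int]]  # 1-based inclusive, on full consensus
    completeness: float = 0.0
    has_5ltr: bool = False
    has_3ltr: bool = False
    has_internal: bool = False
    category: str = "fragment"
    mean_divergence_pct: float = 0.0


class UnknownFamilyError(KeyError):
    """A repeat hit references a family absent from the library."""


def base_family_name(name: str, extra_map: Optional[dict[str, str]] = None) -> str:
    """Map LTR/internal consensus names (FAM_LTR, FAM_I, ...) to one family.

    ``extra_map`` lets callers add library-specific aliases on top of the
    suffix rules.
    """
    if extra_map and name in extra_map:
        return extra_map[name]
    for pat in (_LTR_SUFFIX, _INT_SUFFIX):
        m = pat.search(name)
        if m:
            return name[: m.start()]
    return name


def _is_ltr_part(name: str) -> bool:
    return bool(_LTR_SUFFIX.search(name))


def _is_int_part(name: str) -> bool:
    return bool(_INT_SUFFIX.search(name))


def _union_len(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_b = cur_e = None
    for b, e in ivs:
        if cur_e is None or b > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_b + 1
            cur_b, cur_e = b, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_b + 1
    return total


def _overlap_1based(iv: tuple[int, int], region: tuple[int, int]) -> int:
    b = max(iv[0], region[0])
    e = min(iv[1], region[1])
    return max(0, e - b + 1)


def _cons_candidates(
    hit: RepeatHit, family: TEFamily
) -> list[tuple[int, int]]:
    """Possible placements of a hit's consensus interval on the full consensus.

    A hit against the internal consensus is shifted by one LTR length; a hit
    against the LTR consensus can sit at either terminal repeat, so both
    placements are returned (5' first).  Hits already on the full consensus
    map to themselves.
    """
    b, e = hit.cons_begin, hit.cons_end
    if family.te_class == "LTR" and _is_ltr_part(hit.family):
        off3 = family.consensus_len - family.ltr_len
        return [(b, e), (b + off3, min(e + off3, family.consensus_len))]
    if family.te_class == "LTR" and _is_int_part(hit.family):
        off = family.ltr_len
        return [(b + off, min(e + off, family.consensus_len - family.ltr_len))]
    return [(min(b, family.consensus_len), min(e, family.consensus_len))]


def _consistent(
    copy: TECopy, cand: tuple[int, int], params: MergeParams
) -> bool:
    """Would appending this consensus interval keep the copy colinear?

    Along the genome, consensus coordinates advance for + copies and retreat
    for - copies, with up to ``max_overlap_cons`` nt of tolerated overlap.
    """
    if not copy.cons_intervals:
        return True
    last = copy.cons_intervals[-1]
    if copy.strand == "+":
        return cand[0] >= last[1] + 1 - params.max_overlap_cons
    return cand[1] <= last[0] - 1 + params.max_overlap_cons


def merge_fragments(
    hits: Sequence[RepeatHit],
    library: Sequence[TEFamily],
    params: MergeParams = MergeParams(),
    name_map: Optional[dict[str, str]] = None,
) -> list[TECopy]:
    """Chain repeat fragments into TE copies.

    Two adjacent hits join one copy iff they share contig, mapped family and
    strand, their genomic gap is at most ``params.max_gap``, and their
    consensus coordinates advance consistently with the strand.  Every input
    hit ends up in exactly one copy.  Input must be sorted by
    (contig, start).

    Raises :class:`UnknownFamilyError` if any hit's family (after LTR/internal
    name mapping) is absent from the library.
    """
    fams = {f.name: f for f in library}
    unknown = sorted(
        {
            base_family_name(h.family, name_map)
            for h in hits
            if base_family_name(h.family, name_map) not in fams
        }
    )
    if unknown:
        raise UnknownFamilyError(f"families absent from library: {unknown}")
    last = None
    for h in hits:
        key = (h.contig, h.start)
        if last is not None and key < last:
            raise ValueError("hits must be sorted by (contig, start)")
        last = key

    copies: list[TECopy] = []
    open_copies: dict[tuple[str, str, str], TECopy] = {}
    for hit in hits:
        fam_name = base_family_name(hit.family, name_map)
        family = fams[fam_name]
        key = (hit.contig, fam_name, hit.strand)
        cands = _cons_candidates(hit, family)
        copy = open_copies.get(key)
        joined = False
        if copy is not None and hit.start - copy.end <= params.max_gap:
            order = cands if copy.strand == "+" else cands[::-1]
            for cand in order:
                if _consistent(copy, cand, params):
                    copy.fragments.append(hit)
                    copy.cons_intervals.append(cand)
                    copy.end = max(copy.end, hit.end)
                    joined = True
                    break
        if not joined:
            # a lone LTR placement defaults to the strand's leading terminal
            cand = cands[0] if hit.strand == "+" else cands[-1]
            copy = TECopy(
                family=fam_name,
                contig=hit.contig,
                start=hit.start,
                end=hit.end,
                strand=hit.strand,
                fragments=[hit],
                cons_intervals=[cand],
            )
            copies.append(copy)
            open_copies[key] = copy

    for copy in copies:
        family = fams[copy.family]
        covered = _union_len(copy.cons_intervals)
        copy.completeness = min(1.0, covered / family.consensus_len)
        lengths = np.array([h.end - h.start for h in copy.fragments], dtype=float)
        divs = np.array([h.divergence_pct for h in copy.fragments], dtype=float)
        copy.mean_divergence_pct = float(np.average(divs, weights=lengths))
    copies.sort(key=lambda c: (c.contig, c.start))
    return copies


def classify_copy(
    copy: TECopy, family: TEFamily, params: MergeParams = MergeParams()
) -> TECopy:
    """Set the structural category of a merged copy (in place; also returned).

    Non-LTR classes are full-length iff completeness reaches the threshold.
    LTR-class copies additionally need both terminal repeats and internal
    sequence present; copies covering only LTR sequence are solo-LTRs;
    everything else is a fragment.
    """
    thr = params.full_len_threshold
    if family.te_class != "LTR":
        copy.category = "full_length" if copy.completeness >= thr else "fragment"
        return copy

    L, ltr = family.consensus_len, family.ltr_len
    r5 = (1, ltr)
    r3 = (L - ltr + 1, L)
    interior = (ltr + 1, L - ltr)
    cov5 = sum(_overlap_1based(iv, r5) for iv in copy.cons_intervals)
    cov3 = sum(_overlap_1based(iv, r3) for iv in copy.cons_intervals)
    cov_int = _union_len(
        [
            (max(iv[0], interior[0]), min(iv[1], interior[1]))
            for iv in copy.cons_intervals
            if _overlap_1based(iv, interior) > 0
        ]
    )
    interior_len = max(1, interior[1] - interior[0] + 1)
    copy.has_5ltr = cov5 >= params.ltr_region_cov_min * ltr
    copy.has_3ltr = cov3 >= params.ltr_region_cov_min * ltr
    copy.has_internal = cov_int >= params.ltr_region_cov_min * interior_len

    if (
        copy.completeness >= thr
        and copy.has_5ltr
        and copy.has_3ltr
        and copy.has_internal
    ):
        copy.category = "full_length"
    elif cov_int <= params.max_overlap_cons and (cov5 > 0 or cov3 > 0):
        copy.category = "solo_LTR"
    else:
        copy.category = "fragment"
    return copy


def classify_copies(
    copies: Iterable[TECopy],
    library: Sequence[TEFamily],
    params: MergeParams = MergeParams(),
) -> list[TECopy]:
    """Classify every copy against its library family."""
    fams = {f.name: f for f in library}
    return [classify_copy(c, fams[c.family], params) for c in copies]


@dataclass
class CompositionStats:
    """Locus composition relative to the cluster's transcription strand."""

    n_copies: int
    pct_antisense: float
    pct_antisense_that_are_LTR: Optional[float]
    per_family: pd.DataFrame  # family, te_class, n_copies, full_length, solo_LTR


def composition_stats(
    copies: Sequence[TECopy],
    library: Sequence[TEFamily],
    cluster_strand: str = "+",
) -> CompositionStats:
    """Antisense/LTR composition of a locus and per-family copy numbers.

    A copy is antisense iff its strand differs from ``cluster_strand`` (the
    direction of cluster transcription).  The second percentage — how many of
    the antisense copies belong to LTR-class families — is reported as None
    when there are no antisense copies.
    """
    if not copies:
        raise ValueError("composition undefined for an empty copy list")
    fams = {f.name: f for f in library}
    anti = [c for c in copies if c.strand != cluster_strand]
    pct_anti = 100.0 * len(anti) / len(copies)
    if anti:
        n_ltr = sum(1 for c in anti if fams[c.family].te_class == "LTR")
        pct_anti_ltr = 100.0 * n_ltr / len(anti)
    else:
        pct_anti_ltr = None
    rows = []
    for name in sorted({c.family for c in copies}):
        group = [c for c in copies if c.family == name]
        rows.append(
            {
                "family": name,
                "te_class": fams[name].te_class,
                "n_copies": len(group),
                "full_length": sum(1 for c in group if c.category == "full_length"),
                "solo_LTR": sum(1 for c in group if c.category == "solo_LTR"),
            }
        )
    return CompositionStats(
        n_copies=len(copies),
        pct_antisense=pct_anti,
        pct_antisense_that_are_LTR=pct_anti_ltr,
        per_family=pd.DataFrame(rows),
    )


def window_enrichment(
    items: Iterable,
    contig_len: int,
    family_filter: Optional[set[str]] = None,
    window: int = 100_000,
) -> np.ndarray:
    """Count elements per tiling window ``[k*w, (k+1)*w)`` by start coordinate.

    ``items`` may be TE copies or raw repeat hits — anything with ``start``
    and ``family`` attributes.  The output covers every window (the last may
    be short), including zeros.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n_windows = int(np.ceil(contig_len / window))
    counts = np.zeros(n_windows, dtype=int)
    for it in items:
        if family_filter is not None and it.family not in family_filter:
            continue
        idx = it.start // window
        if 0 <= idx < n_windows:
            counts[idx] += 1
    return counts


@dataclass
class TrapModelReport:
    """Families consistent with the transposon-trap model of the locus.

    ``multicopy_antisense``: families with at least two full-length antisense
    copies (recent repeated trapping).  ``recent_fragment``: families with at
    least one full-length copy anywhere plus an antisense fragment less than
    ``max_div`` percent diverged from the consensus (recently degraded trap
    copies).
    """

    multicopy_antisense: set[str]
    recent_fragment: set[str]
    max_div: float


def read_family_table(path) -> list[TEFamily]:
    """Family metadata table: TSV with columns name, te_class, consensus_len, ltr_len."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "te_class", "consensus_len"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TEFamily(
            name=str(r["name"]),
            te_class=str(r["te_class"]),
            consensus_len=int(r["consensus_len"]),
            ltr_len=int(r.get("ltr_len", 0) or 0),
        )
        for _, r in df.iterrows()
    ]


def write_family_table(library: Sequence[TEFamily], path) -> None:
    pd.DataFrame(
        [
            {
                "name": f.name,
                "te_class": f.te_class,
                "consensus_len": f.consensus_len,
                "ltr_len": f.ltr_len,
            }
            for f in library
        ]
    ).to_csv(path, sep="\t", index=False)


def copies_to_frame(copies: Sequence[TECopy]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": c.family,
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "category": c.category,
                "completeness": round(c.completeness, 4),
                "mean_divergence_pct": round(c.mean_divergence_pct, 3),
                "n_fragments": len(c.fragments),
            }
            for c in copies
        ]
    )


def read_copies_tsv(path) -> list[TECopy]:
    """Read a TECopy table written by :func:`copies_to_frame`.

    Fragment-level detail is not round-tripped; the returned copies carry
    empty fragment lists, which is sufficient for comparative analyses.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TECopy(
            family=str(r["family"]),
            contig=str(r["contig"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
            fragments=[],
            cons_intervals=[],
            completeness=float(r["completeness"]),
            category=str(r["category"]),
            mean_divergence_pct=float(r["mean_divergence_pct"]),
        )
        for _, r in df.iterrows()
    ]


def trap_model_report(
    copies: Sequence[TECopy], cluster_strand: str = "+", max_div: float = 10.0
) -> TrapModelReport:
    fams = sorted({c.family for c in copies})
    multicopy = set()
    recent = set()
    for name in fams:
        group = [c for c in copies if c.family == name]
        fl = [c for c in group if c.category == "full_length"]
        fl_anti = [c for c in fl if c.strand != cluster_strand]
        if len(fl_anti) >= 2:
            multicopy.add(name)
        frag_anti_recent = [
            c
            for c in group
            if c.category == "fragment"
            and c.strand != cluster_strand
            and c.mean_divergence_pct < max_div
        ]
        if fl and frag_anti_recent:
            recent.add(name)
    return TrapModelReport(multicopy, recent, max_div)
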