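"""Weighted small-RNA counting, length histograms, and ping-pong detection.

Multimapping reads are handled by fractional (weighted) counting: a read
placed at ``n`` genomic locations contributes ``1/n`` at each, so its total
mass across placements is exactly 1.  The alternative ``unique`` mode keeps
only single-placement reads at weight 1.

Ping-pong amplification leaves sense/antisense piRNA pairs whose 5' ends
overlap by exactly 10 nt, with an adenine bias at position 10 of the
responder.  For every + strand 5'-end stack we count - strand 5' ends at each
offset 1..20 and score how exceptional the 10-nt offset is against the 19
neighbouring offsets (a local, scale-free mid-rank statistic in [0, 1]).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from pirnakit.io import SmallRNARecord

N_OFFSETS = 20
PP_OFFSET = 10  # 5' ends offset by 10 nt <=> first 10 nt overlap


@dataclass(frozen=True)
class CountMode:
    """How multimapping reads contribute to counts.

    ``weighted``: every record carries weight ``1/n_hits``.
    ``unique``: records with ``n_hits > 1`` are dropped; the rest weigh 1.
    """

    mode: str = "weighted"

    def __post_init__(self):
        if self.mode not in ("weighted", "unique"):
            raise ValueError(f"unknown count mode {self.mode!r}")

    def weight(self, record: SmallRNARecord) -> float:
        if self.mode == "unique":
            return 1.0 if record.n_hits == 1 else 0.0
        return 1.0 / record.n_hits


WEIGHTED = CountMode("weighted")
UNIQUE = CountMode("unique")


@dataclass
class PingPongParams:
    score_threshold: float = 0.9
    count_mode: CountMode = WEIGHTED

    def __post_init__(self):
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")


@dataclass
class PingPongSite:
    """A + strand 5'-end stack with its - strand offset profile.

    ``c_offsets[o]`` (o = 1..20) is the weighted - strand 5'-end count at
    genomic coordinate ``pos + o - 1``; offset 10 is the ping-pong partner
    position.  ``score`` is the mid-rank of the offset-10 count among the 19
    other offsets, in [0, 1].  ``a10_fraction`` is the weighted fraction of
    partner reads with adenine at their 10th position (None when no partner
    reads carry a tenth base).
    """

    contig: str
    pos: int
    h_plus: float
    c_offsets: dict[int, float]
    score: float
    a10_fraction: Optional[float]


def feature_counts(
    records: Iterable[SmallRNARecord],
    regions: Sequence[tuple[str, int, int]],
    mode: CountMode = WEIGHTED,
):
    """Per-region, per-strand weighted counts of small-RNA 5' ends.

    ``regions`` are (contig, start, end) half-open intervals and must not
    overlap one another.  A record is assigned to the region containing its
    5'-end coordinate; mass falling outside every region is reported under
    the key ``None``.  Returns ``{region_or_None: {"+": w, "-": w}}``.
    """
    by_contig: dict[str, list[tuple[int, int, tuple]]] = defaultdict(list)
    for reg in regions:
        by_contig[reg[0]].append((reg[1], reg[2], reg))
    for contig, ivs in by_contig.items():
        ivs.sort()
        for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping regions on {contig}: [{s1},{e1}) and [{s2},{e2})"
                )
    starts = {c: np.array([iv[0] for iv in ivs]) for c, ivs in by_contig.items()}

    counts: dict = {reg: {"+": 0.0, "-": 0.0} for reg in regions}
    counts[None] = {"+": 0.0, "-": 0.0}
    for rec in records:
        w = mode.weight(rec)
        if w == 0.0:
            continue
        target = None
        ivs = by_contig.get(rec.contig)
        if ivs:
            idx = int(np.searchsorted(starts[rec.contig], rec.five_prime_pos, "right")) - 1
            if idx >= 0:
                s, e, reg = ivs[idx]
                if rec.five_prime_pos < e:
                    target = reg
        counts[target][rec.strand] += w
    return counts


def length_histogram(
    records: Sequence[SmallRNARecord], mode: CountMode = WEIGHTED
) -> tuple[dict[int, float], int]:
    """Weighted read-length histogram and the modal length (smallest on ties)."""
    if not records:
        raise ValueError("length histogram undefined for empty input")
    hist: dict[int, float] = defaultdict(float)
    for rec in records:
        hist[rec.length] += mode.weight(rec)
    best = max(hist.values())
    modal = min(l for l, c in hist.items() if c == best)
    return dict(sorted(hist.items())), modal


def _stack_weights(
    records: Iterable[SmallRNARecord], contig: str, mode: CountMode
) -> tuple[dict[int, float], dict[int, float], dict[int, float]]:
    """Weighted 5'-end stacks per strand, plus weighted 10A mass on - stacks."""
    plus: dict[int, float] = defaultdict(float)
    minus: dict[int, float] = defaultdict(float)
    minus_a10: dict[int, float] = defaultdict(float)
    for rec in records:
        if rec.contig != contig:
            continue
        w = mode.weight(rec)
        if w == 0.0:
            continue
        if rec.strand == "+":
            plus[rec.five_prime_pos] += w
        else:
            minus[rec.five_prime_pos] += w
            if rec.tenth_nt == "A":
                minus_a10[rec.five_prime_pos] += w
    return plus, minus, minus_a10


def midrank_score(c10: float, background: Sequence[float]) -> float:
    """Mid-rank of the offset-10 count among its local background, in [0, 1]."""
    below = sum(1 for c in background if c < c10)
    ties = sum(1 for c in background if c == c10)
    score = (below + 0.5 * ties) / len(background)
    return min(1.0, max(0.0, score))


def pingpong_scores(
    records: Sequence[SmallRNARecord],
    contig: str,
    params: PingPongParams = PingPongParams(),
) -> list[PingPongSite]:
    """Score every + strand 5'-end stack for a 10-nt ping-pong offset.

    For a + stack at position ``p``, the - strand 5'-end count at ``p + o - 1``
    is taken for offsets ``o`` in 1..20 (offset 10 means the two 5' ends
    overlap by exactly 10 nt).  The score is the mid-rank of the offset-10
    count among the other 19 offsets — 1.0 when the partner stack towers over
    every neighbouring offset, 0.5 under a flat profile.  Sites are emitted
    only when both the + stack and its offset-10 partner are non-empty;
    results are sorted by position.
    """
    plus, minus, minus_a10 = _stack_weights(records, contig, params.count_mode)
    sites = []
    for pos in sorted(plus):
        h = plus[pos]
        if h <= 0:
            continue
        c = {o: minus.get(pos + o - 1, 0.0) for o in range(1, N_OFFSETS + 1)}
        if c[PP_OFFSET] <= 0:
            continue
        background = [c[o] for o in c if o != PP_OFFSET]
        score = midrank_score(c[PP_OFFSET], background)
        partner_pos = pos + PP_OFFSET - 1
        partner_total = minus.get(partner_pos, 0.0)
        a10 = minus_a10.get(partner_pos, 0.0) / partner_total if partner_total else None
        sites.append(
            PingPongSite(
                contig=contig,
                pos=pos,
                h_plus=h,
                c_offsets=c,
                score=score,
                a10_fraction=a10,
            )
        )
    return sites


def region_signal_fraction(
    sites: Sequence[PingPongSite],
    region: tuple[int, int],
    threshold: float = 0.9,
) -> Optional[float]:
    """Fraction of high-scoring ping-pong sites that fall inside a region.

    High-scoring means ``score >= threshold``; the denominator is every
    high-scoring site on the contig.  Returns None when there are none.
    """
    contigs = {s.contig for s in sites}
    if len(contigs) > 1:
        raise ValueError(f"sites span multiple contigs: {sorted(contigs)}")
    high = [s for s in sites if s.score >= threshold]
    if not high:
        return None
    start, end = region
    inside = sum(1 for s in high if start <= s.pos < end)
    return inside / len(high)
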