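"""piRNA cluster calling, promoter-anchored locus delimitation, and assembly QC.

Cluster calling follows the proTRAC-style recipe: slide a window over each
contig, test its weighted 5'-end count against a uniform-placement Poisson
null, merge significant windows, then screen the merged loci with four
criteria — minimum size, 1U/10A base composition, read-sequence diversity
(the top 1% of distinct sequences must not dominate the locus), and a minimum
main-strand share.  Loci passing a high main-strand share are classified as
uni-strand clusters, the rest as dual-strand.

Assembly QC compares per-window coverage and soft-clip rates inside a cluster
against the 99% quantiles of the same statistics over benchmark single-copy
genes (a BUSCO-style set): windows exceeding either quantile are flagged as
potential misassemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from pirnakit.io import GenomeSequence, SmallRNARecord, revcomp
from pirnakit.srna import CountMode, WEIGHTED


@dataclass
class ClusterParams:
    """Thresholds for proTRAC-style cluster calling.

    min_size
        Minimum merged-locus length in nt (default 1 kb).
    density_p
        Poisson upper-tail p-value a window must reach to seed a cluster.
    u10a_min
        Minimum weighted fraction of reads with 1U (first base T) or 10A.
    top1_max_share
        Reject loci where the top 1% of distinct read sequences carry more
        than this share of the weighted count.
    mainstrand_min
        Minimum weighted fraction of reads on the majority strand.
    uni_strand_cutoff
        Main-strand fraction at or above which a locus is called uni-strand.
    window, step
        Sliding-window geometry for the density scan.
    multiple_testing
        ``"bonferroni"`` (default) requires the Poisson tail probability
        times the number of scanned windows to stay below ``density_p``, so
        ``density_p`` bounds the expected number of false seed windows per
        scan; ``"none"`` applies ``density_p`` to each window's raw tail
        probability.
    """

    min_size: int = 1000
    density_p: float = 0.07
    u10a_min: float = 0.33
    top1_max_share: float = 0.90
    mainstrand_min: float = 0.25
    uni_strand_cutoff: float = 0.75
    window: int = 1000
    step: int = 500
    count_mode: CountMode = WEIGHTED
    multiple_testing: str = "bonferroni"

    def __post_init__(self):
        for name in ("density_p", "u10a_min", "top1_max_share",
                     "mainstrand_min", "uni_strand_cutoff"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if self.min_size < 1 or self.window < 1 or self.step < 1:
            raise ValueError("sizes must be positive")
        if self.multiple_testing not in ("bonferroni", "none"):
            raise ValueError("multiple_testing must be 'bonferroni' or 'none'")


@dataclass
class ClusterCall:
    """A candidate piRNA cluster with its per-criterion outcome."""

    contig: str
    start: int
    end: int
    norm_reads: float
    mainstrand_frac: float
    u10a_frac: float
    top1_share: float
    classification: str  # uni | dual
    passed: bool
    flags: dict[str, bool]  # min_size, u10a, top1, mainstrand

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_counts(
    positions: np.ndarray, weights: np.ndarray, contig_len: int, window: int, step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted 5'-end count for each sliding window start."""
    starts = np.arange(0, max(contig_len - window, 0) + step, step)
    if len(starts) == 0:
        starts = np.array([0])
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    cum = np.concatenate([[0.0], np.cumsum(weights[order])])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, np.minimum(starts + window, contig_len), side="left")
    return starts, cum[hi] - cum[lo]


def call_clusters(
    records: Sequence[SmallRNARecord],
    contig_lengths: dict[str, int],
    params: ClusterParams = ClusterParams(),
) -> list[ClusterCall]:
    """Call candidate piRNA clusters from small-RNA 5'-end density.

    Returns every merged candidate locus with per-criterion flags; loci
    meeting all criteria have ``passed=True``.  An empty record set yields an
    empty list.
    """
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig} has non-positive length")
    if not records:
        return []
    mode = params.count_mode
    total_w = sum(mode.weight(r) for r in records)
    if total_w == 0:
        return []
    L_total = sum(contig_lengths.values())
    lam = total_w * params.window / L_total
    n_windows_total = sum(
        int(np.ceil(max(length - params.window, 0) / params.step)) + 1
        for length in contig_lengths.values()
    )
    correction = n_windows_total if params.multiple_testing == "bonferroni" else 1

    calls = []
    for contig, contig_len in contig_lengths.items():
        recs = [r for r in records if r.contig == contig]
        if not recs:
            continue
        positions = np.array([r.five_prime_pos for r in recs])
        weights = np.array([mode.weight(r) for r in recs])
        starts, counts = _window_counts(
            positions, weights, contig_len, params.window, params.step
        )
        # Poisson upper tail P(X >= k) under uniform placement, corrected for
        # the number of windows scanned
        pvals = stats.poisson.sf(np.ceil(counts) - 1, lam) * correction
        sig = (pvals <= params.density_p) & (counts > 0)
        # merge overlapping significant windows into candidate loci
        loci = []
        for s in starts[sig]:
            e = min(s + params.window, contig_len)
            if loci and s <= loci[-1][1]:
                loci[-1][1] = max(loci[-1][1], e)
            else:
                loci.append([int(s), int(e)])
        for s, e in loci:
            calls.append(_screen_locus(recs, contig, s, e, params))
    return calls


def _screen_locus(
    recs: Sequence[SmallRNARecord], contig: str, start: int, end: int,
    params: ClusterParams,
) -> ClusterCall:
    mode = params.count_mode
    inside = [r for r in recs if start <= r.five_prime_pos < end]
    w = np.array([mode.weight(r) for r in inside])
    total = float(w.sum())

    u10a = sum(
        mode.weight(r)
        for r in inside
        if r.first_nt in ("T", "U") or r.tenth_nt == "A"
    )
    u10a_frac = u10a / total if total else 0.0

    plus = sum(mode.weight(r) for r in inside if r.strand == "+")
    main = max(plus, total - plus)
    mainstrand_frac = main / total if total else 0.0

    # weighted count per distinct read sequence (read_id as fallback identity)
    seq_w: dict[str, float] = {}
    for r in inside:
        key = r.sequence or r.read_id
        seq_w[key] = seq_w.get(key, 0.0) + mode.weight(r)
    if seq_w:
        top_n = int(np.ceil(0.01 * len(seq_w)))
        top = sorted(seq_w.values(), reverse=True)[:top_n]
        top1_share = sum(top) / total
    else:
        top1_share = 0.0

    flags = {
        "min_size": end - start >= params.min_size,
        "u10a": u10a_frac >= params.u10a_min,
        "top1": top1_share <= params.top1_max_share,
        "mainstrand": mainstrand_frac >= params.mainstrand_min,
    }
    return ClusterCall(
        contig=contig,
        start=start,
        end=end,
        norm_reads=total,
        mainstrand_frac=mainstrand_frac,
        u10a_frac=u10a_frac,
        top1_share=top1_share,
        classification=(
            "uni" if mainstrand_frac >= params.uni_strand_cutoff else "dual"
        ),
        passed=all(flags.values()),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# promoter anchoring and locus delimitation


@dataclass(frozen=True)
class AnchorHit:
    position: int
    orientation: str  # + | -
    mismatches: int


def _mismatch_scan(genome: bytes, pattern: bytes) -> np.ndarray:
    g = np.frombuffer(genome, dtype=np.uint8)
    p = np.frombuffer(pattern, dtype=np.uint8)
    if len(g) < len(p):
        return np.zeros(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(g, len(p))
    return (windows != p).sum(axis=1)


def find_anchor(
    genome: GenomeSequence, promoter_seq: str, max_mismatch: int = 0
) -> list[AnchorHit]:
    """Exhaustively locate a promoter sequence in a contig.

    Scans both the given sequence and its reverse complement for ungapped
    matches with at most ``max_mismatch`` mismatches.  Hits are returned
    sorted by position.
    """
    if len(promoter_seq) < 20:
        raise ValueError("promoter_seq must be at least 20 nt")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    g = genome.sequence.upper().encode()
    hits = []
    for orient, pat in (("+", promoter_seq.upper()), ("-", revcomp(promoter_seq.upper()))):
        mm = _mismatch_scan(g, pat.encode())
        for pos in np.nonzero(mm <= max_mismatch)[0]:
            hits.append(AnchorHit(int(pos), orient, int(mm[pos])))
    hits.sort(key=lambda h: (h.position, h.orientation))
    return hits


@dataclass
class LocusParams:
    min_window_count: int = 3
    max_gap_windows: int = 0
    window: int = 100_000


@dataclass
class LocusInterval:
    start: int
    end: int
    stop_reason: str  # below_threshold | contig_end


def delimit_locus(
    anchor: AnchorHit, enrichment: np.ndarray, params: LocusParams
) -> LocusInterval:
    """Extend a locus from a promoter anchor along the enrichment profile.

    Starting at the anchor's window, walk in the direction of transcription
    (increasing coordinates for a + anchor) while windows hold at least
    ``min_window_count`` elements, tolerating up to ``max_gap_windows``
    consecutive windows below threshold.  The locus always includes the
    anchor's window and ends at the last qualifying window; the stopping
    reason distinguishes running off the contig from falling below threshold.
    """
    n = len(enrichment)
    w = params.window
    w0 = anchor.position // w
    if not (0 <= w0 < n):
        raise ValueError("anchor outside the enrichment profile")
    direction = 1 if anchor.orientation == "+" else -1
    last_good = w0
    gap = 0
    i = w0
    reason = "contig_end"
    while True:
        j = i + direction
        if not (0 <= j < n):
            break
        if enrichment[j] >= params.min_window_count:
            last_good = j
            gap = 0
        else:
            gap += 1
            if gap > params.max_gap_windows:
                reason = "below_threshold"
                break
        i = j
    lo, hi = sorted((w0, last_good))
    return LocusInterval(start=lo * w, end=(hi + 1) * w, stop_reason=reason)


# ---------------------------------------------------------------------------
# coverage / soft-clip assembly QC


@dataclass
class QCProfile:
    """Per-window coverage and soft-clip profile with benchmark quantiles.

    The benchmark quantiles are the 99% quantiles of mean coverage and
    soft-clip rate over windows covering benchmark single-copy genes;
    at least 20 benchmark windows are required for a stable quantile.
    """

    contig: str
    window: int
    window_starts: np.ndarray
    coverage: np.ndarray
    clip_rate: np.ndarray
    benchmark_cov_q99: float
    benchmark_clip_q99: float

    @classmethod
    def from_benchmark(
        cls,
        contig: str,
        window: int,
        window_starts: Sequence[int],
        coverage: Sequence[float],
        clip_rate: Sequence[float],
        benchmark_cov: Sequence[float],
        benchmark_clip: Sequence[float],
    ) -> "QCProfile":
        if len(benchmark_cov) < 20 or len(benchmark_clip) < 20:
            raise ValueError("need >= 20 benchmark windows for a stable quantile")
        clip = np.asarray(clip_rate, dtype=float)
        if clip.size and (clip.min() < 0 or clip.max() > 1):
            raise ValueError("clip rates must be in [0, 1]")
        return cls(
            contig=contig,
            window=window,
            window_starts=np.asarray(window_starts, dtype=int),
            coverage=np.asarray(coverage, dtype=float),
            clip_rate=clip,
            benchmark_cov_q99=float(np.quantile(benchmark_cov, 0.99)),
            benchmark_clip_q99=float(np.quantile(benchmark_clip, 0.99)),
        )


@dataclass(frozen=True)
class QCFlag:
    window_start: int
    metric: str  # coverage | soft_clip
    value: float
    quantile: float


def qc_flag(profile: QCProfile, target_region: tuple[int, int]) -> list[QCFlag]:
    """Flag windows in a target region exceeding the benchmark 99% quantiles.

    Each flag names the violated quantile; a window can be flagged for
    coverage, soft clipping, or both.
    """
    start, end = target_region
    flags = []
    for ws, cov, clip in zip(
        profile.window_starts, profile.coverage, profile.clip_rate
    ):
        if not (start <= ws < end):
            continue
        if cov > profile.benchmark_cov_q99:
            flags.append(QCFlag(int(ws), "coverage", float(cov), profile.benchmark_cov_q99))
        if clip > profile.benchmark_clip_q99:
            flags.append(
                QCFlag(int(ws), "soft_clip", float(clip), profile.benchmark_clip_q99)
            )
    return flags
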