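"""Seeded generators for genomes, TE annotation panels, small-RNA reads and QC
profiles, with recorded ground truth.

Every generator is driven by one :class:`SimConfig` and is fully deterministic
given its seed.  The dials default to the study conditions the rest of the
package is meant to recover: a uni-strand locus with 79% antisense insertions
of which 85% are LTR-class, a genotype panel with 54% private insertion
columns, small-RNA reads with modal length 26 nt and 1U/10A biases, fractional
1/n multimapper weighting, and planted 10-nt-offset ping-pong pairs.

The background sequence is i.i.d. uniform A/C/G/T; no attempt is made to model
heterochromatin base composition, sequencing error or read quality.  Truth is
recorded for every planted feature so recovery tests close the loop without
depending on unspecified distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from pirnakit.clusters import QCProfile
from pirnakit.io import GenomeSequence, RepeatHit, SmallRNARecord, revcomp
from pirnakit.te import TEFamily

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """All dials of the synthetic-data generators.

    Fractions are probabilities in [0, 1]; ``sharing_probs`` maps a sharing
    count k (1..panel_size) to the probability that an insertion column is
    present in exactly k genotypes and must sum to 1.  ``seed`` fixes every
    downstream draw.
    """

    seed: int = 0
    # locus / genome
    genome_len: int = 1_200_000
    contig_id: str = "sim_contig"
    # planted insertions are kept at least this far apart in the background,
    # beyond the default merge gap, so copies stay separable after annotation
    min_insertion_spacing: int = 5100
    n_families: int = 30
    ltr_fraction: float = 0.6
    consensus_len_range: tuple[int, int] = (3000, 7000)
    ltr_len: int = 300
    n_insertions: int = 200
    antisense_prob: float = 0.79
    antisense_ltr_prob: float = 0.85
    full_length_prob: float = 0.30
    solo_ltr_prob: float = 0.10
    divergence_rate: float = 0.05
    # genotype panel
    panel_size: int = 7
    sharing_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.54, 2: 0.05, 3: 0.05, 4: 0.05,
                                 5: 0.05, 6: 0.05, 7: 0.21}
    )
    downgrade_prob: float = 0.30
    # small RNA
    n_reads: int = 15_000
    background_frac: float = 2 / 3
    read_len_mode: int = 26
    u1_prob: float = 0.75
    a10_prob: float = 0.75
    pingpong_pair_prob: float = 0.0
    n_pingpong_sites: int = 20
    mainstrand_frac: float = 0.90
    multimap_max: int = 50
    cluster_len: int = 5000
    # QC
    coverage_mean: float = 30.0
    clip_rate: float = 0.02
    qc_window: int = 10_000
    n_benchmark_windows: int = 100
    n_anomalies: int = 0

    def __post_init__(self):
        for name in (
            "ltr_fraction", "antisense_prob", "antisense_ltr_prob",
            "full_length_prob", "solo_ltr_prob", "divergence_rate",
            "background_frac", "u1_prob", "a10_prob", "pingpong_pair_prob",
            "mainstrand_frac", "clip_rate", "downgrade_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sharing_probs:
            if abs(sum(self.sharing_probs.values()) - 1.0) > 1e-9:
                raise ValueError("sharing_probs must sum to 1")
            bad = [k for k in self.sharing_probs if not 1 <= k <= self.panel_size]
            if bad:
                raise ValueError(
                    f"sharing_probs keys outside 1..{self.panel_size}: {bad}"
                )


@dataclass
class PlantedInsertion:
    insertion_id: int
    family: str
    te_class: str
    start: int  # final genomic coordinates, 0-based half-open
    end: int
    strand: str
    category: str  # full_length | solo_LTR | fragment
    divergence_pct: float


@dataclass
class PlantedColumn:
    column_id: str
    family: str
    states: dict[str, str]  # genotype -> category or "absent"

    @property
    def n_present(self) -> int:
        return sum(1 for s in self.states.values() if s != "absent")


@dataclass
class TruthSet:
    """Ground truth for one simulation; every emitted record traces here."""

    library: list[TEFamily] = field(default_factory=list)
    contig_id: str = "sim_contig"
    genome_len: int = 0
    insertions: list[PlantedInsertion] = field(default_factory=list)
    panel_columns: list[PlantedColumn] = field(default_factory=list)
    cluster_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    pingpong_positions: list[int] = field(default_factory=list)
    qc_anomalies: list[int] = field(default_factory=list)

    def family_copy_numbers(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ins in self.insertions:
            out[ins.family] = out.get(ins.family, 0) + 1
        return out


# ---------------------------------------------------------------------------
# library and sequence helpers


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _NT[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> tuple[np.ndarray, float]:
    """Substitute bases at the given per-base rate; returns realized percent."""
    seq = seq.copy()
    mask = rng.random(len(seq)) < rate
    n_mut = int(mask.sum())
    if n_mut:
        # draw a different base for every mutated position
        shifts = rng.integers(1, 4, size=n_mut)
        idx = np.nonzero(mask)[0]
        cur = np.searchsorted(_NT, seq[idx])
        seq[idx] = _NT[(cur + shifts) % 4]
    return seq, 100.0 * n_mut / max(len(seq), 1)


def make_library(config: SimConfig) -> list[TEFamily]:
    """Random TE consensus library: LTR-class families first, then LINE/DNA."""
    rng = _rng(config, 0)
    n_ltr = int(round(config.n_families * config.ltr_fraction))
    families = []
    for i in range(config.n_families):
        lo, hi = config.consensus_len_range
        length = int(rng.integers(lo, hi + 1))
        is_ltr = i < n_ltr
        te_class = "LTR" if is_ltr else ("LINE" if i % 2 == 0 else "DNA")
        seq = "".join(chr(b) for b in _random_seq(rng, length))
        families.append(
            TEFamily(
                name=f"FAM{i + 1}",
                te_class=te_class,
                consensus_len=length,
                ltr_len=config.ltr_len if is_ltr else 0,
                consensus_seq=seq,
            )
        )
    return families


# ---------------------------------------------------------------------------
# locus simulation


def _emit_hits(
    family: TEFamily,
    cons_lo: int,
    cons_hi: int,
    genome_start: int,
    strand: str,
    div: float,
    linkage: int,
) -> list[RepeatHit]:
    """Emit RepeatMasker-style rows for a consensus interval [cons_lo, cons_hi]
    (1-based inclusive on the full consensus).

    LTR families are split at the LTR/internal boundaries and reported
    against the sub-consensus entries (FAM_LTR, FAM_I), the way a repeat
    library with separate LTR and internal consensi annotates them.  For -
    strand copies the genomic order of the pieces is reversed (the genome
    runs 3'->5' along the consensus).
    """
    pieces: list[tuple[str, int, int, int]] = []  # (name, sub_b, sub_e, length)
    L, ltr = family.consensus_len, family.ltr_len
    if family.te_class == "LTR":
        bounds = [
            ("5ltr", 1, ltr),
            ("int", ltr + 1, L - ltr),
            ("3ltr", L - ltr + 1, L),
        ]
        for kind, rb, re_ in bounds:
            b = max(cons_lo, rb)
            e = min(cons_hi, re_)
            if b > e:
                continue
            if kind == "int":
                name = f"{family.name}_I"
                sub_b, sub_e = b - ltr, e - ltr
            else:
                name = f"{family.name}_LTR"
                off = 0 if kind == "5ltr" else L - ltr
                sub_b, sub_e = b - off, e - off
            pieces.append((name, sub_b, sub_e, e - b + 1))
    else:
        pieces.append((family.name, cons_lo, cons_hi, cons_hi - cons_lo + 1))

    if strand == "-":
        pieces = pieces[::-1]
    hits = []
    g = genome_start
    for name, sub_b, sub_e, length in pieces:
        hits.append(
            RepeatHit(
                contig="",  # filled by caller
                start=g,
                end=g + length,
                strand=strand,
                family=name,
                cons_begin=sub_b,
                cons_end=sub_e,
                divergence_pct=round(div, 2),
                linkage_id=linkage,
            )
        )
        g += length
    return hits


def _draw_insertion(
    rng: np.random.Generator, config: SimConfig, library: list[TEFamily]
) -> tuple[TEFamily, str, str, int, int]:
    """Draw (family, strand, category, cons_lo, cons_hi) for one insertion."""
    ltr_fams = [f for f in library if f.te_class == "LTR"]
    other_fams = [f for f in library if f.te_class != "LTR"]
    antisense = rng.random() < config.antisense_prob
    strand = "-" if antisense else "+"
    if antisense and ltr_fams and other_fams:
        pool = ltr_fams if rng.random() < config.antisense_ltr_prob else other_fams
    else:
        pool = library
    family = pool[rng.integers(0, len(pool))]

    u = rng.random()
    if u < config.full_length_prob:
        category = "full_length"
        cons_lo, cons_hi = 1, family.consensus_len
    elif (
        family.te_class == "LTR"
        and u < config.full_length_prob + config.solo_ltr_prob
    ):
        category = "solo_LTR"
        cons_lo, cons_hi = 1, family.ltr_len
    else:
        category = "fragment"
        # contiguous sub-interval, 20-65% of the consensus: always below the
        # full-length threshold and always reaching internal sequence
        frac = rng.uniform(0.20, 0.65)
        length = max(1, int(frac * family.consensus_len))
        start = int(rng.integers(1, family.consensus_len - length + 2))
        cons_lo, cons_hi = start, start + length - 1
    return family, strand, category, cons_lo, cons_hi


def simulate_locus(
    config: SimConfig,
) -> tuple[GenomeSequence, list[RepeatHit], TruthSet]:
    """Simulate one locus: background sequence with planted TE insertions.

    Insertions are spliced into the background at uniformly drawn,
    well-separated points; each is independently antisense with
    ``antisense_prob``, full-length with ``full_length_prob``, else solo-LTR
    (LTR families) or a truncated fragment, and mutated at
    ``divergence_rate``.  Emitted repeat rows mimic RepeatMasker annotation:
    full-length LTR copies appear as LTR + internal + LTR rows against the
    sub-consensus entries.  One cluster interval of ``cluster_len`` nt is
    recorded in the truth for the small-RNA generator.
    """
    rng = _rng(config, 1)
    library = make_library(config)
    spacing = config.min_insertion_spacing
    slots = config.genome_len // spacing - 1
    if config.n_insertions > max(slots, 0):
        raise ValueError(
            f"{config.n_insertions} insertions exceed the capacity of a "
            f"{config.genome_len} nt background at {spacing} nt spacing"
        )
    background = _random_seq(rng, config.genome_len)
    if config.n_insertions > 0:
        points = np.sort(
            (rng.choice(slots, size=config.n_insertions, replace=False) + 1)
            * spacing
        )
    else:
        points = np.array([], dtype=int)

    pieces: list[np.ndarray] = []
    hits: list[RepeatHit] = []
    insertions: list[PlantedInsertion] = []
    prev = 0
    offset = 0  # accumulated inserted length
    for ins_id, point in enumerate(points):
        pieces.append(background[prev:point])
        family, strand, category, cons_lo, cons_hi = _draw_insertion(
            rng, config, library
        )
        cons = np.frombuffer(family.consensus_seq.encode(), dtype=np.uint8)
        insert = cons[cons_lo - 1 : cons_hi]
        insert, realized_div = _mutate(rng, insert, config.divergence_rate)
        if strand == "-":
            insert_seq = np.frombuffer(
                revcomp(insert.tobytes().decode()).encode(), dtype=np.uint8
            )
        else:
            insert_seq = insert
        g_start = int(point) + offset
        pieces.append(insert_seq)
        for h in _emit_hits(
            family, cons_lo, cons_hi, g_start, strand, realized_div, ins_id + 1
        ):
            h.contig = config.contig_id
            hits.append(h)
        insertions.append(
            PlantedInsertion(
                insertion_id=ins_id,
                family=family.name,
                te_class=family.te_class,
                start=g_start,
                end=g_start + len(insert_seq),
                strand=strand,
                category=category,
                divergence_pct=realized_div,
            )
        )
        offset += len(insert_seq)
        prev = point
    pieces.append(background[prev:])
    seq = np.concatenate(pieces) if pieces else background
    genome = GenomeSequence(config.contig_id, seq.tobytes().decode())

    total_len = len(genome)
    clus_len = min(config.cluster_len, total_len)
    clus_start = int(rng.integers(0, max(total_len - clus_len, 0) + 1))
    truth = TruthSet(
        library=library,
        contig_id=config.contig_id,
        genome_len=total_len,
        insertions=insertions,
        cluster_intervals=[(config.contig_id, clus_start, clus_start + clus_len)],
    )
    return genome, hits, truth


# ---------------------------------------------------------------------------
# genotype panels


def simulate_panel(
    config: SimConfig,
) -> tuple[dict[str, tuple[GenomeSequence, list[RepeatHit]]], TruthSet]:
    """Simulate a genotype panel with a controlled sharing spectrum.

    Insertion columns are placed at homologous background positions shared by
    all genotypes; each column is present in exactly k genotypes with
    probability ``sharing_probs[k]``.  Every column is full length in at
    least one genotype; each additional carrier is independently downgraded
    to a fragment with ``downgrade_prob``, exercising the rule that degraded
    copies of a full-length insertion still count as shared.
    """
    if config.panel_size < 2:
        raise ValueError("panel_size must be >= 2")
    if not config.sharing_probs:
        raise ValueError("sharing_probs must be non-empty")
    rng = _rng(config, 2)
    library = make_library(config)
    genotypes = [f"G{i + 1}" for i in range(config.panel_size)]
    spacing = config.min_insertion_spacing
    slots = config.genome_len // spacing - 1
    if config.n_insertions > max(slots, 0):
        raise ValueError("insertions exceed genome capacity")
    background = _random_seq(rng, config.genome_len)
    points = np.sort(
        (rng.choice(slots, size=config.n_insertions, replace=False) + 1) * spacing
    )

    ks = list(config.sharing_probs)
    probs = np.array([config.sharing_probs[k] for k in ks])
    columns: list[PlantedColumn] = []
    per_gt_inserts: dict[str, list[tuple[int, np.ndarray, TEFamily, str, int, int, float]]] = {
        g: [] for g in genotypes
    }
    for col_id, point in enumerate(points):
        family, strand, _, cons_lo, cons_hi = _draw_insertion(rng, config, library)
        # panel columns are anchored on full-length copies
        cons_lo, cons_hi = 1, family.consensus_len
        k = ks[rng.choice(len(ks), p=probs)]
        carriers = list(rng.choice(config.panel_size, size=k, replace=False))
        states = {g: "absent" for g in genotypes}
        cons = np.frombuffer(family.consensus_seq.encode(), dtype=np.uint8)
        for rank, gi in enumerate(carriers):
            g = genotypes[gi]
            if rank == 0 or rng.random() >= config.downgrade_prob:
                category, lo, hi = "full_length", cons_lo, cons_hi
            else:
                category = "fragment"
                frac = rng.uniform(0.20, 0.65)
                length = max(1, int(frac * family.consensus_len))
                start = int(rng.integers(1, family.consensus_len - length + 2))
                lo, hi = start, start + length - 1
            insert, div = _mutate(
                _rng(config, 1000 + col_id * 31 + gi), cons[lo - 1 : hi].copy(),
                config.divergence_rate,
            )
            if strand == "-":
                insert = np.frombuffer(
                    revcomp(insert.tobytes().decode()).encode(), dtype=np.uint8
                )
            per_gt_inserts[g].append((int(point), insert, family, strand, lo, hi, div))
            states[g] = category
        columns.append(PlantedColumn(f"col_{col_id}", family.name, states))

    panel: dict[str, tuple[GenomeSequence, list[RepeatHit]]] = {}
    for g in genotypes:
        inserts = sorted(per_gt_inserts[g], key=lambda t: t[0])
        pieces = []
        hits: list[RepeatHit] = []
        prev = 0
        offset = 0
        for linkage, (point, insert, family, strand, lo, hi, div) in enumerate(inserts):
            pieces.append(background[prev:point])
            g_start = point + offset
            for h in _emit_hits(family, lo, hi, g_start, strand, div, linkage + 1):
                h.contig = f"{g}_locus"
                hits.append(h)
            pieces.append(insert)
            offset += len(insert)
            prev = point
        pieces.append(background[prev:])
        seq = np.concatenate(pieces)
        panel[g] = (GenomeSequence(f"{g}_locus", seq.tobytes().decode()), hits)

    truth = TruthSet(
        library=library,
        genome_len=config.genome_len,
        panel_columns=columns,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# small RNA


def _read_lengths(rng: np.random.Generator, n: int, mode: int) -> np.ndarray:
    """Lengths in [23, 29] peaked at ``mode`` (binomial around the mode)."""
    mode = int(np.clip(mode, 23, 29))
    p = (mode - 23) / 6
    return 23 + rng.binomial(6, p, size=n)


def simulate_small_rna(
    truth: TruthSet, config: SimConfig
) -> tuple[list[SmallRNARecord], TruthSet]:
    """Simulate a small-RNA library over a simulated genome.

    ``background_frac`` of the reads land uniformly on the contig; the rest
    inside the truth's cluster intervals, on the cluster's main strand with
    probability ``mainstrand_frac``.  First bases are T with ``u1_prob``.  A
    fraction ``pingpong_pair_prob`` of all reads is emitted as +/− pairs
    whose 5' ends are offset by exactly 10 nt, concentrated on
    ``n_pingpong_sites`` planted positions; partner reads carry a 10th-base A
    with ``a10_prob``.  Reads starting inside a planted repeat copy get
    ``n_hits`` equal to the family's copy number (capped at
    ``multimap_max``).  Returns the records and the truth updated with the
    planted ping-pong positions.
    """
    if not truth.cluster_intervals and config.background_frac == 0:
        raise ValueError("no cluster intervals in truth and no background reads")
    rng = _rng(config, 3)
    contig = truth.contig_id
    L = truth.genome_len
    if L <= 0:
        raise ValueError("truth carries no genome length")

    copy_numbers = truth.family_copy_numbers()
    ins_starts = np.array([i.start for i in truth.insertions], dtype=int)
    ins_ends = np.array([i.end for i in truth.insertions], dtype=int)
    ins_nhits = np.array(
        [
            min(copy_numbers[i.family], config.multimap_max)
            for i in truth.insertions
        ],
        dtype=int,
    )

    def n_hits_at(pos: int) -> int:
        idx = int(np.searchsorted(ins_starts, pos, side="right")) - 1
        if idx >= 0 and pos < ins_ends[idx]:
            return int(ins_nhits[idx])
        return 1

    records: list[SmallRNARecord] = []
    rid = 0

    def emit(pos: int, strand: str, tenth_a: Optional[bool] = None) -> None:
        nonlocal rid
        length = int(_read_lengths(rng, 1, config.read_len_mode)[0])
        seq = _random_seq(rng, length).tobytes().decode()
        first = "T" if rng.random() < config.u1_prob else "ACG"[rng.integers(0, 3)]
        if tenth_a is None:
            tenth = seq[9]
        else:
            tenth = "A" if tenth_a else "CGT"[rng.integers(0, 3)]
        seq = first + seq[1:9] + tenth + seq[10:]
        records.append(
            SmallRNARecord(
                read_id=f"r{rid}",
                length=length,
                contig=contig,
                five_prime_pos=int(pos),
                strand=strand,
                first_nt=seq[0],
                tenth_nt=seq[9],
                n_hits=n_hits_at(int(pos)),
                sequence=seq,
            )
        )
        rid += 1

    n_pp_reads = int(round(config.pingpong_pair_prob * config.n_reads))
    n_pairs = n_pp_reads // 2
    n_rest = config.n_reads - 2 * n_pairs
    n_bg = int(round(config.background_frac * n_rest))
    n_cluster = n_rest - n_bg

    clusters = [
        (s, e) for (c, s, e) in truth.cluster_intervals if c == contig
    ]
    pp_positions: list[int] = []
    if n_pairs:
        if not clusters:
            raise ValueError("ping-pong pairs need cluster intervals")
        s, e = clusters[0]
        hi = max(s + 1, e - 40)
        pp_positions = sorted(
            int(p) for p in rng.choice(np.arange(s, hi), size=config.n_pingpong_sites,
                                       replace=False)
        )
        site_idx = rng.integers(0, len(pp_positions), size=n_pairs)
        for i in range(n_pairs):
            p = pp_positions[int(site_idx[i])]
            emit(p, "+")
            emit(p + 9, "-", tenth_a=rng.random() < config.a10_prob)

    for _ in range(n_bg):
        emit(int(rng.integers(0, L)), "+" if rng.random() < 0.5 else "-")
    if n_cluster:
        if not clusters:
            raise ValueError("cluster reads requested but truth has no clusters")
        for _ in range(n_cluster):
            s, e = clusters[int(rng.integers(0, len(clusters)))]
            strand = "+" if rng.random() < config.mainstrand_frac else "-"
            emit(int(rng.integers(s, e)), strand)

    truth.pingpong_positions = pp_positions
    return records, truth


# ---------------------------------------------------------------------------
# assembly QC


def simulate_qc(config: SimConfig, genome_len: Optional[int] = None) -> tuple[QCProfile, list[int]]:
    """Simulate per-window coverage/soft-clip profiles with planted anomalies.

    Target windows tile ``genome_len`` (default the configured background
    length); benchmark windows emulate single-copy benchmark genes drawn from
    the same noise distributions.  ``n_anomalies`` target windows get 4x
    coverage and 10x soft clipping, recorded as truth.  Returns the profile
    and the anomalous window starts.
    """
    if config.coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = _rng(config, 4)
    L = genome_len if genome_len is not None else config.genome_len
    w = config.qc_window
    starts = np.arange(0, L, w)
    n = len(starts)

    def draw_cov(size):
        return np.maximum(rng.normal(config.coverage_mean, config.coverage_mean / 6, size), 0.0)

    def draw_clip(size):
        sd = max(config.clip_rate / 3, 1e-4)
        return np.clip(rng.normal(config.clip_rate, sd, size), 0.0, 1.0)

    cov = draw_cov(n)
    clip = draw_clip(n)
    bench_cov = draw_cov(config.n_benchmark_windows)
    bench_clip = draw_clip(config.n_benchmark_windows)

    anomalies: list[int] = []
    if config.n_anomalies > 0:
        idx = rng.choice(n, size=min(config.n_anomalies, n), replace=False)
        for i in np.sort(idx):
            cov[i] = 4.0 * config.coverage_mean
            clip[i] = min(10.0 * config.clip_rate, 0.9)
            anomalies.append(int(starts[i]))

    profile = QCProfile.from_benchmark(
        contig=config.contig_id,
        window=w,
        window_starts=starts,
        coverage=cov,
        clip_rate=clip,
        benchmark_cov=bench_cov,
        benchmark_clip=bench_clip,
    )
    return profile, anomalies
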