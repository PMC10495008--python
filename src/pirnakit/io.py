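"""Readers and writers for the external formats, and coordinate normalization.

All internal coordinates are 0-based half-open.  Every reader converts at
ingestion (RepeatMasker ``.out`` is 1-based inclusive, BED is already 0-based
half-open, SAM POS is 1-based) and every writer converts back, so no other
module ever handles a 1-based coordinate.

Small-RNA alignments are accepted either as SAM (header optional) or as a
7-column tabular dialect designed so tests and simulations need no binary
alignment files::

    read_id  contig  five_prime_pos  strand  length  sequence  n_hits

Tab-separated, ``#`` starts a comment line.  ``five_prime_pos`` is the 0-based
genomic coordinate of the read's 5'-most base: the leftmost aligned base for
``+`` reads, the rightmost for ``-`` reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomeSequence:
    """One assembled contig."""

    contig_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(
                f"contig {self.contig_id!r}: alphabet restricted to A,C,G,T,N"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatHit:
    """One row of a RepeatMasker-style repeat annotation.

    ``start``/``end`` are 0-based half-open genomic coordinates;
    ``cons_begin``/``cons_end`` are 1-based inclusive positions on the family
    consensus, always ordered ``cons_begin <= cons_end`` regardless of strand.
    ``divergence_pct`` is the percent of mismatched bases versus the consensus.
    ``linkage_id`` optionally groups fragments of one element (the .out ID
    column).
    """

    contig: str
    start: int
    end: int
    strand: str
    family: str
    cons_begin: int
    cons_end: int
    divergence_pct: float
    linkage_id: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.cons_begin > self.cons_end:
            raise ValueError("cons_begin must be <= cons_end")
        if not (0.0 <= self.divergence_pct <= 100.0):
            raise ValueError("divergence_pct must be in [0, 100]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class SmallRNARecord:
    """One small-RNA alignment.

    ``five_prime_pos`` is the 0-based genomic coordinate of the 5'-most base
    (rightmost aligned base for ``-`` strand reads).  ``n_hits`` is the number
    of genomic placements of the read; weighted counting downstream assigns
    each placement weight ``1/n_hits``.  ``first_nt``/``tenth_nt`` are in read
    orientation.
    """

    read_id: str
    length: int
    contig: str
    five_prime_pos: int
    strand: str
    first_nt: str
    tenth_nt: str
    n_hits: int = 1
    sequence: str = ""

    def __post_init__(self):
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        if self.tenth_nt and self.length < 10:
            raise ValueError("length must be >= 10 when tenth_nt is set")
        if self.five_prime_pos < 0:
            raise ValueError("negative coordinate")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    genomes = [
        GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [g.contig_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate contig ids")
    return genomes


def write_fasta(genomes: Iterable[GenomeSequence], path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.contig_id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query     matching"
    "  repeat         position in repeat\n"
    "score  div. del. ins.  sequence  begin end    (left)   repeat"
    "         class/family  begin end  (left) ID\n"
    "\n"
)


def read_repeatmasker_out(path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file into :class:`RepeatHit` rows.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    A ``C`` orientation row becomes strand ``-`` and its consensus columns,
    given as ``(left) end begin`` in the file, are reordered so
    ``cons_begin <= cons_end``.  Rows are returned in file order.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            # the standard 3-line header: two label lines then a blank
            if lineno <= 3 and (
                stripped.startswith("SW") or stripped.startswith("score")
            ):
                continue
            fields = stripped.split()
            if len(fields) < 14:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 14 columns, got {len(fields)}"
                )
            try:
                div = float(fields[1])
                begin = int(fields[5])
                end = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            orient = fields[8]
            family = fields[9]
            if orient == "+":
                strand = "+"
                raw = fields[11], fields[12]  # begin end (left)
            elif orient in ("C", "-"):
                strand = "-"
                raw = fields[13], fields[12]  # (left) end begin -> begin, end
            else:
                raise ParseError(f"{path}:{lineno}: bad orientation {orient!r}")
            try:
                cons_begin = int(raw[0].strip("()"))
                cons_end = int(raw[1].strip("()"))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric consensus coordinate"
                ) from exc
            linkage = None
            if len(fields) >= 15:
                try:
                    linkage = int(fields[14])
                except ValueError:
                    linkage = None
            if end < begin:
                raise ParseError(f"{path}:{lineno}: end < begin ({end} < {begin})")
            try:
                hits.append(
                    RepeatHit(
                        contig=fields[4],
                        start=begin - 1,
                        end=end,
                        strand=strand,
                        family=family,
                        cons_begin=cons_begin,
                        cons_end=cons_end,
                        divergence_pct=div,
                        linkage_id=linkage,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_repeatmasker_out(hits: Iterable[RepeatHit], path) -> None:
    """Write hits in the RepeatMasker ``.out`` dialect (inverse of the reader)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(hits, start=1):
            linkage = h.linkage_id if h.linkage_id is not None else i
            if h.strand == "+":
                rep = f"{h.cons_begin} {h.cons_end} (0)"
                orient = "+"
            else:
                rep = f"(0) {h.cons_end} {h.cons_begin}"
                orient = "C"
            fh.write(
                f"1000 {h.divergence_pct:.1f} 0.0 0.0 {h.contig} "
                f"{h.start + 1} {h.end} (0) {orient} {h.family} "
                f"Unknown {rep} {linkage}\n"
            )


# ---------------------------------------------------------------------------
# BED dialect for RepeatHit (BED6 + cons_begin, cons_end, divergence, linkage)


def write_bed_hits(hits: Iterable[RepeatHit], path) -> None:
    """BED6+4: chrom start end family divergence strand cons_begin cons_end linkage."""
    with open(path, "w") as fh:
        for h in hits:
            linkage = "." if h.linkage_id is None else str(h.linkage_id)
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.family}\t"
                f"{h.divergence_pct:g}\t{h.strand}\t{h.cons_begin}\t"
                f"{h.cons_end}\t{linkage}\n"
            )


def read_bed_hits(path) -> list[RepeatHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            try:
                hits.append(
                    RepeatHit(
                        contig=f[0],
                        start=int(f[1]),
                        end=int(f[2]),
                        strand=f[5],
                        family=f[3],
                        cons_begin=int(f[6]),
                        cons_end=int(f[7]),
                        divergence_pct=float(f[4]),
                        linkage_id=None if f[8] == "." else int(f[8]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Plain BED3+ intervals: (contig, start, end), 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# small-RNA alignments


def _cigar_ref_span(cigar: str) -> int:
    span, num = 0, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                span += int(num)
            num = ""
    return span


def _sam_records_text(path) -> Iterable[tuple[str, int, str, int, str, str, Optional[int]]]:
    """Minimal SAM column parser for headerless files pysam cannot open.

    Yields (read_id, flag, contig, pos0, cigar, seq, nh).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ParseError(f"{path}:{lineno}: expected >= 11 SAM columns")
            try:
                flag = int(f[1])
                pos = int(f[3]) - 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric SAM field") from exc
            if pos < 0 and not flag & 0x4:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            nh = None
            for tag in f[11:]:
                if tag.startswith("NH:i:"):
                    nh = int(tag[5:])
            yield f[0], flag, f[2], pos, f[5], f[9], nh


def _iter_sam(path):
    """Yield (read_id, unmapped, contig, pos0, ref_span, strand, read_seq_fwd, nh).

    ``read_seq_fwd`` is the read in its own 5'->3' orientation (SAM stores the
    reverse complement for minus-strand alignments).  Files with an ``@``
    header go through pysam; headerless files through the minimal column
    parser above.
    """
    with open(path) as fh:
        has_header = fh.readline().startswith("@")
    if has_header:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped:
                    yield aln.query_name, True, None, None, None, None, None, None
                    continue
                seq = aln.query_sequence or ""
                if aln.is_reverse:
                    seq = revcomp(seq)
                nh = aln.get_tag("NH") if aln.has_tag("NH") else None
                yield (
                    aln.query_name,
                    False,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end - aln.reference_start,
                    "-" if aln.is_reverse else "+",
                    seq,
                    nh,
                )
    else:
        for rid, flag, contig, pos, cigar, seq, nh in _sam_records_text(path):
            if flag & 0x4:
                yield rid, True, None, None, None, None, None, None
                continue
            strand = "-" if flag & 0x10 else "+"
            if strand == "-":
                seq = revcomp(seq)
            yield rid, False, contig, pos, _cigar_ref_span(cigar), strand, seq, nh


def _looks_like_sam(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@"):
                return True
            return len(line.rstrip("\n").split("\t")) >= 11
    return False


def read_small_rna(path, min_len: int = 23, max_len: int = 29) -> list[SmallRNARecord]:
    """Read small-RNA alignments, keeping reads with ``min_len <= length <= max_len``.

    Accepts SAM (header optional) or the 7-column tabular dialect.  The 5'-end
    coordinate is computed per strand; ``n_hits`` is taken from the NH tag (or
    tabular column) when present, else from the number of records sharing a
    read id, else 1.  Unmapped records are skipped with a logged count.
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if _looks_like_sam(path):
        records = _read_small_rna_sam(path, min_len, max_len)
    else:
        records = _read_small_rna_tabular(path, min_len, max_len)
    return records


def _make_record(rid, contig, five_prime, strand, seq, n_hits) -> SmallRNARecord:
    return SmallRNARecord(
        read_id=rid,
        length=len(seq),
        contig=contig,
        five_prime_pos=five_prime,
        strand=strand,
        first_nt=seq[0].upper() if seq else "N",
        tenth_nt=seq[9].upper() if len(seq) >= 10 else "",
        n_hits=n_hits,
        sequence=seq.upper(),
    )


def _read_small_rna_sam(path, min_len, max_len) -> list[SmallRNARecord]:
    raw = []
    n_unmapped = 0
    id_counts: dict[str, int] = {}
    for rid, unmapped, contig, pos, span, strand, seq, nh in _iter_sam(path):
        if unmapped:
            n_unmapped += 1
            continue
        raw.append((rid, contig, pos, span, strand, seq, nh))
        id_counts[rid] = id_counts.get(rid, 0) + 1
    if n_unmapped:
        logger.info("skipped %d unmapped records in %s", n_unmapped, path)
    out = []
    for rid, contig, pos, span, strand, seq, nh in raw:
        if not (min_len <= len(seq) <= max_len):
            continue
        five = pos if strand == "+" else pos + span - 1
        n_hits = nh if nh is not None else max(id_counts[rid], 1)
        out.append(_make_record(rid, contig, five, strand, seq, n_hits))
    return out


def _read_small_rna_tabular(path, min_len, max_len) -> list[SmallRNARecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(f)}")
            rid, contig, pos_s, strand, length_s, seq, nh_s = f
            try:
                pos = int(pos_s)
                length = int(length_s)
                n_hits = int(nh_s) if nh_s not in (".", "") else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from exc
            if pos < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if length != len(seq):
                raise ParseError(f"{path}:{lineno}: length column != sequence length")
            if not (min_len <= length <= max_len):
                continue
            try:
                records.append(_make_record(rid, contig, pos, strand, seq, n_hits))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_small_rna_tabular(records: Iterable[SmallRNARecord], path) -> None:
    """Write records in the 7-column tabular small-RNA dialect."""
    with open(path, "w") as fh:
        fh.write("# read_id\tcontig\tfive_prime_pos\tstrand\tlength\tsequence\tn_hits\n")
        for r in records:
            seq = r.sequence or "N" * r.length
            fh.write(
                f"{r.read_id}\t{r.contig}\t{r.five_prime_pos}\t{r.strand}\t"
                f"{r.length}\t{seq}\t{r.n_hits}\n"
            )


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Load a YAML config: sections mirroring the parameter types.

    Known sections: ``merge`` (MergeParams), ``cluster`` (ClusterParams),
    ``pingpong`` (PingPongParams), ``align`` (AlignParams), ``ht`` (HTParams),
    ``sim`` (SimConfig).  Unknown keys are preserved and passed through.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    return cfg


def read_contig_lengths(path) -> dict[str, int]:
    """FASTA-index dialect: two or more whitespace-separated columns, name length."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 2:
                raise ParseError(f"{path}:{lineno}: expected name and length")
            out[f[0]] = int(f[1])
    return out
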