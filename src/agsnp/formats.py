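"""Readers and writers for every external representation the pipeline touches.

Coordinate convention: all internal coordinates are 0-based half-open.
Conversion to 1-based happens only at the VCF boundary (and when reading
BLAST tabular hits, whose query coordinates are 1-based inclusive on disk).

Reverse-strand alignments are stored with the read sequence already
reverse-complemented into reference orientation (the SAM convention), so
pileup logic downstream is strand-agnostic; the original strand is retained
per record.
"""
from __future__ import annotations

import enum
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from . import dna


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class Platform(enum.Enum):
    LONG_454 = "Roche454"
    SOLEXA = "Solexa"
    SOLID = "SOLiD"


class Source(enum.Enum):
    GENOMIC = "genomic"
    CDNA = "cDNA"


class DbTag(enum.Enum):
    ORGANELLAR = "organellar"
    REPEAT = "repeat"
    GENE_NT = "gene_nt"
    GENE_PROT = "gene_prot"
    UNIGENE = "unigene"


#: canonical ordering used for platform-combination provenance strings
PLATFORM_ORDER: list[tuple[Platform, Source]] = [
    (Platform.SOLID, Source.GENOMIC),
    (Platform.SOLID, Source.CDNA),
    (Platform.SOLEXA, Source.GENOMIC),
    (Platform.LONG_454, Source.GENOMIC),
]


def platform_label(platform: Platform, source: Source) -> str:
    return f"{platform.value}({source.value})"


def combo_string(platforms: Iterable[tuple[Platform, Source]]) -> str:
    """Deterministic provenance string, e.g. ``SOLiD(genomic)/Solexa(genomic)``."""
    keys = set(platforms)
    return "/".join(platform_label(p, s) for p, s in PLATFORM_ORDER if (p, s) in keys)


@dataclass
class ReadRecord:
    """A sequenced read with optional per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray | None = None  # absent for FASTA input
    platform: Platform = Platform.LONG_454
    source: Source = Source.GENOMIC

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return dna.encode(self.sequence)


@dataclass
class HomologyHit:
    """One alignment hit of a reference read against a named database.

    Query coordinates are 0-based half-open (converted from the 1-based
    inclusive convention of the tabular input).
    """

    query_id: str
    subject_id: str
    db_tag: DbTag
    percent_identity: float
    query_start: int
    query_end: int
    evalue: float

    def __post_init__(self) -> None:
        if not self.query_start < self.query_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: "
                f"query_start {self.query_start} !< query_end {self.query_end}"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")


@dataclass
class AlignmentRecord:
    """One mapped read, in reference orientation. ``ref_start`` is 0-based."""

    read_id: str
    ref_id: str
    ref_start: int
    cigar: str
    mapq: int
    strand: str  # "+" or "-"
    platform: Platform
    source: Source
    sequence: str
    qualities: np.ndarray | None = None


_CIGAR_CONSUMES_QUERY = frozenset("MIS=X")
_CIGAR_CONSUMES_REF = frozenset("MDN=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            if n == 0:
                raise ValueError(f"bad CIGAR {cigar!r}")
            ops.append((ch, n))
            n = 0
    if n:
        raise ValueError(f"bad CIGAR {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in _CIGAR_CONSUMES_QUERY)


def cigar_reference_length(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in _CIGAR_CONSUMES_REF)


class AlignmentSet:
    """Columnar container for one platform/source batch of alignments.

    Sequences live in one flattened uint8 code buffer addressed by
    ``seq_start``/``seq_len`` per alignment, so a read placed at several
    homologous locations shares a single copy of its bases. The
    record-level view (:class:`AlignmentRecord`) is available via
    iteration. ``cigars[i]`` is ``None`` for pure-match alignments
    (CIGAR == "<len>M").
    """

    def __init__(
        self,
        *,
        ref_names: Sequence[str],
        ref_index: np.ndarray,
        ref_start: np.ndarray,
        seq_flat: np.ndarray,
        seq_start: np.ndarray,
        seq_len: np.ndarray,
        mapq: np.ndarray,
        reverse: np.ndarray,
        platform: Platform,
        source: Source,
        cigars: list[str | None] | None = None,
        qual_flat: np.ndarray | None = None,
        read_ids: list[str] | None = None,
    ):
        self.ref_names = list(ref_names)
        self.ref_index = np.asarray(ref_index, dtype=np.int64)
        self.ref_start = np.asarray(ref_start, dtype=np.int64)
        self.seq_flat = np.asarray(seq_flat, dtype=np.uint8)
        self.seq_start = np.asarray(seq_start, dtype=np.int64)
        self.seq_len = np.asarray(seq_len, dtype=np.int64)
        self.mapq = np.asarray(mapq, dtype=np.int16)
        self.reverse = np.asarray(reverse, dtype=bool)
        self.platform = platform
        self.source = source
        self.cigars = cigars if cigars is not None else [None] * len(self.ref_index)
        self.qual_flat = qual_flat
        self.read_ids = read_ids

    def __len__(self) -> int:
        return len(self.ref_index)

    def read_length(self, i: int) -> int:
        return int(self.seq_len[i])

    def seq_codes(self, i: int) -> np.ndarray:
        return self.seq_flat[self.seq_start[i] : self.seq_start[i] + self.seq_len[i]]

    def quals(self, i: int) -> np.ndarray | None:
        if self.qual_flat is None:
            return None
        return self.qual_flat[self.seq_start[i] : self.seq_start[i] + self.seq_len[i]]

    def read_id(self, i: int) -> str:
        if self.read_ids is not None:
            return self.read_ids[i]
        return f"{self.platform.name.lower()}_{self.source.value}_{i}"

    def cigar(self, i: int) -> str:
        c = self.cigars[i]
        return c if c is not None else f"{self.read_length(i)}M"

    def record(self, i: int) -> AlignmentRecord:
        q = self.quals(i)
        return AlignmentRecord(
            read_id=self.read_id(i),
            ref_id=self.ref_names[self.ref_index[i]],
            ref_start=int(self.ref_start[i]),
            cigar=self.cigar(i),
            mapq=int(self.mapq[i]),
            strand="-" if self.reverse[i] else "+",
            platform=self.platform,
            source=self.source,
            sequence=dna.decode(self.seq_codes(i)),
            qualities=None if q is None else q.astype(np.int32),
        )

    def __iter__(self) -> Iterator[AlignmentRecord]:
        for i in range(len(self)):
            yield self.record(i)

    @classmethod
    def from_records(
        cls, records: Sequence[AlignmentRecord], platform: Platform, source: Source
    ) -> "AlignmentSet":
        ref_names: list[str] = []
        ref_lookup: dict[str, int] = {}
        ref_index, ref_start, mapq, reverse = [], [], [], []
        cigars: list[str | None] = []
        seqs, quals, read_ids = [], [], []
        have_qual = all(r.qualities is not None for r in records)
        for r in records:
            if r.ref_id not in ref_lookup:
                ref_lookup[r.ref_id] = len(ref_names)
                ref_names.append(r.ref_id)
            ref_index.append(ref_lookup[r.ref_id])
            ref_start.append(r.ref_start)
            mapq.append(r.mapq)
            reverse.append(r.strand == "-")
            c = r.cigar
            cigars.append(None if c == f"{len(r.sequence)}M" else c)
            seqs.append(dna.encode(r.sequence))
            if have_qual:
                quals.append(np.asarray(r.qualities, dtype=np.uint8))
            read_ids.append(r.read_id)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(lengths)[:-1]]) if seqs else np.empty(0, np.int64)
        return cls(
            ref_names=ref_names,
            ref_index=np.array(ref_index, dtype=np.int64),
            ref_start=np.array(ref_start, dtype=np.int64),
            seq_flat=np.concatenate(seqs) if seqs else np.empty(0, np.uint8),
            seq_start=starts,
            seq_len=lengths,
            mapq=np.array(mapq, dtype=np.int16),
            reverse=np.array(reverse, dtype=bool),
            platform=platform,
            source=source,
            cigars=cigars,
            qual_flat=np.concatenate(quals) if have_qual and quals else None,
            read_ids=read_ids,
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fastx(
    path: str | os.PathLike,
    platform: Platform = Platform.LONG_454,
    source: Source = Source.GENOMIC,
) -> Iterator[ReadRecord]:
    """Stream reads from a FASTA or FASTQ file (auto-detected by first byte).

    FASTA records yield ``qualities=None``. Malformed FASTQ raises
    :class:`ParseError` naming the line number.
    """
    with open(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "":
            return
        if first == ">":
            for rec in SeqIO.parse(fh, "fasta"):
                yield ReadRecord(rec.id, str(rec.seq).upper(), None, platform, source)
        elif first == "@":
            yield from _read_fastq(fh, path, platform, source)
        else:
            raise ParseError(f"{path}: line 1: not FASTA or FASTQ (starts with {first!r})")


def _read_fastq(fh: io.TextIOBase, path, platform, source) -> Iterator[ReadRecord]:
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ParseError(f"{path}: line {lineno}: expected '@' header, got {header[:20]!r}")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline().rstrip("\n")
        qual = fh.readline().rstrip("\n")
        if not qual and not plus:
            raise ParseError(f"{path}: line {lineno}: truncated FASTQ record")
        lineno += 3
        if not plus.startswith("+"):
            raise ParseError(f"{path}: line {lineno - 1}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}: line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        yield ReadRecord(
            header[1:].split()[0], seq.upper(), dna.string_to_phred(qual), platform, source
        )


def write_fastq(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = r.qualities
            if q is None:
                q = np.full(len(r.sequence), 30, dtype=np.int32)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{dna.phred_to_string(q)}\n")


def write_fasta(reads: Iterable[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt-6 dialect)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path: str | os.PathLike, db_tag: DbTag) -> Iterator[HomologyHit]:
    """Stream homology hits from a 12-column tab-separated table.

    Input qstart/qend are 1-based inclusive; emitted hits are 0-based
    half-open. Row order is preserved.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(f"{path}: line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                evalue = float(fields[10])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric evalue {fields[10]!r}"
                ) from None
            qstart, qend = int(fields[6]), int(fields[7])
            yield HomologyHit(
                query_id=fields[0],
                subject_id=fields[1],
                db_tag=db_tag,
                percent_identity=float(fields[2]),
                query_start=qstart - 1,
                query_end=qend,
                evalue=evalue,
            )


def write_hit_table(hits: Iterable[HomologyHit], path: str | os.PathLike) -> None:
    """Write hits back to the 12-column dialect (1-based inclusive coords)."""
    with open(path, "w") as fh:
        for h in hits:
            span = h.query_end - h.query_start
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}", str(span),
                        "0", "0", str(h.query_start + 1), str(h.query_end),
                        "1", str(span), f"{h.evalue:.3g}", "0.0",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_TAG_PLATFORM = "XP"
_TAG_SOURCE = "XO"


def read_sam(
    path: str | os.PathLike,
    platform: Platform | None = None,
    source: Source | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped records from a SAM file; unmapped records are skipped.

    Platform and source come from the ``XP``/``XO`` tags when present, else
    from the arguments (default 454 genomic).
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.reference_id < 0 or rec.reference_name is None:
                raise ParseError(f"{path}: record {rec.query_name}: unknown reference")
            plat = platform or Platform.LONG_454
            src = source or Source.GENOMIC
            if rec.has_tag(_TAG_PLATFORM):
                plat = Platform[rec.get_tag(_TAG_PLATFORM)]
            if rec.has_tag(_TAG_SOURCE):
                src = Source[rec.get_tag(_TAG_SOURCE)]
            quals = rec.query_qualities
            yield AlignmentRecord(
                read_id=rec.query_name,
                ref_id=rec.reference_name,
                ref_start=rec.reference_start,
                cigar=rec.cigarstring,
                mapq=rec.mapping_quality,
                strand="-" if rec.is_reverse else "+",
                platform=plat,
                source=src,
                sequence=(rec.query_sequence or "").upper(),
                qualities=None if quals is None else np.asarray(quals, dtype=np.int32),
            )


def load_alignment_set(
    path: str | os.PathLike, platform: Platform, source: Source
) -> AlignmentSet:
    return AlignmentSet.from_records(list(read_sam(path, platform, source)), platform, source)


def write_sam(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    reference_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Write alignments as headered SAM text."""
    names = list(reference_lengths)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in names:
            fh.write(f"@SQ\tSN:{name}\tLN:{reference_lengths[name]}\n")
        for rec in alignments:
            if rec.ref_id not in reference_lengths:
                raise ParseError(f"alignment {rec.read_id}: unknown reference {rec.ref_id}")
            flag = 16 if rec.strand == "-" else 0
            qual = "*" if rec.qualities is None else dna.phred_to_string(rec.qualities)
            fh.write(
                "\t".join(
                    [
                        rec.read_id, str(flag), rec.ref_id, str(rec.ref_start + 1),
                        str(rec.mapq), rec.cigar, "*", "0", "0",
                        rec.sequence or "*", qual,
                        f"{_TAG_PLATFORM}:Z:{rec.platform.name}",
                        f"{_TAG_SOURCE}:Z:{rec.source.name}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF / BED / TSV
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=agsnp
##INFO=<ID=DP,Number=1,Type=Integer,Description="Merged mapped read depth">
##INFO=<ID=CBR,Number=1,Type=Float,Description="Consensus base ratio">
##INFO=<ID=PLAT,Number=1,Type=String,Description="Platform/source combination">
##INFO=<ID=CAT,Number=1,Type=String,Description="Reference read category">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls, path: str | os.PathLike, contig_lengths: dict[str, int] | None = None):
    """Write variant calls as VCF 4.2 (1-based positions).

    ``calls`` are :class:`agsnp.snp_engine.VariantCall` objects (anything with
    ref_id/pos/ref_base/alt_base/depth/consensus_base_ratio/platforms/
    category/filter_flags works).
    """
    with open(path, "w") as fh:
        header = _VCF_HEADER
        if contig_lengths:
            contigs = "".join(
                f"##contig=<ID={n},length={l}>\n" for n, l in contig_lengths.items()
            )
            header = header.replace("#CHROM", contigs + "#CHROM", 1)
        fh.write(header)
        for c in calls:
            cat = c.category.name if c.category is not None else "."
            filt = "PASS" if not c.filter_flags else ";".join(sorted(c.filter_flags))
            info = (
                f"DP={c.depth};CBR={c.consensus_base_ratio!r};"
                f"PLAT={combo_string(c.platforms)};CAT={cat}"
            )
            fh.write(
                f"{c.ref_id}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t{filt}\t{info}\n"
            )


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a DataFrame.

    This is a reader for the package's own dialect (used for round-trip
    verification); positions come back 0-based, DP/CBR exactly as written.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, filt, info = line.rstrip("\n").split("\t")
            kv = dict(item.split("=", 1) for item in info.split(";"))
            rows.append(
                {
                    "ref_id": chrom,
                    "pos": int(pos) - 1,
                    "ref_base": ref,
                    "alt_base": alt,
                    "filter": filt,
                    "depth": int(kv["DP"]),
                    "consensus_base_ratio": float(kv["CBR"]),
                    "platforms": kv["PLAT"],
                    "category": kv["CAT"],
                }
            )
    columns = [
        "ref_id", "pos", "ref_base", "alt_base", "filter",
        "depth", "consensus_base_ratio", "platforms", "category",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_tsv(report: pd.DataFrame, path: str | os.PathLike) -> None:
    report.to_csv(path, sep="\t", index=False)
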