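"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure the method assumes: a genome dominated
by nested transposable-element (TE) copies (creating repeat junctions),
genes (a few duplicated), uncharacterized low-copy repeat families, and
single-copy intergenic DNA; two genotypes differing only by planted
substitutions; a long-read library of genotype 1 with
homopolymer-dominated indel errors, 3'-decaying quality, organellar
contamination and artificial replicates; and short-read libraries of
genotype 2 with platform-specific substitution errors.

Read placement emulates a mapper in report-all mode: a read sampled from
inside an element copy is aligned at every homologous reference location,
so mapped depth is proportional to genomic copy number -- the signal the
single-copy depth model consumes. Reads spanning an element boundary
(junction reads) place uniquely. References that are plain characterized
repeat (no junction) are not mapping targets by default, since the
pipeline never consults them.

Everything is driven by one numpy Generator seeded from ``SimConfig.seed``;
identical configurations produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dna
from .formats import (
    AlignmentSet,
    DbTag,
    HomologyHit,
    Platform,
    ReadRecord,
    Source,
    write_fasta,
    write_fastq,
    write_hit_table,
    write_sam,
    write_tsv,
)

_BUCKET_SHIFT = 8  # 256 bp genome buckets for reference-interval lookup


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TEFamilySpec:
    name: str
    length: int
    copies: int


@dataclass
class ShortPlatformSpec:
    read_len: int
    coverage: float
    sub_rate: float
    mapq: int = 60
    low_mapq_fraction: float = 0.005


def default_te_library(genome_length: int, repeat_fraction: float = 0.59) -> list[TEFamilySpec]:
    """24 characterized TE families sized to hit the target repeat fraction."""
    lengths = [3000, 4000, 5000, 6000, 8000, 10000] * 4
    per_family = repeat_fraction * genome_length / len(lengths)
    return [
        TEFamilySpec(f"TE{i:02d}", L, max(1, round(per_family / L)))
        for i, L in enumerate(lengths, start=1)
    ]


def _default_short_platforms() -> dict[tuple[Platform, Source], ShortPlatformSpec]:
    # Coverages mirror the study's mapped-coverage scale (deep SOLiD genomic,
    # shallow Solexa, gene-space cDNA); substitution rates are the published
    # consensus-scale platform rates.
    return {
        (Platform.SOLID, Source.GENOMIC): ShortPlatformSpec(50, 8.0, 1.8e-4),
        (Platform.SOLEXA, Source.GENOMIC): ShortPlatformSpec(84, 2.0, 3.5e-4),
        (Platform.SOLID, Source.CDNA): ShortPlatformSpec(50, 3.0, 1.8e-4),
    }


@dataclass
class SimConfig:
    seed: int = 42
    genome_length: int = 5_000_000
    repeat_fraction: float = 0.59
    te_library: list[TEFamilySpec] | None = None  # default: sized from repeat_fraction
    nested_te_fraction: float = 0.25
    n_genes: int = 340
    gene_length_mean: int = 1500
    gene_length_sd: int = 300
    duplicated_gene_fraction: float = 0.05
    uncharacterized_gene_fraction: float = 0.22
    expressed_gene_fraction: float = 0.8
    unchar_repeat_families: list[TEFamilySpec] = field(
        default_factory=lambda: [
            TEFamilySpec("URF1", 3000, 10),
            TEFamilySpec("URF2", 3000, 10),
        ]
    )
    organellar_fraction: float = 0.0164
    organellar_length: int = 120_000
    replicate_fraction: float = 0.1133
    # per-bp SNP planting rates (between the two inbred accessions)
    snp_rate_genic: float = 1.0 / 876.0
    snp_rate_rj: float = 1.0 / 612.0
    snp_rate_unchar: float = 1.0 / 876.0
    rj_window: int = 50
    heterozygosity: float = 0.0
    # long-read (reference) library
    long_read_len_mean: float = 380.5
    long_read_len_sd: float = 80.0
    long_read_min_len: int = 100
    long_read_max_len: int = 800
    long_read_coverage: float = 1.35
    long_sub_rate: float = 1.2e-3
    long_indel_rate: float = 6.2e-3
    homopolymer_indel_fraction: float = 0.85
    error_lowqual_fraction: float = 0.8
    # short-read libraries of genotype 2
    short_platforms: dict[tuple[Platform, Source], ShortPlatformSpec] = field(
        default_factory=_default_short_platforms
    )
    hit_noise: float = 0.02
    te_gene_hit_fraction: float = 0.10  # TE families that also pollute the gene DB
    min_hit_overlap: int = 30
    map_to_repeat_refs: bool = False

    def resolved_te_library(self) -> list[TEFamilySpec]:
        if self.te_library is not None:
            return self.te_library
        return default_te_library(self.genome_length, self.repeat_fraction)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["te_library"] = [dataclasses.asdict(t) for t in self.resolved_te_library()]
        d["unchar_repeat_families"] = [
            dataclasses.asdict(t) for t in self.unchar_repeat_families
        ]
        d["short_platforms"] = {
            f"{p.name}:{s.name}": dataclasses.asdict(spec)
            for (p, s), spec in self.short_platforms.items()
        }
        return d


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class Family:
    name: str
    kind: str  # "te" | "gene" | "unchar_rep"
    length: int
    characterized: bool = True
    expressed: bool = False
    te_gene_hit: bool = False


@dataclass
class GenomeBuild:
    genome: np.ndarray  # genotype-1 codes
    families: list[Family]
    seg_start: np.ndarray
    seg_end: np.ndarray
    seg_family: np.ndarray  # family index, -1 for unique DNA
    seg_elem_off: np.ndarray  # element offset at segment start
    seg_instance: np.ndarray  # element copy id, -1 for unique DNA
    junctions: pd.DataFrame  # gpos, left, right, kind
    n_nested: int

    def segments_frame(self) -> pd.DataFrame:
        fam_names = [f.name for f in self.families]
        return pd.DataFrame(
            {
                "start": self.seg_start,
                "end": self.seg_end,
                "family": [
                    fam_names[f] if f >= 0 else "unique" for f in self.seg_family
                ],
                "family_idx": self.seg_family,
                "elem_off": self.seg_elem_off,
                "instance": self.seg_instance,
            }
        )


def build_genome(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenomeBuild:
    """Assemble genotype 1: unique DNA, genes, TE copies with nesting."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    families: list[Family] = []
    te_specs = cfg.resolved_te_library()
    n_te_gene_hit = round(cfg.te_gene_hit_fraction * len(te_specs))
    for i, spec in enumerate(te_specs):
        families.append(
            Family(spec.name, "te", spec.length, characterized=True,
                   te_gene_hit=i < n_te_gene_hit)
        )
    gene_lengths = np.clip(
        rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, cfg.n_genes),
        600, 3 * cfg.gene_length_mean,
    ).astype(int)
    n_unchar_genes = round(cfg.uncharacterized_gene_fraction * cfg.n_genes)
    unchar_gene_idx = set(rng.choice(cfg.n_genes, n_unchar_genes, replace=False).tolist())
    expressed = rng.random(cfg.n_genes) < cfg.expressed_gene_fraction
    n_dup = round(cfg.duplicated_gene_fraction * cfg.n_genes)
    dup_idx = set(rng.choice(cfg.n_genes, n_dup, replace=False).tolist())
    gene_fam_offset = len(families)
    for g in range(cfg.n_genes):
        families.append(
            Family(
                f"GENE{g + 1:04d}", "gene", int(gene_lengths[g]),
                characterized=g not in unchar_gene_idx,
                expressed=bool(expressed[g]),
            )
        )
    urf_fam_offset = len(families)
    for spec in cfg.unchar_repeat_families:
        families.append(Family(spec.name, "unchar_rep", spec.length, characterized=False))

    elem_seqs = [rng.integers(0, 4, f.length).astype(np.uint8) for f in families]

    # instances: (family_idx, instance_id)
    instances: list[tuple[int, int]] = []
    inst_id = 0
    for i, spec in enumerate(te_specs):
        for _ in range(spec.copies):
            instances.append((i, inst_id))
            inst_id += 1
    te_instances = list(range(len(instances)))
    for g in range(cfg.n_genes):
        copies = 2 if g in dup_idx else 1
        for _ in range(copies):
            instances.append((gene_fam_offset + g, inst_id))
            inst_id += 1
    for j, spec in enumerate(cfg.unchar_repeat_families):
        for _ in range(spec.copies):
            instances.append((urf_fam_offset + j, inst_id))
            inst_id += 1

    # nesting: some TE copies are guests inside other TE copies
    n_nested = round(cfg.nested_te_fraction * len(te_instances))
    nested = rng.choice(len(te_instances), n_nested, replace=False)
    nested_set = set(int(x) for x in nested)
    host_pool = [
        k for k in te_instances
        if k not in nested_set and families[instances[k][0]].length >= 1500
    ]
    guests_of: dict[int, list[tuple[int, int]]] = {}
    for k in nested_set:
        host = int(host_pool[rng.integers(0, len(host_pool))])
        host_len = families[instances[host][0]].length
        pos = int(rng.integers(400, host_len - 400))
        guests_of.setdefault(host, []).append((pos, k))

    top_level = [k for k in range(len(instances)) if k not in nested_set]
    order = rng.permutation(len(top_level))
    top_level = [top_level[i] for i in order]

    element_bp = sum(families[instances[k][0]].length for k in range(len(instances)))
    unique_total = cfg.genome_length - element_bp
    if unique_total < len(top_level) + 1:
        raise ValueError("genome_length too small for the configured elements")
    gaps = rng.multinomial(unique_total, np.full(len(top_level) + 1, 1.0 / (len(top_level) + 1)))

    pieces: list[np.ndarray] = []
    seg_start, seg_end, seg_family, seg_elem_off, seg_instance = [], [], [], [], []
    junction_rows: list[tuple[int, str, str, str]] = []
    cursor = 0

    def emit_segment(codes: np.ndarray, fam: int, off: int, inst: int) -> None:
        nonlocal cursor
        if len(codes) == 0:
            return
        pieces.append(codes)
        seg_start.append(cursor)
        seg_end.append(cursor + len(codes))
        seg_family.append(fam)
        seg_elem_off.append(off)
        seg_instance.append(inst)
        cursor += len(codes)

    def emit_instance(k: int) -> None:
        fam, inst = instances[k]
        seq = elem_seqs[fam]
        for_guests = sorted(guests_of.get(k, []))
        prev = 0
        for pos, guest in for_guests:
            emit_segment(seq[prev:pos], fam, prev, inst)
            gfam, ginst = instances[guest]
            junction_rows.append(
                (cursor, families[fam].name, families[gfam].name, "nested")
            )
            emit_segment(elem_seqs[gfam], gfam, 0, ginst)
            junction_rows.append(
                (cursor, families[gfam].name, families[fam].name, "nested")
            )
            prev = pos
        emit_segment(seq[prev:], fam, prev, inst)

    for i, k in enumerate(top_level):
        emit_segment(rng.integers(0, 4, int(gaps[i])).astype(np.uint8), -1, 0, -1)
        fam = instances[k][0]
        if families[fam].kind == "te":
            junction_rows.append((cursor, "unique", families[fam].name, "boundary"))
        emit_instance(k)
        if families[fam].kind == "te":
            junction_rows.append((cursor, families[fam].name, "unique", "boundary"))
    emit_segment(rng.integers(0, 4, int(gaps[-1])).astype(np.uint8), -1, 0, -1)

    genome = np.concatenate(pieces)
    assert len(genome) == cfg.genome_length
    junctions = pd.DataFrame(junction_rows, columns=["gpos", "left", "right", "kind"])
    return GenomeBuild(
        genome=genome,
        families=families,
        seg_start=np.array(seg_start, dtype=np.int64),
        seg_end=np.array(seg_end, dtype=np.int64),
        seg_family=np.array(seg_family, dtype=np.int64),
        seg_elem_off=np.array(seg_elem_off, dtype=np.int64),
        seg_instance=np.array(seg_instance, dtype=np.int64),
        junctions=junctions,
        n_nested=n_nested,
    )


# ---------------------------------------------------------------------------
# genotype 2
# ---------------------------------------------------------------------------

_CAT_NONE, _CAT_GENIC, _CAT_RJ, _CAT_UNCHAR = 0, 1, 2, 3
_CAT_NAMES = {_CAT_GENIC: "genic", _CAT_RJ: "repeat_junction", _CAT_UNCHAR: "uncharacterized"}


def position_categories(build: GenomeBuild, cfg: SimConfig) -> np.ndarray:
    """Per-base planting category: junction windows override genes override
    unique DNA; element interiors otherwise receive no planted SNPs."""
    G = len(build.genome)
    cat = np.full(G, _CAT_NONE, dtype=np.uint8)
    for s, e, f in zip(build.seg_start, build.seg_end, build.seg_family):
        if f == -1:
            cat[s:e] = _CAT_UNCHAR
        elif build.families[f].kind == "gene":
            cat[s:e] = _CAT_GENIC
    for g in build.junctions["gpos"].to_numpy():
        cat[max(0, g - cfg.rj_window) : min(G, g + cfg.rj_window + 1)] = _CAT_RJ
    return cat


def derive_genotype2(
    build: GenomeBuild, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Plant category-specific substitutions; returns (genome2, SNP table)."""
    cat = position_categories(build, cfg)
    rates = np.array([0.0, cfg.snp_rate_genic, cfg.snp_rate_rj, cfg.snp_rate_unchar])
    mask = rng.random(len(build.genome)) < rates[cat]
    pos = np.nonzero(mask)[0]
    genome2 = build.genome.copy()
    shift = rng.integers(1, 4, len(pos)).astype(np.uint8)
    genome2[pos] = (genome2[pos] + shift) % 4
    snps = pd.DataFrame(
        {
            "gpos": pos,
            "ref_base": [dna.BASES[b] for b in build.genome[pos]],
            "alt_base": [dna.BASES[b] for b in genome2[pos]],
            "category": [_CAT_NAMES[c] for c in cat[pos]],
        }
    )
    return genome2, snps


# ---------------------------------------------------------------------------
# long reads (the genotype-1 reference library)
# ---------------------------------------------------------------------------

@dataclass
class LongRead:
    read_id: str
    codes: np.ndarray
    quals: np.ndarray
    origin: str  # "genomic" | "organellar"
    gstart: int
    glen: int  # genome bases consumed
    g2r: np.ndarray  # genome offset -> read position (-1 where deleted)
    events: np.ndarray  # sorted genome offsets of indel events
    cigar: str  # vs the source genome
    replicate_of: str | None = None

    def __len__(self) -> int:
        return len(self.codes)

    def to_read_record(self) -> ReadRecord:
        return ReadRecord(
            self.read_id, dna.decode(self.codes), self.quals.astype(np.int32),
            Platform.LONG_454, Source.GENOMIC,
        )


def _noisy_long_read(
    genome: np.ndarray, start: int, length: int, cfg: SimConfig, rng: np.random.Generator,
    stats: dict,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, str]:
    """Extract genome[start:start+length] with the long-read error model.

    Returns (codes, quals, g2r, event offsets, cigar-vs-genome).
    """
    orig = genome[start : start + length].copy()
    x = np.arange(length) / max(1, length - 1)
    posw = 0.4 + 1.2 * x  # 3' bases err ~4x more than 5' bases, mean 1.0
    sub_mask = rng.random(length) < cfg.long_sub_rate * posw
    sub_pos = np.nonzero(sub_mask)[0]
    orig[sub_pos] = (orig[sub_pos] + rng.integers(1, 4, len(sub_pos)).astype(np.uint8)) % 4

    indel_mask = rng.random(length) < cfg.long_indel_rate * posw
    ev_pos = np.nonzero(indel_mask)[0]
    if len(ev_pos):
        run_adjacent = np.nonzero(orig[1:] == orig[:-1])[0]  # start of a >=2 run
        relocate = rng.random(len(ev_pos)) < cfg.homopolymer_indel_fraction
        if len(run_adjacent):
            ev_pos = ev_pos.copy()
            ev_pos[relocate] = rng.choice(run_adjacent, int(relocate.sum()))
        ev_pos = np.unique(ev_pos)
        ev_pos = ev_pos[(ev_pos > 0) & (ev_pos < length - 1)]
    is_ins = rng.random(len(ev_pos)) < 0.5
    stats["indels"] = stats.get("indels", 0) + len(ev_pos)
    if len(ev_pos):
        run_set = orig[1:] == orig[:-1]
        near_run = np.zeros(length, dtype=bool)
        near_run[:-1] |= run_set
        near_run[1:] |= run_set
        stats["indels_at_runs"] = stats.get("indels_at_runs", 0) + int(
            near_run[ev_pos].sum()
        )

    # assemble read pieces between events
    pieces, gpos_pieces, cig = [], [], []
    prev = 0
    for p, ins in zip(ev_pos, is_ins):
        p = int(p)
        if p > prev:
            pieces.append(orig[prev:p])
            gpos_pieces.append(np.arange(prev, p))
            cig.append(("M", p - prev))
        if ins:
            pieces.append(np.array([rng.integers(0, 4)], dtype=np.uint8))
            gpos_pieces.append(np.array([-1]))
            cig.append(("I", 1))
            prev = p
        else:
            cig.append(("D", 1))
            prev = p + 1
    if length > prev:
        pieces.append(orig[prev:])
        gpos_pieces.append(np.arange(prev, length))
        cig.append(("M", length - prev))
    codes = np.concatenate(pieces) if pieces else np.empty(0, np.uint8)
    gpos = np.concatenate(gpos_pieces) if gpos_pieces else np.empty(0, np.int64)

    # merge adjacent same-type cigar ops
    merged: list[tuple[str, int]] = []
    for op, n in cig:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    cigar = "".join(f"{n}{op}" for op, n in merged)

    g2r = np.full(length, -1, dtype=np.int32)
    valid = gpos >= 0
    g2r[gpos[valid]] = np.nonzero(valid)[0]

    # qualities: 3'-decaying baseline; erroneous bases usually low quality
    quals = np.clip(np.rint(rng.normal(40 - 6 * x, 2.5)), 2, 40).astype(np.int16)
    read_quals = quals[np.clip(gpos, 0, length - 1)]
    err_read_pos = np.nonzero((gpos == -1) | np.isin(gpos, sub_pos))[0]
    if len(err_read_pos):
        low = rng.random(len(err_read_pos)) < cfg.error_lowqual_fraction
        lowq = rng.integers(5, 26, len(err_read_pos))
        highq = rng.integers(33, 41, len(err_read_pos))
        read_quals = read_quals.copy()
        read_quals[err_read_pos] = np.where(low, lowq, highq)
    return codes, read_quals, g2r, ev_pos.astype(np.int64), cigar


def simulate_long_reads(
    build: GenomeBuild, cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[LongRead], list[list[str]], dict]:
    """Genotype-1 long-read library with organellar contamination and
    artificial replicates. Returns (reads, replicate clusters, stats)."""
    G = len(build.genome)
    organellar = rng.integers(0, 4, cfg.organellar_length).astype(np.uint8)
    n_total = round(cfg.long_read_coverage * G / cfg.long_read_len_mean)
    n_rep = round(cfg.replicate_fraction * n_total)
    n_base = n_total - n_rep
    n_org = round(cfg.organellar_fraction * n_total)

    stats: dict = {"organellar_genome": organellar}
    reads: list[LongRead] = []
    lengths = np.clip(
        np.rint(rng.normal(cfg.long_read_len_mean, cfg.long_read_len_sd, n_base)),
        cfg.long_read_min_len, cfg.long_read_max_len,
    ).astype(int)
    is_org = np.zeros(n_base, dtype=bool)
    is_org[:n_org] = True
    for i in range(n_base):
        L = int(lengths[i])
        if is_org[i]:
            src, src_len, origin = organellar, cfg.organellar_length, "organellar"
        else:
            src, src_len, origin = build.genome, G, "genomic"
        start = int(rng.integers(0, src_len - L))
        codes, quals, g2r, events, cigar = _noisy_long_read(src, start, L, cfg, rng, stats)
        reads.append(
            LongRead(f"L{i:06d}", codes, quals, origin, start, L, g2r, events, cigar)
        )

    clusters: list[list[str]] = []
    genomic_idx = np.nonzero(~is_org)[0]
    originals = rng.choice(genomic_idx, n_rep, replace=True)
    members: dict[int, list[str]] = {}
    for j, oi in enumerate(originals):
        orig = reads[int(oi)]
        off = int(rng.integers(0, 3))
        frac = rng.uniform(0.92, 1.0)
        end = max(off + 30, int(round(len(orig.codes) * frac)))
        codes = orig.codes[off:end].copy()
        quals = orig.quals[off:end].copy()
        n_extra = rng.poisson(0.5)
        if n_extra and len(codes) > 1:
            p = rng.integers(0, len(codes), n_extra)
            codes[p] = (codes[p] + rng.integers(1, 4, n_extra).astype(np.uint8)) % 4
            quals[p] = rng.integers(5, 26, n_extra)
        rid = f"L{n_base + j:06d}"
        reads.append(
            LongRead(
                rid, codes, quals, orig.origin, orig.gstart, orig.glen,
                np.full(orig.glen, -1, dtype=np.int32), np.empty(0, np.int64),
                f"{len(codes)}M", replicate_of=orig.read_id,
            )
        )
        members.setdefault(int(oi), []).append(rid)
    for oi, mids in members.items():
        clusters.append([reads[oi].read_id] + mids)
    stats["n_long_reads"] = len(reads)
    stats["n_organellar"] = int(n_org)
    stats["n_replicates"] = n_rep
    return reads, clusters, stats


# ---------------------------------------------------------------------------
# truth hit tables
# ---------------------------------------------------------------------------

def emit_hit_tables(
    build: GenomeBuild,
    reads: Sequence[LongRead],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[HomologyHit], list[HomologyHit], list[HomologyHit]]:
    """Truth-derived (organellar, repeat, gene) hit tables.

    True hits get E-values below 1e-10; a ``hit_noise`` fraction of reads
    additionally receive a spurious repeat hit above the threshold.
    """
    org_hits: list[HomologyHit] = []
    repeat_hits: list[HomologyHit] = []
    gene_hits: list[HomologyHit] = []

    def true_evalue() -> float:
        return 10.0 ** -rng.uniform(15, 60)

    def read_span(read: LongRead, a: int, b: int) -> tuple[int, int] | None:
        sub = read.g2r[a - read.gstart : b - read.gstart]
        sub = sub[sub >= 0]
        if len(sub) < cfg.min_hit_overlap:
            return None
        return int(sub.min()), int(sub.max()) + 1

    for read in reads:
        if read.origin == "organellar":
            org_hits.append(
                HomologyHit(
                    read.read_id, "organelle_ref", DbTag.ORGANELLAR,
                    float(rng.uniform(95, 100)), 0, len(read), true_evalue(),
                )
            )
            continue
        if read.replicate_of is not None:
            # replicates inherit homology from the template region; emit from
            # the original's coordinates (annotation sees them pre-removal)
            pass
        s, e = read.gstart, read.gstart + read.glen
        lo = int(np.searchsorted(build.seg_end, s, side="right"))
        hi = int(np.searchsorted(build.seg_start, e, side="left"))
        for si in range(lo, hi):
            fam_idx = build.seg_family[si]
            if fam_idx < 0:
                continue
            fam = build.families[fam_idx]
            a = max(s, int(build.seg_start[si]))
            b = min(e, int(build.seg_end[si]))
            if b - a < cfg.min_hit_overlap:
                continue
            if read.replicate_of is not None:
                span = (0, min(len(read), b - a))  # coarse but pre-removal only
            else:
                span = read_span(read, a, b)
            if span is None:
                continue
            ident = float(rng.uniform(95, 100))
            if fam.kind == "te":
                repeat_hits.append(
                    HomologyHit(read.read_id, fam.name, DbTag.REPEAT, ident,
                                span[0], span[1], true_evalue())
                )
                if fam.te_gene_hit:
                    gene_hits.append(
                        HomologyHit(read.read_id, f"TE|{fam.name}_pol", DbTag.GENE_PROT,
                                    ident, span[0], span[1], true_evalue())
                    )
            elif fam.kind == "gene" and fam.characterized:
                gene_hits.append(
                    HomologyHit(read.read_id, fam.name, DbTag.GENE_NT, ident,
                                span[0], span[1], true_evalue())
                )
        n_te_fams = len(cfg.resolved_te_library())
        if n_te_fams and rng.random() < cfg.hit_noise:
            fam = build.families[int(rng.integers(0, n_te_fams))]
            end = min(len(read), cfg.min_hit_overlap + 20)
            repeat_hits.append(
                HomologyHit(read.read_id, fam.name, DbTag.REPEAT,
                            float(rng.uniform(70, 90)), 0, end,
                            10.0 ** -rng.uniform(2, 9))
            )
    return org_hits, repeat_hits, gene_hits


# ---------------------------------------------------------------------------
# read truth categories and mapping targets
# ---------------------------------------------------------------------------

def _read_truth_category(build: GenomeBuild, read: LongRead, cfg: SimConfig) -> tuple[str, bool]:
    """(category, junction_bearing) from truth intervals, mirroring the hit
    rules the annotator will apply."""
    if read.origin == "organellar":
        return "organellar", False
    s, e = read.gstart, read.gstart + read.glen
    lo = int(np.searchsorted(build.seg_end, s, side="right"))
    hi = int(np.searchsorted(build.seg_start, e, side="left"))
    has_te = has_gene_char = has_gene_unchar = False
    for si in range(lo, hi):
        fam_idx = build.seg_family[si]
        if fam_idx < 0:
            continue
        fam = build.families[fam_idx]
        overlap = min(e, int(build.seg_end[si])) - max(s, int(build.seg_start[si]))
        if overlap < cfg.min_hit_overlap:
            continue
        if fam.kind == "te":
            has_te = True
        elif fam.kind == "gene":
            if fam.characterized:
                has_gene_char = True
            else:
                has_gene_unchar = True
    junction_bearing = False
    if has_te:
        g = build.junctions["gpos"].to_numpy()
        inside = g[(g - s >= cfg.min_hit_overlap) & (e - g >= cfg.min_hit_overlap)]
        junction_bearing = len(inside) > 0
        return ("repeat_junction" if junction_bearing else "repeat"), junction_bearing
    if has_gene_char:
        return "gene_char", False
    if has_gene_unchar:
        return "gene_unchar", False
    return "uncharacterized", False


class _TargetIndex:
    """Bucketed interval index from genome coordinates to candidate
    reference reads, plus flattened genome->read projection arrays."""

    def __init__(self, build: GenomeBuild, reads: Sequence[LongRead], cfg: SimConfig):
        categories = []
        target = []
        for r in reads:
            cat, _ = _read_truth_category(build, r, cfg)
            categories.append(cat)
            ok = (
                r.origin == "genomic"
                and r.replicate_of is None
                and (cfg.map_to_repeat_refs or cat != "repeat")
            )
            target.append(ok)
        self.categories = categories
        self.target_mask = np.array(target, dtype=bool)
        self.reads = reads
        idx = np.nonzero(self.target_mask)[0]
        self.target_ids = idx
        self.gstart = np.array([reads[i].gstart for i in idx], dtype=np.int64)
        self.gend = self.gstart + np.array([reads[i].glen for i in idx], dtype=np.int64)
        glens = np.array([reads[i].glen for i in idx], dtype=np.int64)
        self.gofs = np.concatenate([[0], np.cumsum(glens)])
        self.g2r_flat = (
            np.concatenate([reads[i].g2r for i in idx])
            if len(idx) else np.empty(0, np.int32)
        )
        evcum_parts = []
        for i in idx:
            r = reads[i]
            ev = np.zeros(r.glen, dtype=np.int32)
            if len(r.events):
                np.add.at(ev, r.events, 1)
            evcum_parts.append(np.cumsum(ev))
        self.evcum_flat = (
            np.concatenate(evcum_parts) if evcum_parts else np.empty(0, np.int64)
        )
        G = len(build.genome)
        n_buckets = (G >> _BUCKET_SHIFT) + 2
        bucket_lists: list[list[int]] = [[] for _ in range(n_buckets)]
        for t, i in enumerate(idx):
            r = reads[i]
            for b in range(r.gstart >> _BUCKET_SHIFT, (r.gstart + r.glen - 1 >> _BUCKET_SHIFT) + 1):
                bucket_lists[b].append(t)
        width = max(1, max(len(b) for b in bucket_lists))
        self.buckets = np.full((n_buckets, width), -1, dtype=np.int32)
        for b, lst in enumerate(bucket_lists):
            self.buckets[b, : len(lst)] = lst

    def candidates(self, tstarts: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
        """For each target genome start, the candidate target-read rows fully
        containing [tstart, tstart+L). Returns (row indices, target index)."""
        cand = self.buckets[tstarts >> _BUCKET_SHIFT]  # (n, W)
        valid = cand >= 0
        t = np.where(valid, cand, 0)
        valid &= (self.gstart[t] <= tstarts[:, None]) & (self.gend[t] >= (tstarts + L)[:, None])
        rows, cols = np.nonzero(valid)
        return rows, cand[rows, cols]


# ---------------------------------------------------------------------------
# short reads of genotype 2
# ---------------------------------------------------------------------------

def _project_with_events(g2r: np.ndarray, a: int, L: int) -> tuple[int, str] | None:
    """Walk the genome->read map to produce (ref_start, cigar) for a short
    read spanning indel events of the reference long read."""
    ops: list[tuple[str, int]] = []
    r1 = -1
    prev = -1
    for g in range(a, a + L):
        r = int(g2r[g])
        if r < 0:
            op = "I"
        else:
            if r1 < 0:
                r1 = r
            if prev >= 0 and r > prev + 1:
                ops.append(("D", r - prev - 1))
            prev = r
            op = "M"
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    if r1 < 0:
        return None
    return r1, "".join(f"{n}{o}" for o, n in ops)


def simulate_short_reads(
    build: GenomeBuild,
    genome2: np.ndarray,
    index: _TargetIndex,
    key: tuple[Platform, Source],
    spec: ShortPlatformSpec,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> AlignmentSet:
    """Sample genotype-2 reads for one platform/source and place them on the
    long-read reference set (report-all homologous placement)."""
    platform, source = key
    G = len(genome2)
    L = spec.read_len

    if source is Source.CDNA:
        gene_segs = np.nonzero(
            (build.seg_family >= 0)
            & np.array([f >= 0 and build.families[f].kind == "gene" and build.families[f].expressed
                        for f in build.seg_family])
            & (build.seg_end - build.seg_start >= L + 10)
        )[0]
        if len(gene_segs) == 0:
            return _empty_alignment_set(platform, source)
        seg_lens = (build.seg_end - build.seg_start)[gene_segs]
        total = int(seg_lens.sum())
        n = round(spec.coverage * total / L)
        pick = rng.choice(len(gene_segs), n, p=seg_lens / total)
        offs = (rng.random(n) * (seg_lens[pick] - L)).astype(np.int64)
        starts = build.seg_start[gene_segs[pick]] + offs
    else:
        n = round(spec.coverage * G / L)
        starts = rng.integers(0, G - L, n)
    starts = np.sort(starts)

    # sequences with platform substitution errors
    seq = genome2[starts[:, None] + np.arange(L)].reshape(n, L).copy()
    err = rng.random(n * L) < spec.sub_rate
    err_idx = np.nonzero(err)[0]
    flat = seq.reshape(-1)
    flat[err_idx] = (flat[err_idx] + rng.integers(1, 4, len(err_idx)).astype(np.uint8)) % 4
    mapq = np.full(n, spec.mapq, dtype=np.int16)
    mapq[rng.random(n) < spec.low_mapq_fraction] = 10

    # homologous placement
    seg_idx = np.searchsorted(build.seg_start, starts, side="right") - 1
    within = starts + L <= build.seg_end[seg_idx]
    fam_of_read = np.where(within, build.seg_family[seg_idx], -2)

    fam_segs: dict[int, np.ndarray] = {}
    for f in np.unique(build.seg_family):
        if f >= 0:
            fam_segs[int(f)] = np.nonzero(build.seg_family == f)[0]

    read_rows: list[np.ndarray] = []
    tstart_rows: list[np.ndarray] = []
    multi = np.zeros(n, dtype=bool)
    for f, segs in fam_segs.items():
        if len(segs) < 2:
            continue
        r_idx = np.nonzero(fam_of_read == f)[0]
        if len(r_idx) == 0:
            continue
        multi[r_idx] = True
        off = starts[r_idx] - build.seg_start[seg_idx[r_idx]] + build.seg_elem_off[seg_idx[r_idx]]
        for t in segs:
            ts = off + (build.seg_start[t] - build.seg_elem_off[t])
            ok = (ts >= build.seg_start[t]) & (ts + L <= build.seg_end[t])
            read_rows.append(r_idx[ok])
            tstart_rows.append(ts[ok])
    solo = np.nonzero(~multi)[0]
    read_rows.append(solo)
    tstart_rows.append(starts[solo])
    a_read = np.concatenate(read_rows)
    a_tstart = np.concatenate(tstart_rows)

    rows, tgt = index.candidates(a_tstart, L)
    a_read = a_read[rows]
    a_tstart = a_tstart[rows]

    # projection onto read coordinates
    a = a_tstart - index.gstart[tgt]
    base = index.gofs[tgt]
    r1 = index.g2r_flat[base + a]
    glen = index.gofs[tgt + 1] - base
    hi_idx = np.minimum(a + L, glen - 1)
    n_events = index.evcum_flat[base + hi_idx] - np.where(
        a >= 2, index.evcum_flat[base + np.maximum(a - 2, 0)], 0
    )
    plain = (n_events == 0) & (r1 >= 0)

    cigars: list[str | None] = [None] * len(a_read)
    ref_start = r1.astype(np.int64)
    drop = np.zeros(len(a_read), dtype=bool)
    for i in np.nonzero(~plain)[0]:
        res = _project_with_events(
            index.g2r_flat[base[i] : base[i] + glen[i]], int(a[i]), L
        )
        if res is None:
            drop[i] = True
        else:
            ref_start[i], cigars[i] = res[0], res[1]
            if res[1] == f"{L}M":
                cigars[i] = None
    keep = ~drop
    a_read, a_tstart, tgt = a_read[keep], a_tstart[keep], tgt[keep]
    ref_start = ref_start[keep]
    cigars = [c for c, k in zip(cigars, keep) if k]

    order = np.lexsort((ref_start, tgt))
    a_read, tgt, ref_start = a_read[order], tgt[order], ref_start[order]
    cigars = [cigars[i] for i in order]

    ref_names = [index.reads[i].read_id for i in index.target_ids]
    qual_flat = np.full(n * L, 34, dtype=np.uint8)
    return AlignmentSet(
        ref_names=ref_names,
        ref_index=tgt,
        ref_start=ref_start,
        seq_flat=seq.reshape(-1),
        seq_start=a_read.astype(np.int64) * L,
        seq_len=np.full(len(a_read), L, dtype=np.int64),
        mapq=mapq[a_read],
        reverse=np.zeros(len(a_read), dtype=bool),
        platform=platform,
        source=source,
        cigars=cigars,
        qual_flat=qual_flat,
        read_ids=None,
    )


def _empty_alignment_set(platform: Platform, source: Source) -> AlignmentSet:
    z = np.empty(0, np.int64)
    return AlignmentSet(
        ref_names=[], ref_index=z, ref_start=z, seq_flat=np.empty(0, np.uint8),
        seq_start=z, seq_len=z, mapq=np.empty(0, np.int16),
        reverse=np.empty(0, bool), platform=platform, source=source,
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    segments: pd.DataFrame
    junctions: pd.DataFrame
    snps: pd.DataFrame
    reads: pd.DataFrame
    replicate_clusters: list[list[str]]
    n_nested: int


@dataclass
class SimulatedDataset:
    cfg: SimConfig
    build: GenomeBuild
    genome2: np.ndarray
    long_reads: list[LongRead]
    alignments: dict[tuple[Platform, Source], AlignmentSet]
    organellar_hits: list[HomologyHit]
    repeat_hits: list[HomologyHit]
    gene_hits: list[HomologyHit]
    truth: TruthSet
    stats: dict
    index: "_TargetIndex"

    def long_read_records(self) -> list[ReadRecord]:
        return [r.to_read_record() for r in self.long_reads]

    def reference_records(self) -> dict[str, ReadRecord]:
        return {r.read_id: r.to_read_record() for r in self.long_reads}

    def reference_lengths(self) -> dict[str, int]:
        return {r.read_id: len(r) for r in self.long_reads}

    def snp_sites_on_reads(self) -> pd.DataFrame:
        """Planted SNPs projected onto every target reference read covering
        them: columns (ref_id, pos, gpos, ref_base, alt_base, category)."""
        rows = []
        idx = self.index
        for gpos, refb, altb, cat in self.truth.snps.itertuples(index=False):
            ts = np.array([gpos], dtype=np.int64)
            r, tgt = idx.candidates(ts, 1)
            for t in tgt:
                a = int(gpos - idx.gstart[t])
                rp = int(idx.g2r_flat[idx.gofs[t] + a])
                if rp < 0:
                    continue
                rows.append(
                    {
                        "ref_id": idx.reads[idx.target_ids[t]].read_id,
                        "pos": rp,
                        "gpos": int(gpos),
                        "ref_base": refb,
                        "alt_base": altb,
                        "category": cat,
                    }
                )
        return pd.DataFrame(
            rows, columns=["ref_id", "pos", "gpos", "ref_base", "alt_base", "category"]
        )

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fastq(self.long_read_records(), out / "long_reads.fastq")
        write_fasta(
            [ReadRecord("genotype1", dna.decode(self.build.genome))], out / "genotype1.fasta"
        )
        write_fasta(
            [ReadRecord("genotype2", dna.decode(self.genome2))], out / "genotype2.fasta"
        )
        write_hit_table(self.organellar_hits, out / "organellar_hits.tsv")
        write_hit_table(self.repeat_hits, out / "repeat_hits.tsv")
        write_hit_table(self.gene_hits, out / "gene_hits.tsv")
        ref_lens = self.reference_lengths()
        for (p, s), aset in self.alignments.items():
            write_sam(aset, ref_lens, out / f"aln_{p.name}_{s.name}.sam")
        write_tsv(self.truth.snps, out / "truth_snps.tsv")
        write_tsv(self.truth.junctions, out / "truth_junctions.tsv")
        write_tsv(self.truth.reads, out / "truth_reads.tsv")
        write_tsv(self.truth.segments, out / "truth_segments.tsv")
        with open(out / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(self.cfg.to_dict(), fh, sort_keys=False)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Run the full generator: genome, genotypes, reads, alignments, hits."""
    rng = np.random.default_rng(cfg.seed)
    build = build_genome(cfg, rng)
    genome2, snps = derive_genotype2(build, cfg, rng)
    reads, clusters, stats = simulate_long_reads(build, cfg, rng)
    org_hits, rep_hits, gene_hits = emit_hit_tables(build, reads, cfg, rng)
    index = _TargetIndex(build, reads, cfg)
    alignments: dict[tuple[Platform, Source], AlignmentSet] = {}
    for key in sorted(cfg.short_platforms, key=lambda k: (k[0].name, k[1].name)):
        alignments[key] = simulate_short_reads(
            build, genome2, index, key, cfg.short_platforms[key], cfg, rng
        )
    read_rows = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "origin": [r.origin for r in reads],
            "gstart": [r.gstart for r in reads],
            "glen": [r.glen for r in reads],
            "length": [len(r) for r in reads],
            "replicate_of": [r.replicate_of or "" for r in reads],
            "category": index.categories,
            "is_target": index.target_mask,
        }
    )
    truth = TruthSet(
        segments=build.segments_frame(),
        junctions=build.junctions,
        snps=snps,
        reads=read_rows,
        replicate_clusters=clusters,
        n_nested=build.n_nested,
    )
    return SimulatedDataset(
        cfg=cfg,
        build=build,
        genome2=genome2,
        long_reads=reads,
        alignments=alignments,
        organellar_hits=org_hits,
        repeat_hits=rep_hits,
        gene_hits=gene_hits,
        truth=truth,
        stats=stats,
        index=index,
    )


def simulate_reads(
    build: GenomeBuild,
    genotype: np.ndarray,
    cfg: SimConfig,
    key: tuple[Platform, Source],
    rng: np.random.Generator | None = None,
    index: _TargetIndex | None = None,
    reads: Sequence[LongRead] | None = None,
):
    """Spec-level convenience: simulate one platform's reads.

    For the long-read platform returns (LongReads, clusters, stats); for a
    short platform returns the :class:`AlignmentSet` of truth placements
    (requires ``index`` built over the long reads).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if key[0] is Platform.LONG_454 and key not in cfg.short_platforms:
        return simulate_long_reads(build, cfg, rng)
    if index is None:
        if reads is None:
            raise ValueError("short-read simulation needs a target index or long reads")
        index = _TargetIndex(build, reads, cfg)
    return simulate_short_reads(
        build, genotype, index, key, cfg.short_platforms[key], cfg, rng
    )
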