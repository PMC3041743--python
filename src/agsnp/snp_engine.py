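"""Pileup construction, substitution-only variant calling, and
cross-platform merging.

Only single-nucleotide substitutions are ever emitted as candidate calls:
on a long-read reference most short INDEL evidence is homopolymer
sequencing error, so insertions contribute no column and deletion-spanning
observations are excluded from base counts. All stringency lives in the
filter stage (``min_alt`` is 1 here) so that filter combinations can be
studied on the raw candidate set.

Two equivalent pileup paths exist: :func:`build_pileup` yields explicit
per-column records, and :func:`pileup_arrays` computes the same counts as
numpy arrays for whole-dataset runs. Their equivalence is asserted by the
test suite against a brute-force coordinate-walking oracle.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import dna
from .annotate import Category
from .formats import (
    AlignmentRecord,
    AlignmentSet,
    Platform,
    Source,
    cigar_query_length,
    parse_cigar,
)

#: flag given to calls dropped because platforms disagree on the alternate allele
ALT_CONFLICT = "ALT_CONFLICT"


@dataclass
class PileupColumn:
    ref_id: str
    pos: int
    ref_base: str
    base_counts: dict[str, int]
    quals: list[int]
    mapqs: list[int]
    platform: Platform
    source: Source
    n_count: int = 0
    del_count: int = 0
    obs_bases: list[str] = field(default_factory=list)  # per-observation, order matches quals/mapqs

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.n_count


@dataclass
class VariantCall:
    ref_id: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int
    consensus_base_ratio: float
    alt_min_mapq: int = 255
    min_mapq_pass: bool = True
    platform_depths: dict[tuple[Platform, Source], int] = field(default_factory=dict)
    filter_flags: set[str] = field(default_factory=set)
    category: Category | None = None
    rj_near: bool = False

    @property
    def platforms(self) -> set[tuple[Platform, Source]]:
        return set(self.platform_depths)


# ---------------------------------------------------------------------------
# column-wise pileup
# ---------------------------------------------------------------------------

def build_pileup(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    references: Mapping[str, str],
    platform: Platform | None = None,
    source: Source | None = None,
) -> list[PileupColumn]:
    """Build one pileup column per covered reference position.

    Insertions in a read contribute no column; a deletion contributes to
    ``del_count`` of the deleted reference positions, with the observation
    excluded from base counts. N observations count toward depth but not
    toward any allele. Raises on CIGAR/sequence length mismatch.
    """
    if isinstance(alignments, AlignmentSet):
        platform = platform or alignments.platform
        source = source or alignments.source
        alignments = list(alignments)
    else:
        alignments = list(alignments)
        if alignments:
            platform = platform or alignments[0].platform
            source = source or alignments[0].source

    per_ref: dict[str, dict[int, PileupColumn]] = defaultdict(dict)
    for rec in alignments:
        if rec.ref_id not in references:
            raise KeyError(f"alignment {rec.read_id}: unknown reference {rec.ref_id}")
        ref_seq = references[rec.ref_id]
        cols = per_ref[rec.ref_id]
        seq = rec.sequence
        quals = rec.qualities
        if cigar_query_length(rec.cigar) != len(seq):
            raise ValueError(
                f"alignment {rec.read_id}: CIGAR {rec.cigar} consumes "
                f"{cigar_query_length(rec.cigar)} query bases, sequence has {len(seq)}"
            )
        rpos = rec.ref_start
        qpos = 0
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for k in range(n):
                    col = _get_column(cols, rec.ref_id, rpos + k, ref_seq, platform, source)
                    base = seq[qpos + k]
                    if base == "N":
                        col.n_count += 1
                    else:
                        col.base_counts[base] += 1
                        col.obs_bases.append(base)
                        col.quals.append(int(quals[qpos + k]) if quals is not None else 0)
                        col.mapqs.append(rec.mapq)
                rpos += n
                qpos += n
            elif op == "I":
                qpos += n
            elif op in "DN":
                for k in range(n):
                    col = _get_column(cols, rec.ref_id, rpos + k, ref_seq, platform, source)
                    col.del_count += 1
                rpos += n
            elif op == "S":
                qpos += n
            elif op == "H":
                pass
            else:
                raise ValueError(f"alignment {rec.read_id}: unsupported CIGAR op {op}")
        if qpos != len(seq):
            raise ValueError(
                f"alignment {rec.read_id}: CIGAR consumes {qpos} query bases, "
                f"sequence has {len(seq)}"
            )

    out: list[PileupColumn] = []
    for ref_id in per_ref:
        out.extend(per_ref[ref_id][p] for p in sorted(per_ref[ref_id]))
    return out


def _get_column(cols, ref_id, pos, ref_seq, platform, source) -> PileupColumn:
    col = cols.get(pos)
    if col is None:
        if pos >= len(ref_seq):
            raise ValueError(f"pileup position {pos} beyond reference {ref_id}")
        col = PileupColumn(
            ref_id, pos, ref_seq[pos], {b: 0 for b in "ACGT"}, [], [], platform, source
        )
        cols[pos] = col
    return col


def call_substitutions(
    columns: Iterable[PileupColumn], min_alt: int = 1
) -> list[VariantCall]:
    """Emit a candidate call wherever the majority non-reference base has
    count >= min_alt (ties broken toward the alphabetically first base)."""
    calls: list[VariantCall] = []
    for col in columns:
        if col.ref_base not in "ACGT":
            continue
        alt, alt_count = None, 0
        for b in "ACGT":
            if b != col.ref_base and col.base_counts[b] > alt_count:
                alt, alt_count = b, col.base_counts[b]
        if alt is None or alt_count < min_alt:
            continue
        depth = col.depth
        mapqs = [mq for b, mq in zip(col.obs_bases, col.mapqs) if b == alt]
        calls.append(
            VariantCall(
                ref_id=col.ref_id,
                pos=col.pos,
                ref_base=col.ref_base,
                alt_base=alt,
                depth=depth,
                alt_count=alt_count,
                consensus_base_ratio=alt_count / depth,
                alt_min_mapq=min(mapqs) if mapqs else 255,
                platform_depths={(col.platform, col.source): depth},
            )
        )
    return calls


# ---------------------------------------------------------------------------
# array pileup (production path)
# ---------------------------------------------------------------------------

def pileup_arrays(
    aset: AlignmentSet,
    reference_lengths: Mapping[str, int],
    target_refs: set[str] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Vectorised pileup over an alignment set.

    Returns per reference a dict with ``counts`` (L,5 array: A,C,G,T,N),
    ``del_count`` (L,), and ``min_mapq`` (L,4) -- the minimum mapping
    quality among observations of each base. Only references in
    ``target_refs`` (default: all) are piled.
    """
    names = aset.ref_names
    if target_refs is None:
        use_ref = np.ones(len(names), dtype=bool)
    else:
        use_ref = np.array([n in target_refs for n in names], dtype=bool)
    ref_len = np.array([reference_lengths[n] if use_ref[i] else 0 for i, n in enumerate(names)])
    offsets = np.concatenate([[0], np.cumsum(ref_len)])
    total = int(offsets[-1])
    counts_flat = np.zeros(total * 5, dtype=np.int32)
    minmapq = np.full((total, 4), 255, dtype=np.int16)
    del_count = np.zeros(total, dtype=np.int32)

    keep = use_ref[aset.ref_index]
    plain = np.array([c is None for c in aset.cigars], dtype=bool) & keep
    idx_plain = np.nonzero(plain)[0]
    if idx_plain.size:
        lens = aset.seq_len[idx_plain]
        base_off = (
            offsets[aset.ref_index[idx_plain]]
            + aset.ref_start[idx_plain]
            - aset.seq_start[idx_plain]
        )
        # global reference position of every observed base
        gpos = np.repeat(base_off, lens) + _concat_aranges(aset.seq_start[idx_plain], lens)
        codes = _gather_codes(aset, idx_plain, lens)
        np.add.at(counts_flat, gpos * 5 + codes, 1)
        obs_mapq = np.repeat(aset.mapq[idx_plain], lens)
        acgt = codes < 4
        np.minimum.at(minmapq, (gpos[acgt], codes[acgt].astype(np.int64)), obs_mapq[acgt])

    # alignments with indels: walk CIGARs individually (rare)
    for i in np.nonzero(~plain & keep)[0]:
        seq = aset.seq_codes(i)
        base = offsets[aset.ref_index[i]]
        rpos = int(aset.ref_start[i])
        qpos = 0
        mq = int(aset.mapq[i])
        for op, n in parse_cigar(aset.cigars[i]):
            if op in "M=X":
                g = base + rpos + np.arange(n)
                c = seq[qpos : qpos + n].astype(np.int64)
                np.add.at(counts_flat, g * 5 + c, 1)
                acgt = c < 4
                np.minimum.at(minmapq, (g[acgt], c[acgt]), mq)
                rpos += n
                qpos += n
            elif op == "I" or op == "S":
                qpos += n
            elif op in "DN":
                del_count[base + rpos : base + rpos + n] += 1
                rpos += n

    counts = counts_flat.reshape(total, 5)
    out: dict[str, dict[str, np.ndarray]] = {}
    for ri, name in enumerate(names):
        if not use_ref[ri]:
            continue
        s, e = int(offsets[ri]), int(offsets[ri + 1])
        out[name] = {
            "counts": counts[s:e],
            "del_count": del_count[s:e],
            "min_mapq": minmapq[s:e],
        }
    return out


def _concat_aranges(starts: np.ndarray, lens: np.ndarray) -> np.ndarray:
    """Concatenation of [starts[i], starts[i]+lens[i]) as one array."""
    total = int(lens.sum())
    out = np.repeat(starts, lens) + (
        np.arange(total) - np.repeat(np.concatenate([[0], np.cumsum(lens)[:-1]]), lens)
    )
    return out


def _gather_codes(aset: AlignmentSet, idx: np.ndarray, lens: np.ndarray) -> np.ndarray:
    flat_idx = _concat_aranges(aset.seq_start[idx], lens)
    return aset.seq_flat[flat_idx].astype(np.int64)


def calls_from_arrays(
    piles: Mapping[str, Mapping[str, np.ndarray]],
    reference_codes: Mapping[str, np.ndarray],
    platform: Platform,
    source: Source,
    min_alt: int = 1,
) -> list[VariantCall]:
    """Candidate substitutions from array pileups (same rule as
    :func:`call_substitutions`)."""
    calls: list[VariantCall] = []
    for ref_id, pile in piles.items():
        counts = pile["counts"]
        ref_codes = reference_codes[ref_id][: len(counts)]
        depth = counts.sum(axis=1)
        acgt = counts[:, :4].copy()
        rows = np.arange(len(acgt))
        valid_ref = ref_codes < 4
        acgt[rows[valid_ref], ref_codes[valid_ref]] = -1
        alt_code = np.argmax(acgt, axis=1)
        alt_count = acgt[rows, alt_code]
        site = valid_ref & (alt_count >= min_alt)
        for p in np.nonzero(site)[0]:
            ac = int(alt_count[p])
            d = int(depth[p])
            calls.append(
                VariantCall(
                    ref_id=ref_id,
                    pos=int(p),
                    ref_base=dna.BASES[ref_codes[p]],
                    alt_base=dna.BASES[alt_code[p]],
                    depth=d,
                    alt_count=ac,
                    consensus_base_ratio=ac / d,
                    alt_min_mapq=int(pile["min_mapq"][p, alt_code[p]]),
                    platform_depths={(platform, source): d},
                )
            )
    return calls


# ---------------------------------------------------------------------------
# merging across platforms / sources
# ---------------------------------------------------------------------------

def merge_platform_calls(call_sets: Sequence[Sequence[VariantCall]]) -> list[VariantCall]:
    """Merge candidate calls from several platform/source batches.

    Calls at the same (ref_id, pos, alt) sum depth and alt_count and
    recompute the consensus base ratio from the merged counts; their
    platform provenance is unioned. Positions where batches disagree on the
    alternate allele are all retained but flagged ALT_CONFLICT (the filter
    stage drops them).
    """
    by_site: dict[tuple[str, int], dict[str, VariantCall]] = defaultdict(dict)
    for calls in call_sets:
        for c in calls:
            site = by_site[(c.ref_id, c.pos)]
            m = site.get(c.alt_base)
            if m is None:
                site[c.alt_base] = VariantCall(
                    ref_id=c.ref_id,
                    pos=c.pos,
                    ref_base=c.ref_base,
                    alt_base=c.alt_base,
                    depth=c.depth,
                    alt_count=c.alt_count,
                    consensus_base_ratio=c.consensus_base_ratio,
                    alt_min_mapq=c.alt_min_mapq,
                    platform_depths=dict(c.platform_depths),
                    filter_flags=set(c.filter_flags),
                    category=c.category,
                )
            else:
                m.depth += c.depth
                m.alt_count += c.alt_count
                m.consensus_base_ratio = m.alt_count / m.depth
                m.alt_min_mapq = min(m.alt_min_mapq, c.alt_min_mapq)
                for key, d in c.platform_depths.items():
                    m.platform_depths[key] = m.platform_depths.get(key, 0) + d
                m.filter_flags |= c.filter_flags
    merged: list[VariantCall] = []
    for (ref_id, pos), site in by_site.items():
        if len(site) > 1:
            for c in site.values():
                c.filter_flags.add(ALT_CONFLICT)
        merged.extend(site.values())
    merged.sort(key=lambda c: (c.ref_id, c.pos, c.alt_base))
    return merged


def calls_to_frame(calls: Iterable[VariantCall]):
    """Serialize calls to a DataFrame (intermediate TSV representation)."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            {
                "ref_id": c.ref_id,
                "pos": c.pos,
                "ref_base": c.ref_base,
                "alt_base": c.alt_base,
                "depth": c.depth,
                "alt_count": c.alt_count,
                "alt_min_mapq": c.alt_min_mapq,
                "platform_depths": ",".join(
                    f"{p.name}:{s.name}={d}" for (p, s), d in sorted(
                        c.platform_depths.items(), key=lambda kv: (kv[0][0].name, kv[0][1].name)
                    )
                ),
                "flags": ";".join(sorted(c.filter_flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ref_id", "pos", "ref_base", "alt_base", "depth", "alt_count",
            "alt_min_mapq", "platform_depths", "flags",
        ],
    )


def calls_from_frame(df) -> list[VariantCall]:
    """Inverse of :func:`calls_to_frame` (consensus base ratio is
    recomputed from the integer counts, so the round trip is exact)."""
    calls = []
    for row in df.itertuples(index=False):
        pd_map: dict[tuple[Platform, Source], int] = {}
        if isinstance(row.platform_depths, str) and row.platform_depths:
            for item in row.platform_depths.split(","):
                key, d = item.split("=")
                p, s = key.split(":")
                pd_map[(Platform[p], Source[s])] = int(d)
        flags = set()
        if isinstance(row.flags, str) and row.flags:
            flags = set(row.flags.split(";"))
        calls.append(
            VariantCall(
                ref_id=row.ref_id,
                pos=int(row.pos),
                ref_base=row.ref_base,
                alt_base=row.alt_base,
                depth=int(row.depth),
                alt_count=int(row.alt_count),
                consensus_base_ratio=int(row.alt_count) / int(row.depth),
                alt_min_mapq=int(row.alt_min_mapq),
                platform_depths=pd_map,
                filter_flags=flags,
            )
        )
    return calls


def provenance_report(merged_calls: Iterable[VariantCall]):
    """Counts of SNPs per distinct platform-combination string."""
    import pandas as pd

    from .formats import combo_string

    counts: dict[str, int] = defaultdict(int)
    for c in merged_calls:
        counts[combo_string(c.platforms)] += 1
    df = pd.DataFrame(
        {"platform_combination": list(counts), "n_snps": list(counts.values())}
    )
    return df.sort_values("platform_combination", ignore_index=True)
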