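"""The putative-SNP filter stack.

Candidate substitutions survive only if the reference read is long enough
(>= 200 bp) and single-copy, the merged depth is adequate but not
repeat-inflated (per-platform maxima), the consensus base ratio is >= 0.9
(excluding heterozygous loci and alignment noise), every alt observation
maps at quality >= 20, the reference base passes the Q30 / NQS-20
neighbourhood quality standard over an 11-base window, the site is not in
or creating a homopolymer run (the dominant pyrosequencing error mode),
no other candidate lies within 3 bp, and the site is more than 30 bp from
the 3' end of the reference, where long-read quality decays.
Uncharacterized references -- mostly unknown low-copy repeats -- face a
stricter depth ceiling and must carry exactly one passing SNP.

Every rejected call lands in a ledger with its first failing criterion in
the fixed filter order; the passing set itself does not depend on that
order.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import Category, CopyClass, ReadAnnotation, RepeatJunction
from .formats import Platform, ReadRecord, Source
from .snp_engine import ALT_CONFLICT, VariantCall

# rejection flags, in ledger order
FLAG_ALT_CONFLICT = ALT_CONFLICT
FLAG_REF_LEN = "REF_LEN"
FLAG_NOT_SINGLE_COPY = "NOT_SINGLE_COPY"
FLAG_MIN_DEPTH = "MIN_DEPTH"
FLAG_MAX_DEPTH = "MAX_DEPTH"
FLAG_CBR = "CBR"
FLAG_MAPQ = "MAPQ"
FLAG_SNP_QUAL = "SNP_QUAL"
FLAG_HOMOPOLYMER = "HOMOPOLYMER"
FLAG_CLOSE_SNP = "CLOSE_SNP"
FLAG_THREE_PRIME = "THREE_PRIME"
FLAG_UNCHAR_DEPTH = "UNCHAR_DEPTH"
FLAG_UNCHAR_MULTI_SNP = "UNCHAR_MULTI_SNP"


def _default_max_depth() -> dict[tuple[Platform, Source], int]:
    return {
        (Platform.LONG_454, Source.GENOMIC): 5,
        (Platform.SOLEXA, Source.GENOMIC): 10,
        (Platform.SOLID, Source.GENOMIC): 50,
        (Platform.SOLID, Source.CDNA): 100,
    }


def _default_unchar_max_depth() -> dict[tuple[Platform, Source], int]:
    return {
        (Platform.LONG_454, Source.GENOMIC): 5,
        (Platform.SOLEXA, Source.GENOMIC): 5,
        (Platform.SOLID, Source.GENOMIC): 25,
    }


@dataclass
class FilterConfig:
    """Thresholds of the filter stack (defaults are the published criteria)."""

    min_ref_len: int = 200
    min_depth: int = 3
    max_depth: dict[tuple[Platform, Source], int] = field(default_factory=_default_max_depth)
    min_cbr: float = 0.9
    min_mapq: int = 20
    min_snp_qual: int = 30
    nqs_flank: int = 5  # 11-base window: pos +/- 5
    min_nqs_qual: int = 20
    homopolymer_len: int = 3
    min_snp_spacing: int = 4  # required distance; <= 3 bp apart is rejected
    three_prime_margin: int = 30
    illumina_spacing: int = 60  # optional genotyping-assay stage
    illumina_flank: int = 50
    unchar_max_depth: dict[tuple[Platform, Source], int] = field(
        default_factory=_default_unchar_max_depth
    )
    unchar_single_snp_only: bool = True
    rj_window: int = 50

    def to_yaml(self, path) -> None:
        def _depth_map(m):
            return {f"{p.name}:{s.name}": v for (p, s), v in m.items()}

        data = {
            "min_ref_len": self.min_ref_len,
            "min_depth": self.min_depth,
            "max_depth": _depth_map(self.max_depth),
            "min_cbr": self.min_cbr,
            "min_mapq": self.min_mapq,
            "min_snp_qual": self.min_snp_qual,
            "nqs_flank": self.nqs_flank,
            "min_nqs_qual": self.min_nqs_qual,
            "homopolymer_len": self.homopolymer_len,
            "min_snp_spacing": self.min_snp_spacing,
            "three_prime_margin": self.three_prime_margin,
            "illumina_spacing": self.illumina_spacing,
            "illumina_flank": self.illumina_flank,
            "unchar_max_depth": _depth_map(self.unchar_max_depth),
            "unchar_single_snp_only": self.unchar_single_snp_only,
            "rj_window": self.rj_window,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)

        def _parse_map(m):
            out = {}
            for key, v in m.items():
                p, s = key.split(":")
                out[(Platform[p], Source[s])] = int(v)
            return out

        for key in ("max_depth", "unchar_max_depth"):
            if key in data:
                data[key] = _parse_map(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# predicates
# ---------------------------------------------------------------------------

def nqs_pass(ref_quals: Sequence[int] | np.ndarray, pos: int, cfg: FilterConfig) -> bool:
    """Neighbourhood quality standard: the site base must reach
    ``min_snp_qual`` and every base in the 11-base window (truncated at the
    reference ends) must reach ``min_nqs_qual``."""
    quals = np.asarray(ref_quals)
    if quals[pos] < cfg.min_snp_qual:
        return False
    lo = max(0, pos - cfg.nqs_flank)
    hi = min(len(quals), pos + cfg.nqs_flank + 1)
    return bool(np.all(quals[lo:hi] >= cfg.min_nqs_qual))


def homopolymer_reject(ref_seq: str, pos: int, alt_base: str, cfg: FilterConfig) -> bool:
    """Reject if the site sits in (or its substitution would create) a
    single-base run of length >= ``homopolymer_len``."""
    if _run_length(ref_seq, pos) >= cfg.homopolymer_len:
        return True
    substituted = ref_seq[:pos] + alt_base + ref_seq[pos + 1 :]
    return _run_length(substituted, pos) >= cfg.homopolymer_len


def _run_length(seq: str, pos: int) -> int:
    b = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == b:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == b:
        j += 1
    return j - i + 1


def proximity_reject(calls: Sequence[VariantCall], cfg: FilterConfig) -> set[int]:
    """Positions (on one reference) with another candidate within
    ``min_snp_spacing - 1`` bp. Both members of a close pair are flagged;
    distance is measured on the original candidate positions."""
    positions = sorted({c.pos for c in calls})
    close: set[int] = set()
    for a, b in zip(positions, positions[1:]):
        if b - a < cfg.min_snp_spacing:
            close.add(a)
            close.add(b)
    return close


def three_prime_reject(pos: int, reference_length: int, cfg: FilterConfig) -> bool:
    """Reject sites within ``three_prime_margin`` bp of the 3' (right) end."""
    return reference_length - pos <= cfg.three_prime_margin


# ---------------------------------------------------------------------------
# the full stack
# ---------------------------------------------------------------------------

def apply_filters(
    merged_calls: Sequence[VariantCall],
    annotations: Mapping[str, ReadAnnotation],
    references: Mapping[str, ReadRecord],
    cfg: FilterConfig | None = None,
    depth_models: Mapping | None = None,
) -> tuple[list[VariantCall], pd.DataFrame]:
    """Apply the complete filter stack to merged candidate calls.

    Returns (passing calls, rejection ledger). The ledger has one row per
    rejected call with its first failing flag. ``depth_models`` is accepted
    for interface symmetry but unused: copy classes already live on the
    annotations. Raises ``KeyError`` for a call on an unknown reference.
    """
    cfg = cfg or FilterConfig()
    by_ref: dict[str, list[VariantCall]] = defaultdict(list)
    for c in merged_calls:
        if c.ref_id not in references:
            raise KeyError(f"call at {c.ref_id}:{c.pos}: unknown reference")
        if c.ref_id not in annotations:
            raise KeyError(f"call at {c.ref_id}:{c.pos}: reference has no annotation")
        by_ref[c.ref_id].append(c)

    rejected: list[tuple[VariantCall, str]] = []
    provisional: list[VariantCall] = []

    for ref_id, calls in by_ref.items():
        ref = references[ref_id]
        ann = annotations[ref_id]
        close = proximity_reject(calls, cfg)
        for c in calls:
            c.category = ann.category
            flag = _first_failure(c, ref, ann, close, cfg)
            if flag is None:
                provisional.append(c)
            else:
                c.filter_flags.add(flag)
                rejected.append((c, flag))

    # stricter rules for uncharacterized references
    passing: list[VariantCall] = []
    unchar_by_ref: dict[str, list[VariantCall]] = defaultdict(list)
    for c in provisional:
        if c.category is Category.UNCHARACTERIZED:
            flag = _unchar_depth_failure(c, cfg)
            if flag:
                c.filter_flags.add(flag)
                rejected.append((c, flag))
            else:
                unchar_by_ref[c.ref_id].append(c)
        else:
            passing.append(c)
    for ref_id, calls in unchar_by_ref.items():
        if cfg.unchar_single_snp_only and len(calls) > 1:
            for c in calls:
                c.filter_flags.add(FLAG_UNCHAR_MULTI_SNP)
                rejected.append((c, FLAG_UNCHAR_MULTI_SNP))
        else:
            passing.extend(calls)

    ledger = pd.DataFrame(
        {
            "ref_id": [c.ref_id for c, _ in rejected],
            "pos": [c.pos for c, _ in rejected],
            "alt_base": [c.alt_base for c, _ in rejected],
            "flag": [f for _, f in rejected],
        }
    )
    passing.sort(key=lambda c: (c.ref_id, c.pos))
    return passing, ledger


def _first_failure(
    c: VariantCall,
    ref: ReadRecord,
    ann: ReadAnnotation,
    close: set[int],
    cfg: FilterConfig,
) -> str | None:
    if ALT_CONFLICT in c.filter_flags:
        return FLAG_ALT_CONFLICT
    if len(ref) < cfg.min_ref_len:
        return FLAG_REF_LEN
    if ann.copy_class is not CopyClass.SINGLE:
        return FLAG_NOT_SINGLE_COPY
    if c.depth < cfg.min_depth:
        return FLAG_MIN_DEPTH
    for key, d in c.platform_depths.items():
        if d > cfg.max_depth.get(key, max(cfg.max_depth.values())):
            return FLAG_MAX_DEPTH
    if c.consensus_base_ratio < cfg.min_cbr:
        return FLAG_CBR
    c.min_mapq_pass = c.alt_min_mapq >= cfg.min_mapq
    if not c.min_mapq_pass:
        return FLAG_MAPQ
    if ref.qualities is not None and not nqs_pass(ref.qualities, c.pos, cfg):
        return FLAG_SNP_QUAL
    if homopolymer_reject(ref.sequence, c.pos, c.alt_base, cfg):
        return FLAG_HOMOPOLYMER
    if c.pos in close:
        return FLAG_CLOSE_SNP
    if three_prime_reject(c.pos, len(ref), cfg):
        return FLAG_THREE_PRIME
    return None


def _unchar_depth_failure(c: VariantCall, cfg: FilterConfig) -> str | None:
    for key, d in c.platform_depths.items():
        ceiling = cfg.unchar_max_depth.get(key, cfg.max_depth.get(key))
        if ceiling is not None and d > ceiling:
            return FLAG_UNCHAR_DEPTH
    return None


def illumina_spacing_filter(
    passing_calls: Sequence[VariantCall],
    references: Mapping[str, ReadRecord],
    cfg: FilterConfig | None = None,
) -> list[VariantCall]:
    """Optional genotyping-assay stage: keep calls >= ``illumina_spacing``
    bp from the nearest other passing call with >= ``illumina_flank`` bp of
    reference on both sides."""
    cfg = cfg or FilterConfig()
    by_ref: dict[str, list[VariantCall]] = defaultdict(list)
    for c in passing_calls:
        by_ref[c.ref_id].append(c)
    kept: list[VariantCall] = []
    for ref_id, calls in by_ref.items():
        L = len(references[ref_id])
        positions = sorted(c.pos for c in calls)
        for c in calls:
            others = [abs(c.pos - p) for p in positions if p != c.pos]
            if others and min(others) < cfg.illumina_spacing:
                continue
            if c.pos < cfg.illumina_flank or (L - 1 - c.pos) < cfg.illumina_flank:
                continue
            kept.append(c)
    kept.sort(key=lambda c: (c.ref_id, c.pos))
    return kept


def rj_snp_tag(
    passing_calls: Iterable[VariantCall],
    junctions: Mapping[str, Sequence[RepeatJunction]],
    window: int = 50,
) -> list[VariantCall]:
    """Mark calls within ``window`` bp of a repeat junction on the same
    reference (``rj_near`` attribute)."""
    out = []
    for c in passing_calls:
        c.rj_near = any(
            abs(c.pos - j.junction_pos) <= window for j in junctions.get(c.ref_id, ())
        )
        out.append(c)
    return out
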