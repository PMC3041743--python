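"""Category annotation of reference reads and repeat-junction discovery.

Each surviving long read is assigned exactly one category with the
precedence REPEAT > GENE_CHAR > UNCHARACTERIZED: a read with any repeat
hit at or below the E-value threshold is a repeat even if it also has gene
homology, mirroring the sequential removal order of the annotation
pipeline. Gene hits whose subject is itself transposon-related never
confer gene status. Uncharacterized reads with sufficient cDNA mapping
evidence are promoted to uncharacterized genes. Repeat junctions -- the
unique boundaries created when a transposable element inserts into another
element, a gene or other DNA -- are recomputed from hit geometry on reads
of the repeat class.
"""
from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats import AlignmentSet, HomologyHit, ReadRecord


class Category(enum.Enum):
    REPEAT = "repeat"
    REPEAT_JUNCTION = "repeat_junction"
    GENE_CHAR = "gene_characterized"
    GENE_UNCHAR = "gene_uncharacterized"
    UNCHARACTERIZED = "uncharacterized"


class CopyClass(enum.Enum):
    SINGLE = "single"
    MULTI = "multi"
    UNKNOWN = "unknown"


#: gene-database subjects with this prefix are transposon-related and do not
#: confer gene status
TE_SUBJECT_PREFIX = "TE|"


@dataclass
class ReadAnnotation:
    read_id: str
    category: Category
    copy_class: CopyClass = CopyClass.UNKNOWN
    supporting_hits: list[str] = field(default_factory=list)


@dataclass
class RepeatJunction:
    """A boundary between two annotated intervals on a repeat read."""

    read_id: str
    junction_pos: int  # 0-based offset on the read
    left_label: str
    right_label: str
    left_flank: int
    right_flank: int


def classify_reads(
    reads: Sequence[ReadRecord],
    repeat_hits: Iterable[HomologyHit],
    gene_hits: Iterable[HomologyHit],
    evalue_max: float = 1e-10,
) -> dict[str, ReadAnnotation]:
    """Assign REPEAT / GENE_CHAR / UNCHARACTERIZED with repeat precedence."""
    repeat_by_read: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in repeat_hits:
        if h.evalue <= evalue_max:
            repeat_by_read[h.query_id].append(h)
    gene_by_read: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in gene_hits:
        if h.evalue <= evalue_max and not h.subject_id.startswith(TE_SUBJECT_PREFIX):
            gene_by_read[h.query_id].append(h)

    annotations: dict[str, ReadAnnotation] = {}
    for r in reads:
        if r.read_id in repeat_by_read:
            cat = Category.REPEAT
            hits = repeat_by_read[r.read_id]
        elif r.read_id in gene_by_read:
            cat = Category.GENE_CHAR
            hits = gene_by_read[r.read_id]
        else:
            cat = Category.UNCHARACTERIZED
            hits = []
        annotations[r.read_id] = ReadAnnotation(
            r.read_id, cat, CopyClass.UNKNOWN, [h.subject_id for h in hits]
        )
    return annotations


def identify_uncharacterized_genes(
    annotations: dict[str, ReadAnnotation],
    cdna_alignments: AlignmentSet | Iterable,
    min_cdna_depth: int = 2,
) -> dict[str, ReadAnnotation]:
    """Promote UNCHARACTERIZED reads to GENE_UNCHAR on cDNA evidence.

    A read is promoted iff at least ``min_cdna_depth`` cDNA reads map to it
    (over one base or more). Reads of any other category keep their
    precedence. Mutates and returns ``annotations``.
    """
    counts: dict[str, int] = defaultdict(int)
    if isinstance(cdna_alignments, AlignmentSet):
        aset = cdna_alignments
        for idx in aset.ref_index:
            counts[aset.ref_names[idx]] += 1
    else:
        for rec in cdna_alignments:
            counts[rec.ref_id] += 1
    for read_id, n in counts.items():
        ann = annotations.get(read_id)
        if ann is not None and ann.category is Category.UNCHARACTERIZED and n >= min_cdna_depth:
            ann.category = Category.GENE_UNCHAR
    return annotations


def _merge_same_element(hits: Sequence[HomologyHit]) -> list[tuple[int, int, str]]:
    """Merge overlapping/adjacent hit intervals of the same element."""
    by_elem: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for h in hits:
        by_elem[h.subject_id].append((h.query_start, h.query_end))
    merged: list[tuple[int, int, str]] = []
    for elem, ivs in by_elem.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e, elem))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e, elem))
    merged.sort()
    return merged


def find_repeat_junctions(
    read: ReadRecord,
    repeat_hits_on_read: Sequence[HomologyHit],
    min_flank: int = 30,
) -> list[RepeatJunction]:
    """Locate repeat junctions from hit geometry on one repeat read.

    A junction is emitted (a) at every boundary where two distinct merged
    element intervals abut or overlap-switch (position = boundary, or the
    midpoint of the overlap), and (b) where a repeat interval ends at least
    ``min_flank`` bases inside the read (repeat/unknown junction). Every
    emitted junction has both flanks >= min_flank.
    """
    n = len(read)
    merged = _merge_same_element(repeat_hits_on_read)
    junctions: list[RepeatJunction] = []

    def emit(pos: int, left: str, right: str) -> None:
        if min(pos, n - pos) >= min_flank and 0 < pos < n:
            junctions.append(RepeatJunction(read.read_id, pos, left, right, pos, n - pos))

    # element/element boundaries
    for (s1, e1, el1), (s2, e2, el2) in zip(merged, merged[1:]):
        if el1 == el2:
            continue  # disjoint occurrences of the same element: not a boundary switch
        if s2 <= e1:  # overlap: junction at the midpoint of the overlap
            emit((s2 + e1) // 2, el1, el2)
        elif s2 == e1 or s2 - e1 < min_flank:
            # abutting (or separated by less than a usable flank of unknown)
            if s2 == e1:
                emit(e1, el1, el2)
        # a gap of >= min_flank unknown sequence is handled by the edge rule
    # repeat/unknown junctions at interior ends of the outermost coverage and gaps
    if merged:
        covered: list[tuple[int, int]] = []
        for s, e, _ in merged:
            if covered and s <= covered[-1][1]:
                covered[-1] = (covered[-1][0], max(covered[-1][1], e))
            else:
                covered.append((s, e))
        labels_at = merged
        for s, e in covered:
            left_label = next(el for ms, me, el in labels_at if ms <= s < me)
            right_label = next(el for ms, me, el in reversed(labels_at) if ms < e <= me)
            if s >= min_flank:
                emit(s, "unknown", left_label)
            if n - e >= min_flank:
                emit(e, right_label, "unknown")
    junctions.sort(key=lambda j: j.junction_pos)
    return junctions


def tag_repeat_junctions(
    annotations: dict[str, ReadAnnotation],
    reads: Mapping[str, ReadRecord],
    repeat_hits: Iterable[HomologyHit],
    min_flank: int = 30,
    evalue_max: float = 1e-10,
) -> dict[str, list[RepeatJunction]]:
    """Find junctions on every REPEAT read; reads with at least one junction
    are re-categorized REPEAT_JUNCTION. Returns junctions keyed by read id."""
    hits_by_read: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in repeat_hits:
        if h.evalue <= evalue_max:
            hits_by_read[h.query_id].append(h)
    out: dict[str, list[RepeatJunction]] = {}
    for read_id, ann in annotations.items():
        if ann.category is not Category.REPEAT:
            continue
        read = reads.get(read_id)
        if read is None:
            continue
        junctions = find_repeat_junctions(read, hits_by_read.get(read_id, []), min_flank)
        if junctions:
            ann.category = Category.REPEAT_JUNCTION
            out[read_id] = junctions
    return out


def annotation_table(annotations: dict[str, ReadAnnotation]):
    """Annotation summary as a DataFrame (read_id, category, copy_class, n_hits)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": list(annotations),
            "category": [a.category.value for a in annotations.values()],
            "copy_class": [a.copy_class.value for a in annotations.values()],
            "n_hits": [len(a.supporting_hits) for a in annotations.values()],
        }
    )
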