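"""Pre-processing of the long-read reference library.

Two artifact classes are removed before annotation: reads of organellar
origin (chloroplast/mitochondrial homology at E <= 1e-10) and artificial
replicates, the pyrosequencing artifact in which the same template bead is
read multiple times, inflating apparent depth. Replicate clustering follows
the published thresholds (98% identity, 90% coverage) with a greedy
longest-first strategy: reads are compared ungapped, anchored at their
starts, after a shared-prefix seed lookup makes the scan near-linear.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .formats import HomologyHit, ReadRecord

logger = logging.getLogger(__name__)

_SEED_LEN = 20


@dataclass
class ReplicateCluster:
    """A group of artificial replicates; the representative is the longest
    member (ties broken by lexicographically smallest id)."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)


def filter_organellar(
    reads: Sequence[ReadRecord],
    hits: Iterable[HomologyHit],
    evalue_max: float = 1e-10,
) -> tuple[list[ReadRecord], list[str]]:
    """Partition reads into (kept, removed_ids) on organellar homology.

    A read is removed iff it has at least one organellar hit with
    evalue <= evalue_max. Hits for unknown read ids are ignored with a
    warning. The partition is exhaustive and disjoint.
    """
    known = {r.read_id for r in reads}
    flagged: set[str] = set()
    for h in hits:
        if h.query_id not in known:
            logger.warning("organellar hit for unknown read %s ignored", h.query_id)
            continue
        if h.evalue <= evalue_max:
            flagged.add(h.query_id)
    kept = [r for r in reads if r.read_id not in flagged]
    removed = [r.read_id for r in reads if r.read_id in flagged]
    return kept, removed


def _ungapped_match(rep: np.ndarray, member: np.ndarray, offset: int) -> float:
    """Identity of ``member`` against ``rep[offset:]``, over the shorter span."""
    span = min(len(member), len(rep) - offset)
    if span <= 0:
        return 0.0
    a = rep[offset : offset + span]
    b = member[:span]
    return float(np.count_nonzero(a == b)) / span


def remove_artificial_replicates(
    reads: Sequence[ReadRecord],
    identity_min: float = 0.98,
    coverage_min: float = 0.90,
    start_window: int = 3,
) -> tuple[list[ReadRecord], list[ReplicateCluster]]:
    """Greedy longest-first replicate clustering.

    A read joins an existing cluster when (1) its prefix seed matches the
    representative within ``start_window`` bases of the representative's
    start, (2) ungapped identity over the shorter read is >= identity_min,
    and (3) the shorter read covers >= coverage_min of the longer. One
    representative (the longest member, ties by smallest id) is kept per
    cluster. Kept reads are returned in the original input order.
    """
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), reads[i].read_id))
    codes = {i: reads[i].codes for i in order}
    # seed index: k-mer at representative offsets 0..start_window -> [(rep_i, offset)]
    seed_index: dict[bytes, list[tuple[int, int]]] = {}
    assignment: dict[int, int] = {}  # member index -> representative index

    for i in order:
        seq = codes[i]
        if len(seq) < _SEED_LEN:
            assignment[i] = i  # too short to seed; becomes its own cluster
        else:
            seed = seq[:_SEED_LEN].tobytes()
            rep_found = None
            for rep_i, offset in seed_index.get(seed, ()):
                rep_seq = codes[rep_i]
                if len(seq) / len(rep_seq) < coverage_min:
                    continue
                if _ungapped_match(rep_seq, seq, offset) >= identity_min:
                    rep_found = rep_i
                    break
            assignment[i] = rep_found if rep_found is not None else i
        if assignment[i] == i and len(seq) >= _SEED_LEN:
            for off in range(min(start_window, len(seq) - _SEED_LEN) + 1):
                key = seq[off : off + _SEED_LEN].tobytes()
                seed_index.setdefault(key, []).append((i, off))

    clusters: dict[int, ReplicateCluster] = {}
    for i in order:
        rep = assignment[i]
        cl = clusters.setdefault(rep, ReplicateCluster(reads[rep].read_id))
        cl.member_ids.append(reads[i].read_id)
    kept_idx = {rep for rep in clusters}
    kept = [r for i, r in enumerate(reads) if i in kept_idx]
    return kept, [clusters[rep] for rep in sorted(clusters)]
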