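"""Platform error-rate estimation against a trusted reference.

Single-read rates count insertion/deletion/substitution events from the
alignment walk of each read against an error-free reference, with total
aligned read bases as the denominator. Consensus rates first collapse the
mapped reads into a majority-vote consensus (ties resolved to the
reference base) and compare that to the truth -- the transparent
equivalent of consensus calling at desk scale. Variant-calling error mode
is consensus mode with a long-read-derived reference standing in for
truth, so errors on both sides contribute.

The quality and position profiles tie substitution errors to base quality
(is the error removable by the Q30 / NQS-20 filter?) and to relative
position in the read (long-read quality decays toward the 3' end).
"""
from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import dna
from .formats import AlignmentRecord, AlignmentSet, Platform, parse_cigar


class ErrorMode(enum.Enum):
    SINGLE_READ = "single_read"
    CONSENSUS = "consensus"
    VARIANT_CALLING = "variant_calling"


@dataclass
class ErrorReport:
    platform: Platform
    mode: ErrorMode
    total_bases: int
    insertion_errors: int
    deletion_errors: int
    substitution_errors: int

    @property
    def total_errors(self) -> int:
        return self.insertion_errors + self.deletion_errors + self.substitution_errors

    @property
    def overall_rate(self) -> float:
        return self.total_errors / self.total_bases if self.total_bases else 0.0

    @property
    def indel_rate(self) -> float:
        if not self.total_bases:
            return 0.0
        return (self.insertion_errors + self.deletion_errors) / self.total_bases

    @property
    def substitution_rate(self) -> float:
        return self.substitution_errors / self.total_bases if self.total_bases else 0.0

    @property
    def composition(self) -> dict[str, float]:
        """Percent of errors in each class (sums to 100 up to rounding)."""
        t = self.total_errors
        if t == 0:
            return {"insertion": 0.0, "deletion": 0.0, "substitution": 0.0}
        return {
            "insertion": 100.0 * self.insertion_errors / t,
            "deletion": 100.0 * self.deletion_errors / t,
            "substitution": 100.0 * self.substitution_errors / t,
        }

    def to_frame(self) -> pd.DataFrame:
        comp = self.composition
        return pd.DataFrame(
            [
                {
                    "platform": self.platform.value,
                    "mode": self.mode.value,
                    "total_bases": self.total_bases,
                    "insertion_errors": self.insertion_errors,
                    "deletion_errors": self.deletion_errors,
                    "substitution_errors": self.substitution_errors,
                    "overall_rate": self.overall_rate,
                    "indel_rate": self.indel_rate,
                    "substitution_rate": self.substitution_rate,
                    "insertion_pct": comp["insertion"],
                    "deletion_pct": comp["deletion"],
                    "substitution_pct": comp["substitution"],
                }
            ]
        )


def _iter_alignments(alignments) -> Iterable[AlignmentRecord]:
    if isinstance(alignments, AlignmentSet):
        yield from alignments
    else:
        yield from alignments


def single_read_error_rate(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    truth: Mapping[str, str],
    platform: Platform = Platform.LONG_454,
) -> ErrorReport:
    """Count I/D/X events of individual reads against an error-free truth."""
    ins = dele = sub = total = 0
    for rec in _iter_alignments(alignments):
        if rec.ref_id not in truth:
            raise KeyError(f"alignment {rec.read_id}: reference {rec.ref_id} absent from truth")
        ref = truth[rec.ref_id]
        rpos, qpos = rec.ref_start, 0
        seq = rec.sequence
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for k in range(n):
                    if seq[qpos + k] != ref[rpos + k]:
                        sub += 1
                total += n
                rpos += n
                qpos += n
            elif op == "I":
                ins += n
                total += n
                qpos += n
            elif op in "DN":
                dele += n
                rpos += n
            elif op == "S":
                qpos += n
    return ErrorReport(platform, ErrorMode.SINGLE_READ, total, ins, dele, sub)


def _consensus(alignments, truth_len: Mapping[str, int]):
    """Majority-vote consensus per reference: returns per-ref arrays of
    (consensus code, covered mask, deletion-majority mask) plus insertion
    majorities keyed by (ref, pos)."""
    counts: dict[str, np.ndarray] = {}
    dels: dict[str, np.ndarray] = {}
    inserts: dict[tuple[str, int], list[int]] = defaultdict(list)
    for rec in _iter_alignments(alignments):
        L = truth_len[rec.ref_id]
        if rec.ref_id not in counts:
            counts[rec.ref_id] = np.zeros((L, 4), dtype=np.int32)
            dels[rec.ref_id] = np.zeros(L, dtype=np.int32)
        cnt, dl = counts[rec.ref_id], dels[rec.ref_id]
        seq = dna.encode(rec.sequence)
        rpos, qpos = rec.ref_start, 0
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                sl = seq[qpos : qpos + n]
                ok = sl < 4
                np.add.at(cnt, (rpos + np.nonzero(ok)[0], sl[ok].astype(np.int64)), 1)
                rpos += n
                qpos += n
            elif op == "I":
                inserts[(rec.ref_id, rpos)].append(n)
                qpos += n
            elif op in "DN":
                dl[rpos : rpos + n] += 1
                rpos += n
            elif op == "S":
                qpos += n
    return counts, dels, inserts


def consensus_error_rate(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    truth: Mapping[str, str],
    platform: Platform,
    mode: ErrorMode = ErrorMode.CONSENSUS,
) -> ErrorReport:
    """Errors between the majority-vote consensus and the trusted truth.

    The denominator is the number of consensus (covered) bases. A position
    where deletions outnumber base observations is a deletion error; an
    insertion carried by more than half of the covering reads is an
    insertion error of its majority length.
    """
    truth_len = {k: len(v) for k, v in truth.items()}
    counts, dels, inserts = _consensus(alignments, truth_len)
    ins_err = del_err = sub_err = total = 0
    for ref_id, cnt in counts.items():
        truth_codes = dna.encode(truth[ref_id])[: len(cnt)]
        base_depth = cnt.sum(axis=1)
        covered = (base_depth + dels[ref_id]) > 0
        total += int(np.count_nonzero(covered))
        del_mask = covered & (dels[ref_id] > base_depth)
        del_err += int(np.count_nonzero(del_mask))
        eval_mask = covered & ~del_mask & (base_depth > 0)
        cons = np.argmax(cnt, axis=1)
        top = cnt[np.arange(len(cnt)), cons]
        # tie -> reference base (reference meaning the trusted sequence here)
        tie = eval_mask & (cnt[np.arange(len(cnt)), np.minimum(truth_codes, 3)] == top)
        cons[tie] = truth_codes[tie]
        sub_err += int(np.count_nonzero(eval_mask & (cons != truth_codes)))
    for (ref_id, pos), lens in inserts.items():
        depth = counts[ref_id][pos].sum() if pos < len(counts[ref_id]) else 0
        if len(lens) * 2 > depth:
            ins_err += int(np.median(lens))
    return ErrorReport(platform, mode, total, ins_err, del_err, sub_err)


def variant_calling_error_rate(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    reference_reads: Mapping[str, str],
    platform: Platform,
) -> ErrorReport:
    """Consensus error against a long-read-derived reference (both the
    reads and the imperfect reference contribute errors)."""
    return consensus_error_rate(
        alignments, reference_reads, platform, mode=ErrorMode.VARIANT_CALLING
    )


def split_reads(read_ids: Sequence[str], seed: int) -> tuple[list[str], list[str]]:
    """Seeded random half-split of a read set (reference half, query half)."""
    rng = np.random.default_rng(seed)
    ids = list(read_ids)
    rng.shuffle(ids)
    half = len(ids) // 2
    return ids[:half], ids[half:]


# ---------------------------------------------------------------------------
# error profiles
# ---------------------------------------------------------------------------

def _iter_substitution_errors(alignments, truth):
    """Yield (read qual, read pos, read length, nqs window quals) per
    substitution error in single-read alignments."""
    for rec in _iter_alignments(alignments):
        ref = truth[rec.ref_id]
        quals = rec.qualities
        L = len(rec.sequence)
        rpos, qpos = rec.ref_start, 0
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for k in range(n):
                    if rec.sequence[qpos + k] != ref[rpos + k]:
                        q = int(quals[qpos + k]) if quals is not None else 0
                        lo = max(0, qpos + k - 5)
                        hi = min(L, qpos + k + 6)
                        window = quals[lo:hi] if quals is not None else []
                        yield q, qpos + k, L, window
                rpos += n
                qpos += n
            elif op in "IS":
                qpos += n
            elif op in "DN":
                rpos += n


def quality_error_profile(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    truth: Mapping[str, str],
    min_snp_qual: int = 30,
    min_nqs_qual: int = 20,
    qual_bin_width: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Substitution errors binned by base quality and NQS status.

    Returns the profile table and the fraction of substitution errors that
    the (Q30, NQS-20) filter would remove.
    """
    rows: dict[tuple[int, bool], int] = defaultdict(int)
    removed = count = 0
    for q, _pos, _L, window in _iter_substitution_errors(alignments, truth):
        nqs_ok = q >= min_snp_qual and all(int(w) >= min_nqs_qual for w in window)
        rows[(q // qual_bin_width * qual_bin_width, nqs_ok)] += 1
        count += 1
        if not nqs_ok:
            removed += 1
    df = pd.DataFrame(
        {
            "qual_bin": [k[0] for k in rows],
            "nqs_pass": [k[1] for k in rows],
            "errors": list(rows.values()),
        }
    ).sort_values(["qual_bin", "nqs_pass"], ignore_index=True)
    return df, (removed / count if count else 0.0)


def position_error_profile(
    alignments: Iterable[AlignmentRecord] | AlignmentSet,
    truth: Mapping[str, str],
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float, float]:
    """Substitution errors per relative-position decile of the read.

    Returns (table, Pearson r of decile index vs error count, p-value).
    """
    bins = np.zeros(n_bins, dtype=np.int64)
    for _q, pos, L, _w in _iter_substitution_errors(alignments, truth):
        bins[min(n_bins - 1, pos * n_bins // L)] += 1
    df = pd.DataFrame({"position_decile": np.arange(n_bins), "errors": bins})
    if np.all(bins == bins[0]):
        return df, 0.0, 1.0
    r, p = stats.pearsonr(np.arange(n_bins), bins)
    return df, float(r), float(p)
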