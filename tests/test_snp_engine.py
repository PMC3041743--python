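"""Pileup construction, substitution calling, and platform merging,
checked against brute-force coordinate-walking oracles."""
import numpy as np
import pytest

from agsnp import dna
from agsnp.formats import AlignmentRecord, AlignmentSet, Platform, Source
from agsnp.snp_engine import (
    ALT_CONFLICT,
    PileupColumn,
    VariantCall,
    build_pileup,
    calls_from_arrays,
    calls_from_frame,
    calls_to_frame,
    call_substitutions,
    merge_platform_calls,
    pileup_arrays,
    provenance_report,
)

SOLID_G = (Platform.SOLID, Source.GENOMIC)
SOLEXA_G = (Platform.SOLEXA, Source.GENOMIC)


def _aln(ref_id, start, seq, cigar=None, mapq=60, quals=None):
    return AlignmentRecord(
        "q", ref_id, start, cigar or f"{len(seq)}M", mapq, "+",
        Platform.SOLID, Source.GENOMIC, seq,
        quals if quals is not None else np.full(len(seq), 30),
    )


def _pileup_oracle(alignments, references):
    """Independent per-base CIGAR walk: returns {(ref,pos): {base: count}}
    plus deletion counts."""
    counts, dels = {}, {}
    for rec in alignments:
        rpos, qpos = rec.ref_start, 0
        num = ""
        for ch in rec.cigar:
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch in "M=X":
                for k in range(n):
                    b = rec.sequence[qpos + k]
                    counts.setdefault((rec.ref_id, rpos + k), {}).setdefault(b, 0)
                    counts[(rec.ref_id, rpos + k)][b] += 1
                rpos += n
                qpos += n
            elif ch in "IS":
                qpos += n
            elif ch in "DN":
                for k in range(n):
                    dels[(rec.ref_id, rpos + k)] = dels.get((rec.ref_id, rpos + k), 0) + 1
                rpos += n
    return counts, dels


def _random_alignments(rng, ref_len=200, n=30, with_indels=True):
    refs = {"ref": dna.decode(rng.integers(0, 4, ref_len).astype(np.uint8))}
    alns = []
    for _ in range(n):
        L = int(rng.integers(20, 60))
        start = int(rng.integers(0, ref_len - L - 12))
        seq = dna.decode(rng.integers(0, 5, L).astype(np.uint8))  # includes N
        if with_indels and rng.random() < 0.3:
            a = int(rng.integers(5, L - 10))
            b = int(rng.integers(2, 5))
            kind = rng.choice(["I", "D"])
            if kind == "I":
                cigar = f"{a}M{b}I{L - a - b}M"
            else:
                cigar = f"{a}M{b}D{L - a}M"
        else:
            cigar = f"{L}M"
        alns.append(_aln("ref", start, seq, cigar, mapq=int(rng.integers(0, 61))))
    return refs, alns


class TestBuildPileup:
    def test_three_agreeing_reads(self):
        refs = {"r": "A" * 20}
        alns = [_aln("r", 8, "GGGG") for _ in range(3)]
        cols = build_pileup(alns, refs)
        col10 = [c for c in cols if c.pos == 10][0]
        assert col10.base_counts == {"A": 0, "C": 0, "G": 3, "T": 0}

    def test_insertion_adds_no_columns(self):
        refs = {"r": "ACGTACGTACGT"}
        cols = build_pileup([_aln("r", 0, "ACGTTTACGT", "4M2I4M")], refs)
        assert [c.pos for c in cols] == list(range(8))

    def test_deletion_excluded_from_base_counts(self):
        refs = {"r": "ACGTACGT"}
        cols = build_pileup([_aln("r", 0, "ACACGT", "2M2D4M")], refs)
        at2 = [c for c in cols if c.pos == 2][0]
        assert sum(at2.base_counts.values()) == 0
        assert at2.del_count == 1

    def test_n_counts_toward_depth_not_alleles(self):
        refs = {"r": "ACGTACGT"}
        cols = build_pileup([_aln("r", 0, "ANGT")], refs)
        at1 = [c for c in cols if c.pos == 1][0]
        assert at1.n_count == 1 and sum(at1.base_counts.values()) == 0
        assert at1.depth == 1

    def test_cigar_length_mismatch_raises(self):
        refs = {"r": "ACGTACGT"}
        with pytest.raises(ValueError, match="CIGAR"):
            build_pileup([_aln("r", 0, "ACGT", "6M")], refs)

    def test_column_invariant_and_oracle(self, rng):
        for _ in range(25):
            refs, alns = _random_alignments(rng)
            cols = build_pileup(alns, refs)
            oracle_counts, oracle_dels = _pileup_oracle(alns, refs)
            for col in cols:
                assert sum(col.base_counts.values()) == len(col.quals)
                expect = oracle_counts.get(("ref", col.pos), {})
                for b in "ACGT":
                    assert col.base_counts[b] == expect.get(b, 0)
                assert col.n_count == expect.get("N", 0)
                assert col.del_count == oracle_dels.get(("ref", col.pos), 0)

    def test_array_path_equals_column_path(self, rng):
        """The vectorised production pileup matches the explicit one."""
        for _ in range(15):
            refs, alns = _random_alignments(rng)
            aset = AlignmentSet.from_records(alns, *SOLID_G)
            piles = pileup_arrays(aset, {"ref": len(refs["ref"])})
            cols = {c.pos: c for c in build_pileup(alns, refs)}
            counts = piles["ref"]["counts"]
            for pos in range(len(refs["ref"])):
                col = cols.get(pos)
                expect = [0] * 5 if col is None else [
                    col.base_counts["A"], col.base_counts["C"],
                    col.base_counts["G"], col.base_counts["T"], col.n_count,
                ]
                assert counts[pos].tolist() == expect
                if col is not None:
                    assert piles["ref"]["del_count"][pos] == col.del_count


class TestCallSubstitutions:
    def test_example_cbr(self):
        col = PileupColumn(
            "r", 5, "C", {"A": 0, "C": 1, "G": 0, "T": 9},
            [30] * 10, [60] * 10, *SOLID_G, obs_bases=["T"] * 9 + ["C"],
        )
        (call,) = call_substitutions([col])
        assert call.alt_base == "T"
        assert call.consensus_base_ratio == pytest.approx(0.9)

    def test_no_alt_no_call(self):
        col = PileupColumn(
            "r", 5, "A", {"A": 5, "C": 0, "G": 0, "T": 0},
            [30] * 5, [60] * 5, *SOLID_G, obs_bases=["A"] * 5,
        )
        assert call_substitutions([col]) == []

    def test_min_alt_threshold(self):
        col = PileupColumn(
            "r", 5, "A", {"A": 5, "C": 1, "G": 0, "T": 0},
            [30] * 6, [60] * 6, *SOLID_G, obs_bases=["A"] * 5 + ["C"],
        )
        assert len(call_substitutions([col], min_alt=1)) == 1
        assert call_substitutions([col], min_alt=2) == []

    def test_thousand_random_columns_match_exhaustive_oracle(self, rng):
        for _ in range(1000):
            ref_base = "ACGT"[rng.integers(0, 4)]
            counts = {b: int(rng.integers(0, 6)) for b in "ACGT"}
            if sum(counts.values()) == 0:
                counts[ref_base] = 1
            obs = [b for b in "ACGT" for _ in range(counts[b])]
            col = PileupColumn(
                "r", 0, ref_base, dict(counts), [30] * len(obs), [60] * len(obs),
                *SOLID_G, obs_bases=obs,
            )
            calls = call_substitutions([col])
            # oracle: best non-reference base by count, ties to first in ACGT
            best, best_n = None, 0
            for b in "ACGT":
                if b != ref_base and counts[b] > best_n:
                    best, best_n = b, counts[b]
            if best is None:
                assert calls == []
            else:
                assert calls[0].alt_base == best
                assert calls[0].alt_count == best_n
                assert calls[0].depth == sum(counts.values())

    def test_array_calls_equal_column_calls(self, rng):
        for _ in range(10):
            refs, alns = _random_alignments(rng, with_indels=False)
            aset = AlignmentSet.from_records(alns, *SOLID_G)
            piles = pileup_arrays(aset, {"ref": len(refs["ref"])})
            fast = calls_from_arrays(piles, {"ref": dna.encode(refs["ref"])}, *SOLID_G)
            slow = call_substitutions(build_pileup(alns, refs))
            assert [(c.pos, c.alt_base, c.depth, c.alt_count) for c in fast] == [
                (c.pos, c.alt_base, c.depth, c.alt_count) for c in slow
            ]

    def test_alt_min_mapq_tracks_alt_observations(self):
        refs = {"r": "AAAA"}
        alns = [
            _aln("r", 0, "ATAA", mapq=50),
            _aln("r", 0, "ATAA", mapq=13),
            _aln("r", 0, "AAAA", mapq=2),
        ]
        aset = AlignmentSet.from_records(alns, *SOLID_G)
        piles = pileup_arrays(aset, {"r": 4})
        (call,) = calls_from_arrays(piles, {"r": dna.encode("AAAA")}, *SOLID_G)
        assert call.pos == 1 and call.alt_base == "T"
        assert call.alt_min_mapq == 13  # the mapq-2 read supports the reference


def _mk_call(pos, alt, depth, alt_count, key=SOLID_G, ref="C"):
    return VariantCall(
        ref_id="r", pos=pos, ref_base=ref, alt_base=alt, depth=depth,
        alt_count=alt_count, consensus_base_ratio=alt_count / depth,
        platform_depths={key: depth},
    )


class TestMergePlatformCalls:
    def test_same_snp_two_platforms_merges(self):
        merged = merge_platform_calls(
            [[_mk_call(10, "T", 4, 4)], [_mk_call(10, "T", 2, 2, key=SOLEXA_G)]]
        )
        (m,) = merged
        assert m.depth == 6 and m.alt_count == 6
        assert m.platforms == {SOLID_G, SOLEXA_G}
        assert m.consensus_base_ratio == 1.0

    def test_single_platform_identity(self):
        calls = [_mk_call(3, "G", 5, 4), _mk_call(9, "T", 6, 6)]
        merged = merge_platform_calls([calls])
        assert [(c.pos, c.alt_base, c.depth, c.alt_count) for c in merged] == [
            (3, "G", 5, 4), (9, "T", 6, 6)
        ]
        assert all(not c.filter_flags for c in merged)

    def test_conflicting_alts_both_flagged(self):
        merged = merge_platform_calls(
            [[_mk_call(10, "T", 4, 4)], [_mk_call(10, "G", 3, 3, key=SOLEXA_G)]]
        )
        assert len(merged) == 2
        assert all(ALT_CONFLICT in c.filter_flags for c in merged)

    def test_alt_count_conservation(self, rng):
        sets = []
        for key in (SOLID_G, SOLEXA_G):
            sets.append(
                [
                    _mk_call(int(p), "T", int(d), int(a), key=key)
                    for p, d, a in zip(
                        rng.choice(50, 20, replace=False),
                        rng.integers(2, 12, 20),
                        rng.integers(1, 3, 20),
                    )
                ]
            )
        merged = merge_platform_calls(sets)
        assert sum(c.alt_count for c in merged) == sum(
            c.alt_count for s in sets for c in s
        )

    def test_merging_never_lowers_depth(self, rng):
        a = [_mk_call(int(p), "T", 4, 2) for p in range(10)]
        b = [_mk_call(int(p), "T", 3, 3, key=SOLEXA_G) for p in range(5, 15)]
        merged = {c.pos: c for c in merge_platform_calls([a, b])}
        for c in a + b:
            assert merged[c.pos].depth >= c.depth

    def test_round_trip_through_frame(self):
        calls = merge_platform_calls(
            [[_mk_call(10, "T", 4, 4)], [_mk_call(10, "T", 2, 2, key=SOLEXA_G)]]
        )
        back = calls_from_frame(calls_to_frame(calls))
        assert back[0].platform_depths == calls[0].platform_depths
        assert back[0].consensus_base_ratio == calls[0].consensus_base_ratio


class TestProvenance:
    def test_single_combo(self):
        calls = [_mk_call(p, "T", 4, 4) for p in range(3)]
        df = provenance_report(calls)
        assert len(df) == 1
        assert df.loc[0, "n_snps"] == 3
        assert df.loc[0, "platform_combination"] == "SOLiD(genomic)"

    def test_counts_sum_to_total(self, small_run):
        _, result, _ = small_run
        df = provenance_report(result.passing)
        assert df["n_snps"].sum() == len(result.passing)

    def test_shared_fraction_rises_with_overlap(self, rng):
        """More cross-platform overlap -> more multi-platform SNPs."""
        shared_frac = []
        for overlap in (0.1, 0.5, 0.9):
            n = 200
            n_shared = int(overlap * n)
            a = [_mk_call(p, "T", 4, 4) for p in range(n)]
            b = [
                _mk_call(p, "T", 3, 3, key=SOLEXA_G)
                for p in range(n - n_shared, 2 * n - n_shared)
            ]
            merged = merge_platform_calls([a, b])
            multi = sum(1 for c in merged if len(c.platforms) > 1)
            shared_frac.append(multi / len(merged))
        assert shared_frac[0] < shared_frac[1] < shared_frac[2]
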