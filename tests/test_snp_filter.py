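"""The filter stack: each predicate against a brute-force oracle, the full
stack against an independent straight-line reimplementation, and the
monotonicity/conservation properties."""
import dataclasses

import numpy as np
import pytest

from agsnp import dna
from agsnp.annotate import Category, CopyClass, ReadAnnotation, RepeatJunction
from agsnp.formats import Platform, ReadRecord, Source
from agsnp.snp_engine import ALT_CONFLICT, VariantCall
from agsnp.snp_filter import (
    FilterConfig,
    apply_filters,
    homopolymer_reject,
    illumina_spacing_filter,
    nqs_pass,
    proximity_reject,
    rj_snp_tag,
    three_prime_reject,
)

SOLID_G = (Platform.SOLID, Source.GENOMIC)
CFG = FilterConfig()


class TestNqs:
    def test_all_high_passes(self):
        assert nqs_pass(np.full(50, 40), 25, CFG)

    def test_site_quality_29_fails(self):
        quals = np.full(50, 40)
        quals[25] = 29
        assert not nqs_pass(quals, 25, CFG)

    def test_neighbor_19_fails(self):
        quals = np.full(50, 40)
        quals[28] = 19
        assert not nqs_pass(quals, 25, CFG)

    def test_window_truncates_at_edges(self):
        quals = np.full(8, 40)
        assert nqs_pass(quals, 0, CFG)
        assert nqs_pass(quals, 7, CFG)

    def test_matches_sliding_window_oracle(self, rng):
        for _ in range(300):
            L = int(rng.integers(12, 60))
            quals = rng.integers(0, 41, L)
            pos = int(rng.integers(0, L))
            oracle = quals[pos] >= 30 and all(
                quals[i] >= 20 for i in range(max(0, pos - 5), min(L, pos + 6))
            )
            assert nqs_pass(quals, pos, CFG) == oracle


class TestHomopolymer:
    def test_reference_run_of_three(self):
        assert homopolymer_reject("AAAG", 1, "G", CFG)

    def test_no_run_keeps(self):
        assert not homopolymer_reject("ACGT", 1, "T", CFG)

    def test_substitution_creating_run_rejected(self):
        assert homopolymer_reject("CATTG", 1, "T", CFG)  # creates TTT

    def test_matches_run_length_oracle(self, rng):
        def run_len(seq, pos):
            b, i, j = seq[pos], pos, pos
            while i > 0 and seq[i - 1] == b:
                i -= 1
            while j + 1 < len(seq) and seq[j + 1] == b:
                j += 1
            return j - i + 1

        for _ in range(300):
            L = int(rng.integers(4, 30))
            seq = dna.decode(rng.integers(0, 4, L).astype(np.uint8))
            pos = int(rng.integers(0, L))
            alt = "ACGT"[int(rng.integers(0, 4))]
            sub = seq[:pos] + alt + seq[pos + 1 :]
            oracle = run_len(seq, pos) >= 3 or run_len(sub, pos) >= 3
            assert homopolymer_reject(seq, pos, alt, CFG) == oracle


def _call(pos, ref_id="r", alt="T", depth=5, alt_count=5, key=SOLID_G, mapq=60):
    return VariantCall(
        ref_id=ref_id, pos=pos, ref_base="C", alt_base=alt, depth=depth,
        alt_count=alt_count, consensus_base_ratio=alt_count / depth,
        alt_min_mapq=mapq, platform_depths={key: depth},
    )


class TestProximity:
    def test_pair_at_three_bp_both_rejected(self):
        close = proximity_reject([_call(100), _call(103)], CFG)
        assert close == {100, 103}

    def test_single_call_kept(self):
        assert proximity_reject([_call(100)], CFG) == set()

    def test_triplet_example(self):
        close = proximity_reject([_call(10), _call(13), _call(20)], CFG)
        assert close == {10, 13}

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            positions = sorted(rng.choice(60, int(rng.integers(1, 12)), replace=False))
            calls = [_call(int(p)) for p in positions]
            oracle = {
                p for p in positions
                if any(q != p and abs(q - p) <= 3 for q in positions)
            }
            assert proximity_reject(calls, CFG) == oracle


class TestThreePrime:
    def test_mid_reference_kept(self):
        assert not three_prime_reject(150, 200, CFG)  # 50 bp from the end

    def test_near_end_rejected(self):
        assert three_prime_reject(175, 200, CFG)  # 25 <= 30

    def test_boundary_enumeration(self):
        # margin 30: distance L - pos; reject iff <= 30
        for pos in range(160, 200):
            assert three_prime_reject(pos, 200, CFG) == (200 - pos <= 30)
        assert not three_prime_reject(169, 200, CFG)  # 31 from end


# ---------------------------------------------------------------------------
# the full stack vs an independent straight-line oracle
# ---------------------------------------------------------------------------

def _oracle_pass(call, ref, ann, all_positions, cfg):
    """Independent straight-line restatement of every criterion."""
    if ALT_CONFLICT in call.filter_flags:
        return False
    if len(ref.sequence) < cfg.min_ref_len:
        return False
    if ann.copy_class is not CopyClass.SINGLE:
        return False
    if call.depth < cfg.min_depth:
        return False
    for key, d in call.platform_depths.items():
        if d > cfg.max_depth.get(key, max(cfg.max_depth.values())):
            return False
    if call.consensus_base_ratio < cfg.min_cbr:
        return False
    if call.alt_min_mapq < cfg.min_mapq:
        return False
    q = ref.qualities
    if q is not None:
        if q[call.pos] < cfg.min_snp_qual:
            return False
        lo, hi = max(0, call.pos - 5), min(len(q), call.pos + 6)
        if any(int(q[i]) < cfg.min_nqs_qual for i in range(lo, hi)):
            return False
    seq = ref.sequence

    def run(s, p):
        b, i, j = s[p], p, p
        while i > 0 and s[i - 1] == b:
            i -= 1
        while j + 1 < len(s) and s[j + 1] == b:
            j += 1
        return j - i + 1

    if run(seq, call.pos) >= cfg.homopolymer_len:
        return False
    sub = seq[: call.pos] + call.alt_base + seq[call.pos + 1 :]
    if run(sub, call.pos) >= cfg.homopolymer_len:
        return False
    if any(p != call.pos and abs(p - call.pos) <= 3 for p in all_positions):
        return False
    if len(seq) - call.pos <= cfg.three_prime_margin:
        return False
    return True


def _random_fixture(rng, n_refs=6, n_calls=80):
    refs, anns, calls = {}, {}, []
    for i in range(n_refs):
        L = int(rng.integers(150, 450))
        rid = f"ref{i}"
        quals = rng.integers(10, 41, L)
        refs[rid] = ReadRecord(rid, dna.decode(rng.integers(0, 4, L).astype(np.uint8)),
                               quals.astype(np.int32))
        cat = [Category.GENE_CHAR, Category.UNCHARACTERIZED, Category.REPEAT_JUNCTION][
            int(rng.integers(0, 3))
        ]
        anns[rid] = ReadAnnotation(
            rid, cat,
            CopyClass.SINGLE if rng.random() < 0.8 else CopyClass.MULTI,
        )
    for _ in range(n_calls):
        rid = f"ref{int(rng.integers(0, n_refs))}"
        L = len(refs[rid].sequence)
        pos = int(rng.integers(0, L))
        ref_base = refs[rid].sequence[pos]
        alt = "ACGT"[int(rng.integers(0, 4))]
        if alt == ref_base:
            alt = "ACGT"[("ACGT".index(alt) + 1) % 4]
        depth = int(rng.integers(1, 60))
        alt_count = int(rng.integers(1, depth + 1))
        key = [SOLID_G, (Platform.SOLEXA, Source.GENOMIC), (Platform.LONG_454, Source.GENOMIC)][
            int(rng.integers(0, 3))
        ]
        c = VariantCall(
            ref_id=rid, pos=pos, ref_base=ref_base, alt_base=alt, depth=depth,
            alt_count=alt_count, consensus_base_ratio=alt_count / depth,
            alt_min_mapq=int(rng.integers(0, 61)), platform_depths={key: depth},
        )
        if rng.random() < 0.05:
            c.filter_flags.add(ALT_CONFLICT)
        calls.append(c)
    # drop duplicate (ref,pos) to keep the oracle's proximity rule simple
    seen = set()
    unique = []
    for c in calls:
        if (c.ref_id, c.pos) not in seen:
            seen.add((c.ref_id, c.pos))
            unique.append(c)
    return refs, anns, unique


class TestApplyFilters:
    def test_depth_two_rejected_min_depth(self, rng):
        refs = {"r": ReadRecord("r", "ACGT" * 60, np.full(240, 40))}
        anns = {"r": ReadAnnotation("r", Category.GENE_CHAR, CopyClass.SINGLE)}
        passing, ledger = apply_filters([_call(100, depth=2, alt_count=2)], anns, refs)
        assert passing == []
        assert ledger.loc[0, "flag"] == "MIN_DEPTH"

    def test_perfect_call_passes(self, rng):
        refs = {"r": ReadRecord("r", "ACGT" * 60, np.full(240, 40))}
        anns = {"r": ReadAnnotation("r", Category.GENE_CHAR, CopyClass.SINGLE)}
        passing, ledger = apply_filters([_call(100, depth=5, alt_count=5)], anns, refs)
        assert len(passing) == 1 and len(ledger) == 0

    def test_unknown_reference_raises(self):
        with pytest.raises(KeyError):
            apply_filters([_call(1, ref_id="ghost")], {}, {})

    def test_stack_matches_straightline_oracle_on_500_calls(self, rng):
        total = 0
        while total < 500:
            refs, anns, calls = _random_fixture(rng)
            total += len(calls)
            by_ref = {}
            for c in calls:
                by_ref.setdefault(c.ref_id, []).append(c.pos)
            passing, ledger = apply_filters(calls, anns, refs)
            got = {(c.ref_id, c.pos) for c in passing}
            # oracle, including the uncharacterized extras
            prelim = {}
            for c in calls:
                ok = _oracle_pass(c, refs[c.ref_id], anns[c.ref_id], by_ref[c.ref_id], CFG)
                if ok and anns[c.ref_id].category is Category.UNCHARACTERIZED:
                    for key, d in c.platform_depths.items():
                        lim = CFG.unchar_max_depth.get(key, CFG.max_depth.get(key))
                        if lim is not None and d > lim:
                            ok = False
                prelim[(c.ref_id, c.pos)] = ok
            by_ref_pass = {}
            for (rid, pos), ok in prelim.items():
                if ok and anns[rid].category is Category.UNCHARACTERIZED:
                    by_ref_pass.setdefault(rid, []).append(pos)
            expect = set()
            for (rid, pos), ok in prelim.items():
                if not ok:
                    continue
                if anns[rid].category is Category.UNCHARACTERIZED and len(
                    by_ref_pass.get(rid, [])
                ) > 1:
                    continue
                expect.add((rid, pos))
            assert got == expect
            # ledger conservation: passing + rejected == input, each flagged
            assert len(passing) + len(ledger) == len(calls)
            assert (ledger["flag"] != "").all()

    def test_tightening_thresholds_never_gains_calls(self, rng):
        refs, anns, calls = _random_fixture(rng, n_calls=120)
        base_cfg = FilterConfig()
        base_n = len(apply_filters([dataclasses.replace(c) for c in calls], anns, refs, base_cfg)[0])
        tighter = [
            dict(min_ref_len=300), dict(min_depth=5), dict(min_cbr=0.95),
            dict(min_mapq=40), dict(min_snp_qual=35), dict(min_nqs_qual=30),
            dict(homopolymer_len=2), dict(min_snp_spacing=8), dict(three_prime_margin=60),
        ]
        for kw in tighter:
            cfg = dataclasses.replace(FilterConfig(), **kw)
            n = len(apply_filters([dataclasses.replace(c) for c in calls], anns, refs, cfg)[0])
            assert n <= base_n, kw

    def test_unchar_single_snp_rule(self):
        L = 400
        seq = ("ACGT" * 100)[:L]
        refs = {"u": ReadRecord("u", seq, np.full(L, 40))}
        anns = {"u": ReadAnnotation("u", Category.UNCHARACTERIZED, CopyClass.SINGLE)}
        two = [_call(100, ref_id="u", depth=5, alt_count=5),
               _call(200, ref_id="u", depth=5, alt_count=5)]
        passing, ledger = apply_filters(two, anns, refs)
        assert passing == []
        assert set(ledger["flag"]) == {"UNCHAR_MULTI_SNP"}
        one = [_call(100, ref_id="u", depth=5, alt_count=5)]
        passing, _ = apply_filters(one, anns, refs)
        assert len(passing) == 1

    def test_unchar_stricter_depth(self):
        L = 400
        refs = {"u": ReadRecord("u", ("ACGT" * 100)[:L], np.full(L, 40))}
        anns = {"u": ReadAnnotation("u", Category.UNCHARACTERIZED, CopyClass.SINGLE)}
        # depth 30 passes the global SOLiD-genomic ceiling (50) but not the
        # uncharacterized ceiling (25)
        passing, ledger = apply_filters([_call(100, ref_id="u", depth=30, alt_count=30)], anns, refs)
        assert passing == []
        assert ledger.loc[0, "flag"] == "UNCHAR_DEPTH"


class TestIlluminaSpacing:
    def _refs(self):
        L = 400
        return {"r": ReadRecord("r", ("ACGT" * 100)[:L], np.full(L, 40))}

    def test_pair_59_apart_both_dropped(self):
        calls = [_call(100), _call(159)]
        assert illumina_spacing_filter(calls, self._refs()) == []

    def test_isolated_mid_reference_kept(self):
        calls = [_call(200)]
        assert len(illumina_spacing_filter(calls, self._refs())) == 1

    def test_flank_requirement(self):
        assert illumina_spacing_filter([_call(30)], self._refs()) == []  # < 50 bp left flank

    def test_matches_distance_matrix_oracle(self, rng):
        refs = self._refs()
        for _ in range(100):
            positions = sorted(rng.choice(400, int(rng.integers(1, 8)), replace=False))
            calls = [_call(int(p)) for p in positions]
            kept = {c.pos for c in illumina_spacing_filter(calls, refs)}
            oracle = {
                p for p in positions
                if all(q == p or abs(q - p) >= 60 for q in positions)
                and p >= 50 and (400 - 1 - p) >= 50
            }
            assert kept == oracle


class TestRjTag:
    def test_snp_near_junction_flagged(self):
        calls = [_call(110)]
        junctions = {"r": [RepeatJunction("r", 100, "A", "B", 100, 100)]}
        rj_snp_tag(calls, junctions)
        assert calls[0].rj_near

    def test_snp_on_junction_free_reference_not_flagged(self):
        calls = [_call(110)]
        rj_snp_tag(calls, {})
        assert not calls[0].rj_near

    def test_window_boundary(self):
        junctions = {"r": [RepeatJunction("r", 100, "A", "B", 100, 100)]}
        inside, outside = _call(150), _call(151)
        rj_snp_tag([inside, outside], junctions)
        assert inside.rj_near and not outside.rj_near

    def test_planted_junction_snps_all_and_only_flagged(self, small_run):
        ds, result, _ = small_run
        for c in result.passing:
            junctions = result.junctions.get(c.ref_id, [])
            expect = any(abs(c.pos - j.junction_pos) <= 50 for j in junctions)
            assert c.rj_near == expect


def test_filter_config_yaml_round_trip(tmp_path):
    cfg = FilterConfig(min_depth=4, min_cbr=0.85)
    p = tmp_path / "f.yaml"
    cfg.to_yaml(p)
    back = FilterConfig.from_yaml(p)
    assert back == cfg
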