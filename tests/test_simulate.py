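"""The synthetic-data generator: determinism, composition, planting rates,
error-model accounting, and closed-loop consistency with the annotator."""
import hashlib
from pathlib import Path

import numpy as np
import pytest

from agsnp import dna
from agsnp.annotate import Category, classify_reads
from agsnp.formats import Platform, Source
from agsnp.simulate import (
    ShortPlatformSpec,
    SimConfig,
    TEFamilySpec,
    build_genome,
    derive_genotype2,
    simulate_dataset,
    simulate_long_reads,
)
from conftest import small_sim_config


def _dir_digest(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
    }


class TestBuildGenome:
    def test_no_tes_no_junctions(self):
        cfg = SimConfig(seed=2, genome_length=100_000, te_library=[], n_genes=10,
                        unchar_repeat_families=[])
        build = build_genome(cfg)
        assert len(build.junctions) == 0
        assert len(build.genome) == cfg.genome_length

    def test_realized_repeat_fraction_near_target(self):
        cfg = SimConfig(seed=3, genome_length=2_000_000, repeat_fraction=0.59)
        build = build_genome(cfg)
        te = {i for i, f in enumerate(build.families) if f.kind == "te"}
        bp = sum(
            int(e - s)
            for s, e, f in zip(build.seg_start, build.seg_end, build.seg_family)
            if f in te
        )
        assert abs(bp / cfg.genome_length - 0.59) <= 0.02

    def test_nested_insertions_make_two_breakpoints_each(self):
        cfg = small_sim_config(seed=4)
        build = build_genome(cfg)
        nested = build.junctions[build.junctions["kind"] == "nested"]
        assert len(nested) == 2 * build.n_nested

    def test_segments_tile_genome(self):
        build = build_genome(small_sim_config(seed=5))
        assert build.seg_start[0] == 0
        assert (build.seg_start[1:] == build.seg_end[:-1]).all()
        assert build.seg_end[-1] == len(build.genome)


class TestDeriveGenotype2:
    def test_zero_rates_identical_genotypes(self):
        cfg = small_sim_config(seed=6, snp_rate_genic=0.0, snp_rate_rj=0.0,
                               snp_rate_unchar=0.0)
        build = build_genome(cfg, np.random.default_rng(cfg.seed))
        g2, snps = derive_genotype2(build, cfg, np.random.default_rng(1))
        assert len(snps) == 0
        assert np.array_equal(g2, build.genome)

    def test_genic_planting_matches_poisson_expectation(self):
        cfg = small_sim_config(seed=7)
        build = build_genome(cfg, np.random.default_rng(cfg.seed))
        _, snps = derive_genotype2(build, cfg, np.random.default_rng(2))
        gene_fams = {i for i, f in enumerate(build.families) if f.kind == "gene"}
        gene_bp = sum(
            int(e - s)
            for s, e, f in zip(build.seg_start, build.seg_end, build.seg_family)
            if f in gene_fams
        )
        expected = gene_bp * cfg.snp_rate_genic
        got = (snps["category"] == "genic").sum()
        assert abs(got - expected) < 4 * np.sqrt(expected) + 5

    def test_rj_snps_within_window_of_truth_junction(self):
        cfg = small_sim_config(seed=8)
        build = build_genome(cfg, np.random.default_rng(cfg.seed))
        _, snps = derive_genotype2(build, cfg, np.random.default_rng(3))
        junction_pos = build.junctions["gpos"].to_numpy()
        rj = snps[snps["category"] == "repeat_junction"]["gpos"].to_numpy()
        assert len(rj) > 0
        for g in rj:
            assert np.abs(junction_pos - g).min() <= cfg.rj_window

    def test_alt_differs_from_ref(self):
        cfg = small_sim_config(seed=9)
        build = build_genome(cfg, np.random.default_rng(cfg.seed))
        _, snps = derive_genotype2(build, cfg, np.random.default_rng(4))
        assert (snps["ref_base"] != snps["alt_base"]).all()


class TestLongReads:
    def _run(self, **overrides):
        cfg = small_sim_config(seed=10, **overrides)
        rng = np.random.default_rng(cfg.seed)
        build = build_genome(cfg, rng)
        return cfg, build, *simulate_long_reads(build, cfg, rng)

    def test_error_free_reads_are_exact_substrings(self):
        cfg, build, reads, _, _ = self._run(
            long_sub_rate=0.0, long_indel_rate=0.0,
            organellar_fraction=0.0, replicate_fraction=0.0,
        )
        for r in reads[:50]:
            assert np.array_equal(r.codes, build.genome[r.gstart : r.gstart + r.glen])
            assert r.cigar == f"{r.glen}M"

    def test_homopolymer_indel_bias(self):
        cfg, build, reads, _, stats = self._run()
        assert stats["indels_at_runs"] / stats["indels"] >= 0.8

    def test_mean_coverage_matches_target(self):
        cfg, build, reads, _, _ = self._run(organellar_fraction=0.0, replicate_fraction=0.0)
        cov = np.zeros(len(build.genome) + 1, dtype=np.int32)
        for r in reads:
            cov[r.gstart] += 1
            cov[r.gstart + r.glen] -= 1
        mean_depth = np.cumsum(cov[:-1]).mean()
        assert abs(mean_depth - cfg.long_read_coverage) < 0.07

    def test_replicate_and_organellar_counts(self):
        cfg, build, reads, clusters, stats = self._run()
        n = len(reads)
        n_rep = sum(1 for r in reads if r.replicate_of)
        n_org = sum(1 for r in reads if r.origin == "organellar")
        assert abs(n_rep / n - cfg.replicate_fraction) < 0.01
        assert abs(n_org / n - cfg.organellar_fraction) < 0.005

    def test_g2r_projection_consistent(self):
        cfg, build, reads, _, _ = self._run()
        genomic = [r for r in reads if r.origin == "genomic" and not r.replicate_of]
        matches = total = 0
        for r in genomic[:50]:
            valid = np.nonzero(r.g2r >= 0)[0]
            # read base at projected position matches the genome unless a
            # substitution error was planted there
            genome_slice = build.genome[r.gstart + valid]
            read_slice = r.codes[r.g2r[valid]]
            matches += int((genome_slice == read_slice).sum())
            total += len(valid)
        assert matches / total > 0.99


class TestShortReads:
    def test_error_free_alignments_match_reference_reads(self, rng):
        cfg = small_sim_config(
            seed=12, snp_rate_genic=0.0, snp_rate_rj=0.0, snp_rate_unchar=0.0,
            long_sub_rate=0.0, long_indel_rate=0.0,
            organellar_fraction=0.0, replicate_fraction=0.0,
            short_platforms={
                (Platform.SOLID, Source.GENOMIC): ShortPlatformSpec(50, 2.0, 0.0, low_mapq_fraction=0.0)
            },
        )
        ds = simulate_dataset(cfg)
        aset = ds.alignments[(Platform.SOLID, Source.GENOMIC)]
        refs = {r.read_id: r.codes for r in ds.long_reads}
        idx = rng.choice(len(aset), 200, replace=False)
        for i in idx:
            rec = aset.record(int(i))
            ref = refs[rec.ref_id]
            assert rec.cigar == "50M"
            assert np.array_equal(
                dna.encode(rec.sequence), ref[rec.ref_start : rec.ref_start + 50]
            )

    def test_multicopy_reads_place_at_all_copies(self):
        """A read fully inside an uncharacterized 10-copy element appears at
        roughly copy-number x coverage depth on its references."""
        cfg = SimConfig(
            seed=13, genome_length=500_000, te_library=[], n_genes=20,
            unchar_repeat_families=[TEFamilySpec("URF1", 4000, 10)],
            short_platforms={
                (Platform.SOLID, Source.GENOMIC): ShortPlatformSpec(50, 4.0, 1.8e-4)
            },
        )
        ds = simulate_dataset(cfg)
        from agsnp.depth_model import depth_per_reference

        aset = ds.alignments[(Platform.SOLID, Source.GENOMIC)]
        depths = depth_per_reference(aset, ds.reference_lengths())
        segs = ds.truth.segments
        urf = segs[segs.family == "URF1"]
        us, ue = urf.start.to_numpy(), urf.end.to_numpy()
        urf_depths, gene_depths = [], []
        for row in ds.truth.reads.itertuples(index=False):
            if row.origin != "genomic" or row.replicate_of:
                continue
            frac = np.maximum(
                0, np.minimum(ue, row.gstart + row.glen) - np.maximum(us, row.gstart)
            ).sum() / row.glen
            if frac >= 0.9:
                urf_depths.append(depths[row.read_id])
            elif row.category == "gene_char" and frac == 0:
                gene_depths.append(depths[row.read_id])
        assert np.median(urf_depths) > 5 * np.median(gene_depths)

    def test_hit_tables_closed_loop_with_annotator(self, small_dataset):
        """With the E-value threshold applied, truth hit tables reproduce
        the planted categories for non-junction reads."""
        ds = small_dataset
        reads = [r.to_read_record() for r in ds.long_reads if r.origin == "genomic"
                 and not r.replicate_of]
        ann = classify_reads(reads, ds.repeat_hits, ds.gene_hits)
        truth = ds.truth.reads.set_index("read_id")
        mismatch = 0
        for r in reads:
            t = truth.loc[r.read_id, "category"]
            got = ann[r.read_id].category
            if t in ("repeat", "repeat_junction"):
                ok = got is Category.REPEAT
            elif t == "gene_char":
                ok = got is Category.GENE_CHAR
            else:  # gene_unchar and uncharacterized lack database entries
                ok = got is Category.UNCHARACTERIZED
            mismatch += not ok
        assert mismatch / len(reads) < 0.01

    def test_organellar_hit_fraction(self, small_dataset):
        ds = small_dataset
        n = len(ds.long_reads)
        flagged = {h.query_id for h in ds.organellar_hits}
        f = ds.cfg.organellar_fraction
        assert abs(len(flagged) / n - f) < 3 * np.sqrt(f * (1 - f) / n) + 0.002


class TestDeterminism:
    def test_identical_config_byte_identical_outputs(self, tmp_path):
        cfg = small_sim_config(seed=21, genome_length=120_000, n_genes=12,
                               te_library=[TEFamilySpec("TE01", 3000, 10)],
                               unchar_repeat_families=[])
        simulate_dataset(cfg).write(tmp_path / "a")
        simulate_dataset(cfg).write(tmp_path / "b")
        assert _dir_digest(tmp_path / "a") == _dir_digest(tmp_path / "b")

    def test_different_seed_different_genome(self):
        cfg_a = small_sim_config(seed=22)
        cfg_b = small_sim_config(seed=23)
        ga = build_genome(cfg_a).genome
        gb = build_genome(cfg_b).genome
        assert not np.array_equal(ga, gb)
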