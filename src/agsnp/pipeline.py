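"""End-to-end orchestration: preprocess -> annotate -> depth model ->
calling -> filtering -> reports.

The core entry point is :func:`run_pipeline`, which operates on in-memory
objects (reads, hit tables, alignment sets) and returns a
:class:`PipelineResult` carrying every intermediate product plus a run
manifest whose stage counts chain (the output count of each stage is the
input count of the next). :func:`run_all` is the file-based wrapper used
by the command line: it materialises simulator output to disk and runs
each stage through the same readers the subcommands use, so a manual
composition of subcommands reproduces its outputs byte for byte.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (
    Category,
    CopyClass,
    ReadAnnotation,
    RepeatJunction,
    annotation_table,
    classify_reads,
    identify_uncharacterized_genes,
    tag_repeat_junctions,
)
from .depth_model import (
    DepthModel,
    classify_copy_number,
    depth_per_reference,
    fit_depth_model,
)
from .formats import (
    AlignmentSet,
    Platform,
    ReadRecord,
    Source,
    combo_string,
    write_bed,
    write_tsv,
    write_vcf,
)
from .preprocess import filter_organellar, remove_artificial_replicates
from .simulate import SimConfig, SimulatedDataset, simulate_dataset
from .snp_engine import (
    VariantCall,
    calls_from_arrays,
    merge_platform_calls,
    pileup_arrays,
    provenance_report,
)
from .snp_filter import FilterConfig, apply_filters, rj_snp_tag

#: categories eligible for SNP discovery once single-copy
SNP_CATEGORIES = frozenset(
    {Category.GENE_CHAR, Category.GENE_UNCHAR, Category.REPEAT_JUNCTION, Category.UNCHARACTERIZED}
)


@dataclass
class PipelineResult:
    kept_reads: dict[str, ReadRecord]
    annotations: dict[str, ReadAnnotation]
    junctions: dict[str, list[RepeatJunction]]
    depth_model: DepthModel
    depths: dict[str, int]
    merged_calls: list[VariantCall]
    passing: list[VariantCall]
    ledger: pd.DataFrame
    summary: pd.DataFrame
    provenance: pd.DataFrame
    manifest: dict


def nucleotides_per_snp(total_length: int, n_snps: int) -> int:
    """bp per SNP as reported: integer part of length / count."""
    if n_snps == 0:
        return 0
    return int(total_length // n_snps)


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage with half-up rounding at ``digits`` decimals."""
    if denominator == 0:
        return 0.0
    scale = 10**digits
    return np.floor(100.0 * numerator / denominator * scale + 0.5) / scale


def run_pipeline(
    reads: Sequence[ReadRecord],
    organellar_hits: Iterable,
    repeat_hits: Sequence,
    gene_hits: Sequence,
    alignments: Mapping[tuple[Platform, Source], AlignmentSet],
    filters: FilterConfig | None = None,
    *,
    evalue_max: float = 1e-10,
    min_cdna_depth: int = 2,
    min_flank: int = 30,
    depth_key: tuple[Platform, Source] | None = None,
    ev_family: str = "gumbel",
    seed: int | None = None,
) -> PipelineResult:
    """Run every stage on in-memory inputs."""
    filters = filters or FilterConfig()
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": [],
    }

    def stage(name: str, n_in: int, n_out: int, **extra) -> None:
        manifest["stages"].append({"stage": name, "in": n_in, "out": n_out, **extra})

    # 1. preprocess
    n0 = len(reads)
    kept, removed_org = filter_organellar(reads, organellar_hits, evalue_max)
    stage("organellar_filter", n0, len(kept), removed=len(removed_org))
    kept, clusters = remove_artificial_replicates(kept)
    n_rep = sum(len(c.member_ids) - 1 for c in clusters)
    stage("replicate_filter", n0 - len(removed_org), len(kept), removed=n_rep)
    kept_reads = {r.read_id: r for r in kept}

    # 2. annotation
    annotations = classify_reads(kept, repeat_hits, gene_hits, evalue_max)
    junctions = tag_repeat_junctions(annotations, kept_reads, repeat_hits, min_flank, evalue_max)
    cdna_key = next((k for k in alignments if k[1] is Source.CDNA), None)
    if cdna_key is not None:
        identify_uncharacterized_genes(annotations, alignments[cdna_key], min_cdna_depth)
    cat_counts = {c.name: 0 for c in Category}
    for a in annotations.values():
        cat_counts[a.category.name] += 1
    stage("annotate", len(kept), len(annotations), categories=cat_counts)

    # 3. depth model and copy-number classification
    genomic = {k: v for k, v in alignments.items() if k[1] is Source.GENOMIC}
    if depth_key is None:
        depth_key = max(genomic or alignments, key=lambda k: len(alignments[k]))
    classed_refs = {
        rid: len(kept_reads[rid])
        for rid, a in annotations.items()
        if a.category in SNP_CATEGORIES and rid in kept_reads
    }
    depths = depth_per_reference(alignments[depth_key], classed_refs)
    gene_depths = {
        rid: d
        for rid, d in depths.items()
        if annotations[rid].category is Category.GENE_CHAR
    }
    model = fit_depth_model(gene_depths, depth_key[0], depth_key[1], family=ev_family)
    classify_copy_number(annotations, depths, model)
    n_single = sum(1 for a in annotations.values() if a.copy_class is CopyClass.SINGLE)
    stage("depth_model", len(classed_refs), n_single,
          cutoff=model.cutoff, xbar=round(model.xbar, 3), s=round(model.s, 3))

    # 4. per-platform calling on the single-copy reference set
    single_refs = {
        rid for rid, a in annotations.items() if a.copy_class is CopyClass.SINGLE
    }
    ref_codes = {rid: kept_reads[rid].codes for rid in single_refs}
    ref_lengths = {rid: len(kept_reads[rid]) for rid in single_refs}
    call_sets = []
    n_raw = 0
    for key in sorted(alignments, key=lambda k: (k[0].name, k[1].name)):
        aset = alignments[key]
        present = single_refs & set(aset.ref_names)
        piles = pileup_arrays(aset, ref_lengths, target_refs=present)
        calls = calls_from_arrays(piles, ref_codes, key[0], key[1])
        n_raw += len(calls)
        call_sets.append(calls)
    merged = merge_platform_calls(call_sets)
    stage("call", n_raw, len(merged))

    # 5. filtering
    passing, ledger = apply_filters(merged, annotations, kept_reads, filters)
    rj_snp_tag(passing, junctions, filters.rj_window)
    stage("filter", len(merged), len(passing), rejected=len(ledger),
          flags=ledger["flag"].value_counts().to_dict() if len(ledger) else {})

    summary = summarize(passing, annotations, kept_reads)
    prov = provenance_report(passing)
    manifest["filters"] = {"min_depth": filters.min_depth, "min_cbr": filters.min_cbr}
    return PipelineResult(
        kept_reads=kept_reads,
        annotations=annotations,
        junctions=junctions,
        depth_model=model,
        depths=depths,
        merged_calls=merged,
        passing=passing,
        ledger=ledger,
        summary=summary,
        provenance=prov,
        manifest=manifest,
    )


def summarize(
    passing: Sequence[VariantCall],
    annotations: Mapping[str, ReadAnnotation],
    references: Mapping[str, ReadRecord],
) -> pd.DataFrame:
    """Per-category SNP summary: single-copy reference length, SNP count,
    nucleotides/SNP, references with SNPs, junction-proximal SNPs."""
    rows = []
    by_cat: dict[Category, list[VariantCall]] = {c: [] for c in Category}
    for c in passing:
        if c.category is not None:
            by_cat[c.category].append(c)
    for cat in Category:
        refs_single = [
            rid
            for rid, a in annotations.items()
            if a.category is cat and a.copy_class is CopyClass.SINGLE and rid in references
        ]
        total_len = sum(len(references[r]) for r in refs_single)
        calls = by_cat[cat]
        rows.append(
            {
                "category": cat.name,
                "single_copy_refs": len(refs_single),
                "single_copy_length_bp": total_len,
                "n_snps": len(calls),
                "nucleotides_per_snp": nucleotides_per_snp(total_len, len(calls)),
                "refs_with_snps": len({c.ref_id for c in calls}),
                "rj_near_snps": sum(1 for c in calls if c.rj_near),
            }
        )
    total_len = sum(r["single_copy_length_bp"] for r in rows)
    rows.append(
        {
            "category": "TOTAL",
            "single_copy_refs": sum(r["single_copy_refs"] for r in rows),
            "single_copy_length_bp": total_len,
            "n_snps": len(passing),
            "nucleotides_per_snp": nucleotides_per_snp(total_len, len(passing)),
            "refs_with_snps": len({c.ref_id for c in passing}),
            "rj_near_snps": sum(1 for c in passing if c.rj_near),
        }
    )
    return pd.DataFrame(rows)


def check_manifest_chain(manifest: dict) -> bool:
    """Stage counts chain: each stage's input equals the previous output
    (the annotate and depth stages narrow scope explicitly, so chaining is
    asserted for the preprocess pair and the call->filter pair)."""
    stages = {s["stage"]: s for s in manifest["stages"]}
    ok = stages["replicate_filter"]["in"] == stages["organellar_filter"]["out"]
    ok &= stages["annotate"]["in"] == stages["replicate_filter"]["out"]
    ok &= stages["filter"]["in"] == stages["call"]["out"]
    return bool(ok)


# ---------------------------------------------------------------------------
# truth-based evaluation (simulated data)
# ---------------------------------------------------------------------------

def evaluate_against_truth(
    passing: Sequence[VariantCall], dataset: SimulatedDataset
) -> dict:
    """Precision/recall of passing calls against planted SNPs.

    Recall is reported against (a) planted SNPs covered by at least one
    usable reference read ("discoverable") and (b) all planted SNPs.
    """
    sites = dataset.snp_sites_on_reads()
    site_key = set(zip(sites["ref_id"], sites["pos"], sites["alt_base"]))
    site_gpos = dict(zip(zip(sites["ref_id"], sites["pos"]), sites["gpos"]))
    tp_calls = [c for c in passing if (c.ref_id, c.pos, c.alt_base) in site_key]
    found_gpos = {site_gpos[(c.ref_id, c.pos)] for c in tp_calls}
    n_discoverable = sites["gpos"].nunique()
    n_planted = len(dataset.truth.snps)
    precision = len(tp_calls) / len(passing) if passing else 0.0
    per_cat = {}
    for cat in ("genic", "repeat_junction", "uncharacterized"):
        cat_sites = sites[sites["category"] == cat]
        cat_gpos = set(cat_sites["gpos"])
        found = len(found_gpos & cat_gpos)
        per_cat[cat] = {
            "discoverable": cat_sites["gpos"].nunique(),
            "found": found,
            "recall": found / cat_sites["gpos"].nunique() if len(cat_sites) else 0.0,
        }
    return {
        "n_passing": len(passing),
        "n_true_positive": len(tp_calls),
        "precision": precision,
        "n_planted": n_planted,
        "n_discoverable": n_discoverable,
        "n_found": len(found_gpos),
        "recall_discoverable": len(found_gpos) / n_discoverable if n_discoverable else 0.0,
        "recall_planted": len(found_gpos) / n_planted if n_planted else 0.0,
        "per_category": per_cat,
    }


def run_simulated(
    cfg: SimConfig, filters: FilterConfig | None = None, **kwargs
) -> tuple[SimulatedDataset, PipelineResult, dict]:
    """Simulate a dataset, run the pipeline on it in memory, evaluate."""
    ds = simulate_dataset(cfg)
    result = run_pipeline(
        ds.long_read_records(),
        ds.organellar_hits,
        ds.repeat_hits,
        ds.gene_hits,
        ds.alignments,
        filters,
        seed=cfg.seed,
        **kwargs,
    )
    evaluation = evaluate_against_truth(result.passing, ds)
    return ds, result, evaluation


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------

def run_all(
    cfg: SimConfig,
    outdir,
    filters: FilterConfig | None = None,
) -> PipelineResult:
    """One-command end-to-end run on simulated data, through files.

    Simulator inputs are written to ``outdir/inputs`` and the pipeline
    reads them back with the same readers the CLI subcommands use, so the
    outputs are reproducible by composing subcommands manually.
    """
    from .formats import load_alignment_set, read_fastx, read_hit_table
    from .formats import DbTag

    out = Path(outdir)
    inputs = out / "inputs"
    ds = simulate_dataset(cfg)
    ds.write(inputs)

    reads = list(read_fastx(inputs / "long_reads.fastq", Platform.LONG_454, Source.GENOMIC))
    org_hits = list(read_hit_table(inputs / "organellar_hits.tsv", DbTag.ORGANELLAR))
    rep_hits = list(read_hit_table(inputs / "repeat_hits.tsv", DbTag.REPEAT))
    gene_hits = list(read_hit_table(inputs / "gene_hits.tsv", DbTag.GENE_NT))
    alignments = {}
    for key in sorted(ds.alignments, key=lambda k: (k[0].name, k[1].name)):
        p, s = key
        alignments[key] = load_alignment_set(inputs / f"aln_{p.name}_{s.name}.sam", p, s)

    result = run_pipeline(reads, org_hits, rep_hits, gene_hits, alignments, filters, seed=cfg.seed)
    write_outputs(result, out)
    return result


def write_outputs(result: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = {rid: len(r) for rid, r in result.kept_reads.items()}
    used = sorted({c.ref_id for c in result.passing})
    write_vcf(result.passing, out / "snps.vcf", {rid: contigs[rid] for rid in used})
    write_bed(
        (
            (rid, j.junction_pos, j.junction_pos + 1, f"{j.left_label}|{j.right_label}")
            for rid, js in sorted(result.junctions.items())
            for j in js
        ),
        out / "junctions.bed",
    )
    write_tsv(result.summary, out / "summary.tsv")
    write_tsv(result.provenance, out / "provenance.tsv")
    write_tsv(result.ledger, out / "rejections.tsv")
    write_tsv(annotation_table(result.annotations), out / "annotations.tsv")
    result.depth_model.to_json(out / "depth_model.json")
    manifest = dict(result.manifest)
    manifest["vcf_sha256"] = hashlib.sha256((out / "snps.vcf").read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
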