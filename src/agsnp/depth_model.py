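"""Single-copy calibration from the mapped read-depth distribution.

Most genes sit at single-copy dose, so the depth of genotype-2 reads mapped
onto characterized gene reads estimates the expected depth of any
single-copy sequence. That depth distribution is well approximated by an
extreme-value law; a Gumbel (or optionally Weibull, which suits the
left-skewed shape seen at very low coverage) is fitted by maximum
likelihood to the histogram with the repeat-inflated upper tail trimmed at
the empirical 99th percentile. The single-copy cutoff is the integer part
of mean + 2 standard deviations of the fitted law; reads at or below the
cutoff are classed single-copy, above it multi-copy.
"""
from __future__ import annotations

import json
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .annotate import Category, CopyClass, ReadAnnotation
from .formats import AlignmentSet, Platform, Source, cigar_reference_length

_EULER_GAMMA = 0.5772156649015329

#: categories whose copy number is decided by depth; plain repeats stay UNKNOWN
_DEPTH_CLASSED = frozenset(
    {Category.GENE_CHAR, Category.GENE_UNCHAR, Category.REPEAT_JUNCTION, Category.UNCHARACTERIZED}
)


@dataclass
class DepthModel:
    platform: Platform
    source: Source
    histogram: dict[int, int]
    xbar: float
    s: float
    cutoff: int
    family: str = "gumbel"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "platform": self.platform.name,
                    "source": self.source.name,
                    "xbar": self.xbar,
                    "s": self.s,
                    "cutoff": self.cutoff,
                    "family": self.family,
                    "histogram": {str(k): v for k, v in self.histogram.items()},
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "DepthModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            platform=Platform[d["platform"]],
            source=Source[d["source"]],
            histogram={int(k): v for k, v in d["histogram"].items()},
            xbar=d["xbar"],
            s=d["s"],
            cutoff=d["cutoff"],
            family=d.get("family", "gumbel"),
        )


def depth_per_reference(
    alignments: AlignmentSet | Iterable,
    reference_lengths: Mapping[str, int],
) -> dict[str, int]:
    """Median per-position coverage for every reference.

    All positions of the reference (including uncovered ones) enter the
    median once the reference has at least one aligned read; references with
    no reads have depth 0. Returns integer depths (numpy median of an
    integer coverage vector, floored).
    """
    if isinstance(alignments, AlignmentSet):
        starts_by_ref: dict[str, list[tuple[int, int]]] = defaultdict(list)
        lens = alignments.seq_len
        cigars = alignments.cigars
        names = alignments.ref_names
        ref_index = alignments.ref_index
        ref_start = alignments.ref_start
        for i in range(len(alignments)):
            c = cigars[i]
            span = int(lens[i]) if c is None else cigar_reference_length(c)
            starts_by_ref[names[ref_index[i]]].append((int(ref_start[i]), span))
    else:
        starts_by_ref = defaultdict(list)
        for rec in alignments:
            starts_by_ref[rec.ref_id].append(
                (rec.ref_start, cigar_reference_length(rec.cigar))
            )

    depths: dict[str, int] = {}
    for ref_id, L in reference_lengths.items():
        ivs = starts_by_ref.get(ref_id)
        if not ivs:
            depths[ref_id] = 0
            continue
        diff = np.zeros(L + 1, dtype=np.int32)
        for start, span in ivs:
            s = max(0, min(start, L))
            e = max(0, min(start + span, L))
            diff[s] += 1
            diff[e] -= 1
        cov = np.cumsum(diff[:-1])
        depths[ref_id] = int(np.median(cov))
    return depths


def fit_extreme_value(
    histogram: Mapping[int, int],
    family: str = "gumbel",
    tail_quantile: float = 0.99,
) -> tuple[float, float, int]:
    """Fit an extreme-value law to a depth histogram; return (xbar, s, cutoff).

    Depths in [1, q99] are fitted by maximum likelihood (the zero class and
    the repeat-inflated tail beyond the empirical ``tail_quantile`` are
    excluded). ``xbar`` and ``s`` are the mean and standard deviation of the
    fitted distribution and ``cutoff = int(xbar + 2 s)`` (truncation, so the
    published example 10.7 + 2*21.3 = 53.3 prints as 53).
    """
    if not histogram:
        raise ValueError("empty depth histogram")
    depths = np.array(sorted(histogram), dtype=np.float64)
    counts = np.array([histogram[int(d)] for d in depths], dtype=np.int64)
    samples = np.repeat(depths, counts)
    samples = samples[samples >= 1]
    if samples.size == 0:
        warnings.warn("no non-zero depths; degenerate model at 0")
        return 0.0, 0.0, 0
    if np.all(samples == samples[0]):
        d = float(samples[0])
        warnings.warn(f"degenerate depth histogram (all at {d:g}); s = 0")
        return d, 0.0, int(d)
    q99 = np.quantile(samples, tail_quantile)
    trimmed = samples[samples <= q99]
    if np.all(trimmed == trimmed[0]):
        d = float(trimmed[0])
        warnings.warn(f"degenerate trimmed histogram (all at {d:g}); s = 0")
        return d, 0.0, int(d)
    if family == "gumbel":
        loc, scale = stats.gumbel_r.fit(trimmed)
        xbar = loc + _EULER_GAMMA * scale
        s = math.pi * scale / math.sqrt(6.0)
    elif family == "weibull":
        shape, loc, scale = stats.weibull_min.fit(trimmed, floc=0.0)
        xbar, var = stats.weibull_min.stats(shape, loc=loc, scale=scale, moments="mv")
        xbar, s = float(xbar), math.sqrt(float(var))
    else:
        raise ValueError(f"unknown extreme-value family {family!r}")
    return float(xbar), float(s), cutoff_from_moments(xbar, s)


def cutoff_from_moments(xbar: float, s: float) -> int:
    """Single-copy depth cutoff: integer part of xbar + 2 s."""
    return int(xbar + 2.0 * s)


def fit_depth_model(
    depths: Mapping[str, int],
    platform: Platform,
    source: Source,
    family: str = "gumbel",
) -> DepthModel:
    """Build the histogram over reference depths and fit the cutoff."""
    histogram: dict[int, int] = defaultdict(int)
    for d in depths.values():
        histogram[int(d)] += 1
    xbar, s, cutoff = fit_extreme_value(histogram, family=family)
    return DepthModel(platform, source, dict(histogram), xbar, s, cutoff, family)


def classify_copy_number(
    annotations: dict[str, ReadAnnotation],
    depths: Mapping[str, int],
    model: DepthModel,
) -> dict[str, ReadAnnotation]:
    """Set copy_class from depth: SINGLE iff depth <= cutoff else MULTI.

    Applied to gene, repeat-junction and uncharacterized reads; plain
    repeat reads keep copy_class UNKNOWN. Mutates and returns
    ``annotations``.
    """
    for read_id, ann in annotations.items():
        if ann.category in _DEPTH_CLASSED and read_id in depths:
            depth = depths[read_id]
            ann.copy_class = CopyClass.SINGLE if depth <= model.cutoff else CopyClass.MULTI
    return annotations
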