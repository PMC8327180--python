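"""Quality-control pipeline for BCR-Seq samples.

Implements the three sequential read-retention stages used on technical
duplicate libraries — a V_H sequence must appear in both replicates, CDR3
and full VDJ annotation must be present, and a minimum summed abundance of
2 reads — plus the duplicate Spearman correlation and
rarefaction analysis with the 99 %-saturation statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_airr import REGIONS, V_REGIONS, RearrangementRecord, RepertoireSample


class InsufficientDataError(ValueError):
    """Too few shared sequences for the requested statistic."""


@dataclass
class FilterReport:
    """Per-stage record accounting through the QC pipeline."""

    input_unique: int = 0
    after_intersection: Optional[int] = None
    after_cdr3_vdj_filter: Optional[int] = None
    after_min_reads: Optional[int] = None
    rejections: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_unique": self.input_unique,
            "after_intersection": self.after_intersection,
            "after_cdr3_vdj_filter": self.after_cdr3_vdj_filter,
            "after_min_reads": self.after_min_reads,
            "rejections": dict(self.rejections),
        }


# ---------------------------------------------------------------------------
# Stage 1: duplicate intersection
# ---------------------------------------------------------------------------


def intersect_duplicates(
    a: RepertoireSample,
    b: RepertoireSample,
    combine: str = "sum",
) -> RepertoireSample:
    """Retain only V_H sequences observed in both technical duplicates.

    Read counts of retained sequences are combined across duplicates
    (``sum`` by default, preserving total evidence; ``mean`` available).
    The result carries no duplicate label.
    """
    if (a.mouse_id, a.tissue) != (b.mouse_id, b.tissue):
        raise ValueError(
            "duplicates must come from the same mouse/tissue: "
            f"{a.mouse_id}/{a.tissue} vs {b.mouse_id}/{b.tissue}"
        )
    if combine not in ("sum", "mean"):
        raise ValueError(f"unknown combine rule {combine!r}")
    b_counts = {rec.sequence_nt: rec.read_count for rec in b.records}
    records = []
    for rec in a.records:
        if rec.sequence_nt not in b_counts:
            continue
        total = rec.read_count + b_counts[rec.sequence_nt]
        count = total if combine == "sum" else max(1, round(total / 2))
        records.append(replace(rec, read_count=count))
    return RepertoireSample(
        mouse_id=a.mouse_id,
        tissue=a.tissue,
        condition=a.condition,
        duplicate_id=None,
        records=records,
    )


# ---------------------------------------------------------------------------
# Stages 2 and 3: annotation completeness and minimum abundance
# ---------------------------------------------------------------------------


def _has_complete_annotation(rec: RearrangementRecord) -> bool:
    if not rec.cdr3_nt:
        return False
    if not rec.v_call or not rec.j_call:
        return False
    return all(r in rec.region_bounds for r in REGIONS)


def apply_quality_filters(
    sample: RepertoireSample,
    min_reads: int = 2,
) -> tuple[RepertoireSample, FilterReport]:
    """Apply the annotation-completeness and minimum-abundance criteria.

    ``min_reads`` is evaluated on the post-intersection (summed) counts;
    the default of 2 reads reflects standard VDJ-abundance filtering.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    report = FilterReport(input_unique=sample.n_unique)
    report.after_intersection = sample.n_unique

    annotated = [r for r in sample.records if _has_complete_annotation(r)]
    report.rejections["missing_cdr3_or_vdj"] = sample.n_unique - len(annotated)
    report.after_cdr3_vdj_filter = len(annotated)

    abundant = [r for r in annotated if r.read_count >= min_reads]
    report.rejections["below_min_reads"] = len(annotated) - len(abundant)
    report.after_min_reads = len(abundant)

    filtered = RepertoireSample(
        mouse_id=sample.mouse_id,
        tissue=sample.tissue,
        condition=sample.condition,
        duplicate_id=sample.duplicate_id,
        records=abundant,
    )
    return filtered, report


def filter_pipeline(
    a: RepertoireSample,
    b: RepertoireSample,
    min_reads: int = 2,
) -> tuple[RepertoireSample, FilterReport]:
    """Full QC: intersection -> annotation filter -> abundance filter."""
    input_unique = a.n_unique + b.n_unique
    intersected = intersect_duplicates(a, b)
    filtered, report = apply_quality_filters(intersected, min_reads=min_reads)
    report.input_unique = input_unique
    report.after_intersection = intersected.n_unique
    report.rejections["not_in_both_duplicates"] = input_unique - 2 * intersected.n_unique
    return filtered, report


# ---------------------------------------------------------------------------
# Duplicate correlation
# ---------------------------------------------------------------------------


def duplicate_correlation(
    a: RepertoireSample, b: RepertoireSample
) -> tuple[float, float]:
    """Spearman rank correlation of per-sequence transcript counts over the
    sequences shared by both duplicates; returns (rho, two-sided p)."""
    b_counts = {rec.sequence_nt: rec.read_count for rec in b.records}
    pairs = [
        (rec.read_count, b_counts[rec.sequence_nt])
        for rec in a.records
        if rec.sequence_nt in b_counts
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} shared sequences; need >= 3 for correlation"
        )
    xs, ys = zip(*pairs)
    result = stats.spearmanr(xs, ys)
    return float(result.statistic), float(result.pvalue)


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


@dataclass
class RarefactionCurve:
    """Mean unique-sequence richness (as a fraction of total unique) at each
    read-subsampling depth fraction."""

    depth_fraction: np.ndarray
    mean_richness_fraction: np.ndarray
    n_iterations: int
    total_reads: int
    total_unique: int

    def validate(self) -> None:
        if np.any(np.diff(self.mean_richness_fraction) < -1e-12):
            raise ValueError("richness fraction must be non-decreasing in depth")
        if abs(self.depth_fraction[-1] - 1.0) < 1e-12 and not np.isclose(
            self.mean_richness_fraction[-1], 1.0
        ):
            raise ValueError("richness fraction at full depth must be 1.0")


def rarefaction_curve(
    sample: RepertoireSample,
    grid: Optional[Sequence[float]] = None,
    n_iterations: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefy by repeatedly subsampling reads without replacement.

    Observed richness (the number of unique V_H sequences) is estimated as
    a function of subsampled read depth, the classical ecological species
    rarefaction applied to sequencing reads.  Each
    iteration permutes the full read multiset once and evaluates richness on
    nested prefixes, so the mean curve is monotone by construction.
    """
    if not sample.records:
        raise ValueError("cannot rarefy an empty sample")
    if grid is None:
        grid = np.round(np.arange(0.02, 1.0 + 1e-9, 0.02), 10)
    grid = np.asarray(sorted(grid), dtype=float)
    if np.any(grid <= 0) or np.any(grid > 1):
        raise ValueError("depth grid must lie in (0, 1]")

    counts = np.array([r.read_count for r in sample.records])
    total_reads = int(counts.sum())
    total_unique = len(counts)
    expanded = np.repeat(np.arange(total_unique), counts)
    depths = np.maximum(1, np.round(grid * total_reads).astype(int))
    depths[np.isclose(grid, 1.0)] = total_reads

    rng = np.random.default_rng(seed)
    richness_sum = np.zeros(len(grid))
    for _ in range(n_iterations):
        perm = rng.permutation(expanded)
        # first occurrence position of each unique sequence in this permutation
        _, first_pos = np.unique(perm, return_index=True)
        first_pos.sort()
        richness_sum += np.searchsorted(first_pos, depths, side="left")
    mean_richness = richness_sum / n_iterations / total_unique
    curve = RarefactionCurve(
        depth_fraction=grid,
        mean_richness_fraction=mean_richness,
        n_iterations=n_iterations,
        total_reads=total_reads,
        total_unique=total_unique,
    )
    curve.validate()
    return curve


#: sentinel for a curve that never reaches the saturation target
NOT_SATURATED = None


def saturation_depth(
    curve: RarefactionCurve, target: float = 0.99
) -> Optional[float]:
    """Smallest grid depth at which mean richness reaches ``target`` (the
    99 %-diversity depth by default); ``None`` if never reached."""
    if not 0 < target <= 1:
        raise ValueError("target must lie in (0, 1]")
    reached = np.flatnonzero(curve.mean_richness_fraction >= target - 1e-12)
    if len(reached) == 0:
        return NOT_SATURATED
    return float(curve.depth_fraction[reached[0]])
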