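"""Single-compartment repertoire measures.

Clonally related B cells are defined as those sharing the same V_H and J_H
gene groups (allele suffixes stripped) and an identical CDR3 nucleotide
sequence.  Clone abundance (polarization) is based on read frequency; most
other measures — CDRH3 length, V-gene usage, isotype distribution, SHM —
are computed per unique V_H sequence, unweighted by reads (a read-weighted
variant is available behind a flag).

Diversity follows the Hill-number family

    D_q = (sum_i p_i^q) ** (1 / (1 - q))

with p_i the read frequency of clone i; q = 0 is richness S, q = 1 the
analytic limit exp(Shannon entropy), q = 2 the inverse Simpson index.  The
default order is q = 2, weighting abundant clones most strongly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_airr import (
    GAP,
    ISOTYPES,
    V_REGIONS,
    GermlineSet,
    RearrangementRecord,
    RepertoireSample,
    ValidationError,
    strip_allele,
)

CloneKey = tuple[str, str, str]  # (v_gene, j_gene, cdr3_nt)


@dataclass
class Clone:
    v_gene: str
    j_gene: str
    cdr3_nt: str
    members: list[str] = field(default_factory=list)  # sequence_ids
    read_count: int = 0
    unique_count: int = 0
    isotype_counts: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> CloneKey:
        return (self.v_gene, self.j_gene, self.cdr3_nt)


@dataclass
class CloneSet:
    clones: list[Clone]

    @property
    def S(self) -> int:
        return len(self.clones)

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clones)

    @property
    def frequencies(self) -> np.ndarray:
        counts = np.array([c.read_count for c in self.clones], dtype=float)
        return counts / counts.sum()

    def keys(self) -> set[CloneKey]:
        return {c.key for c in self.clones}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "cdr3_nt": c.cdr3_nt,
                "read_count": c.read_count,
                "unique_count": c.unique_count,
            }
            for c in self.clones
        ]
        df = pd.DataFrame(
            rows, columns=["v_gene", "j_gene", "cdr3_nt", "read_count", "unique_count"]
        )
        if len(df):
            df["frequency"] = df["read_count"] / df["read_count"].sum()
        return df


def cluster_clones(sample: RepertoireSample) -> CloneSet:
    """Partition unique sequences into clones by (V gene, J gene, CDR3 nt)
    with 100 % CDR3 nucleotide identity; allele tags are stripped first."""
    table: dict[CloneKey, Clone] = {}
    for rec in sample.records:
        key = (strip_allele(rec.v_call), strip_allele(rec.j_call), rec.cdr3_nt)
        clone = table.get(key)
        if clone is None:
            clone = Clone(v_gene=key[0], j_gene=key[1], cdr3_nt=key[2])
            table[key] = clone
        clone.members.append(rec.sequence_id)
        clone.read_count += rec.read_count
        clone.unique_count += 1
        clone.isotype_counts[rec.isotype] = clone.isotype_counts.get(rec.isotype, 0) + 1
    # deterministic order, independent of record order
    clones = [table[k] for k in sorted(table)]
    return CloneSet(clones=clones)


# ---------------------------------------------------------------------------
# Clonal polarization and diversity
# ---------------------------------------------------------------------------


def polarization_count(clones: CloneSet, threshold: float = 0.8) -> int:
    """Number of clones (largest first) needed to account for ``threshold``
    of all reads — the clones-to-80 % polarization statistic.  Ties in read
    count are broken by ascending CDR3 string for determinism."""
    if clones.S == 0:
        raise ValueError("polarization of an empty clone set is undefined")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(clones.clones, key=lambda c: (-c.read_count, c.cdr3_nt))
    total = float(clones.total_reads)
    cum = 0.0
    for k, clone in enumerate(ordered, start=1):
        cum += clone.read_count / total
        if cum >= threshold - 1e-12:
            return k
    return clones.S


def hill_diversity(clones: CloneSet, q: float = 2.0) -> float:
    """Hill diversity D_q of the clone read-frequency distribution.

    q = 1 is evaluated as the analytic limit exp(-sum p ln p); the direct
    formula is undefined there.  The result lies in [1, S].
    """
    if clones.S == 0:
        raise ValueError("diversity of an empty clone set is undefined")
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    p = clones.frequencies
    p = p[p > 0]
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


# ---------------------------------------------------------------------------
# CDRH3 length
# ---------------------------------------------------------------------------


def cdrh3_length_distribution(
    sample: RepertoireSample,
    unit: str = "aa",
    read_weighted: bool = False,
) -> tuple[pd.Series, float]:
    """Histogram and median of CDRH3 length, one value per unique sequence
    (or per read with ``read_weighted``).  ``unit`` is ``aa`` or ``nt``."""
    if unit not in ("aa", "nt"):
        raise ValueError(f"unknown unit {unit!r}")
    lengths = []
    for rec in sample.records:
        n = len(rec.cdr3_aa) if unit == "aa" else len(rec.cdr3_nt)
        lengths.extend([n] * (rec.read_count if read_weighted else 1))
    if not lengths:
        raise ValueError("no sequences with CDRH3 annotation")
    series = pd.Series(lengths)
    hist = series.value_counts().sort_index()
    hist.index.name = f"cdrh3_length_{unit}"
    return hist, float(series.median())


def cdrh3_lengths(sample: RepertoireSample, unit: str = "aa") -> list[int]:
    """Raw per-unique-sequence CDRH3 lengths (for distribution comparisons)."""
    if unit not in ("aa", "nt"):
        raise ValueError(f"unknown unit {unit!r}")
    return [
        len(rec.cdr3_aa) if unit == "aa" else len(rec.cdr3_nt)
        for rec in sample.records
    ]


def compare_distributions(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Nonparametric, unpaired, two-sided Mann-Whitney rank-sum test with tie
    correction; returns (U statistic, two-sided p)."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(result.statistic), float(result.pvalue)


# ---------------------------------------------------------------------------
# V-gene usage
# ---------------------------------------------------------------------------


@dataclass
class UsageTable:
    """Per-V-gene unique-sequence counts and frequencies."""

    table: pd.DataFrame  # columns: v_gene, unique_count, frequency

    def frequency_of(self, gene: str) -> float:
        row = self.table.loc[self.table["v_gene"] == gene, "frequency"]
        return float(row.iloc[0]) if len(row) else 0.0

    def count_of(self, gene: str) -> int:
        row = self.table.loc[self.table["v_gene"] == gene, "unique_count"]
        return int(row.iloc[0]) if len(row) else 0

    @property
    def total_unique(self) -> int:
        return int(self.table["unique_count"].sum())


def v_gene_usage(
    sample: RepertoireSample,
    germline: Optional[GermlineSet] = None,
    read_weighted: bool = False,
) -> UsageTable:
    """Quantify the number of unique V_H sequences annotated to each V gene.

    With a germline set supplied, genes with zero usage appear as zero rows.
    """
    counts: dict[str, int] = {}
    if germline is not None:
        counts = {g: 0 for g in germline.v_gene_names}
    for rec in sample.records:
        gene = rec.v_gene
        weight = rec.read_count if read_weighted else 1
        counts[gene] = counts.get(gene, 0) + weight
    df = pd.DataFrame(
        {"v_gene": list(counts), "unique_count": list(counts.values())}
    )
    total = df["unique_count"].sum()
    df["frequency"] = df["unique_count"] / total if total else 0.0
    return UsageTable(table=df)


def clone_usage(
    clones: CloneSet, germline: Optional[GermlineSet] = None
) -> UsageTable:
    """V-gene usage counted per clone (one count per clone, regardless of
    member or read counts) — the independent-unit table used as the basal
    reference for common-clone enrichment testing."""
    counts: dict[str, int] = {}
    if germline is not None:
        counts = {g: 0 for g in germline.v_gene_names}
    for clone in clones.clones:
        counts[clone.v_gene] = counts.get(clone.v_gene, 0) + 1
    df = pd.DataFrame(
        {"v_gene": list(counts), "unique_count": list(counts.values())}
    )
    total = df["unique_count"].sum()
    df["frequency"] = df["unique_count"] / total if total else 0.0
    return UsageTable(table=df)


def average_usage(tables: Sequence[UsageTable]) -> UsageTable:
    """Average V-gene frequencies across samples (e.g. the two naive
    bone-marrow IgM repertoires that define basal usage)."""
    if not tables:
        raise ValueError("no usage tables to average")
    genes = sorted({g for t in tables for g in t.table["v_gene"]})
    freq = {g: float(np.mean([t.frequency_of(g) for t in tables])) for g in genes}
    count = {g: int(sum(t.count_of(g) for t in tables)) for g in genes}
    df = pd.DataFrame(
        {
            "v_gene": genes,
            "unique_count": [count[g] for g in genes],
            "frequency": [freq[g] for g in genes],
        }
    )
    total = df["frequency"].sum()
    if total > 0:
        df["frequency"] = df["frequency"] / total
    return UsageTable(table=df)


def basal_sorted_usage(target: UsageTable, basal: UsageTable) -> UsageTable:
    """Reorder ``target`` rows by the basal (naive bone-marrow IgM) V-gene
    order, most to least abundant; genes absent from the target appear with
    zero counts, genes absent from basal are appended last."""
    basal_sorted = basal.table.sort_values(
        ["frequency", "v_gene"], ascending=[False, True]
    )["v_gene"].tolist()
    extra = [g for g in target.table["v_gene"] if g not in basal_sorted]
    order = basal_sorted + sorted(extra)
    rows = []
    for idx, gene in enumerate(order):
        rows.append(
            {
                "v_gene": gene,
                "unique_count": target.count_of(gene),
                "frequency": target.frequency_of(gene),
                "basal_order": idx,
            }
        )
    return UsageTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Isotype distribution
# ---------------------------------------------------------------------------


def isotype_distribution(
    sample: RepertoireSample, level: str = "subclass"
) -> dict[str, float]:
    """Isotype frequencies over unique V_H sequences.  At ``class`` level the
    IgG subclasses are merged into a single IGHG category."""
    if level not in ("class", "subclass"):
        raise ValueError(f"unknown level {level!r}")
    counts: dict[str, int] = {}
    for rec in sample.records:
        iso = rec.isotype
        if level == "class" and iso.startswith("IGHG"):
            iso = "IGHG"
        counts[iso] = counts.get(iso, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {iso: n / total for iso, n in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Somatic hypermutation
# ---------------------------------------------------------------------------


def shm_count(record: RearrangementRecord) -> int:
    """Mutation count of one unique V_H sequence against its germline.

    Counts substitution positions plus indel events (one contiguous gap run
    in either string = one event) over the germline-templated V region; the
    CDR3/junction is excluded because it is not germline-encoded, so
    differences there would not be somatic mutations.
    """
    seq, germ = record.sequence_nt, record.germline_nt
    if len(seq) != len(germ):
        raise ValidationError(
            f"{record.sequence_id}: sequence and germline alignment lengths differ"
        )
    excluded = record.region_bounds.get("CDR3")
    n = 0
    in_gap = False
    for i, (s, g) in enumerate(zip(seq, germ)):
        if excluded and excluded[0] <= i < excluded[1]:
            in_gap = False
            continue
        if s == GAP or g == GAP:
            if not in_gap:
                n += 1  # a gap run counts as a single indel event
                in_gap = True
            continue
        in_gap = False
        if s != g:
            n += 1
    return n


def shm_values(sample: RepertoireSample) -> np.ndarray:
    return np.array([shm_count(r) for r in sample.records])


def shm_summary(
    sample: RepertoireSample, stratify_by_isotype: bool = False
) -> pd.DataFrame:
    """Per-sequence SHM distribution summaries (mean/median/quartiles), one
    row overall or one per isotype stratum with at least one sequence."""
    rows = []
    values_by_stratum: dict[str, list[int]] = {}
    for rec in sample.records:
        stratum = rec.isotype if stratify_by_isotype else "all"
        values_by_stratum.setdefault(stratum, []).append(shm_count(rec))
    for stratum in sorted(values_by_stratum):
        v = np.array(values_by_stratum[stratum])
        rows.append(
            {
                "stratum": stratum,
                "n": len(v),
                "mean": float(v.mean()),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows, columns=["stratum", "n", "mean", "median", "q1", "q3"])


def shm_distribution(
    sample: RepertoireSample, stratify_by_isotype: bool = False
) -> pd.DataFrame:
    """Long-format raw SHM values for violin-style plotting/export."""
    rows = [
        {
            "sequence_id": rec.sequence_id,
            "isotype": rec.isotype if stratify_by_isotype else "all",
            "shm": shm_count(rec),
        }
        for rec in sample.records
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "isotype", "shm"])
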