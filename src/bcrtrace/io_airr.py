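"""Record-level data model and I/O for annotated V_H rearrangement tables.

The unit of analysis is the *unique V_H sequence*: one row per distinct
primer-trimmed heavy-chain variable-region nucleotide string, carrying its
germline V/J annotation, isotype call, CDRH3, region boundaries, a
germline-aligned reference string and a transcript (read) count.  Tables are
plain UTF-8 TSV with AIRR-community-style column names by default; a schema
map supports other export dialects (e.g. MiXCR headers).

Coordinates are 0-based half-open throughout, expressed in the aligned frame
shared by ``sequence_nt`` and ``germline_nt`` (gap character ``-``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GAP = "-"

#: The five murine heavy-chain isotypes reported by the assay.
ISOTYPES = ("IGHM", "IGHG1", "IGHG2A", "IGHG2B", "IGHG3")

#: Germline-templated V-region segments, in genomic order.
V_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

#: All annotated regions of the observed sequence (CDR3 is non-templated).
REGIONS = V_REGIONS + ("CDR3",)

TISSUES = ("tumor", "dln", "blood", "bone_marrow")
CONDITIONS = ("treated", "naive")


class SchemaError(ValueError):
    """A required column cannot be resolved in the input table."""


class ValidationError(ValueError):
    """A record or table violates the data-model invariants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RearrangementRecord:
    """One unique V_H sequence with annotations and a transcript count."""

    sequence_id: str
    v_call: str
    j_call: str
    isotype: str
    cdr3_nt: str
    cdr3_aa: str
    region_bounds: Mapping[str, tuple[int, int]]
    sequence_nt: str
    germline_nt: str
    read_count: int

    def validate(self) -> None:
        if self.read_count < 1:
            raise ValidationError(
                f"{self.sequence_id}: read_count must be >= 1, got {self.read_count}"
            )
        if self.isotype not in ISOTYPES:
            raise ValidationError(
                f"{self.sequence_id}: unknown isotype {self.isotype!r}"
            )
        if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValidationError(
                f"{self.sequence_id}: cdr3_nt length {len(self.cdr3_nt)} is not "
                f"3x cdr3_aa length {len(self.cdr3_aa)}"
            )
        if self.cdr3_aa and str(Seq(self.cdr3_nt).translate()) != self.cdr3_aa:
            raise ValidationError(
                f"{self.sequence_id}: cdr3_aa is not the translation of cdr3_nt"
            )
        if len(self.sequence_nt) != len(self.germline_nt):
            raise ValidationError(
                f"{self.sequence_id}: sequence_nt and germline_nt differ in "
                "aligned length"
            )
        last_end = 0
        for region in REGIONS:
            if region not in self.region_bounds:
                continue
            start, end = self.region_bounds[region]
            if not (last_end <= start <= end <= len(self.sequence_nt)):
                raise ValidationError(
                    f"{self.sequence_id}: region {region} bounds ({start},{end}) "
                    "overlap or exceed sequence length"
                )
            last_end = end
        for s, g in zip(self.sequence_nt, self.germline_nt):
            if s == GAP and g == GAP:
                raise ValidationError(
                    f"{self.sequence_id}: gap aligned to gap in sequence/germline"
                )

    @property
    def v_gene(self) -> str:
        """Gene-level V call (allele suffix stripped)."""
        return strip_allele(self.v_call)

    @property
    def j_gene(self) -> str:
        return strip_allele(self.j_call)


def strip_allele(call: str) -> str:
    """Reduce a germline call to the gene group, dropping ``*NN`` allele tags."""
    if not call:
        raise ValidationError("empty germline gene call")
    return call.split("*", 1)[0].strip()


@dataclass
class RepertoireSample:
    """All unique V_H sequences for one (mouse, tissue) compartment."""

    mouse_id: str
    tissue: str
    condition: str = "treated"
    duplicate_id: Optional[str] = None
    records: list[RearrangementRecord] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.sequence_nt in seen:
                raise ValidationError(
                    f"duplicate sequence identity within sample "
                    f"{self.mouse_id}/{self.tissue}: {rec.sequence_id}"
                )
            seen.add(rec.sequence_nt)
        if self.records and self.total_reads <= 0:
            raise ValidationError("non-empty sample with zero total reads")

    @property
    def total_reads(self) -> int:
        return sum(r.read_count for r in self.records)

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def sequence_set(self) -> set[str]:
        return {r.sequence_nt for r in self.records}


def pool_samples(
    samples: Sequence[RepertoireSample],
    mouse_id: str = "pooled",
) -> RepertoireSample:
    """Pool reads from several samples into one compartment.

    Identical sequences are merged by summing read counts (first-seen
    annotations kept), preserving the unique-sequence identity invariant.
    """
    if not samples:
        raise ValueError("no samples to pool")
    tissue = samples[0].tissue
    condition = samples[0].condition
    merged: dict[str, RearrangementRecord] = {}
    for sample in samples:
        for rec in sample.records:
            prev = merged.get(rec.sequence_nt)
            if prev is None:
                merged[rec.sequence_nt] = rec
            else:
                merged[rec.sequence_nt] = replace(
                    prev, read_count=prev.read_count + rec.read_count
                )
    return RepertoireSample(
        mouse_id=mouse_id,
        tissue=tissue,
        condition=condition,
        records=list(merged.values()),
    )


@dataclass(frozen=True)
class GermlineGene:
    name: str
    sequence: str
    #: region name -> (start, end), 0-based half-open within ``sequence``
    bounds: Mapping[str, tuple[int, int]]


@dataclass
class GermlineSet:
    """Reference germline V and J genes with annotated region boundaries."""

    genes: dict[str, GermlineGene]

    @property
    def v_gene_names(self) -> list[str]:
        return [n for n in self.genes if n.startswith("IGHV")]

    @property
    def j_gene_names(self) -> list[str]:
        return [n for n in self.genes if n.startswith("IGHJ")]

    def __getitem__(self, name: str) -> GermlineGene:
        return self.genes[name]

    def __contains__(self, name: str) -> bool:
        return name in self.genes


# ---------------------------------------------------------------------------
# Rearrangement table I/O
# ---------------------------------------------------------------------------

#: logical field -> default (AIRR-style) column name
DEFAULT_SCHEMA: dict[str, str] = {
    "sequence_id": "sequence_id",
    "v_call": "v_call",
    "j_call": "j_call",
    "isotype": "c_call",
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "sequence_nt": "sequence_alignment",
    "germline_nt": "germline_alignment",
    "read_count": "duplicate_count",
    "region_bounds": "region_bounds",
}

_REQUIRED = (
    "sequence_id",
    "v_call",
    "j_call",
    "isotype",
    "cdr3_nt",
    "sequence_nt",
    "germline_nt",
    "read_count",
)

_META_COLS = ("mouse_id", "tissue", "condition", "duplicate_id")


def _bounds_to_str(bounds: Mapping[str, tuple[int, int]]) -> str:
    return ";".join(f"{r}:{s}-{e}" for r, (s, e) in bounds.items())


def _bounds_from_str(text: str) -> dict[str, tuple[int, int]]:
    bounds: dict[str, tuple[int, int]] = {}
    if not text or text != text:  # empty or NaN
        return bounds
    for part in str(text).split(";"):
        region, span = part.split(":")
        start, end = span.split("-")
        bounds[region] = (int(start), int(end))
    return bounds


def read_rearrangements(
    path: str | Path,
    schema: Optional[Mapping[str, str]] = None,
    mouse_id: Optional[str] = None,
    tissue: Optional[str] = None,
    condition: Optional[str] = None,
    duplicate_id: Optional[str] = None,
) -> RepertoireSample:
    """Read an annotated rearrangement TSV into a :class:`RepertoireSample`.

    Rows whose required fields cannot be parsed are rejected (counted and
    logged), never silently dropped.  Sample-level metadata is taken from the
    table's ``mouse_id``/``tissue``/... columns when present, overridable by
    the keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in _REQUIRED:
        if colmap[logical] not in df.columns:
            raise SchemaError(
                f"required column {colmap[logical]!r} (field {logical}) "
                f"missing from {path}"
            )

    meta = {}
    for key in _META_COLS:
        meta[key] = df[key].iloc[0] if (key in df.columns and len(df)) else None
    if mouse_id is not None:
        meta["mouse_id"] = mouse_id
    if tissue is not None:
        meta["tissue"] = tissue
    if condition is not None:
        meta["condition"] = condition
    if duplicate_id is not None:
        meta["duplicate_id"] = duplicate_id

    records: list[RearrangementRecord] = []
    rejected = 0
    for idx, row in df.iterrows():
        try:
            cdr3_nt = row[colmap["cdr3_nt"]]
            if not cdr3_nt:
                raise ValidationError("missing cdr3")
            cdr3_aa = (
                row[colmap["cdr3_aa"]]
                if colmap["cdr3_aa"] in df.columns and row[colmap["cdr3_aa"]]
                else str(Seq(cdr3_nt).translate())
            )
            rec = RearrangementRecord(
                sequence_id=row[colmap["sequence_id"]],
                v_call=row[colmap["v_call"]],
                j_call=row[colmap["j_call"]],
                isotype=row[colmap["isotype"]],
                cdr3_nt=cdr3_nt,
                cdr3_aa=cdr3_aa,
                region_bounds=_bounds_from_str(row.get(colmap["region_bounds"], "")),
                sequence_nt=row[colmap["sequence_nt"]],
                germline_nt=row[colmap["germline_nt"]],
                read_count=int(row[colmap["read_count"]]),
            )
            rec.validate()
        except (ValidationError, ValueError, KeyError) as exc:
            rejected += 1
            logger.warning("%s row %d rejected: %s", path.name, idx, exc)
            continue
        records.append(rec)

    if rejected:
        logger.warning("%s: %d row(s) rejected during load", path.name, rejected)
    if not records:
        logger.warning("%s: loaded an empty sample", path.name)

    sample = RepertoireSample(
        mouse_id=meta["mouse_id"] or "unknown",
        tissue=meta["tissue"] or "unknown",
        condition=meta["condition"] or "treated",
        duplicate_id=meta["duplicate_id"] or None,
        records=records,
    )
    sample.validate()  # raises on duplicate sequence identity within the file
    sample.n_rejected = rejected  # type: ignore[attr-defined]
    return sample


def write_rearrangements(sample: RepertoireSample, path: str | Path) -> None:
    """Write a sample as a TSV that round-trips through the reader."""
    path = Path(path)
    rows = []
    for rec in sample.records:
        rows.append(
            {
                "sequence_id": rec.sequence_id,
                "v_call": rec.v_call,
                "j_call": rec.j_call,
                "c_call": rec.isotype,
                "junction": rec.cdr3_nt,
                "junction_aa": rec.cdr3_aa,
                "sequence_alignment": rec.sequence_nt,
                "germline_alignment": rec.germline_nt,
                "duplicate_count": rec.read_count,
                "region_bounds": _bounds_to_str(rec.region_bounds),
                "mouse_id": sample.mouse_id,
                "tissue": sample.tissue,
                "condition": sample.condition,
                "duplicate_id": sample.duplicate_id or "",
            }
        )
    columns = [
        "sequence_id", "v_call", "j_call", "c_call", "junction", "junction_aa",
        "sequence_alignment", "germline_alignment", "duplicate_count",
        "region_bounds", "mouse_id", "tissue", "condition", "duplicate_id",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Germline reference I/O (FASTA + TSV boundary sidecar)
# ---------------------------------------------------------------------------


def read_germline_set(fasta_path: str | Path, bounds_path: str | Path) -> GermlineSet:
    """Load germline genes from FASTA plus a (gene, region, start, end) sidecar."""
    fasta_path, bounds_path = Path(fasta_path), Path(bounds_path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate gene name in FASTA: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    bounds_df = pd.read_csv(bounds_path, sep="\t")
    bounds: dict[str, dict[str, tuple[int, int]]] = {n: {} for n in seqs}
    for _, row in bounds_df.iterrows():
        gene = row["gene"]
        if gene not in seqs:
            raise ValidationError(f"boundary row for unknown gene {gene!r}")
        start, end = int(row["start"]), int(row["end"])
        if not (0 <= start <= end <= len(seqs[gene])):
            raise ValidationError(
                f"{gene} {row['region']}: boundary ({start},{end}) outside sequence"
            )
        bounds[gene][row["region"]] = (start, end)
    genes = {
        name: GermlineGene(name=name, sequence=seq, bounds=bounds[name])
        for name, seq in seqs.items()
    }
    return GermlineSet(genes=genes)


def write_germline_set(
    germline: GermlineSet, fasta_path: str | Path, bounds_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.name, description="")
        for g in germline.genes.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {"gene": g.name, "region": region, "start": s, "end": e}
        for g in germline.genes.values()
        for region, (s, e) in g.bounds.items()
    ]
    pd.DataFrame(rows, columns=["gene", "region", "start", "end"]).to_csv(
        bounds_path, sep="\t", index=False
    )
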