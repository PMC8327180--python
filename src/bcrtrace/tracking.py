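"""Per-mouse cross-tissue clonal analyses.

A *common clone* is a clone (same V gene, J gene and CDR3 nucleotide
sequence) observed in the tumor and in at least one additional tissue of
the same animal.  This module identifies common clones, quantifies their
share of the tumor repertoire, tests per-V-gene enrichment of common clones
against basal (naive bone-marrow IgM) usage with Dunn-Šidák correction,
profiles per-codon SHM across the dominant common clones, reports the
IgG1/IgG2A subclass ratio, and tabulates pairwise tissue sharing.

All analyses are strictly per mouse: common clones are rarely shared across
individuals, so cross-mouse pooling is not meaningful here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_airr import GermlineSet, RepertoireSample, V_REGIONS
from .measures import CloneKey, CloneSet, strip_allele


@dataclass
class CommonCloneTable:
    """Tumor clones also present in >= 1 other tissue, with per-tissue
    frequencies and the clone's dominance rank within the tumor."""

    mouse_id: str
    table: pd.DataFrame  # v_gene, j_gene, cdr3_nt, tissues_present,
    #                      tumor_rank, freq_<tissue>, unique_<tissue>
    tissues: list[str]

    def keys(self) -> set[CloneKey]:
        return {
            (r.v_gene, r.j_gene, r.cdr3_nt)
            for r in self.table.itertuples(index=False)
        }

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class EnrichmentResult:
    v_gene: str
    basal_frequency: float
    common_frequency: float
    log2_fold_change: float
    p_raw: float
    p_adjusted: float
    direction: str  # over | under | ns


def find_common_clones(
    per_tissue_clones: Mapping[str, CloneSet],
    mouse: str,
) -> CommonCloneTable:
    """Identify the tumor clones whose key occurs in at least one non-tumor
    tissue of the same mouse."""
    if "tumor" not in per_tissue_clones:
        raise ValueError("common-clone analysis requires a tumor clone set")
    tissues = list(per_tissue_clones)
    freq_maps = {}
    unique_maps = {}
    for tissue, cs in per_tissue_clones.items():
        total = cs.total_reads or 1
        freq_maps[tissue] = {c.key: c.read_count / total for c in cs.clones}
        unique_maps[tissue] = {c.key: c.unique_count for c in cs.clones}

    tumor = per_tissue_clones["tumor"]
    ranked = sorted(tumor.clones, key=lambda c: (-c.read_count, c.cdr3_nt))
    rows = []
    for rank, clone in enumerate(ranked, start=1):
        present = [
            t for t in tissues if t != "tumor" and clone.key in freq_maps[t]
        ]
        if not present:
            continue
        row = {
            "v_gene": clone.v_gene,
            "j_gene": clone.j_gene,
            "cdr3_nt": clone.cdr3_nt,
            "tissues_present": ",".join(["tumor"] + present),
            "tumor_rank": rank,
        }
        for t in tissues:
            row[f"freq_{t}"] = freq_maps[t].get(clone.key, 0.0)
            row[f"unique_{t}"] = unique_maps[t].get(clone.key, 0)
        rows.append(row)
    columns = ["v_gene", "j_gene", "cdr3_nt", "tissues_present", "tumor_rank"]
    columns += [f"freq_{t}" for t in tissues] + [f"unique_{t}" for t in tissues]
    return CommonCloneTable(
        mouse_id=mouse, table=pd.DataFrame(rows, columns=columns), tissues=tissues
    )


def common_clone_read_fraction(
    table: CommonCloneTable, tumor_clones: CloneSet
) -> tuple[float, float]:
    """(fraction of tumor clones that are common, fraction of tumor reads
    they carry) — the '20 % of clones, 80 % of reads' summary."""
    if tumor_clones.S == 0:
        return 0.0, 0.0
    common_keys = table.keys()
    clone_fraction = len(common_keys) / tumor_clones.S
    common_reads = sum(
        c.read_count for c in tumor_clones.clones if c.key in common_keys
    )
    read_fraction = common_reads / tumor_clones.total_reads
    return clone_fraction, read_fraction


# ---------------------------------------------------------------------------
# V-gene enrichment with Dunn-Šidák correction
# ---------------------------------------------------------------------------


def sidak_adjust(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Dunn-Šidák family-wise adjustment: p_adj = 1 - (1 - p)^m."""
    if m is None:
        m = len(p_values)
    out = []
    for p in p_values:
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, max(0.0, 1.0 - (1.0 - p) ** m)))
    return out


def v_gene_enrichment(
    common: CommonCloneTable,
    basal: "UsageTableLike",
    alpha: float = 0.05,
    count_unit: str = "clone",
) -> list[EnrichmentResult]:
    """Per-V-gene over/under-representation of common clones vs basal usage.

    Each gene gets a two-sided Fisher exact test on the 2x2 table of
    (gene, not-gene) x (common, basal), a log2 fold-change of frequencies
    with a 0.5 pseudocount on both numerators, and a Šidák adjustment over
    the number of genes tested.

    ``count_unit`` sets the counting unit on the common-clone side: the
    default ``clone`` counts each common clone once, since clone members
    share their V gene and are not independent observations of usage —
    counting sequences pseudoreplicates large clones and inflates the
    family-wise error rate.  ``unique`` counts tumor unique sequences
    instead.  The basal table is used at whatever unit it was built with
    (build it from clone-collapsed data for a like-for-like comparison).
    """
    if count_unit not in ("clone", "unique"):
        raise ValueError(f"unknown count_unit {count_unit!r}")
    basal_df = basal.table
    if basal_df["unique_count"].sum() == 0:
        raise ValueError("basal usage table is empty")
    common_counts: dict[str, int] = {}
    for row in common.table.itertuples(index=False):
        unit = 1 if count_unit == "clone" else int(getattr(row, "unique_tumor", 0))
        common_counts[row.v_gene] = common_counts.get(row.v_gene, 0) + unit
    n_common = sum(common_counts.values())
    n_basal = int(basal_df["unique_count"].sum())
    genes = sorted(set(basal_df["v_gene"]) | set(common_counts))
    m = len(genes)
    results = []
    raw_ps = []
    for gene in genes:
        a = common_counts.get(gene, 0)
        b = int(basal_df.loc[basal_df["v_gene"] == gene, "unique_count"].sum())
        table = [[a, max(n_common - a, 0)], [b, max(n_basal - b, 0)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        raw_ps.append(float(p))
        f_common = (a + 0.5) / n_common if n_common else 0.0
        f_basal = (b + 0.5) / n_basal
        lfc = math.log2(f_common / f_basal) if n_common else float("-inf")
        results.append((gene, f_basal, f_common, lfc))
    adjusted = sidak_adjust(raw_ps, m)
    out = []
    for (gene, f_basal, f_common, lfc), p, p_adj in zip(results, raw_ps, adjusted):
        if p_adj < alpha and lfc > 0:
            direction = "over"
        elif p_adj < alpha and lfc < 0:
            direction = "under"
        else:
            direction = "ns"
        out.append(
            EnrichmentResult(
                v_gene=gene,
                basal_frequency=f_basal,
                common_frequency=f_common,
                log2_fold_change=lfc,
                p_raw=p,
                p_adjusted=p_adj,
                direction=direction,
            )
        )
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "v_gene": r.v_gene,
                "basal_frequency": r.basal_frequency,
                "common_frequency": r.common_frequency,
                "log2_fold_change": r.log2_fold_change,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "direction": r.direction,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Per-codon SHM profile of dominant common clones
# ---------------------------------------------------------------------------


def per_codon_shm_profile(
    clones: CommonCloneTable,
    samples: Mapping[str, RepertoireSample],
    germline: GermlineSet,
    top_n: int = 50,
) -> pd.DataFrame:
    """Per-codon mutation frequency across the ``top_n`` dominant common
    clones (ranked by tumor read count).

    For each clone, a codon's value is the fraction of member unique
    sequences (tumor compartment) mutated at any nucleotide of that codon.
    Columns are a (region, codon) MultiIndex over FR1..FR3 and CDR1..CDR2;
    CDR3 is excluded (non-templated).
    """
    tumor = samples.get("tumor")
    if tumor is None:
        raise ValueError("per-codon SHM profile needs the tumor sample")
    by_key: dict[CloneKey, list] = {}
    for rec in tumor.records:
        key = (strip_allele(rec.v_call), strip_allele(rec.j_call), rec.cdr3_nt)
        by_key.setdefault(key, []).append(rec)

    top = clones.table.sort_values(["tumor_rank"]).head(top_n)
    max_codons = {
        region: max(
            (germline[g].bounds[region][1] - germline[g].bounds[region][0]) // 3
            for g in germline.v_gene_names
        )
        for region in V_REGIONS
    }
    columns = pd.MultiIndex.from_tuples(
        [(r, i) for r in V_REGIONS for i in range(max_codons[r])],
        names=["region", "codon"],
    )
    rows = []
    index = []
    for row in top.itertuples(index=False):
        key = (row.v_gene, row.j_gene, row.cdr3_nt)
        if row.v_gene not in germline:
            raise ValueError(f"V gene {row.v_gene} absent from germline set")
        gene = germline[row.v_gene]
        members = by_key.get(key, [])
        values = np.full(len(columns), np.nan)
        col_pos = {c: i for i, c in enumerate(columns)}
        for region in V_REGIONS:
            start, end = gene.bounds[region]
            n_codons = (end - start) // 3
            for ci in range(n_codons):
                mutated = 0
                for rec in members:
                    s0 = start + 3 * ci
                    if rec.sequence_nt[s0:s0 + 3] != rec.germline_nt[s0:s0 + 3]:
                        mutated += 1
                values[col_pos[(region, ci)]] = (
                    mutated / len(members) if members else 0.0
                )
        rows.append(values)
        index.append("|".join(key))
    return pd.DataFrame(rows, index=index, columns=columns)


# ---------------------------------------------------------------------------
# IgG subclass ratio and tissue sharing
# ---------------------------------------------------------------------------


def igg_subclass_ratio(clone_subset: CloneSet) -> Optional[float]:
    """IgG1/IgG2A unique-sequence ratio; ``None`` when no IgG2A sequences
    exist (a distinguished undefined result, not an error)."""
    igg1 = sum(c.isotype_counts.get("IGHG1", 0) for c in clone_subset.clones)
    igg2a = sum(c.isotype_counts.get("IGHG2A", 0) for c in clone_subset.clones)
    if igg2a == 0:
        return None
    return igg1 / igg2a


def tissue_sharing_table(
    per_tissue_clones: Mapping[str, CloneSet],
    mouse: str,
) -> pd.DataFrame:
    """Pairwise clone sharing between tissues: shared-clone count and the
    summed read frequency those clones hold in the row tissue.  A tabular
    stand-in for a circos-style sharing plot."""
    tissues = list(per_tissue_clones)
    if len(tissues) < 2:
        raise ValueError("sharing table needs at least two tissues")
    keysets = {t: per_tissue_clones[t].keys() for t in tissues}
    freqs = {}
    for t, cs in per_tissue_clones.items():
        total = cs.total_reads or 1
        freqs[t] = {c.key: c.read_count / total for c in cs.clones}
    rows = []
    for t1 in tissues:
        for t2 in tissues:
            if t1 == t2:
                continue
            shared = keysets[t1] & keysets[t2]
            rows.append(
                {
                    "mouse_id": mouse,
                    "tissue_from": t1,
                    "tissue_to": t2,
                    "n_shared_clones": len(shared),
                    "shared_read_fraction": sum(
                        freqs[t1].get(k, 0.0) for k in shared
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "tissue_from",
            "tissue_to",
            "n_shared_clones",
            "shared_read_fraction",
        ],
    )
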