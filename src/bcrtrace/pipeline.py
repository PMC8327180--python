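"""End-to-end orchestration: simulate -> filter -> measure -> track -> report.

One YAML config drives both the synthetic study and its analysis, so a
single command exercises the whole simulate-then-recover loop.  Every
figure-equivalent output is written as tidy TSV/JSON, and a manifest with
content digests makes reruns verifiable: identical config + seed reproduces
identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .io_airr import (
    GermlineSet,
    RepertoireSample,
    pool_samples,
    read_rearrangements,
    write_germline_set,
    write_rearrangements,
)
from .measures import (
    average_usage,
    cdrh3_length_distribution,
    clone_usage,
    cluster_clones,
    hill_diversity,
    isotype_distribution,
    polarization_count,
    shm_summary,
    v_gene_usage,
    basal_sorted_usage,
    UsageTable,
)
from .preprocess import filter_pipeline, rarefaction_curve, saturation_depth
from .simulate import (
    SimulationConfig,
    config_from_dict,
    emit_technical_duplicates,
    generate_germline_set,
    simulate_study,
)
from .tracking import (
    common_clone_read_fraction,
    enrichment_frame,
    find_common_clones,
    igg_subclass_ratio,
    per_codon_shm_profile,
    tissue_sharing_table,
    v_gene_enrichment,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# Demo study configuration
# ---------------------------------------------------------------------------

_IGG_SHM = {"IGHG1": 9.0, "IGHG2A": 9.0, "IGHG2B": 9.0, "IGHG3": 9.0}


def demo_config(seed: int = 0, scale: float = 1.0) -> dict:
    """Default demo study: four treated mice with four tissues and two naive
    mice with three, emulating the design and directions of the source
    study at desk scale.

    Tumor: strongly polarized (Zipf exponent 2.0), IgM-dominant with a
    bimodal IgM SHM mixture (affinity-matured but non-class-switched cells)
    and IgG SHM around 12 mutations.  Bone marrow: polyclonal, 75 % IgM with
    low IgM SHM.  Blood: 96 % IgM.  DLN: IgG-skewed, intermediate
    polarization.  ``scale`` multiplies clone and read counts.
    """

    def n(x: float) -> int:
        return max(1, int(round(x * scale)))

    treated_tissues = [
        {
            "name": "tumor",
            "n_clones": n(400),
            "clone_size_zipf_exponent": 2.0,
            "n_reads": n(30000),
            # read-level draw; unique-sequence IgM share lands lower because
            # low-SHM IgM members collapse into fewer unique sequences
            "isotype_probs": {
                "IGHM": 0.75, "IGHG1": 0.06, "IGHG2A": 0.08,
                "IGHG2B": 0.06, "IGHG3": 0.05,
            },
            "shm_model": {
                "IGHM": {"weight": 0.5, "mean_low": 2.0, "mean_high": 12.0},
                "IGHG1": 12.0, "IGHG2A": 12.0, "IGHG2B": 12.0, "IGHG3": 12.0,
            },
        },
        {
            "name": "dln",
            "n_clones": n(1500),
            "clone_size_zipf_exponent": 1.3,
            "n_reads": n(30000),
            "isotype_probs": {
                "IGHM": 0.40, "IGHG1": 0.18, "IGHG2A": 0.20,
                "IGHG2B": 0.12, "IGHG3": 0.10,
            },
            "shm_model": {"IGHM": 3.0, **_IGG_SHM},
        },
        {
            "name": "blood",
            "n_clones": n(1800),
            "clone_size_zipf_exponent": 1.1,
            "n_reads": n(30000),
            "isotype_probs": {
                "IGHM": 0.96, "IGHG1": 0.01, "IGHG2A": 0.01,
                "IGHG2B": 0.01, "IGHG3": 0.01,
            },
            "shm_model": {"IGHM": 1.5, **{k: 6.0 for k in _IGG_SHM}},
        },
        {
            "name": "bone_marrow",
            "n_clones": n(3000),
            "clone_size_zipf_exponent": 1.0,
            "n_reads": n(30000),
            "isotype_probs": {
                "IGHM": 0.75, "IGHG1": 0.10, "IGHG2A": 0.06,
                "IGHG2B": 0.05, "IGHG3": 0.04,
            },
            "shm_model": {"IGHM": 1.0, **{k: 8.0 for k in _IGG_SHM}},
        },
    ]
    naive_tissues = []
    for td in treated_tissues[1:]:
        td = {**td, "isotype_probs": dict(td["isotype_probs"])}
        td["clone_size_zipf_exponent"] = 1.0
        td["shm_model"] = {"IGHM": 1.0, **{k: 5.0 for k in _IGG_SHM}}
        naive_tissues.append(td)

    return {
        "germline": {"n_v": 19, "n_j": 4, "seed": 7},
        "treated": {
            "n_mice": 4,
            "condition": "treated",
            "tissues": treated_tissues,
            "sharing_matrix": {
                "tumor": {"dln": 0.10, "blood": 0.06, "bone_marrow": 0.06},
                "dln": {"tumor": 0.004, "blood": 0.02, "bone_marrow": 0.02},
                "blood": {"tumor": 0.002, "dln": 0.02, "bone_marrow": 0.02},
                "bone_marrow": {"tumor": 0.001, "dln": 0.01, "blood": 0.01},
            },
            "sharing_dominance": 0.015,
            "seq_error_rate": 0.001,
            "seed": seed,
        },
        "naive": {
            "n_mice": 2,
            "condition": "naive",
            "tissues": naive_tissues,
            "sharing_matrix": {},
            "seq_error_rate": 0.001,
            "seed": seed + 1,
        },
        "min_reads": 2,
        "rarefaction": {"grid_step": 0.02, "n_iterations": 5},
        "top_n_common": 50,
        "alpha": 0.05,
    }


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


@dataclass
class StudyManifest:
    config_hash: str
    seed: int
    version: str
    file_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "file_digests": self.file_digests,
                    "stage_counts": self.stage_counts,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_config(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _load_config(config: Mapping | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise PipelineError(f"config: file not found: {path}")
        config = yaml.safe_load(path.read_text())
    if not isinstance(config, Mapping):
        raise PipelineError("config: expected a mapping")
    cfg = dict(config)
    if "treated" not in cfg and "inputs" not in cfg:
        raise PipelineError("config: needs a 'treated' simulation arm or 'inputs'")
    if "inputs" in cfg:
        for entry in cfg["inputs"]:
            if not Path(entry["path"]).exists():
                raise PipelineError(f"config: input file missing: {entry['path']}")
    return cfg


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> StudyManifest:
    """Execute the full study pipeline and write all outputs to ``out_dir``.

    Stages: simulate (or load) -> duplicate QC filter -> rarefaction ->
    pooled per-tissue measures -> per-mouse clone tracking -> manifest.
    """
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("treated", {}).get("seed", 0))
    manifest = StudyManifest(
        config_hash=_hash_config(cfg), seed=seed, version=__version__
    )

    stage = "simulate"
    try:
        filtered, germline, basal = _stage_inputs(cfg, out, manifest)
        stage = "measure"
        _stage_measures(cfg, out, filtered, germline, basal, manifest)
        stage = "track"
        _stage_tracking(cfg, out, filtered, germline, basal, manifest)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        manifest.write(out / "manifest.partial.json")
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.file_digests[str(path.relative_to(out))] = _sha256(path)
    manifest.write(out / "manifest.json")
    return manifest


def _stage_inputs(cfg, out: Path, manifest: StudyManifest):
    """Simulate (or load) samples and run the duplicate QC filter.

    Returns (filtered samples by condition/mouse/tissue, germline, basal
    usage table from naive bone-marrow IgM sequences).
    """
    raw_dir = out / "samples"
    raw_dir.mkdir(exist_ok=True)
    filtered: dict[str, dict[str, dict[str, RepertoireSample]]] = {
        "treated": {}, "naive": {},
    }
    reports = {}
    rarefy_cfg = cfg.get("rarefaction", {})
    grid_step = float(rarefy_cfg.get("grid_step", 0.02))
    n_iter = int(rarefy_cfg.get("n_iterations", 5))
    import numpy as np

    grid = np.round(np.arange(grid_step, 1.0 + 1e-9, grid_step), 10)
    rarefaction_rows = []
    saturation_rows = []
    correlation_rows = []

    if "treated" in cfg:
        g = cfg.get("germline", {"n_v": 19, "n_j": 4, "seed": 7})
        germline = generate_germline_set(
            int(g.get("n_v", 19)), int(g.get("n_j", 4)), int(g.get("seed", 7))
        )
        write_germline_set(
            germline, out / "germline.fasta", out / "germline_bounds.tsv"
        )
        for arm in ("treated", "naive"):
            if arm not in cfg:
                continue
            sim_cfg = config_from_dict({**cfg[arm], "condition": arm})
            samples, truth = simulate_study(sim_cfg, germline)
            truth_summary = {
                "clones_to_80": {
                    f"{m}/{t}": v for (m, t), v in truth.clones_to_80.items()
                },
                "n_common_clones": {
                    m: len(s) for m, s in truth.common_clones.items()
                },
            }
            (out / f"truth_{arm}.json").write_text(
                json.dumps(truth_summary, indent=2, sort_keys=True)
            )
            err_rate = sim_cfg.seq_error_rate
            for mouse, per_tissue in samples.items():
                filtered[arm][mouse] = {}
                for tissue, sample in per_tissue.items():
                    digest = hashlib.sha256(
                        f"{sim_cfg.seed}:{mouse}:{tissue}".encode()
                    ).digest()
                    dup_seed = int.from_bytes(digest[:4], "big") % (2**31 - 2)
                    a, b, _registry = emit_technical_duplicates(
                        sample, err_rate, seed=dup_seed
                    )
                    write_rearrangements(
                        a, raw_dir / f"{mouse}_{tissue}_A.tsv"
                    )
                    write_rearrangements(
                        b, raw_dir / f"{mouse}_{tissue}_B.tsv"
                    )
                    from .preprocess import duplicate_correlation

                    rho, pval = duplicate_correlation(a, b)
                    correlation_rows.append(
                        {
                            "mouse_id": mouse, "tissue": tissue,
                            "spearman_rho": rho, "p_value": pval,
                        }
                    )
                    fsample, report = filter_pipeline(
                        a, b, min_reads=int(cfg.get("min_reads", 2))
                    )
                    filtered[arm][mouse][tissue] = fsample
                    reports[f"{mouse}/{tissue}"] = report.to_dict()
                    curve = rarefaction_curve(
                        fsample, grid=grid, n_iterations=n_iter,
                        seed=dup_seed + 1,
                    )
                    for d, r in zip(
                        curve.depth_fraction, curve.mean_richness_fraction
                    ):
                        rarefaction_rows.append(
                            {
                                "mouse_id": mouse, "tissue": tissue,
                                "depth_fraction": d, "richness_fraction": r,
                            }
                        )
                    sat = saturation_depth(curve, target=0.99)
                    saturation_rows.append(
                        {
                            "mouse_id": mouse, "tissue": tissue,
                            "saturation_depth_99": sat if sat is not None else "NA",
                        }
                    )
                    logger.info(
                        "%s/%s: %d unique after filtering", mouse, tissue,
                        fsample.n_unique,
                    )
    else:
        germline = None
        for entry in cfg["inputs"]:
            sample = read_rearrangements(entry["path"])
            arm = sample.condition if sample.condition in filtered else "treated"
            filtered[arm].setdefault(sample.mouse_id, {})[sample.tissue] = sample

    pd.DataFrame(rarefaction_rows).to_csv(
        out / "rarefaction_curves.tsv", sep="\t", index=False
    )
    pd.DataFrame(saturation_rows).to_csv(
        out / "saturation_depths.tsv", sep="\t", index=False
    )
    pd.DataFrame(correlation_rows).to_csv(
        out / "duplicate_correlation.tsv", sep="\t", index=False
    )
    (out / "filter_reports.json").write_text(
        json.dumps(reports, indent=2, sort_keys=True)
    )
    manifest.stage_counts["filter"] = {
        k: v["after_min_reads"] for k, v in reports.items()
    }

    basal = _basal_usage(filtered, germline)  # (unique-level, clone-level)
    return filtered, germline, basal


def _basal_usage(filtered, germline):
    """Basal V-gene usage from naive bone-marrow IgM sequences.

    Returns (unique-sequence-level usage averaged across naive mice — the
    sort reference for usage plots; clone-level usage — the independent-unit
    reference for enrichment testing).
    """
    tables = []
    clone_tables = []
    for mouse, per_tissue in filtered.get("naive", {}).items():
        bm = per_tissue.get("bone_marrow")
        if bm is None:
            continue
        igm = RepertoireSample(
            mouse_id=bm.mouse_id, tissue=bm.tissue, condition=bm.condition,
            records=[r for r in bm.records if r.isotype == "IGHM"],
        )
        if igm.records:
            tables.append(v_gene_usage(igm, germline=germline))
            clone_tables.append(clone_usage(cluster_clones(igm), germline=germline))
    if not tables:
        return None, None
    return average_usage(tables), average_usage(clone_tables)


def _stage_measures(cfg, out: Path, filtered, germline, basal_pair, manifest) -> None:
    """Pooled per-tissue repertoire measures for both study arms."""
    basal, _ = basal_pair
    measure_rows = []
    isotype_rows = []
    shm_rows = []
    cdrh3_rows = []
    usage_frames = []
    for arm in ("treated", "naive"):
        per_tissue_pools: dict[str, RepertoireSample] = {}
        tissues = sorted({t for m in filtered[arm].values() for t in m})
        for tissue in tissues:
            samples = [
                m[tissue] for m in filtered[arm].values() if tissue in m
            ]
            if not samples:
                continue
            per_tissue_pools[tissue] = pool_samples(samples, mouse_id=f"{arm}_pool")
        for tissue, pooled in per_tissue_pools.items():
            if not pooled.records:
                continue
            clones = cluster_clones(pooled)
            hist, median = cdrh3_length_distribution(pooled, unit="aa")
            measure_rows.append(
                {
                    "condition": arm,
                    "tissue": tissue,
                    "n_unique": pooled.n_unique,
                    "n_reads": pooled.total_reads,
                    "n_clones": clones.S,
                    "clones_to_80pct": polarization_count(clones, 0.8),
                    "hill_q0": hill_diversity(clones, 0),
                    "hill_q1": hill_diversity(clones, 1),
                    "hill_q2": hill_diversity(clones, 2),
                    "cdrh3_median_aa": median,
                }
            )
            for length, count in hist.items():
                cdrh3_rows.append(
                    {
                        "condition": arm, "tissue": tissue,
                        "cdrh3_length_aa": length, "n_unique": count,
                    }
                )
            for level in ("class", "subclass"):
                for iso, freq in isotype_distribution(pooled, level).items():
                    isotype_rows.append(
                        {
                            "condition": arm, "tissue": tissue,
                            "level": level, "isotype": iso, "frequency": freq,
                        }
                    )
            summary = shm_summary(pooled, stratify_by_isotype=True)
            overall = shm_summary(pooled, stratify_by_isotype=False)
            for _, row in pd.concat([overall, summary]).iterrows():
                shm_rows.append(
                    {"condition": arm, "tissue": tissue, **row.to_dict()}
                )
            usage = v_gene_usage(pooled, germline=germline)
            if basal is not None:
                usage = basal_sorted_usage(usage, basal)
            frame = usage.table.copy()
            frame.insert(0, "tissue", tissue)
            frame.insert(0, "condition", arm)
            usage_frames.append(frame)
    pd.DataFrame(measure_rows).to_csv(out / "measures.tsv", sep="\t", index=False)
    pd.DataFrame(isotype_rows).to_csv(
        out / "isotype_distribution.tsv", sep="\t", index=False
    )
    pd.DataFrame(shm_rows).to_csv(out / "shm_summary.tsv", sep="\t", index=False)
    pd.DataFrame(cdrh3_rows).to_csv(
        out / "cdrh3_lengths.tsv", sep="\t", index=False
    )
    if usage_frames:
        pd.concat(usage_frames).to_csv(
            out / "v_gene_usage.tsv", sep="\t", index=False
        )
    if basal is not None:
        basal.table.to_csv(out / "basal_usage.tsv", sep="\t", index=False)
    manifest.stage_counts["measures"] = {
        f"{r['condition']}/{r['tissue']}": r["n_clones"] for r in measure_rows
    }


def _stage_tracking(cfg, out: Path, filtered, germline, basal_pair, manifest) -> None:
    """Per-mouse common-clone analyses (treated arm only)."""
    _, basal = basal_pair
    track_dir = out / "tracking"
    track_dir.mkdir(exist_ok=True)
    summary_rows = []
    sharing_frames = []
    for mouse, per_tissue in filtered["treated"].items():
        if "tumor" not in per_tissue:
            continue
        clone_sets = {t: cluster_clones(s) for t, s in per_tissue.items()}
        common = find_common_clones(clone_sets, mouse)
        common.table.to_csv(
            track_dir / f"common_clones_{mouse}.tsv", sep="\t", index=False
        )
        clone_frac, read_frac = common_clone_read_fraction(
            common, clone_sets["tumor"]
        )
        ratio = igg_subclass_ratio(clone_sets["tumor"])
        summary_rows.append(
            {
                "mouse_id": mouse,
                "n_tumor_clones": clone_sets["tumor"].S,
                "n_common_clones": len(common),
                "common_clone_fraction": clone_frac,
                "common_read_fraction": read_frac,
                "tumor_igg1_igg2a_ratio": ratio if ratio is not None else "NA",
            }
        )
        if basal is not None and len(common):
            results = v_gene_enrichment(
                common, basal, alpha=float(cfg.get("alpha", 0.05))
            )
            enrichment_frame(results).to_csv(
                track_dir / f"v_gene_enrichment_{mouse}.tsv", sep="\t", index=False
            )
        if germline is not None and len(common):
            profile = per_codon_shm_profile(
                common, per_tissue, germline,
                top_n=int(cfg.get("top_n_common", 50)),
            )
            flat = profile.copy()
            flat.columns = [f"{r}:{c}" for r, c in profile.columns]
            flat.to_csv(track_dir / f"shm_profile_{mouse}.tsv", sep="\t")
        sharing_frames.append(tissue_sharing_table(clone_sets, mouse))
    if summary_rows:
        pd.DataFrame(summary_rows).to_csv(
            track_dir / "common_clone_summary.tsv", sep="\t", index=False
        )
    if sharing_frames:
        pd.concat(sharing_frames).to_csv(
            track_dir / "tissue_sharing.tsv", sep="\t", index=False
        )
    manifest.stage_counts["tracking"] = {
        r["mouse_id"]: r["n_common_clones"] for r in summary_rows
    }


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_REPORT_SECTIONS = [
    ("Duplicate QC and rarefaction", ["duplicate_correlation.tsv",
                                      "saturation_depths.tsv"]),
    ("Clonal polarization and diversity", ["measures.tsv"]),
    ("Isotype distribution", ["isotype_distribution.tsv"]),
    ("Somatic hypermutation", ["shm_summary.tsv"]),
    ("Clone tracking", ["tracking/common_clone_summary.tsv",
                        "tracking/tissue_sharing.tsv"]),
]


def render_report(out_dir: str | Path) -> Path:
    """Render a single human-readable markdown summary of pipeline outputs.

    Missing tables are listed as absent; the report always renders.
    Regeneration is idempotent.
    """
    out = Path(out_dir)
    lines = ["# Repertoire analysis report", ""]
    for title, files in _REPORT_SECTIONS:
        lines.append(f"## {title}")
        lines.append("")
        for rel in files:
            path = out / rel
            if not path.exists():
                lines.append(f"*{rel}: absent*")
                lines.append("")
                continue
            df = pd.read_csv(path, sep="\t")
            preview = df.head(25)
            lines.append("```")
            lines.append(preview.to_string(index=False))
            lines.append("```")
            if len(df) > 25:
                lines.append(f"\n({len(df) - 25} more rows in {rel})")
            lines.append("")
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path
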