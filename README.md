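# bcrtrace

Downstream analysis of annotated antibody heavy-chain (V_H) repertoires from
BCR-Seq experiments, built for multi-tissue studies of tumor-infiltrating
B cells (TIL-Bs) in mouse models: the package quantifies how strongly a
B-cell compartment is clonally polarized, how diverse and mutated it is,
which isotypes it uses, and which clones are shared between the tumor and
other tissues of the same animal.

It operates on annotated rearrangement tables (plain TSV, one row per unique
V_H nucleotide sequence with V/J/isotype calls, region boundaries, a
germline-aligned reference and a read count — the level of output a
VDJ-annotation tool such as MiXCR produces), and ships a synthetic
multi-mouse, multi-tissue repertoire simulator with recorded ground truth so
every analysis stage can be validated by parameter recovery without any
external sequencing data.

## What it computes

**Quality control.** BCR-Seq error handling by technical duplicates: only
V_H sequences observed in both replicate libraries are retained, followed by
annotation-completeness and minimum-abundance (≥ 2 reads) filters; duplicate
agreement is summarized by Spearman rank
correlation of per-sequence counts, and sequencing depth by rarefaction —
repeated read subsampling without replacement, reporting the depth at which
unique-sequence diversity reaches 99 %.

**Clonal architecture.** Clones are sets of sequences sharing the same V and
J gene groups and an identical CDR3 nucleotide sequence. Polarization is the
number of clones accounting for 80 % of reads. Diversity is the Hill-number
family over clone read frequencies p_i:

    D_q = (Σ_i p_i^q)^(1/(1−q)),   q = 0, 1, 2

with q = 1 taken as the analytic limit exp(−Σ p_i ln p_i) (exponential
Shannon entropy) and q = 2 — the inverse Simpson index — as the default, so
abundant clones dominate the measure.

**Repertoire measures.** CDRH3 length distributions (Mann-Whitney
comparison between compartments), V-gene usage sorted against basal naive
bone-marrow IgM usage, isotype distributions over the five murine classes
(IgM, IgG1, IgG2A, IgG2B, IgG3), and somatic hypermutation (SHM) counted per
unique sequence against the germline alignment (substitutions plus indel
events, junction excluded).

**Clone tracking.** Per mouse: common clones (present in the tumor and ≥ 1
other tissue), their share of tumor clones and tumor reads, per-V-gene
enrichment of common clones versus basal usage (Fisher exact per gene with
Dunn-Šidák correction, `p_adj = 1 − (1−p)^m`), per-codon SHM profiles of the
50 dominant common clones, the IgG1/IgG2A subclass ratio, and a pairwise
tissue-sharing matrix.

## Worked example

```python
from bcrtrace import (
    generate_germline_set, simulate_study, emit_technical_duplicates,
    filter_pipeline, cluster_clones, polarization_count, hill_diversity,
)
from bcrtrace.simulate import ShmModel, SimulationConfig, TissueConfig

germline = generate_germline_set(n_v=19, n_j=4, seed=7)
tumor = TissueConfig(
    name="tumor", n_clones=200, clone_size_zipf_exponent=2.0, n_reads=10_000,
    isotype_probs={"IGHM": 0.75, "IGHG1": 0.06, "IGHG2A": 0.08,
                   "IGHG2B": 0.06, "IGHG3": 0.05},
    shm_model={"IGHM": ShmModel(weight=0.5, mean_low=2, mean_high=12),
               "IGHG1": ShmModel(mean=12), "IGHG2A": ShmModel(mean=12),
               "IGHG2B": ShmModel(mean=12), "IGHG3": ShmModel(mean=12)},
)
samples, truth = simulate_study(
    SimulationConfig(n_mice=1, tissues=[tumor], seed=1), germline
)
a, b, registry = emit_technical_duplicates(samples["M1"]["tumor"], 0.002, seed=2)
filtered, report = filter_pipeline(a, b, min_reads=2)
clones = cluster_clones(filtered)
print(clones.S, polarization_count(clones, 0.8), hill_diversity(clones, q=2))
```

prints `70 3 2.2771576957666695`: the filtered tumor sample retains 70
clones, of which just 3 account for 80 % of all reads, and the
inverse-Simpson Hill diversity is ≈ 2.3 — a strongly polarized, oligoclonal
compartment (the QC filter drops the long tail of singleton sequences, so
fewer clones survive than were simulated).
The scripts in `examples/` walk through each capability (QC, measures,
tracking, full pipeline) with commentary on the printed numbers.

The same analyses are available from the shell:

```bash
bcrtrace simulate --config examples/demo_config.yaml --out sim/
bcrtrace filter --dup-a sim/M1_tumor_A.tsv --dup-b sim/M1_tumor_B.tsv \
         --min-reads 2 --out filtered.tsv --report report.json
bcrtrace measure --in filtered.tsv --out measures.json
bcrtrace run --demo --seed 0 --out demo_out/   # full 6-mouse demo study
bcrtrace report --out demo_out/
```

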