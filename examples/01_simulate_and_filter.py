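"""Simulate one tumor repertoire, add sequencing errors via technical
duplicates, and clean it with the duplicate-intersection QC filter.

Prints the per-stage record accounting and the duplicate Spearman
correlation: a high rho means duplicate counts are reproducible, and the
drop from raw to intersected unique sequences is the error load removed.
"""

import json

from bcrtrace import (
    emit_technical_duplicates,
    filter_pipeline,
    duplicate_correlation,
    generate_germline_set,
    simulate_study,
)
from bcrtrace.simulate import ShmModel, SimulationConfig, TissueConfig

germline = generate_germline_set(n_v=19, n_j=4, seed=7)

tumor = TissueConfig(
    name="tumor",
    n_clones=200,
    clone_size_zipf_exponent=2.0,   # few clones dominate
    n_reads=10_000,
    isotype_probs={"IGHM": 0.75, "IGHG1": 0.06, "IGHG2A": 0.08,
                   "IGHG2B": 0.06, "IGHG3": 0.05},
    shm_model={
        "IGHM": ShmModel(weight=0.5, mean_low=2.0, mean_high=12.0),
        "IGHG1": ShmModel(mean=12.0), "IGHG2A": ShmModel(mean=12.0),
        "IGHG2B": ShmModel(mean=12.0), "IGHG3": ShmModel(mean=12.0),
    },
)
config = SimulationConfig(n_mice=1, tissues=[tumor], seed=1)
samples, truth = simulate_study(config, germline)
sample = samples["M1"]["tumor"]
print(f"simulated: {sample.n_unique} unique V_H sequences, "
      f"{sample.total_reads} reads")

dup_a, dup_b, registry = emit_technical_duplicates(sample, 0.002, seed=2)
print(f"duplicate A: {dup_a.n_unique} unique "
      f"({len(registry['A'])} error artifacts injected)")

rho, p = duplicate_correlation(dup_a, dup_b)
print(f"duplicate Spearman rho = {rho:.3f} (p = {p:.2e})")

filtered, report = filter_pipeline(dup_a, dup_b, min_reads=2)
print("filter accounting:", json.dumps(report.to_dict(), indent=2))
surviving_artifacts = filtered.sequence_set() - sample.sequence_set()
print(f"error artifacts surviving the filter: {len(surviving_artifacts)} "
      f"(all registry-labelled cross-duplicate collisions: "
      f"{surviving_artifacts <= registry['collisions']})")
print("note: deeply covered dominant clones regenerate the same single-base"
      " error in both duplicates, so some collisions are expected; the"
      " registry labels every one of them")
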