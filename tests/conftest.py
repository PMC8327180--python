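"""Shared fixtures: hand-buildable records and small simulated studies."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from bcrtrace.io_airr import (
    GAP,
    GermlineSet,
    RearrangementRecord,
    RepertoireSample,
)
from bcrtrace.simulate import (
    ShmModel,
    SimulationConfig,
    TissueConfig,
    generate_germline_set,
    simulate_study,
)


@pytest.fixture(scope="session")
def germline() -> GermlineSet:
    return generate_germline_set(19, 4, seed=1)


@pytest.fixture(scope="session")
def tiny_germline() -> GermlineSet:
    return generate_germline_set(3, 2, seed=2)


def build_record(
    germline: GermlineSet,
    v_call: str = "IGHV1-1",
    j_call: str = "IGHJ1",
    cdr3_nt: str = "TGTGCCAGATAC",
    isotype: str = "IGHM",
    read_count: int = 1,
    substitutions: tuple[tuple[int, str], ...] = (),
    sequence_id: str = "s1",
) -> RearrangementRecord:
    """Assemble a consistent record from germline parts, optionally applying
    V-region substitutions given as (position, new_base)."""
    v = germline[v_call.split("*")[0]]
    j = germline[j_call.split("*")[0]]
    seq = list(v.sequence)
    for pos, base in substitutions:
        seq[pos] = base
    sequence_nt = "".join(seq) + cdr3_nt + j.sequence
    germline_nt = v.sequence + GAP * len(cdr3_nt) + j.sequence
    bounds = dict(v.bounds)
    bounds["CDR3"] = (len(v.sequence), len(v.sequence) + len(cdr3_nt))
    return RearrangementRecord(
        sequence_id=sequence_id,
        v_call=v_call,
        j_call=j_call,
        isotype=isotype,
        cdr3_nt=cdr3_nt,
        cdr3_aa=str(Seq(cdr3_nt).translate()),
        region_bounds=bounds,
        sequence_nt=sequence_nt,
        germline_nt=germline_nt,
        read_count=read_count,
    )


def make_sample(records, mouse="M1", tissue="tumor", condition="treated",
                duplicate_id=None) -> RepertoireSample:
    return RepertoireSample(
        mouse_id=mouse, tissue=tissue, condition=condition,
        duplicate_id=duplicate_id, records=list(records),
    )


def small_tissue(
    name: str = "tumor",
    n_clones: int = 80,
    zipf: float = 2.0,
    n_reads: int = 4000,
    igm_shm: ShmModel | None = None,
) -> TissueConfig:
    return TissueConfig(
        name=name,
        n_clones=n_clones,
        clone_size_zipf_exponent=zipf,
        n_reads=n_reads,
        isotype_probs={
            "IGHM": 0.6, "IGHG1": 0.15, "IGHG2A": 0.1,
            "IGHG2B": 0.1, "IGHG3": 0.05,
        },
        shm_model={
            "IGHM": igm_shm or ShmModel(mean=2.0),
            "IGHG1": ShmModel(mean=8.0),
            "IGHG2A": ShmModel(mean=8.0),
            "IGHG2B": ShmModel(mean=8.0),
            "IGHG3": ShmModel(mean=8.0),
        },
    )


def small_config(seed: int = 0, **kwargs) -> SimulationConfig:
    defaults = dict(
        n_mice=1,
        tissues=[
            small_tissue("tumor"),
            small_tissue("blood", n_clones=200, zipf=1.1),
        ],
        sharing_matrix={"tumor": {"blood": 0.2}},
        seed=seed,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study(germline):
    cfg = small_config(seed=11)
    samples, truth = simulate_study(cfg, germline)
    return cfg, samples, truth
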