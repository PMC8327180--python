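"""Synthetic multi-mouse, multi-tissue antibody repertoire generator.

Emulates the statistical structure of a treated-vs-naive murine BCR-Seq
study: Zipf-distributed clone sizes (strong polarization in the tumor
compartment), per-isotype somatic-hypermutation (SHM) loads including a
bimodal tumor-IgM mode, murine IgM/IgG subclass mixes, clones shared across
tissues of the same animal, and sequencing-error-bearing technical
duplicates.  Every draw is recorded in a :class:`SimulationTruth` object so
each downstream analysis stage can be tested by parameter recovery.

Randomness: one master seed deterministically spawns per-mouse / per-tissue /
per-duplicate substreams (``numpy.random.SeedSequence``), so adding a tissue
or mouse does not perturb the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_airr import (
    GAP,
    ISOTYPES,
    V_REGIONS,
    GermlineGene,
    GermlineSet,
    RearrangementRecord,
    RepertoireSample,
)

NT = np.array(list("ACGT"))
_STOP = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = np.array([c for c in _CODONS if c not in _STOP])


class ConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShmModel:
    """Per-isotype mutation-count distribution.

    Either a plain Poisson (``mean``) or a two-component Poisson mixture
    (``weight`` on the low mode) for the bimodal tumor-IgM pattern of
    affinity-matured but non-class-switched B cells.
    """

    mean: Optional[float] = None
    weight: Optional[float] = None
    mean_low: Optional[float] = None
    mean_high: Optional[float] = None

    def validate(self) -> None:
        if self.mean is not None:
            if self.mean < 0:
                raise ConfigError("SHM mean must be >= 0")
        elif None in (self.weight, self.mean_low, self.mean_high):
            raise ConfigError("mixture SHM model needs weight, mean_low, mean_high")
        elif not 0 <= self.weight <= 1:
            raise ConfigError("mixture weight must lie in [0,1]")

    @property
    def expected(self) -> float:
        if self.mean is not None:
            return float(self.mean)
        return self.weight * self.mean_low + (1 - self.weight) * self.mean_high

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.mean is not None:
            return rng.poisson(self.mean, size)
        low = rng.random(size) < self.weight
        means = np.where(low, self.mean_low, self.mean_high)
        return rng.poisson(means)

    @classmethod
    def from_dict(cls, d: Mapping[str, float] | float) -> "ShmModel":
        if isinstance(d, (int, float)):
            return cls(mean=float(d))
        model = cls(**{k: float(v) for k, v in d.items()})
        model.validate()
        return model


@dataclass
class TissueConfig:
    """Per-tissue generative parameters."""

    name: str
    n_clones: int
    clone_size_zipf_exponent: float
    n_reads: int
    isotype_probs: Mapping[str, float]
    shm_model: Mapping[str, ShmModel]
    mean_members_per_clone: float = 3.0

    def validate(self) -> None:
        if self.n_clones < 1 or self.n_reads < 1:
            raise ConfigError(f"{self.name}: n_clones and n_reads must be >= 1")
        if self.clone_size_zipf_exponent <= 0:
            raise ConfigError(f"{self.name}: Zipf exponent must be > 0")
        total = sum(self.isotype_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"{self.name}: isotype_probs sum to {total}, not 1")
        for iso in self.isotype_probs:
            if iso not in ISOTYPES:
                raise ConfigError(f"{self.name}: unknown isotype {iso!r}")
        for iso, model in self.shm_model.items():
            model.validate()


@dataclass
class SimulationConfig:
    """Full study-arm configuration (one condition, ``n_mice`` animals)."""

    n_mice: int
    tissues: list[TissueConfig]
    sharing_matrix: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sharing_dominance: float = 0.0
    seq_error_rate: float = 0.001
    min_cdr3_aa: int = 8
    max_cdr3_aa: int = 20
    cdr3_length_probs: Optional[Sequence[float]] = None
    cdr_fr_bias: float = 3.0
    #: optional planted signal: multiply the sharing probability of clones
    #: using this V gene by ``sharing_bias_factor`` (for power analyses)
    sharing_bias_gene: Optional[str] = None
    sharing_bias_factor: float = 1.0
    condition: str = "treated"
    seed: int = 0

    def validate(self) -> None:
        if self.n_mice < 1:
            raise ConfigError("n_mice must be >= 1")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate tissue names")
        for t in self.tissues:
            t.validate()
        for origin, targets in self.sharing_matrix.items():
            for target, p in targets.items():
                if not 0 <= p <= 1:
                    raise ConfigError(
                        f"sharing_matrix[{origin}][{target}] = {p} outside [0,1]"
                    )
        if not 0 <= self.seq_error_rate < 1:
            raise ConfigError("seq_error_rate must lie in [0,1)")
        if not 1 <= self.min_cdr3_aa <= self.max_cdr3_aa:
            raise ConfigError("CDR3 length range invalid")
        if self.cdr3_length_probs is not None:
            n = self.max_cdr3_aa - self.min_cdr3_aa + 1
            if len(self.cdr3_length_probs) != n:
                raise ConfigError("cdr3_length_probs length mismatch")
            if abs(sum(self.cdr3_length_probs) - 1.0) > 1e-9:
                raise ConfigError("cdr3_length_probs must sum to 1")

    def length_probs(self) -> np.ndarray:
        """CDRH3 amino-acid length distribution (default: binomial-shaped,
        mode near 13 aa, the median observed in murine repertoires)."""
        if self.cdr3_length_probs is not None:
            return np.asarray(self.cdr3_length_probs, dtype=float)
        lengths = np.arange(self.min_cdr3_aa, self.max_cdr3_aa + 1)
        n = self.max_cdr3_aa - self.min_cdr3_aa
        mode = min(max(13, self.min_cdr3_aa), self.max_cdr3_aa)
        p = (mode - self.min_cdr3_aa) / n if n else 0.5
        pmf = np.array(
            [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
        )
        return pmf / pmf.sum()


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Realized ground truth for parameter-recovery tests.

    ``clone_tables[(mouse, tissue)]`` holds the realized clone table
    (clones with at least one read), ``common_clones[mouse]`` the set of
    (v_gene, j_gene, cdr3_nt) keys present in the tumor and at least one
    other tissue, ``clones_to_80`` the polarization count computed directly
    on realized read counts, and ``error_registry`` the artifact sequences
    injected per technical duplicate.
    """

    clone_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    common_clones: dict[str, set[tuple[str, str, str]]] = field(default_factory=dict)
    clones_to_80: dict[tuple[str, str], int] = field(default_factory=dict)
    configured_shm: dict[tuple[str, str], float] = field(default_factory=dict)
    error_registry: dict[tuple[str, str, str], dict[str, str]] = field(
        default_factory=dict
    )


def clones_to_fraction(read_counts: Sequence[int], cdr3s: Sequence[str],
                       threshold: float = 0.8) -> int:
    """Smallest number of clones (largest first, ties by CDR3 string) whose
    cumulative read share reaches ``threshold``.  Used to record truth; the
    analysis-side implementation lives in :mod:`bcrtrace.measures`."""
    order = sorted(range(len(read_counts)), key=lambda i: (-read_counts[i], cdr3s[i]))
    total = float(sum(read_counts))
    cum = 0.0
    for k, i in enumerate(order, start=1):
        cum += read_counts[i] / total
        if cum >= threshold - 1e-12:
            return k
    return len(order)


# ---------------------------------------------------------------------------
# Germline generation
# ---------------------------------------------------------------------------

# codon counts per V region: FR1, CDR1, FR2, CDR2, FR3 (sum 96 codons)
_REGION_CODONS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 8, "FR3": 38}
_J_CODONS = 5  # J tail begins with the conserved Y anchor


def generate_germline_set(n_v: int, n_j: int, seed: int) -> GermlineSet:
    """Generate an artificial germline reference with IGHV/IGHJ-style names
    and FR/CDR boundaries tiling each V gene without gaps or overlap."""
    if n_v < 1 or n_j < 1:
        raise ConfigError("n_v and n_j must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E]))
    genes: dict[str, GermlineGene] = {}
    for i in range(n_v):
        family, member = i % 7 + 1, i // 7 + 1
        name = f"IGHV{family}-{member}"
        codons = rng.choice(_SENSE_CODONS, size=sum(_REGION_CODONS.values()))
        seq = "".join(codons)
        bounds: dict[str, tuple[int, int]] = {}
        pos = 0
        for region, n_codons in _REGION_CODONS.items():
            bounds[region] = (pos, pos + 3 * n_codons)
            pos += 3 * n_codons
        genes[name] = GermlineGene(name=name, sequence=seq, bounds=bounds)
    for i in range(n_j):
        name = f"IGHJ{i + 1}"
        tail = "".join(rng.choice(_SENSE_CODONS, size=_J_CODONS - 1))
        seq = "TAC" + tail  # TAC = Tyr, the J-region anchor
        genes[name] = GermlineGene(name=name, sequence=seq, bounds={"J": (0, len(seq))})
    return GermlineSet(genes=genes)


# ---------------------------------------------------------------------------
# Study simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _CloneSpec:
    v_call: str
    j_call: str
    cdr3_nt: str


def _draw_clone_specs(
    rng: np.random.Generator,
    n_clones: int,
    germline: GermlineSet,
    length_probs: np.ndarray,
    min_len: int,
) -> list[_CloneSpec]:
    v_names = germline.v_gene_names
    j_names = germline.j_gene_names
    max_len = min_len + len(length_probs) - 1
    if n_clones > len(_SENSE_CODONS) ** min_len // 2:
        raise ConfigError("n_clones exceeds available distinct CDR3 diversity")
    specs: list[_CloneSpec] = []
    seen: set[tuple[str, str, str]] = set()
    attempts = 0
    while len(specs) < n_clones:
        attempts += 1
        if attempts > 50 * n_clones:
            raise ConfigError("could not draw enough distinct clone keys")
        v = v_names[rng.integers(len(v_names))]
        j = j_names[rng.integers(len(j_names))]
        length = min_len + int(rng.choice(len(length_probs), p=length_probs))
        cdr3 = "".join(rng.choice(_SENSE_CODONS, size=length))
        key = (v, j, cdr3)
        if key in seen:
            continue
        seen.add(key)
        specs.append(_CloneSpec(v_call=v, j_call=j, cdr3_nt=cdr3))
    return specs


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _mutate_v_region(
    rng: np.random.Generator,
    gene: GermlineGene,
    n_mut: int,
    cdr_fr_bias: float,
) -> tuple[str, int]:
    """Apply ``n_mut`` substitutions to the germline V region with CDR-biased
    placement; returns the mutated string and the realized mutation count."""
    seq = np.array(list(gene.sequence))
    weights = np.ones(len(seq))
    for region in ("CDR1", "CDR2"):
        s, e = gene.bounds[region]
        weights[s:e] = cdr_fr_bias
    weights /= weights.sum()
    n_mut = min(n_mut, len(seq))
    if n_mut == 0:
        return gene.sequence, 0
    positions = rng.choice(len(seq), size=n_mut, replace=False, p=weights)
    for pos in positions:
        alternatives = NT[NT != seq[pos]]
        seq[pos] = alternatives[rng.integers(3)]
    return "".join(seq), int(n_mut)


def simulate_sample(
    rng: np.random.Generator,
    mouse_id: str,
    tissue_cfg: TissueConfig,
    clone_specs: list[_CloneSpec],
    weights: np.ndarray,
    germline: GermlineSet,
    cfg: SimulationConfig,
) -> tuple[RepertoireSample, pd.DataFrame]:
    """Realize one compartment: reads multinomial over clones, member unique
    sequences by SHM draws, reads multinomial over members.  Returns the
    sample plus its realized truth clone table."""
    clone_reads = rng.multinomial(tissue_cfg.n_reads, weights)
    records: dict[str, RearrangementRecord] = {}
    truth_rows = []
    default_shm = ShmModel(mean=2.0)
    for ci, (spec, reads) in enumerate(zip(clone_specs, clone_reads)):
        if reads == 0:
            continue
        v_gene = germline[spec.v_call]
        j_gene = germline[spec.j_call]
        n_members = int(min(reads, 1 + rng.poisson(
            max(tissue_cfg.mean_members_per_clone - 1, 0.0))))
        member_reads = rng.multinomial(reads, np.full(n_members, 1 / n_members))
        isotypes = list(tissue_cfg.isotype_probs)
        iso_p = np.array([tissue_cfg.isotype_probs[i] for i in isotypes])
        member_iso = rng.choice(isotypes, size=n_members, p=iso_p)
        vlen = len(v_gene.sequence)
        cdr3 = spec.cdr3_nt
        member_shm: list[int] = []
        clone_iso_counts: dict[str, int] = {}
        realized_members = 0
        for mi in range(n_members):
            if member_reads[mi] == 0:
                continue
            iso = str(member_iso[mi])
            model = tissue_cfg.shm_model.get(iso, default_shm)
            target_mut = int(model.draw(rng, 1)[0])
            mutated_v, n_mut = _mutate_v_region(rng, v_gene, target_mut, cfg.cdr_fr_bias)
            seq = mutated_v + cdr3 + j_gene.sequence
            germ = v_gene.sequence + GAP * len(cdr3) + j_gene.sequence
            prev = records.get(seq)
            if prev is not None:
                # identical V_H string: cluster into the existing unique sequence
                records[seq] = RearrangementRecord(
                    **{**prev.__dict__, "read_count": prev.read_count
                       + int(member_reads[mi])}
                )
                continue
            bounds = dict(v_gene.bounds)
            bounds["CDR3"] = (vlen, vlen + len(cdr3))
            records[seq] = RearrangementRecord(
                sequence_id=f"{mouse_id}:{tissue_cfg.name}:c{ci}:m{mi}",
                v_call=spec.v_call,
                j_call=spec.j_call,
                isotype=iso,
                cdr3_nt=cdr3,
                cdr3_aa=str(Seq(cdr3).translate()),
                region_bounds=bounds,
                sequence_nt=seq,
                germline_nt=germ,
                read_count=int(member_reads[mi]),
            )
            member_shm.append(n_mut)
            clone_iso_counts[iso] = clone_iso_counts.get(iso, 0) + 1
            realized_members += 1
        truth_rows.append(
            {
                "v_gene": spec.v_call,
                "j_gene": spec.j_call,
                "cdr3_nt": cdr3,
                "read_count": int(reads),
                "unique_count": realized_members,
                "mean_shm": float(np.mean(member_shm)) if member_shm else 0.0,
                "isotype_counts": clone_iso_counts,
            }
        )
    table = pd.DataFrame(truth_rows)
    if len(table):
        table["frequency"] = table["read_count"] / table["read_count"].sum()
    sample = RepertoireSample(
        mouse_id=mouse_id,
        tissue=tissue_cfg.name,
        condition=cfg.condition,
        records=list(records.values()),
    )
    return sample, table


def simulate_study(
    config: SimulationConfig, germline: GermlineSet
) -> tuple[dict[str, dict[str, RepertoireSample]], SimulationTruth]:
    """Simulate every (mouse, tissue) compartment of one study arm.

    Sharing across tissues: each clone generated in its origin tissue seeds
    every other tissue with probability ``min(1, base + dominance * S * w_i)``
    where ``base`` comes from ``sharing_matrix`` and ``w_i`` is the clone's
    Zipf weight at origin — expanded clones are the likelier migrants.
    Seeded copies receive an independent size draw from the Zipf tail of the
    recipient tissue.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    mouse_seeds = master.spawn(config.n_mice)
    samples: dict[str, dict[str, RepertoireSample]] = {}
    truth = SimulationTruth()
    prefix = "M" if config.condition == "treated" else "N"

    for m in range(config.n_mice):
        mouse_id = f"{prefix}{m + 1}"
        tissue_seeds = mouse_seeds[m].spawn(len(config.tissues) + 1)
        clone_rng = np.random.default_rng(tissue_seeds[-1])

        # per-tissue origin clones and their Zipf weights
        origin: dict[str, list[_CloneSpec]] = {}
        origin_w: dict[str, np.ndarray] = {}
        length_probs = config.length_probs()
        for t in config.tissues:
            specs = _draw_clone_specs(
                clone_rng, t.n_clones, germline, length_probs, config.min_cdr3_aa
            )
            origin[t.name] = specs
            origin_w[t.name] = _zipf_weights(t.n_clones, t.clone_size_zipf_exponent)

        # sharing draws (origin-rank weighted)
        incoming: dict[str, list[_CloneSpec]] = {t.name: [] for t in config.tissues}
        for t in config.tissues:
            base_row = config.sharing_matrix.get(t.name, {})
            w = origin_w[t.name]
            S = t.n_clones
            for u in config.tissues:
                if u.name == t.name:
                    continue
                base = base_row.get(u.name, 0.0)
                if base == 0.0 and config.sharing_dominance == 0.0:
                    continue
                p = base + config.sharing_dominance * S * w
                if config.sharing_bias_gene is not None:
                    biased = np.array(
                        [s.v_call == config.sharing_bias_gene
                         for s in origin[t.name]]
                    )
                    p = np.where(biased, p * config.sharing_bias_factor, p)
                p = np.minimum(1.0, p)
                seeded = clone_rng.random(S) < p
                for spec in np.array(origin[t.name], dtype=object)[seeded]:
                    incoming[u.name].append(spec)

        samples[mouse_id] = {}
        for ti, t in enumerate(config.tissues):
            rng = np.random.default_rng(tissue_seeds[ti])
            specs = list(origin[t.name])
            # unnormalized Zipf mass by origin rank; migrants draw a random
            # rank in the same law (independent size draws), then one joint
            # normalization over all resident clones
            weights = np.arange(1, t.n_clones + 1, dtype=float) ** (
                -t.clone_size_zipf_exponent
            )
            extra = [s for s in incoming[t.name]
                     if (s.v_call, s.j_call, s.cdr3_nt)
                     not in {(o.v_call, o.j_call, o.cdr3_nt) for o in specs}]
            if extra:
                ranks = rng.integers(1, t.n_clones + 1, size=len(extra))
                extra_w = ranks.astype(float) ** (-t.clone_size_zipf_exponent)
                specs += extra
                weights = np.concatenate([weights, extra_w])
            weights = weights / weights.sum()
            sample, table = simulate_sample(
                rng, mouse_id, t, specs, weights, germline, config
            )
            samples[mouse_id][t.name] = sample
            truth.clone_tables[(mouse_id, t.name)] = table
            if len(table):
                truth.clones_to_80[(mouse_id, t.name)] = clones_to_fraction(
                    table["read_count"].tolist(), table["cdr3_nt"].tolist()
                )
            for iso, model in t.shm_model.items():
                truth.configured_shm[(t.name, iso)] = model.expected

        # realized common clones: key present in tumor and >= 1 other tissue
        tables = {t.name: truth.clone_tables[(mouse_id, t.name)]
                  for t in config.tissues}
        if "tumor" in tables and len(tables["tumor"]):
            tumor_keys = {
                tuple(r) for r in
                tables["tumor"][["v_gene", "j_gene", "cdr3_nt"]].itertuples(index=False)
            }
            other_keys: set = set()
            for name, table in tables.items():
                if name == "tumor" or not len(table):
                    continue
                other_keys |= {
                    tuple(r) for r in
                    table[["v_gene", "j_gene", "cdr3_nt"]].itertuples(index=False)
                }
            truth.common_clones[mouse_id] = tumor_keys & other_keys
    return samples, truth


# ---------------------------------------------------------------------------
# Technical duplicates
# ---------------------------------------------------------------------------


def emit_technical_duplicates(
    sample: RepertoireSample,
    seq_error_rate: float,
    seed: int,
) -> tuple[RepertoireSample, RepertoireSample, dict]:
    """Split a sample into two technical duplicates with independent per-base
    substitution errors.

    Each read of each unique sequence independently acquires errors at
    ``seq_error_rate`` per base; error-bearing reads become new (artifact)
    unique sequences unless the error string coincides with a true sequence
    of the sample, in which case the reads are absorbed there.  The registry
    maps artifact sequence -> origin sequence_id per duplicate, with the
    cross-duplicate collisions listed separately.
    """
    if not 0 <= seq_error_rate < 1:
        raise ConfigError("seq_error_rate must lie in [0,1)")
    seeds = np.random.SeedSequence(seed).spawn(2)
    true_set = sample.sequence_set()
    registry: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    duplicates: list[RepertoireSample] = []
    for dup_id, dup_seed in zip("AB", seeds):
        rng = np.random.default_rng(dup_seed)
        out: dict[str, RearrangementRecord] = {}
        artifacts: dict[str, tuple[RearrangementRecord, int]] = {}
        for rec in sample.records:
            ungapped = rec.sequence_nt.replace(GAP, "")
            L = len(ungapped)
            p_any = 1.0 - (1.0 - seq_error_rate) ** L
            n_err = int(rng.binomial(rec.read_count, p_any)) if seq_error_rate else 0
            n_clean = rec.read_count - n_err
            if n_clean > 0:
                prev = out.get(rec.sequence_nt)
                count = n_clean + (prev.read_count if prev else 0)
                out[rec.sequence_nt] = RearrangementRecord(
                    **{**rec.__dict__, "read_count": count}
                )
            if n_err == 0:
                continue
            # number of errors per error-bearing read: 1 + Binomial(L-1, rate)
            ks = 1 + rng.binomial(L - 1, seq_error_rate, size=n_err)
            arr = np.array(list(rec.sequence_nt))
            non_gap = np.flatnonzero(arr != GAP)
            for k in ks:
                mutated = arr.copy()
                positions = rng.choice(non_gap, size=min(int(k), L), replace=False)
                for pos in positions:
                    alternatives = NT[NT != mutated[pos]]
                    mutated[pos] = alternatives[rng.integers(3)]
                err_seq = "".join(mutated)
                if err_seq in true_set:
                    continue_rec = out.get(err_seq)
                    # error string collides with a real sequence: absorb read
                    if continue_rec is not None:
                        out[err_seq] = RearrangementRecord(
                            **{**continue_rec.__dict__,
                               "read_count": continue_rec.read_count + 1}
                        )
                    else:
                        src = next(
                            r for r in sample.records if r.sequence_nt == err_seq
                        )
                        out[err_seq] = RearrangementRecord(
                            **{**src.__dict__, "read_count": 1}
                        )
                    continue
                if err_seq in artifacts:
                    arec, c = artifacts[err_seq]
                    artifacts[err_seq] = (arec, c + 1)
                else:
                    arec = RearrangementRecord(
                        **{
                            **rec.__dict__,
                            "sequence_id": f"{rec.sequence_id}:err{dup_id}"
                            f"{len(artifacts)}",
                            "sequence_nt": err_seq,
                            "read_count": 1,
                        }
                    )
                    artifacts[err_seq] = (arec, 1)
                    registry[dup_id][err_seq] = rec.sequence_id
        for err_seq, (arec, c) in artifacts.items():
            out[err_seq] = RearrangementRecord(
                **{**arec.__dict__, "read_count": c}
            )
        duplicates.append(
            RepertoireSample(
                mouse_id=sample.mouse_id,
                tissue=sample.tissue,
                condition=sample.condition,
                duplicate_id=dup_id,
                records=list(out.values()),
            )
        )
    collisions = set(registry["A"]) & set(registry["B"])
    full_registry = {
        "A": registry["A"],
        "B": registry["B"],
        "collisions": collisions,
    }
    return duplicates[0], duplicates[1], full_registry


# ---------------------------------------------------------------------------
# Config parsing (YAML-friendly dict form)
# ---------------------------------------------------------------------------


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML-loaded) mapping."""
    tissues = []
    for td in d["tissues"]:
        shm = {iso: ShmModel.from_dict(v) for iso, v in td["shm_model"].items()}
        tissues.append(
            TissueConfig(
                name=td["name"],
                n_clones=int(td["n_clones"]),
                clone_size_zipf_exponent=float(td["clone_size_zipf_exponent"]),
                n_reads=int(td["n_reads"]),
                isotype_probs=dict(td["isotype_probs"]),
                shm_model=shm,
                mean_members_per_clone=float(td.get("mean_members_per_clone", 3.0)),
            )
        )
    cfg = SimulationConfig(
        n_mice=int(d["n_mice"]),
        tissues=tissues,
        sharing_matrix={k: dict(v) for k, v in d.get("sharing_matrix", {}).items()},
        sharing_dominance=float(d.get("sharing_dominance", 0.0)),
        seq_error_rate=float(d.get("seq_error_rate", 0.001)),
        min_cdr3_aa=int(d.get("min_cdr3_aa", 8)),
        max_cdr3_aa=int(d.get("max_cdr3_aa", 20)),
        cdr3_length_probs=d.get("cdr3_length_probs"),
        cdr_fr_bias=float(d.get("cdr_fr_bias", 3.0)),
        sharing_bias_gene=d.get("sharing_bias_gene"),
        sharing_bias_factor=float(d.get("sharing_bias_factor", 1.0)),
        condition=d.get("condition", "treated"),
        seed=int(d.get("seed", 0)),
    )
    cfg.validate()
    return cfg
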