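# Methods

This note documents the models, conventions and numerical choices behind
bcrtrace, and what the synthetic-data validation does and does not show
about real data.

## Data model

The unit of analysis is the *unique V_H sequence*: a distinct primer-trimmed
heavy-chain variable-region nucleotide string. Its `read_count` is the
number of transcripts observed for that string; "unique sequences" and
"reads" are therefore two different denominators and each measure states
which it uses. Sequence identity within a sample is exact string equality of
the full trimmed V_H, matching the upstream clustering of reads into unique
sequences. Coordinates are 0-based half-open in the aligned frame shared by
the observed and germline strings (gap character `-`); the isotype
vocabulary is fixed to the five murine classes the assay primers capture
(IGHM, IGHG1, IGHG2A, IGHG2B, IGHG3), and an unknown isotype is a load
error rather than a silent category.

## Quality control

Three sequential retention stages mirror standard duplicate-library
practice: a sequence must appear in both technical duplicates (counts of
retained sequences are then summed across duplicates, preserving total
evidence; a mean-combine rule is available); CDR3 and the full set of
V-region boundaries must be annotated; and post-intersection abundance
must reach `min_reads` (default 2). Duplicate agreement is Spearman's rank
correlation over shared sequences' count pairs (at least 3 shared sequences
required).

The intersection filter removes errors because an artifact must arise
independently in both libraries to survive. Its known failure mode is
faithfully reproduced by the simulator: a deeply covered dominant clone can
regenerate the same single-base error in both duplicates, so a small number
of collision artifacts pass the filter at high coverage. The simulator's
error registry labels these, and the tests assert that every filter
survivor is either a true sequence or a labelled collision.

**Rarefaction.** Reads are subsampled without replacement on a depth grid
(default 2 % steps, 10 iterations). Each iteration permutes the full read
multiset once and evaluates richness on nested prefixes, which makes the
mean curve monotone non-decreasing by construction and exactly 1.0 at full
depth — properties independent per-depth draws only satisfy in expectation.
The saturation statistic is the smallest grid depth whose mean richness
fraction reaches 99 %, with a distinguished "not saturated" result (`None`)
when the target is never reached; ties resolve to the smallest grid point.

## Clonal measures

Clones are equivalence classes of (V gene group, J gene group, CDR3
nucleotide sequence), with allele suffixes (`*01`) stripped before
comparison. Clone frequency p_i uses read counts. Polarization is the
smallest k such that the k largest clones reach 80 % of reads; ties in read
count break by ascending CDR3 string so k is deterministic.

Hill diversity D_q = (Σ p_i^q)^(1/(1−q)). q = 0 is richness, q = 2 (the
default) the inverse Simpson index; q = 1 is evaluated as the analytic
limit exp(−Σ p_i ln p_i) because the closed form is undefined there. The
implementation is continuous across q = 1 to ~1e-4 and satisfies
D_0 ≥ D_1 ≥ D_2.

CDRH3 length, V-gene usage and isotype distribution are counted per unique
sequence, unweighted by reads (read-weighted variants sit behind flags):
these are properties of distinct receptors, not of transcription levels.
Basal V-gene usage is the per-naive-mouse bone-marrow IgM usage averaged
across naive mice, and other usage tables are reported in that descending
basal order.

**SHM counting.** One mutation count per unique sequence over the
germline-templated V region: substitution positions plus indel events,
where one contiguous gap run in either string counts as a single event
(an indel is one mutational event regardless of length). The CDR3/junction
is excluded — it is not germline-templated, so sequence differences there
are rearrangement diversity, not somatic mutation. Region boundaries are
interpreted in the aligned frame.

## Clone tracking (per mouse)

Common clones are tumor clones whose (V, J, CDR3) key occurs in at least
one other tissue of the same animal; cross-mouse pooling is disabled in
this module because clone keys rarely recur between individuals. Summary
fractions report common clones as a share of tumor clones and of tumor
reads.

**V-gene enrichment.** Per gene, a two-sided Fisher exact test on the 2×2
table (gene / other) × (common clones / basal), Dunn-Šidák adjusted over
the genes tested (p_adj = 1 − (1−p)^m), with log2 fold-change computed on
frequencies with a 0.5 pseudocount on both numerators so absent genes stay
finite. The counting unit defaults to *clones*, not unique sequences:
members of a clone share their V gene by construction, so sequence-level
counting pseudoreplicates expanded clones and demonstrably inflates the
family-wise error rate under the global null (measured 10/20 null
simulations with a false call at sequence level versus 0/20 at clone
level, at equal power to detect a planted 8× sharing bias). The basal
table should be built at the same unit (`bcrtrace.measures.clone_usage`);
`count_unit="unique"` restores sequence-level counting for comparability
with usage tables.

**Per-codon SHM profile.** For the top-50 common clones by tumor read count
(ties by CDR3 string), each V-region codon's value is the fraction of the
clone's member unique sequences mutated at any nucleotide of that codon;
columns are labelled FR1..FR3/CDR1..CDR2 and CDR3 is excluded.

The IgG1/IgG2A ratio is a unique-sequence count ratio with a distinguished
undefined result (`None`) when no IgG2A sequences exist. No significance
test is attached to it.

## Synthetic repertoire generator

The generator emulates the statistical structure of a treated-vs-naive
multi-tissue murine study, not its molecular mechanism:

- **Clone sizes** are Zipf over clone ranks (weight ∝ rank^−a), the
  simplest heavy-tailed law producing "few clones dominate". Default
  exponents: tumor 2.0 (strong polarization), draining lymph node 1.3,
  blood 1.1, bone marrow 1.0 (polyclonal).
- **Clone keys** draw V and J genes uniformly from the germline set and a
  CDR3 from a length distribution over 8–20 aa with mode 13 aa (the median
  length of murine CDRH3) and uniform sense codons.
- **Members.** Each realized clone contains 1 + Poisson(mean − 1) member
  unique sequences (default mean 3); member reads are multinomial within
  the clone. Each member draws an isotype and an isotype-specific SHM
  count: Poisson, or a two-component Poisson mixture for the tumor-IgM
  compartment (default weight 0.5, means 2 and 12 — affinity-matured but
  non-class-switched cells next to naive ones). Substitutions are placed
  without replacement with a CDR:FR position weight of 3:1, reproducing the
  CDR-elevated per-codon profile. Identical member strings are collapsed
  with summed reads, which is why unique-sequence isotype fractions land
  below their member-level draw probabilities for low-SHM isotypes.
- **Sharing.** Each clone generated in its origin tissue seeds every other
  tissue with probability min(1, base + dominance · S · w_i), where `base`
  is the sharing-matrix entry and w_i the clone's Zipf weight: expanded
  clones are the likelier migrants, which is what makes a small fraction of
  common clones carry most tumor reads. A flat matrix is the dominance = 0
  special case. Seeded copies draw an independent size from the recipient
  tissue's Zipf law at a uniformly random rank. An optional planted bias
  multiplies the sharing probability of one V gene's clones for power
  analyses.
- **Technical duplicates.** Each read independently acquires per-base
  substitution errors at `seq_error_rate` (default 0.001, a free parameter
  — not an estimate of any platform); error-bearing reads become new
  unique sequences unless they coincide with a true sequence. The registry
  records every artifact per duplicate and the cross-duplicate collisions.
- **Determinism.** One master seed spawns per-mouse/tissue/duplicate
  substreams (`numpy.random.SeedSequence`), so identical (config, seed)
  pairs are byte-identical and adding a tissue does not perturb the others.

**Ground truth** is recorded on *realized* draws (clone tables with reads
\> 0, clones-to-80 % from realized counts, common-clone keys present in the
realized tumor and ≥ 1 other tissue, the artifact registry), so recovery
tests are exact set/count comparisons rather than distributional ones.

What the generator does *not* emulate: V(D)J junction machinery (P/N
nucleotides, exonuclease chew-back), AID hotspot motifs, clonal lineage
structure within a clone, indel sequencing errors, per-position quality.
Passing parameter-recovery tests therefore shows the analysis code is
correct under a realistic abundance/mutation structure; it does not certify
behaviour under annotation errors or indel-rich platforms.

## Demo study and problem sizes

The built-in demo study is 4 treated mice × 4 tissues plus 2 naive mice ×
3 tissues, 30,000 reads per tissue at full scale, with tissue parameters
(isotype mixes 75 % IgM bone marrow, 96 % IgM blood, IgG-skewed DLN,
IgM-dominant tumor; SHM means ~1 in naive compartments up to 12 in the
tumor; Zipf exponents as above) chosen to emulate the study conditions this
kind of experiment reports. The test suite and the acceptance script run
the same study at reduced scale (0.25× and 0.5× clone/read counts) — the
package's chosen desk-scale problem sizes — which preserves every
qualitative contrast (tumor: lowest clones-to-80 % and Hill D2, highest
SHM, IgM-dominant with a bimodal IgM SHM histogram; common clones: a
minority of tumor clones carrying the large majority of tumor reads).

## Numerical conventions and edge cases

- Threshold comparisons in polarization and saturation use a 1e-12 slack so
  exact-fraction cases (e.g. ten equal clones at threshold 0.8) are not
  missed to float rounding.
- Empty clone sets raise on polarization/diversity (undefined), while
  empty common-clone tables, zero-IgG2A ratios and unsaturated rarefaction
  curves return distinguished values instead of raising.
- Rows that fail to parse on load are rejected, counted and logged — never
  silently dropped; duplicate sequence identity within one file is an
  error.
- `min_reads` is evaluated on post-intersection summed counts.
- Šidák adjustment clips to [0, 1] and is monotone in both p and m.

## Known limitations

- The duplicate filter's collision leakage grows with coverage per
  sequence; the registry quantifies it in simulation, but on real data it
  is invisible — deeper error models (UMIs) are out of scope.
- Enrichment compares common clones against basal usage from a different
  compartment; any systematic V-annotation bias between compartments would
  confound it.
- The CDRH3 boundary convention is taken from the annotation (the region
  between the FR3 anchor and the J-region tyrosine); the package does not
  re-derive junctions from sequence.
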