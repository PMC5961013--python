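# Methods

## Scope and data model

`nnkqc` analyses single-end amplicon reads from NNK-encoded random-peptide
phage-display libraries.  A read is modelled as a fixed layout —
`upstream_flank [cys] insert [cys] downstream_flank` — with a barcode
embedded in the upstream flank at a fixed offset.  All coordinates are
0-based, half-open.  The library design (`LibraryDesign`) is immutable and
validated at construction: sequences over ACGT, the cysteine codon of
constrained (CXnC) designs must encode Cys, and the barcode must be a
substring of the upstream flank at its declared offset.

The cysteine codon defaults to TGT.  Which Cys codon flanks constrained
inserts, and whether it was hard-coded or NNK-drawn, is rarely reported for
real libraries; TGT is NNK-compatible (third base T) and configurable.

## NNK code

The 32 NNK codons are enumerated rather than tabulated by hand.  Two facts
that the enumeration makes explicit:

- TAG (amber) is the **only** stop codon in the NNK set; TAA and TGA both
  end in A, which the K constraint excludes.  Stop-class bookkeeping still
  recognises TGA/TAA (`other_stop`, with precedence over `uag_only`) for
  inputs that bypass validation, e.g. raw reads carrying sequencing errors.
- Amber-aware residue accounting uses 21 classes: the 20 amino acids plus
  the amber-derived glutamine kept separate from CAG-encoded Gln.  Their
  NNK multiplicities sum to 32.  This is what makes the degeneracy-
  normalized distribution of a codon-uniform library exactly flat at 1/21:
  each class's raw frequency is multiplicity/32, dividing by multiplicity
  gives a constant, and renormalizing over 21 classes gives 1/21 ≈ 0.048.
  Merging amber-Gln into Gln (multiplicity 2) would instead give a flat
  1/20; the separate-class convention is the one under which the 0.048
  reference line is meaningful.  `nnk_degeneracy_table` exposes both merged
  variants (amber-as-Gln and amber-as-stop) for translation-level uses.

Theoretical complexity is defined at the amino-acid level, 20^n, the
convention used when library "complexity" is tabulated; the nucleotide-level
32^n is exposed separately (`nnk_nucleotide_complexity`) and is not that
quantity.

## Read filtering

Filters run in a fixed order and each read is tallied under exactly the
first reason that fails, so the report is reproducible and conservative:

1. barcode: 100% fidelity at the fixed offset (`barcode_mismatch`);
2. flanks: zero mismatches over the whole non-insert region
   (`flank_mismatch`) — the upstream flank anchored at the read start, the
   downstream flank at the read end;
3. insert validation: expected length, K-constraint on every random codon's
   third base, fixed Cys codons for constrained designs, no ambiguous base
   calls (`wrong_length`, `non_nnk`, `missing_cys`, `ambiguous_base`).

Anchoring the downstream flank at the 3′ end (still a fixed offset — no
alignment or sliding search) makes a 1-nt indel inside the insert surface
as `wrong_length`, i.e. as a failure of the insert-length criterion, rather
than as a spurious flank defect.  Reads with an N in the insert are
rejected, not imputed; an N at a K slot trips the `non_nnk` check first
because that check precedes the ambiguity check, which keeps the order
deterministic.  Reads are assumed forward-oriented (amplicon sequencing
with a fixed primer); base qualities are ignored by default because the
filtering criteria are purely sequence-based, with an optional
`min_mean_q` threshold tallied under its own `low_quality` key.

Conservation (`accepted + Σ rejected = total`) holds on every input,
including empty files, and is property-tested on arbitrary read lists.

## Synthesis model and calibration

Base incorporation at a degenerate position follows a single-step
multiplicative model: P(b) ∝ stock_b × efficiency_b, normalised over ACGT
at N positions and over GT at K positions.  No neighbour or context effects
are modelled — the model is the simplest one that is identifiable from
composition data and whose inverse yields a compensating recipe.  Under it:

- `predict_composition(stock, eff)` is the forward map;
- `fit_efficiencies(observed, stock)` inverts it (efficiencies identifiable
  up to scale, fixed by the convention G ≡ 1.0);
- `solve_stock_ratios(eff, target)` returns stock_b ∝ target_b/eff_b, the
  mix that makes the predicted composition hit the target exactly.

These are exact algebraic inverses (property-tested over random positive
inputs), so the calibration residual on fitted data is zero to machine
precision; with finite reads the recovered ratios converge to truth at the
usual 1/√n Monte-Carlo rate.  `calibrate_from_library` pools N-slot
compositions across positions by a read-weighted mean — assuming one
efficiency vector shared across positions — fits efficiencies against the
stock assumed for the sequenced synthesis (equimolar by default), and
solves for the equimolar-target mix; K slots are handled analogously.  An
efficiency skew of (G 1.0, A 2/3, T 2/3, C 0.625) yields the compensating
ratios N = G:1.0, A:1.5, T:1.5, C:1.6 and K = G:1.0, T:1.5.

Calibration should be run on a library that has not been grown under
differential fitness: amber enrichment inflates T/A/G at amber-compatible
slots and would confound the efficiency fit.  The mass-spectrometric
readout used when calibrating synthesized oligos directly is out of scope;
the observed base composition is the measurement surrogate.

## Growth model

Host passage is a deterministic exponential weight update: clone weight is
multiplied by fitness^generations, with

- displaying (stop-free) clones: fitness 1 − burden;
- amber-bearing clones: 1 − s·burden, where s is the amber suppression
  efficiency (0 in supE44− hosts, so abortive termination yields a
  wild-type-phenotype phage with fitness 1);
- TGA/TAA-bearing clones (only reachable when validation is bypassed):
  fitness 1 − s_opal·burden with s_opal = 0 by default — no common host
  suppresses opal, so these clones always present the wild-type phenotype.

`display_burden` is a scalar per design (a dimensionless per-generation
fitness cost in [0, 1]); burden is known to grow with displayed-peptide
length, and a length-dependent burden can be expressed simply by
constructing hosts with different scalar burdens per design.  Expectation
dynamics (no demographic noise) were chosen deliberately: the quantity of
interest is the median amber fraction trajectory, and the deterministic
update gives a closed form
f′ = f·w_uag^g / (f·w_uag^g + (1−f)·w_disp^g)
that tests can check exactly.  A stochastic birth-death mode is out of
scope.  Under this model the amber fraction is non-decreasing in
generations whenever suppression is absent and burden is positive, and
invariant when burden is zero or suppression is complete — the qualitative
supE44−/supE44+ contrast.

The simulator does not attempt to reproduce the low (~12%) amber fractions
observed in freshly ligated material after one hour of growth, which sit
well below the naive NNK expectation of ~27% for reasons the growth model
does not capture; it reproduces the divergence between host genotypes over
time.

## Read emission

Reads are sampled with probability proportional to clone weight, assembled
in the fixed layout, and hit by independent per-base substitution errors
(uniform over the three other bases).  A configurable fraction of reads
additionally carries one deliberate defect, drawn uniformly from
{±1-nt indel in the insert, barcode substitution, non-NNK third base},
exercising each filter; the defect per read is recorded in an optional
ground-truth TSV.  Indels occur only through the defect channel; PCR bias,
chimeras, paired ends and quality modelling are out of scope.  Output is
4-line FASTQ with constant Phred+33 quality (Q40 default).  All randomness
flows through one `numpy` Generator, so a fixed seed gives byte-identical
FASTQ.

## Diagnostics

- Per-position base fractions are read-count weighted over the random
  region (fixed Cys codons excluded).
- Deviation from the NNK ideal (25/25/25/25 at N, 50/50 at K) is reported
  per position as a Pearson chi-square statistic plus per-base fold-over-
  expected.  No p-values or multiplicity corrections are attached: the
  statistic ranks and flags positions, it does not test hypotheses.
- The expected amber fraction 1 − (31/32)^n assumes equimolar NNK; a
  bias-adjusted companion computes P(TAG) per codon from the observed slot
  fractions.  Both appear in the report.
- Over-representation screening ranks peptides by read count with
  fold = count/(total/unique), ties broken lexicographically — a screen for
  clones amplified by replication or assembly advantage rather than
  diversity.
- Uniqueness is counted at the nucleotide-insert level (synonymous NNK
  codons make distinct inserts encode one peptide); peptide-level counts
  are also exposed.

Empty tables yield NaN fractions (undefined, not zero) and statistics on
empty input raise rather than fabricate values.

## Pooling

For a mixed pool of libraries of different lengths, member i receives
N_i = target·U_i/ΣU_j phages, equalising copies per unique clone.
Effective uniqueness U_i is the coupon-collector expectation
C(1 − (1 − 1/C)^n) of distinct clones among n transformants drawn from C
equiprobable amino-acid sequences, capped by the transformant count, and
computed via `expm1`/`log1p` so that the astronomically large C of long
designs does not underflow.  This operationalisation of "equal copies per
unique peptide" is an interpretation — equalising by raw transformant
counts is available as `mode="plain"`.

## Problem sizes and test design

Monte-Carlo checks in the test and acceptance suites use 10^4–10^5
synthesized inserts, with convergence asserted at 3σ binomial bounds and
parameter recovery at 3% relative tolerance; brute-force oracles
(enumeration of all 32^n inserts for n ≤ 3, exhaustive outcome averaging
for the uniqueness expectation) pin the closed forms exactly.  Composition
convergence is measured on the synthesized pool itself (one observation
per clone): resampling reads from a finite pool adds clone-duplication
variance that a plain binomial bound does not model.  All stochastic tests
run with fixed seeds.

What passing simulator-driven tests does and does not show: the generator
draws bases independently per position from the effective incorporation
distribution and injects clean, single-defect aberrant reads.  Real
libraries add PCR amplification bias, position-dependent and context-
dependent synthesis effects, indel-bearing sequencing errors, and growth
stochasticity; agreement on simulated data validates the statistical
machinery and its expectations, not the absence of those effects in any
particular sequencing run.
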