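# Methods

## Quantification model

Both estimators assume peptide-level MS1 intensities have already been
assigned to protein groups by an upstream search engine, with razor/shared
peptide assignment resolved there. Intensities of duplicate rows of the same
peptide–sample pair (charge states, modified forms collapsed to plain
sequence) are summed before anything else.

- **iBAQ / riBAQ.** iBAQ divides a group's summed intensity by the number of
  distinct theoretical tryptic peptides of its representative protein within
  a 7–30-residue window at 0 missed cleavages (the common iBAQ convention;
  both window and missed cleavages are configurable). The count is floored
  at 1 so short or cleavage-poor proteins remain quantifiable. riBAQ is iBAQ
  renormalized to sum to 1 over the non-decoy, non-contaminant groups of a
  sample.
- **Length-normalized relative intensity (I_L^rel).** Summed intensity
  divided by the representative protein's sequence length, renormalized
  within the sample. If peptide intensity were exactly proportional to molar
  amount × peptide length and the digest covered each protein completely and
  without overlap, I_L^rel would equal the molar fraction identically; this
  algebraic identity is the basis of the exactness tests.
- **Representative protein.** The longest member of the group, ties broken
  lexicographically by ID. Group-to-protein indirection is optional: by
  default a group ID is taken to be its single member protein's ID.

Cleavage follows the simple rule "after K or R, not before P", enumerated by
pyteomics; semi-specific digestion keeps peptides with at least one tryptic
terminus, and unspecific digestion enumerates all substrings inside a
5–65-residue window.

## Filtering and loss accounting

Each filter returns a ledger with the *quantitative loss*: the fraction of
pre-filter relative abundance held by the removed groups, computed on the
weights as normalized before the step. Because every step renormalizes,
losses compose multiplicatively — 1 − Π(1 − loss_i) over a chain equals the
loss measured directly between first and last sets — which is asserted as a
property test.

Quality filtering keeps a group when its identification score is at least
`min_score` (default 40) and it either has ≥ `min_peptides` observed
peptides (default 2) or clears a high-confidence score override (default
100). Requiring duplicate identification keeps only groups with positive
intensity in both technical replicates of a sample × method combination.
Suspect-outlier flagging (single peptide, single analytical method, peptide
promiscuity ≥ 1000 external matches) never removes anything: removal is an
explicit, separately logged action, mirroring manual curation practice.
Pearson correlations are computed on the intersection of groups quantified
in both vectors by default; union-with-zeros is available by flag. Zero
variance is reported as a missing value with a reason, not as a number.

## Amino-acid composition

The peptide-level estimator weights each peptide's residue frequencies by
its relative MS1 intensity within the set; the protein-level estimator
weights full-length protein residue frequencies by I_L^rel. The two target
slightly different quantities: the peptide-level estimator converges (in the
intensity ∝ amount × length limit) on the *residue-molar* composition —
moles of each residue over total residue moles, which is also what acid
hydrolysis + AAA measures — while the protein-level estimator is a
protein-molar average of frequencies. The difference is small for realistic
length distributions and both are reported.

AAA conversion: mg/g amounts are reduced to weight fractions, divided by the
free amino acid's molecular weight (residue + water) and multiplied by the
average AA molecular weight including water, 128 g/mol. The raw converted
values sum to 128 · Σ(w_i/MW_i), not exactly 1; both the raw values and the
renormalized composition are kept, since whether to renormalize after the
conversion is a genuinely open choice. Pooled Asx/Glx entries use the
molecular weights of Asp/Glu — hydrolysis deamidates the amide forms before
quantification. The essential set defaults to His, Ile, Leu, Lys, Met, Phe,
Thr, Trp, Val (FAO adult convention) and is configurable; pooled Asx/Glx
count as non-essential. Cys/Trp rows absent from an AAA table are treated as
missing, not zero.

## Subcellular distributions

Compartment labels come from a fixed 10-category vocabulary; anything else
maps to "unknown" with a warning, and unknown mass is excluded from the
pooled "intracellular" (non-extracellular) fraction so that intracellular +
extracellular + unknown partitions 1. A group inherits its representative
protein's label. Replicate spread is mean ± sd; the sd of the pooled sum
assumes independent compartments (root of summed variances). Extract
contrasts use one-way ANOVA with Tukey HSD at α = 0.05 (statsmodels'
studentized-range implementation), annotated with `*`/`**`/`ns` and a
compact letter display generated by insert-and-absorb with ties broken by
group mean. All-constant inputs short-circuit to "ns" with a note rather
than erroring.

## Functional-peptide post-processing

Net charge at pH 7 uses the Henderson–Hasselbalch sum with the pKa set
(N-term 9.0, C-term 3.55, D 3.65, E 4.25, C 8.3, Y 10.1, H 6.0, K 10.5,
R 12.5), which reproduces every published reference-peptide charge after
half-away-from-zero rounding to one decimal; the packaged
`reference_peptides.tsv` regression keeps it honest. Score thresholds are
strict inequalities (emulsifier z > 2, SCA > 0.43, CHE > 0.3). Length rules
(α ≥ 15, β 9–16) are advisory flags only. Overlap is defined in parent
coordinates — identical sequences at different loci do not overlap — and
clustering is the transitive closure of single-residue interval overlap
within one parent, with the highest-scoring member (ties: longer, then
earlier) as representative. Top-k selection is greedy by descending score,
rejecting any candidate that overlaps an accepted one; the cluster linkage
used by external antioxidant predictors is not published, so the interval
closure here is a declared stand-in validated against the known worked
selection structure (fifth representative at rank 86 when the top 85 form
four chains).

## Synthetic data generator

The generator emulates: log-normal protein lengths (median 200 residues,
σ 0.45) and molar abundances (σ 1.5, a realistically skewed dynamic range);
compartments drawn from eukaryote-like priors; three extract conditions that
reweight non-extracellular abundances (×1.0 / ×0.35 / ×1.3) to mimic how
well each enzymatic treatment liberates intracellular protein; per-peptide
base intensity = abundance × length × 0.7 per M/H/W/C residue (the
detectability penalty); duplicate replicates with log-normal noise at CV
0.2; 10% independent peptide dropout; 5% contaminants, reversed decoys and
two low-scoring spurious single-peptide groups exclusive to one analytical
method. The length-proportional intensity convention makes the estimators
exact in the noise-free limit, giving parameter-recovery tests a clean
target; a flag switches it off to study length bias.

What it does **not** emulate: spectrum-level effects (ionization
competition, co-isolation), retention time, charge states, modifications,
FDR/decoy competition, shared-peptide ambiguity between homologous proteins,
or correlated (batch-like) noise. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated generative
assumptions, not robustness to everything real data does.

Identification realism has one deliberate consequence: the default tryptic
mode observes only 7–30-residue peptides, so per-protein intensity coverage
varies and I_L^rel acquires a protein-specific coverage bias (truth
correlation drops from ≈0.998 to ≈0.79 at default noise). The
`complete_coverage` mode removes the window and restores the exact limit;
recovery acceptance checks run in that mode because their premise is the
intensity ∝ amount × length identity, while the windowed mode remains the
default for end-to-end pipeline exercises.

## Problem sizes and numerics

Test and acceptance runs use 8–50-protein proteomes, 100 random datasets for
normalization properties, and 20 seeds for stochastic recovery and bias
checks — sizes chosen so the full suite exercises every code path in
seconds while leaving the statistical assertions comfortable margins.
Normalization invariants are asserted to 1e-9; oracle equivalences
(closed-form digest counts, textbook Pearson, brute-force overlap closure,
loss chain rule) to 1e-9 or better; all randomness flows from explicit
integer seeds through `numpy.random.default_rng`.

Known limitations: no match-between-runs or absolute (copy-number)
quantification; no modification-aware quantification; AAA hydrolysis losses
are not modelled (the conversion treats reported mg/g as is); Tukey letters
assume balanced-ish replicate counts as provided.
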