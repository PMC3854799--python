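# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Subtractive proteomics

**Model.** Peptide-level evidence rows carry (experiment, peptide, q-value,
spectral count, mapped proteins). Identification is a three-step pipeline:

1. *Peptide filter*: retain peptides with q ≤ `q_max` (default 0.002,
   boundary inclusive). Protein-level FDR is not re-estimated; the peptide
   threshold is the exposed control.
2. *Parsimony inference*: a protein with ≥1 peptide mapping only to it is
   reported as a unique singleton. Among the remainder, peptides already
   explained by a uniquely identified protein are discarded (a shared
   peptide is not, by itself, evidence for a second protein); proteins left
   with no unexplained peptide are not reported; the rest are grouped by
   connected components of the shared-peptide graph (identical peptide sets
   are trivially one group). Group numbering is deterministic (sorted by
   member label), so inference is invariant to input order.
3. *Subtractive call*: the pollen-tube set is the union of identifications
   over pollinated labeled replicates minus any identifier seen in **any**
   negative control — a single control spectrum excludes, which is exactly
   how the study's four label-escape proteins were handled.

**NSAF.** Within one experiment, nsaf_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j)
over the entries identified there; the reported value is the mean over the
experiments in which the entry was identified (technical and biological
replicates are not distinguished — a deliberate simplification, exposed as
the averaging policy). A group's length is the mean of its members'
lengths; the source data do not dictate a convention. An experiment with
zero total count yields no NSAF values (flagged by absence, NaN mean).

**Replicate overlap** is Jaccard: |A∩B|/|A∪B| per pair and for the full
intersection/union. Under independent detection at probability p the
pairwise overlap tends to p²/(2p − p²); p = 0.75 gives 0.60, the anchor
for the generator's default detection probability.

## Site-frequency statistics

For a locus of n chromosomes after infinite-sites filtering (drop columns
with missing calls or >2 ingroup alleles; keep monomorphic columns for
length only):

* π = Σ_j k_j(n−k_j)/C(n,2) over segregating columns (mean pairwise
  difference);
* θ_W = S/a₁ with a₁ = Σ_{i<n} 1/i;
* D = (π − θ_W)/√(e₁S + e₂S(S−1)) with Tajima's constants; D is undefined
  (NaN) at S = 0 and such loci are excluded from the empirical tails;
* θ_H = Σ_i 2S_i i²/(n(n−1)) over derived counts i after polarizing each
  site by one outgroup taxon (outgroup allele = ancestral); H = π − θ_H,
  the original unnormalized statistic. Sites whose outgroup allele is
  missing or absent from the ingroup are dropped from H (but not from D,
  which needs no polarity). H is computed independently per outgroup.
* Expected heterozygosity per biallelic site is 2p(1−p)·n/(n−1); the
  small-sample factor is a flag (default on).

**Empirical tails.** Exactly k = ⌊α/2 · n_loci⌋ loci are flagged per tail
by rank (α default 0.05), ties broken by locus id. The printed thresholds
(most extreme unflagged values) are descriptive output, not inputs — with
2,352 loci this yields the 58 + 58 = 116 design.

## Coalescent simulation and p-values

Genealogies follow the standard neutral coalescent without recombination:
while k lineages remain, T_k ~ Exp(k(k−1)/2) in units of 4N generations and
a uniform pair merges. Mutations are placed on branches proportionally to
length, either exactly S mutations (fixed-S) or Poisson(θL/2) (θ mode).
E[S] = θ·a₁; the generator's default θ = 2.25 per locus makes the median S
at n = 56 equal 10, the desk-scale stand-in for the study's per-gene SNP
yield.

Per-locus p-values condition on the observed S (the standard practice for
D-based simulation tests; θ-conditioning exists as an option) and count
replicates with a statistic **strictly more extreme** than observed, in
the direction of the locus's tail. For H, replicates are polarized exactly
(the simulator knows each mutation's derived state).

A vectorized engine simulates replicate site-frequency spectra directly by
accumulating, per derived-copy-number class, the total branch length
subtending that many leaves, then placing mutations multinomially. This is
distribution-identical to building haplotype matrices (the test suite
checks exact agreement of the two routes on shared spectra) and makes
10,000-replicate per-locus tests cheap.

**A caveat worth knowing.** On a *fully neutral* ensemble, the flagged loci
are by definition the empirical 2.5% boundary, and loci with small S
(whose D is fat-tailed) are overrepresented in the pooled tails; their own
fixed-S quantiles therefore concentrate *at* 2.5% rather than below it,
and the maximum p-value over flagged loci fluctuates around 2.5–3% across
ensemble seeds. Real tail loci carrying genuine selection signal sit
deeper in their conditional nulls. The acceptance check consequently
allows the binomial Monte-Carlo margin on the 2.5% bound.

## GY94 codon models

The substitution process is a 61-state (universal-code sense codons)
reversible Markov chain: q_ij = π_j · κ^[transition] · ω^[nonsynonymous]
for single-nucleotide codon changes, 0 otherwise. For a single-class model
the generator is scaled to one expected substitution per codon; in site
mixtures **one normalization constant is shared across classes**
(C = Σ_k w_k rate_k), so selected classes genuinely evolve faster — the
main source of LRT signal. Transition matrices come from a symmetric
eigendecomposition of the reversible generator, batched over classes.

Likelihoods use Felsenstein pruning over unique column patterns; columns
containing any gap/ambiguity are masked. Codon frequencies default to F1X4
(position-averaged nucleotide frequencies, stops renormalized away; F61
optional). Alignments must be in frame, stop-free internally; taxa with
<75% unambiguous bases are dropped, and a gene needs ≥3 surviving taxa for
site-model fitting (2 suffice for pairwise rates).

**Site models.** M8/M8a discretize Beta(p, q) into K = 10 equal-probability
categories (ω at quantile midpoints) with total weight p₀, plus one class
at ω_s (free and ≥ 1 under M8; fixed at 1 under M8a). Fitting maximizes
over (κ, a global tree-scale factor, model parameters) with L-BFGS-B on
log/logit-transformed parameters, from dispersed starting points (default
3 restarts, best lnL kept). Fits are chained for speed and stability: M0
(3 parameters, cheap) seeds κ and the scale for M8a; the M8a optimum seeds
M8. Because ω_s = 1 lies on the boundary of M8's space, where M8 coincides
with M8a, the M8 fit is floored at the M8a optimum — the nesting
inequality lnL(M8) ≥ lnL(M8a) holds by construction. Within one fit,
eigendecompositions are cached by (κ, class ωs) and per-class site
likelihoods by (κ, class ωs, effective scale), which makes the numerical
gradient's weight-only perturbations nearly free.

**LRT.** 2ΔlnL against χ²(1) (default), clipped at 0; the 50:50 χ²₀:χ²₁
boundary mixture is available and is the more accurate reference for this
null — the plain χ²(1) is conservative, which the type-I simulation
confirms. q-values use Storey's single-λ estimator at λ = 0.5
(π₀ = #{p > 0.5}/(0.5m), capped at 1) for determinism;
Benjamini–Hochberg is the π₀ = 1 special case.

**NG86.** Pairwise dN/dS by counting: per-position synonymous site
fractions exclude stop neighbors from the denominator; differences at
multi-hit codons are averaged over stop-free minimal pathways; the
Jukes–Cantor map d = −¾ln(1 − 4p/3) converts proportions (p ≥ 3/4 is
flagged as saturated). Note that pathway averaging can assign a small
nonsynonymous fraction to codon pairs produced by two synonymous hits, so
dN under ω = 0 is near — not identically — zero. NJ trees use
Saitou–Nei on JC-corrected nucleotide distances (scikit-bio's
implementation) with negative branch lengths clipped to 0.

## Synthetic-data generators

All generators are pure functions of (config, seed).

* **Proteomics** defaults mirror the study's scale: 1,244 pollen-tube-only,
  1,310 shared and 1,298 style-only proteins, three labeled replicates,
  detection probability 0.75 (→ ~60% pairwise overlap), four label-escape
  proteins in one pooled negative control (one spectrum each). Spectral
  counts are negative-binomial (mean 6, dispersion 1 — the source data give
  no count model); a configurable fraction of peptides is shared between
  random protein pairs to exercise grouping, and a few high-q noise
  peptides exercise the filter. Not emulated: spectrum-level noise,
  homology structure in peptide sharing, incomplete isotope incorporation.
* **Population ensemble** defaults: 2,352 loci × 56 chromosomes (28
  diploids), neutral coalescent at θ = 2.25/locus. Planted loci re-weight
  the neutral SFS (w_i ∝ 1/i) in log space: sweep loci boost singletons
  and the high-frequency-derived classes (D < 0, H < 0; in the
  infinite-skew limit singletons dominate), balancing loci boost
  intermediate frequencies (D > 0). Sites are exchangeable (no linkage)
  and outgroup columns carry the true ancestral state with a configurable
  mispolarization rate (default 0). Not emulated: linkage, recombination,
  demography, sequencing/genotyping error.
* **Codon fixture** defaults: five taxa, 300 codons, κ = 2, uniform codon
  frequencies, tree ((t1:0.08,t2:0.08):0.04,(t3:0.08,t4:0.08):0.04,t5:0.12)
  in substitutions/codon — modest divergence comparable to a young species
  complex. Background genes evolve under M0 (ω₀ = 0.2, strong but not
  extreme constraint); positive genes under M8 with p₀ = 0.9,
  Beta(0.5, 2), ω_s = 4; ω_s = 1 simulates the boundary null for type-I
  checks. Not emulated: indels, alignment error, rate variation beyond ω,
  base-composition heterogeneity.

Passing tests on these fixtures demonstrates the estimators and the
screening logic, not robustness to the artifacts (misalignment, linked
selection, demography, mispolarization) that real data add.

## Candidate integration

A gene is a candidate if (i) it sits in an empirical D tail **and** its
simulation p ≤ α/2 (sweep or balancing), or (ii) its M8-vs-M8a q ≤ 0.10
and it survives manual alignment review (an explicit exclusion list).
H confirmation per outgroup annotates sweep candidates but never filters
them. Two tally policies exist for the headline total: `sum`
(population + adaptive, counting a dual-evidence gene twice) and `union`
(distinct genes); `sum` is the default. A generic 2×2 Fisher's exact test
(hypergeometric, via SciPy) supports enrichment comparisons over
user-supplied label tables; no GO database ships with the package.

## Problem sizes in the checked examples

The test suite exercises the pipeline at the study's scale where that is
cheap (2,352-locus ensembles; 10,000-replicate per-locus simulations) and
at deliberately reduced scale where fitting cost dominates: codon-model
calibration uses 100 boundary-null genes and 20 positively selected genes
of 300 codons each, fitted with one dispersed restart plus a confirmation
refit (three restarts) for genes whose LRT statistic lands near the
rejection threshold — a safeguard against optimizer noise masquerading as
significance.
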