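# Methods

## The problem

Translational selection leaves two footprints on a genome: synonymous-codon
choice drifts toward codons that are abundant genome-wide and well served by
the tRNA pool, and codon diversity within selected genes shrinks. `codonadapt`
measures both footprints per gene and asks whether a condition-induced gene
set (here: white-rot fungal genes induced by growth on a wood-like substrate
relative to glucose) is more adapted to the translational machinery than the
rest of the genome.

## Indices

All indices operate on validated coding sequences: nucleotide length
divisible by 3, terminal stop stripped and never counted, no internal stops,
no ambiguity codes (rejections are per record and logged with a reason).
`l_g` denotes gene length in codifying codons.

**RSCU.** For codon *c* in a synonymous family of size *k* with family count
*n_fam*: RSCU_c = count_c / (n_fam / k). Families never observed in the
corpus are flagged and carry NaN — "unused codon of an observed family"
(RSCU 0) is kept distinct from "family never seen".

**CAI.** Reference weights come from the corpus itself (genome-wide usage,
matching how the original analysis parameterized it), not a curated
highly-expressed set: weight_c = f(c)/max f over the family, with a floor of
0.01 for codons never observed (the EMBOSS convention; configurable). CAI is
the geometric mean of weights over *all* codons of the gene, Met/Trp
included (again the EMBOSS convention; a Sharp–Li style exclusion of
single-codon families is available via `exclude_single_families`).

**Nc.** Wright's effective number of codons. Per family with usage n ≥ 2,
the homozygosity is F̂ = (nΣp² − 1)/(n − 1); classes are averaged by
degeneracy (9 two-fold, Ile alone as the three-fold class, 5 four-fold,
3 six-fold) and Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. A
missing three-fold class is imputed as (F̄₂+F̄₄)/2 (the CodonW convention);
a missing two-, four- or six-fold class, or a non-positive class mean
(possible only for very short genes), leaves Nc undefined (NaN, flagged).

**CPS / CPB.** The codon-pair score uses the amino-acid-corrected
independence ratio, natural log:

    CPS(AB) = ln[ f(AB)/(f(A)·f(B)) · (f(X)·f(Y))/f(XY) ]

with f(AB) per thousand ordered adjacent pairs, f(A) per thousand codons,
f(X)/f(XY) per thousand residues / residue pairs. Pairs never span gene
boundaries, and stop codons never enter (terminal stops are stripped at
load). The per-thousand scalings cancel, so CPS equals the count-ratio form;
we keep the per-thousand formulation because it matches how the quantities
are defined and reported. Pairs unobserved in the reference corpus are
*absent* from the table, never −∞: strict mode raises, naming the pair, when
a scored gene contains one; lenient mode gives unobserved pairs a 0.5
pseudocount (flagged in the output). CPB is the arithmetic mean of CPS over
the gene's l_g − 1 adjacent pairs (undefined below 2 codons).

For single-codon families the amino-acid correction absorbs the pair
frequency exactly, so any pair of two single-codon-family codons has CPS = 0
by construction — worth knowing when reading the tables.

**W_i, tAI, AAtAI.** Absolute adaptiveness of codon *i* to the tRNA pool:
W_i = Σ_j (1 − S_ij)·tGCN_ij over the recognizing anticodons — the
Watson–Crick reverse complement (S = 0) plus wobble partners from a
configurable rule set (`data/wobble_rules.yaml`). Default constraints follow
the standard eukaryotic tAI parameterization: G:U 0.41, I:C 0.28, I:A
0.9999, U:G 0.68, with ATA additionally read by the CAT anticodon at 0.89
and no wobble partner for ATG or TGG (their generic wobble anticodon belongs
to another amino acid or reads a stop). The source study never published its
constraint values, which is why they live in a config file rather than code.
tGCN (gene copy number per anticodon) is taken as the tRNA abundance proxy.
Scanner-isotype/anticodon disagreements are resolved in favor of the
anticodon, with a warning — W_i is anticodon-driven.

tAI_g is the geometric mean of w_i = W_i/W_max over the gene's codons;
AAtAI_g the geometric mean of ᴬᴬw_i = W_i/W_AAmax, the within-family
relative adaptiveness. Since W_AAmax ≤ W_max, AAtAI ≥ tAI always. Codons the
pool leaves at W = 0 receive the geometric mean of the non-zero w (resp.
ᴬᴬw) values — the reference tAI convention; a hard zero would annihilate the
geometric mean of every gene containing the codon. Substitutions are flagged
in the vector's provenance. The family-normalized column W_i/Σ_family W_j
(used for RSCU-level correlations) optionally multiplies by family size
(`family_norm_scale`), since both conventions appear in practice.

**Z-scores.** Z = (x − mean)/SD per index over the whole scored gene set,
population SD (n denominator). At genome scale the n vs n−1 distinction is
far below reporting precision; the choice is fixed here for reproducibility.
Genes with an undefined index are excluded from that index's moments.

## Expression integration

The expression table carries per-gene log2 signals for the two conditions
and a p-value. The fold change is recomputed as 2^(log2₂ − log2₁) rather
than trusted from an input column. Groups: A repressed ≥ 2-fold with
p < 0.05, B induced ≥ 2-fold with p < 0.05, C p ≥ 0.05, D significant but
< 2-fold. Boundary policy is fixed: fold threshold inclusive, significance
strict, p exactly at alpha → C. Group B is contrasted against each other
group with two-sided Mann–Whitney tests (exact null for small untied
samples, tie-corrected normal approximation otherwise) and each index is
Spearman-correlated with each expression variable, unstratified and within
p-value strata ([0, 0.001), [0.001, 0.05), [0.05, 1]). Spearman is invariant
to monotone transforms, so correlating log2 or linear signals is equivalent.
Raw p-values are reported (no multiplicity correction by default;
Benjamini–Hochberg is available but off, matching the descriptive use of
these tests).

## Synthetic data

The generator emulates the three real inputs so that every stage has ground
truth:

* **tRNA pool** — every synonymous family is guaranteed one Watson–Crick
  anticodon; each remaining anticodon is present with probability 0.5; copy
  numbers are 1 + NegBin(1.2, 0.3), a long-tailed distribution giving a few
  heavily expanded isoacceptors over a background of singletons (total
  ≈ 150–200 genes, matching a typical fungal complement). Genes get
  scaffolds, coordinates, scores and introns (72%) and are written in
  tRNAscan-SE tabular layout.
* **CDS** — amino acids i.i.d. after a fixed Met start; within its family a
  codon is drawn with probability ∝ exp(β_g·w_c). β_g ~ Gamma(0.8, 5):
  L-shaped, most genes weakly selected with a long strongly-selected tail.
  The shape matters: the codon-*pair* signal in this generator arises purely
  from between-gene heterogeneity in β (within a gene, adjacent codons are
  conditionally independent), so a β distribution with substantial variance
  is what makes CPB respond to selection at all. Defaults: 2000 genes,
  lengths 100–2000 codons (mean ≈ 350, Gamma-shaped).
* **Expression** — baseline log2 signal N(10, 1); 15% of genes are
  "induced", drawn uniformly from the top-β tertile, with log2 effect
  1 + Exp(1) and p ~ 10^U(−6, −1.4); 7.5% are "repressed"
  (β-independent, mirrored effect); background genes get N(0, 0.25) effects
  and Uniform(0, 1) p-values, so the expected C/D split is analytic
  (1 − α vs α of the background).

What the generator does *not* emulate: GC/mutational bias, genome
architecture (introns, scaffold structure of CDS), amino-acid composition
bias, length–expression correlations, and any real codon-pair chemistry
beyond the heterogeneity effect above. Passing tests therefore show the
*pipeline* recovers a planted translational-selection signal; they are not
evidence about any particular genome.

One `numpy.random.default_rng(seed)` drives everything; a fixed seed gives
byte-identical files.

## Numerical choices and degenerate inputs

* Geometric means are computed in log space (direct products underflow
  beyond a few hundred codons).
* Genes shorter than 2 codons have undefined CPB; genes where no degeneracy
  class is computable have undefined Nc; both are NaN-flagged, excluded from
  that index's Z-moments, and never silently zeroed.
* An all-zero adaptiveness vector (pool recognizing nothing) and a
  zero-variance index are hard errors, not NaNs.
* The worked-example checks tolerate 1% on recomputed fold changes (the
  published signals are printed to two decimals) and ±0.02 on the affine
  Z-prediction (printed three-decimal rounding propagated through the fit).

## Problem sizes

The analysis scripts and the acceptance script use the default 2000-gene
simulation; the shared test corpus uses 100 genes; oracle-equivalence checks
run all six indices against independent brute-force transcriptions on that
corpus at 1e-10. The full simulate → indices → integrate chain completes in
well under a minute on one CPU.

## Known limitations

* Only translation table 1 is tested; other table ids parse but the Nc
  degeneracy classes and wobble rules assume the standard code.
* tGCN is a proxy for tRNA abundance; no expression-weighted s-vector
  optimization of the wobble constraints is attempted.
* The Mann–Whitney/Spearman machinery is descriptive, mirroring how such
  group contrasts are conventionally reported; it is not a calibrated
  multiple-testing procedure.
* Group D (significant but sub-twofold) is intrinsically small under the
  default generator (≈ α times the background), so its contrasts are the
  noisiest; at the default scale they still resolve clearly.
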