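# Methods

## Scope and model

`ecpdx` implements the desk-scale genomic characterization of endometrial
carcinoma / carcinosarcoma PDX cohorts: burden metrics, COSMIC-v2-style
mutational-signature refitting, HRD genomic-scar scoring, four-way
molecular subtyping, lineage clonality analysis, and two-arm in-vivo
response quantification.  Inputs are already-called somatic variant tables
(MAF-like TSV), allele-specific copy-number segments (SEG-like TSV with
integer total and minor copy number), microsatellite panel summaries, and
tumor-volume series.  Raw-read processing, variant calling, and
subclonal copy-number deconvolution are outside the package's scope.

Coordinates are 1-based inclusive in every file dialect and converted once
at ingestion to 0-based half-open internally.  Only the 22 autosomes are
considered: the burden and scar metrics assume a diploid-heterozygous
baseline, which does not hold on X/Y.  The bundled genome table carries
GRCh37 autosome lengths with centromere bounds rounded to 0.1 Mb —
sufficient for arm-level logic; a configurable mini-genome is provided for
tests.

## Burden metrics

* **TMB** = all somatic small variants (SNV, MNV, indel) / callable Mb.
  The callable size is an explicit per-sample input (default 30 Mb,
  exome-like) because the appropriate denominator depends on the assay.
* **MSI score** = 100 · unstable / assessed panel sites; ≥ 3% is treated
  as microsatellite unstable.  The site-level summary stands in for
  read-level MSI callers (e.g. MSIsensor), which need alignments.
* **CNA burden**: a segment is altered iff its (total, minor) state is not
  (2, 1) — an absolute baseline, not ploidy-relative, so whole-genome
  duplicated samples read as globally altered.  Consecutive same-state
  segments merge before counting (coverage gaps do not split a run), and
  the denominator is the segmented genome only.

## Signature refitting

Catalogs follow the standard 96-channel convention: substitution classes
C>A, C>G, C>T, T>A, T>C, T>G on the pyrimidine strand × 16 flanking
contexts in lexicographic order; purine-reference SNVs are
reverse-complemented in.  Refitting mimics the deconstructSigs recipe
without copying its internals:

1. **Forward selection** on the weight simplex: starting from the best
   single signature, repeatedly blend in the signature whose optimal convex
   step `(1−t)·reconstruction + t·signature` (an exact 1-D quadratic,
   clipped to [0, 1]) most reduces the SSE between reconstructed and
   observed spectra; stop when the relative SSE improvement falls below
   1e-3.  Ties break by catalog order for determinism.
2. **Cut-off**: drop signatures with weight < 0.15 (the 15% minimum
   contribution rule, guarding against overfitting the 30-signature set).
3. **Restricted NNLS** over the survivors, renormalized to sum to 1; a
   survivor pushed back under the cut-off by the joint refit is dropped
   once and the NNLS repeated.

A **dominant etiology** is reported when the top exposure reaches 30%;
below that the sample counts as having no dominant signature.  Etiologies:
Signatures 1/5 age, 2/13 APOBEC, 3 HRD, 6/15/20/26 MMR, 10 POLE, 14
POLE+MMR, others "other".

**The signature matrix is synthetic.**  The published COSMIC v2 matrix is
not redistributable from this environment, so the package generates a
deterministic 30-signature stand-in: the signatures the analysis depends on
carry their literature-described channel structure (Signature 1 C>T at
NpCpG; 2/13 APOBEC C>T / C>G at TpCpN; 3 flat/featureless; 5 broad with a
T>C lean; 6/15/20/26 MMR-flavored C>T patterns; 10 POLE C>A at TpCpT; 14
C>A-heavy), and the remainder are fixed-seed Dirichlet spectra that mimic
the diversity of the full set.  Because the simulator and the refitter
share this catalog, all recovery statements are internally consistent;
exposures are not comparable to published COSMIC fits on real tumors.

## HRD scars

From allele-specific segments, per the scar literature:

* **HRD-LOH**: merged LOH runs (minor = 0, total ≥ 1) with summed length
  > 15 Mb, excluding whole-chromosome LOH, operationalized as a run
  spanning ≥ 90% of its chromosome (the source literature says "shorter
  than the whole chromosome" without a numeric rule).
* **LST**: per arm (split at the centromere midpoint — a single
  unambiguous coordinate), iteratively smooth away segments < 3 Mb
  (smallest first, re-merging same-state neighbours), then count adjacent
  different-state pairs with both sides ≥ 10 Mb.
* **NtAI**: merged allelic-imbalance runs (minor ≠ major) that include the
  first or last segmented base of their chromosome and do not cross the
  centromere midpoint.

The sum is compared against the ≥ 42 cut-off established for HRD in breast
and ovarian cancer.  Run lengths sum member segments, so all components are
invariant to splitting a segment into same-state pieces.  No ploidy
renormalization of allelic imbalance is applied under WGD (scarHRD variants
differ here; a `wgd_adjust` config field is reserved but inactive).
HRDetect is deliberately not computed: it requires published trained
weights and rearrangement signatures outside this package's inputs; the
evidence summary carries a null field instead.

## Subtype classification

Decision order POLE → MMRd → CN-high → CN-low, with defaults
POLE = exonuclease-domain missense (codons 268–471, configurable; the
domain is named in the literature without exact boundaries) AND
TMB > 100/Mb (guarding against passenger domain variants in quiet
genomes); MMRd = MSI ≥ 3% AND TMB > 20/Mb; CN-high = pct CNA > 25% AND
> 15 segments AND TMB ≤ 10/Mb.  The MMRd-before-CN-high precedence matches
how hypermutated samples carrying non-exonuclease POLE variants are
handled in practice.  TP53 status and MMR-gene hits are reported as
evidence only, never used as criteria (MMR deficiency can be epigenetic;
CN-high tumors are usually but not necessarily TP53-mutant).  CN-low is
the residual class — "moderately stable genome" has no numeric definition.

## Lineage heterogeneity

* **Purity** = min(1, 2 × mode) of the VAF distribution of variants with
  depth ≥ 30 in copy-neutral regions, the mode located by a Gaussian
  kernel density (fixed bandwidth 0.03) on a grid over [0.02, 1] (step
  0.001).  At least 50 qualifying variants are required.  The estimator
  presumes a dominant clonal peak: in samples where a large subclone rivals
  the clonal cluster (equal peak masses), the mode can land on the
  subclonal peak and underestimate purity — visible on the synthetic
  divergent-lineage primary, and a genuine failure mode on real data.
* **Panels**: a mutation is "detected" in a sample iff VAF ≥ 0.05 and
  depth ≥ 10 (the underlying pileup-recheck thresholds used in such
  studies are not standardized; these defaults are surfaced in config).
  Euler regions are counts per presence pattern and always conserve the
  mutation universe.
* **Cellular prevalence**: closed form at multiplicity 1,
  `cp = clamp(vaf · (purity·CN + (1−purity)·2) / purity, 0, 1)`; mutations
  in zero-copy segments are excluded; undetected mutations enter
  clustering at cp 0, since absence is the informative signal for
  lineage-private clones.
* **Clustering**: seeded k-means (10 restarts) over per-sample cp vectors,
  k = 1..8 chosen by maximum mean silhouette; k = 1 only when the total cp
  variance falls below 1e-3 (silhouette is undefined there).  Clusters
  holding < 5% of all substitutions are flagged minor; the rest are the
  reported "top" clusters.  This deterministic procedure replaces
  Dirichlet-process clustering (PyClone) by design: it is a declared
  simplification, not a re-implementation.
* **Clone trees**: exhaustive enumeration of rooted trees over ≤ 8
  clusters.  The root is the cluster with maximal worst-case prevalence and
  must dominate every cluster in every sample within the tolerance; a tree
  is kept iff, in every sample, each parent's prevalence covers the sum of
  its children's within tolerance 0.05 (absorbing sampling noise on
  clamped prevalences).  Trees are ordered by total unexplained prevalence
  (slack), tightest first.

## In-vivo response

Per-animal relative change = 100·(V_end − V_0)/V_0 at the end-of-study day
(or the last prior measurement); TGI = 100·(1 − ΔT/ΔC) on arm-mean volume
deltas, undefined (null, with a warning) when the vehicle arm does not
grow.  RECIST-style categories are read from the drug arm's mean relative
volume change: PR ≤ −30%, PD ≥ +20%, SD between.  Classical RECIST applies
these thresholds to lesion diameters; volume is the default here (the
common mouse-study convention) and a `diameter_equivalent` cube-root
transform is exposed for the alternative reading.  The optional two-sample
permutation test on final volumes (10,000 seeded permutations) is a
convenience stand-in for repeated-measures mixed-effects testing and is
labelled as such.

## Synthetic cohort generator

The generator emulates the features downstream stages measure, and only
those:

* SNV counts are Poisson around the preset mean; channel identities come
  from the signature mixture under **uniform trinucleotide opportunity**
  (no genome-context weighting — refitting operates on catalogs, and the
  refitter applies no opportunity normalization either, keeping the two
  consistent); positions are uniform on the autosomes; VAFs are
  Binomial(depth, purity/2)/depth for clonal heterozygous diploid
  variants, depth 100 by default.
* Subtype presets: POLE ~19,500 mutations (≈ 650/Mb over the 30 Mb
  default callable size), 0.8/0.2 Signature 10/1, 0.5% unstable sites;
  MMRd ~1,200 mutations (≈ 40/Mb), MMR-signature mix, 10% unstable sites
  plus frameshift drivers (PTEN, ARID1A, RPL22 A8, MSH6); CN-low ~120
  mutations, age signatures; CN-high ~150 mutations, dominant APOBEC, TP53
  R273H, and a structurally altered genome.  The microsatellite panel is
  1000 sites, placing samples clearly on either side of the 3% rule.
* Segment profiles are realized one event per chromosome arm on a diploid
  background (arm-level balanced gains on the largest arms
  deterministically; interstitial losses/LOH and telomeric-AI events on
  randomly chosen qualifying arms with ≥ 10 Mb diploid margins), so every
  planted burden and scar count is exact by construction.  The CN-high
  preset plants > 25% altered genome across > 15 segments while keeping
  its scar sum near 8 (HR-proficient); the HRD-positive control plants
  ~56 qualifying events.
* Lineage panels sample a planted clone tree (validated against the sum
  rule before sampling) with binomial reads; mutations drawing zero alt
  reads are absent from that sample's table, which is what makes
  lineage-private clones visible.  The bundled divergent-lineage scenario
  gives one PDX lineage twice the truncal mutation count privately, so it
  shares one third of its substitutions with the primary tumor.
* Volume curves are exponential with multiplicative lognormal noise after
  baseline; baselines are drawn once per animal index and shared between
  arms (a paired design), so equal rates at zero noise give TGI exactly 0.

What passing tests on these cohorts does **not** show: robustness to
context-biased mutation spectra, subclonal copy number, mouse stromal
contamination, read-level artifacts, or segmentation noise — none of which
the generator emulates.

## Problem sizes and numerical choices

The test and acceptance runs use 50 seeded samples per preset for the
burden bounds, 10 for the scar bound, catalogs of 3,000–5,000 SNVs for
refitting, 500 variants for purity recovery, and 20 seeded three-clone
panels (~600 mutations each) for cluster-count recovery — sizes at which
every stochastic margin in play is wide relative to its Monte-Carlo noise.
Refitting tolerances: line-search stop 1e-3 relative SSE; weight cut-off
0.15; dominance 0.30.  Floating-point report output is fixed-formatted and
row-sorted, making reruns byte-identical.

## Known limitations

Besides the generator gaps above: the purity estimator's subclonal-peak
failure mode; absolute-baseline CNA burden conflates WGD with focal
instability; scar scores are not ploidy-adjusted; tree enumeration is
exponential and capped at 8 clusters; the VCF adapter trusts caller-side
normalization; and the synthetic signature matrix means absolute exposure
values should not be compared against published COSMIC refits.
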