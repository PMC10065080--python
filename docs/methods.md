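# Methods

## The analysis in one paragraph

A genetic-rescue experiment compares four conditions in hematopoietic
progenitors — wild type with an empty vector, enhancer-knockout with an
empty vector, and the knockout re-expressing either the wild-type
transcription factor or a pathogenic variant — with four replicates each.
Three two-group contrasts against the knockout-empty reference (versus wild
type, versus the factor, versus the variant) define enhancer-, factor-, and
variant-regulated gene sets. `gatarescue` classifies every gene by how the
factor and the variant restore (or fail to restore, or ectopically create)
its regulation, then asks whether those classes are mirrored in chromatin:
differential accessibility peaks are linked to the nearest regulated gene,
per-class chromatin-transition proportions are compared with proportion and
rank tests, peak sequences are scanned for GATA-family motif grammars, and
factor-versus-variant occupancy peak sets are intersected and summarized.

## Contrast orientation

Every contrast is reported as log2(comparator / knockout-empty): enhancer =
WT-empty vs KO-empty, rescue = KO+factor vs KO-empty, variant = KO+variant
vs KO-empty. A positive log2 fold change therefore always reads "the
enhancer / factor / variant activates this gene", and an opening chromatin
peak always has a positive fold change. Class definitions and every summary
percentage are invariant to this sign convention.

## Differential expression model

Counts are modeled per gene as negative binomial with variance
mu + alpha * mu^2. The engine follows the standard bulk RNA-seq recipe:

* **Normalization** — median-of-ratios size factors (reference = per-gene
  geometric mean across samples over genes expressed everywhere; linear-
  space median of count/reference ratios per sample; factors rescaled to
  geometric mean 1). When no gene is expressed in every sample, a
  `pseudo_reference=True` fallback uses the geometric mean over positive
  counts only.
* **Dispersion** — per-gene method-of-moments estimate from the pooled
  within-group variance (Bessel-corrected, ddof = n_A + n_B − 2), shrunk
  50/50 toward a lowess trend of those estimates over log10 mean. The shrink
  is arithmetic on the natural dispersion scale rather than geometric in log
  space: with four replicates per group the moment estimate is frequently
  floored at zero, and a geometric combination would be biased low there,
  inflating the Wald test's type-I error. Full empirical-Bayes dispersion
  machinery (DESeq2-style) is deliberately out of scope; this is a
  documented fidelity limit, and exact agreement with any DESeq2 release is
  not claimed.
* **Effect size** — log2FC = log2((mu_B + 0.5) / (mu_A + 0.5)) on
  normalized counts. The 0.5 pseudo-count keeps estimates finite and
  sign-preserving for groups with zero counts. No shrinkage of fold changes
  is applied.
* **Test** — Wald z = log2FC / SE with a delta-method standard error from
  Var(mean) = mu * mean(1/sf)/n + alpha * mu^2 / n per group, two-sided
  normal p, Benjamini-Hochberg adjustment across all genes with any nonzero
  count. All-zero genes get log2FC 0 and p 1 and are excluded from BH
  (adjusted p = NaN) — the only independent filtering applied.
* **DEG call** — |log2FC| >= 1 (inclusive) and adjusted p < 0.05 (strict)
  for expression; accessibility peaks use a strictly greater |log2FC| > 1,
  matching the different wording of the two thresholds.

Calibration is checked empirically: under a 2,000-gene NB null (alpha 0.05,
4 vs 4) the raw p < 0.05 rate stays within [0.03, 0.07] (test suite, three
seeds).

## Regulatory catalog

Per gene and per side: shared classes I.I / II.I (factor- and
variant-regulated), exclusive classes I.II / II.II (factor only), ectopic
classes III / IV (variant only); I = I.I ∪ I.II and II = II.I ∪ II.II by
construction. Direction conflicts across contrasts (activated in one,
repressed in another) are retained per contrast and flagged `discordant`
rather than resolved — no resolution rule is defensible, and the flag keeps
them auditable. Venn-region labels over the three contrasts are tracked per
side so region counts sum to the union of the three DEG sets.

Derived summaries:

* **Rescue fraction** — among genes whose enhancer contrast shows any
  endogenous activation (log2FC > 0, no significance cutoff), the fraction
  whose rescue contrast is sign-concordant; same for repression.
* **Retained activity** — at mutually regulated genes (|log2FC| >= 1 in
  both contrasts by default; a rescue-only mode exists because the printed
  description leaves this ambiguous), the variant's effect as a percentage
  of the factor's. The default scale is the log2FC ratio (100 ×
  lfc_variant / lfc_rescue); a linear-fold alternative
  (100 × (2^|v| − 1)/(2^|r| − 1)) is switchable, since the scale of the
  published "percent of the level conferred" is not stated. The expression
  filter requires TPM >= 1 in every replicate of the rescue condition for
  activation and of the knockout-empty condition for repression; genes
  dropped by the filter are counted.
* **Robustness scan** — DEG sets re-called at ten equally spaced adjusted-p
  cutoffs 0.01, 0.02, …, 0.10 (the spacing of the published "from 0.01 to
  0.1" scan is not stated; equal spacing is the simplest choice); the
  activated and repressed percentage series are compared with a two-sided
  Mann-Whitney U test, exact at these sample sizes. Monotonicity in the
  cutoff is *not* asserted — set differences need not be monotone.
* **Percent of maximal regulation** — for spacer-variant panels,
  100 × (v − empty)/(full − empty) for activation and the mirror for
  repression; values may leave [0, 100]; a value of exactly 50% counts as
  retained (fixed tie rule); zero-dynamic-range genes are excluded.
* **Percentage arithmetic** — every printed-style percentage uses half-up
  rounding at the printed precision (e.g. 13.57 → 14, 35.38 → 35);
  fold ratios round half-up to one decimal. Zero denominators give NaN
  ("undefined"), never 0. Rounding happens only in the report layer;
  intermediates keep full precision.

## Chromatin integration

Differential peaks reuse the NB Wald engine on peak counts. Each
differential peak is assigned to the nearest DEG by |peak midpoint − TSS|
(the anchor is parameterizable; the published text does not say midpoint
versus edge), with exact-distance ties broken to the lexicographically
smaller gene id and an optional distance cap (100 kb default, matching the
motif-analysis window). Linking is restricted to DEGs; an all-genes mode
exists for diagnostics. A gene with both an opening and a closing linked
peak counts in both transition numerators — the per-side proportions are
reported independently and need not partition. Promoter analysis aggregates
normalized peak counts over the strand-oriented window −2 kb to +100 bp
around the TSS (half-open; the minus-strand window for TSS t is
[t − 100, t + 2000)); unstranded annotations fall back to the plus
convention with a warning.

Statistics: the two-sample proportion test is the classical pooled-variance
z with Yates continuity correction (correction capped at the observed
difference, statistic floored at zero). Rank tests (one-sample signed rank
against a zero shift, paired signed rank, Mann-Whitney) use exact null
distributions up to n = 25 and the tie-corrected normal approximation
beyond; they are thin wrappers over scipy.stats, and the test suite checks
them against exhaustive enumeration oracles at small n.

## Motif grammars

Scanning is IUPAC-consensus based (no position weight matrices — presence
and enrichment are what the analysis consumes). Defaults: GATA = WGATAR,
E-box = CANNTG, ETS = AGGAAR, EBF = TCCCNNGGGA; the families are standard
literature consensi and fully configurable, and heatmap-level fidelity to
any motif-library tool is not claimed. Conventions: 0-based forward
coordinates; a minus-strand hit is a window whose reverse complement
matches, reported at forward coordinates; a palindromic double match
collapses to one plus-strand hit; sequence N matches only consensus code N.
Composite elements require an E-box and a WGATAR on the same strand, E-box
5′ of the WGATAR, separated by 6–14 bases (bounds inclusive; the spacer
counts bases strictly between footprints). The published orientation rule
for composites is unstated; same-strand/left-5′ is the documented default
and both the strand requirement and bounds are parameters. Double-WGATAR
elements are non-overlapping pairs with a gap of at most 5 bases; allowed
strand combinations default to same-strand plus convergent. Enrichment
between peak classes uses the comparison class itself as background (as the
published analysis contrasts activated against repressed peak sets), via the
proportion test on presence and Mann-Whitney on per-peak counts.

## Occupancy integration

"Reduced occupancy" is operationalized as factor peaks with no overlapping
variant peak (loss = factor_total − shared, at >= 1 bp overlap). Occupancy
peaks are linked to catalog genes with the same nearest-gene machinery, and
loss percentages / the activated-versus-repressed fold ratio use the same
rounding rules. Peak calling, replicate merging and spike-in normalization
are upstream of this package: peak sets are inputs, and the simple
union-merge provided is for synthetic mode only.

Two published parentheticals are internally inconsistent with their own
counts (69%/61% versus 64.7%/54.7% computed, and 90% versus 89.5%
computed); the package always reports percentages as computed from the
counts it is given.

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes, not any real
dataset:

* **Design** — four conditions × 4 replicates; 14,000 genes; category
  proportions chosen so expected class sizes match the published tallies
  (1,061 activated of which 144 shared, 1,077 repressed of which 381
  shared, 132/282 ectopic, ~1,168 enhancer-only). The enhancer-knockout
  effect is a single dosage latent: factor-regulated genes also respond to
  enhancer loss with probability 0.43 (the published three-way overlap),
  with the same effect size.
* **Effects** — per-category |log2FC| defaults to 2.5; shared genes' variant
  effect is scaled by the retained fractions 0.65 (activation) and 0.56
  (repression), the published medians.
* **Counts** — NB with default dispersion alpha = 0.05 (typical bulk
  RNA-seq overdispersion); per-gene baselines log-uniform on 2^[2, 10];
  library totals log-uniform on [2e6, 4e6] to exercise normalization.
  There is no claim that this noise model matches the deposited libraries —
  it is a stand-in with the right first two moments.
* **Peaks** — Poisson(2) peaks per gene, 400 bp wide, within 25 kb of the
  TSS on a single 1 Gb synthetic chromosome (mouse-like gene density,
  ~71 kb spacing, so nearest-gene linking is usually unambiguous).
  Regulated genes receive an opening/closing peak with the published
  per-side probabilities (0.35/0.086 activated, 0.05/0.40 repressed);
  shifts are ±2.5 log2 units, scaled for shared genes and variant-only for
  ectopic genes.
* **Sequences** — uniform-random DNA with motif instances planted per kb at
  class-dependent densities (WGATAR 2.0/kb in activated-class peaks vs
  0.5/kb elsewhere; ETS and EBF biased toward repressed-class peaks); every
  plant is recorded in a manifest. Planted instances may overwrite each
  other at random positions; the manifest, not the sequence, is ground
  truth for planting.
* **Occupancy** — factor peaks near regulated genes' TSS with per-side
  probabilities 561/1061 and 190/1077; the variant retains a factor peak
  with probability 33/561 (activated) or 20/190 (repressed) and gains peaks
  at 10% of ectopic genes. These defaults are parameterized directly from
  the published occupancy tallies.
* **Determinism** — one seed; named sub-streams (annotation, truth, counts,
  peaks, sequences, occupancy) are spawned with fixed keys so adding a
  stage never perturbs earlier draws; identical configs are byte-identical.

What passing on synthetic data does **not** show: robustness to GC and
fragment-length bias, batch structure, isoform-level effects, multi-modal
dispersion, or peak-calling artifacts — none of which the generator
emulates. Genome-scale published numbers that derive from the deposited
sequencing data are not reproduced in absolute terms; the package
reproduces the printed worked-example arithmetic exactly and the
qualitative genome-scale structure statistically.

## Numerical choices and degenerate inputs

* BH adjustment is a straight step-up with stable sorting; adjusted p is
  monotone in rank and capped at 1.
* Zero-variance rows in z-scoring return all-zero vectors (flagged by the
  caller); FPKM z-scores use log10(FPKM + 1e-3) with population SD.
* Expression filters are inclusive (TPM >= threshold).
* Empty cohorts, zero denominators and zero-gene simulations propagate as
  NaN/empty outputs, never silently as zeros; the pipeline completes
  cleanly on a zero-gene configuration.
* Problem sizes in the test suite and acceptance script (2,000-gene null
  panels, the 14,000-gene default run, 500-peak oracle comparisons) were
  chosen to make sampling error small relative to the asserted margins.

## Known limitations

* The NB Wald engine is a faithful two-group reimplementation, not a GLM:
  no covariates, no batch terms, no isoform quantification.
* Dispersion moderation is method-of-moments + lowess, not empirical Bayes;
  per-gene power at very low counts differs from DESeq2.
* Consensus scanning has no affinity model; motif "presence" is binary.
* The catalog treats the three contrasts symmetrically; it does not model
  the correlation induced by the shared knockout-empty reference group.
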