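# Methods

This note documents the models implemented in `ailmap`, the defaults of the
synthetic-data generator, the numerical choices, and what the validation
experiments do and do not demonstrate.

## The mapping design being modeled

The package implements the analysis workflow of a two-line advanced
intercross: two phenotypically divergent but outbred founder populations (a
selected broiler-type line, called line A or "HQLA-like", and an unselected
native breed, line B) are crossed and random-mated for many generations,
accumulating recombinations that shrink the mapping interval of a
large-effect body-weight QTL. Fine mapping proceeds in stages: (i) markers
nearly fixed for alternative alleles in the founders (|ΔAF| ≥ 0.95) paint
founder-line origin along descendant chromatids, defining breed-level
recombination blocks tested against the trait; (ii) denser tag SNPs
(|ΔAF| ≥ 0.75, thinned to ≥ 100 bp spacing; putatively functional SNPs
admitted at ≥ 0.3) support multi-locus association and haplotype effects;
(iii) an unrelated multi-breed panel split into high- and low-weight groups
localizes sub-segments of the growth-increasing "Q" haplotype shared across
independently selected heavy breeds.

## Synthetic-data generator

The simulator emulates the study conditions; its defaults are fixed and are
the conditions under which every validation experiment runs.

- **Region and map.** 168.6–171.7 Mb (3.1 Mb) at a constant 2.8 cM/Mb; SNP
  grid of one site per 2 kb (1,550 sites), so 2-kb sharing bins are never
  empty.
- **Founder pools.** Each line carries four ancestral haplotypes (mosaic
  standing variation). 5% of sites are line-diagnostic (fixed 1 in A, 0 in
  B); remaining sites get independent line frequencies from Beta(0.4, 0.4),
  yielding a realistic U-shaped ΔAF spectrum. The Q haplotype is the
  majority haplotype of line A (weight 0.7): directional selection on the
  line is assumed to have driven it to high frequency, and the sharing
  scan's "modal haplotype of the reference group" definition of Q requires
  the majority interpretation to be meaningful. Inside configured
  `q_intervals` the Q haplotype carries private derived alleles absent from
  all other ancestral haplotypes. QTL sites are divergently fixed (high
  allele fixed in line A, absent in B) — the founder-line IBD mapping stage
  explicitly assumes divergent QTL-allele fixation.
- **Pedigree.** F0 of 16 + 15 founders; F1 by interline crosses; later
  generations by random non-self mating with replacement within the
  previous generation, equal sex ratio enforced at creation. Intermediate
  generations default to 150 and the mapped generation to 600, matching the
  study scale. Crossovers per meiosis are Poisson(genetic length in
  Morgans) with uniform placement (no interference); only a per-Mb rate is
  known, so a renewal model would add unsupported structure.
- **Phenotype.** weight = 700 g baseline + Σ dosage×effect (defaults: two
  loci of 120 g and 90 g per high-allele copy) + 250 g for males + small
  hatch-batch offsets + N(0, 100 g). The founder lines then differ by
  roughly the QTL span, and the F9 mean (~1,000 g) and SD sit near the
  observed scale of the modeled population.
- **Unlinked background loci.** `simulate_background_loci` transmits extra
  biallelic loci through the same pedigree with free recombination — the
  single-region simulator's stand-in for the rest of the genome. They give a
  well-defined truth when a segment is planted to explain a stated fraction
  of the genetic variance, and play the role of outside-region control
  markers in elimination experiments.
- **Multi-breed panel.** Each breed draws background chromatids from the
  combined ancestral pool and carries the Q haplotype across each planted
  interval with a per-breed carrier frequency (defaults: ~0.85–0.9 in the
  three high-weight breeds, 0.05–0.1 in the seven low-weight breeds),
  emulating shared selection on Q sub-segments with breed sample sizes
  matching the modeled panel (~230 birds).
- **Seeding.** One root seed; every operation consumes an
  `numpy.random.Generator` spawned deterministically from it. Identical
  config + seed reproduces outputs byte for byte.

What the generator does **not** emulate: genotyping error and missingness
(painting handles them, but the generator emits complete calls), selection
during the AIL, sex-chromosome inheritance, epistasis, mutation during the
pedigree, and genome-scale LD beyond the focal region. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated model, not robustness to real-data artifacts.

## Statistical models and numerical choices

- **REML (assoc.fit_null).** y = Xβ + g + e with g ~ N(0, Vg·K). After
  eigendecomposition K = U D U', the restricted likelihood is profiled down
  to the heritability ratio h = Vg/(Vg+Ve), maximized by bounded Brent
  search on (0, 1) with 1e-10 tolerance; the total variance is closed-form.
  Zero residual variance (phenotype an exact function of covariates) raises
  a degeneracy error rather than returning a silent boundary fit.
- **Choice of K.** A marker GRM restricted to a single 3 Mb region is
  near-degenerate: its spectrum collapses onto a few founder-haplotype
  directions and REML estimates of Vg become unstable. Where a genome-wide
  GRM is unavailable by construction (region-only simulations), the
  validation experiments use the pedigree additive relationship matrix A
  (tabular method, founders unrelated): for any additive architecture
  transmitted through the pedigree, cov(g) = Vg·A exactly, making A the
  principled single-region analogue of a genome-wide GRM. The pipeline's
  VCF-only GWAS stage uses the marker GRM it can compute, which is adequate
  for locus detection but not for variance-component interpretation.
- **Scan (assoc.assoc_scan).** GCTA-MLMA-style single null fit: the variance
  structure is estimated once and each SNP tested by GLS Wald test with
  t-reference (n − p − 1 df). With K = I this reduces exactly to
  covariate-adjusted OLS (tested to 1e-8).
- **variance_explained.** Segment classes (founder-origin diplotypes or
  genotype classes) are fitted jointly with covariates by least squares; the
  segment variance is the frequency-weighted variance of fitted class
  effects, divided by the REML Vg. Classes with n < 3 merge into the class
  with the nearest phenotype mean. Invariant to affine rescaling of y.
- **IBD painting.** Phase across heterozygous diagnostic markers is resolved
  by minimizing total origin switches over both chromatids (dynamic program
  over the two phase choices per het site; ties prefer no switch, then a
  fixed state order). Missing markers inherit the left flank's origin;
  origin runs shorter than `min_support` (default 2) markers are relabeled
  to the flanking consensus as a genotyping-noise guard. Breakpoints use the
  midpoint of the flanking marker interval, 0-based half-open internally.
  This deterministic rule set replaces statistical imputation/phasing; it is
  exact when diagnostic markers are truly near-fixed and dense.
- **EM haplotype frequencies.** Enumerates phase-compatible diplotypes
  (first heterozygous site anchored to halve the space; refuses > 16 het
  sites), uniform initialization, convergence at max frequency change
  < 1e-6 or 1,000 iterations; the log-likelihood is asserted non-decreasing
  every iteration.
- **Substitution effects.** Sum-to-zero contrast on u — no reference
  haplotype is privileged and effects are reported as deviations, matching
  how substitution effects are usually displayed. Rank deficiency beyond
  the forced constraint raises an error naming the aliased columns.
- **Backward elimination.** Each round fits one joint model, computes
  per-candidate Wald p-values and applies Benjamini–Hochberg **with the
  denominator fixed at the initial candidate count**; if any candidate
  fails, the single largest-p candidate is dropped (tie → larger position)
  and the model refit. With the per-round denominator instead, a lone null
  survivor passes at p ≤ α and null data would retain a SNP ~79% of the
  time with 30 candidates; the fixed family size keeps the null retention
  near the nominal 5%. Monomorphic and perfectly collinear candidates are
  removed up front (later position loses); saturated designs are
  pre-screened by marginal p to n/2 predictors.
- **Sharing scan.** Q is the modal haplotype of the reference founder group
  per bin (ties → lexicographically smallest string); the differential is
  signed (High − Low) because the criterion is directional. Bins tile the
  region from its start; SNP-less bins break merge adjacency. Regions are
  named Q1..Qk left to right.
- **Sweep statistics.** π uses accessible (not just polymorphic) sites in
  the denominator and reports undefined windows as NaN at fixed step;
  Tajima's D returns NaN (never 0) for S = 0; Fst defaults to Hudson's
  two-population estimator with ratio-of-averages windowing
  (Weir–Cockerham behind a flag for cross-checking) because no estimator is
  canonical for this design; XP-EHH computes population EHH outward from
  the core (core allele included in the extended haplotype), integrates by
  trapezoid over genetic distance, truncates at EHH < 0.05, and
  z-normalizes raw log-ratios at scan level — the common defaults of the
  standard scan tools. Sites with chromatid call rate < 0.9 are excluded
  everywhere, mirroring the design's global QC threshold. Both published
  bin-size presets (fine and coarse) are exposed; neither is privileged.
- **Coordinates.** 0-based half-open internally and in BED output; 1-based
  inclusive in VCF and scan TSVs.

## Validation experiments (module `validation`)

Problem sizes were chosen to represent the study scale while keeping a full
run around a minute on one CPU: F9 cohorts of n = 600 (n = 400 for null
calibrations) over the 1,550-site grid, 50 replicates for recovery and null
experiments, 25 for elimination power.

- **Haplotype-effect recovery.** Eight tag SNPs across the 1.2 Mb
  fine-mapping interval define haplotype classes; true effects span −59 to
  +65 g (centered for sum-to-zero identifiability). Reported: fraction of
  estimates within 2 SE of truth (expected ~95% if SEs are honest).
- **Segment variance recovery.** One divergently fixed segment locus scaled
  to 15% of an 8,000 g² genetic variance, the rest from 60 unlinked
  background loci; Vg re-estimated per replicate by REML against A.
- **Pipeline Q-region recovery.** `run-all` on the demo config with three
  planted shared intervals; reported: fraction of planted length covered by
  detected Q regions.
- **Backward-elimination power and null.** Candidate panels mirror the
  modeled design: the causal loci, the region's approximately independent
  tags (pairwise and causal–null r² ≤ 0.1 — the structure-analysis pruning
  threshold; looser screens leave causal/proxy selection unidentifiable in
  a deep intercross), topped up to 28 nulls with unlinked background
  markers. Null runs permute the phenotype within sex strata with sex kept
  in the model, so only the genotype–phenotype link is broken.
- **Scan calibration.** Within-sex permuted phenotypes tested against 500
  unlinked background loci. Focal-region sites remain mutually correlated
  even after LD pruning (an AIL region supports only a few dozen effective
  tests), which breaks the binomial reference for the rejection count;
  independently transmitted background loci restore it.

## Known limitations

- Painting supports two founder lines only; no probabilistic (HMM) ancestry
  posterior.
- The haplotype effect model has a single residual term (no GRM), as
  specified for this analysis; confounding by relatedness is handled only
  through the covariates.
- `n_independent` from LD pruning is a convention, not an estimate of the
  effective number of tests.
- XP-EHH truncation/normalization choices follow common practice; absolute
  scores are not comparable across tools, only scan-level ranks.
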