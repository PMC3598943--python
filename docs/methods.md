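# Methods

This document records the statistical model, algorithmic conventions and
numerical choices behind panelforge, in enough detail to reproduce any
number it emits.

## 1. Data model

A **catalog** is a (chromosome, position)-sorted table of candidate
SNPs. Fixed columns: `snp_id`, `chrom`, `pos` (1-based), `ref`, `alt`,
`global_quality`, `global_maf` (folded, ≤ 0.5), `in_prior_panel`,
`coding`, `annotation`, and probe design scores for both strands
(`fwd_16mer`, `fwd_pconvert`, `rev_16mer`, `rev_pconvert`). Each
registered line `X` contributes `X_seg` (does the site segregate in the
line), `X_maf`, `X_qual`, `X_cov`. Missing values are written as `.` in
the TSV dialect; duplicate (chrom, pos, alt) sites and positions < 1 are
hard errors. Lines carry a group (`broiler`, `WEL`, `BEL`, `inbred`,
`experimental`), a commercial flag and an optional fill-order rank.

A **genetic map** is a set of strictly increasing (bp, cM) anchors per
chromosome. bp→cM conversion is linear interpolation between anchors;
outside the anchored range the terminal interval's rate extrapolates,
floored at 0 cM. Non-monotone anchors are a hard error, never silently
repaired; single-anchor chromosomes degrade to constant cM with a
warning.

**Genotypes** are alt-allele dosages 0/1/2 with −1 for missing, stored
sample × SNP, readable from TSV or VCF (GT fields via pysam).

## 2. Filter cascade

Stages run in a fixed order; each only removes records, so every filter
is idempotent and order within the catalog is preserved. Defaults in
`FilterPolicy`:

1. **Quality/MAF** — keep a SNP if any single line reaches quality ≥ 60
   *and* folded MAF ≥ 0.05 (both inclusive), or the global all-lines
   analysis does, or it was on a prior panel. Chromosome 16 (MHC) and
   ChrZ are exempt: their content is scarce enough that the screen would
   strip them.
2. **Proximity** — a SNP needs ≥ 10 SNP-free bases on one side and ≥ 4
   on the other (either orientation), measured against its neighbours in
   the *original* configuration: a single, non-iterative pass, so a
   removed neighbour still "shields" a survivor. Chromosome ends count
   as infinite gaps. Exempt chromosomes skip the rule.
3. **Design scores** — keep if, on at least one strand, the probe's
   16-mer genome count is ≤ 100 *and* its conversion propensity is
   ≥ 0.2 (both inclusive). Records lacking all design scores are
   removed with a warning.
4. **Coverage outliers** — per line, remove SNPs whose pooled coverage
   strictly exceeds mean + 3 sample standard deviations (ddof = 1) of
   that line's coverage distribution (a proxy for collapsed repeats);
   lines with < 2 covered records are skipped with a warning.

After validation genotyping a separate step removes assays with exact
HWE p < 1e-5 (strict inequality; SNPs without a p-value are kept).

`mask_frequent_kmers` reproduces the genome-preparation step: every
16-mer occurring more than 100 times genome-wide is lower-cased
(soft-masked) wherever it occurs; windows containing N are ignored.
Intervals are reported 0-based half-open and merged.

## 3. Panel selection

See README for the algorithm statement. Conventions that matter for
reproducibility:

- **Backbone spacing** is strict: a candidate at distance exactly `t`
  from an accepted SNP is rejected. Passes run in the order all lines →
  all inbred → all layer (WEL + BEL) → all broiler; each pass scans
  positions left to right per chromosome and sees the SNPs accepted by
  earlier passes. Counters `N, I, I_u, L, L_u, B, C` record per-pass
  acceptances, where `I_u`/`L_u` count backbone SNPs unique to
  inbred/layer lines (segregating in no commercial/broiler line).
- **Segments** for line *i* are bounded by the cM positions of already
  selected SNPs segregating in *i*, plus the chromosome's map ends;
  candidates exactly at a boundary belong to neither side.
- **Quota**: 0 if the segment is shorter than one inter-marker interval
  (1/dᵢ cM, with a 1e-9 relative tolerance at the boundary), else
  `ℓ·dᵢ` rounded half-up.
- **Gap-filling DP** minimises the sum of squared consecutive cM gaps
  including both bounds. The backward table `g[k][j]` holds the optimal
  cost from the k-th chosen candidate `j` to the right bound; the
  forward reconstruction takes, at each step, the smallest index whose
  accumulated cost meets the optimum within 1e-9 relative tolerance —
  i.e. ties break to the lexicographically smallest position tuple.
  If the quota exceeds the candidate supply, all candidates are taken.
- **Density calibration** bisects the scalar `s` (panel size is
  monotone in `s`, asserted during bracketing) until the realised size
  is within ±2% of the budget. If the backbone alone exceeds the
  budget the calibration fails fast with the advice `t ≈ genome
  length / budget`; if the budget exceeds the candidate supply the full
  catalog is returned with a warning.
- Everything is deterministic: no randomness, stable sorts, fixed pass
  and line order.

## 4. Validation statistics

- **Conversion classes**: `failed` if call rate < 0.98; else
  `monomorphic_low_allele_count` if the minor-allele count over called
  genotypes is < 2; else `polymorphic`.
- **Mendelian check**: a 3×3×3 transmission table over
  sire × dam × offspring dosages; a trio with any missing genotype at a
  SNP carries no evidence (consistent). Sex chromosomes (Z/W) are
  skipped by default because hemizygosity breaks the diploid rules.
- **Exact HWE test** (conditional on allele counts): enumerate every
  heterozygote count of matching parity, weight each by
  `n! / (n_AA! n_AB! n_BB!) · 2^{n_AB}` (computed via `lgamma` in log
  space), normalise, and sum the probabilities of all outcomes no more
  probable than the observed one (two-sided), with a 1 + 1e-12
  relative tolerance on the comparison. Worked examples:
  (1, 2, 1) → p = 1.0; (2, 0, 2) → p = 6/70. An optional mid-p variant
  subtracts half the observed outcome's probability. The test suite
  verifies the implementation against a first-principles enumeration
  oracle on every table with n ≤ 8.
- **MAF**: folded allele frequency of called dosages, optionally per
  line subset; NaN when everything is missing.

## 5. Population structure

PCA operates on HWE-normalised dosages: per SNP, `p̂ = mean(g)/2`,
fixed SNPs dropped, missing imputed at `2p̂`, entries scaled to
`(g − 2p̂)/√(2p̂(1−p̂))`. Components come from the eigendecomposition
of the sample × sample covariance `ZZᵀ/m` (efficient for samples ≪
SNPs), equal to the SVD of `Z` up to sign; the sign is fixed so each
component's largest-|loading| SNP loads positively, making results
reproducible. Sex chromosomes are excluded by default.

Adjacent-pair LD is the squared Pearson correlation of dosages between
consecutive panel SNPs within a chromosome, over samples called at
both; pairs with a monomorphic member or < 2 joint calls yield NaN, and
chromosome boundaries emit no pair.

## 6. Report arithmetic

All percentages are rounded half-up (via `decimal.Decimal`, not
banker's rounding) to two decimals, and group means to one decimal of a
million, so printed figures recompute exactly from their counts.
`panelforge.datasets` carries the published design-study inputs (24
per-line segregating-SNP counts, the 1,829,290-SNP validation summary,
the 580,954-SNP final-panel annotation breakdown) as worked-example
inputs; the package derives none of them. Spacing statistics include
chromosome-terminal gaps so each chromosome's gap multiset sums exactly
to its length; the two report curves are the fraction of inter-SNP gaps
≤ g and the fraction of the genome not lying in gaps > g. Venn sharing
counts a SNP toward the exact combination of (three) groups in which it
segregates in at least one line. MAF histograms use left-open,
right-closed bins of width 0.05, with exact zeros in the first bin.

## 7. Synthetic data generator

The generator (`panelforge.simulate`) emulates the *shape* of a pooled
resequencing design study, not any real genome:

- **Lines**: 6 white-egg layers, 5 brown-egg layers, 4 broilers, one
  unselected experimental layer, 8 inbred lines (24 total).
- **Frequencies**: ancestral `p ~ U(0.05, 0.95)`; group frequencies
  drift by Balding–Nichols `Beta(p(1−F)/F, (1−p)(1−F)/F)` with
  F_group = 0.10; line frequencies drift from their group with
  F_line = 0.05, or F_inbred = 0.90 for inbred lines, which fixes most
  sites and reproduces the order-of-magnitude segregation contrast
  between commercial and inbred lines.
- **Segregation call**: both alleles observed in a binomial pool of
  2 × 10 allele draws at the line frequency — so rare alleles are
  missed, as in real pooled sequencing.
- **Genome**: seven chromosomes (~60 Mb total) spanning a macro/micro
  contrast of 2–15 cM/Mb, with within-chromosome rate multipliers
  (0.8/1.0/1.3/0.9), so cM-evenness differs materially from
  bp-evenness. This scaled-down size is the package's own choice to
  keep tests fast; the algorithms carry no assumption tied to it, and
  `t` should scale as genome length / budget.
- **Design scores** pass at rates 0.93 (16-mer) and 0.73 (conversion
  propensity) per strand, matching the character of probe attrition.
- **Genotypes**: Hardy–Weinberg draws at the line frequency, with
  configurable genotyping-error (dosage shifted mod 3) and missingness
  rates. **Trios** transmit alleles correctly, then an injection rate
  replaces offspring calls with parent-incompatible genotypes and logs
  them in a ledger, giving the Mendelian check an exact closed loop
  (injections skip sex chromosomes and het × het parents, which have no
  incompatible offspring dosage).
- **Determinism**: one integer-seeded PCG64 stream for the catalog;
  per-line streams seeded by `[seed, crc32(line), salt]` so adding a
  line never perturbs another line's draws. Identical configuration
  and seed give byte-identical files on any platform.

What it does **not** emulate: linkage disequilibrium within lines
(sites are independent), ascertainment bias of the discovery panel,
sequencing depth variation along the genome, and real chicken
chromosome count (39) or map lengths.

## 8. Numerical choices

- Exact tests and multinomial weights in log space (`lgamma`) to avoid
  overflow at large n.
- Half-up rounding through `decimal.Decimal(repr(x))` so that e.g.
  0.125 → 0.13 regardless of binary representation.
- The DP uses vectorised numpy inner loops (O(m²n) time, O(mn) space)
  and float64 throughout; its optimality is tested against exhaustive
  enumeration, and reconstruction tolerances are relative (1e-9).
- Panel-size calibration brackets before bisecting and asserts
  monotonicity instead of assuming it.

## 9. Limitations

- Gap-filling is greedy across lines: earlier lines in `line_order`
  constrain later ones, so the realised per-line densities (not the
  targets) can deviate where supply is thin; the budget tolerance
  absorbs this.
- The proximity filter's single-pass semantics follow the original
  design-study convention; an iterative variant exists behind
  `proximity_iterative` for sensitivity analysis.
- The exact HWE test is conservative (discrete support), so its null
  rejection rate sits below the nominal level.
- `adjacent_ld` measures composite (genotypic) correlation, not
  haplotype r²; for HWE populations they agree in expectation.
- The VCF writer emits minimal records (GT only, fixed A/C alleles)
  intended for round-tripping simulated data, not for annotation-rich
  exports.
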