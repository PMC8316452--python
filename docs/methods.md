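# Methods

This document records the statistical model behind the synthetic-data
generator, the analysis choices made by each pipeline stage, and the known
limitations of both.

## Identification cascade

A candidate transcript is called a lincRNA only if **all six** predicates
hold; every candidate keeps a full audit trail of individual results, so a
rejection names the exact predicates that failed.

1. **Intergenic ('u') position** — the candidate's genomic *span* (first exon
   start to last exon end) overlaps no reference transcript span by ≥ 1 bp,
   on either strand. Span rather than exon overlap makes intronic candidates
   non-intergenic, and strand-agnosticism is the conservative reading for a
   class defined by genomic position.
2. **Mature length > 200 nt** — the sum of exon lengths, not the genomic
   span; a transcript of exactly 200 nt is rejected.
3. **≥ 2 exons** — mono-exonic assemblies are enriched for fragments and
   transcriptional noise.
4. **Coding score < 0** — the score is the longest forward-frame ORF
   (ATG → stop, same frame) as a fraction of transcript length, minus 0.35.
   A transcript whose longest ORF covers a third of its length or more is
   treated as potentially coding.
5. **No protein/domain hit** — no exact 8-mer peptide match between any of
   the candidate's six translation frames and an index of known protein
   8-mers. Stops and ambiguous residues break the k-mer stream.
6. **FPKM > 0.5 in at least one sample** — strictly greater; max FPKM of
   exactly 0.5 is rejected.

Called lincRNAs are split into *known* (span overlaps a known-lincRNA record
by ≥ 1 bp) and *novel*.

## Quantification

FPKM is computed as `counts · 1e9 / (library_size · length)` with the library
size equal to the per-sample column sum and length equal to the mature
(exonic) length. This definition conserves mass exactly: for every sample,
`Σ_f FPKM_f · L_f / 1e3 = 1e6` to within 1 ulp-scale rounding (verified at
1e-12 relative tolerance). The implementation scales before dividing
(`(counts·1e9)/lib/L`) so that inputs for which the defining formula is a
dyadic rational — boundary fixtures such as FPKM exactly 0.5 — are computed
exactly.

## Differential expression

`de_test` is a trend-moderated t-test on `log2(FPKM + 1)`:

- per-feature pooled two-group variance with `df = n1 + n2 − 2`;
- a lowess trend (frac 0.5) of log variance against mean expression supplies
  a per-feature prior variance; the prior degrees of freedom are fit by
  matching the moments of the observed variance/trend ratios to a scaled F
  distribution (trigamma inversion solved by Brent's method);
- the posterior variance `(d0·s0² + d·s²)/(d0 + d)` is used in the t
  statistic with `d0 + d` degrees of freedom.

With three replicates per stage, an unmoderated t-test has so little power
that a 4-fold planted shift is mostly missed; borrowing strength across
features is what makes `n = 3` designs workable, which is why the moderated
statistic is the package default rather than an option. The reported effect
size is `log2((mean_B + 1)/(mean_A + 1))` on the FPKM scale, and a feature is
*differential* iff `|log2FC| ≥ 1` and BH-adjusted `p ≤ 0.05` (thresholds are
arguments). Operating characteristics, measured on a dedicated two-group
negative-binomial simulator (2,000 features, 100 planted at log2FC = 2,
dispersion 0.05, n = 3 per group, 20 seeds): type-I rate at p ≤ 0.05 of
0.049 under the pure null, sensitivity 0.998, empirical FDR 0.018.

## Target prediction

Correlations are Pearson on `log2(FPKM + 1)` across all samples, with
p-values from the t transform `t = r·√(n−2)/√(1−r²)`; a constant vector
yields (r = 0, p = 1) and |r| = 1 yields p = 0. The t-transform p agrees with
a 100,000-draw Monte-Carlo sample of the normal-theory null to within
Monte-Carlo error (this is an exact identity by the spherical symmetry of the
Gaussian null, so the Monte-Carlo check is a machinery test, not a
calibration).

- **cis**: candidate genes on the same chromosome whose span lies strictly
  within 100 kb of the lincRNA span (gap of exactly 100 kb is excluded,
  overlap counts as distance 0); kept at `|r| ≥ 0.8` and raw `p ≤ 0.01`.
  Proximity is the prior; the raw-p gate reflects the small,
  hypothesis-driven candidate set.
- **trans**: all (lincRNA, gene) pairs genome-wide; kept at `|r| ≥ 0.96` and
  BH `p ≤ 0.05`, with the BH adjustment running across *every tested pair*.
  The much stricter r gate compensates for the genome-wide search space.
- A pair passing both gates is reported once, as cis, so network edges stay
  unique.

Negative correlations pass both gates on |r| and are reported with
`sign = negative`.

## Synthetic world

The generator plants a complete, checkable truth:

- **Geometry** — 6 chromosomes × 5 Mb; 80 foreground coding genes, 30 true
  lincRNAs, and 60 decoys (10 per failure mode), each decoy violating
  *exactly one* cascade predicate (overlapping, short, mono-exonic,
  coding-like sequence, planted 8-mer domain hit, sub-threshold expression).
- **Expression** — base expression is drawn in FPKM space; 300 background
  coding genes absorb the residual library mass so the per-sample FPKM·bp
  budget is exactly 1e9, and counts are negative binomial (dispersion 0.05)
  at library size 5e7. The library size is chosen so that a feature at the
  0.5-FPKM identification boundary still has ~25 expected counts per
  kilobase — deep enough that boundary behavior is governed by the
  thresholds, not by count shot noise.
- **Stage effects** — selected lincRNAs and genes receive ±log2FC = 2 stage
  patterns (step or bump across the three stages), recorded per contrast.
- **Target pairs** — cis pairs (same chromosome, span gap < 50 kb) and trans
  pairs (different chromosomes) share a per-sample latent factor. The factor
  loading is calibrated so the *expected* Pearson r on log-FPKM matches the
  configured latent r: `loading² = ρ/(1−ρ) · σ²`, where σ² is the member's
  non-factor log2 variance — negative-binomial noise `(1/μ + φ)/ln²2` *plus*
  the variance of any stage effect already planted on that member. Pair
  genes are drawn from foreground coding genes only: a background
  mass-absorber carries so much of the library that planting a factor on it
  perturbs the per-sample library size itself, which nonlinearly compresses
  its log-FPKM and decorrelates the pair below the configured latent r.
- **QTLs and terms** — trait intervals with a configurable fraction
  overlapping true lincRNA spans, and a gene→term map for enrichment.

Recovery rates at the default thresholds (10 seeds, 20 cis / 10 trans planted
pairs, no stage effects): cis recall 0.97 / precision 0.95, trans recall
0.93 / precision 0.95. Trans recall below 1 is intrinsic: at latent r = 0.99
and n = 9 samples, sampling spread of the realized correlation puts a few
percent of pairs below the 0.96 gate on any given draw.

## Limitations

- **DE detection of pair members.** A feature that is both planted
  differential and a member of a high-latent-r pair is essentially
  undetectable by the DE test: at ρ = 0.99 the shared factor's standard
  deviation is ~10× the count noise, and the factor is within-group variance
  from the test's point of view. This is a property of the planted design
  (shared-factor correlation is modeled as sample-level, not
  stage-structured), so world-level DE sensitivity understates the test's
  power; the dedicated two-group simulator measures the test itself.
- **Pseudocount compression.** Effect sizes on `log2(FPKM + 1)` are shrunk
  for features with base FPKM near or below 1; a 4-fold shift at base FPKM
  0.5 falls below a |log2FC| ≥ 1 gate. This is the usual price of a
  pseudocount that keeps zeros finite.
- **Small-n permutation nulls.** At n = 9, the data-conditional permutation
  distribution of r differs from the unconditional normal-theory null by
  O(1/n); p-values from the t transform describe the latter.
- The coding-potential score is a deliberate single-feature stand-in for
  alignment-based classifiers; it is exact and auditable, not
  state-of-the-art.
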