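# Methods

This note documents the statistical procedures implemented in `metacna`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Copy-number calling from exome coverage

**Log2 ratios.** For each sample, tumor and matched-normal per-target read
counts are scaled to equal totals, a pseudocount `c = 1` is added to guard
zero counts without materially biasing deep targets, and the per-target
ratio `r_i = log2((t_i + c) / (n_i + c))` is median-centered. Total-scaling
makes global ploidy unidentifiable by construction — only relative copy
number is measured. Where a matched normal is missing, a pooled reference
(per-target mean of the total-scaled remaining normals, at least two) is
substituted, mirroring standard matched/pooled ngCGH practice. Sex
chromosomes are removed at ingestion: their coverage ratio is confounded
with patient sex. Coordinates are 0-based half-open internally; SEG export
is 1-based inclusive, converted only at the I/O boundary.

**Segmentation.** Per chromosome, the segmenter recursively searches for
the contiguous window `x[i:j)` maximizing the pooled two-sample t statistic
against its complement — the circular-binary-style statistic, which unlike
a single-cut search can score an interior focal event directly against
both flanks. A split is retained when its within-segment permutation
p-value is below `alpha_split = 0.01` (200 permutations by default; the
permutation loop terminates early once significance is ruled out, which
does not change the decision). Accepted splits recurse into the window and
both flanks; afterwards adjacent segments whose means differ by less than
`merge_delta = 0.1` are merged, so segments always tile the chromosome.
Windows and complements must hold at least `min_targets = 3` targets. The
permutation seed comes from the run configuration, so segmentation is
reproducible. Zero-variance (noiseless) steps score +inf and are recovered
exactly; segmentation is idempotent on its own segment means.

**Calls and QC.** Five-level calls are assigned from segment means with
inclusive thresholds at ±0.2 (gain/loss) and ±1.0 (high-gain /
homozygous-loss); these defaults correspond to roughly a half-copy and a
two-fold change in a diploid background and are configurable. Per-sample
QC reports DLRS — the median absolute difference of adjacent
same-chromosome ratios over √2, a robust per-target noise estimate that is
independent of true copy-number structure — and the fraction of the
segmented genome (in base pairs) carrying a non-neutral call.

## Recurrence (G-score / Q-bound)

For a chosen direction (gains and losses are scored in separate passes),
each region of the union breakpoint grid receives
`G_r = (1/N) Σ_s min(amplitude_rs, 2.0) · event_rs`, the per-sample mean of
capped event amplitudes. The 2.0 cap bounds the influence of extreme focal
amplifications. The null rotates each sample's capped event-amplitude
track by an independent uniform cyclic shift along the grid — preserving
that sample's event burden and segment autocorrelation, a deliberately
conservative null for segmented data — and the empirical p-value is
`(1 + #{G_null,r ≥ G_r}) / (B + 1)`, compared per region against its own
null draws. Benjamini–Hochberg adjustment yields the Q-bound; regions at
q ≤ 0.05 are significant. Maximal runs of adjacent significant regions are
merged into peaks; runs broader than `max_span_bp` (default 10 Mb) are
treated as arm-scale rather than focal and excluded. A post-filter on the
peak G-score is available but off by default, since selecting *low*
G-scores inverts the statistic's intent.

## Group comparisons and power calculus

Unmatched groups are compared per region with the pooled-variance test of
equal proportions with Yates continuity correction (degenerate tables — no
events, identical frequencies — return p = 1); matched pairs use McNemar's
test, exact two-sided binomial on the discordant counts when b + c < 25 and
continuity-corrected chi-square otherwise. The genome-wide scan uses the
two-tailed Fisher exact test (probability mass of tables no more likely
than the one observed, margins fixed), reporting both unadjusted p — with
the conventional 0.005 flagging threshold for exploratory scans — and BH-
adjusted p. Continuity corrections are on by default because the event
counts per region are typically small.

The power calculus uses the per-group normal-approximation sample size

    n = (z_{α/2} √(2 p̄ q̄) + z_β √(p₁q₁ + p₂q₂))² / (p₂ − p₁)²

with the Fleiss continuity correction
`n' = n/4 · (1 + √(1 + 4/(n·d)))²` applied by default (the uncorrected
value is returned alongside). At p₁ = 0.10, p₂ = 0.40, two-sided
α = 0.05/29,736 ≈ 1.7e-6 and 80% power this gives 137 per group — 274
patients in total — which is what makes unadjusted-threshold reporting,
rather than family-wise correction, the honest choice for cohorts an order
of magnitude smaller.

## Survival scan

The log-rank statistic is computed in chi-square form: over distinct event
times, `U = Σ (d₁ − d·n₁/n)` and the aggregated hypergeometric variance
`V = Σ d(n−d)/(n−1) · (n₁/n)(1 − n₁/n)` (ties pooled within event times),
with `χ² = U²/V` and the convention χ² = 0 when V = 0 (the grouping carries
no information, e.g. one group all censored before any event). The
implementation is vectorized over regions as two matrix products per
permutation, so a scan costs O(B·(samples + regions)) rather than
O(B·samples·regions).

Permutation p-values permute the (time, event) *pairs* jointly across
samples — preserving the marginal censoring pattern, the standard reading
of "permuting the survival times" — and compare each permuted statistic
with the observed one at a 1e-9 relative tolerance, so permutations that
reproduce the observed partition (or its complement, mathematically equal
but rounded differently) count as ties; without this the small-sample
permutation p is biased low by up to a factor of two. One shared
permutation stream serves all regions by default, making region p-values
positively coupled but the scan fast; independent per-region streams are a
flag. `B = 1999` by default so the 0.005 reporting threshold is attainable
with resolution 5e-4; regions with fewer than 3 carriers or 3 non-carriers
are reported untested rather than given a meaningless p. The Kaplan–Meier
estimator is the standard product limit with the median defined as the
smallest event time with S ≤ 0.5 (undefined when never reached).

## Lesion response classification

Per-lesion longest-diameter trajectories are classified with inclusive
thresholds: intrinsic resistance (IRES) if the *first* evaluation at or
before week 8 shows ≥ 20% growth over baseline; otherwise any later
measurement ≥ 1.2× the running nadir (baseline included) marks acquired
resistance (ARES) — this also routes late growth without a documented
response to ARES; otherwise partial response (PR) if the nadir reached
≤ 70% of baseline, else stable disease (SD). ARES deliberately takes
precedence over PR/SD when a response is followed by regrowth. All rules
are diameter ratios, so classification is scale-invariant and total.

## Expression concordance

Carriers and non-carriers of an event are compared per gene with a
negative-binomial likelihood-ratio test: per-gene dispersion by method of
moments on library-size-normalized counts, pooled within groups and
floored at 1e-8; group means fitted by Newton iteration on log μ with
library-size offsets; LRT against the common-mean null referred to χ²₁.
The dispersion is estimated once and shared between null and alternative,
which keeps the test calibrated near the nominal level (measured rejection
≈ 0.06 at p < 0.05 on a 20 vs 20 null with dispersion 0.1). Fold change is
the ratio of normalized group means (carriers over non-carriers), so
fc(A,B) = 1/fc(B,A). A gene is concordant when mean AND median RPKM exceed
1 in the higher-expressing group (a flag switches to requiring both
groups; the literal rule is ambiguous on this point and the
higher-expressing-group reading is the default), FDR < 0.1 over the genes
tested in the analysis at hand, and FC strictly beyond 1.5 in the
direction of the event (fc > 1.5 for gains, fc < 1/1.5 for losses).
RPKM = 1e9 · count / (length · library size).

Library sizes default to column totals; when an event region carries a
large fraction of the measured transcriptome, total-count normalization
absorbs part of the dosage effect and biases fold changes toward 1
(composition bias). This matters only for implausibly large regions in
small gene panels — focal regions in genome-wide data are unaffected —
but it is why the concordance tests use focal planted regions.

## Synthetic cohorts

The generator emulates the *shape* of a longitudinal metastasis cohort,
not any particular patient data: defaults of 97 pre-treatment and 43
post-treatment samples; per-target tumor and normal depths drawn
negative-binomial with mean 150 and dispersion 0.05 (Poisson in the
zero-dispersion limit), with carrier targets scaled by 2^log2_shift;
progression times exponential with baseline rate log 2 / 9.7 per month (a
9.7-month median PFS) times the product of carried hazard ratios, censored
by an independent exponential at 0.02/month; expression counts
negative-binomial (dispersion 0.1) around lognormal gene means, scaled by
the dosage multiplier for carried regions; treatment covariates drawn at
70% bevacizumab and a 68/22/10 oxaliplatin/irinotecan/other regimen mix.
Carrier status is Bernoulli per sample and region with timepoint-specific
frequency. Truth labels (region table, carrier matrix) are written to
separate files, never into analysis inputs.

Deliberately not modeled: tumor purity and subclonal fractions, GC/
mappability waves, batch effects, matched primary tumors, raw reads.
Passing recovery tests therefore shows the statistics behave correctly on
idealized signals of realistic size and noise — not that the caller is
robust to the full messiness of real exome data.

The default per-target overdispersion (0.05) is honest about noise:
per-target log2-ratio sd is ≈ 0.49 (DLRS ≈ 0.33). Breakpoint localization
to ±2 targets at ≥ 95% coverage is achievable at low overdispersion
(≤ 0.01 at shift 0.58, where the property test pins it) but not at the
noisy end — at per-target SNR below 1 no change-point method localizes
that sharply, and recovery degrades to ~65%.

## Numerical conventions

- Empirical permutation p-values are `(1 + #exceed)/(B + 1)` and can never
  be 0; they honor the lower bound 1/(B+1).
- BH adjustment is the step-up with cumulative-min monotonicity, mapped
  back to input order; the largest p is never changed.
- Call thresholds are inclusive at their boundary; lesion-rule thresholds
  are inclusive per their "≥" definitions, and the SD bounds strict.
- Segment tie-breaks: the flattened argmax takes the first-best window;
  noiseless ties are resolved deterministically.
- Problem sizes in the test suite (cohorts of 50–120 samples, 1–4
  chromosomes of 20–100 targets, 2000-region null scans, B = 999–9999)
  were chosen as the smallest sizes at which the tested property is
  statistically decidable.

## Known limitations

- No GISTIC2-style peel-off peak deconvolution or separate arm-level
  statistic; broad runs are simply excluded from the focal list.
- The recurrence null's shared grid treats all regions as exchangeable in
  width; very uneven grids make the cyclic-shift null more conservative
  for wide regions.
- The shared permutation stream couples region p-values within a scan
  (their joint distribution is exchangeable but not independent); use
  per-region streams when independence matters more than speed.
- The NB test's moments dispersion is per-gene with no shrinkage across
  genes; for very small groups an empirical-Bayes approach (as in DESeq2 /
  edgeR) would be more powerful.
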