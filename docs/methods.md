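# Methods

## Ratios and detectability

All analyses operate on per-gene expression ratios between two named
conditions of a TPM matrix, computed as

    r_g = (x_g,num + c) / (x_g,den + c)

with a symmetric pseudocount c (default 1 TPM). The pseudocount guarantees
strictly positive ratios for zero-expression genes at the cost of shrinking
ratios of low-expressed genes toward 1; with the default detectability
filter in place (TPM ≥ 1 in ≥ 1 condition) the shrinkage is at most 2-fold
at the detection floor and negligible for well-expressed genes. No
between-sample normalization is applied beyond what TPM already provides:
the pipeline assumes its inputs are comparable, and replicate columns, if
any, are collapsed beforehand with `average_columns`.

Detectability is deliberately a two-parameter rule (`min_tpm`,
`min_conditions`) because "detectable" can reasonably mean detected in one
sample or in all samples; the default (≥ 1 TPM in ≥ 1 condition) is the
most permissive reading, and every report echoes the values used.

## Reversal analysis

Two ratios describe the core comparison: r₁ = perturbed/baseline and
r_T = treated/perturbed. Genes are binned by log₂ r₁ into `n_bins`
(default 14) equal-width bins of width 0.5 over [−3.5, +3.5), lower edge
inclusive, with the outer bins absorbing out-of-range values; the binning
is equal-width because the group count alone does not determine edges, and
a symmetric half-log₂-unit grid covers >10-fold changes on both sides.
Per bin we report the mean of log₂ r_T and its standard error (sample SD /
√n, undefined below n = 2).

The treated response is a pure fold-change rule, not a significance test:
r_T within [0.67, 1.50] (inclusive at both ends) is *not significant*,
above is *increased*, below is *decreased*. Strata on r₁ use strict
inequalities: r₁ < 0.50 is the down stratum ("down-regulated by more than
50%"), r₁ > 2.00 the up stratum ("up-regulated by more than 100%"). A
significant response opposing the stratum direction is interpreted as
*reversed*, one amplifying it as *consistent*, a non-significant one as
*unaffected*; genes outside both strata are *not applicable*. Inclusivity
choices are fixed by design (band edges inclusive, stratum edges
exclusive) and only the numeric thresholds are configurable — making
inclusivity configurable would double the parameter space for no analytic
gain, and ties at the exact edges have measure zero in real data.

Stratum reports give counts and one-decimal percentages per
stratum × interpretation; percentages are relative to the stratum total.

## Trajectory favorability

Three ratios locate each gene's change on the reprogramming trajectory:
r₁ = perturbed/baseline, r₂ = endpoint/baseline (the change the
destination cell state actually requires), r₃ = pre-endpoint/endpoint
(how a stalled intermediate differs from the destination). The classifier
first selects responsive genes (r₁ beyond a strict 2-fold threshold in
either direction) and then applies, in log₂ space with d₁ = log₂ r₁ and
d₂ = log₂ r₂, the default four-way rule in this order:

1. `un_necessary` iff |d₂| < 1 (the endpoint barely moves, so the induced
   change addresses nothing);
2. `opposite` iff sign(d₁) ≠ sign(d₂);
3. `over_regulated` iff |d₁| > |d₂| + 1 (right direction, overshooting);
4. `consistent` otherwise.

Genes missing from r₂ or r₃ are `unclassified` and stay in the
denominator. The unfavorable percentage pools `un_necessary`, `opposite`
and `over_regulated` over the full selected-gene total, reported to the
nearest integer (ties rounded half-up; category percentages likewise).

The 1-log₂-unit endpoint and overshoot margins mirror the 2-fold
convention used everywhere else in the pipeline. The rule function is
pluggable — any callable `(d1, d2, d3, config) -> category` can replace
the default, and reports record the rule name — because the four
categories admit more than one sensible operationalization; in particular
d₃ is exposed to rule functions but unused by the default rule, which is
the simplest rule that uses only the two ratios whose roles are
unambiguous. The time-course variant re-applies responsive-gene selection
at each time point, so each report carries its own responsive-gene count;
a time point with no responsive genes yields a missing report rather than
an error.

## Pathway summaries

For a gene set, the report counts detectable members, the fractions moved
up (r₁ > 1) and down (r₁ < 1) by the perturbation — a ratio of exactly 1
counts in neither, so the two fractions sum to 1 only when no member sits
exactly at 1 — and the fraction whose treated ratio opposes their
perturbation direction. The divergent-gene shortlist keeps members with
|log₂ r₁| ≥ 1.0 and |log₂ r_T| ≥ 0.585 (1.5-fold, the edge of the
not-significant band), sorted by descending |log₂ r₁|; these thresholds
are this package's own defaults and are flagged as such in reports.

The shipped GMT fixture (`tests/data/synthetic_kegg_sets.gmt`) is a
synthetic stand-in with plausible murine symbols at realistic set sizes
(116 oxidative-phosphorylation, 60 glycolysis members); tests assert set
sizes and parsing behavior, never member identities.

## Synthetic generator

The generator is the package's testing instrument: it produces matrices
with the statistical structure the analyses assume, plus ground truth.

* **Baseline**: log₂ TPM ∼ N(3, 2) per gene — a log-normal abundance
  distribution spanning silent to highly expressed genes, the simplest
  positive-valued model for TPM data.
* **Perturbation**: 24% of genes are perturbed (12% down + 12% up by
  default, echoing a genome-wide responsive share of roughly a quarter
  split evenly between directions), with signed log₂ effects of magnitude
  |N(2.5, 0.3)|. Direction is coupled to baseline expression rank through
  a logistic link, logit p(down) = logit p₀ + 4·(−κ)·(2u − 1), where u is
  the baseline rank percentile and κ = `baseline_coupling` (default −0.8):
  negative κ sends highly expressed genes down and lowly expressed genes
  up, reproducing the characteristic perturbation pattern. The slope 4 is
  an internal link constant recorded via the config echo.
* **Treatment**: a Bernoulli(ρ = `reversal_fraction`, default 0.5) subset
  of perturbed genes has `reversal_strength` (default 1.0, full undo) of
  its effect subtracted in the treated column.
* **Endpoint** (attractor mode, default): each perturbed gene draws a
  trajectory category with probabilities consistent 0.34 / opposite 0.28 /
  un-necessary 0.28 / over-regulated 0.10 — normalizing published
  category counts of comparable analyses, with the pooled
  opposite/un-necessary mass split evenly — and its endpoint effect is
  constructed to realize that category (e₂ = d₁, −d₁, 0, or a
  same-direction value smaller than |d₁| by a clear margin). Independent
  mode draws endpoint effects unrelated to the perturbation. The
  pre-endpoint column adds N(0, 0.5) log₂ jitter to the endpoint.
* **Time course**: transient effects (opposite and un-necessary
  categories) ramp linearly from amplitude 0.4 to 1.0 at the programmed
  peak index and decay to 0.1 by the last time point, while persistent
  effects hold amplitude 1.0 throughout; the unfavorable share of
  responsive genes therefore peaks exactly at the programmed index, which
  is what the recovery test asserts.
* **Noise**: every measured cell is multiplied by 2^N(0, `noise_log2_sd`)
  (default 0.2) independently — multiplicative log-normal measurement
  noise.

Everything is drawn from one `numpy` generator seeded by `seed`, so output
is bit-reproducible per seed.

What the generator does **not** emulate: count overdispersion (it works in
TPM, not reads), gene–gene correlation, compositional coupling between
TPM values, batch structure, or cell-population heterogeneity. Passing
recovery tests therefore demonstrates that the classifiers invert the
generative model they were designed for at realistic noise, not that real
bulk RNA-seq satisfies that model.

## Numerical and reporting choices

* Matrix TSV round-trips at full float64 precision (`%.17g` on write,
  round-trip float parsing on read).
* Binning uses half-open intervals, lower edge inclusive; a log₂ ratio of
  exactly 0 falls in the first bin whose interval contains 0.
* Headline percentages round to the nearest integer, detailed report
  percentages to one decimal, both half-up.
* Reports are JSON with sorted keys and no timestamps; re-running any
  stage with identical inputs reproduces identical bytes.
* The pipeline logs gene-count conservation (input = retained + filtered)
  at the detectability step and propagates stage errors with the stage
  name attached. Exit codes: 0 success, 2 validation error, 1 runtime
  error.

## Problem sizes

Recovery analyses run at n = 2000 genes (≈ 480 perturbed), 10–20 seeds per
condition: large enough that the binomial standard error of the
reversed-fraction estimate (≈ 0.02) cleanly separates the tested ρ values
0.2 / 0.5 / 0.8, small enough to keep the whole suite interactive. The
recovery tolerance is three single-run binomial standard errors,
√(ρ(1−ρ)/n_perturbed), applied to the across-seed mean.

## Known limitations

* The four-way rule is one defensible operationalization; analyses whose
  category definitions differ (for example rules that use d₃) need a
  custom rule function.
* Pseudocounting biases ratios of near-floor genes toward 1, which at
  noise SD 0.2 converts a small share (~2%) of truly unaffected genes into
  apparent reversals and hides reversals of barely detectable genes; the
  recovery tests quantify the net effect.
* No multiple-testing machinery: the N/S band is a fold-change rule by
  design, and callers wanting significance tests should compute them
  upstream and intersect.
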