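# Methods

## The model

Gene expression over a reprogramming time course is modelled as a linear
function of derived combination variables — products of the three Oct4
binding-peak characteristics with fixed functions of developmental time
*t* (in days, the literal values {0, 1, 3, 5, 7, 11, 15, 18}, never a rank
index):

```
Exp(g, t) = β₁·H·eᵗ + β₂·D·f(t) + β₃·W·log₁₀(t+1) + ε,
```

with f(t) one of {t, t², t³, 0.5ᵗ} (Models 1–4).  The disturbance ε is
assumed normal; its location is estimated as the fitted intercept (so each
fit reports one ε number) and its dispersion as the residual standard
deviation √(RSS/(n−k−1)).  The full candidate set V for selection holds
all 18 products of {H, D, W} with {t, t², t³, eᵗ, 0.5ᵗ, log₁₀(t+1)}.

Assumptions worth stating explicitly: expression depends on the
*strongest* promoter peak only; records are treated as independent across
genes and days (no autocorrelation or per-gene random effects); the
disturbance is homoscedastic on the modelled scale.

## Peak features and coordinates

Coordinates are 0-based half-open throughout (native bedGraph/BED).  The
promoter window is [TSS − 1500, TSS + 500) on `+` and the reflection
[TSS − 500, TSS + 1500) on `−`.  From the strongest peak (maximal height;
ties broken by distance to TSS, then leftmost start — deterministic in
input order):

* H = maximum signal over the peak,
* W = end − start,
* D = |floor((start+end)/2) − TSS|, **unsigned**: the minimal reading of
  "distance to the TSS", and it keeps D ≥ 0 in the D·f(t) terms.

"Midpoint" is the geometric centre of the peak interval, not the summit;
the summit is retained on the `Peak` type for diagnostics.  Genes without
a qualifying peak at a timepoint are dropped from that timepoint with a
warning.  When peaks must be derived from a signal track, a peak is a
maximal run of contiguous intervals with value ≥ `min_height` (default
1.0 signal unit, configurable; synthetic pipelines use a smaller threshold
when a decaying height law pushes peaks below 1).

## Numerical choices in the fit

The design spans an enormous dynamic range (H·eᵗ ≈ 6.6·10⁷·H at day 18),
so `fit_lsm` normalises every column (including the intercept) to unit
Euclidean norm, solves by QR, and back-transforms coefficients and
standard errors to the raw scale.  Rank deficiency is detected on the R
factor at a tolerance of `max(n,p)·eps` relative to the largest diagonal
and reported with the offending column's name.  The normal equations are
never formed.  The intercept is always included by default; a
no-intercept mode exists but voids the TSS = ESS + RSS identity and warns.

Inference uses centred sums of squares (TSS = Σ(Yᵢ−Ȳ)², ESS = Σ(Ŷᵢ−Ȳ)²,
RSS = Σ(Yᵢ−Ŷᵢ)²) and the standard overall F statistic
F = (ESS/k)/(RSS/(n−k−1)) with the F(k, n−k−1) null — the only scaling
consistent with that reference distribution.  A variant that scales by
TSS/(n−k−1) instead is available behind `tss_denominator=True` for
comparison but carries no calibrated p-value.  Coefficient t tests are
two-sided on n−k−1 degrees of freedom.  Degenerate cases are explicit:
RSS = 0 reports F = ∞, p = 0; ESS = 0 reports F = 0, p = 1; zero residual
degrees of freedom disables inference with a warning rather than emitting
NaNs silently.

## Stepwise selection

Bidirectional stepwise from the intercept-only model.  Candidates are
ranked by |t| of the entering coefficient (equivalent to the partial F,
and immune to p-value underflow when the signal is strong — with ~10⁴
signal-to-noise the naive p of every correlated candidate rounds to 0 and
an alphabetical tie-break would admit junk).  Two criteria:

* `pvalue` (recommended): the best candidate enters if its p-value,
  Bonferroni-adjusted for the number of candidates examined at that step,
  is below `alpha_enter` (0.05); terms are removed when their unadjusted
  p exceeds `alpha_remove` (0.10).  The adjustment holds the familywise
  false-entry rate near α across the ~16 inactive candidates; without it
  the expected false-entry rate at the stopping step is 1−0.95¹⁶ ≈ 0.56
  and exact recovery of a true active pair would be the exception, not
  the rule.
* `aic`: plain Akaike comparison, deliberately liberal (each extra null
  term is accepted with probability ≈ P(χ²₁ > 2) ≈ 0.16, and the minimum
  over many candidates makes overselection likely).  Kept as the familiar
  default for exploratory use; the exact-recovery guarantees quoted in
  the tests hold for the `pvalue` mode.

Ties break alphabetically, so selection is deterministic given the input.

## Classification protocol

A sample is one (gene, day) record.  The 30%-quantile rule sorts
expressions in descending order, labels the top m = ⌊0.3·n⌋ high and the
bottom m low, and takes the m-th largest value as the threshold; any value
≥ threshold is called positive.  The middle band can either inherit
labels from the threshold rule or be excluded (strict-extremes mode —
what the synthetic protocol uses, giving balanced classes and a chance
level of exactly 0.5).

Cross-validation (default k = 10, seeded shuffle, fold sizes differing by
at most one) refits the pooled regression *and recomputes the threshold*
on the training folds only; confusion counts are pooled across folds
before metrics (Acc, Sn, Sp, Mcc) are computed — the more stable
convention at n ≈ 200.  Mcc with a zero marginal is reported as 0 with a
degenerate flag rather than NaN.

The baseline is a feedforward network with one hidden layer of two
sigmoid units and a sigmoid output, trained by full-batch gradient
descent on mean-squared error (learning rate 0.1, 2000 epochs, weights
initialised U(−0.5, 0.5) from the run seed, inputs min-max normalised
per column).  Final training loss above 0.24 is flagged as
non-convergence, never fatal.  It shares the exact fold assignment with
the regression classifier.

Min-max normalisation of (H, D, W, Exp) is applied by default in the
pipeline's classify stage, mirroring the application protocol for real
data.  Note that record-level normalisation breaks the exact product
structure of the basis (it injects a pure eᵗ component no regressor can
represent), so the synthetic benchmark protocol evaluates on raw records,
where the generative model is exactly representable.

## The synthetic generator

`generate_timecourse` draws per-gene features — H₀ ~ U[1, 10] signal
units, W ~ U[50, 500] bp, D ~ U[0, 1500] bp clamped so the whole peak
fits inside the promoter window (clamps recorded in the truth metadata) —
evolves them under a chosen law (constant; exponential height decay
H₀e^(−0.1t); logarithmic width growth), and emits Exp from the Model-4
form with β = (0.5, −0.3, 1.2), intercept 0.1 and Gaussian noise.  These
marginals are generator conventions chosen to span realistic ChIP-seq
peak geometry; they are not measured quantities.  `write_genomic_artifacts`
places gene *i* at TSS 10000·(i+1) on one synthetic chromosome with
alternating strands and writes one rectangular bedGraph peak per (gene,
day), printed with `repr` so every float round-trips exactly; the
extraction pipeline must reproduce (H, D, W) bit-exactly, and does.

`generate_classification_set` builds two gene populations whose
deterministic expressions differ by `separation · σ`.  The high
population holds a 30% share of genes so that, at strong separation, the
quantile labels coincide with population membership and every training
threshold falls inside the inter-population gap — without this the
threshold cuts inside the high population's noise distribution and no
classifier can be exact.  Within each population the deterministic
expression is flat across days (the height trajectory is solved from the
target level, with a 5%-of-σ jitter keeping the design full rank), which
makes the null case (separation 0) genuinely unpredictable: labels are
then pure noise and cross-validated accuracy sits at the 0.5 chance
level.  What passing these benchmarks does *not* show: real binding data
have correlated features, non-Gaussian noise, missing timepoints and
overlapping peaks from neighbouring genes, none of which the generator
emulates.

## Problem sizes

The test and acceptance workloads use 30 genes × 8 days for recovery
(200 replicates; 500 for interval coverage), 2000 null simulations for
F-test calibration, 100 stepwise runs, three 10-gene round-trip datasets,
and 20-seed sweeps of the 27-gene classification protocol — sizes at
which every quantity of interest is stable to well within its tolerance.

## Known limitations

* Per-gene fits at n = 8 leave 4 residual degrees of freedom; their
  t-based inference is exact under normality but fragile to outliers.
* The pooling rule for across-gene fits is a plain pooled regression; no
  per-gene random effects are offered.
* No regularised variants; the eᵗ regressor makes extrapolation beyond
  day 18 meaningless.
* The GEO-deposited source data behind the original study are not
  downloaded or processed here; real inputs enter through the documented
  bedGraph/narrowPeak + BED6/GTF + TSV interface.
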