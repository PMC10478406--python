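# Methods

This note documents the statistical model, the extraction rules, the
synthetic-data generator and the numerical choices behind `auccaliper`,
including the places where the design was genuinely open and what the
package chose.

## The smooth-null model

The analysis object is the histogram of reported AUC values in 100
half-open bins `(k/100, (k+1)/100]`, k = 0..99. The half-open
convention matters at the thresholds: a value of exactly 0.70 belongs
to (0.69, 0.70], so threshold-equal values count *below* the threshold
and the bin just above, (0.70, 0.71], is untouched by them.

The null hypothesis of no threshold-targeting is that the bin counts
follow a smooth intensity. We model counts with a Poisson GLM (log
link) on an intercept plus a natural cubic spline of the bin midpoints
with 4 degrees of freedom: three interior knots at the 25th/50th/75th
percentiles of the midpoints entering the fit, boundary knots at the
extreme midpoints, and linearity constraints beyond the boundary. The
basis is the classical truncated-power construction; the fit is
iteratively reweighted least squares (delegated to statsmodels' GLM)
with convergence at a relative deviance change below 1e-8 or 100
iterations. Because the intercept is in the model, the Poisson score
equations force the fitted counts to sum to the observed counts, so
residuals always sum to ~0 over the fitted bins.

Residuals are defined as **observed − fitted**: an excess of values in
a bin is a positive residual. (The opposite sign convention appears in
some descriptions of this method; we fix the sign so that "excess above
the threshold" is literally a positive number, and report it alongside
the descriptive convenience `excess_ratio_above = observed/fitted`.)

Values printed with a single decimal place ("0.8") are excluded from
the histogram by default: rounding alone would pile them onto the
thresholds and mimic the signature under study. They are still
extracted and counted, so the exclusion is auditable.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `df` | 4 | spline degrees of freedom (excluding intercept) |
| `thresholds` | 0.7, 0.8, 0.9 | bins reported: (t−0.01, t] and (t, t+0.01] |
| `fit_domain` | all 100 bins | optionally restrict the fitted bins, e.g. `(0.5, 1.0]`, when the data occupy only part of the scale |
| `roles_included` | `{point}` | CI limits are analysed separately by switching to `{ci_lower}` or `{ci_upper}` |

A df of 4 is deliberately stiff: the smooth must not be able to chase a
one-bin excess, otherwise residuals would absorb the signal. Whether
the covariate is the bin midpoint, lower edge or index is immaterial
for fit quality on an equally spaced grid (affine reparameterisation);
we use midpoints.

## Extraction rules

Numbers are claimed by the nearest statistic cue to their left within a
250-character window. The window does not cross into a sentence that
has its own statistic cues, and a cue can reach at most one sentence
forward. Competing cues (sensitivity, specificity, accuracy, Brier,
predictive values, ratios, ...) block a claim — the main source of
false positives in abstracts that list many statistics. Further guards:

* numbers followed by measurement units (`ng·h/mL`, `mg`, `h`, ...) and
  acronyms with pharmacokinetic subscripts (`AUC0-24`, `AUCinf`) are
  rejected — pharmacokinetic "AUC" is drug exposure, not discrimination;
* sentences that define the AUC scale ("ranges between", "values
  between ... were considered acceptable") yield nothing;
* percent values are divided by 100; a bare number in (1, 100] is only
  treated as a percent when the sentence gives percent context,
  otherwise it is rejected rather than silently rescaled;
* after normalization, values < 0 or ≥ 1 are dropped. Values of
  exactly 1 cannot be reliably distinguished from scale references, so
  "an AUC of 1" is never extracted;
* `a (95% CI b to c)` and the variants `(b–c)`, `(b, c)`, `[b to c]`
  classify as point/lower/upper. Reversed limits are kept as printed
  and flagged `ci_reversed`; if one limit is dropped by the range
  filter the survivor is flagged `out_of_range_partner`.

Decimal places are counted on the printed token; percent tokens get two
extra places so "80%" is comparable to "0.80". The convention is
applied after deciding percent-ness but the count always refers to the
printed form.

All cue lists, guard lists and the window length live in a single
declarative YAML file (`auccaliper/data/default_config.yaml`); every
rejected candidate carries a machine-readable reason code, making the
extractor auditable end to end. The design leans deliberately toward
missing unusual presentations rather than including wrong numbers.

## The synthetic-data generator

The generator defines the study conditions for every simulation-based
test. One corpus consists of abstracts with:

* a per-abstract value count from a geometric distribution with
  p = 0.35 (median 2 values, quartiles 1 and 4 — typical of abstracts
  that compare several models);
* true AUC values drawn from a smooth base density on (0, 1);
* a **promotion** mechanism standing in for hacking: a value in
  (t − δ, t] is, with probability h, replaced by a uniform draw from
  (t, t + ε]. Defaults δ = 0.03, ε = 0.01. This is the minimal
  mechanism that produces the predicted signature — deficit just below,
  excess just above — without committing to any specific re-analysis
  behaviour;
* reporting styles in fixed proportions: plain point values 0.68,
  point-with-CI 0.22 (which makes CI limits ≈ 31% of all rendered
  values), percent 0.08, one-decimal 0.01, exactly-one 0.01;
* decoy content (pharmacokinetic sentences with units,
  sensitivity/specificity lists, scale-definition sentences, plain
  filler), a fraction of abstracts with no AUC at all, and small
  fractions of pharmacokinetic studies, meta-analyses and ultra-short
  notes that exercise the exclusion cascade;
* a MEDLINE-dialect XML serialization that round-trips through the
  parser, so tests can run the full pipeline from bytes.

### Choice of the base distribution

The base density must be *smooth in the sense of the analysis model*:
under h = 0 the histogram has to be representable by the df = 4 Poisson
spline, otherwise lack-of-fit bias at the threshold bins would be
indistinguishable from a planted signal. Closed-form families fail
this requirement quantitatively: for scaled Beta or truncated-normal
bases the deterministic lack-of-fit at threshold-adjacent bins is
roughly 8–40 times the Monte-Carlo standard error of the calibration
studies (200 replicates × 20,000 values), i.e. the null would appear
systematically miscalibrated for reasons that have nothing to do with
threshold behaviour.

The default base is therefore **log-spline**: density ∝ exp(g(x)) with
g a natural cubic spline on exactly the knot vector the analysis uses,
with coefficients least-squares-matched to a truncated normal (mode
0.75, sd 0.12) for a realistic unimodal shape. Any coefficient vector
keeps the null inside the model family (up to a bin-integral vs
midpoint correction of order w²/24, measured at < 0.05 counts per bin
at n = 20,000 — two orders of magnitude below sampling noise). A
scaled-Beta family remains available (`base_family="scaled_beta"`) for
robustness experiments, with the caveat above.

Sampling is by inverse-CDF interpolation on a 4,096-point grid —
smooth, atom-free, and deterministic under a seeded generator.

### What the generator does not emulate

Rendered abstracts are templated, not linguistically realistic; real
abstracts present statistics in open-ended formats the extractor will
miss (its design accepts that, preferring precision). Real AUC
distributions mix eras, specialties and journals and need not resemble
any single smooth density; publication bias is not modelled as a
separate mechanism. Passing tests therefore demonstrate that the
pipeline recovers what it is designed to recover under controlled
conditions — not that extraction recall on real PubMed text equals the
synthetic value.

## Validation statistics

Presence/absence agreement between extractor and manual annotation is
summarised by NPV and PPV with the denominators conditioned on the
algorithm's call, and exact Clopper–Pearson 95% intervals (beta-quantile
form; the method reproduces the canonical limits 0.964 for 100/100 and
0.946 for 99/100 exactly, which is the reason it was chosen over
approximate intervals). Per-abstract count differences (algorithm −
manual, over abstracts where either found a value) are summarised by
Bland–Altman limits of agreement, mean ± z·sd with sd on n − 1 degrees
of freedom, and 90% coverage by default (z = 1.6449).

## Numerical choices and degenerate inputs

* Bin membership uses `ceil(100·v − 1e-9) − 1` so exact edge values
  land in their closed-upper bin despite floating-point noise.
* A value of exactly 0 has no bin on (0, 1] and raises; the upstream
  range filter cannot emit it from text, so this only concerns direct
  API use.
* All-zero histograms and fits with fewer than df + 2 bins raise;
  non-convergence returns the fit flagged `converged=False`.
* Unicode dashes and NBSP are normalized 1:1 (offset-preserving) before
  extraction; thousands separators are stripped at the token level.
* Promotion landings use `t + ε·(1 − U)` with U ∈ [0, 1), keeping the
  landing strictly inside (t, t + ε].
* Simulation studies use the generator's value layer directly
  (continuous values, no printing/rounding); the text layer rounds
  values to 2–3 decimals for rendering, which is an extraction concern,
  not a distribution-analysis one.

## Problem sizes

The shipped calibration and power studies use 200 replicates × 20,000
values (null) and 100 replicates × 50,000 values (signal, h = 0.3), and
the default synthetic corpus holds 5,000 abstracts. These sizes give
Monte-Carlo standard errors small enough that calibration failures of
practical size would be visible, while keeping the full suite fast
enough to run routinely.

## Known limitations

* The extractor's grammar is a reconstruction of behaviours described
  for this class of text-mining problems, validated behaviourally on
  the synthetic corpus; real-world recall will be lower and should be
  estimated by manual annotation on the corpus of interest (the
  `validate` subcommand exists for exactly that).
* The residual analysis is descriptive; no formal discontinuity test is
  computed. With df = 4 the smooth cannot absorb one-bin excesses, but
  systematic misfit of real data (which need not be log-spline) will
  leak into residuals everywhere, so residuals at thresholds should be
  read against the residuals at neighbouring bins.
* Histogram conservation is defined over values in (0, 1); the pipeline
  never emits values outside that range.
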