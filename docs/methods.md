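# Methods

`creawell` re-implements, as a reusable and tested pipeline, the measurement
and inference chain of a cross-sectional cohort study of schizotypal traits,
creative potential and wellbeing in adolescents and young adults: bespoke
creativity-task and questionnaire scoring, dual frequentist–Bayesian
correlation with a triangulation criterion, and age-adjusted partial
correlations — exercised end to end on a synthetic cohort generator, because
the original raw data are not publicly deposited.

## Measurement models

### Alternate Uses Task (AUT)

Participants list non-normal uses for three objects (bucket, comb, belt),
two minutes each. For a scoring sample of `N` participants, the *relative
frequency* of a use is (number of participants giving it) / `N` — computed
within an item, with the denominator including participants who gave no
response for that item, and with duplicate tokens within one participant
counted once. Three indices:

- **Fluency** — mean valid-response count over the three items. A valid
  response is any non-empty token after canonicalization (lower-casing,
  whitespace collapsing, optional synonym map). The study's human-rater
  judgement of whether a use is genuinely non-normal is not modelled; this
  divergence is deliberate and documented here.
- **Overall originality** — per item, one minus the mean relative frequency
  of the participant's uses; averaged over items with at least one response.
  Bounded in [0, 1 − 1/N]; a participant with no responses anywhere is
  missing (propagated by pairwise deletion downstream, while fluency scores
  0 and peak originality 0).
- **Peak originality** — the count, totalled across the three items, of
  uses given by 10% or less of the sample (inclusive threshold, compared
  exactly on participant counts). A total rather than an average: published
  descriptives (peak mean 5.21 alongside per-item fluency 4.91) are only
  consistent with a three-item total.

### Other measures

- **OKC** (overcoming knowledge constraints): 3 minus the number of
  example-primed drawing elements present (four limbs, two antennae, tail);
  higher = less constrained.
- **Leisure engagement**: per domain, the sum over endorsed activities of a
  days-per-week weight (less than once 0.5; 1–2 days 1.5; 3–4 days 3.5; 5–6
  days 5.5; every day 7). Only creative hobbies enter the analysis.
- **SWLS-C** (5 items, 1–5): item mean. **SPANE** (12 items, 1–5): positive
  and negative 6-item sums. **MHC-SF** (14 items, 6 categories coded 0–5):
  item mean. **SPQ-BRU** (32 items, 1–5): nine 3–4-item subscale sums;
  cognitive-perceptual (ideas of reference, suspiciousness, magical
  thinking, unusual perceptions), interpersonal (no close friends,
  constricted affect) and disorganized (eccentric behaviour, odd speech)
  factor sums; and a total over all 32 items. The total spans all nine
  subscales including social anxiety — the three factor means fall short of
  the published total mean by exactly one subscale's worth. Mean- vs
  sum-scoring per instrument was chosen to match the magnitudes of the
  published descriptives.
- The exact SPQ-BRU item→subscale map and the SPANE item partition are
  configuration inputs. The defaults follow the instruments' published
  structure with sequential item numbering and are **not verified against
  the emulated study's administration**.
- Missing items are never prorated: any missing item voids the instrument's
  score for that participant, producing instrument-level missingness.
- **Cronbach's alpha**: `k/(k−1) · (1 − Σ var_i / var_total)` with sample
  (n−1) variances on complete cases; undefined (flagged) at zero total
  variance. A reverse-coding hook exists but no instrument here uses it by
  default.

## Dual inference

Each of the 78 variable pairs is assessed on its pairwise-complete cases:

- Pearson `r` with the two-sided p from `t = r·√((n−2)/(1−r²))` on `n−2` df.
- The default two-sided Bayes factor for a correlation,
  `BF10 = ∫ f(r|ρ,n) π(ρ) dρ / f(r|0,n)`, with `f` the exact sampling
  density of the sample correlation (Gauss-hypergeometric form) and `π` the
  stretched-beta prior of width `κ` (default `κ = 1`, i.e. uniform on
  (−1,1) — the documented default of the common desktop Bayesian-statistics
  tools). Because `f` depends on the data only through `(r, n)`, `BF10` is
  computable from summary statistics alone, which is what makes the
  published values desk-reproducible. The implementation integrates by
  adaptive quadrature (absolute tolerance 1e−8, hard failure on
  non-convergence); an analytically integrated closed form
  (`bf10_closed_form`) serves as an independent cross-check and agrees to
  ≤1e−6 relative error over a wide (r, n) grid.
- **Triangulation**: a pair is *supported* only if `p < 0.05` **and**
  `BF10 > 3` (strict inequalities); `p < 0.05` with `BF10 ≤ 3` is *partial,
  frequentist-only*. No multiple-testing correction is applied by default —
  triangulation is the error-control device; a Benjamini–Hochberg utility is
  provided but excluded from default reports. Evidence labels follow the
  conventional bands (anecdotal to 3, moderate to 10, strong to 30, very
  strong to 100, extreme above; reciprocal bands below 1).
- Supported pairs are re-assessed as first-order partial correlations
  controlling for age, `r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))`,
  on listwise-complete cases with p on `n−3` df. The stability screen
  compares each partial with the zero-order r recomputed *on the same
  listwise case set* and flags |Δ| > 0.040 as age-influenced (boundary
  inclusive on the "within" side). With a perfectly collinear covariate the
  formula is 0/0; its limit 0 is returned with an explicit flag.

## Synthetic cohort generator

No generative model is published for this study, so the generator uses the
simplest structure able to reproduce Pearson-correlation targets for scores
that are all sums/means of ordinal items or counts: a latent multivariate
normal over the 13 analysis variables with a configurable target correlation
matrix (default: the published zero-order structure, eigenvalue-clip
repaired to the nearest valid correlation matrix), plus observation layers:

- **Likert items**: item = `a·latent + √(1−a²)·noise` (default loading
  `a = 0.7`), discretized at per-scale-group cut-points. Cut-points are
  calibrated at configuration time by 1-D root finding so the population
  item mean (hence the score mean) equals its target exactly; the item SD
  parameter is set from the target score SD under an exchangeable-items
  approximation and only the means are guaranteed.
- **AUT**: per-item response counts Poisson with rate
  `4.91·exp(s·latent − s²/2)` (`s = 0.17`, set so the fluency-score SD
  is near the published 1.54); tokens drawn without replacement from a
  60-token per-item lexicon with Zipf weights (exponent 1.1, participant
  exponent tilted by the originality latents, tilt 0.35), via Gumbel top-k
  sampling. With these defaults roughly the top eight lexicon ranks are
  "common" (>10% of the sample) and the tail provides peak-original uses at
  a realistic rate. Overall and peak originality are *emergent* from this
  mechanism and are not mean-calibrated: no coherent published target exists
  for a score bounded in [0, 1).
- **OKC**: each element present with probability 0.47 (probit-driven by the
  negated OKC latent), giving a reversed-score mean of 1.59 exactly.
- **Leisure**: creative-domain activity count Poisson-modulated by the
  hobbies latent, with i.i.d. frequency categories; the rate is calibrated
  so the expected creative score is 6.99. Counts×weights reproduces the
  strong right skew of real leisure scores (published SD ≈ mean); higher
  moments are not otherwise matched.
- **Missingness**: instrument-level MCAR (whole instruments, never single
  items), default rates emulating the published pairwise-n pattern (SPANE
  4/76, MHC-SF 1/76, SPQ 4/76).
- **Demographics**: three age cohorts (16.76±0.28 at 50%, 18.82±0.39 at
  26%, 21.15±0.44 at 24%, clipped to cohort ranges) and the cohort's gender
  mix.

One root seed drives a seed-sequence split in a fixed order (demographics →
latents → items → AUT → missingness, with named substreams inside the item
stage), so identical configs give byte-identical bundles and adding stages
cannot perturb earlier draws.

Discretization and task noise attenuate scored correlations below their
latent targets. An optional calibration step (`calibrate_scored_rho=True`,
off by default) estimates per-variable attenuation factors from an
independent-latents probe cohort and inflates the latent targets
accordingly. Generator validation therefore uses *self-consistency*: the
scored correlation at n=5000 is compared against the value the same
generator+scoring path produces at n=100,000 (Monte-Carlo SE ≈ 0.003,
negligible against the ±0.04 acceptance band), with those large-n
predictions frozen in the test suite.

### What passing tests do and do not show

The generator emulates the *statistical shape* of the study's data — score
ranges, means, missingness pattern, and a controllable correlation
structure. It does not emulate free-text responses (tokens are coded IDs),
rater validity judgements, item-level missingness, longitudinal structure,
or higher moments beyond the leisure skew. Pipeline correctness established
on synthetic cohorts therefore transfers to real data only for the scoring
and inference logic, not for any substantive claim about the constructs.

## Numerical choices and degenerate inputs

- BF quadrature: `scipy.integrate.quad`, tolerance 1e−8, limit 200;
  |r| = 1 is refused for the BF (and returns the smallest positive double
  as the p-value limit, flagged).
- Pearson r clipped to [−1, 1] against floating-point overshoot; pairs with
  n < 3 or zero variance are flagged missing, never silently dropped.
- The matrix repair returns already-PSD inputs unchanged (tolerance
  −1e−12 on the smallest eigenvalue); otherwise eigenvalues are clipped at
  zero and the matrix rescaled to unit diagonal.
- Display rounding (r 3 dp; p 3 dp with "<0.001"; BF 2 dp with ">100") is
  applied only at render time; all stored values keep full precision.
- Problem sizes in the default suite: calibration and recovery checks use
  n=5000 cohorts; the null (type-I) check uses 1000 cohorts of n=72 with a
  single variable pair, chosen to keep the full suite fast while leaving the
  binomial error of the rate estimate (3 SE ≈ 0.021) well inside the margin
  being tested.

## Known limitations

- The SPQ/SPANE item maps are plausible defaults, not study-verified.
- Scored correlations are attenuated relative to latent targets unless the
  optional calibration is enabled; the default configuration therefore
  reproduces the published correlation structure only qualitatively.
- Zero-AUT-response participants are indistinguishable, in the CSV
  interchange, from participants who skipped the task; the pipeline treats
  participants absent from the AUT table as missing on all three AUT
  indices (under default settings everyone responds, so this edge is
  practically unreachable at study scale).
- Bayes factors are reported for zero-order correlations only; partials are
  assessed frequentist-only, and no posterior/credible intervals for ρ are
  provided, matching the analysis being emulated.
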