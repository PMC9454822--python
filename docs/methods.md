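# Methods

This note records the scientific and numerical choices behind the package:
what is computed, under which conventions, and what the synthetic-data
tests do and do not establish.

## The surprisal proxy

SP treats the reference lexicon as the prior over word frequencies and the
study list as the observation. For the word at position *i* with frequency
*f* (occurrences per million):

1. **Interval.** The upper bound is *f*; the lower bound is the highest
   frequency among already-presented words that does not exceed *f*. When
   no such word exists, the fallback is the lexicon's minimum frequency
   (`lower_bound_mode="lexicon_min"`, the default) or the first presented
   word's frequency capped at *f* (`"first_word"`, the variant relevant to
   pure lists, where it makes the first word's SP degenerate by
   construction).
2. **Counting.** *C* is the number of lexicon words inside the interval,
   **closed on both ends**. The printed reference values cannot
   disambiguate the boundary convention; closed intervals are used
   everywhere, and the acceptance machinery injects known counts so the
   convention cannot corrupt the checks.
3. **Tie groups.** A maximal run of immediately consecutive list words
   with the exact same frequency counts as one event of size *m*; all its
   members share one SP record. Grouping looks ahead over the whole list —
   it is a property of the list composition, not of the presentation
   prefix so far.
4. **Value.** SP = log10( sqrt(C/T) · W / (m/n) ). The log base is 10,
   hard-coded: back-computing the embedded worked example yields 1.54 only
   in base 10 (natural log would give ≈ 3.55).

Degenerate cases — zero interval width (a repeated frequency presented
non-consecutively, or a word at the lexicon minimum with no smaller
predecessor) or an empty interval — yield SP = −∞ with a flag, not an
error. List words below the lexicon minimum are an error unless
`clamp_low` is set, in which case the interval collapses and the value is
flagged degenerate. `n_override` lets a scored prefix use the full list's
length in the m/n term, which is how the six-word worked example (a prefix
of a 30-word list) reproduces exactly.

SP is a proxy statistic computed by the analyst; no claim is made that
participants compute it.

## Lexicon modelling

- **Zipf fit.** Words are ranked by descending frequency (ties broken
  lexicographically; ranks stay 1..N) and freq(r) = a·exp(−b·r) is fitted
  by nonlinear least squares on the raw frequency scale, with R² = 1 −
  SS_res/SS_tot on that scale. A log-scale linear fit is available behind
  `scale="log"` since the fitting scale of the reference analyses is not
  determinable. Note a caveat discovered while testing: because ranking
  sorts the data, *any* sample yields a monotone curve that an exponential
  tracks to R² ≈ 0.95; a flat (non-Zipfian) pool is better diagnosed by
  b·N ≪ 1 (no decay across the whole rank range) than by a low R².
- **Binning.** The frequency range is split into k (default 10) bins of
  equal log10 width, half-open on the right with the last bin closed, so
  each word falls in exactly one bin and counts conserve the total. A
  single-frequency lexicon falls back to one unit-width bin.
- **Distribution discrepancy.** The Bayes factor compares H1 ("the pool's
  bin distribution differs from the language's") to H0 (multinomial at the
  lexicon's bin proportions). H1's marginal likelihood uses a symmetric
  Dirichlet(α = 1) prior — uniform over the simplex; α is exposed for
  sensitivity analysis. A reference bin with probability 0 but observed
  mass makes BF10 = +∞, flagged. The closed form is validated against a
  Pólya-urn enumeration over all bin-assignment sequences.

## Mixed-model inference

- **Likelihood.** Per subject, the product of Bernoulli-logit terms is
  integrated over u ~ N(0, ψ) by fixed-node Gauss–Hermite quadrature on
  the standardised effect, default 21 nodes. 21 nodes give ≈ 1e-10
  agreement with brute-force numeric integration at ψ ≈ 0.35, degrading to
  ≈ 4e-6 at ψ = 2.25; doubling the nodes on the default scenario moves the
  log-likelihood by < 1e-4. Adaptive (per-subject-centred) quadrature is a
  documented trade-off left out of scope.
- **Parameterisation.** ψ = exp(2·log σ) keeps the variance non-negative;
  estimates with σ below 1e-4 are reported as ψ = 0 with a boundary flag
  (and the fixed-effect fit then equals the plain-GLM fit). Optimisation
  is L-BFGS-B over (γ, log σ) with the analytic gradient (the γ-gradient
  is the posterior-node-weighted Bernoulli score; the log σ gradient
  reuses the same weights), tolerance 1e-8 on the log-likelihood.
- **Start values.** γ starts at the ψ = 0 GLM solution; σ starts at 0.5
  rather than near zero because ∂loglik/∂log σ vanishes as σ → 0 (the
  likelihood depends on σ² to first order), which can stall quasi-Newton
  steps on the boundary.
- **Standard errors** come from the observed information (finite
  differences of the analytic gradient at the optimum).
- **Separation** is flagged (not errored) when coefficients are extreme or
  every response is fitted past 0.99/0.01.
- **BIC** uses k = number of fixed effects + 1 for ψ and n = number of
  trials (the convention of the mixed-model software family this analysis
  style comes from; the alternative n = subjects would shift every BIC by
  k·(ln n_trials − ln n_subjects) but not the within-zoo ordering here,
  since all models share the grouping).
- **Bayes factors.** BF10 = exp((BIC_ref − BIC_alt)/2), posterior
  BF10/(1+BF10) under equal model priors.
- **Pruning** removes one predictor *family* per step (a descriptor's
  linear and quadratic terms, and any interaction touching it, leave
  together), keeps protected families (typically the order polynomial),
  moves to the best single-removal candidate whenever it does not increase
  BIC, and breaks ties (within 1e-9) toward the smaller model. The audit
  trail records every fitted candidate.
- Predictors are not standardised: coefficients stay on raw descriptor
  scales. Random-slope models are out of scope.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, not any real
dataset:

- **Lexicon:** freq(r) = a·exp(−b·r) with multiplicative log-normal noise
  (keeping frequencies positive). Defaults n = 2,000, a = 1,000,
  b = 0.004, noise SD 0.1 — about 3.5 decades of frequency, the order of
  coverage word-frequency norms provide, at a size that keeps the test
  suite fast.
- **Lists:** pure-LF / pure-HF lists draw from the bottom / top of the ten
  equal-log-width bins (disjoint by construction); mixed lists draw a
  non-exhausted bin uniformly, then a word uniformly within it. Sampling
  is without replacement.
- **Recall:** logit P = γ00 + u_0j + β_SP·SP + β_1·pos + β_2·pos², with
  u_0j ~ N(0, ψ) per subject and independent Bernoulli responses. Trials
  with non-finite SP (zero-width intervals, rare under the defaults) are
  dropped and counted.
- **Defaults:** 45 subjects × one 34-word mixed list, γ00 = −1.35,
  β_SP = 0.5, order betas 0, ψ = 0.5 — chosen once so the marginal mean
  recall sits near .39, the shape of a moderately sized within-subject FR
  experiment. The β values are this package's own synthetic choices; no
  generative effect sizes exist to copy.
- **Determinism:** every stage draws from a child generator seeded by
  (master seed, CRC32 of the stage name), so identical configurations are
  byte-identical and stages can be regenerated independently.

What passing tests show: the estimator recovers the generating
(γ00, β_SP, ψ) without material bias at realistic sizes, BIC selection
finds a true SP effect and discards noise descriptors, and every
deterministic quantity matches its brute-force oracle. What they cannot
show: anything about rehearsal, output interference, semantic structure,
or other real-recall dynamics the generative model omits — conclusions
about real data still require real data.

## Known limitations

- Fixed-node quadrature loses accuracy for very large ψ; raise `n_quad`
  there.
- The multinomial Bayes factor's Dirichlet(1) prior is one defensible
  choice, not the only one; BF magnitudes (unlike their qualitative
  direction at large n) are prior-sensitive.
- The worked example's third word is reported as NaN because its interval
  count depends on the full reference database, which is deliberately not
  shipped.
- `first_word` mode makes position 1 degenerate by construction; it is
  intended for studying SP dynamics across pure lists, not as a default.
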