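# Methods

`lexdrift` simulates the lexical diffusion of an articulatorily-motivated
sound change — a reduction like American English flapping — through
iterated learning, with each generation's learner performing hierarchical
inference over the corpus the previous generation produced. This note
documents the model, the estimators, the synthetic data, and the numerical
and design choices, in that order.

## The generative model

A sublexicon of word types eligible for the change is fixed for a run:
word `w` has token frequency `Freq_w`, constant across generations (no
lexicon turnover). A generation's corpus is produced word by word:

    p_red(w) = logit^-1( b0 + bFreq * T(Freq_w) + u_w )
    n_red(w) ~ Binomial(Freq_w, p_red(w))

* `b0` — baseline log-odds of producing the reduced variant. Defaults used
  in the experiments: −1 (27% on the probability scale) and −3 (5%).
* `bFreq` — the automatization pressure: every (transformed) token of
  practice raises the log-odds of reduction. Experimental settings: 0.02
  ("strong") and 0.0002 ("weak") under the raw transform; 0.11 under the
  log transform (chosen so the mean pressure term matches the raw case).
* `T` — raw token count, or its natural log (so hapax legomena receive no
  practice effect; no +1 shift is applied).
* `u_w` — the word effect: at Generation 1, an i.i.d. draw from
  Normal(0, `b_w`) with `b_w` = 0.4; in later generations, the learner's
  conditional mode for the word.

## The learner

Each generation fits a binomial mixed model with a by-word random
intercept to the previous generation's corpus by maximum marginal
likelihood. Three variants differ in which fixed effects they estimate:
intercept only (`L1`), nothing (`L2`, random effects only), or intercept
plus a frequency slope (`L3`). With a single grouping factor the marginal
likelihood factorizes into one-dimensional integrals per word, evaluated
by adaptive Gauss–Hermite quadrature centred and scaled at each word's
conditional mode; `n_quad = 1` is the Laplace approximation.

Two defaults coexist deliberately. `fit()` defaults to `n_quad = 15`,
which tracks the exact marginal MLE to ~1e−6 against dense numerical
integration. `ChainConfig` — the simulation engine — defaults to
`n_quad = 1`, because the learners being modelled are what standard
mixed-model software computes, and on the sparse, polarized corpora that
arise late in a chain the Laplace objective genuinely places the
variance-component optimum much further out than the exact likelihood
does (e.g. on a 10-word corpus with nine unreduced words, Laplace gives
σ̂ ≈ 4.2 where the exact MLE is ≈ 1.9). These are not small numerical
discrepancies: they compound across generations into different rates of
radicalization and different outcome taxonomies. The engine's Laplace
fits reproduce R's lme4 `glmer` (Laplace default) to about three decimal
places on seed-stage, mid-chain, and fully degenerate states; this
cross-check is part of the test suite.

### Optimization

The marginal likelihood over (fixed effects, log σ) is genuinely
multimodal on polarized corpora: a pooled basin with small σ coexists
with a polarized basin in which a large σ licenses extreme word effects.
The optimizer therefore always evaluates a coarse profiled grid over
log σ (fixed effects profiled out at each grid value by a PQL-style
penalized IRLS inner loop) plus the σ = 0 boundary candidate, takes the
best point as the L-BFGS-B start, and compares the result against a
token-pooled start when that start is competitive. σ is optimized as
log σ bounded in [−10, 5]; a solution at the lower bound is reported as
σ̂ = 0 (and then all conditional modes are exactly 0). Fixed effects are
bounded at ±30, consistent with clipping of the linear predictor (a
log-odds of ±30 is indistinguishable from certainty in double
precision). On fully categorical corpora (every word at 0% or 100%) the
likelihood is a ridge unbounded in σ; the reported optimum is then the
bounded MLE, and its exact location is immaterial to the dynamics
because the regenerated probabilities are saturated either way.

Conditional modes are found by damped Newton iterations, vectorized
across words, to a gradient tolerance of 1e−10, started from a one-step
partial-pooling approximation. Words with complete separation (all or no
tokens reduced) need no special casing: the Normal prior keeps their
modes finite.

Each generation's learner fits afresh — fits are deliberately not
warm-started from the previous generation. A warm start that inherits a
σ̂ = 0 solution sits in a flat basin of the next generation's likelihood
and traps every subsequent fit there, silently changing the dynamics.
When consecutive generations produce byte-identical count vectors (frozen
polarized states), the previous fit is reused, since the fit is a
deterministic function of the data.

## Regeneration

The next corpus is drawn from the learner's estimates with the
automatization pressure re-applied:

    eta_w = b0_hat (if estimated) + (bFreq + bFreq_hat if estimated) * T(Freq_w) + u_hat_w

Practice does not stop acting because the learner has an opinion about
it: the original `bFreq` is added every generation, which is the ratchet
that drives frequent words toward categorical reduction. The learner's
conditional modes — shrunken toward zero in inverse proportion to each
word's evidence — replace the Normal draws of Generation 1. This partial
pooling is what produces both lexicalization (radicalized conservative
words whose effects grow ever more negative) and the transient U-shaped
frequency effect.

## Chains, stopping, outcomes

A chain seeds Generation 1 and iterates fit → regenerate for up to
`max_generations` (300 for the outcome-taxonomy experiments, 100 for the
flap-scale polarization tables). After every generation, including the
first, the token-weighted mean reduction (reduced tokens over total
tokens) is checked: ≥ 0.99 ends the chain as *completed*, ≤ 0.01 as
*sputtered*; reaching the horizon without crossing is *stable*
(polarized) variation. Stable chains additionally report a signature: the
set of words empirically categorical (p̂ exactly 1, or exactly 0) in
every one of the last 10 generations.

Randomness is counter-keyed: the substream for (chain i, generation g) is
derived from the master seed by spawn keys, so a chain's result depends
only on (master seed, i), never on ensemble size, execution order, or how
much state is stored.

## The synthetic sublexica

Real sublexicon frequency vectors are not reproducible here, so the
generator emulates them under hard constraints: exactly `n_types` types,
exactly `n_hapax` hapax legomena, maximum frequency exactly `max_freq`.
The flap-like setting is (762, 236, 2793); the /ð/-like setting is
(24, 4, 50000) — the head magnitude of that sublexicon is not published,
and 50,000 is a configurable placeholder of the right order for *the*-like
function words. The 10-word "headless" /ð/ lexicon used by the
outcome-taxonomy experiments is exact and built in as a fixture
(frequencies 1, 1, 1, 3, 4, 7, 9, 20, 30, 211).

The rank-frequency curve is Zipf–Mandelbrot, `freq(r) ∝ (r + β)^(−α)`.
Pinning the curve at both ends (max frequency at rank 1; the 1.5 rounding
boundary at the first hapax rank) leaves β unidentified, and β controls
how heavily tokens concentrate in the head. β = 0 — pure Zipf between the
pinned endpoints — was selected on seed-side statistics alone: it gives a
seeded type-mean reduction of 31% (reference value 32%) and the right
ordering and rough magnitudes of variance explained by log vs raw
frequency. A lognormal type-frequency spectrum (the classic LNRE
alternative, also fully pinned by the three constraints) was evaluated
and rejected on the same statistics. Interior ranks receive mild seeded
lognormal jitter (sd 0.08 in log space) before an exact adjustment
re-imposes the three constraints, so they hold exactly for every seed.

What the synthetic profile does not capture: the true mid-frequency token
mass of the conversational flap sublexicon. In the synthetic lexicon the
words that end up categorically conservative hold about 2.5% of tokens,
so late-stage chains stall near 97–98% token-weighted reduction rather
than the ~91% reported for the real lexicon, and the count of
categorically conservative types runs high (≈80 vs ≈63). Results that
depend on where mid-frequency token mass sits should be read as
qualitative for real sublexica; the polarization itself (≈679 of 762
types categorically reduced, a clear bimodal distribution, top-2/top-3
stable signatures on the headless lexicon) is robust.

## Diagnostics

* Frequency-effect curves bin words into near-equal frequency-rank bins
  (ties broken by word id) and report per-bin quartiles of p̂.
* The U-shape index splits the lexicon into rank terciles and flags
  mid-tercile medians at least δ below both extremes; δ defaults to 0.01
  and the raw medians are always reported so the boolean is auditable.
  For the learner-contrast check the margin is raised to 0.1 and applied
  in the window where the token-weighted mean lies in [0.85, 0.95],
  because near saturation the granularity of small-denominator
  proportions produces shallow (≤ 0.12) spurious dips under any learner.
* Variance explained is the squared Pearson correlation between T(freq)
  and the empirical per-word proportions, unweighted across types. On
  empirical proportions the hapax-heavy tail adds binomial noise that
  deflates R² well below what the latent probabilities give; both views
  are computable, and the reported diagnostic states which it uses.
* The polarization table counts types per p̂ bin with singleton bins at
  exactly 0 and exactly 1 (the categorical states the taxonomy is about),
  uniform 0.1-wide interior bins, and per-bin means across chains.
* Outcome taxonomies are compared by Fisher's exact test on the 3×2
  count table, enumerated exactly over all tables with the observed
  margins (two-sided by the point-probability rule, matching R's
  `fisher.test`); feasible because ensemble sizes are hundreds at most.

## Reference behavior and reproduction scale

With the exact in-text 10-word lexicon, 100 chains per condition and a
300-generation horizon, the strong-pressure condition yields stable
polarized variation in the mid-90s out of 100 chains with top-2/top-3
modal signatures, and the weak-pressure condition splits between
sputtering and completion with a small number of split-state stable
chains. The weak-condition split is knife-edge: it is governed by the
ratio of a small upward drift (the token-weighted automatization push) to
per-generation binomial noise, and it is measurably sensitive to how the
fitted model resolves near-flat likelihood surfaces — reference values
for it should be treated as having substantial implementation variance in
addition to sampling variance.

Flap-scale experiments run at 10 chains to generation 100 (fits on 762
words take tens of milliseconds, so this scale keeps full runs in
minutes); Generation-1 statistics average 20 seed replicates.

## Limitations

* One learner per generation; no population structure, speakers, or
  additional random effects (morphemes, constructions) — the model
  surface is deliberately the minimal hierarchical case.
* The lexicon is closed: no word birth, death, or frequency drift.
* Binary variant choice only; no continuous articulatory parameter.
* The synthetic frequency profiles match three published constraints
  exactly and everything else only qualitatively (see above).
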