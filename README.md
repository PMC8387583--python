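# lexdrift

Iterated-learning simulation of articulatorily-motivated sound change,
for phoneticians, historical linguists and cultural-evolution modellers
who want to ask *when a reductive change runs to completion, when it
sputters out, and when it freezes into stable, lexicalized variation.*

## The model

A sublexicon of word types eligible for a reduction (say, flappable /t, d/)
carries fixed token frequencies. One generation's corpus is generated as

    p_red(w) = logit⁻¹( b₀ + b_Freq · T(Freq_w) + u_w )
    n_red(w) ~ Binomial(Freq_w, p_red(w)),

where `b₀` is the baseline log-odds of the reduced variant, `b_Freq` the
automatization pressure per (raw or log) token of practice, and `u_w` a
word-specific effect — Normal(0, b_w) draws at Generation 1. The next
generation *learns* from this corpus by fitting exactly the matching
hierarchical model — a binomial mixed-effects regression with a by-word
random intercept, maximized by adaptive Gauss–Hermite quadrature (the
Laplace approximation, standard mixed-model practice, is the simulation
default) — and then regenerates the corpus from its estimates with the
automatization pressure applied again on top. Iterating fit → regenerate
produces lexical diffusion: partial pooling shrinks rare words toward the
lexicon mean while frequent exceptions "radicalize", their random effects
growing ever more extreme. Chains stop when the token-weighted share of
reduced tokens exceeds 99% (completion) or falls below 1% (sputtering
out); reaching the horizon in between is stable polarized variation.

## Worked example

Run 100 chains on the built-in 10-word "headless" /ð/ sublexicon
(frequencies 1, 1, 1, 3, 4, 7, 9, 20, 30, 211) under strong automatization:

```python
import lexdrift as ld

lex = ld.fixture_headless_eth()
cfg = ld.ChainConfig(
    seed_params=ld.SeedParams(b0=-3.0, b_freq=0.02, b_w=0.4),
    learner=ld.L1,            # estimates intercept + word effects
    max_generations=300,
    master_seed=11,
)
ens = ld.run_ensemble(lex, cfg, 100)
print(ens.outcome_counts)
stable = [c for c in ens.chains if c.outcome == "stable"]
print(sorted(ld.stable_state_signature(stable[0], tail=10)))
```

prints

```
{'sputtered': 0, 'completed': 6, 'stable': 94}
['eth09', 'eth10']
```

— under strong frequency-driven reduction this lexicon almost never
completes or dies: it lexicalizes. 94 of 100 chains freeze into polarized
variation, and the first stable chain's categorically-reduced signature is
exactly the two most frequent words (`eth09` and `eth10`, frequencies 30
and 211), with everything else categorically conservative; across the
ensemble the modal signatures are the top-2 and top-3 sets. Dropping
`b_freq` to 0.0002 flips the taxonomy: chains then mostly sputter out or
run to completion instead of stabilizing, and
`ld.outcome_comparison(weak_counts, strong_counts)` puts a Fisher exact
p-value far below 0.0001 on that contrast.

The same machinery runs from a shell:

```bash
lexdrift lexicon --zipf 762 236 2793 --seed 1 --out flap.tsv
lexdrift run --config experiment.yaml --chains 100 --out results/
lexdrift summarize results/weak results/strong
```

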