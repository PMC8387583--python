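"""Iterated-learning chains and replicate ensembles.

One chain is the loop: seed a first-generation corpus from the generative
model, then repeatedly (fit the learner's mixed model to the current
corpus) -> (regenerate the corpus from the fit plus the automatization
pressure), for up to ``max_generations`` generations.  Iteration stops
early when the token-weighted mean reduction probability of a regenerated
corpus exceeds ``upper_stop`` (the change has *run to completion*) or falls
under ``lower_stop`` (it has *sputtered out*); a chain that reaches the
horizon without crossing either threshold is in *stable (polarized)
variation*.  Ensembles are replicate chains with seeds derived from a
master seed by counter-based keying, so each chain's result depends only on
(master_seed, chain_index) — never on execution order or on how much state
is stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .generative import GenerationState, SeedParams, regenerate, seed_generation
from .inference import FitResult, LearnerSpec, fit
from .lexicon import Lexicon

__all__ = [
    "ChainConfig",
    "ChainResult",
    "EnsembleResult",
    "OUTCOMES",
    "token_weighted_mean",
    "run_chain",
    "run_ensemble",
    "stable_state_signature",
]

OUTCOMES = ("sputtered", "completed", "stable")


@dataclass(frozen=True)
class ChainConfig:
    """Settings for one iterated-learning chain (or a replicate ensemble)."""

    seed_params: SeedParams
    learner: LearnerSpec
    max_generations: int = 20
    upper_stop: float = 0.99
    lower_stop: float = 0.01
    master_seed: int = 0
    #: quadrature order for the learner's fits.  The default is the Laplace
    #: approximation (n_quad = 1), the estimator standard mixed-model
    #: software uses and the one the reference simulation results assume;
    #: on the sparse, near-categorical corpora that arise late in a chain,
    #: Laplace and exact-likelihood (higher n_quad) learners radicalize
    #: exceptional words at measurably different rates.
    n_quad: int = 1
    store_states: bool = True

    def __post_init__(self):
        if not (0.0 < self.lower_stop < self.upper_stop < 1.0):
            raise ValueError("need 0 < lower_stop < upper_stop < 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class ChainResult:
    """Trajectory and outcome of one chain.

    ``mean_trajectory[g]`` is the token-weighted mean reduction of
    generation g+1.  ``states``/``fits`` hold per-generation detail
    (states empty when the chain was run with ``store_states=False``;
    fits start at generation 2, since generation 1 is seeded, not fitted).
    """

    mean_trajectory: np.ndarray
    outcome: str
    generations_run: int
    states: list[GenerationState] = field(default_factory=list)
    fits: list[FitResult] = field(default_factory=list)

    @property
    def final_mean(self) -> float:
        return float(self.mean_trajectory[-1])


@dataclass
class EnsembleResult:
    """Replicate chains run under one configuration."""

    n_chains: int
    outcome_counts: dict[str, int]
    chains: list[ChainResult]

    def outcome_vector(self) -> tuple[int, int, int]:
        """Counts as (sputtered, completed, stable)."""
        return tuple(self.outcome_counts[o] for o in OUTCOMES)


def token_weighted_mean(state: GenerationState) -> float:
    """Reduced tokens over total tokens: the quantity the stop rules watch."""
    return float(state.n_red.sum() / state.lexicon.n_tokens)


def _rng(master_seed: int, chain_index: int, generation: int) -> np.random.Generator:
    """Counter-keyed substream: one independent stream per (chain, generation)."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(chain_index, generation))
    )


def _classify(mean: float, cfg: ChainConfig) -> str | None:
    if mean >= cfg.upper_stop:
        return "completed"
    if mean <= cfg.lower_stop:
        return "sputtered"
    return None


def run_chain(lex: Lexicon, cfg: ChainConfig, chain_index: int = 0) -> ChainResult:
    """Run one seeded chain to a stopping threshold or the horizon."""
    transform = cfg.seed_params.freq_transform
    state = seed_generation(lex, cfg.seed_params, _rng(cfg.master_seed, chain_index, 1))
    trajectory = [token_weighted_mean(state)]
    states = [state] if cfg.store_states else []
    fits: list[FitResult] = []

    outcome = _classify(trajectory[-1], cfg)
    gen = 1
    prev_counts: tuple | None = None
    prev_fit: FitResult | None = None
    while outcome is None and gen < cfg.max_generations:
        gen += 1
        try:
            # each generation's learner starts inference afresh, as a new
            # learner would (no warm starts); but identical data yields an
            # identical fit, so frozen polarized states skip re-fitting
            counts = tuple(state.n_red.tolist())
            if prev_counts == counts and prev_fit is not None:
                f = prev_fit
            else:
                f = fit(
                    state,
                    cfg.learner,
                    n_quad=cfg.n_quad,
                    generative_transform=transform,
                )
            prev_counts, prev_fit = counts, f
            state = regenerate(
                lex,
                f,
                cfg.seed_params,
                cfg.learner,
                _rng(cfg.master_seed, chain_index, gen),
            )
        except Exception as exc:
            raise RuntimeError(
                f"chain {chain_index}, generation {gen}: {exc}"
            ) from exc
        fits.append(f)
        trajectory.append(token_weighted_mean(state))
        if cfg.store_states:
            states.append(state)
        outcome = _classify(trajectory[-1], cfg)

    if outcome is None:
        outcome = "stable"
    return ChainResult(
        mean_trajectory=np.asarray(trajectory),
        outcome=outcome,
        generations_run=gen,
        states=states,
        fits=fits,
    )


def run_ensemble(lex: Lexicon, cfg: ChainConfig, n_chains: int) -> EnsembleResult:
    """Run ``n_chains`` independent replicate chains of one configuration."""
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    chains = [run_chain(lex, cfg, chain_index=i) for i in range(n_chains)]
    counts = {o: 0 for o in OUTCOMES}
    for c in chains:
        counts[c.outcome] += 1
    return EnsembleResult(n_chains=n_chains, outcome_counts=counts, chains=chains)


def stable_state_signature(
    result: ChainResult, tail: int = 10, side: str = "innovative"
) -> set[str]:
    """Words that are categorical throughout the last ``tail`` generations.

    ``side="innovative"`` returns words with empirical reduction proportion
    exactly 1 in every one of the last ``tail`` stored generations;
    ``side="conservative"`` returns those at exactly 0 throughout.  Only
    meaningful — and only allowed — for chains in stable variation.
    """
    if result.outcome != "stable":
        raise ValueError("stable_state_signature requires a stable-outcome chain")
    if side not in ("innovative", "conservative"):
        raise ValueError("side must be 'innovative' or 'conservative'")
    if not result.states:
        raise ValueError("chain was run without stored states")
    if tail < 1 or tail > len(result.states):
        raise ValueError("tail must be in [1, generations stored]")
    tail_states = result.states[-tail:]
    lex = tail_states[0].lexicon
    if side == "innovative":
        mask = np.ones(lex.n_types, dtype=bool)
        for s in tail_states:
            mask &= s.n_red == s.freqs
    else:
        mask = np.ones(lex.n_types, dtype=bool)
        for s in tail_states:
            mask &= s.n_red == 0
    return {lex.words[i] for i in np.nonzero(mask)[0]}
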