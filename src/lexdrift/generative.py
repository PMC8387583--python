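"""The generative model of articulatorily-motivated reduction.

A word ``w`` with token frequency ``Freq_w`` is produced with the reduced
variant with probability

    p_red(w) = logit^-1( b0 + bFreq * T(Freq_w) + u_w )

where ``T`` is either the identity (every token of practice increments the
log-odds of reduction equally) or the natural log, ``b0`` is the baseline
log-odds of reduction, ``bFreq`` the automatization pressure per
(transformed) token, and ``u_w`` a word-specific effect.  The number of
reduced tokens is a binomial draw:

    n_red(w) ~ Binomial(Freq_w, p_red(w)).

At Generation 1 the word effects are drawn fresh from Normal(0, bw).  In
every later generation the corpus is *regenerated* from a learner's fit:
the inferred conditional modes replace the Normal draws, the inferred
intercept replaces ``b0`` (when estimated), and the automatization pressure
``bFreq`` is always re-applied on top of whatever frequency effect the
learner inferred — articulatory practice does not stop acting just because
the learner has an opinion about it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import expit

from .lexicon import Lexicon

if TYPE_CHECKING:  # pragma: no cover
    from .inference import FitResult, LearnerSpec

__all__ = [
    "SeedParams",
    "GenerationState",
    "inv_logit",
    "transform_freq",
    "linear_predictor",
    "seed_generation",
    "regenerate",
]

#: log-odds beyond which a probability is indistinguishable from 0/1 at
#: double precision; linear predictors are clipped here before expit.
ETA_CLIP = 30.0


@dataclass(frozen=True)
class SeedParams:
    """Free parameters of the generative model.

    b0
        Baseline log-odds of reduction (the reference experiments use -1,
        i.e. a 27% baseline, and -3, i.e. 5%).
    b_freq
        Automatization increment on the log-odds scale per (transformed)
        token of practice.
    b_w
        Standard deviation of the word effect at Generation 1 (log-odds).
    freq_transform
        ``"raw"`` — log-odds grow linearly in token count; ``"log"`` —
        linearly in natural-log token count (hapaxes get 0 either way under
        log since ln 1 = 0).
    """

    b0: float
    b_freq: float
    b_w: float
    freq_transform: str = "raw"

    def __post_init__(self):
        if self.b_w < 0:
            raise ValueError("b_w (word-effect standard deviation) must be >= 0")
        if self.freq_transform not in ("raw", "log"):
            raise ValueError("freq_transform must be 'raw' or 'log'")


def inv_logit(eta) -> np.ndarray | float:
    """Inverse logit with the linear predictor clipped to +/- ETA_CLIP."""
    return expit(np.clip(eta, -ETA_CLIP, ETA_CLIP))


def transform_freq(freqs, transform: str) -> np.ndarray:
    """Apply the frequency transform T: identity or natural log."""
    arr = np.asarray(freqs, dtype=float)
    if transform == "raw":
        return arr
    if transform == "log":
        return np.log(arr)
    raise ValueError(f"unknown frequency transform {transform!r}")


def linear_predictor(freq, u, params: SeedParams) -> np.ndarray | float:
    """eta = b0 + bFreq * T(freq) + u on the log-odds scale."""
    return params.b0 + params.b_freq * transform_freq(freq, params.freq_transform) + u


class GenerationState:
    """One generation's corpus: per-word reduced-token counts.

    Also records the word effects ``u`` (Normal draws at Generation 1,
    learner conditional modes afterwards) that produced the counts.
    """

    __slots__ = ("lexicon", "u", "n_red")

    def __init__(self, lexicon: Lexicon, u: np.ndarray, n_red: np.ndarray):
        u = np.asarray(u, dtype=float)
        n_red = np.asarray(n_red, dtype=np.int64)
        if u.shape != (lexicon.n_types,) or n_red.shape != (lexicon.n_types,):
            raise ValueError("u and n_red must have one entry per word type")
        if np.any(n_red < 0) or np.any(n_red > lexicon.freqs):
            raise ValueError("n_red must satisfy 0 <= n_red <= freq per word")
        self.lexicon = lexicon
        self.u = u
        self.n_red = n_red

    @property
    def freqs(self) -> np.ndarray:
        return self.lexicon.freqs

    @property
    def p_hat(self) -> np.ndarray:
        """Per-word empirical reduction proportion n_red / freq."""
        return self.n_red / self.lexicon.freqs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.lexicon.words,
                "freq": self.lexicon.freqs,
                "u": self.u,
                "n_red": self.n_red,
                "p_hat": self.p_hat,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:
        mean = self.n_red.sum() / self.lexicon.n_tokens
        return (
            f"GenerationState(n_types={self.lexicon.n_types}, "
            f"token_mean={mean:.3f})"
        )


def seed_generation(
    lex: Lexicon, params: SeedParams, rng: np.random.Generator
) -> GenerationState:
    """Draw Generation 1: fresh Normal(0, b_w) word effects, binomial counts."""
    u = rng.normal(0.0, params.b_w, size=lex.n_types)
    p = inv_logit(linear_predictor(lex.freqs, u, params))
    n_red = rng.binomial(lex.freqs, p)
    return GenerationState(lex, u, n_red)


def regenerate(
    lex: Lexicon,
    fit: "FitResult",
    params: SeedParams,
    spec: "LearnerSpec",
    rng: np.random.Generator,
) -> GenerationState:
    """Produce the next generation's corpus from a learner's estimates.

    Per word:  eta = b0_hat (if the learner estimated an intercept, else 0)
    + (bFreq_original + bFreq_hat if estimated) * T(freq) + u_hat, and
    n_red ~ Binomial(freq, inv_logit(eta)).  Frequencies never change.
    """
    u_hat = fit.u_for(lex)
    b0 = fit.b0_hat if spec.estimate_intercept else 0.0
    b_freq = params.b_freq + (fit.b_freq_hat if spec.estimate_freq_effect else 0.0)
    eta = b0 + b_freq * transform_freq(lex.freqs, params.freq_transform) + u_hat
    p = inv_logit(eta)
    n_red = rng.binomial(lex.freqs, p)
    return GenerationState(lex, u_hat, n_red)
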