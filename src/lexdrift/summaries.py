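"""Diagnostics of simulated change: frequency-effect curves, U-shape
detection, variance explained by frequency, polarization tables,
radicalization traces, and the exact outcome-taxonomy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .engine import OUTCOMES, ChainResult
from .generative import GenerationState, transform_freq

__all__ = [
    "frequency_effect_curve",
    "ushape_index",
    "variance_explained",
    "default_probability_bins",
    "probability_distribution",
    "random_effect_trace",
    "fisher_exact_2xk",
    "outcome_comparison",
]


def _rank_order(state: GenerationState) -> np.ndarray:
    """Indices sorting words by ascending frequency, ties broken by word id."""
    lex = state.lexicon
    return np.lexsort((np.asarray(lex.words), lex.freqs))


def frequency_effect_curve(state: GenerationState, n_bins: int) -> pd.DataFrame:
    """Median and quartiles of p_hat in near-equal frequency-rank bins.

    Words are ranked by frequency (ascending; ties broken by word id) and
    split into ``n_bins`` near-equal bins — the rank transform used when
    plotting the frequency effect, which keeps Zipfian heads from
    compressing the rest of the lexicon into one pixel.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    order = _rank_order(state)
    p = state.p_hat[order]
    f = state.freqs[order]
    rows = []
    for b, idx in enumerate(np.array_split(np.arange(len(p)), n_bins)):
        if len(idx) == 0:
            continue
        q1, med, q3 = np.percentile(p[idx], [25, 50, 75])
        rows.append(
            {
                "bin": b,
                "n_types": len(idx),
                "freq_min": int(f[idx].min()),
                "freq_max": int(f[idx].max()),
                "q1": q1,
                "median": med,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)


def ushape_index(
    state: GenerationState, delta: float = 0.01
) -> tuple[float, float, float, bool]:
    """Tercile-median U-shape detector.

    Splits the lexicon into frequency-rank terciles and reports their
    median empirical reduction proportions ``(low, mid, high)`` plus a
    boolean that is true when the middle tercile sits at least ``delta``
    below both extremes — the signature of exceptionally conservative
    medium-frequency words coexisting with reduced rare and frequent words.
    """
    if state.lexicon.n_types < 3:
        raise ValueError("need at least 3 word types")
    order = _rank_order(state)
    p = state.p_hat[order]
    low, mid, high = (
        float(np.median(chunk)) for chunk in np.array_split(p, 3)
    )
    is_u = (mid < low - delta) and (mid < high - delta)
    return low, mid, high, is_u


def variance_explained(state: GenerationState, transform: str = "log") -> float:
    """Squared Pearson correlation between T(freq) and p_hat across types.

    Unweighted over word types; defined as 0 when p_hat is constant.
    """
    if state.lexicon.n_types < 3:
        raise ValueError("need at least 3 word types")
    t = transform_freq(state.freqs, transform)
    p = state.p_hat
    if np.std(t) < 1e-15:
        raise ValueError("frequency predictor is constant")
    if np.std(p) < 1e-15:
        return 0.0
    r = np.corrcoef(t, p)[0, 1]
    return float(r * r)


def default_probability_bins() -> list[tuple[float, float]]:
    """Bins over p_hat: singletons at exactly 0 and exactly 1, then
    (0, 0.05], (0.05, 0.15], ..., (0.85, 0.95], (0.95, 1).

    Exact 0 and exact 1 get their own bins because "never reduced" and
    "always reduced" are the modes of polarized variation and the
    categorical states the outcome taxonomy cares about.
    """
    edges = [0.0, 0.05] + [round(0.05 + 0.1 * k, 10) for k in range(1, 10)]
    bins = [(0.0, 0.0)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        bins.append((lo, hi))
    bins.append((0.95, 1.0))  # open interval (0.95, 1)
    bins.append((1.0, 1.0))
    return bins


def _bin_label(lo: float, hi: float) -> str:
    if lo == hi:
        return f"{lo:g}"
    if hi == 1.0:  # the interval below the exact-1 singleton is open above
        return f"({lo:g}, 1)"
    return f"({lo:g}, {hi:g}]"


def probability_distribution(
    states: list[GenerationState],
    bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Distribution of per-word reduction proportions across word types.

    Counts word types per p_hat bin separately for each chain's state, then
    reports the per-bin mean count across chains.  Singleton bins are exact
    matches; interval bins are open-below / closed-above, except the
    interval immediately below 1 which excludes the exact value 1.
    """
    if not states:
        raise ValueError("no states given")
    lex = states[0].lexicon
    if any(s.lexicon != lex for s in states[1:]):
        raise ValueError("states must share a lexicon")
    if bins is None:
        bins = default_probability_bins()
    counts = np.zeros((len(states), len(bins)))
    for i, s in enumerate(states):
        p = s.p_hat
        for j, (lo, hi) in enumerate(bins):
            if lo == hi:
                mask = p == lo
            elif hi == 1.0:  # interval just below the exact-1 singleton
                mask = (p > lo) & (p < 1.0)
            else:
                mask = (p > lo) & (p <= hi)
            counts[i, j] = mask.sum()
    per_chain = counts.sum(axis=1)
    if not np.all(per_chain == lex.n_types):
        raise AssertionError("probability bins do not partition [0, 1]")
    return pd.DataFrame(
        {
            "bin": [_bin_label(lo, hi) for lo, hi in bins],
            "mean_count": counts.mean(axis=0),
        }
    )


def random_effect_trace(
    result: ChainResult, radical_sd: float = 2.0, k_consecutive: int = 3
) -> pd.DataFrame:
    """Per-generation summaries of the learned word effects u_hat.

    For each fitted generation reports min/quartiles/max of u_hat and of
    u_hat scaled by that generation's sigma_hat, plus the number of
    "radicalized" words: words whose u_hat has been below ``-radical_sd *
    sigma_hat`` for at least ``k_consecutive`` consecutive generations up
    to and including this one.  Radicalized words are the exceptionally
    conservative lexical items whose effects grow ever more negative as the
    reduced variant takes over, stabilizing the change short of completion.
    """
    if not result.fits:
        raise ValueError("chain has no stored fits")
    words = list(result.fits[0].u_hat.keys())
    below = np.zeros(len(words), dtype=int)
    rows = []
    for g, f in enumerate(result.fits, start=2):
        u = np.array([f.u_hat[w] for w in words])
        sigma = f.sigma_hat
        flag = u < -radical_sd * sigma if sigma > 0 else np.zeros(len(u), bool)
        below = np.where(flag, below + 1, 0)
        q = np.percentile(u, [0, 25, 50, 75, 100])
        rows.append(
            {
                "generation": g,
                "sigma_hat": sigma,
                "u_min": q[0],
                "u_q1": q[1],
                "u_median": q[2],
                "u_q3": q[3],
                "u_max": q[4],
                "u_min_sd": q[0] / sigma if sigma > 0 else 0.0,
                "n_radicalized": int(np.sum(below >= k_consecutive)),
            }
        )
    return pd.DataFrame(rows)


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided Fisher exact test for a 2-column contingency table.

    Enumerates all tables with the observed margins (feasible because the
    column totals here are replicate counts of at most a few hundred) and
    sums the point probabilities of tables no more probable than the
    observed one — the same two-sided rule R's ``fisher.test`` uses.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("table must be k x 2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("zero-total table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n_total = t.sum()
    log_margin = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n_total + 1)

    def log_prob(first_col: np.ndarray) -> float:
        cells = np.concatenate([first_col, row - first_col])
        return float(log_margin - gammaln(cells + 1).sum())

    lp_obs = log_prob(t[:, 0])

    k = t.shape[0]
    p_sum = 0.0

    def recurse(i: int, remaining: int, first_col: list[int]):
        nonlocal p_sum
        if i == k - 1:
            if remaining <= row[i]:
                lp = log_prob(np.array(first_col + [remaining]))
                if lp <= lp_obs + 1e-10:
                    p_sum += np.exp(lp)
            return
        for x in range(0, min(int(row[i]), remaining) + 1):
            recurse(i + 1, remaining - x, first_col + [x])

    recurse(0, int(col[0]), [])
    return min(p_sum, 1.0)


def outcome_comparison(
    a: dict[str, int] | tuple[int, int, int],
    b: dict[str, int] | tuple[int, int, int],
) -> float:
    """Exact two-sided p-value comparing two ensembles' outcome taxonomies.

    ``a`` and ``b`` are per-outcome chain counts (sputtered / completed /
    stable) for two parameter settings; the test is Fisher's exact test on
    the resulting 3 x 2 table.
    """

    def as_vec(x) -> np.ndarray:
        if isinstance(x, dict):
            return np.array([x[o] for o in OUTCOMES], dtype=np.int64)
        return np.asarray(x, dtype=np.int64)

    va, vb = as_vec(a), as_vec(b)
    if va.shape != vb.shape:
        raise ValueError("outcome vectors must have the same categories")
    return fisher_exact_2xk(np.column_stack([va, vb]))
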