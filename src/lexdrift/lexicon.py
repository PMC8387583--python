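"""Word-frequency lexicons.

Every simulation is seeded by a *sublexicon*: the set of word types eligible
to undergo a particular reductive sound change (e.g. words with a flappable
/t, d/, or words beginning with /ð/), each carrying the token frequency with
which it occurs in a corpus.  Real sublexica are highly skewed (Zipfian),
and the shape of that skew — how many rare words there are, and how extreme
the head of the distribution is — turns out to govern whether the simulated
change completes, sputters out, or lexicalizes.

This module provides:

* :class:`Lexicon` — an immutable list of (word, frequency) pairs,
* :func:`load_lexicon` / :meth:`Lexicon.to_tsv` — two-column delimited I/O,
* :func:`generate_zipf_lexicon` — a Zipf–Mandelbrot generator constrained to
  hit a requested type count, hapax count, and maximum frequency *exactly*,
* :func:`make_headless` — remove the high-frequency head of a lexicon,
* :func:`fixture_headless_eth` — the 10-word headless /ð/ sublexicon used
  throughout the outcome-taxonomy experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Lexicon",
    "ZipfSpec",
    "LexiconError",
    "load_lexicon",
    "generate_zipf_lexicon",
    "make_headless",
    "fixture_headless_eth",
]


class LexiconError(ValueError):
    """Raised for malformed lexicon files or infeasible generator specs."""


class Lexicon:
    """An ordered, immutable collection of word types with token frequencies.

    Parameters
    ----------
    entries
        Iterable of ``(word_id, freq)`` pairs.  Word ids must be unique and
        frequencies must be positive integers.
    """

    __slots__ = ("_words", "_freqs")

    def __init__(self, entries: Iterable[tuple[str, int]]):
        words: list[str] = []
        freqs: list[int] = []
        for word, freq in entries:
            words.append(str(word))
            freqs.append(int(freq))
        if not words:
            raise LexiconError("no entries")
        if len(set(words)) != len(words):
            dupes = sorted({w for w in words if words.count(w) > 1})
            raise LexiconError(f"duplicate word ids: {dupes}")
        arr = np.asarray(freqs, dtype=np.int64)
        if np.any(arr < 1):
            bad = [words[i] for i in np.nonzero(arr < 1)[0]]
            raise LexiconError(f"non-positive frequency for: {bad}")
        self._words = tuple(words)
        self._freqs = arr
        self._freqs.setflags(write=False)

    @property
    def words(self) -> tuple[str, ...]:
        return self._words

    @property
    def freqs(self) -> np.ndarray:
        """Token frequencies as a read-only int64 array, in entry order."""
        return self._freqs

    @property
    def n_types(self) -> int:
        return len(self._words)

    @property
    def n_tokens(self) -> int:
        return int(self._freqs.sum())

    @property
    def n_hapax(self) -> int:
        """Number of hapax legomena (types with token frequency 1)."""
        return int(np.sum(self._freqs == 1))

    @property
    def max_freq(self) -> int:
        return int(self._freqs.max())

    def __len__(self) -> int:
        return self.n_types

    def __iter__(self):
        return iter(zip(self._words, self._freqs.tolist()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return self._words == other._words and np.array_equal(
            self._freqs, other._freqs
        )

    def __repr__(self) -> str:
        return (
            f"Lexicon(n_types={self.n_types}, n_tokens={self.n_tokens}, "
            f"max_freq={self.max_freq})"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"word": self._words, "freq": self._freqs})

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ZipfSpec:
    """Constraints for the synthetic Zipf–Mandelbrot lexicon generator.

    ``n_types`` word types, exactly ``n_hapax`` of which occur once, with the
    most frequent type occurring exactly ``max_freq`` times.  These three
    statistics are the only properties of a real sublexicon the generative
    model can see, so matching them is what "emulating" a corpus means here.
    """

    n_types: int
    n_hapax: int
    max_freq: int
    seed: int = 0

    def validate(self) -> None:
        if self.n_types < 1:
            raise LexiconError("n_types must be >= 1")
        if not (0 <= self.n_hapax <= self.n_types):
            raise LexiconError("n_hapax must be in [0, n_types]")
        if self.max_freq < 1:
            raise LexiconError("max_freq must be >= 1")
        if self.max_freq == 1 and self.n_hapax != self.n_types:
            raise LexiconError(
                "max_freq = 1 forces every type to be a hapax legomenon"
            )
        if self.n_hapax == self.n_types and self.max_freq > 1:
            raise LexiconError(
                "all-hapax lexicon is incompatible with max_freq > 1"
            )


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a two-column (word, frequency) delimited text file.

    Tab, comma, and whitespace delimiters are auto-detected per line; a
    single header line is skipped if its second field is not an integer.
    """
    path = Path(path)
    entries: list[tuple[str, int]] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            fields = [f.strip() for f in line.split("\t")]
        elif "," in line:
            fields = [f.strip() for f in line.split(",")]
        else:
            fields = line.split()
        if len(fields) != 2:
            raise LexiconError(
                f"{path.name}, line {lineno}: expected 2 columns, got {len(fields)}"
            )
        word, freq_str = fields
        try:
            freq = int(freq_str)
        except ValueError:
            if lineno == 1 and not entries:
                continue  # header row
            raise LexiconError(
                f"{path.name}, line {lineno}: frequency {freq_str!r} is not an integer"
            ) from None
        if freq < 1:
            raise LexiconError(
                f"{path.name}, line {lineno}: frequency must be positive, got {freq}"
            )
        entries.append((word, freq))
    if not entries:
        raise LexiconError("no entries")
    try:
        return Lexicon(entries)
    except LexiconError as exc:
        raise LexiconError(f"{path.name}: {exc}") from None


def generate_zipf_lexicon(spec: ZipfSpec) -> Lexicon:
    """Generate a rank-frequency lexicon under hard count constraints.

    The rank-frequency profile follows a Zipf–Mandelbrot curve
    ``freq(r) = C * (r + beta)**(-alpha)``.  Pinning the curve at both ends
    (``max_freq`` at rank 1 and the rounding boundary 1.5 at the first hapax
    rank) leaves the Mandelbrot shift unidentified, so ``beta`` takes the
    parsimony value 0 (pure Zipf between the constrained endpoints) and
    ``alpha`` follows in closed form.  Interior ranks get mild seeded
    lognormal jitter, then an exact adjustment pins the constraints: the
    lowest ``n_hapax`` ranks are set to frequency 1, interior ranks are
    clipped to [2, max_freq], and rank 1 is set to ``max_freq``.  The result
    is bit-reproducible for a fixed spec.
    """
    spec.validate()
    n, h, m = spec.n_types, spec.n_hapax, spec.max_freq
    if m == 1:
        freqs = np.ones(n, dtype=np.int64)
    elif n == 1:
        freqs = np.array([m], dtype=np.int64)
    elif h == n - 1:
        freqs = np.concatenate([[m], np.ones(n - 1, dtype=np.int64)])
    else:
        beta = 0.0
        # Curve crosses 1.5 at the boundary rank between non-hapax and hapax
        # region (or just past the last rank when no hapaxes are requested).
        r_star = (n - h) + 0.5
        alpha = math.log(m / 1.5) / math.log((r_star + beta) / (1.0 + beta))
        alpha = max(alpha, 1e-3)
        ranks = np.arange(1, n + 1, dtype=float)
        curve = m * ((ranks + beta) / (1.0 + beta)) ** (-alpha)
        rng = np.random.default_rng(spec.seed)
        jitter = np.exp(rng.normal(0.0, 0.08, size=n))
        freqs = np.rint(curve * jitter).astype(np.int64)
        n_interior = n - h  # ranks 1..n_interior must stay above hapax level
        freqs[n_interior:] = 1
        np.clip(freqs[:n_interior], 2, m, out=freqs[:n_interior])
        freqs[0] = m
        freqs = -np.sort(-freqs)  # restore monotone rank order after jitter
    width = len(str(n))
    words = [f"w{r:0{width}d}" for r in range(1, n + 1)]
    lex = Lexicon(zip(words, freqs.tolist()))
    assert lex.n_types == n and lex.n_hapax == h and lex.max_freq == m
    return lex


def make_headless(lex: Lexicon, cutoff: int) -> Lexicon:
    """Drop the head of the frequency distribution: keep freq <= cutoff.

    Removing the most frequent words — the lexical leaders of an
    articulatorily-driven change — is the manipulation that lets a change
    run to completion instead of lexicalizing.
    """
    if cutoff < 1:
        raise LexiconError("cutoff must be >= 1")
    entries = [(w, f) for w, f in lex if f <= cutoff]
    if not entries:
        raise LexiconError("headless lexicon empty")
    return Lexicon(entries)


#: Token frequencies of the /ð/-initial Switchboard sublexicon after removing
#: all words above 900 tokens: 3 hapax legomena plus 7 more frequent words.
HEADLESS_ETH_FREQS: Sequence[int] = (1, 1, 1, 3, 4, 7, 9, 20, 30, 211)


def fixture_headless_eth() -> Lexicon:
    """The 10-word headless /ð/ sublexicon (287 tokens)."""
    words = [f"eth{i:02d}" for i in range(1, len(HEADLESS_ETH_FREQS) + 1)]
    return Lexicon(zip(words, HEADLESS_ETH_FREQS))
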