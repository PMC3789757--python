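"""Synthetic vocabularies of four-letter words with controlled anagram structure.

The simulations need vocabularies of N unique lowercase four-letter words in
which either (a) no two words are anagrams of each other, or (b) a prescribed
subset of words forms disjoint anagram pairs (e.g. ``life``/``file``) while
the rest remain pairwise non-anagrammatic.  Words are drawn from an embedded
pool of common English words when possible and completed with random letter
strings otherwise.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .words import WORD_POOL

_ALPHABET = set(string.ascii_lowercase)


class LexiconError(ValueError):
    """Raised for infeasible generation requests or malformed word lists."""


def _is_valid_word(w: str) -> bool:
    return len(w) == 4 and set(w) <= _ALPHABET


def _multiset(w: str) -> str:
    return "".join(sorted(w))


@dataclass(frozen=True)
class Lexicon:
    """An ordered vocabulary of unique lowercase four-letter words.

    Parameters
    ----------
    words
        The vocabulary, in presentation order.
    anagram_pair
        Symmetric map from each anagram-annotated word to its unique partner.
        Words absent from the map have no full anagram inside the lexicon.
    """

    words: tuple[str, ...]
    anagram_pair: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, w in enumerate(self.words):
            if not _is_valid_word(w):
                raise LexiconError(f"invalid word {w!r} at position {i}")
        if len(set(self.words)) != len(self.words):
            raise LexiconError("duplicate words in lexicon")
        wordset = set(self.words)
        for a, b in self.anagram_pair.items():
            if a not in wordset or b not in wordset:
                raise LexiconError(f"anagram pair ({a},{b}) not in lexicon")
            if self.anagram_pair.get(b) != a:
                raise LexiconError(f"anagram map not symmetric at {a!r}")
            if _multiset(a) != _multiset(b) or a == b:
                raise LexiconError(f"({a},{b}) is not an anagram pair")

    @property
    def size(self) -> int:
        return len(self.words)

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    def index(self, word: str) -> int:
        return self.words.index(word)

    @property
    def anagram_words(self) -> tuple[str, ...]:
        """Words that belong to an annotated anagram pair, in lexicon order."""
        return tuple(w for w in self.words if w in self.anagram_pair)

    @property
    def normal_words(self) -> tuple[str, ...]:
        """Words with no annotated anagram partner, in lexicon order."""
        return tuple(w for w in self.words if w not in self.anagram_pair)

    def check_anagram_annotation(self) -> None:
        """Verify the anagram annotation against exhaustive pairwise tests.

        Raises :class:`LexiconError` if two non-annotated words are anagrams
        of each other, or if the annotation itself is inconsistent (the
        latter is already rejected at construction).
        """
        seen: dict[str, str] = {}
        for w in self.words:
            m = _multiset(w)
            if m in seen:
                other = seen[m]
                if self.anagram_pair.get(w) != other:
                    raise LexiconError(
                        f"unannotated anagram pair ({other},{w})"
                    )
            else:
                seen[m] = w


def _random_word(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(string.ascii_lowercase), size=4))


def _permute_word(w: str, rng: np.random.Generator) -> str:
    letters = list(w)
    for _ in range(20):
        perm = rng.permutation(4)
        cand = "".join(letters[i] for i in perm)
        if cand != w:
            return cand
    return w  # only for words with 4 identical letters


def generate_lexicon(
    n_words: int, n_anagram_words: int = 0, seed: int | np.random.Generator = 0
) -> Lexicon:
    """Generate a vocabulary of ``n_words`` unique four-letter words.

    Exactly ``n_anagram_words`` of them (an even number) form
    ``n_anagram_words / 2`` disjoint anagram pairs; the remaining words are
    pairwise non-anagrammatic.  Deterministic given ``seed``.

    Words come from an embedded English pool when possible.  Anagram partners
    missing from the pool are built by permuting the letters of a pool word,
    and random letter strings are used as a last resort, so arbitrarily large
    requests remain feasible up to the combinatorial limit.
    """
    if n_anagram_words < 0 or n_words < n_anagram_words:
        raise LexiconError("need n_words >= n_anagram_words >= 0")
    if n_anagram_words % 2:
        raise LexiconError("n_anagram_words must be even")
    rng = np.random.default_rng(seed)

    pool = list(WORD_POOL)
    rng.shuffle(pool)
    by_multiset: dict[str, list[str]] = {}
    for w in pool:
        by_multiset.setdefault(_multiset(w), []).append(w)

    n_pairs = n_anagram_words // 2
    words: list[str] = []
    pairs: list[tuple[str, str]] = []
    used_multisets: set[str] = set()

    # Anagram pairs straight from the pool first.
    for m, group in by_multiset.items():
        if len(pairs) == n_pairs:
            break
        if len(group) >= 2:
            pairs.append((group[0], group[1]))
            used_multisets.add(m)
    # Then pairs built by permuting a pool word's letters.
    for w in pool:
        if len(pairs) == n_pairs:
            break
        m = _multiset(w)
        if m in used_multisets or len(set(w)) < 2:
            continue
        partner = _permute_word(w, rng)
        if partner != w:
            pairs.append((w, partner))
            used_multisets.add(m)
    # Random strings as a last resort (requests beyond the pool).
    attempts = 0
    while len(pairs) < n_pairs:
        if attempts > 10000 * n_pairs:
            raise LexiconError(f"cannot build {n_pairs} anagram pairs")
        attempts += 1
        w = _random_word(rng)
        m = _multiset(w)
        if m in used_multisets or len(set(w)) < 2:
            continue
        partner = _permute_word(w, rng)
        pairs.append((w, partner))
        used_multisets.add(m)

    for a, b in pairs:
        words.extend((a, b))

    # Non-anagram words: pairwise distinct letter multisets, disjoint from
    # the pair multisets.
    n_normal = n_words - n_anagram_words
    for w in pool:
        if len(words) == n_words:
            break
        m = _multiset(w)
        if m in used_multisets:
            continue
        words.append(w)
        used_multisets.add(m)
    attempts = 0
    while len(words) < n_words:
        if attempts > 10000 * max(n_normal, 1):
            raise LexiconError(f"cannot build {n_words} words")
        attempts += 1
        w = _random_word(rng)
        m = _multiset(w)
        if m in used_multisets:
            continue
        words.append(w)
        used_multisets.add(m)

    order = rng.permutation(len(words))
    words = [words[i] for i in order]
    pair_map: dict[str, str] = {}
    for a, b in pairs:
        pair_map[a] = b
        pair_map[b] = a
    return Lexicon(words=tuple(words), anagram_pair=pair_map)


def load_lexicon(path) -> Lexicon:
    """Load a word list (one lowercase four-letter word per line).

    Anagram pairs are detected automatically: any two words sharing a letter
    multiset are annotated as partners.  A multiset occurring three or more
    times is rejected, since pairs must be disjoint.
    """
    words: list[str] = []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            w = line.strip()
            if not w:
                continue
            if not _is_valid_word(w):
                raise LexiconError(f"{path}:{lineno}: invalid word {w!r}")
            words.append(w)
    by_multiset: dict[str, list[str]] = {}
    for w in words:
        by_multiset.setdefault(_multiset(w), []).append(w)
    pair_map: dict[str, str] = {}
    for m, group in by_multiset.items():
        if len(group) == 2:
            pair_map[group[0]] = group[1]
            pair_map[group[1]] = group[0]
        elif len(group) > 2:
            raise LexiconError(
                f"{path}: {len(group)} mutual anagrams {group}; only "
                "disjoint pairs are supported"
            )
    return Lexicon(words=tuple(words), anagram_pair=pair_map)


def save_lexicon(lex: Lexicon, path) -> None:
    """Write one word per line (LF-terminated ASCII)."""
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for w in lex.words:
            fh.write(w + "\n")
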