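"""Low-level text processing: tokenization, stop words, Porter stemming.

The indexing pipeline folds case, strips a standard English stop-word
list and reduces inflected word forms to stems before any similarity,
classification or feature computation.  The stemmer is the classic
Porter (1980) suffix-stripping algorithm, implemented here because no
stemming library ships with the runtime environment.
"""

from __future__ import annotations

import re
from functools import lru_cache

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

#: Default stop-word set (frozen, lower-case).
DEFAULT_STOPWORDS: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Case-fold *text* and split into maximal alphanumeric runs."""
    return _TOKEN_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(word: str) -> int:
    """Number of VC sequences in *word* ([C](VC)^m[V] decomposition)."""
    m = 0
    i = 0
    n = len(word)
    while i < n and _is_cons(word, i):
        i += 1
    while i < n:
        while i < n and not _is_cons(word, i):
            i += 1
        if i >= n:
            break
        m += 1
        while i < n and _is_cons(word, i):
            i += 1
    return m


def _has_vowel(word: str) -> bool:
    return any(not _is_cons(word, i) for i in range(len(word)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


@lru_cache(maxsize=65536)
def porter_stem(word: str) -> str:
    """Stem a single lower-case word with the Porter algorithm."""
    w = word
    if len(w) <= 2:
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        stripped = None
        if w.endswith("ed") and _has_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is not None:
            w = stripped
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suf, rep in _STEP2:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + rep
            break

    # step 3
    for suf, rep in _STEP3:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + rep
            break

    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 1:
                if suf == "ion" and not stem.endswith(("s", "t")):
                    break
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


def stem_tokens(
    tokens: list[str],
    stemmer: str = "porter",
    stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
) -> list[str]:
    """Drop stop words from *tokens* and stem the remainder.

    ``stemmer`` is ``"porter"`` or ``"none"``.  Stop words are removed
    before stemming (the list is defined on surface forms).
    """
    if stemmer not in ("porter", "none"):
        raise ValueError(f"unknown stemmer {stemmer!r}")
    kept = [t for t in tokens if t not in stopwords]
    if stemmer == "porter":
        return [porter_stem(t) for t in kept]
    return kept
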