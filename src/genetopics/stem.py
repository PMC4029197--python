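"""Porter suffix-stripping stemmer.

Implements the classic 1980 rule set: five sequential steps of suffix
rewrites, each guarded by conditions on the "measure" m of the remaining
stem (the number of vowel-consonant sequences), the presence of a vowel,
double consonants, and the consonant-vowel-consonant shape used to restore
a trailing ``e``. Within a step, the first suffix that matches decides the
rule; if its condition fails, the word passes through unchanged.

The stemmer is used to collapse inflected forms in titles and abstracts
("activity", "activation", "active" -> "activ") before topic modelling, so
that topics are estimated over stems rather than surface words.
"""

from __future__ import annotations

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        # y is a consonant at the start of a word or after a vowel
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel->consonant transitions ([C](VC)^m[V])."""
    n = 0
    i = 0
    length = len(stem)
    while i < length and _is_consonant(stem, i):
        i += 1
    while i < length:
        while i < length and not _is_consonant(stem, i):
            i += 1
        if i >= length:
            break
        n += 1
        while i < length and _is_consonant(stem, i):
            i += 1
    return n


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant, final consonant not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


_STEP2 = (
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def stem(word: str) -> str:
    """Return the Porter stem of ``word`` (expects lowercase input)."""
    w = word
    if len(w) <= 2:
        return w

    # step 1a: plurals
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b: -eed / -ed / -ing
    cleanup = False
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    elif w.endswith("ed"):
        if _has_vowel(w[:-2]):
            w = w[:-2]
            cleanup = True
    elif w.endswith("ing"):
        if _has_vowel(w[:-3]):
            w = w[:-3]
            cleanup = True
    if cleanup:
        if w.endswith(("at", "bl", "iz")):
            w += "e"
        elif _ends_double_consonant(w) and w[-1] not in "lsz":
            w = w[:-1]
        elif _measure(w) == 1 and _ends_cvc(w):
            w += "e"

    # step 1c: y -> i when the stem contains a vowel
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2: double-suffix reductions (m > 0)
    for suffix, repl in _STEP2:
        if w.endswith(suffix):
            base = w[: -len(suffix)]
            if _measure(base) > 0:
                w = base + repl
            break

    # step 3: -ful, -ness, -icate, ... (m > 0)
    for suffix, repl in _STEP3:
        if w.endswith(suffix):
            base = w[: -len(suffix)]
            if _measure(base) > 0:
                w = base + repl
            break

    # step 4: strip residual suffixes (m > 1)
    for suffix in _STEP4:
        if w.endswith(suffix):
            base = w[: -len(suffix)]
            if _measure(base) > 1 and (
                suffix != "ion" or (base and base[-1] in "st")
            ):
                w = base
            break

    # step 5a: drop a final e
    if w.endswith("e"):
        base = w[:-1]
        m = _measure(base)
        if m > 1 or (m == 1 and not _ends_cvc(base)):
            w = base

    # step 5b: -ll -> -l for long stems
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        w = w[:-1]

    return w
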