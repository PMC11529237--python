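"""Porter stemmer (original 1980 rule set).

No stemming library ships with the target environment, so the algorithm is
implemented here in full.  The implementation follows the original rule
tables, including the longest-match-per-step discipline: within a step, only
the longest matching suffix is considered, and if its condition fails no
shorter suffix of that step is tried.

Note on a known quirk: canonical Porter maps ``programmer`` -> ``programm``
(not ``program``); this module deliberately matches the canonical behaviour
rather than informal descriptions of it.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiou")


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        # 'y' is a vowel when preceded by a consonant
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in *stem* (the measure m of the algorithm)."""
    m = 0
    prev_cons = True
    seen_vowel = False
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if cons and seen_vowel:
            m += 1
            seen_vowel = False
        elif not cons:
            seen_vowel = True
        prev_cons = cons  # noqa: F841 - kept for clarity of the scan
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    """consonant-vowel-consonant ending where the last consonant is not w/x/y."""
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    flag = False
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        w = w[:-2]
        flag = True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w = w[:-3]
        flag = True
    if flag:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_consonant(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


_STEP2 = (
    ("ational", "ate"),
    ("tional", "tion"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("izer", "ize"),
    ("abli", "able"),
    ("alli", "al"),
    ("entli", "ent"),
    ("eli", "e"),
    ("ousli", "ous"),
    ("ization", "ize"),
    ("ation", "ate"),
    ("ator", "ate"),
    ("alism", "al"),
    ("iveness", "ive"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("aliti", "al"),
    ("iviti", "ive"),
    ("biliti", "ble"),
)

_STEP3 = (
    ("icate", "ic"),
    ("ative", ""),
    ("alize", "al"),
    ("iciti", "ic"),
    ("ical", "ic"),
    ("ful", ""),
    ("ness", ""),
)

_STEP4 = (
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
)


def _longest_match(w: str, suffixes) -> str | None:
    best = None
    for s in suffixes:
        if w.endswith(s) and (best is None or len(s) > len(best)):
            best = s
    return best


def _step2(w: str) -> str:
    match = _longest_match(w, [s for s, _ in _STEP2])
    if match is None:
        return w
    repl = dict(_STEP2)[match]
    stem = w[: -len(match)]
    if _measure(stem) > 0:
        return stem + repl
    return w


def _step3(w: str) -> str:
    match = _longest_match(w, [s for s, _ in _STEP3])
    if match is None:
        return w
    repl = dict(_STEP3)[match]
    stem = w[: -len(match)]
    if _measure(stem) > 0:
        return stem + repl
    return w


def _step4(w: str) -> str:
    match = _longest_match(w, _STEP4)
    if match is None:
        return w
    stem = w[: -len(match)]
    if _measure(stem) <= 1:
        return w
    if match == "ion" and not stem.endswith(("s", "t")):
        return w
    return stem


def _step5a(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1:
            return stem
        if m == 1 and not _ends_cvc(stem):
            return stem
    return w


def _step5b(w: str) -> str:
    if _measure(w) > 1 and _ends_double_consonant(w) and w.endswith("l"):
        return w[:-1]
    return w


def porter_stem(word: str) -> str:
    """Return the Porter stem of a lowercase word.

    Words of length <= 2 are returned unchanged, per the original algorithm.
    """
    if len(word) <= 2:
        return word
    w = _step1a(word)
    w = _step1b(w)
    w = _step1c(w)
    w = _step2(w)
    w = _step3(w)
    w = _step4(w)
    w = _step5a(w)
    w = _step5b(w)
    return w
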