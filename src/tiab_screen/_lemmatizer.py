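"""Default rule-based English lemmatizer.

The lemmatizer component is injectable (any ``Callable[[str], str]`` works);
this default is a small suffix-rule engine that undoes plural, past-tense and
progressive inflection and leaves unknown or underived forms untouched
(``analyzing -> analyze``, ``programming -> program``, but the noun
``programmer`` passes through unchanged).  Since a Porter stem step follows
in the standard pipeline, residual imperfections here mostly wash out; the
lemma step exists to merge inflection families *before* stemming so that the
two reductions compose (e.g. ``analyzing`` and ``analyze`` meet at the lemma
before both stem to ``analyz``).
"""

from __future__ import annotations

_VOWELS = set("aeiou")

# irregular forms worth special-casing in scientific abstracts
_EXCEPTIONS = {
    "analyses": "analysis",
    "hypotheses": "hypothesis",
    "criteria": "criterion",
    "data": "data",
    "children": "child",
    "women": "woman",
    "men": "man",
    "studies": "study",
    "was": "be",
    "were": "be",
    "is": "be",
    "are": "be",
    "has": "have",
    "had": "have",
    "done": "do",
    "found": "find",
    "shown": "show",
}

# after stripping -ing/-ed, these stem endings take a restored final 'e'
_RESTORE_E = ("at", "bl", "iz", "yz", "us", "uc", "ud", "ur", "iv", "as", "os")


def _undo_progressive(stem: str) -> str:
    if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS and stem[-1] not in "lsz":
        return stem[:-1]
    if stem.endswith(_RESTORE_E):
        return stem + "e"
    return stem


def default_lemmatize(token: str) -> str:
    """Lemmatize one lowercase token; unknown shapes pass through unchanged."""
    if token in _EXCEPTIONS:
        return _EXCEPTIONS[token]
    if len(token) <= 3:
        return token
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("sses"):
        return token[:-2]
    if token.endswith("s") and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    if token.endswith("ing") and len(token) > 5:
        return _undo_progressive(token[:-3])
    if token.endswith("ed") and len(token) > 4:
        return _undo_progressive(token[:-2])
    return token
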