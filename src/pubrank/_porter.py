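"""Classic Porter (1980) suffix-stripping stemmer.

Implements the original published algorithm: five rule steps over a
consonant/vowel measure m, longest-suffix matching within each step, no
later extensions (so e.g. "dies" -> "di", "ties" -> "ti", as in the
original definition).  Words of length <= 2 are returned unchanged.
"""

from __future__ import annotations

__all__ = ["porter_stem"]

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """m in [C](VC)^m[V]: the number of vowel->consonant transitions."""
    m = 0
    prev_cons = True
    started = False
    for i in range(len(stem)):
        cons = _is_consonant(stem, i)
        if not cons:
            started = True
        if cons and started and not prev_cons:
            m += 1
        prev_cons = cons
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
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _longest_rule(word: str, rules: list[tuple[str, str]]) -> tuple[str, str] | None:
    best = None
    for suffix, repl in rules:
        if word.endswith(suffix) and (best is None or len(suffix) > len(best[0])):
            best = (suffix, repl)
    return best


def _apply_measure_rules(word: str, rules: list[tuple[str, str]], min_m: int) -> str:
    """Longest matching suffix; replace only if m(stem) > min_m - fails closed."""
    match = _longest_rule(word, rules)
    if match is None:
        return word
    suffix, repl = match
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) >= min_m:
        return stem + repl
    return word


def _step1a(word: str) -> str:
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies"):
        return word[:-2]
    if word.endswith("ss"):
        return word
    if word.endswith("s"):
        return word[:-1]
    return word


def _step1b(word: str) -> str:
    if word.endswith("eed"):
        stem = word[:-3]
        if _measure(stem) > 0:
            return word[:-1]
        return word
    fired = False
    if word.endswith("ed"):
        stem = word[:-2]
        if _contains_vowel(stem):
            word, fired = stem, True
    elif word.endswith("ing"):
        stem = word[:-3]
        if _contains_vowel(stem):
            word, fired = stem, True
    if fired:
        if word.endswith(("at", "bl", "iz")):
            return word + "e"
        if _ends_double_consonant(word) and word[-1] not in "lsz":
            return word[:-1]
        if _measure(word) == 1 and _ends_cvc(word):
            return word + "e"
    return word


def _step1c(word: str) -> str:
    if word.endswith("y") and _contains_vowel(word[:-1]):
        return word[:-1] + "i"
    return word


_STEP2_RULES = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3_RULES = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4_SUFFIXES = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _step4(word: str) -> str:
    match = _longest_rule(word, [(s, "") for s in _STEP4_SUFFIXES])
    if match is None:
        return word
    suffix = match[0]
    stem = word[: len(word) - len(suffix)]
    if suffix == "ion" and (not stem or stem[-1] not in "st"):
        return word
    if _measure(stem) > 1:
        return stem
    return word


def _step5a(word: str) -> str:
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            return stem
    return word


def _step5b(word: str) -> str:
    if _measure(word) > 1 and _ends_double_consonant(word) and word[-1] == "l":
        return word[:-1]
    return word


def porter_stem(word: str) -> str:
    """Stem a single lowercase word with the classic Porter algorithm."""
    if len(word) <= 2:
        return word
    word = _step1a(word)
    word = _step1b(word)
    word = _step1c(word)
    word = _apply_measure_rules(word, _STEP2_RULES, 1)
    word = _apply_measure_rules(word, _STEP3_RULES, 1)
    word = _step4(word)
    word = _step5a(word)
    word = _step5b(word)
    return word
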