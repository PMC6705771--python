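"""Porter2 (Snowball English) stemming algorithm.

Self-contained implementation of the standard English Snowball stemmer:
lowercase input, exceptional-form table, R1/R2 regions, and steps 0-5
exactly as the algorithm defines them.  Input is expected to be a single
lowercase word; callers handle case folding.
"""

from __future__ import annotations

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDINGS = frozenset("cdeghkmnrt")

_EXCEPTIONS1 = {
    "skis": "ski",
    "skies": "sky",
    "dying": "die",
    "lying": "lie",
    "tying": "tie",
    "idly": "idl",
    "gently": "gentl",
    "ugly": "ugli",
    "early": "earli",
    "only": "onli",
    "singly": "singl",
    "sky": "sky",
    "news": "news",
    "howe": "howe",
    "atlas": "atlas",
    "cosmos": "cosmos",
    "bias": "bias",
    "andes": "andes",
}

_EXCEPTIONS2 = frozenset(
    ["inning", "outing", "canning", "herring", "earring",
     "proceed", "exceed", "succeed"]
)

_SPECIAL_R1_PREFIXES = ("gener", "commun", "arsen")

_STEP2_RULES = [
    # (suffix, replacement); longest-match-wins, special cases handled inline
    ("ization", "ize"),
    ("ational", "ate"),
    ("fulness", "ful"),
    ("ousness", "ous"),
    ("iveness", "ive"),
    ("tional", "tion"),
    ("biliti", "ble"),
    ("lessli", "less"),
    ("entli", "ent"),
    ("ation", "ate"),
    ("alism", "al"),
    ("aliti", "al"),
    ("ousli", "ous"),
    ("iviti", "ive"),
    ("fulli", "ful"),
    ("enci", "ence"),
    ("anci", "ance"),
    ("abli", "able"),
    ("izer", "ize"),
    ("ator", "ate"),
    ("alli", "al"),
    ("bli", "ble"),
    ("ogi", "og"),   # only if preceded by l
    ("li", ""),      # only if preceded by a valid li-ending
]

_STEP3_RULES = [
    ("ational", "ate"),
    ("tional", "tion"),
    ("alize", "al"),
    ("icate", "ic"),
    ("iciti", "ic"),
    ("ative", ""),   # only if in R2
    ("ical", "ic"),
    ("ness", ""),
    ("ful", ""),
]

_STEP4_SUFFIXES = [
    "ement", "ance", "ence", "able", "ible", "ment",
    "ant", "ent", "ism", "ate", "iti", "ous", "ive", "ize",
    "ion", "al", "er", "ic",
]


def _mark_ys(word: str) -> str:
    # y at start or after a vowel acts as a consonant; mark it Y
    chars = list(word)
    for i, c in enumerate(chars):
        if c == "y" and (i == 0 or chars[i - 1] in "aeiouy"):
            chars[i] = "Y"
    return "".join(chars)


def _regions(word: str) -> tuple[int, int]:
    n = len(word)

    def region_after(start: int) -> int:
        i = start
        while i < n and word[i] not in "aeiouy":
            i += 1
        while i < n and word[i] in "aeiouy":
            i += 1
        # i now at first non-vowel after a vowel (or end)
        return min(i + 1, n)

    r1 = n
    for pfx in _SPECIAL_R1_PREFIXES:
        if word.startswith(pfx):
            r1 = len(pfx)
            break
    else:
        r1 = region_after(0)
    r2 = region_after(r1)
    return r1, r2


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return word[0] in "aeiouy" and word[1] not in "aeiouy"
    if n >= 3:
        a, b, c = word[-3], word[-2], word[-1]
        return (
            b in "aeiouy"
            and a not in "aeiouy"
            and c not in "aeiouy"
            and c not in "wxY"
        )
    return False


def _is_short(word: str, r1: int) -> bool:
    return r1 >= len(word) and _ends_short_syllable(word)


def _contains_vowel(s: str) -> bool:
    return any(c in "aeiouy" for c in s)


def stem(word: str) -> str:
    """Return the Porter2 stem of a lowercase English word."""
    if len(word) <= 2:
        return word
    if word.startswith("'"):
        word = word[1:]
    if word in _EXCEPTIONS1:
        return _EXCEPTIONS1[word]
    if len(word) <= 2:
        return word

    word = _mark_ys(word)
    r1, r2 = _regions(word)

    # step 0: strip apostrophe suffixes
    for sfx in ("'s'", "'s", "'"):
        if word.endswith(sfx):
            word = word[: -len(sfx)]
            break

    # step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-2] if len(word) > 4 else word[:-1]
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if _contains_vowel(word[:-2]):
            word = word[:-1]

    if word in _EXCEPTIONS2:
        return word

    # step 1b
    step1b_done = False
    for sfx in ("eedly", "eed"):
        if word.endswith(sfx):
            if len(word) - len(sfx) >= r1:
                word = word[: -len(sfx)] + "ee"
            step1b_done = True
            break
    if not step1b_done:
        for sfx in ("ingly", "edly", "ing", "ed"):
            if word.endswith(sfx):
                stem_part = word[: -len(sfx)]
                if _contains_vowel(stem_part):
                    word = stem_part
                    if word.endswith(("at", "bl", "iz")):
                        word += "e"
                    elif word.endswith(_DOUBLES):
                        word = word[:-1]
                    elif _is_short(word, r1):
                        word += "e"
                break

    # step 1c
    if (
        len(word) > 2
        and word[-1] in "yY"
        and word[-2] not in "aeiouy"
    ):
        word = word[:-1] + "i"

    # step 2
    for sfx, repl in _STEP2_RULES:
        if word.endswith(sfx):
            if len(word) - len(sfx) >= r1:
                if sfx == "ogi":
                    if word.endswith("logi"):
                        word = word[:-1]
                elif sfx == "li":
                    if len(word) > 2 and word[-3] in _LI_ENDINGS:
                        word = word[:-2]
                else:
                    word = word[: -len(sfx)] + repl
            break

    # step 3
    for sfx, repl in _STEP3_RULES:
        if word.endswith(sfx):
            if len(word) - len(sfx) >= r1:
                if sfx == "ative":
                    if len(word) - len(sfx) >= r2:
                        word = word[: -len(sfx)]
                else:
                    word = word[: -len(sfx)] + repl
            break

    # step 4
    for sfx in _STEP4_SUFFIXES:
        if word.endswith(sfx):
            if len(word) - len(sfx) >= r2:
                if sfx == "ion":
                    if len(word) > 3 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(sfx)]
            break

    # step 5
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("ll") and len(word) - 1 >= r2:
        word = word[:-1]

    return word.replace("Y", "y")
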