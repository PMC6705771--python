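"""Sentence splitting, tokenization, stemming, entity blanking and the
four-way token categorization.

Tokens keep internal hyphens, slashes and colons so that fusion surface
forms such as ``BCR-ABL``, ``bcr/abl`` or ``BCR:ABL1`` survive
tokenization as single tokens; punctuation tokens are discarded.  Every
token is assigned exactly one of four categories — Biological,
Miscellaneous, Function, Literal — with precedence
Literal > Function > Biological > Miscellaneous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._porter2 import stem as porter2_stem
from .corpus_io import Document
from .lexicon import SEPARATORS, Lexicon

CATEGORIES = ("Biological", "Miscellaneous", "Function", "Literal")

#: placeholder vocabulary used by entity blanking
PLACEHOLDERS = {
    "gene": "GENE",
    "fusion": "FUSION",
    "disease": "DISEASE",
    "action": "ACTION",
}

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:[-–—/:][A-Za-z0-9]+)*")
_SENT_PUNCT_RE = re.compile(r"[.!?]+")

#: words after which a period does not end a sentence
ABBREVIATIONS = frozenset(
    ["e.g", "i.e", "et", "al", "fig", "figs", "dr", "vs", "cf",
     "ref", "refs", "approx", "resp"]
)


@dataclass
class Sentence:
    doc_id: str
    index: int
    text: str
    span: tuple[int, int]  # in document body


@dataclass
class Token:
    surface: str
    span: tuple[int, int]  # in sentence text
    stem: str | None = None
    category: str | None = None

    @property
    def is_separator_form(self) -> bool:
        return any(c in SEPARATORS for c in self.surface)


def split_sentences(document: Document) -> list[Sentence]:
    """Rule-based sentence splitting.

    A sentence boundary is terminal punctuation followed by whitespace and
    an uppercase letter or digit, unless the preceding word is a known
    abbreviation.  Sentence spans tile the body without overlap, so the
    concatenation of all sentence texts reproduces the body exactly.
    """
    body = document.body
    if not body.strip():
        return []
    starts = [0]
    for m in _SENT_PUNCT_RE.finditer(body):
        rest = body[m.end():]
        ws = len(rest) - len(rest.lstrip())
        if ws == 0 or len(rest) == ws:
            continue
        nxt = rest[ws]
        if not (nxt.isupper() or nxt.isdigit()):
            continue
        prev_word = re.findall(r"[\w.]+", body[: m.start()])
        if prev_word and prev_word[-1].casefold().rstrip(".") in ABBREVIATIONS:
            continue
        starts.append(m.end() + ws)
    starts = sorted(set(starts))
    sentences = []
    for i, start in enumerate(starts):
        end = starts[i + 1] if i + 1 < len(starts) else len(body)
        sentences.append(
            Sentence(
                doc_id=document.doc_id,
                index=i,
                text=body[start:end],
                span=(start, end),
            )
        )
    return sentences


def tokenize(sentence: Sentence | str) -> list[Token]:
    """Split a sentence into word tokens, discarding punctuation.

    Internal hyphens (including en/em dashes), slashes and colons joining
    alphanumeric runs are kept inside one token, so ``BCR-ABL-selective``,
    ``BCR/ABL`` and ``bcr:abl`` each come out as a single token.
    """
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    return [
        Token(surface=m.group(), span=(m.start(), m.end()))
        for m in _TOKEN_RE.finditer(text)
    ]


def stem_tokens(tokens: list[Token]) -> list[Token]:
    """Attach Porter2 stems in place (and return the list).

    Tokens containing separator characters are candidate fusion forms and
    are exempt from stemming: their stem is the case-folded surface.
    """
    for token in tokens:
        folded = token.surface.casefold()
        token.stem = folded if token.is_separator_form else porter2_stem(folded)
    return tokens


def blank_entities(
    sentence_text: str,
    spans: list[tuple[int, int, str]],
) -> str:
    """Replace recognized entity spans with class placeholders.

    ``spans`` holds (start, end, label) triples relative to the sentence
    text; labels outside the placeholder vocabulary are left untouched.
    Replacement proceeds span-descending so earlier offsets stay valid;
    on overlap the outermost (longest, then leftmost) span wins.
    """
    kept: list[tuple[int, int, str]] = []
    for start, end, label in sorted(
        spans, key=lambda s: (-(s[1] - s[0]), s[0])
    ):
        if label not in PLACEHOLDERS:
            continue
        if any(start < k_end and k_start < end for k_start, k_end, _ in kept):
            continue
        kept.append((start, end, label))
    text = sentence_text
    for start, end, label in sorted(kept, key=lambda s: -s[0]):
        text = text[:start] + PLACEHOLDERS[label] + text[end:]
    return text


def categorize_tokens(tokens: list[Token], lexicon: Lexicon) -> list[Token]:
    """Assign each token one of the four categories, in place.

    Precedence: (1) Literal for stopwords; (2) Function for action-verb
    variants/stems and evaluative adjectives; (3) Biological for domain
    adjectives, gene symbols, fusion aliases and gene-pair separator
    forms; (4) Miscellaneous otherwise.
    """
    if any(t.stem is None for t in tokens):
        stem_tokens(tokens)
    for token in tokens:
        folded = token.surface.casefold()
        if folded in lexicon.stopwords:
            token.category = "Literal"
        elif (
            lexicon.action_lemma(folded) is not None
            or folded in lexicon.evaluative_adjectives
        ):
            token.category = "Function"
        elif (
            folded in lexicon.domain_adjectives
            or lexicon.gene_symbol(folded) is not None
            or lexicon.fusion_alias(folded) is not None
            or _is_gene_pair_form(folded, lexicon)
        ):
            token.category = "Biological"
        else:
            token.category = "Miscellaneous"
    return tokens


def _is_gene_pair_form(folded_surface: str, lexicon: Lexicon) -> bool:
    if not any(c in SEPARATORS for c in folded_surface):
        return False
    parts = re.split(f"[{re.escape(SEPARATORS)}]", folded_surface)
    if len(parts) < 2:
        return False
    return (
        lexicon.gene_symbol(parts[0]) is not None
        and lexicon.gene_symbol(parts[1]) is not None
    )
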