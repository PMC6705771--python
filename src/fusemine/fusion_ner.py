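"""Fusion-mention detection, normalization, and sentence-level relation
extraction.

A fusion mention is a two-gene surface form (``BCR-ABL``, ``bcr/abl1``,
``BCR:ABL`` ...) detected either because both parts resolve to gene
symbols and a fusion keyword occurs nearby, or because the whole form is
a known fusion alias.  Interactions and disease links are same-sentence
co-occurrence tuples pairing a fusion with a partner gene (or disease
term) through an action verb; no syntactic role assignment is attempted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .corpus_io import AnnotationSet, Corpus, Document, Mention
from .lexicon import SEPARATORS, Lexicon
from .textproc import Sentence, Token, categorize_tokens, split_sentences, tokenize

log = logging.getLogger(__name__)

_SPLIT_RE = re.compile(f"[{re.escape(SEPARATORS)}]")

#: default token window for fusion-keyword support
KEYWORD_WINDOW = 5


class NormalizationError(ValueError):
    """A surface form could not be resolved to a normalized fusion id."""


@dataclass
class FusionMention:
    gene_a: str
    gene_b: str
    separator: str
    surface: str
    span: tuple[int, int]  # in sentence text
    normalized_id: str
    keyword_support: bool


@dataclass
class InteractionMention:
    fusion: FusionMention
    partner: str  # normalized gene symbol
    action_lemma: str
    sentence_ref: tuple[str, int]  # (doc_id, sentence index)
    evidence: str


@dataclass
class DiseaseLink:
    fusion: FusionMention
    disease: str
    action_lemma: str
    sentence_ref: tuple[str, int]


def normalize_fusion(surface_form: str, lexicon: Lexicon) -> str:
    """Map a fusion surface form to its canonical ``GENEA-GENEB`` id.

    Case-folds, maps every separator dialect (hyphen, en/em dash, slash,
    colon) to a hyphen, and resolves both the whole form and its parts
    through the alias tables.  Idempotent on its own output.
    """
    alias = lexicon.fusion_alias(surface_form)
    if alias is not None:
        return alias
    folded = _SPLIT_RE.sub("-", surface_form.casefold())
    parts = folded.split("-")
    parts = [p for p in parts if p]
    if len(parts) >= 2:
        # try every split point so gene names containing hyphens resolve
        for k in range(1, len(parts)):
            left = lexicon.gene_symbol("-".join(parts[:k]))
            right = lexicon.gene_symbol("-".join(parts[k:]))
            if left and right:
                return f"{left.upper()}-{right.upper()}"
        # trailing non-gene parts (e.g. "-selective") are tolerated
        left = lexicon.gene_symbol(parts[0])
        right = lexicon.gene_symbol(parts[1])
        if left and right:
            return f"{left.upper()}-{right.upper()}"
    raise NormalizationError(
        f"cannot normalize fusion surface form {surface_form!r}"
    )


def find_keyword_positions(tokens: list[Token], lexicon: Lexicon) -> list[int]:
    """Token indices at which a fusion-keyword variant starts."""
    return [i for i, _ in _scan_forms(tokens, lexicon.keyword_forms())]


def _scan_forms(
    tokens: list[Token], forms: dict[tuple[str, ...], str]
) -> list[tuple[int, tuple[int, str]]]:
    """Greedy longest-match scan of multiword variants over tokens.

    Returns (start index, (length, canonical)) pairs.
    """
    folded = [t.surface.casefold() for t in tokens]
    max_len = max((len(f) for f in forms), default=0)
    hits = []
    i = 0
    while i < len(folded):
        matched = False
        for length in range(min(max_len, len(folded) - i), 0, -1):
            canonical = forms.get(tuple(folded[i : i + length]))
            if canonical is not None:
                hits.append((i, (length, canonical)))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return hits


def detect_fusion_mentions(
    sentence: Sentence | str,
    tokens: list[Token],
    lexicon: Lexicon,
    keyword_window: int = KEYWORD_WINDOW,
) -> list[FusionMention]:
    """Detect fusion mentions among the tokens of one sentence.

    A separator-joined token is emitted as a mention when (a) its first
    two parts resolve to gene symbols and a fusion keyword occurs within
    ``keyword_window`` tokens, or (b) the whole form is a known fusion
    alias (no keyword required).  ``keyword_support`` records whether a
    keyword was found in the window.
    """
    keyword_positions = find_keyword_positions(tokens, lexicon)
    mentions = []
    for i, token in enumerate(tokens):
        if not token.is_separator_form:
            continue
        folded = token.surface.casefold()
        has_keyword = any(
            abs(k - i) <= keyword_window for k in keyword_positions
        )
        alias = lexicon.fusion_alias(folded)
        if alias is None:
            parts = [p for p in _SPLIT_RE.split(folded) if p]
            if len(parts) < 2:
                continue
            gene_a = lexicon.gene_symbol(parts[0])
            gene_b = lexicon.gene_symbol(parts[1])
            if gene_a is None or gene_b is None:
                if (gene_a is None) != (gene_b is None):
                    log.debug(
                        "ambiguous pair %r: gene on one side only", folded
                    )
                continue
            if not has_keyword:
                continue
            normalized = f"{gene_a.upper()}-{gene_b.upper()}"
        else:
            gene_a, _, gene_b = alias.partition("-")
            normalized = alias
        mentions.append(
            FusionMention(
                gene_a=gene_a,
                gene_b=gene_b,
                separator=next(c for c in token.surface if c in SEPARATORS),
                surface=token.surface,
                span=token.span,
                normalized_id=normalized,
                keyword_support=has_keyword,
            )
        )
    return mentions


def _nearest_action(
    action_positions: list[tuple[int, str]], i: int, j: int
) -> str | None:
    """Action lemma nearest to the token interval [min(i,j), max(i,j)].

    Action tokens lying between the two entities win over tokens outside;
    ties break toward the earliest token.  Returns None when no action
    token exists.
    """
    if not action_positions:
        return None
    lo, hi = min(i, j), max(i, j)

    def distance(pos: int) -> int:
        if lo <= pos <= hi:
            return 0
        return lo - pos if pos < lo else pos - hi

    best = min(action_positions, key=lambda ap: (distance(ap[0]), ap[0]))
    return best[1]


def find_action_positions(
    tokens: list[Token], lexicon: Lexicon
) -> list[tuple[int, str]]:
    out = []
    for i, token in enumerate(tokens):
        if token.is_separator_form:
            continue
        lemma = lexicon.action_lemma(token.surface)
        if lemma is not None:
            out.append((i, lemma))
    return out


def detect_interactions(
    sentence: Sentence,
    tokens: list[Token],
    fusion_mentions: list[FusionMention],
    lexicon: Lexicon,
) -> list[InteractionMention]:
    """Extract (fusion, partner gene, action) co-occurrence tuples.

    One interaction is emitted per (fusion, partner) pair present in the
    sentence, provided an action token occurs in it; the action lemma is
    the one nearest to the pair.  A single action verb thus distributes
    over coordinated fusion lists ("... bind NPM-ALK and ATIC-ALK").
    Partners never equal a component gene of any fusion in the sentence.
    """
    if not fusion_mentions:
        return []
    actions = find_action_positions(tokens, lexicon)
    if not actions:
        return []
    components = {
        g.casefold() for m in fusion_mentions for g in (m.gene_a, m.gene_b)
    }
    fusion_by_span = {m.span: m for m in fusion_mentions}
    partners = []
    for i, token in enumerate(tokens):
        if token.span in fusion_by_span or token.is_separator_form:
            continue
        symbol = lexicon.gene_symbol(token.surface)
        if symbol is not None and symbol.casefold() not in components:
            partners.append((i, symbol))
    index_of = {
        m.span: next(
            i for i, t in enumerate(tokens) if t.span == m.span
        )
        for m in fusion_mentions
    }
    out = []
    seen = set()
    for mention in fusion_mentions:
        fi = index_of[mention.span]
        for pi, symbol in partners:
            key = (mention.normalized_id, symbol)
            if key in seen:
                continue
            lemma = _nearest_action(actions, fi, pi)
            if lemma is None:
                continue
            seen.add(key)
            out.append(
                InteractionMention(
                    fusion=mention,
                    partner=symbol,
                    action_lemma=lemma,
                    sentence_ref=(sentence.doc_id, sentence.index),
                    evidence=sentence.text.strip(),
                )
            )
    return out


def detect_disease_links(
    sentence: Sentence,
    tokens: list[Token],
    fusion_mentions: list[FusionMention],
    lexicon: Lexicon,
) -> list[DiseaseLink]:
    """Extract (fusion, disease term, action verb) co-occurrence triples."""
    if not fusion_mentions:
        return []
    actions = find_action_positions(tokens, lexicon)
    if not actions:
        return []
    disease_hits = _scan_forms(tokens, lexicon.disease_forms())
    index_of = {
        m.span: next(i for i, t in enumerate(tokens) if t.span == m.span)
        for m in fusion_mentions
    }
    out = []
    seen = set()
    for mention in fusion_mentions:
        fi = index_of[mention.span]
        for di, (_, canonical) in disease_hits:
            key = (mention.normalized_id, canonical, di)
            if key in seen:
                continue
            lemma = _nearest_action(actions, fi, di)
            if lemma is None:
                continue
            seen.add(key)
            out.append(
                DiseaseLink(
                    fusion=mention,
                    disease=canonical,
                    action_lemma=lemma,
                    sentence_ref=(sentence.doc_id, sentence.index),
                )
            )
    return out


# -- document/corpus annotation -----------------------------------------

def annotate_document(
    document: Document,
    lexicon: Lexicon,
    keyword_window: int = KEYWORD_WINDOW,
) -> AnnotationSet:
    """Run sentence splitting, tagging and relation extraction on one
    document, returning document-level annotations.

    Mention labels: ``fusion``, ``gene`` (gene tokens outside fusions),
    ``action``, ``disease``, ``keyword``.
    """
    aset = AnnotationSet(doc_id=document.doc_id)
    for sentence in split_sentences(document):
        offset = sentence.span[0]
        tokens = tokenize(sentence)
        categorize_tokens(tokens, lexicon)
        fusions = detect_fusion_mentions(
            sentence, tokens, lexicon, keyword_window
        )
        fusion_spans = {m.span for m in fusions}
        for m in fusions:
            aset.mentions.append(
                Mention(
                    start=offset + m.span[0],
                    end=offset + m.span[1],
                    label="fusion",
                    normalized_id=m.normalized_id,
                    surface=m.surface,
                )
            )
        for i, token in enumerate(tokens):
            if token.span in fusion_spans:
                continue
            symbol = None if token.is_separator_form else lexicon.gene_symbol(token.surface)
            if symbol is not None:
                aset.mentions.append(
                    Mention(
                        start=offset + token.span[0],
                        end=offset + token.span[1],
                        label="gene",
                        normalized_id=symbol,
                        surface=token.surface,
                    )
                )
        for i, lemma in find_action_positions(tokens, lexicon):
            token = tokens[i]
            aset.mentions.append(
                Mention(
                    start=offset + token.span[0],
                    end=offset + token.span[1],
                    label="action",
                    normalized_id=lemma,
                    surface=token.surface,
                )
            )
        for start_idx, (length, canonical) in _scan_forms(
            tokens, lexicon.disease_forms()
        ):
            first, last = tokens[start_idx], tokens[start_idx + length - 1]
            aset.mentions.append(
                Mention(
                    start=offset + first.span[0],
                    end=offset + last.span[1],
                    label="disease",
                    normalized_id=canonical,
                    surface=sentence.text[first.span[0] : last.span[1]],
                )
            )
        for start_idx, (length, canonical) in _scan_forms(
            tokens, lexicon.keyword_forms()
        ):
            first, last = tokens[start_idx], tokens[start_idx + length - 1]
            aset.mentions.append(
                Mention(
                    start=offset + first.span[0],
                    end=offset + last.span[1],
                    label="keyword",
                    normalized_id=canonical,
                    surface=sentence.text[first.span[0] : last.span[1]],
                )
            )
        for im in detect_interactions(sentence, tokens, fusions, lexicon):
            aset.interactions.append(
                {
                    "fusion": im.fusion.normalized_id,
                    "partner": im.partner,
                    "action": im.action_lemma,
                    "doc_id": im.sentence_ref[0],
                    "sentence_index": im.sentence_ref[1],
                    "evidence": im.evidence,
                }
            )
        for dl in detect_disease_links(sentence, tokens, fusions, lexicon):
            aset.disease_links.append(
                {
                    "fusion": dl.fusion.normalized_id,
                    "disease": dl.disease,
                    "mesh_id": lexicon.mesh_id(dl.disease),
                    "action": dl.action_lemma,
                    "doc_id": dl.sentence_ref[0],
                    "sentence_index": dl.sentence_ref[1],
                }
            )
    aset.mentions.sort(key=lambda m: (m.start, m.end, m.label))
    return aset


def annotate_corpus(
    corpus: Corpus, lexicon: Lexicon, keyword_window: int = KEYWORD_WINDOW
) -> dict[str, AnnotationSet]:
    return {
        doc.doc_id: annotate_document(doc, lexicon, keyword_window)
        for doc in corpus
    }


# -- evidence network ----------------------------------------------------

def export_network(
    interaction_mentions: list[dict | InteractionMention],
    path: str | Path,
) -> nx.Graph:
    """Write the evidence graph as GraphML plus a TSV edge list.

    Nodes are normalized fusion ids and partner gene symbols; each edge
    carries the sorted action lemmas and supporting doc_ids.  Duplicate
    evidence for one (fusion, partner) pair collapses onto one edge.
    ``path`` is a base name; ``<path>.graphml`` and ``<path>.tsv`` are
    written with deterministic node and edge order.
    """
    records = []
    for im in interaction_mentions:
        if isinstance(im, InteractionMention):
            records.append(
                (im.fusion.normalized_id, im.partner, im.action_lemma,
                 im.sentence_ref[0])
            )
        else:
            records.append(
                (im["fusion"], im["partner"], im["action"], im["doc_id"])
            )
    graph = nx.Graph()
    edges: dict[tuple[str, str], dict[str, set]] = {}
    for fusion, partner, action, doc_id in records:
        key = (fusion, partner)
        entry = edges.setdefault(key, {"actions": set(), "doc_ids": set()})
        entry["actions"].add(action)
        entry["doc_ids"].add(doc_id)
    for fusion, partner in sorted(edges):
        if fusion not in graph:
            graph.add_node(fusion, kind="fusion")
        if partner not in graph:
            graph.add_node(partner, kind="gene")
    for (fusion, partner), entry in sorted(edges.items()):
        graph.add_edge(
            fusion,
            partner,
            actions=",".join(sorted(entry["actions"])),
            doc_ids=",".join(sorted(entry["doc_ids"])),
            n_documents=len(entry["doc_ids"]),
        )
    base = Path(path)
    nx.write_graphml(graph, base.with_suffix(".graphml"))
    lines = ["fusion\tpartner\tactions\tdoc_ids"]
    for (fusion, partner), entry in sorted(edges.items()):
        lines.append(
            f"{fusion}\t{partner}\t"
            f"{','.join(sorted(entry['actions']))}\t"
            f"{','.join(sorted(entry['doc_ids']))}"
        )
    base.with_suffix(".tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return graph
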