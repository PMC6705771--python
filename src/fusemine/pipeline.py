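"""End-to-end convenience layer over the tagging and evaluation modules.

Bundles the steps the command-line interface and the evaluation harness
share: corpus loading by format, corpus-level tagging, gold-vs-predicted
scoring of mentions and relations, and document-level classification.
"""

from __future__ import annotations

from pathlib import Path

from .classify_eval import EvalReport, _report_from_counts, cross_validate
from .corpus_io import AnnotationSet, Corpus, read_medline, read_pubmed_xml
from .features import corpus_features
from .fusion_ner import annotate_corpus
from .lexicon import Lexicon, default_lexicon


def read_corpus(path: str | Path) -> Corpus:
    """Load a corpus, dispatching on file extension (.xml -> PubMed XML,
    anything else -> MEDLINE flat file)."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return read_pubmed_xml(path)
    return read_medline(path)


def _mention_keys(sets: dict[str, AnnotationSet], label: str) -> set[tuple]:
    return {
        (doc_id, m.start, m.end, m.normalized_id)
        for doc_id, aset in sets.items()
        for m in aset.mentions
        if m.label == label
    }


def _interaction_keys(sets: dict[str, AnnotationSet]) -> set[tuple]:
    return {
        (doc_id, i["fusion"], i["partner"], i["action"])
        for doc_id, aset in sets.items()
        for i in aset.interactions
    }


def _disease_keys(sets: dict[str, AnnotationSet]) -> set[tuple]:
    return {
        (doc_id, l["fusion"], l["disease"], l["action"])
        for doc_id, aset in sets.items()
        for l in aset.disease_links
    }


def score_against_gold(
    gold: dict[str, AnnotationSet],
    predicted: dict[str, AnnotationSet],
) -> dict[str, EvalReport]:
    """Precision/recall/F for fusion mentions, interactions and disease
    links, comparing predicted annotations with gold.

    Mentions match on (doc_id, span, normalized id); interactions on
    (doc_id, fusion, partner, action); disease links on (doc_id, fusion,
    disease, action).
    """
    out = {}
    for name, keyfn in (
        ("fusion_mentions", lambda s: _mention_keys(s, "fusion")),
        ("interactions", _interaction_keys),
        ("disease_links", _disease_keys),
    ):
        g, p = keyfn(gold), keyfn(predicted)
        tp = len(g & p)
        out[name] = _report_from_counts(tp, len(p - g), len(g - p), 0)
    return out


def classify_documents(
    corpus: Corpus,
    labels: dict[str, str],
    lexicon: Lexicon | None = None,
    annotation_sets: dict[str, AnnotationSet] | None = None,
    positive_label: str = "positive",
    k: int = 10,
    seed: int = 0,
    alpha: float = 1.0,
    vocab_size: int = 1000,
    ngram_range: tuple[int, int] = (1, 2),
) -> EvalReport:
    """Tag, vectorize and cross-validate the document-level classifier."""
    lexicon = lexicon or default_lexicon()
    if annotation_sets is None:
        annotation_sets = annotate_corpus(corpus, lexicon)
    matrix = corpus_features(
        corpus, lexicon, annotation_sets,
        ngram_range=ngram_range, vocab_size=vocab_size,
    )
    y = [labels[doc_id] for doc_id in matrix.doc_ids]
    return cross_validate(
        matrix.values, y, positive_label=positive_label,
        k=k, seed=seed, alpha=alpha,
    )
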