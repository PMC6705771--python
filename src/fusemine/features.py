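"""N-gram extraction, corpus statistics and bag-of-words features.

A token s in document a is weighted by the frequency-score threshold

    T(s, a) = FS(s, a) * log10(tau / sigma(s))

where FS is the in-document frequency of s, tau the number of documents
in the corpus, and sigma(s) the number of documents containing s.  The
global vocabulary is the top-V grams ranked by their maximum T over
documents; each document then becomes a fixed-length vector of its own
T values over that vocabulary, rescaled to unit sum.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .corpus_io import Corpus
from .lexicon import Lexicon
from .textproc import (
    blank_entities,
    categorize_tokens,
    split_sentences,
    stem_tokens,
    tokenize,
)

Gram = tuple[str, ...]


class FeatureError(ValueError):
    pass


@dataclass
class NGramSet:
    n: int
    grams: Counter  # gram tuple -> count

    @property
    def total(self) -> int:
        return sum(self.grams.values())


@dataclass
class CorpusStats:
    tau: int = 0
    sigma_by_token: dict[Gram, int] = field(default_factory=dict)
    fs_by_doc: dict[str, Counter] = field(default_factory=dict)  # doc -> gram counts


@dataclass
class FeatureMatrix:
    doc_ids: list[str]
    vocabulary: list[Gram]
    values: sparse.csr_matrix  # docs x vocabulary, unit-sum rows

    def row(self, doc_id: str) -> np.ndarray:
        return self.values[self.doc_ids.index(doc_id)].toarray().ravel()


def extract_ngrams(stems: list[str], n: int) -> NGramSet:
    """Contiguous n-grams (1 <= n <= 4) over a stem sequence, with counts.

    For a sequence of L tokens the counts sum to max(L - n + 1, 0).
    """
    if not 1 <= n <= 4:
        raise FeatureError(f"n must be in 1..4, got {n}")
    grams = Counter(
        tuple(stems[i : i + n]) for i in range(len(stems) - n + 1)
    )
    return NGramSet(n=n, grams=grams)


def document_grams(
    document_stems: list[str], ngram_range: tuple[int, int] = (1, 2)
) -> Counter:
    """Union of n-gram counts for every n in the inclusive range."""
    lo, hi = ngram_range
    counts: Counter = Counter()
    for n in range(lo, hi + 1):
        counts.update(extract_ngrams(document_stems, n).grams)
    return counts


def compute_stats(corpus_grams: dict[str, Counter]) -> CorpusStats:
    """Corpus-level statistics: tau, per-gram document frequency sigma,
    and per-(gram, document) frequency FS."""
    sigma: Counter = Counter()
    for counts in corpus_grams.values():
        sigma.update(set(counts))
    return CorpusStats(
        tau=len(corpus_grams),
        sigma_by_token=dict(sigma),
        fs_by_doc=dict(corpus_grams),
    )


def threshold_score(fs: float, tau: int, sigma: int) -> float:
    """The frequency-score threshold T = FS * log10(tau / sigma).

    A token occurring in every document scores 0; rarer tokens score
    higher for the same in-document frequency.
    """
    if sigma < 1 or sigma > tau:
        raise FeatureError(f"need 1 <= sigma <= tau, got sigma={sigma} tau={tau}")
    if fs < 0:
        raise FeatureError(f"fs must be non-negative, got {fs}")
    return fs * math.log10(tau / sigma)


def build_bag_of_words(
    corpus_stats: CorpusStats,
    vocab_size: int = 1000,
    min_threshold: float = 0.0,
) -> FeatureMatrix:
    """Fixed-dimension bag-of-words vectors over a global vocabulary.

    The vocabulary is the top ``vocab_size`` grams ranked by
    max-over-documents threshold score (ties broken lexicographically),
    filtered to score >= ``min_threshold``.  Each document row holds its
    own T(s, a) values over that vocabulary, rescaled to unit sum;
    all-zero rows are left as zero.
    """
    if vocab_size < 1:
        raise FeatureError("vocab_size must be >= 1")
    tau = corpus_stats.tau
    if tau == 0:
        return FeatureMatrix(
            doc_ids=[], vocabulary=[], values=sparse.csr_matrix((0, 0))
        )
    max_score: dict[Gram, float] = {}
    for counts in corpus_stats.fs_by_doc.values():
        for gram, fs in counts.items():
            score = threshold_score(fs, tau, corpus_stats.sigma_by_token[gram])
            if score > max_score.get(gram, -1.0):
                max_score[gram] = score
    ranked = sorted(max_score.items(), key=lambda kv: (-kv[1], kv[0]))
    vocabulary = [
        gram for gram, score in ranked[:vocab_size] if score >= min_threshold
    ]
    col = {gram: j for j, gram in enumerate(vocabulary)}
    doc_ids = list(corpus_stats.fs_by_doc)
    matrix = sparse.lil_matrix((len(doc_ids), len(vocabulary)))
    for i, doc_id in enumerate(doc_ids):
        counts = corpus_stats.fs_by_doc[doc_id]
        for gram, fs in counts.items():
            j = col.get(gram)
            if j is not None:
                matrix[i, j] = threshold_score(
                    fs, tau, corpus_stats.sigma_by_token[gram]
                )
    csr = matrix.tocsr()
    row_sums = np.asarray(csr.sum(axis=1)).ravel()
    scale = np.divide(
        1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0
    )
    csr = sparse.diags(scale) @ csr
    return FeatureMatrix(doc_ids=doc_ids, vocabulary=vocabulary, values=csr.tocsr())


# -- corpus-level pipeline ----------------------------------------------

def corpus_stem_sequences(
    corpus: Corpus,
    lexicon: Lexicon,
    annotation_sets: dict | None = None,
    blank: bool = True,
) -> dict[str, list[str]]:
    """Per-document stem sequences, with entity blanking on by default.

    When ``annotation_sets`` is given and ``blank`` is true, recognized
    entity spans (genes, fusions, diseases, actions) are replaced by
    their class placeholders before tokenization, so features generalize
    across specific entities.
    """
    out: dict[str, list[str]] = {}
    for doc in corpus:
        stems: list[str] = []
        aset = (annotation_sets or {}).get(doc.doc_id)
        for sentence in split_sentences(doc):
            text = sentence.text
            if blank and aset is not None:
                lo, hi = sentence.span
                spans = [
                    (m.start - lo, m.end - lo, m.label)
                    for m in aset.mentions
                    if lo <= m.start and m.end <= hi
                ]
                text = blank_entities(text, spans)
            tokens = stem_tokens(tokenize(text))
            stems.extend(t.stem for t in tokens)
        out[doc.doc_id] = stems
    return out


def corpus_features(
    corpus: Corpus,
    lexicon: Lexicon,
    annotation_sets: dict | None = None,
    ngram_range: tuple[int, int] = (1, 2),
    vocab_size: int = 1000,
    min_threshold: float = 0.0,
    blank: bool = True,
) -> FeatureMatrix:
    """Tokenize, stem, (optionally) blank, and vectorize a whole corpus."""
    sequences = corpus_stem_sequences(corpus, lexicon, annotation_sets, blank)
    grams = {
        doc_id: document_grams(stems, ngram_range)
        for doc_id, stems in sequences.items()
    }
    stats = compute_stats(grams)
    return build_bag_of_words(stats, vocab_size, min_threshold)


def token_category_table(
    corpus: Corpus,
    lexicon: Lexicon,
    annotation_sets: dict | None = None,
) -> pd.DataFrame:
    """Per-document token-category counts.

    Columns: fusion-protein tokens (fusion keyword hits), fusion-gene
    tokens (detected fusion mentions), biological tokens, miscellaneous
    tokens.
    """
    from .fusion_ner import annotate_corpus

    if annotation_sets is None:
        annotation_sets = annotate_corpus(corpus, lexicon)
    rows = []
    for doc in corpus:
        aset = annotation_sets[doc.doc_id]
        n_bio = n_misc = 0
        for sentence in split_sentences(doc):
            tokens = categorize_tokens(tokenize(sentence), lexicon)
            n_bio += sum(t.category == "Biological" for t in tokens)
            n_misc += sum(t.category == "Miscellaneous" for t in tokens)
        rows.append(
            {
                "doc_id": doc.doc_id,
                "fusion_protein_tokens": sum(
                    m.label == "keyword" for m in aset.mentions
                ),
                "fusion_gene_tokens": sum(
                    m.label == "fusion" for m in aset.mentions
                ),
                "biological_tokens": n_bio,
                "miscellaneous_tokens": n_misc,
            }
        )
    return pd.DataFrame(rows)


# -- export --------------------------------------------------------------

def export_features(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the sparse matrix as MTX plus a vocabulary TSV."""
    base = Path(path)
    spio.mmwrite(str(base.with_suffix(".mtx")), matrix.values.tocoo())
    lines = ["index\tgram"]
    for j, gram in enumerate(matrix.vocabulary):
        lines.append(f"{j}\t{' '.join(gram)}")
    base.with_suffix(".vocab.tsv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )
    base.with_suffix(".docs.tsv").write_text(
        "doc_id\n" + "\n".join(matrix.doc_ids) + "\n", encoding="utf-8"
    )
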