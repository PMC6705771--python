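"""Reading and writing documents and annotations.

Supports the two PubMed interchange dialects (MEDLINE flat file and
PubMed XML), a JSON annotation format for tagged mentions and extracted
interactions, an HTML highlight report, and an optional networked
abstract fetcher.  Character offsets are 0-based, half-open and counted
in Unicode code points on the raw document body.
"""

from __future__ import annotations

import html
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Medline
from lxml import etree

log = logging.getLogger(__name__)


class CorpusIOError(ValueError):
    """Raised on malformed corpus or annotation inputs."""


@dataclass
class Document:
    doc_id: str
    title: str = ""
    body: str = ""
    year: int | None = None
    is_full_text: bool = False

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusIOError("doc_id must be non-empty")


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusIOError(f"duplicate doc_id(s) in corpus: {dupes}")

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, doc_id: str) -> Document:
        for doc in self.documents:
            if doc.doc_id == doc_id:
                return doc
        raise KeyError(doc_id)


@dataclass
class Mention:
    """An entity mention: document-level span, label, normalized id."""

    start: int
    end: int
    label: str  # gene | fusion | disease | action | keyword
    normalized_id: str
    surface: str = ""


@dataclass
class AnnotationSet:
    doc_id: str
    mentions: list[Mention] = field(default_factory=list)
    interactions: list[dict] = field(default_factory=list)
    disease_links: list[dict] = field(default_factory=list)


# -- MEDLINE flat file ---------------------------------------------------

def read_medline(path: str | Path) -> Corpus:
    """Read a MEDLINE flat file (PMID-/TI-/AB- tagged records).

    Records missing an abstract are kept with an empty body (and logged);
    records without a PMID are skipped with a warning.  Latin-1 encoded
    files are transcoded on read.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError:
        text = path.read_text(encoding="latin-1")
    documents = []
    skipped = 0
    with_handle = text.splitlines(keepends=True)
    for record in Medline.parse(iter(with_handle)):
        pmid = record.get("PMID")
        if not pmid:
            skipped += 1
            log.warning("skipping MEDLINE record without PMID")
            continue
        body = record.get("AB", "")
        if not body:
            log.warning("record %s has no abstract (AB field)", pmid)
        year = _year_from_dp(record.get("DP", ""))
        documents.append(
            Document(
                doc_id=pmid,
                title=record.get("TI", ""),
                body=body,
                year=year,
            )
        )
    if skipped:
        log.warning("skipped %d malformed MEDLINE record(s)", skipped)
    return Corpus(documents=documents, provenance=str(path))


def _year_from_dp(dp: str) -> int | None:
    m = re.search(r"\b(1[89]\d\d|20\d\d)\b", dp)
    return int(m.group(1)) if m else None


def write_medline(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as a MEDLINE flat file (inverse of read_medline)."""
    lines = []
    for doc in corpus:
        lines.append(f"PMID- {doc.doc_id}")
        if doc.year is not None:
            lines.append(f"DP  - {doc.year}")
        if doc.title:
            lines.append(f"TI  - {doc.title}")
        if doc.body:
            lines.append(f"AB  - {doc.body}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# -- PubMed XML ----------------------------------------------------------

def read_pubmed_xml(path: str | Path) -> Corpus:
    """Read a PubmedArticleSet XML file.

    Labeled abstract sections are concatenated with single spaces.  A
    parse failure is a hard error reporting the position in the input.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusIOError(
            f"XML parse failure in {path} at line {exc.lineno}, "
            f"column {exc.position[1]}: {exc.msg}"
        ) from exc
    documents = []
    for article in tree.iter("PubmedArticle"):
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            log.warning("skipping PubmedArticle without PMID")
            continue
        title_el = article.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        sections = [
            " ".join("".join(ab.itertext()).split())
            for ab in article.findall(".//Abstract/AbstractText")
        ]
        body = " ".join(s for s in sections if s)
        year = None
        year_el = article.find(".//JournalIssue/PubDate/Year")
        if year_el is not None and year_el.text:
            year = int(year_el.text[:4])
        else:
            medline_date = article.find(".//JournalIssue/PubDate/MedlineDate")
            if medline_date is not None and medline_date.text:
                year = _year_from_dp(medline_date.text)
        documents.append(
            Document(doc_id=pmid_el.text.strip(), title=title, body=body, year=year)
        )
    return Corpus(documents=documents, provenance=str(path))


# -- annotation JSON -----------------------------------------------------

ANNOTATION_SCHEMA_VERSION = 1


def write_annotations(
    corpus: Corpus,
    annotation_sets: Iterable[AnnotationSet],
    path: str | Path,
) -> None:
    """Serialize annotation sets to JSON (stable key order, UTF-8).

    Every annotation must reference an existing doc_id; reading the file
    back reproduces spans, labels and normalized ids exactly.
    """
    known = {doc.doc_id for doc in corpus}
    payload = {"schema_version": ANNOTATION_SCHEMA_VERSION, "documents": []}
    for aset in annotation_sets:
        if aset.doc_id not in known:
            raise CorpusIOError(
                f"annotation references unknown doc_id {aset.doc_id!r}"
            )
        doc = corpus[aset.doc_id]
        for m in aset.mentions:
            if not (0 <= m.start < m.end <= len(doc.body)):
                raise CorpusIOError(
                    f"span ({m.start}, {m.end}) outside body of {aset.doc_id}"
                )
        payload["documents"].append(
            {
                "doc_id": aset.doc_id,
                "mentions": [asdict(m) for m in aset.mentions],
                "interactions": list(aset.interactions),
                "disease_links": list(aset.disease_links),
            }
        )
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=False)
        + "\n",
        encoding="utf-8",
    )


def read_annotations(path: str | Path) -> dict[str, AnnotationSet]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = {}
    for entry in payload["documents"]:
        out[entry["doc_id"]] = AnnotationSet(
            doc_id=entry["doc_id"],
            mentions=[Mention(**m) for m in entry["mentions"]],
            interactions=entry.get("interactions", []),
            disease_links=entry.get("disease_links", []),
        )
    return out


# -- HTML highlights -----------------------------------------------------

def render_highlighted(document: Document, annotation_set: AnnotationSet) -> str:
    """Render the document body with mention spans wrapped in <mark> tags.

    Tags are keyed by mention label via the class attribute.  Overlapping
    spans: the outermost (longest, then leftmost) wins; inner spans are
    dropped with a warning.
    """
    kept: list[Mention] = []
    for m in sorted(annotation_set.mentions, key=lambda m: (-(m.end - m.start), m.start)):
        if any(m.start < k.end and k.start < m.end for k in kept):
            log.warning(
                "dropping overlapping mention (%d, %d) in %s",
                m.start, m.end, document.doc_id,
            )
            continue
        kept.append(m)
    kept.sort(key=lambda m: m.start)
    parts = [f"<p data-doc-id={html.escape(document.doc_id, quote=True)!r}>"]
    cursor = 0
    body = document.body
    for m in kept:
        parts.append(html.escape(body[cursor:m.start]))
        parts.append(
            f'<mark class="{html.escape(m.label, quote=True)}" '
            f'title="{html.escape(m.normalized_id, quote=True)}">'
            f"{html.escape(body[m.start:m.end])}</mark>"
        )
        cursor = m.end
    parts.append(html.escape(body[cursor:]))
    parts.append("</p>")
    return "".join(parts)


# -- networked fetch (optional, never used by tests) ---------------------

def fetch_pubmed(
    query: str,
    max_articles: int,
    email: str = "fusemine@example.org",
    offline: bool = False,
) -> Corpus:
    """Fetch abstracts matching a PubMed query via Entrez.

    Requires network access; ``offline=True`` refuses with a clear error.
    ``max_articles=0`` returns an empty corpus without any network call.
    """
    if max_articles < 0:
        raise CorpusIOError("max_articles must be non-negative")
    if max_articles == 0:
        return Corpus(documents=[], provenance=f"pubmed:{query}")
    if offline:
        raise RuntimeError("network disabled: cannot fetch from PubMed")
    from Bio import Entrez

    Entrez.email = email
    with Entrez.esearch(db="pubmed", term=query, retmax=max_articles) as h:
        ids = Entrez.read(h)["IdList"]
    if not ids:
        return Corpus(documents=[], provenance=f"pubmed:{query}")
    with Entrez.efetch(
        db="pubmed", id=",".join(ids), rettype="medline", retmode="text"
    ) as h:
        records = list(Medline.parse(h))
    documents = [
        Document(
            doc_id=r["PMID"],
            title=r.get("TI", ""),
            body=r.get("AB", ""),
            year=_year_from_dp(r.get("DP", "")),
        )
        for r in records
        if r.get("PMID")
    ]
    return Corpus(documents=documents, provenance=f"pubmed:{query}")
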