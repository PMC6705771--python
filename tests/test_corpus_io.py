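"""Corpus readers/writers, annotation JSON round-trips, highlighting."""

import logging

import pytest

from fusemine.corpus_io import (
    AnnotationSet,
    Corpus,
    CorpusIOError,
    Document,
    Mention,
    fetch_pubmed,
    read_annotations,
    read_medline,
    read_pubmed_xml,
    render_highlighted,
    write_annotations,
    write_medline,
)

MEDLINE_TWO_RECORDS = """\
PMID- 9747873
DP  - 1998
TI  - Bcr-Abl oncogenic potential.
AB  - Both Bcr-Abl fusion proteins exhibit an increased tyrosine kinase activity.

PMID- 24186139
DP  - 2013
TI  - Fusion gene detection.
AB  - The BCR-ABL fusion protein was detected.
"""

PUBMED_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>9747873</PMID>
      <Article>
        <Journal><JournalIssue><PubDate><Year>1998</Year></PubDate></JournalIssue></Journal>
        <ArticleTitle>Bcr-Abl oncogenic potential.</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Fusion proteins drive cancer.</AbstractText>
          <AbstractText Label="METHODS">We analyzed cells.</AbstractText>
          <AbstractText Label="RESULTS">BCR-ABL was active.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


class TestReadMedline:
    def test_two_records_in_file_order(self, tmp_path):
        path = tmp_path / "two.txt"
        path.write_text(MEDLINE_TWO_RECORDS)
        corpus = read_medline(path)
        assert [d.doc_id for d in corpus] == ["9747873", "24186139"]
        assert corpus["9747873"].year == 1998

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        assert len(read_medline(path)) == 0

    def test_record_without_abstract_kept_and_logged(self, tmp_path, caplog):
        path = tmp_path / "noab.txt"
        path.write_text("PMID- 1\nTI  - A title only.\n")
        with caplog.at_level(logging.WARNING):
            corpus = read_medline(path)
        assert len(corpus) == 1
        assert corpus["1"].body == ""
        assert any("no abstract" in r.message for r in caplog.records)

    def test_latin1_transcoded(self, tmp_path):
        path = tmp_path / "latin.txt"
        path.write_bytes(
            "PMID- 2\nTI  - caf\xe9 study\nAB  - Body text.\n".encode("latin-1")
        )
        corpus = read_medline(path)
        assert "café" in corpus["2"].title

    def test_round_trip_through_writer(self, tmp_path):
        path = tmp_path / "rt.txt"
        path.write_text(MEDLINE_TWO_RECORDS)
        corpus = read_medline(path)
        out = tmp_path / "out.txt"
        write_medline(corpus, out)
        again = read_medline(out)
        assert [(d.doc_id, d.title, d.body, d.year) for d in corpus] == [
            (d.doc_id, d.title, d.body, d.year) for d in again
        ]


class TestReadPubmedXml:
    def test_single_article(self, tmp_path):
        path = tmp_path / "one.xml"
        path.write_text(PUBMED_XML)
        corpus = read_pubmed_xml(path)
        assert len(corpus) == 1
        assert corpus["9747873"].year == 1998

    def test_labeled_sections_joined_with_single_spaces(self, tmp_path):
        path = tmp_path / "one.xml"
        path.write_text(PUBMED_XML)
        body = read_pubmed_xml(path)["9747873"].body
        assert body == (
            "Fusion proteins drive cancer. We analyzed cells. BCR-ABL was active."
        )

    def test_missing_pubdate_is_not_an_error(self, tmp_path):
        xml = PUBMED_XML.replace(
            "<PubDate><Year>1998</Year></PubDate>", "<PubDate></PubDate>"
        )
        path = tmp_path / "noyear.xml"
        path.write_text(xml)
        assert read_pubmed_xml(path)["9747873"].year is None

    def test_parse_failure_names_position(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<PubmedArticleSet><unclosed>")
        with pytest.raises(CorpusIOError, match="line"):
            read_pubmed_xml(path)


class TestCorpusInvariants:
    def test_duplicate_doc_id_rejected(self):
        with pytest.raises(CorpusIOError, match="duplicate"):
            Corpus(documents=[Document(doc_id="1"), Document(doc_id="1")])

    def test_empty_doc_id_rejected(self):
        with pytest.raises(CorpusIOError):
            Document(doc_id="")


class TestAnnotationRoundTrip:
    def _corpus(self):
        return Corpus(
            documents=[
                Document(doc_id="d1", body="The BCR–ABL fusion was seen here.")
            ]
        )

    def test_empty_annotation_set(self, tmp_path):
        corpus = self._corpus()
        path = tmp_path / "ann.json"
        write_annotations(corpus, [AnnotationSet(doc_id="d1")], path)
        back = read_annotations(path)
        assert back["d1"].mentions == []

    def test_span_round_trip(self, tmp_path):
        corpus = self._corpus()
        aset = AnnotationSet(
            doc_id="d1",
            mentions=[Mention(start=14, end=21, label="keyword",
                              normalized_id="fusion", surface="fusion ")],
        )
        path = tmp_path / "ann.json"
        write_annotations(corpus, [aset], path)
        back = read_annotations(path)["d1"].mentions[0]
        assert (back.start, back.end) == (14, 21)

    def test_unicode_endash_preserved_byte_exact(self, tmp_path):
        corpus = self._corpus()
        surface = corpus["d1"].body[4:11]
        assert "–" in surface
        aset = AnnotationSet(
            doc_id="d1",
            mentions=[Mention(start=4, end=11, label="fusion",
                              normalized_id="BCR-ABL", surface=surface)],
        )
        path = tmp_path / "ann.json"
        write_annotations(corpus, [aset], path)
        assert read_annotations(path)["d1"].mentions[0].surface == surface

    def test_double_round_trip_is_fixed_point(self, tmp_path):
        corpus = self._corpus()
        aset = AnnotationSet(
            doc_id="d1",
            mentions=[Mention(start=4, end=11, label="fusion",
                              normalized_id="BCR-ABL", surface="BCR–ABL")],
            interactions=[{"fusion": "BCR-ABL", "partner": "GRB2",
                           "action": "bind", "doc_id": "d1",
                           "sentence_index": 0, "evidence": "x"}],
        )
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_annotations(corpus, [aset], p1)
        write_annotations(corpus, list(read_annotations(p1).values()), p2)
        assert p1.read_text() == p2.read_text()

    def test_dangling_doc_id_is_hard_error(self, tmp_path):
        with pytest.raises(CorpusIOError, match="ghost"):
            write_annotations(
                self._corpus(),
                [AnnotationSet(doc_id="ghost")],
                tmp_path / "ann.json",
            )

    def test_out_of_body_span_rejected(self, tmp_path):
        aset = AnnotationSet(
            doc_id="d1",
            mentions=[Mention(start=0, end=999, label="fusion",
                              normalized_id="X-Y")],
        )
        with pytest.raises(CorpusIOError, match="span"):
            write_annotations(self._corpus(), [aset], tmp_path / "ann.json")


class TestRenderHighlighted:
    def test_no_mentions_body_unchanged(self):
        doc = Document(doc_id="d", body="plain text")
        html = render_highlighted(doc, AnnotationSet(doc_id="d"))
        assert "plain text" in html
        assert "<mark" not in html

    def test_single_fusion_highlight(self):
        doc = Document(doc_id="d", body="The BCR-ABL fusion protein")
        aset = AnnotationSet(
            doc_id="d",
            mentions=[Mention(start=4, end=11, label="fusion",
                              normalized_id="BCR-ABL")],
        )
        html = render_highlighted(doc, aset)
        assert html.count("<mark") == 1
        assert 'class="fusion"' in html

    def test_two_label_classes_in_one_sentence(self):
        doc = Document(doc_id="d", body="GRB10 interacts with BCR-ABL")
        aset = AnnotationSet(
            doc_id="d",
            mentions=[
                Mention(start=21, end=28, label="fusion", normalized_id="BCR-ABL"),
                Mention(start=6, end=15, label="action", normalized_id="interact"),
            ],
        )
        html = render_highlighted(doc, aset)
        assert html.count("<mark") == 2
        assert 'class="fusion"' in html and 'class="action"' in html

    def test_overlap_outermost_wins(self, caplog):
        doc = Document(doc_id="d", body="chronic myeloid leukemia here")
        aset = AnnotationSet(
            doc_id="d",
            mentions=[
                Mention(start=0, end=24, label="disease",
                        normalized_id="chronic myeloid leukemia"),
                Mention(start=16, end=24, label="disease",
                        normalized_id="leukemia"),
            ],
        )
        with caplog.at_level(logging.WARNING):
            html = render_highlighted(doc, aset)
        assert html.count("<mark") == 1
        assert any("overlap" in r.message for r in caplog.records)


class TestFetchPubmed:
    def test_zero_articles_no_network(self):
        corpus = fetch_pubmed("BCR-ABL", max_articles=0, offline=True)
        assert len(corpus) == 0

    def test_offline_mode_refuses(self):
        with pytest.raises(RuntimeError, match="network disabled"):
            fetch_pubmed("BCR-ABL", max_articles=10, offline=True)
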