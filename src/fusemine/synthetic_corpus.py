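"""Deterministic synthetic abstracts with gold annotations.

The generator emulates the surface phenomena the taggers are sensitive
to: fusion mentions rendered in separator dialects (hyphen, en dash,
slash, colon) and case variants, interaction statements built from the
action-verb corpus, disease co-mentions, and distractor tokens that a
naive pattern matcher would confuse with fusions (hyphenated adjectives,
year ranges, hyphenated chemical names).  Positive documents carry at
least one planted fusion mention; negative documents carry gene mentions
and distractors only.  Every planted span, normalized id and interaction
tuple is recorded in the gold annotations, and the same configuration
always yields byte-identical output.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus_io import (
    AnnotationSet,
    Corpus,
    Document,
    Mention,
    write_annotations,
    write_medline,
)
from .lexicon import Lexicon, default_lexicon

POSITIVE, NEGATIVE = "positive", "negative"

_SEP_CHARS = {"hyphen": "-", "endash": "–", "slash": "/", "colon": ":"}

_DEFAULT_DIALECT_WEIGHTS = {
    "hyphen-upper": 0.35,
    "hyphen-lower": 0.10,
    "hyphen-title": 0.10,
    "slash-upper": 0.15,
    "slash-lower": 0.05,
    "colon-upper": 0.15,
    "colon-lower": 0.05,
    "endash-upper": 0.05,
}


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_docs: int = 200
    positive_fraction: float = 0.5
    dialect_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DIALECT_WEIGHTS)
    )
    p_interaction: float = 0.8
    p_coordination: float = 0.25
    p_disease: float = 0.4
    p_alias_fusion: float = 0.5
    distractor_rate: float = 1.5
    template_set: str = "default"

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise GeneratorError("n_docs must be >= 1")
        for name in ("positive_fraction", "p_interaction", "p_coordination",
                     "p_disease", "p_alias_fusion"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GeneratorError(f"{name} must lie in [0, 1]")
        if self.distractor_rate < 0:
            raise GeneratorError("distractor_rate must be >= 0")
        total = sum(self.dialect_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise GeneratorError(f"dialect_weights sum to {total}, expected 1")
        for key in self.dialect_weights:
            sep, _, case = key.partition("-")
            if sep not in _SEP_CHARS or case not in ("upper", "lower", "title"):
                raise GeneratorError(f"unknown dialect {key!r}")


def _load_templates(template_set: str) -> dict[str, list[str]]:
    path = resources.files("fusemine").joinpath("data/templates.json")
    sets = json.loads(path.read_text(encoding="utf-8"))
    if template_set not in sets:
        raise GeneratorError(f"unknown template set {template_set!r}")
    return sets[template_set]


_SLOT_RE = re.compile(r"\{(\w+)\}")


def _render(template: str, values: dict[str, str]) -> tuple[str, dict[str, tuple[int, int]]]:
    """Fill a sentence skeleton, returning the text and each slot's span."""
    out: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    pos = 0
    for m in _SLOT_RE.finditer(template):
        out.append(template[pos : m.start()])
        cursor += m.start() - pos
        value = values[m.group(1)]
        spans[m.group(1)] = (cursor, cursor + len(value))
        out.append(value)
        cursor += len(value)
        pos = m.end()
    out.append(template[pos:])
    return "".join(out), spans


def _verb_3sg(lemma: str) -> str:
    if lemma.endswith(("s", "x", "z", "ch", "sh")):
        return lemma + "es"
    return lemma + "s"


class _FusionSampler:
    def __init__(self, config: GeneratorConfig, lexicon: Lexicon, rng: random.Random):
        self.config = config
        self.rng = rng
        self.aliases = sorted(lexicon.entries["fusion_alias"])
        self.genes = sorted(lexicon.entries["gene_symbol"])
        self.dialects = sorted(config.dialect_weights)
        self.weights = [config.dialect_weights[d] for d in self.dialects]

    def sample(self) -> tuple[str, bool]:
        """Return (normalized id, is_alias)."""
        if self.rng.random() < self.config.p_alias_fusion:
            return self.rng.choice(self.aliases), True
        a, b = self.rng.sample(self.genes, 2)
        return f"{a}-{b}", False

    def render(self, normalized_id: str) -> str:
        dialect = self.rng.choices(self.dialects, weights=self.weights, k=1)[0]
        sep_name, _, case = dialect.partition("-")
        a, _, b = normalized_id.partition("-")
        if case == "lower":
            a, b = a.lower(), b.lower()
        elif case == "title":
            a, b = a.capitalize(), b.capitalize()
        return f"{a}{_SEP_CHARS[sep_name]}{b}"


def generate_corpus(
    config: GeneratorConfig, lexicon: Lexicon | None = None
) -> tuple[Corpus, dict[str, AnnotationSet], dict[str, str]]:
    """Generate a synthetic corpus with gold annotations and labels.

    Returns (corpus, gold annotation sets keyed by doc_id, gold document
    labels keyed by doc_id).  Positive documents contain at least one
    planted fusion mention; with probability ``p_interaction`` also an
    interaction sentence (coordinated over two fusions with probability
    ``p_coordination``), and with ``p_disease`` a disease statement.
    Negative documents contain gene mentions and distractors only.
    """
    lexicon = lexicon or default_lexicon()
    templates = _load_templates(config.template_set)
    rng = random.Random(config.seed)
    sampler = _FusionSampler(config, lexicon, rng)
    actions = sorted(lexicon.entries["action_verb"])
    diseases = sorted(lexicon.entries["disease_term"])
    genes = sampler.genes

    documents: list[Document] = []
    gold: dict[str, AnnotationSet] = {}
    labels: dict[str, str] = {}
    n_positive = int(round(config.n_docs * config.positive_fraction))
    for i in range(config.n_docs):
        doc_id = f"SYN{i:07d}"
        is_positive = i < n_positive
        sentences: list[tuple[str, list[Mention], list[dict], list[dict]]] = []

        if is_positive:
            fusion_id, is_alias = sampler.sample()
            components = set(fusion_id.split("-"))
            sentences.append(
                _positive_sentence(templates, sampler, rng, fusion_id, is_alias)
            )
            if rng.random() < config.p_interaction:
                coordinated = (
                    is_alias and rng.random() < config.p_coordination
                )
                sentences.append(
                    _interaction_sentence(
                        templates, sampler, rng, lexicon, fusion_id,
                        is_alias, actions, genes, components, coordinated,
                    )
                )
            if rng.random() < config.p_disease:
                sentences.append(
                    _disease_sentence(
                        templates, sampler, rng, fusion_id, is_alias, diseases
                    )
                )
        else:
            for _ in range(rng.randint(1, 2)):
                gene = rng.choice(genes)
                text, _spans = _render(
                    rng.choice(templates["negative"]), {"gene": gene}
                )
                sentences.append((text, [], [], []))

        n_distractors = _poisson(rng, config.distractor_rate)
        for _ in range(n_distractors):
            template = rng.choice(templates["distractor"])
            year1 = rng.randint(1995, 2015)
            text, _spans = _render(
                template,
                {"year1": str(year1), "year2": str(year1 + rng.randint(1, 9))},
            )
            sentences.append((text, [], [], []))
        rng.shuffle(sentences)

        body_parts: list[str] = []
        mentions: list[Mention] = []
        interactions: list[dict] = []
        disease_links: list[dict] = []
        offset = 0
        for s_index, (text, s_mentions, s_inter, s_links) in enumerate(sentences):
            for m in s_mentions:
                mentions.append(
                    Mention(
                        start=m.start + offset,
                        end=m.end + offset,
                        label=m.label,
                        normalized_id=m.normalized_id,
                        surface=m.surface,
                    )
                )
            for inter in s_inter:
                interactions.append(
                    {**inter, "doc_id": doc_id, "sentence_index": s_index}
                )
            for link in s_links:
                disease_links.append(
                    {**link, "doc_id": doc_id, "sentence_index": s_index}
                )
            body_parts.append(text)
            offset += len(text) + 1  # single joining space
        body = " ".join(body_parts)
        year = rng.randint(2013, 2017)
        documents.append(
            Document(
                doc_id=doc_id,
                title=f"Synthetic abstract {i}",
                body=body,
                year=year,
            )
        )
        gold[doc_id] = AnnotationSet(
            doc_id=doc_id,
            mentions=sorted(mentions, key=lambda m: (m.start, m.end)),
            interactions=interactions,
            disease_links=disease_links,
        )
        labels[doc_id] = POSITIVE if is_positive else NEGATIVE
    corpus = Corpus(documents=documents, provenance=f"synthetic:seed={config.seed}")
    return corpus, gold, labels


def _fusion_mention(span: tuple[int, int], surface: str, normalized: str) -> Mention:
    return Mention(
        start=span[0], end=span[1], label="fusion",
        normalized_id=normalized, surface=surface,
    )


def _positive_sentence(templates, sampler, rng, fusion_id, is_alias):
    surface = sampler.render(fusion_id)
    text, spans = _render(
        rng.choice(templates["positive"]),
        {"fusion": surface, "keyword": rng.choice(["fusion", "fusion protein", "fusion gene"])},
    )
    return text, [_fusion_mention(spans["fusion"], surface, fusion_id)], [], []


def _interaction_sentence(
    templates, sampler, rng, lexicon, fusion_id, is_alias,
    actions, genes, components, coordinated,
):
    verb = rng.choice(actions)
    partner = rng.choice([g for g in genes if g not in components])
    surface = sampler.render(fusion_id)
    mentions = []
    interactions = []
    if coordinated:
        fusion2_id = rng.choice(
            [f for f in sampler.aliases if f != fusion_id and partner not in f.split("-")]
        )
        surface2 = sampler.render(fusion2_id)
        text, spans = _render(
            rng.choice(templates["interaction_coordinated"]),
            {"partner": partner, "verb": verb,
             "fusion": surface, "fusion2": surface2},
        )
        mentions.append(_fusion_mention(spans["fusion"], surface, fusion_id))
        mentions.append(_fusion_mention(spans["fusion2"], surface2, fusion2_id))
        interactions.append({"fusion": fusion_id, "partner": partner, "action": verb})
        interactions.append({"fusion": fusion2_id, "partner": partner, "action": verb})
        return text, mentions, interactions, []
    pool = templates["interaction"]
    if not is_alias:
        # pair-form fusions need keyword support in the same sentence
        pool = [t for t in pool if "{keyword}" in t]
    text, spans = _render(
        rng.choice(pool),
        {"partner": partner, "verb": verb, "verb_3sg": _verb_3sg(verb),
         "fusion": surface, "keyword": "fusion protein"},
    )
    mentions.append(_fusion_mention(spans["fusion"], surface, fusion_id))
    interactions.append({"fusion": fusion_id, "partner": partner, "action": verb})
    return text, mentions, interactions, []


def _disease_sentence(templates, sampler, rng, fusion_id, is_alias, diseases):
    disease = rng.choice(diseases)
    surface = sampler.render(fusion_id)
    template = rng.choice(templates["disease"])
    action = "cause" if "causes" in template else "induce"
    text, spans = _render(
        template,
        {"fusion": surface, "disease": disease, "keyword": "fusion protein"},
    )
    mentions = [_fusion_mention(spans["fusion"], surface, fusion_id)]
    links = [{"fusion": fusion_id, "disease": disease, "action": action}]
    return text, mentions, [], links


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's Poisson sampler on the generator's own random stream."""
    if lam <= 0:
        return 0
    limit = pow(2.718281828459045, -lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def corrupt_labels(
    labels: dict[str, str] | list[str], flip_rate: float, seed: int
) -> dict[str, str] | list[str]:
    """Flip each positive/negative label independently with ``flip_rate``."""
    if not 0.0 <= flip_rate <= 1.0:
        raise GeneratorError("flip_rate must lie in [0, 1]")
    rng = random.Random(seed)

    def flip(value: str) -> str:
        if rng.random() < flip_rate:
            return NEGATIVE if value == POSITIVE else POSITIVE
        return value

    if isinstance(labels, dict):
        return {k: flip(v) for k, v in labels.items()}
    return [flip(v) for v in labels]


def write_outputs(
    corpus: Corpus,
    gold: dict[str, AnnotationSet],
    labels: dict[str, str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the MEDLINE corpus, gold annotation JSON and labels TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "medline": outdir / "corpus.medline.txt",
        "gold": outdir / "gold.annotations.json",
        "labels": outdir / "labels.tsv",
    }
    write_medline(corpus, paths["medline"])
    write_annotations(corpus, [gold[d.doc_id] for d in corpus], paths["gold"])
    lines = ["doc_id\tlabel"] + [
        f"{doc.doc_id}\t{labels[doc.doc_id]}" for doc in corpus
    ]
    paths["labels"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths
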