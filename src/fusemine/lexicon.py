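"""Synonym dictionaries and the normalization / regular-expression rule base.

The tagger relies on five dictionaries (fusion keywords, action verbs,
fusion aliases, gene symbols, disease terms), a small rule base of
normalization and token patterns, and auxiliary word lists (stopwords,
domain adjectives, evaluative adjectives) used by the four-way token
categorizer.  All resources are plain TSV/text files; the packaged set is
seeded from the worked examples of the fusion-mining literature and can be
swapped for larger tables via :func:`load_lexicon`.

TSV format: one entry per line, ``canonical<TAB>variant1|variant2|...``.
Variant matching is case-insensitive; a variant may not map to two
different canonicals within one entry kind.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from ._porter2 import stem as porter2_stem

ENTRY_KINDS = (
    "fusion_keyword",
    "action_verb",
    "fusion_alias",
    "gene_symbol",
    "disease_term",
)

#: separator characters accepted inside fusion surface forms
SEPARATORS = "-–—/:"
_SEP_TRANS = str.maketrans({"–": "-", "—": "-", "/": "-", ":": "-"})


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon resources."""


@dataclass(frozen=True)
class SynonymEntry:
    canonical: str
    variants: tuple[str, ...]
    entry_kind: str

    def __post_init__(self) -> None:
        if not self.canonical:
            raise LexiconError("canonical form must be non-empty")
        if not self.variants:
            raise LexiconError(f"entry {self.canonical!r} has no variants")


@dataclass(frozen=True)
class RuleBase:
    """Ordered normalization rules and named token patterns."""

    normalization_rules: tuple[tuple[str, str, str], ...] = ()
    token_patterns: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        for name, pattern, _ in self.token_patterns:
            try:
                re.compile(pattern)
            except re.error as exc:
                raise LexiconError(f"pattern {name!r} does not compile: {exc}")


def compile_rules(rule_base: RuleBase) -> dict[str, re.Pattern]:
    """Compile the token patterns of a rule base into named matchers.

    The result preserves rule order (first matching rule wins) and is
    idempotent: compiling twice yields an equal matcher set.
    """
    return {
        name: re.compile(pattern)
        for name, pattern, _ in rule_base.token_patterns
    }


@dataclass
class Lexicon:
    """Compiled dictionary set used by the taggers.

    ``entries`` maps entry kind to ``{canonical: SynonymEntry}``;
    ``_index`` holds the case-folded variant -> canonical lookup per kind.
    """

    entries: dict[str, dict[str, SynonymEntry]] = field(
        default_factory=lambda: {k: {} for k in ENTRY_KINDS}
    )
    rule_base: RuleBase = field(default_factory=RuleBase)
    mesh_map: dict[str, str] = field(default_factory=dict)
    stopwords: frozenset[str] = frozenset()
    domain_adjectives: frozenset[str] = frozenset()
    evaluative_adjectives: frozenset[str] = frozenset()
    _index: dict[str, dict[str, str]] = field(
        default_factory=lambda: {k: {} for k in ENTRY_KINDS}, repr=False
    )
    _action_stem_index: dict[str, str] = field(default_factory=dict, repr=False)

    # -- construction ----------------------------------------------------
    def add_entry(self, entry: SynonymEntry) -> None:
        if entry.entry_kind not in self.entries:
            raise LexiconError(f"unknown entry kind {entry.entry_kind!r}")
        index = self._index[entry.entry_kind]
        for variant in entry.variants:
            key = variant.casefold()
            prior = index.get(key)
            if prior is not None and prior != entry.canonical:
                raise LexiconError(
                    f"variant {variant!r} maps to both {prior!r} and "
                    f"{entry.canonical!r} within kind {entry.entry_kind!r}"
                )
            index[key] = entry.canonical
            if entry.entry_kind == "fusion_alias":
                # separator-insensitive alias lookup
                index.setdefault(key.translate(_SEP_TRANS), entry.canonical)
            if entry.entry_kind == "action_verb":
                self._action_stem_index.setdefault(
                    porter2_stem(key), entry.canonical
                )
        self.entries[entry.entry_kind][entry.canonical] = entry

    # -- lookup ----------------------------------------------------------
    def lookup(self, entry_kind: str, surface: str) -> str | None:
        """Case-insensitive variant -> canonical lookup; None if absent."""
        return self._index[entry_kind].get(surface.casefold())

    def gene_symbol(self, surface: str) -> str | None:
        return self.lookup("gene_symbol", surface)

    def fusion_alias(self, surface: str) -> str | None:
        index = self._index["fusion_alias"]
        key = surface.casefold()
        hit = index.get(key)
        if hit is None:
            hit = index.get(key.translate(_SEP_TRANS))
        return hit

    def action_lemma(self, surface: str) -> str | None:
        """Resolve a token to its canonical action verb.

        Tries the explicit variant table first, then falls back on stem
        identity so that unseen regular inflections still resolve.
        """
        key = surface.casefold()
        hit = self._index["action_verb"].get(key)
        if hit is None:
            hit = self._action_stem_index.get(porter2_stem(key))
        return hit

    def keyword_forms(self) -> dict[tuple[str, ...], str]:
        """Fusion-keyword variants as case-folded word tuples.

        Multi-word variants ("gene fusion") are returned as tuples so the
        tagger can match them against consecutive tokens.
        """
        forms: dict[tuple[str, ...], str] = {}
        for canonical, entry in self.entries["fusion_keyword"].items():
            for variant in entry.variants:
                forms[tuple(variant.casefold().split())] = canonical
        return forms

    def disease_forms(self) -> dict[tuple[str, ...], str]:
        forms: dict[tuple[str, ...], str] = {}
        for canonical, entry in self.entries["disease_term"].items():
            for variant in entry.variants:
                forms[tuple(variant.casefold().split())] = canonical
        return forms

    def mesh_id(self, disease_canonical: str) -> str | None:
        return self.mesh_map.get(disease_canonical.casefold())


def expand_morphology(verb_lemma: str) -> list[str]:
    """Expand a verb lemma into its regular surface variants.

    Applies the suffix family {-s, -d/-ed, -ing, -ion/-ation, -or/-er}
    with standard e-drop, e.g. ``activate`` -> activates, activated,
    activating, activation, activator.  The lemma itself is always
    included; output is deduplicated and lowercase.
    """
    if not verb_lemma or not verb_lemma.isalpha():
        raise LexiconError(f"lemma must be alphabetic, got {verb_lemma!r}")
    lemma = verb_lemma.lower()
    root = lemma[:-1] if lemma.endswith("e") else lemma
    variants = [
        lemma,
        lemma + "s",
        root + "ed",
        root + "ing",
        root + "ion",
        root + "ation",
        root + "or",
        root + "er",
    ]
    if lemma.endswith("e"):
        variants.append(lemma + "d")
    seen: dict[str, None] = {}
    for v in variants:
        seen.setdefault(v, None)
    return list(seen)


# -- file loading --------------------------------------------------------

def _read_lines(path: Path) -> list[str]:
    if not path.is_file():
        raise LexiconError(f"lexicon file not found: {path}")
    return path.read_text(encoding="utf-8").splitlines()


def _parse_synonym_tsv(path: Path, entry_kind: str) -> list[SynonymEntry]:
    entries = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        try:
            canonical, variants = line.split("\t")
        except ValueError:
            raise LexiconError(
                f"{path}:{lineno}: expected 'canonical<TAB>v1|v2|...'"
            )
        entries.append(
            SynonymEntry(
                canonical=canonical.strip(),
                variants=tuple(
                    v.strip() for v in variants.split("|") if v.strip()
                ),
                entry_kind=entry_kind,
            )
        )
    return entries


def _parse_rulebase_tsv(path: Path) -> RuleBase:
    norm, patterns = [], []
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise LexiconError(f"{path}:{lineno}: expected 4 TSV fields")
        kind, name, pattern, attrs = fields
        if kind == "norm":
            norm.append((name, pattern, attrs))
        elif kind == "pattern":
            patterns.append((name, pattern, attrs))
        else:
            raise LexiconError(f"{path}:{lineno}: unknown rule kind {kind!r}")
    return RuleBase(tuple(norm), tuple(patterns))


def _parse_two_col(path: Path) -> dict[str, str]:
    mapping = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        try:
            key, value = line.split("\t")
        except ValueError:
            raise LexiconError(f"{path}:{lineno}: expected 2 TSV fields")
        mapping[key.strip().casefold()] = value.strip()
    return mapping


_KIND_TO_FILE = {
    "fusion_keyword": "fusion_keywords.tsv",
    "action_verb": "action_verbs.tsv",
    "fusion_alias": "fusion_aliases.tsv",
    "gene_symbol": "gene_symbols.tsv",
    "disease_term": "disease_terms.tsv",
}


def _data_dir() -> Path:
    return Path(str(resources.files("fusemine").joinpath("data")))


def load_lexicon(paths: Mapping[str, str | Path] | None = None) -> Lexicon:
    """Build a :class:`Lexicon` from TSV resources.

    ``paths`` maps any of the entry kinds plus ``rulebase``, ``mesh_map``,
    ``stopwords``, ``domain_adjectives``, ``evaluative_adjectives`` to file
    paths; unspecified resources fall back to the packaged defaults.
    """
    data = _data_dir()
    resolved: dict[str, Path] = {
        kind: data / fname for kind, fname in _KIND_TO_FILE.items()
    }
    resolved["rulebase"] = data / "rulebase.tsv"
    resolved["mesh_map"] = data / "mesh_map.tsv"
    resolved["stopwords"] = data / "stopwords.txt"
    resolved["domain_adjectives"] = data / "domain_adjectives.txt"
    resolved["evaluative_adjectives"] = data / "evaluative_adjectives.txt"
    for key, value in (paths or {}).items():
        if key not in resolved:
            raise LexiconError(f"unknown lexicon resource {key!r}")
        resolved[key] = Path(value)

    lexicon = Lexicon(rule_base=_parse_rulebase_tsv(resolved["rulebase"]))
    for kind in ENTRY_KINDS:
        for entry in _parse_synonym_tsv(resolved[kind], kind):
            lexicon.add_entry(entry)
    lexicon.mesh_map = _parse_two_col(resolved["mesh_map"])
    lexicon.stopwords = frozenset(
        w.strip().casefold()
        for w in _read_lines(resolved["stopwords"])
        if w.strip()
    )
    lexicon.domain_adjectives = frozenset(
        w.strip().casefold()
        for w in _read_lines(resolved["domain_adjectives"])
        if w.strip()
    )
    lexicon.evaluative_adjectives = frozenset(
        w.strip().casefold()
        for w in _read_lines(resolved["evaluative_adjectives"])
        if w.strip()
    )
    return lexicon


def default_lexicon() -> Lexicon:
    """The packaged default lexicon (cached on first use)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_lexicon()
    return _DEFAULT


_DEFAULT: Lexicon | None = None
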