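"""Sentence/annotation data model, corpus filtering, BIO encoding, splits, augmentation.

Character offsets are 0-based and half-open throughout: a span ``(start, end)``
covers ``text[start:end]``.
"""

from __future__ import annotations

import logging
import math
import re
import string
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: The closed set of entity categories recognised by the data model.
ENTITY_CATEGORIES = frozenset(
    {
        "STRAIN",
        "SPECIES",
        "ORGANISM",
        "PHENOTYPE",
        "EFFECT",
        "DISEASE",
        "MEDIUM",
        "ISOLATE",
        "COMPOUND",
    }
)

#: The closed set of relation types.
RELATION_TYPES = frozenset(
    {
        "GROWS_ON",
        "INHABITS",
        "PRODUCES",
        "DEGRADES",
        "RESISTS",
        "PRESENTS",
        "ASSOCIATED_WITH",
        "PROMOTES",
        "SYMBIONT_OF",
        "INFECTS",
        "INHIBITS",
    }
)

#: Section labels excluded from the corpus (matched as case-insensitive substrings).
EXCLUDED_SECTION_KEYWORDS = (
    "acknowledg",
    "author declaration",
    "data availability",
    "legend",
)

#: Records need strictly more than this English-language confidence to survive.
DEFAULT_MIN_ENGLISH_CONFIDENCE = 0.40

#: Paragraphs strictly shorter than this many characters are emitted whole.
PARAGRAPH_CHAR_LIMIT = 512

_HYPHEN_RE = re.compile(r"(?<=\w)-(?=\w)")
_SENTENCE_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\[\"])")
_WS_RE = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    """A contiguous slice of sentence text."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"token offsets must satisfy start < end, got {self}")


@dataclass(frozen=True)
class EntitySpan:
    """One annotated entity mention with half-open character offsets."""

    category: str
    start: int
    end: int
    term: str

    def __post_init__(self) -> None:
        if self.category not in ENTITY_CATEGORIES:
            raise ValueError(f"unknown entity category {self.category!r}")
        if not self.start < self.end:
            raise ValueError(f"span offsets must satisfy start < end, got {self}")


@dataclass(frozen=True)
class RelationAnnotation:
    """Binary relation label between two entity spans of one sentence.

    ``source`` and ``target`` are indices into the sentence's span list.
    """

    relation_type: str
    source: int
    target: int
    label: int

    def __post_init__(self) -> None:
        if self.relation_type not in RELATION_TYPES:
            raise ValueError(f"unknown relation type {self.relation_type!r}")
        if self.label not in (0, 1):
            raise ValueError("relation label must be binary")

    def typed_name(self, spans: list[EntitySpan]) -> str:
        """Render the conventional ``sourceENTITY-targetENTITY:RELATIONTYPE`` name."""
        return (
            f"{spans[self.source].category}-{spans[self.target].category}"
            f":{self.relation_type}"
        )


@dataclass
class AnnotatedSentence:
    id: str
    text: str
    section: str = ""
    journal: str = ""
    english_confidence: float = 1.0
    tokens: list[Token] = field(default_factory=list)
    spans: list[EntitySpan] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.text)
        for sp in self.spans:
            if sp.end > n:
                raise ValueError(f"span {sp} exceeds text length {n}")
            if self.text[sp.start : sp.end] != sp.term:
                raise ValueError(
                    f"span term {sp.term!r} != slice "
                    f"{self.text[sp.start:sp.end]!r}"
                )
        for tok in self.tokens:
            if self.text[tok.start : tok.end] != tok.text:
                raise ValueError(f"token {tok} does not match its slice")

    def spans_of(self, category: str) -> list[EntitySpan]:
        return [s for s in self.spans if s.category == category]


@dataclass(frozen=True)
class AugmentationPlan:
    """How many synthetic positive sentences to create for one target."""

    target: str
    n_pos: int
    n_neg: int
    mode: str  # "NER" | "RE"
    n_aug: int
    seed: int = 0


@dataclass(frozen=True)
class SplitSpec:
    """Three-way split specification (train, validation, test)."""

    fractions: tuple[float, float, float] = (0.65, 0.175, 0.175)
    strata: str = "entity-signature"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) >= 1e-9:
            raise ValueError("fractions must sum to 1")


# ---------------------------------------------------------------------------
# Corpus filtering
# ---------------------------------------------------------------------------


def replace_hyphens(text: str) -> str:
    """Replace the hyphen in hyphenated words with a space."""
    return _HYPHEN_RE.sub(" ", text)


def split_sentences(text: str) -> list[str]:
    """Deterministic rule-based sentence splitter (terminator + capital/digit)."""
    parts = [p.strip() for p in _SENTENCE_BOUNDARY_RE.split(text)]
    return [p for p in parts if p]


def _dedup_key(text: str) -> str:
    return _WS_RE.sub(" ", text.casefold()).strip()


def _section_excluded(section: str) -> bool:
    s = section.casefold()
    return any(k in s for k in EXCLUDED_SECTION_KEYWORDS)


def filter_corpus(
    records,
    min_english_confidence: float = DEFAULT_MIN_ENGLISH_CONFIDENCE,
    journal_allowlist: set[str] | None = None,
) -> tuple[list[AnnotatedSentence], dict[str, int]]:
    """Filter raw text records into tokenized sentences.

    Parameters
    ----------
    records
        Iterable of mappings with keys ``id``, ``text``, ``section``,
        ``journal`` (optional) and ``english_confidence``.
    min_english_confidence
        Records need confidence strictly greater than this to be kept.
    journal_allowlist
        Optional set of permitted journal names; when given, records from
        other journals are dropped.

    Returns
    -------
    (sentences, drop_counts)
        The retained, tokenized sentences and a counter of drop reason codes
        (``no_text``, ``excluded_section``, ``journal``, ``low_confidence``,
        ``duplicate``).

    Notes
    -----
    Excluded sections are dropped; hyphens inside hyphenated words become
    spaces; paragraphs shorter than 512 characters are emitted whole while
    longer ones are emitted sentence-by-sentence; duplicates (exact match
    after case-folding and whitespace collapsing) are dropped.
    """
    drops: dict[str, int] = {
        "no_text": 0,
        "excluded_section": 0,
        "journal": 0,
        "low_confidence": 0,
        "duplicate": 0,
    }
    seen: set[str] = set()
    out: list[AnnotatedSentence] = []
    for rec in records:
        text = rec.get("text")
        if not text:
            drops["no_text"] += 1
            continue
        section = rec.get("section", "")
        if _section_excluded(section):
            drops["excluded_section"] += 1
            continue
        if journal_allowlist is not None and rec.get("journal", "") not in journal_allowlist:
            drops["journal"] += 1
            continue
        conf = float(rec.get("english_confidence", 1.0))
        if not conf > min_english_confidence:
            drops["low_confidence"] += 1
            continue
        text = replace_hyphens(text)
        units = [text] if len(text) < PARAGRAPH_CHAR_LIMIT else split_sentences(text)
        for j, unit in enumerate(units):
            key = _dedup_key(unit)
            if key in seen:
                drops["duplicate"] += 1
                continue
            seen.add(key)
            sid = rec.get("id", "")
            if len(units) > 1:
                sid = f"{sid}.s{j}"
            out.append(
                AnnotatedSentence(
                    id=sid,
                    text=unit,
                    section=section,
                    journal=rec.get("journal", ""),
                    english_confidence=conf,
                    tokens=tokenize(unit),
                )
            )
    return out, drops


# ---------------------------------------------------------------------------
# Reference tokenizer
# ---------------------------------------------------------------------------

_PUNCT = set(string.punctuation)


def tokenize(text: str) -> list[Token]:
    """Whitespace tokenizer with leading/trailing punctuation detached.

    Deterministic reference tokenizer: splits on whitespace, then peels
    punctuation characters off both ends of each chunk as single-character
    tokens.  Offsets always reconstruct slices of ``text``.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        start, end = m.start(), m.end()
        # leading punctuation
        lead = start
        while lead < end and text[lead] in _PUNCT:
            tokens.append(Token(text[lead], lead, lead + 1))
            lead += 1
        # trailing punctuation (collected, emitted after the core)
        trail = end
        while trail > lead and text[trail - 1] in _PUNCT:
            trail -= 1
        if lead < trail:
            tokens.append(Token(text[lead:trail], lead, trail))
        for i in range(trail, end):
            tokens.append(Token(text[i], i, i + 1))
    return tokens


# ---------------------------------------------------------------------------
# BIO encoding
# ---------------------------------------------------------------------------


def bio_encode(sentence: AnnotatedSentence, category: str) -> list[str]:
    """Per-token B/I/O labels for one entity category.

    The first token overlapping a span is labelled ``B``, subsequent tokens
    of the same span ``I``, all other tokens ``O``.  Overlapping spans of the
    same category are an annotation defect and raise ``ValueError``.
    """
    if category not in ENTITY_CATEGORIES:
        raise ValueError(f"unknown entity category {category!r}")
    spans = sorted(sentence.spans_of(category), key=lambda s: (s.start, s.end))
    for a, b in zip(spans, spans[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping {category} spans: {a} / {b}")
    labels = ["O"] * len(sentence.tokens)
    for sp in spans:
        first = True
        for i, tok in enumerate(sentence.tokens):
            if tok.start < sp.end and tok.end > sp.start:  # overlap
                labels[i] = "B" if first else "I"
                first = False
    return labels


def bio_decode(tokens: list[Token], labels: list[str]) -> list[tuple[int, int]]:
    """Character extents of entity runs in a BIO sequence (inverse of encoding).

    Requires one label per token; ``I`` directly after ``O`` is invalid.
    """
    if len(labels) != len(tokens):
        raise ValueError("labels and tokens must have equal length")
    extents: list[tuple[int, int]] = []
    run: list[Token] = []
    for tok, lab in zip(tokens, labels):
        if lab == "B":
            if run:
                extents.append((run[0].start, run[-1].end))
            run = [tok]
        elif lab == "I":
            if not run:
                raise ValueError("label I may not follow O")
            run.append(tok)
        elif lab == "O":
            if run:
                extents.append((run[0].start, run[-1].end))
                run = []
        else:
            raise ValueError(f"invalid BIO label {lab!r}")
    if run:
        extents.append((run[0].start, run[-1].end))
    return extents


def spans_from_bio(
    sentence: AnnotatedSentence, labels: list[str], category: str
) -> list[EntitySpan]:
    """Reconstruct :class:`EntitySpan` objects from BIO labels of a sentence."""
    return [
        EntitySpan(category, start, end, sentence.text[start:end])
        for start, end in bio_decode(sentence.tokens, labels)
    ]


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------


def allocate_counts(total: int, fractions: tuple[float, ...]) -> list[int]:
    """Subset sizes for ``total`` items: round all but the last fraction to the
    nearest integer; the last subset absorbs the remainder."""
    sizes = [round(total * f) for f in fractions[:-1]]
    last = total - sum(sizes)
    if last < 0:
        raise ValueError("fractions over-allocate the total")
    sizes.append(last)
    return sizes


def entity_signature(sentence: AnnotatedSentence) -> tuple[str, ...]:
    """Multi-hot entity-presence signature used as the NER stratification key."""
    return tuple(sorted({s.category for s in sentence.spans}))


def relation_signature(sentence: AnnotatedSentence) -> tuple[str, ...]:
    """Per-relation signature used for RE stratification."""
    return tuple(
        sorted({r.typed_name(sentence.spans) for r in sentence.relations if r.label == 1})
    )


def stratified_split(
    sentences: list[AnnotatedSentence],
    spec: SplitSpec,
    key=entity_signature,
) -> tuple[list[AnnotatedSentence], list[AnnotatedSentence], list[AnnotatedSentence]]:
    """Partition sentences into three disjoint subsets, stratified by ``key``.

    Strata smaller than 3 items fall back to one pooled stratum (logged).
    Deterministic for a fixed ``spec.seed``.
    """
    if len(sentences) < 3:
        raise ValueError("need at least 3 sentences to split")
    rng = np.random.default_rng(spec.seed)
    strata: dict[tuple, list[int]] = {}
    for i, s in enumerate(sentences):
        strata.setdefault(key(s), []).append(i)
    pooled: list[int] = []
    for k in sorted(strata):
        if len(strata[k]) < 3:
            pooled.extend(strata[k])
    if pooled:
        logger.info("pooled %d items from strata smaller than 3", len(pooled))
    parts: tuple[list[int], ...] = ([], [], [])
    for k in sorted(strata):
        idx = strata[k]
        if len(idx) < 3:
            continue
        _assign(idx, spec.fractions, rng, parts)
    if pooled:
        _assign(pooled, spec.fractions, rng, parts)
    return tuple([sentences[i] for i in sorted(p)] for p in parts)  # type: ignore[return-value]


def _assign(idx: list[int], fractions, rng, parts) -> None:
    order = rng.permutation(len(idx))
    sizes = allocate_counts(len(idx), tuple(fractions))
    pos = 0
    for part, size in zip(parts, sizes):
        part.extend(idx[j] for j in order[pos : pos + size])
        pos += size


# ---------------------------------------------------------------------------
# Class-imbalance augmentation
# ---------------------------------------------------------------------------


def plan_augmentation(
    target: str, n_pos: int, n_neg: int, mode: str, seed: int = 0
) -> AugmentationPlan:
    """Number of synthetic positive sentences to add for one entity or relation.

    NER mode closes the positive/negative gap entirely,
    ``n_aug = max(0, n_neg - n_pos)``; RE mode adds one-fifth of the gap,
    ``n_aug = ceil(0.2 * (n_neg - n_pos))`` when the gap is positive.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if mode == "NER":
        n_aug = max(0, n_neg - n_pos)
    elif mode == "RE":
        n_aug = math.ceil(0.2 * (n_neg - n_pos)) if n_neg > n_pos else 0
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    return AugmentationPlan(target=target, n_pos=n_pos, n_neg=n_neg, mode=mode,
                            n_aug=n_aug, seed=seed)


def augment_by_strain_swap(
    sentences: list[AnnotatedSentence],
    catalog_terms: list[str],
    plan: AugmentationPlan,
) -> list[AnnotatedSentence]:
    """Create ``plan.n_aug`` synthetic sentences by swapping STRAIN terms.

    Each synthetic sentence is a copy of a randomly chosen eligible sentence
    (one containing at least one STRAIN span) in which every STRAIN span's
    text is replaced by a random catalog term; all span offsets, including
    those of downstream non-STRAIN spans, are recomputed.  Seeded via
    ``plan.seed`` and fully reproducible.
    """
    if plan.n_aug == 0:
        return []
    if not catalog_terms:
        raise ValueError("catalog must be non-empty")
    eligible = [s for s in sentences if s.spans_of("STRAIN")]
    if not eligible:
        raise ValueError("no eligible sentence with a STRAIN span")
    rng = np.random.default_rng(plan.seed)
    out: list[AnnotatedSentence] = []
    for k in range(plan.n_aug):
        base = eligible[int(rng.integers(len(eligible)))]
        out.append(_swap_strains(base, catalog_terms, rng, f"{base.id}.aug{k}"))
    return out


def _swap_strains(
    base: AnnotatedSentence, catalog_terms: list[str], rng, new_id: str
) -> AnnotatedSentence:
    order = sorted(range(len(base.spans)), key=lambda i: base.spans[i].start)
    pieces: list[str] = []
    cursor = 0
    new_spans: dict[int, EntitySpan] = {}
    offset = 0
    for i in order:
        sp = base.spans[i]
        pieces.append(base.text[cursor : sp.start])
        if sp.category == "STRAIN":
            term = str(catalog_terms[int(rng.integers(len(catalog_terms)))])
        else:
            term = sp.term
        new_start = sp.start + offset
        new_spans[i] = replace(sp, start=new_start, end=new_start + len(term), term=term)
        offset += len(term) - (sp.end - sp.start)
        pieces.append(term)
        cursor = sp.end
    pieces.append(base.text[cursor:])
    text = "".join(pieces)
    sent = AnnotatedSentence(
        id=new_id,
        text=text,
        section=base.section,
        journal=base.journal,
        english_confidence=base.english_confidence,
        tokens=tokenize(text),
        spans=[new_spans[i] for i in range(len(base.spans))],
        relations=list(base.relations),
    )
    sent.validate()
    return sent
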