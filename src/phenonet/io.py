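"""Readers and writers for the plain-text dialects used across the pipeline.

All offsets in serialized spans are 0-based, half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from phenonet.benchmark import ReferenceRecord
from phenonet.corpus import (
    AnnotatedSentence,
    EntitySpan,
    RelationAnnotation,
    tokenize,
)
from phenonet.genepheno import AssemblyAnnotation
from phenonet.network import RelationRecord
from phenonet.normalize import MappingEntry, StrainCatalogEntry


# --- sentence / annotation JSONL -------------------------------------------


def write_sentences(sentences: list[AnnotatedSentence], path) -> None:
    """JSONL with fields {id, text, section, journal, english_confidence}."""
    with open(path, "w") as fh:
        for s in sentences:
            fh.write(
                json.dumps(
                    {
                        "id": s.id,
                        "text": s.text,
                        "section": s.section,
                        "journal": s.journal,
                        "english_confidence": s.english_confidence,
                    }
                )
                + "\n"
            )


def read_raw_records(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_annotations(sentences: list[AnnotatedSentence], path) -> None:
    """JSONL: {sentence_id, spans: [{category,start,end}], relations: [...]}."""
    with open(path, "w") as fh:
        for s in sentences:
            fh.write(
                json.dumps(
                    {
                        "sentence_id": s.id,
                        "spans": [
                            {"category": sp.category, "start": sp.start, "end": sp.end}
                            for sp in s.spans
                        ],
                        "relations": [
                            {
                                "type": r.relation_type,
                                "source_idx": r.source,
                                "target_idx": r.target,
                                "label": r.label,
                            }
                            for r in s.relations
                        ],
                    }
                )
                + "\n"
            )


def read_annotated_sentences(sentences_path, annotations_path) -> list[AnnotatedSentence]:
    """Join a sentence JSONL with its annotation JSONL into the data model."""
    ann = {}
    with open(annotations_path) as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                ann[rec["sentence_id"]] = rec
    out = []
    for rec in read_raw_records(sentences_path):
        text = rec["text"]
        a = ann.get(rec["id"], {"spans": [], "relations": []})
        spans = [
            EntitySpan(
                sp["category"], sp["start"], sp["end"], text[sp["start"] : sp["end"]]
            )
            for sp in a["spans"]
        ]
        relations = [
            RelationAnnotation(r["type"], r["source_idx"], r["target_idx"], r["label"])
            for r in a["relations"]
        ]
        sent = AnnotatedSentence(
            id=rec["id"],
            text=text,
            section=rec.get("section", ""),
            journal=rec.get("journal", ""),
            english_confidence=rec.get("english_confidence", 1.0),
            tokens=tokenize(text),
            spans=spans,
            relations=relations,
        )
        sent.validate()
        out.append(sent)
    return out


# --- relation records -------------------------------------------------------

_RELATION_FIELDS = (
    "sentence_id",
    "source_term",
    "source_category",
    "target_term",
    "target_category",
    "relation_type",
    "score",
)


def write_relation_records(records: list[RelationRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps({f: getattr(r, f) for f in _RELATION_FIELDS}) + "\n")


def read_relation_records(path) -> list[RelationRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(RelationRecord(**{f: rec[f] for f in _RELATION_FIELDS}))
    return out


# --- catalogs and normalization ---------------------------------------------


def write_catalog(entries: list[StrainCatalogEntry], path) -> None:
    """TSV (canonical_id, alias); one row per alias."""
    rows = [
        {"canonical_id": e.canonical_id, "alias": a} for e in entries for a in e.aliases
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[StrainCatalogEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        StrainCatalogEntry(canonical_id=cid, aliases=tuple(group["alias"]))
        for cid, group in df.groupby("canonical_id", sort=True)
    ]


def write_normalization_map(entries: list[MappingEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "term": e.term,
                "canonical_id": e.canonical_id if e.canonical_id is not None else "",
                "distance": e.distance,
                "stage": e.stage,
            }
            for e in entries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_overrides(path) -> dict[str, str]:
    """TSV (variant, canonical_term) of curated rewrites."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# --- benchmark reference -----------------------------------------------------


def read_reference(path) -> list[ReferenceRecord]:
    """TSV (accession, category, value)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ReferenceRecord(r.accession, r.category, r.value)
        for r in df.itertuples(index=False)
    ]


def read_conflicts(path) -> dict[str, tuple[str, ...]]:
    """TSV (pattern, conflict_pattern)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, tuple[str, ...]] = {}
    for r in df.itertuples(index=False):
        out[r.pattern] = out.get(r.pattern, ()) + (r.conflict_pattern,)
    return out


# --- genomes -----------------------------------------------------------------


def write_interproscan(annotation: AssemblyAnnotation, path) -> None:
    """Headerless InterProScan-dialect TSV with one Pfam row per copy."""
    with open(path, "w") as fh:
        prot = 0
        for acc in sorted(annotation.counts):
            for _ in range(annotation.counts[acc]):
                prot += 1
                fields = [
                    f"{annotation.assembly_id}_p{prot:05d}",
                    "0" * 32,
                    "300",
                    "Pfam",
                    acc,
                    "synthetic family",
                    "1",
                    "250",
                    "1e-30",
                    "T",
                    "2024-01-01",
                ]
                fh.write("\t".join(fields) + "\n")


def read_pfam2go(path) -> dict[str, list[str]]:
    """TSV (pfam_accession, go_term)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r[0], []).append(r[1])
    return out


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
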