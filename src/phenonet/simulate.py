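"""Seeded generators for every input the pipeline consumes, with ground truth.

Every generator takes a config carrying a ``seed`` and is bit-reproducible:
the same config yields byte-identical output.  Each returns, alongside its
records, a ground-truth object sufficient to score the downstream operation
that consumes them exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from phenonet.corpus import AnnotatedSentence, EntitySpan, RelationAnnotation, tokenize
from phenonet.network import RelationRecord
from phenonet.normalize import StrainCatalogEntry
from phenonet.genepheno import AssemblyAnnotation
from phenonet.trophic import TRIAD_SIGNS, EnvironmentSubnetwork

# ---------------------------------------------------------------------------
# Vocabularies and templates
# ---------------------------------------------------------------------------

GENERA = (
    "Escherichia",
    "Bacillus",
    "Pseudomonas",
    "Lactobacillus",
    "Streptomyces",
    "Mycobacterium",
    "Staphylococcus",
    "Klebsiella",
    "Rhodococcus",
    "Sphingomonas",
)
SPECIES_EPITHETS = (
    "coli",
    "subtilis",
    "putida",
    "plantarum",
    "griseus",
    "smegmatis",
    "aureus",
    "pneumoniae",
    "erythropolis",
    "paucimobilis",
)
VOCAB = {
    "COMPOUND": ("glucose", "xylan", "nisin", "tetracycline", "cellulose", "lactate"),
    "MEDIUM": ("LB", "TSB", "nutrient agar", "MRS broth", "R2A"),
    "PHENOTYPE": ("gram negative", "thermophilic", "motile", "spore forming"),
    "ORGANISM": ("maize", "mouse", "Arabidopsis thaliana", "honeybee"),
    "DISEASE": ("mastitis", "cholera", "soft rot", "sepsis"),
    "ISOLATE": ("soil", "rhizosphere", "wastewater", "marine sediment"),
    "EFFECT": ("plant growth", "biofilm formation", "immune modulation"),
    "SPECIES": ("Escherichia coli", "Bacillus subtilis", "Pseudomonas putida"),
}

# (prefix, secondary category, infix, suffix, relation type)
_STRAIN_TEMPLATES = (
    ("Strain ", "ISOLATE", " was isolated from ", ".", "INHABITS"),
    ("", "COMPOUND", " produces ", " in culture.", "PRODUCES"),
    ("", "COMPOUND", " degrades ", " efficiently.", "DEGRADES"),
    ("", "COMPOUND", " is resistant to ", ".", "RESISTS"),
    ("", "MEDIUM", " grows on ", " plates.", "GROWS_ON"),
    ("", "PHENOTYPE", " is a ", " bacterium.", "PRESENTS"),
    ("", "ORGANISM", " infects ", ".", "INFECTS"),
    ("", "DISEASE", " is associated with ", ".", "ASSOCIATED_WITH"),
    ("", "EFFECT", " promotes ", ".", "PROMOTES"),
    ("", "SPECIES", " inhibits ", " in vitro.", "INHIBITS"),
)
_NONSTRAIN_TEMPLATES = (
    ("COMPOUND", "", " is a common metabolite in soils."),
    ("ORGANISM", "The microbiome of ", " is highly diverse."),
)
_FREE_TEMPLATES = (
    "The experiment was repeated three times.",
    "Results were consistent with previous reports.",
    "Samples were stored at 4 degrees until processing.",
    "Statistical analyses were performed in R.",
    "The sequencing depth was sufficient for assembly.",
)


def _strain_name(rng: np.random.Generator) -> str:
    g = GENERA[int(rng.integers(len(GENERA)))]
    s = SPECIES_EPITHETS[int(rng.integers(len(SPECIES_EPITHETS)))]
    return f"{g} {s} {'ABCDEFGHJK'[int(rng.integers(10))]}{int(rng.integers(10, 99))}"


# ---------------------------------------------------------------------------
# Corpus generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusConfig:
    n_sentences: int = 1000
    #: per-sentence probability of containing at least one STRAIN span
    strain_fraction: float = 0.642
    #: per-sentence probability of a non-STRAIN entity-only sentence
    nonstrain_fraction: float = 0.007  # leaves 0.351 entity-free by default
    #: relative weights over secondary entity categories in strain sentences
    entity_weights: dict[str, float] = field(default_factory=dict)
    seed: int = 0


@dataclass
class CorpusGroundTruth:
    entity_free_ids: list[str]
    strain_sentence_ids: list[str]
    category_sentence_counts: dict[str, int]


def gen_corpus(config: CorpusConfig) -> tuple[list[AnnotatedSentence], CorpusGroundTruth]:
    """Template-based sentences with planted entity spans and relations.

    Each sentence is, independently, a STRAIN-bearing sentence (probability
    ``strain_fraction``; one STRAIN span, one secondary entity span, one
    positive relation), a non-STRAIN entity sentence (``nonstrain_fraction``),
    or entity-free (the remainder; 0.351 under the defaults, mirroring the
    annotated-corpus composition).
    """
    if config.strain_fraction + config.nonstrain_fraction > 1 + 1e-12:
        raise ValueError("strain_fraction + nonstrain_fraction must be <= 1")
    if not _FREE_TEMPLATES:
        raise ValueError("empty template set")
    rng = np.random.default_rng(config.seed)
    weights = np.array(
        [config.entity_weights.get(t[1], 1.0) for t in _STRAIN_TEMPLATES], dtype=float
    )
    if weights.sum() == 0:
        weights[:] = 1.0
    weights /= weights.sum()
    sentences: list[AnnotatedSentence] = []
    gt = CorpusGroundTruth([], [], {})
    for i in range(config.n_sentences):
        sid = f"syn{i:05d}"
        u = rng.random()
        if u < config.strain_fraction:
            ti = int(rng.choice(len(_STRAIN_TEMPLATES), p=weights))
            prefix, cat2, infix, suffix, rel = _STRAIN_TEMPLATES[ti]
            strain = _strain_name(rng)
            words = VOCAB[cat2]
            term2 = words[int(rng.integers(len(words)))]
            text = f"{prefix}{strain}{infix}{term2}{suffix}"
            s0 = len(prefix)
            s1 = len(prefix) + len(strain) + len(infix)
            spans = [
                EntitySpan("STRAIN", s0, s0 + len(strain), strain),
                EntitySpan(cat2, s1, s1 + len(term2), term2),
            ]
            relations = [RelationAnnotation(rel, 0, 1, 1)]
            gt.strain_sentence_ids.append(sid)
            for c in ("STRAIN", cat2):
                gt.category_sentence_counts[c] = gt.category_sentence_counts.get(c, 0) + 1
        elif u < config.strain_fraction + config.nonstrain_fraction:
            cat, pre, post = _NONSTRAIN_TEMPLATES[
                int(rng.integers(len(_NONSTRAIN_TEMPLATES)))
            ]
            words = VOCAB[cat]
            term = words[int(rng.integers(len(words)))]
            text = f"{pre}{term}{post}"
            spans = [EntitySpan(cat, len(pre), len(pre) + len(term), term)]
            relations = []
            gt.category_sentence_counts[cat] = gt.category_sentence_counts.get(cat, 0) + 1
        else:
            text = _FREE_TEMPLATES[int(rng.integers(len(_FREE_TEMPLATES)))]
            spans = []
            relations = []
            gt.entity_free_ids.append(sid)
        sent = AnnotatedSentence(
            id=sid, text=text, tokens=tokenize(text), spans=spans, relations=relations
        )
        sent.validate()
        sentences.append(sent)
    return sentences, gt


# ---------------------------------------------------------------------------
# Relation-record generator (power-law degree structure)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelationNetworkConfig:
    n_strains: int = 1000
    alpha: float = 2.5
    xmin: int = 1
    max_degree: int = 100_000
    #: optional explicit out-degree sequence overriding the power-law draw
    degree_sequence: tuple[int, ...] | None = None
    seed: int = 0


@dataclass
class RelationNetworkGroundTruth:
    out_degrees: dict[str, int]
    n_edges: int
    n_nodes: int


_TARGET_SCHEMA = (
    ("PHENOTYPE", "PRESENTS"),
    ("COMPOUND", "PRODUCES"),
    ("ISOLATE", "INHABITS"),
    ("MEDIUM", "GROWS_ON"),
    ("ORGANISM", "INFECTS"),
    ("COMPOUND", "DEGRADES"),
)


def sample_power_law(
    n: int, alpha: float, rng: np.random.Generator, xmin: int = 1, kmax: int = 100_000
) -> np.ndarray:
    """Draw ``n`` values from a discrete power law ``p(k) ~ k^-alpha`` on
    ``[xmin, kmax]`` by inverse-transform on the truncated pmf."""
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    ks = np.arange(xmin, kmax + 1, dtype=float)
    pmf = ks**-alpha
    pmf /= pmf.sum()
    return rng.choice(np.arange(xmin, kmax + 1), size=n, p=pmf)


def gen_relation_records(
    config: RelationNetworkConfig,
) -> tuple[list[RelationRecord], RelationNetworkGroundTruth]:
    """Relation records whose strain out-degree follows a discrete power law.

    Each strain node draws an out-degree from the configured power law and is
    wired to globally distinct target entities (so parallel-edge collapse
    never alters the degree sequence, and a forced all-ones degree sequence
    yields a perfect matching).  Relation types and target categories follow
    the schema constraints of the data model.
    """
    if config.n_strains < 1:
        raise ValueError("need at least one strain")
    rng = np.random.default_rng(config.seed)
    if config.degree_sequence is not None:
        degrees = np.asarray(config.degree_sequence, dtype=np.int64)
        if len(degrees) != config.n_strains:
            raise ValueError("degree sequence length must equal n_strains")
    else:
        degrees = sample_power_law(
            config.n_strains, config.alpha, rng, config.xmin, config.max_degree
        )
    total = int(degrees.sum())
    targets = [
        (f"{_TARGET_SCHEMA[j % len(_TARGET_SCHEMA)][0]}", f"t{j:07d}")
        for j in range(total)
    ]
    order = rng.permutation(total)
    records: list[RelationRecord] = []
    gt_degrees: dict[str, int] = {}
    pos = 0
    for i in range(config.n_strains):
        strain = f"strain_{i:06d}"
        gt_degrees[strain] = int(degrees[i])
        for _ in range(int(degrees[i])):
            j = int(order[pos])
            pos += 1
            cat, rel = _TARGET_SCHEMA[j % len(_TARGET_SCHEMA)]
            records.append(
                RelationRecord(
                    sentence_id=f"s{pos:08d}",
                    source_term=strain,
                    source_category="STRAIN",
                    target_term=f"t{j:07d}",
                    target_category=cat,
                    relation_type=rel,
                    score=float(np.round(0.5 + 0.5 * rng.random(), 6)),
                )
            )
    gt = RelationNetworkGroundTruth(
        out_degrees=gt_degrees, n_edges=total, n_nodes=config.n_strains + total
    )
    return records, gt


# ---------------------------------------------------------------------------
# Trophic subnetwork generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrophicConfig:
    #: planted triads: (strain_i, strain_j, triad type, count)
    plants: tuple[tuple[str, str, str, int], ...] = ()
    #: number of decoy edges completing no motif
    n_decoys: int = 0
    environment_term: str = "soil"
    seed: int = 0


@dataclass
class TrophicGroundTruth:
    #: unordered strain pair -> (n_plus, n_minus)
    pair_counts: dict[tuple, tuple[int, int]]
    n_triads: int


def gen_trophic(config: TrophicConfig) -> tuple[EnvironmentSubnetwork, TrophicGroundTruth]:
    """A subnetwork containing exactly the planted triads plus inert decoys.

    Every planted triad uses a fresh mediating compound, so triads never
    interfere across plants; decoy edges involve compounds with only one
    incident relation and therefore complete no motif.
    """
    for si, sj, ttype, count in config.plants:
        if ttype not in TRIAD_SIGNS:
            raise ValueError(f"unknown triad type {ttype!r}")
        if si == sj:
            raise ValueError("a triad needs two distinct strains")
        if count < 0:
            raise ValueError("plant counts must be non-negative")
    rng = np.random.default_rng(config.seed)
    env = ("ISOLATE", config.environment_term)
    strains = {("STRAIN", si) for si, _, _, _ in config.plants}
    strains |= {("STRAIN", sj) for _, sj, _, _ in config.plants}
    edges: set[tuple] = set()
    pair_counts: dict[tuple, list[int]] = {}
    n_triads = 0
    cidx = 0
    for si, sj, ttype, count in config.plants:
        a, b = ("STRAIN", si), ("STRAIN", sj)
        for _ in range(count):
            c = ("COMPOUND", f"c{cidx:05d}")
            cidx += 1
            if ttype == "competition":
                edges.add((a, c, "DEGRADES"))
                edges.add((b, c, "DEGRADES"))
            elif ttype == "cross_feeding":
                edges.add((a, c, "PRODUCES"))
                edges.add((b, c, "DEGRADES"))
            elif ttype == "direct_inhibition":
                edges.add((a, c, "PRODUCES"))
                edges.add((c, b, "INHIBITS"))
            elif ttype == "resistance":
                edges.add((a, c, "PRODUCES"))
                edges.add((b, c, "RESISTS"))
            pair = tuple(sorted((a, b)))
            plus, minus = pair_counts.setdefault(pair, [0, 0])
            if TRIAD_SIGNS[ttype] > 0:
                pair_counts[pair][0] = plus + 1
            else:
                pair_counts[pair][1] = minus + 1
            n_triads += 1
    # decoys: single-relation compounds, guaranteed motif-free
    decoy_kinds = ("PRODUCES", "DEGRADES", "RESISTS", "INHIBITS")
    for d in range(config.n_decoys):
        s = ("STRAIN", f"decoy_strain_{d:04d}")
        strains.add(s)
        c = ("COMPOUND", f"c{cidx:05d}")
        cidx += 1
        kind = decoy_kinds[int(rng.integers(len(decoy_kinds)))]
        if kind == "INHIBITS":
            edges.add((c, s, kind))
        else:
            edges.add((s, c, kind))
    sub = EnvironmentSubnetwork(
        environment=env, strains=frozenset(strains), edges=tuple(sorted(edges))
    )
    gt = TrophicGroundTruth(
        pair_counts={p: (v[0], v[1]) for p, v in sorted(pair_counts.items())},
        n_triads=n_triads,
    )
    return sub, gt


# ---------------------------------------------------------------------------
# Genome / feature-matrix generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    n_assemblies: int = 200
    n_features: int = 50
    #: planted feature index -> logistic effect size beta
    planted: tuple[tuple[int, float], ...] = ((0, 4.0),)
    background_rate: float = 1.0  # Poisson mean of copy counts
    genus_weights: tuple[tuple[str, float], ...] = tuple(
        (g, 1.0) for g in GENERA[:6]
    )
    seed: int = 0


@dataclass
class GenomeGroundTruth:
    planted_features: list[str]
    betas: dict[str, float]
    probabilities: np.ndarray
    genus_weights: dict[str, float]


def gen_genomes(
    config: GenomeConfig,
) -> tuple[list[AssemblyAnnotation], np.ndarray, GenomeGroundTruth]:
    """Poisson copy-count features with labels from a logistic model.

    Copy counts are Poisson(``background_rate``); the label logit is
    ``sum_f beta_f * (x_f - rate - 0.5) / sqrt(rate)`` over planted features,
    centred between integer counts so that a single feature with beta = 4
    supports hold-out accuracy above 0.8.  Genus assignment follows the
    configured mixture.
    """
    if config.n_features < len(config.planted):
        raise ValueError("need at least as many features as planted effects")
    for idx, _ in config.planted:
        if not 0 <= idx < config.n_features:
            raise ValueError("planted feature index out of range")
    weights = np.array([w for _, w in config.genus_weights], dtype=float)
    if weights.sum() <= 0 or (weights < 0).any():
        raise ValueError("degenerate genus mixture")
    weights /= weights.sum()
    genera = [g for g, _ in config.genus_weights]
    rng = np.random.default_rng(config.seed)
    feats = [f"PF{i:05d}" for i in range(config.n_features)]
    X = rng.poisson(config.background_rate, size=(config.n_assemblies, config.n_features))
    logit = np.zeros(config.n_assemblies)
    scale = np.sqrt(config.background_rate) if config.background_rate > 0 else 1.0
    for idx, beta in config.planted:
        logit += beta * (X[:, idx] - config.background_rate - 0.5) / scale
    prob = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.random(config.n_assemblies) < prob).astype(int)
    genus_idx = rng.choice(len(genera), size=config.n_assemblies, p=weights)
    annotations = []
    for i in range(config.n_assemblies):
        counts = {feats[j]: int(X[i, j]) for j in range(config.n_features) if X[i, j] > 0}
        annotations.append(
            AssemblyAnnotation(
                assembly_id=f"GCF_{i:09d}.1",
                strain_id=f"strain_{i:06d}",
                genus=genera[int(genus_idx[i])],
                counts=counts,
            )
        )
    gt = GenomeGroundTruth(
        planted_features=[feats[idx] for idx, _ in config.planted],
        betas={feats[idx]: beta for idx, beta in config.planted},
        probabilities=prob,
        genus_weights={g: float(w) for g, w in zip(genera, weights)},
    )
    return annotations, labels, gt


# ---------------------------------------------------------------------------
# Catalog generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogConfig:
    n_entries: int = 50
    edit_budget: int = 1
    variants_per_entry: int = 1
    abbreviate: bool = True
    seed: int = 0


@dataclass
class CatalogGroundTruth:
    #: corrupted/abbreviated term -> true canonical id
    term_to_canonical: dict[str, str]


def _random_edit(term: str, rng: np.random.Generator) -> str:
    letters = string.ascii_lowercase
    op = int(rng.integers(3))
    i = int(rng.integers(len(term)))
    ch = letters[int(rng.integers(len(letters)))]
    if op == 0 and len(term) > 1:  # delete
        return term[:i] + term[i + 1 :]
    if op == 1:  # insert
        return term[:i] + ch + term[i:]
    if term[i] == ch:  # substitution must change the string
        ch = letters[(letters.index(ch) + 1) % len(letters)]
    return term[:i] + ch + term[i + 1 :]


def gen_catalog(
    config: CatalogConfig,
) -> tuple[list[StrainCatalogEntry], list[str], CatalogGroundTruth]:
    """Canonical strain names plus bounded-edit and abbreviation variants.

    Canonical names carry unique numeric codes, so names stay well separated
    and any variant within the edit budget resolves unambiguously.  With an
    edit budget of 0, variants equal the aliases and match at distance 0.
    """
    rng = np.random.default_rng(config.seed)
    entries: list[StrainCatalogEntry] = []
    corrupted: list[str] = []
    truth: dict[str, str] = {}
    for i in range(config.n_entries):
        genus = GENERA[i % len(GENERA)]
        epithet = SPECIES_EPITHETS[(i // len(GENERA)) % len(SPECIES_EPITHETS)]
        name = f"{genus} {epithet} DSM {10000 + 7 * i}"
        cid = f"SS{i:05d}"
        entries.append(StrainCatalogEntry(canonical_id=cid, aliases=(name,)))
        for _ in range(config.variants_per_entry):
            variant = name
            for _ in range(config.edit_budget):
                variant = _random_edit(variant, rng)
            corrupted.append(variant)
            truth[variant] = cid
        if config.abbreviate:
            abbrev = f"{genus[0]}. {epithet} DSM {10000 + 7 * i}"
            corrupted.append(abbrev)
            truth[abbrev] = cid
    return entries, corrupted, CatalogGroundTruth(term_to_canonical=truth)
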