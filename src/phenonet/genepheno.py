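"""Pfam copy-count features, phenotype clusters, gradient boosting, GO enrichment."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Column layout of the InterProScan TSV dialect (no header row).
INTERPROSCAN_COLUMNS = (
    "protein_accession",
    "md5",
    "sequence_length",
    "analysis",
    "signature_accession",
    "signature_description",
    "start",
    "stop",
    "score",
    "status",
    "date",
)


@dataclass
class AssemblyAnnotation:
    """Pfam copy counts for one genome assembly."""

    assembly_id: str
    strain_id: str
    genus: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValueError("genus must be non-empty")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("copy counts must be non-negative")


@dataclass
class PhenotypeCluster:
    """Binarized strain labels for one (relation type, entity term) pair."""

    relation_type: str
    term: str
    positives: frozenset  # assembly ids labelled 1
    universe: tuple  # all assembly ids of the relation type, ordered

    def __post_init__(self) -> None:
        if not self.positives <= set(self.universe):
            raise ValueError("positives must be a subset of the universe")

    @property
    def cluster_id(self) -> str:
        return f"{self.relation_type}:{self.term}"

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if a in self.positives else 0 for a in self.universe])


@dataclass(frozen=True)
class ModelConfig:
    max_depth: int = 6
    learning_rate: float = 0.3
    objective: str = "binary:logistic"
    eval_metric: str = "logloss"
    max_rounds: int = 5000
    early_stopping_rounds: int = 10
    validation_fraction: float = 0.1  # inner split carved from training
    seed: int = 0


@dataclass
class TrainedModelSummary:
    cluster_id: str
    accuracy: float
    gains: dict[str, float]  # feature -> gain (total impurity gain / split count)
    n_rounds: int

    @property
    def retained(self) -> bool:
        return self.accuracy > 0.8  # strict, as printed

    def ranked_features(self) -> list[tuple[str, float]]:
        return sorted(self.gains.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class EnrichmentResult:
    relation_type: str
    go_term: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_value: float
    q_value: float = float("nan")


# ---------------------------------------------------------------------------
# Annotation input
# ---------------------------------------------------------------------------


def read_annotations(
    manifest: pd.DataFrame, genus_overrides: dict[str, str] | None = None
) -> list[AssemblyAnnotation]:
    """Read per-assembly InterProScan tables into Pfam copy-count annotations.

    ``manifest`` needs columns ``assembly_id``, ``strain_id``, ``organism``
    and ``path`` (path to a headerless InterProScan TSV).  Only rows whose
    analysis column equals ``Pfam`` are counted; malformed rows are skipped
    with a warning.  The genus is the first whitespace token of the organism
    name, unless overridden per assembly.
    """
    out: list[AssemblyAnnotation] = []
    genus_overrides = genus_overrides or {}
    for row in manifest.itertuples(index=False):
        counts = count_pfam_rows(row.path)
        genus = genus_overrides.get(row.assembly_id) or str(row.organism).split()[0]
        out.append(
            AssemblyAnnotation(
                assembly_id=row.assembly_id,
                strain_id=row.strain_id,
                genus=genus,
                counts=counts,
            )
        )
    return out


def count_pfam_rows(path) -> dict[str, int]:
    """Count Pfam signature hits per accession in one InterProScan TSV."""
    counts: dict[str, int] = {}
    n_rows = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                logger.warning("%s:%d: malformed row skipped", path, line_no)
                continue
            n_rows += 1
            if parts[3] != "Pfam":
                continue
            acc = parts[4]
            counts[acc] = counts.get(acc, 0) + 1
    if n_rows == 0:
        raise ValueError(f"empty annotation table: {path}")
    return counts


def feature_matrix(annotations: list[AssemblyAnnotation]) -> pd.DataFrame:
    """Wide assemblies x Pfam copy-count matrix (missing families are 0)."""
    rows = {a.assembly_id: a.counts for a in annotations}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int).sort_index(
        axis=0
    ).sort_index(axis=1)


# ---------------------------------------------------------------------------
# Phenotype clusters
# ---------------------------------------------------------------------------


def define_clusters(
    records,
    annotations: list[AssemblyAnnotation],
    min_term_count: int = 3,
) -> list[PhenotypeCluster]:
    """One cluster per (relation type, term) with term occurrence >= threshold.

    The universe of a relation type is every assembly whose strain appears in
    any record of that type; a cluster's positives are the assemblies whose
    strain co-occurs with the term.  Entity terms appearing fewer than
    ``min_term_count`` times (record occurrences) are discarded.  Output is
    deterministic and independent of record order.
    """
    by_strain: dict[str, list[str]] = {}
    for a in annotations:
        by_strain.setdefault(a.strain_id, []).append(a.assembly_id)
    universes: dict[str, set] = {}
    term_counts: dict[tuple[str, str], int] = {}
    term_assemblies: dict[tuple[str, str], set] = {}
    for rec in records:
        if rec.source_category == "STRAIN":
            strain_term, term = rec.source_term, rec.target_term
        elif rec.target_category == "STRAIN":
            strain_term, term = rec.target_term, rec.source_term
        else:
            continue
        assemblies = by_strain.get(strain_term)
        if not assemblies:
            continue
        key = (rec.relation_type, term)
        universes.setdefault(rec.relation_type, set()).update(assemblies)
        term_counts[key] = term_counts.get(key, 0) + 1
        term_assemblies.setdefault(key, set()).update(assemblies)
    clusters = []
    for key in sorted(term_counts):
        if term_counts[key] < min_term_count:
            continue
        rel, term = key
        clusters.append(
            PhenotypeCluster(
                relation_type=rel,
                term=term,
                positives=frozenset(term_assemblies[key]),
                universe=tuple(sorted(universes[rel])),
            )
        )
    return clusters


def filter_clusters(
    clusters: list[PhenotypeCluster],
    annotations: list[AssemblyAnnotation],
    min_assemblies: int = 10,
    min_genera: int = 5,
    max_genus_share: float = 0.30,
) -> list[PhenotypeCluster]:
    """Keep clusters with >= 10 positives from >= 5 genera where the most
    abundant genus holds strictly less than 30% of the positive strains."""
    genus_of = {a.assembly_id: a.genus for a in annotations}
    kept = []
    for cl in clusters:
        genera = [genus_of[a] for a in cl.positives if a in genus_of]
        if len(genera) < min_assemblies:
            continue
        uniq, counts = np.unique(genera, return_counts=True)
        if len(uniq) < min_genera:
            continue
        if counts.max() / len(genera) >= max_genus_share:
            continue
        kept.append(cl)
    return kept


# ---------------------------------------------------------------------------
# Gradient boosting
# ---------------------------------------------------------------------------


def _per_feature_gain(model: GradientBoostingClassifier, feature_names) -> dict[str, float]:
    """Gain per feature: total impurity improvement over its splits, divided
    by the number of splits (the conventional "average gain" statistic)."""
    total = np.zeros(len(feature_names))
    splits = np.zeros(len(feature_names))
    for stage in model.estimators_:
        tree = stage[0].tree_
        for node in range(tree.node_count):
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:  # leaf
                continue
            f = tree.feature[node]
            gain = (
                tree.weighted_n_node_samples[node] * tree.impurity[node]
                - tree.weighted_n_node_samples[left] * tree.impurity[left]
                - tree.weighted_n_node_samples[right] * tree.impurity[right]
            )
            total[f] += max(gain, 0.0)
            splits[f] += 1
    gains = np.divide(total, splits, out=np.zeros_like(total), where=splits > 0)
    return {name: float(g) for name, g in zip(feature_names, gains)}


def train_and_rank(
    cluster: PhenotypeCluster,
    features: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    test_fraction: float = 0.2,
    seed: int | None = None,
) -> TrainedModelSummary:
    """Train a gradient-boosted tree classifier on one phenotype cluster.

    A stratified 80/20 split separates train and hold-out test sets; early
    stopping monitors log loss on an inner validation fraction carved from
    the training data.  Hold-out accuracy sets the ``retained`` flag
    (strictly > 0.8) and features are ranked by average gain.
    """
    y = cluster.labels
    if len(set(y)) < 2:
        raise ValueError("cluster must contain both classes")
    if len(y) < 10:
        raise ValueError("need at least 10 labelled assemblies")
    missing = [a for a in cluster.universe if a not in features.index]
    if missing:
        raise ValueError(f"feature matrix is missing assemblies: {missing[:5]}")
    X = features.loc[list(cluster.universe)].to_numpy(dtype=float)
    seed = config.seed if seed is None else seed
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    model = GradientBoostingClassifier(
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        n_estimators=config.max_rounds,
        n_iter_no_change=config.early_stopping_rounds,
        validation_fraction=config.validation_fraction,
        random_state=seed,
    )
    model.fit(X_tr, y_tr)
    accuracy = float((model.predict(X_te) == y_te).mean())
    gains = _per_feature_gain(model, list(features.columns))
    return TrainedModelSummary(
        cluster_id=cluster.cluster_id,
        accuracy=accuracy,
        gains=gains,
        n_rounds=int(model.n_estimators_),
    )


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------


def go_enrichment(
    relation_type: str,
    clusters: list[PhenotypeCluster],
    pfam2go: dict[str, list[str]],
    annotations: list[AssemblyAnnotation],
) -> list[EnrichmentResult]:
    """Pooled Fisher-exact GO enrichment at the level of one relation type.

    Genes (Pfam copies) of all positive assemblies of the given clusters are
    pooled as the foreground; the background is every annotated gene of the
    universe assemblies not in the foreground.  Per GO term a 2x2 table of
    with/without-term gene counts is tested two-sided; q-values are
    Benjamini-Hochberg.
    """
    if not pfam2go:
        raise ValueError("empty pfam2go mapping")
    clusters = [c for c in clusters if c.relation_type == relation_type]
    fg_assemblies = set().union(*(c.positives for c in clusters)) if clusters else set()
    universe = set().union(*(set(c.universe) for c in clusters)) if clusters else set()
    counts = {a.assembly_id: a.counts for a in annotations}

    def pooled(assemblies) -> tuple[dict[str, int], int]:
        go_counts: dict[str, int] = {}
        total = 0
        for aid in assemblies:
            for pfam, n in counts.get(aid, {}).items():
                total += n
                for go in pfam2go.get(pfam, ()):
                    go_counts[go] = go_counts.get(go, 0) + n
        return go_counts, total

    fg_go, fg_total = pooled(fg_assemblies)
    bg_go, bg_total = pooled(universe - fg_assemblies)
    results = []
    for go in sorted(set(fg_go) | set(bg_go)):
        a = fg_go.get(go, 0)
        b = fg_total - a
        c = bg_go.get(go, 0)
        d = bg_total - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(
            EnrichmentResult(relation_type, go, ((a, b), (c, d)), float(p))
        )
    if results:
        qs = bh_qvalues([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = q
    return results


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    return multipletests(pvalues, method="fdr_bh")[1]
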