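import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import brute_force_fisher, reference_bh
from phenonet.genepheno import (
    AssemblyAnnotation,
    ModelConfig,
    PhenotypeCluster,
    TrainedModelSummary,
    bh_qvalues,
    count_pfam_rows,
    define_clusters,
    feature_matrix,
    filter_clusters,
    go_enrichment,
    read_annotations,
    train_and_rank,
)
from phenonet.io import write_interproscan
from phenonet.network import RelationRecord
from phenonet.simulate import GENERA, GenomeConfig, gen_genomes


def _record(sid, strain, term, rel="PRESENTS", tcat="PHENOTYPE"):
    return RelationRecord(sid, strain, "STRAIN", term, tcat, rel, 0.9)


def _annotation(i, genus="Escherichia", counts=None):
    return AssemblyAnnotation(
        assembly_id=f"GCF_{i:09d}.1",
        strain_id=f"strain_{i}",
        genus=genus,
        counts=counts or {"PF00001": 1},
    )


class TestReadAnnotations:
    def test_writer_reader_roundtrip(self, tmp_path):
        ann = _annotation(1, counts={"PF00005": 3, "PF00072": 1})
        path = tmp_path / "a.tsv"
        write_interproscan(ann, path)
        assert count_pfam_rows(path) == ann.counts

    def test_non_pfam_rows_ignored(self, tmp_path):
        path = tmp_path / "mixed.tsv"
        row = ["p1", "0" * 32, "100", "Pfam", "PF00005", "d", "1", "50", "1e-5", "T", "d"]
        other = list(row)
        other[3], other[4] = "PANTHER", "PTHR1234"
        path.write_text("\t".join(row) + "\n" + "\t".join(other) + "\n")
        assert count_pfam_rows(path) == {"PF00005": 1}

    def test_malformed_row_skipped(self, tmp_path):
        path = tmp_path / "bad.tsv"
        good = "\t".join(["p1", "0" * 32, "100", "Pfam", "PF00005"])
        path.write_text("oops\n" + good + "\n")
        assert count_pfam_rows(path) == {"PF00005": 1}

    def test_empty_table_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            count_pfam_rows(path)

    def test_genus_from_organism_with_override(self, tmp_path):
        ann = _annotation(1)
        path = tmp_path / "a.tsv"
        write_interproscan(ann, path)
        manifest = pd.DataFrame(
            [{"assembly_id": "A1", "strain_id": "s1",
              "organism": "Escherichia coli K12", "path": str(path)},
             {"assembly_id": "A2", "strain_id": "s2",
              "organism": "Bacillus subtilis", "path": str(path)}]
        )
        out = read_annotations(manifest, genus_overrides={"A2": "Priestia"})
        assert out[0].genus == "Escherichia"
        assert out[1].genus == "Priestia"


class TestDefineClusters:
    def _annotations(self, n=20):
        return [_annotation(i) for i in range(n)]

    def test_below_threshold_dropped(self):
        anns = self._annotations(5)
        records = [_record(f"s{i}", f"strain_{i}", "motile") for i in range(2)]
        assert define_clusters(records, anns) == []

    def test_binarization(self):
        anns = self._annotations(20)
        records = [_record(f"p{i}", f"strain_{i}", "motile") for i in range(5)]
        records += [_record(f"q{i}", f"strain_{i}", "rod") for i in range(20)]
        clusters = define_clusters(records, anns)
        motile = next(c for c in clusters if c.term == "motile")
        assert len(motile.universe) == 20
        assert sorted(motile.labels) == [0] * 15 + [1] * 5

    def test_order_invariance(self):
        anns = self._annotations(10)
        records = [_record(f"r{i}", f"strain_{i % 5}", "motile") for i in range(6)]
        a = define_clusters(records, anns)
        b = define_clusters(list(reversed(records)), anns)
        assert [(c.relation_type, c.term, c.positives) for c in a] == [
            (c.relation_type, c.term, c.positives) for c in b
        ]

    def test_universe_per_relation_type(self):
        anns = self._annotations(10)
        records = [_record(f"a{i}", f"strain_{i}", "motile") for i in range(4)]
        records += [_record(f"b{i}", f"strain_{i + 4}", "LB", rel="GROWS_ON",
                            tcat="MEDIUM") for i in range(4)]
        clusters = define_clusters(records, anns)
        motile = next(c for c in clusters if c.term == "motile")
        assert len(motile.universe) == 4  # GROWS_ON assemblies not in universe


class TestFilterClusters:
    def _cluster(self, positives, universe_n=40):
        universe = tuple(f"GCF_{i:09d}.1" for i in range(universe_n))
        return PhenotypeCluster("PRESENTS", "t", frozenset(positives), universe)

    def _annotations_with_genera(self, genera):
        return [_annotation(i, genus=g) for i, g in enumerate(genera)]

    def test_too_few_assemblies_dropped(self):
        genera = [GENERA[i % 9] for i in range(40)]
        anns = self._annotations_with_genera(genera)
        cl = self._cluster([f"GCF_{i:09d}.1" for i in range(9)])
        assert filter_clusters([cl], anns) == []

    def test_thirty_percent_is_strict(self):
        # 12 positives, 6 genera, largest genus 4/12 ≈ 33% -> dropped
        genera = ["A"] * 4 + ["B", "C", "D", "E"] * 2
        anns = self._annotations_with_genera(genera + ["F"] * 28)
        positives = [f"GCF_{i:09d}.1" for i in range(12)]
        cl = self._cluster(positives)
        assert filter_clusters([cl], anns) == []

    def test_kept_cluster(self):
        # 20 positives, 5 genera, largest 5/20 = 25% -> kept
        genera = (["A"] * 5 + ["B"] * 5 + ["C"] * 4 + ["D"] * 3 + ["E"] * 3)
        anns = self._annotations_with_genera(genera + ["F"] * 20)
        cl = self._cluster([f"GCF_{i:09d}.1" for i in range(20)])
        assert len(filter_clusters([cl], anns)) == 1

    def test_too_few_genera_dropped(self):
        genera = ["A", "B", "C", "D"] * 5
        anns = self._annotations_with_genera(genera)
        cl = self._cluster([f"GCF_{i:09d}.1" for i in range(20)])
        assert filter_clusters([cl], anns) == []

    def test_monotone_in_positives(self):
        # adding positives never flips kept -> dropped for the >=10/>=5 rules
        genera = ["A", "B", "C", "D", "E"] * 8
        anns = self._annotations_with_genera(genera)
        base = [f"GCF_{i:09d}.1" for i in range(15)]
        kept_small = filter_clusters([self._cluster(base)], anns)
        assert kept_small
        bigger = self._cluster(base + [f"GCF_{i:09d}.1" for i in range(15, 25)])
        assert filter_clusters(
            [bigger], anns, max_genus_share=1.01  # isolate the two monotone rules
        )


class TestTrainAndRank:
    def _cluster_from(self, annotations, labels):
        ids = [a.assembly_id for a in annotations]
        return PhenotypeCluster(
            "PRESENTS", "synthetic",
            frozenset(i for i, l in zip(ids, labels) if l),
            tuple(sorted(ids)),
        )

    def test_planted_feature_top_ranked(self):
        ann, labels, gt = gen_genomes(
            GenomeConfig(n_assemblies=200, n_features=51, planted=((7, 4.0),), seed=0)
        )
        summary = train_and_rank(self._cluster_from(ann, labels),
                                 feature_matrix(ann), seed=0)
        assert summary.ranked_features()[0][0] == gt.planted_features[0]
        assert summary.accuracy > 0.8 and summary.retained

    def test_null_labels_not_retained(self):
        ann, labels, _ = gen_genomes(
            GenomeConfig(n_assemblies=200, n_features=30, planted=((0, 0.0),), seed=2)
        )
        summary = train_and_rank(self._cluster_from(ann, labels),
                                 feature_matrix(ann), seed=2)
        assert 0.3 <= summary.accuracy <= 0.7
        assert not summary.retained

    def test_retained_threshold_strict(self):
        s = TrainedModelSummary("c", 0.80, {}, 10)
        assert not s.retained
        assert TrainedModelSummary("c", 0.801, {}, 10).retained

    def test_single_class_error(self):
        ann, _, _ = gen_genomes(GenomeConfig(n_assemblies=20, seed=1))
        cl = self._cluster_from(ann, [1] * 20)
        with pytest.raises(ValueError, match="both classes"):
            train_and_rank(cl, feature_matrix(ann))

    def test_missing_assembly_error(self):
        ann, labels, _ = gen_genomes(GenomeConfig(n_assemblies=20, seed=1))
        labels = [0, 1] * 10
        cl = self._cluster_from(ann, labels)
        feats = feature_matrix(ann).drop(index=ann[0].assembly_id)
        with pytest.raises(ValueError, match="missing"):
            train_and_rank(cl, feats)

    def test_config_defaults_match_printed_values(self):
        cfg = ModelConfig()
        assert (cfg.max_depth, cfg.learning_rate) == (6, 0.3)
        assert (cfg.max_rounds, cfg.early_stopping_rounds) == (5000, 10)


class TestGoEnrichment:
    def test_fisher_matches_brute_force_oracle(self):
        for table in ([[10, 0], [0, 10]], [[5, 3], [2, 8]], [[1, 9], [9, 1]],
                      [[0, 5], [5, 0]], [[4, 4], [4, 4]]):
            _, p = stats.fisher_exact(table, alternative="two-sided")
            assert p == pytest.approx(brute_force_fisher(table), abs=1e-10)

    def test_extreme_table_value(self):
        # [[10,0],[0,10]] -> p = 2 / C(20,10)
        _, p = stats.fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    def test_equal_proportions_p_one(self):
        _, p = stats.fisher_exact([[5, 5], [50, 50]])
        assert p == pytest.approx(1.0)

    def test_bh_equal_pvalues(self):
        qs = bh_qvalues([0.01] * 7)
        assert np.allclose(qs, 0.01)

    def test_bh_matches_reference(self, rng):
        ps = rng.random(40)
        assert np.allclose(bh_qvalues(ps), reference_bh(ps))

    def test_bh_monotone_in_rank(self, rng):
        ps = np.sort(rng.random(25))
        qs = bh_qvalues(ps)
        assert np.all(np.diff(qs) >= -1e-15)
        assert np.all(qs >= ps - 1e-15)

    def _setup(self):
        anns = [
            _annotation(0, counts={"PF1": 5, "PF2": 5}),
            _annotation(1, counts={"PF1": 5, "PF2": 5}),
            _annotation(2, counts={"PF2": 10}),
            _annotation(3, counts={"PF2": 10}),
        ]
        ids = [a.assembly_id for a in anns]
        cluster = PhenotypeCluster("PRESENTS", "t", frozenset(ids[:2]), tuple(ids))
        return anns, cluster

    def test_enrichment_directionality(self):
        anns, cluster = self._setup()
        res = go_enrichment("PRESENTS", [cluster], {"PF1": ["GO:1"], "PF2": ["GO:2"]},
                            anns)
        by_go = {r.go_term: r for r in res}
        # GO:1 only in the foreground: strongly enriched
        assert by_go["GO:1"].p_value < 0.01
        assert by_go["GO:1"].table[0][0] == 10 and by_go["GO:1"].table[1][0] == 0
        assert all(0 <= r.q_value <= 1 for r in res)

    def test_empty_mapping_error(self):
        anns, cluster = self._setup()
        with pytest.raises(ValueError, match="empty"):
            go_enrichment("PRESENTS", [cluster], {}, anns)
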