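import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sentence
from phenonet import corpus
from phenonet.corpus import (
    AnnotatedSentence,
    EntitySpan,
    SplitSpec,
    allocate_counts,
    augment_by_strain_swap,
    bio_encode,
    filter_corpus,
    plan_augmentation,
    spans_from_bio,
    stratified_split,
    tokenize,
)


class TestFilterCorpus:
    def _rec(self, i, text, section="results", conf=0.9):
        return {"id": f"r{i}", "text": text, "section": section,
                "english_confidence": conf}

    def test_excluded_section_dropped(self):
        kept, drops = filter_corpus([self._rec(0, "Some text.", section="Acknowledgements")])
        assert kept == [] and drops["excluded_section"] == 1

    def test_hyphen_replaced(self):
        kept, _ = filter_corpus([self._rec(0, "Gram-negative rod")])
        assert kept[0].text == "Gram negative rod"

    def test_duplicates_dropped(self):
        kept, drops = filter_corpus(
            [self._rec(0, "Same sentence."), self._rec(1, "Same sentence.")]
        )
        assert len(kept) == 1 and drops["duplicate"] == 1

    def test_duplicate_after_normalization(self):
        kept, _ = filter_corpus([self._rec(0, "A  b c."), self._rec(1, "a B C.")])
        assert len(kept) == 1

    def test_low_confidence_dropped_at_threshold(self):
        # rule is strictly greater than 0.40
        kept, drops = filter_corpus([self._rec(0, "Texto.", conf=0.40)])
        assert kept == [] and drops["low_confidence"] == 1

    def test_confidence_just_above_kept(self):
        kept, _ = filter_corpus([self._rec(0, "Text.", conf=0.41)])
        assert len(kept) == 1

    def test_missing_text_reason_code(self):
        kept, drops = filter_corpus([{"id": "x", "section": "results"}])
        assert kept == [] and drops["no_text"] == 1

    def test_short_paragraph_kept_whole(self):
        text = "First sentence here. Second sentence follows."
        kept, _ = filter_corpus([self._rec(0, text)])
        assert len(kept) == 1 and kept[0].text == text

    def test_long_paragraph_split_into_sentences(self):
        text = ("A" * 300 + " ends here. ") + ("B" * 300 + " also ends.")
        assert len(text) >= 512
        kept, _ = filter_corpus([self._rec(0, text)])
        assert len(kept) == 2
        assert kept[0].id == "r0.s0" and kept[1].id == "r0.s1"

    def test_journal_allowlist(self):
        recs = [dict(self._rec(0, "Text one."), journal="J Bact"),
                dict(self._rec(1, "Text two."), journal="Astrophys J")]
        kept, drops = filter_corpus(recs, journal_allowlist={"J Bact"})
        assert len(kept) == 1 and drops["journal"] == 1


class TestTokenize:
    def test_punctuation_detached(self):
        assert [t.text for t in tokenize("E. coli grows.")] == [
            "E", ".", "coli", "grows", ".",
        ]

    def test_empty(self):
        assert tokenize("") == []

    def test_offsets_reconstruct(self):
        text = "pH 7.0, (aerobic) growth!"
        for t in tokenize(text):
            assert text[t.start : t.end] == t.text

    @settings(max_examples=200, deadline=None)
    @given(st.text(max_size=60))
    def test_roundtrip_property(self, text):
        toks = tokenize(text)
        # tokens are ordered, non-overlapping, and tile the non-whitespace text
        rebuilt = list(text)
        last = 0
        for t in toks:
            assert t.start >= last
            assert text[t.start : t.end] == t.text
            for i in range(t.start, t.end):
                rebuilt[i] = None
            last = t.end
        assert all(ch is None or ch.isspace() for ch in rebuilt)


class TestBioEncode:
    def test_single_token_span(self):
        s = make_sentence("Strain X33 grows", spans=[("STRAIN", 7, 10)])
        assert bio_encode(s, "STRAIN") == ["O", "B", "O"]

    def test_multi_token_span(self):
        text = "Bacillus subtilis 168 sporulates"
        s = make_sentence(text, spans=[("STRAIN", 0, 21)])
        assert bio_encode(s, "STRAIN") == ["B", "I", "I", "O"]

    def test_no_spans_all_o(self, strain_sentence):
        assert bio_encode(strain_sentence, "DISEASE") == ["O"] * len(
            strain_sentence.tokens
        )

    def test_overlapping_spans_error(self):
        text = "Bacillus subtilis 168"
        s = AnnotatedSentence(
            id="x", text=text, tokens=tokenize(text),
            spans=[EntitySpan("STRAIN", 0, 17, text[0:17]),
                   EntitySpan("STRAIN", 9, 21, text[9:21])],
        )
        with pytest.raises(ValueError, match="overlapping"):
            bio_encode(s, "STRAIN")

    def test_encode_decode_identity(self, strain_sentence):
        for cat in ("STRAIN", "MEDIUM", "COMPOUND"):
            labels = bio_encode(strain_sentence, cat)
            got = spans_from_bio(strain_sentence, labels, cat)
            assert [(s.start, s.end) for s in got] == [
                (s.start, s.end) for s in strain_sentence.spans_of(cat)
            ]


class TestStratifiedSplit:
    def test_allocation_3979(self):
        # frozen via the rounding rule: round all but last, last absorbs rest
        assert allocate_counts(3979, (0.65, 0.175, 0.175)) == [2586, 696, 697]

    def test_allocation_10(self):
        assert allocate_counts(10, (0.6, 0.2, 0.2)) == [6, 2, 2]

    def _sentences(self, n):
        out = []
        for i in range(n):
            if i % 2:
                out.append(make_sentence("Strain X33 grows", spans=[("STRAIN", 7, 10)],
                                         sid=f"s{i}"))
            else:
                out.append(make_sentence("No entities here", sid=f"s{i}"))
        return out

    def test_partition_disjoint_exhaustive(self):
        sents = self._sentences(40)
        parts = stratified_split(sents, SplitSpec(seed=7))
        ids = [s.id for p in parts for s in p]
        assert sorted(ids) == sorted(s.id for s in sents)
        assert len(set(ids)) == len(ids)

    def test_per_stratum_proportions_within_one(self):
        sents = self._sentences(200)
        parts = stratified_split(sents, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=3))
        for frac, part in zip((0.6, 0.2, 0.2), parts):
            with_strain = sum(1 for s in part if s.spans)
            assert abs(with_strain - frac * 100) <= 1
            assert abs(len(part) - frac * 200) <= 2  # two strata, ≤1 each

    def test_deterministic(self):
        sents = self._sentences(50)
        a = stratified_split(sents, SplitSpec(seed=11))
        b = stratified_split(sents, SplitSpec(seed=11))
        assert [[s.id for s in p] for p in a] == [[s.id for s in p] for p in b]

    def test_small_input_errors(self):
        with pytest.raises(ValueError):
            stratified_split(self._sentences(2), SplitSpec())

    def test_tiny_strata_pooled(self):
        sents = self._sentences(9)
        parts = stratified_split(sents, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=0))
        assert sum(len(p) for p in parts) == 9

    def test_invalid_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))


class TestPlanAugmentation:
    @pytest.mark.parametrize(
        "n_pos,n_neg,mode,expected",
        [(100, 300, "NER", 200), (300, 100, "NER", 0), (100, 300, "RE", 40),
         (0, 0, "NER", 0), (10, 11, "RE", 1)],
    )
    def test_formula(self, n_pos, n_neg, mode, expected):
        assert plan_augmentation("STRAIN", n_pos, n_neg, mode).n_aug == expected

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            plan_augmentation("STRAIN", -1, 5, "NER")

    def test_unknown_mode_error(self):
        with pytest.raises(ValueError):
            plan_augmentation("STRAIN", 1, 5, "XX")

    def test_ner_closes_gap_exactly(self):
        plan = plan_augmentation("STRAIN", 120, 500, "NER")
        assert plan.n_pos + plan.n_aug == plan.n_neg


class TestAugmentBySwap:
    def test_zero_plan_empty(self, strain_sentence):
        plan = plan_augmentation("STRAIN", 5, 5, "NER")
        assert augment_by_strain_swap([strain_sentence], ["A"], plan) == []

    def test_counts_and_nonstrain_text_unchanged(self, strain_sentence):
        plan = plan_augmentation("STRAIN", 0, 5, "NER", seed=42)
        catalog = [f"Synthetica str{i}" for i in range(10)]
        out = augment_by_strain_swap([strain_sentence], catalog, plan)
        assert len(out) == 5
        for s in out:
            s.validate()
            strain = s.spans_of("STRAIN")[0]
            assert strain.term in catalog
            # removing the strain text leaves the template unchanged
            stripped = s.text[: strain.start] + "@" + s.text[strain.end :]
            orig = strain_sentence.spans_of("STRAIN")[0]
            assert stripped == (
                strain_sentence.text[: orig.start] + "@" + strain_sentence.text[orig.end :]
            )

    def test_no_eligible_sentence_error(self):
        s = make_sentence("No strain here")
        plan = plan_augmentation("STRAIN", 0, 2, "NER")
        with pytest.raises(ValueError, match="eligible"):
            augment_by_strain_swap([s], ["A"], plan)

    def test_reproducible(self, strain_sentence):
        plan = plan_augmentation("STRAIN", 0, 4, "NER", seed=9)
        cat = ["Aa bb 1", "Cc dd 2", "Ee ff 3"]
        a = augment_by_strain_swap([strain_sentence], cat, plan)
        b = augment_by_strain_swap([strain_sentence], cat, plan)
        assert [s.text for s in a] == [s.text for s in b]

    def test_bio_valid_after_many_swaps(self, strain_sentence, rng):
        # derived property: every synthetic sentence BIO-encodes cleanly
        plan = plan_augmentation("STRAIN", 0, 1000, "NER", seed=5)
        catalog = [f"Genus species S{i}" for i in range(25)]
        sents = [
            strain_sentence,
            make_sentence("Both X1 and Y22 grow.",
                          spans=[("STRAIN", 5, 7), ("STRAIN", 12, 15)], sid="s2"),
        ]
        for s in augment_by_strain_swap(sents, catalog, plan):
            for cat in corpus.ENTITY_CATEGORIES:
                labels = bio_encode(s, cat)
                got = spans_from_bio(s, labels, cat)
                assert [(x.start, x.end) for x in got] == [
                    (x.start, x.end) for x in sorted(s.spans_of(cat), key=lambda v: v.start)
                ]
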