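import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvcausal as pv
from pvcausal.preprocess import (
    AGE_CLASSES,
    DOSE_CLASSES,
    EndpointLabel,
    MISSING,
    convert_dose_to_mg,
)


class TestNormalizeMissing:
    @pytest.mark.parametrize("raw", ["UNKNOWN", "UNK", "()", "unk", "", "   "])
    def test_missing_tokens(self, raw):
        assert pv.normalize_missing(raw) is MISSING

    def test_trims_and_passes_through(self):
        assert pv.normalize_missing(" Tramadol ") == "Tramadol"

    def test_normalize_report_drops_missing_terms(self):
        r = pv.CaseReport("r1", {"gender": {"UNK"}, "drug": {" APAP ", "()"}})
        out = pv.normalize_report(r)
        assert out.values == {"gender": set(), "drug": {"APAP"}}


class TestDose:
    @pytest.mark.parametrize(
        "dose,expected",
        [(650, DOSE_CLASSES[1]), (50, DOSE_CLASSES[0]), (100, DOSE_CLASSES[0]),
         (100.01, DOSE_CLASSES[1]), (0, DOSE_CLASSES[0])],
    )
    def test_boundary(self, dose, expected):
        assert pv.categorize_dose(dose) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pv.categorize_dose(-1)

    @pytest.mark.parametrize(
        "value,unit,mg", [(1, "g", 1000.0), (500, "mg", 500.0), (200, "mcg", 0.2)]
    )
    def test_unit_conversion(self, value, unit, mg):
        assert convert_dose_to_mg(value, unit) == pytest.approx(mg)

    def test_unknown_unit_is_missing(self):
        assert convert_dose_to_mg(5, "drops") is MISSING


class TestAge:
    @pytest.mark.parametrize(
        "age,expected",
        [(17, "<18"), (18, "18-39"), (39, "18-39"), (40, "40-64"),
         (64, "40-64"), (65, "65+"), (90, "65+"), (0, "<18")],
    )
    def test_bins(self, age, expected):
        assert pv.categorize_age(age) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pv.categorize_age(-0.5)


class TestEndpointLabel:
    def test_positive_negative_excluded(self, toy_schema):
        mk = lambda out: pv.CaseReport("r", {"gender": {"male"}, "drug": {"APAP"}, "outcomes": out})
        assert pv.label_endpoint(mk({"death", "recovered"}), toy_schema) is EndpointLabel.POSITIVE
        assert pv.label_endpoint(mk({"recovered"}), toy_schema) is EndpointLabel.NEGATIVE
        assert pv.label_endpoint(mk(set()), toy_schema) is EndpointLabel.EXCLUDED

    def test_partition_is_exhaustive(self, planted_study):
        labels = [pv.label_endpoint(r, planted_study["schema"]) for r in planted_study["reports"]]
        assert all(l in EndpointLabel for l in labels)
        assert len(labels) == len(planted_study["reports"])


class TestSentenceGeneration:
    def test_deterministic(self, planted_study):
        r = planted_study["reports"][0]
        s1 = pv.generate_sentence(r, planted_study["schema"])
        s2 = pv.generate_sentence(r, planted_study["schema"])
        assert s1 == s2

    def test_missing_slots_render_placeholder(self, toy_schema):
        schema = pv.default_schema()
        r = pv.CaseReport("r1", {"primary suspect drug": {"tramadol"}, "outcomes": {"recovered"}})
        s = pv.generate_sentence(r, schema)
        assert "tramadol" in s.text and "unknown" in s.text and s.label == 0

    def test_outcomes_endpoint_drops_whole_clause(self):
        schema = pv.default_schema()
        r = pv.CaseReport(
            "r1",
            {"gender": {"female"}, "age": {"18-39"}, "primary suspect drug": {"APAP"},
             "dose": set(), "indication": {"pain"},
             "adverse events": {"nausea"}, "outcomes": {"death", "hospitalization"}},
        )
        s = pv.generate_sentence(r, schema)
        assert s.label == 1
        assert "death" not in s.text and "hospitalization" not in s.text
        assert "leading to" not in s.text

    def test_adverse_event_endpoint_excises_only_the_term(self):
        schema = pv.FeatureSchema(
            features=("gender", "adverse events"),
            vocab={"gender": {"male", "female"},
                   "adverse events": {"acute liver failure", "nausea"}},
            endpoint_feature="adverse events",
            endpoint_term="acute liver failure",
            multi_valued={"adverse events"},
        )
        r = pv.CaseReport("r1", {"gender": {"female"},
                                 "adverse events": {"acute liver failure", "nausea"}})
        s = pv.generate_sentence(r, schema)
        assert s.label == 1
        assert "acute liver failure" not in s.text and "nausea" in s.text

    def test_corpus_never_leaks_endpoint(self, planted_study):
        # fuzz over the whole generated corpus: no rendered sentence carries
        # any outcomes term (outcome-endpoint mode drops the clause)
        schema = planted_study["schema"]
        outcome_terms = schema.vocab["outcomes"]
        for s in planted_study["sentences"]:
            for term in outcome_terms:
                assert term not in s.text


class TestStratifiedSplit:
    @staticmethod
    def _records(n_pos, n_neg):
        recs = [pv.SentenceRecord(f"p{i}", "x", 1) for i in range(n_pos)]
        recs += [pv.SentenceRecord(f"n{i}", "x", 0) for i in range(n_neg)]
        return recs

    def test_exact_multiples(self):
        split = pv.stratified_split(self._records(100, 100), (0.64, 0.16, 0.20), seed=0)
        for part, n in (("train", 64), ("dev", 16), ("test", 20)):
            recs = getattr(split, part)
            assert sum(r.label for r in recs) == n and len(recs) == 2 * n

    @pytest.mark.parametrize("n_pos,n_neg", [(7, 13), (101, 99), (1, 1), (333, 667)])
    def test_conservation_and_disjointness(self, n_pos, n_neg):
        recs = self._records(n_pos, n_neg)
        split = pv.stratified_split(recs, seed=3)
        ids = [r.report_id for r in split.all_records]
        assert sorted(ids) == sorted(r.report_id for r in recs)
        assert sum(r.label for r in split.all_records) == n_pos

    def test_seed_determinism(self):
        recs = self._records(50, 70)
        a = pv.stratified_split(recs, seed=11)
        b = pv.stratified_split(recs, seed=11)
        c = pv.stratified_split(recs, seed=12)
        assert [r.report_id for r in a.train] == [r.report_id for r in b.train]
        assert [r.report_id for r in a.train] != [r.report_id for r in c.train]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pv.stratified_split([pv.SentenceRecord("p", "x", 1)], seed=0)

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            pv.stratified_split(self._records(5, 5), (1.0, 0.0, 0.0), seed=0)


class TestDatasetSummary:
    @pytest.mark.parametrize(
        "n_pos,n_neg,ratio", [(15224, 21437, 0.71), (9846, 17399, 0.57), (1, 1, 1.0)]
    )
    def test_printed_ratios(self, n_pos, n_neg, ratio):
        recs = [pv.SentenceRecord(f"p{i}", "a b", 1) for i in range(n_pos)]
        recs += [pv.SentenceRecord(f"n{i}", "a b c", 0) for i in range(n_neg)]
        assert pv.dataset_summary(recs).pos_neg_ratio == ratio

    def test_zero_negatives_reported_as_undefined(self):
        recs = [pv.SentenceRecord("p0", "a", 1)]
        assert pv.dataset_summary(recs).pos_neg_ratio is None

    def test_length_statistics(self):
        recs = [pv.SentenceRecord("a", "one two three", 1),
                pv.SentenceRecord("b", "one", 0)]
        s = pv.dataset_summary(recs)
        assert s.mean_length == 2.0
        assert s.sd_length == pytest.approx(math.sqrt(2.0))


class TestTfidf:
    def test_three_document_oracle(self):
        # independent evaluation of the smoothed-idf / L2-normalized formula
        docs = ["apple banana", "apple cherry", "apple banana banana"]
        recs = [pv.SentenceRecord(f"d{i}", t, 0) for i, t in enumerate(docs)]
        vocab = ["apple", "banana", "cherry"]
        tf = np.array([[1, 1, 0], [1, 0, 1], [1, 2, 0]], dtype=float)
        df = np.array([3, 2, 1], dtype=float)
        idf = np.log((1 + 3) / (1 + df)) + 1
        w = tf * idf
        w = w / np.linalg.norm(w, axis=1, keepdims=True)
        expected = dict(zip(vocab, w.mean(axis=0)))
        got = dict(pv.tfidf_top_terms(recs, k=3))
        for term in vocab:
            assert got[term] == pytest.approx(expected[term], abs=1e-12)

    def test_rare_term_outranks_ubiquitous_term_within_document(self):
        from pvcausal.preprocess import tfidf_matrix

        docs = ["alpha gamma", "alpha beta", "alpha beta", "alpha beta"]
        recs = [pv.SentenceRecord(f"d{i}", t, 0) for i, t in enumerate(docs)]
        terms, mat = tfidf_matrix(recs)
        idx = {t: i for i, t in enumerate(terms)}
        dense = mat.toarray()
        # in the document holding both at equal tf, the singleton term's
        # higher idf puts it above the term present everywhere
        assert dense[0, idx["gamma"]] > dense[0, idx["alpha"]]

    def test_k_larger_than_vocabulary(self):
        recs = [pv.SentenceRecord("d0", "solo word", 0)]
        assert len(pv.tfidf_top_terms(recs, k=99)) == 2

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            pv.tfidf_top_terms([pv.SentenceRecord("d0", "x", 0)], k=0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    n_pos=st.integers(min_value=2, max_value=80),
    n_neg=st.integers(min_value=2, max_value=80),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_split_is_pure_function_of_inputs(n_pos, n_neg, seed):
    recs = [pv.SentenceRecord(f"p{i}", "x", 1) for i in range(n_pos)]
    recs += [pv.SentenceRecord(f"n{i}", "x", 0) for i in range(n_neg)]
    a = pv.stratified_split(recs, seed=seed)
    b = pv.stratified_split(recs, seed=seed)
    assert [r.report_id for r in a.all_records] == [r.report_id for r in b.all_records]
    assert len(a.all_records) == n_pos + n_neg
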