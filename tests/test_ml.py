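import numpy as np
import pytest

from tnmstage import (
    assemble_patients,
    build_patient_vector,
    predict,
    train_embeddings,
    train_task_classifier,
)
from tnmstage.ml import PatientVector


@pytest.fixture(scope="module")
def toy_embeddings():
    sentences = [
        ["organ", "confined", "disease", "noted"],
        ["organ", "confined", "tumor", "present"],
        ["extracapsular", "extension", "disease", "seen"],
        ["extracapsular", "extension", "tumor", "found"],
        ["bone", "scan", "negative", "today"],
        ["bone", "scan", "positive", "today"],
    ] * 3
    return train_embeddings(sentences, d=16, window=2, seed=3, epochs=2)


class TestTrainEmbeddings:
    def test_vector_length_matches_d(self, toy_embeddings):
        assert toy_embeddings.vectors.shape[1] == 16
        assert all(len(toy_embeddings.vector(t)) == 16 for t in toy_embeddings.vocabulary)

    def test_deterministic_under_fixed_seed(self):
        sents = [["alpha", "beta", "gamma"], ["beta", "gamma", "delta"]] * 4
        a = train_embeddings(sents, d=8, seed=5, epochs=2)
        b = train_embeddings(sents, d=8, seed=5, epochs=2)
        assert np.array_equal(a.vectors, b.vectors)
        assert a.vocabulary == b.vocabulary

    def test_vocabulary_from_repeated_sentence(self):
        sents = [["psa", "stable", "today"]] * 5
        model = train_embeddings(sents, d=8, seed=0, epochs=1, min_count=2)
        assert set(model.vocabulary) == {"psa", "stable", "today"}

    def test_min_count_excludes_rare_tokens(self):
        sents = [["common", "word"], ["common", "rare"]]
        model = train_embeddings(sents, d=8, seed=0, epochs=1, min_count=2)
        assert "rare" not in model.vocabulary and "common" in model.vocabulary

    def test_empty_corpus_is_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            train_embeddings([], d=8)

    def test_save_load_round_trip(self, toy_embeddings, tmp_path):
        toy_embeddings.save(tmp_path / "emb")
        from tnmstage.embeddings import EmbeddingModel

        back = EmbeddingModel.load(tmp_path / "emb")
        assert back.vocabulary == toy_embeddings.vocabulary
        assert np.allclose(back.vectors, toy_embeddings.vectors)


class TestBuildPatientVector:
    def test_single_context_sentence_is_sentence_mean(self, toy_embeddings, note_factory, lexicon):
        (rec,) = assemble_patients(
            [note_factory(text="Prostatectomy specimen shows organ confined disease.",
                          note_type="pathology")]
        )
        pv = build_patient_vector(rec, "pT", toy_embeddings, lexicon)
        toks = [t for t in ["prostatectomy", "specimen", "shows", "organ", "confined", "disease"]
                if t in toy_embeddings]
        expected = np.mean([toy_embeddings.vector(t) for t in toks], axis=0)
        assert not pv.degenerate
        assert np.allclose(pv.vector, expected)

    def test_two_context_sentences_average(self, toy_embeddings, note_factory, lexicon):
        (rec,) = assemble_patients(
            [
                note_factory(note_id="a", note_type="pathology",
                             text="Organ confined disease. Extracapsular extension present."),
            ]
        )
        pv = build_patient_vector(rec, "pT", toy_embeddings, lexicon)
        assert pv.n_context_sentences == 2

    def test_no_keyword_match_is_degenerate(self, toy_embeddings, note_factory, lexicon):
        (rec,) = assemble_patients([note_factory(text="Vital signs stable today.")])
        pv = build_patient_vector(rec, "cT", toy_embeddings, lexicon)
        assert pv.degenerate and not pv.vector.any()

    def test_mean_norm_bounded_by_max_token_norm(self, toy_embeddings, note_factory, lexicon):
        (rec,) = assemble_patients(
            [note_factory(note_type="pathology",
                          text="Organ confined disease. Extracapsular extension noted.")]
        )
        pv = build_patient_vector(rec, "pT", toy_embeddings, lexicon)
        max_norm = np.linalg.norm(toy_embeddings.vectors, axis=1).max()
        assert np.linalg.norm(pv.vector) <= max_norm + 1e-12

    def test_invariant_to_duplicate_non_context_sentences(self, toy_embeddings, note_factory, lexicon):
        ctx = "Organ confined disease."
        (rec1,) = assemble_patients(
            [note_factory(note_type="pathology", text=ctx + " Vitals stable.")]
        )
        (rec2,) = assemble_patients(
            [note_factory(note_type="pathology",
                          text="Vitals stable. " + ctx + " Vitals stable. Vitals stable.")]
        )
        v1 = build_patient_vector(rec1, "pT", toy_embeddings, lexicon)
        v2 = build_patient_vector(rec2, "pT", toy_embeddings, lexicon)
        assert np.allclose(v1.vector, v2.vector)


def _separable_vectors(n=60, seed=0):
    rng = np.random.default_rng(seed)
    vecs, labels = [], {}
    for i in range(n):
        positive = i % 3 == 0
        center = np.ones(8) if positive else -np.ones(8)
        v = center + rng.normal(0, 0.05, 8)
        pid = f"P{i}"
        vecs.append(PatientVector(pid, "cN", v, 1, False))
        labels[pid] = "N1" if positive else "N0"
    return vecs, labels


class TestTaskClassifier:
    def test_separable_data_reaches_perfect_heldout_f1(self):
        vecs, labels = _separable_vectors()
        clf = train_task_classifier(vecs, labels, seed=1, n_search=10)
        assert clf.heldout_metrics["f1_macro"] == 1.0

    def test_single_class_labels_fatal(self):
        vecs, labels = _separable_vectors()
        labels = {pid: "N0" for pid in labels}
        with pytest.raises(ValueError, match="single class"):
            train_task_classifier(vecs, labels, seed=1, n_search=5)

    def test_deterministic_given_seed(self):
        vecs, labels = _separable_vectors()
        a = train_task_classifier(vecs, labels, seed=7, n_search=10)
        b = train_task_classifier(vecs, labels, seed=7, n_search=10)
        assert a.hyperparameters == b.hyperparameters
        assert a.cv_scores == b.cv_scores
        preds_a = predict(a, vecs)
        preds_b = predict(b, vecs)
        assert preds_a == preds_b

    def test_degenerate_vectors_excluded_from_training(self):
        vecs, labels = _separable_vectors()
        vecs.append(PatientVector("ghost", "cN", np.zeros(8), 0, True))
        labels["ghost"] = "N1"
        clf = train_task_classifier(vecs, labels, seed=1, n_search=5)
        assert clf.heldout_metrics["n_train"] + clf.heldout_metrics["n_test"] == 60


class TestPredict:
    def test_degenerate_abstains(self):
        vecs, labels = _separable_vectors()
        clf = train_task_classifier(vecs, labels, seed=1, n_search=5)
        out = predict(clf, [PatientVector("x", "cN", np.zeros(8), 0, True)])
        assert out == {"x": None}

    def test_separable_training_points_recover_their_labels(self):
        vecs, labels = _separable_vectors()
        clf = train_task_classifier(vecs, labels, seed=1, n_search=10)
        out = predict(clf, vecs)
        agree = sum(out[pid] == labels[pid] for pid in labels)
        assert agree == len(labels)

    def test_empty_input_empty_output(self):
        vecs, labels = _separable_vectors()
        clf = train_task_classifier(vecs, labels, seed=1, n_search=5)
        assert predict(clf, []) == {}

    def test_dimension_mismatch_fatal(self):
        vecs, labels = _separable_vectors()
        clf = train_task_classifier(vecs, labels, seed=1, n_search=5)
        with pytest.raises(ValueError, match="dimension"):
            predict(clf, [PatientVector("x", "cN", np.zeros(5), 1, False)])
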