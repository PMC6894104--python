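"""Tagger training, checkpointing, fine-tuning and prediction."""

import copy

import numpy as np
import pytest

from phitag.corpus import Document, PhiSpan
from phitag.model.tagger import HyperParams, PhiTagger, merge_corpora
from phitag.synthetic import GeneratorConfig, generate_corpus

from conftest import tiny_tagger


def one_sentence_doc(i=0):
    text = "Patient Brian Anderson seen on 03/14/2015 in clinic.\n"
    return Document(f"s{i}", text, [
        PhiSpan(8, 22, "NAME", "Brian Anderson"),
        PhiSpan(31, 41, "DATE", "03/14/2015"),
    ])


class TestHyperParams:
    def test_reference_defaults(self):
        hp = HyperParams()
        assert (hp.word_dim, hp.char_dim, hp.char_lstm_out,
                hp.word_lstm_out) == (300, 25, 25, 100)
        assert (hp.semantic_feat_dim, hp.lexical_feat_dim) == (20, 15)
        assert (hp.lr, hp.momentum, hp.dropout) == (0.005, 0.9, 0.5)
        assert hp.grad_clip == 5.0
        assert (hp.epochs_scratch, hp.epochs_finetune) == (30, 15)


class TestInputWidth:
    def test_default_configuration_width(self):
        # word 300 + char BiLSTM 2x25 + knowledge 20 + POS 15 + shape 15
        est = PhiTagger()
        assert est.input_width() == 400

    def test_features_disabled_width(self):
        est = PhiTagger(use_lexical=False, use_knowledge=False)
        assert est.input_width() == 350

    def test_separate_knowledge_wiring_width(self):
        est = PhiTagger(knowledge_wiring="separate")
        assert est.input_width() == 420

    def test_encoded_matrix_matches_reported_width(self):
        est = tiny_tagger(epochs=0)
        est.fit([one_sentence_doc()])
        [sent] = est._prepare(one_sentence_doc(), False)
        assert est.encode_inputs(sent).shape == (len(sent.tokens),
                                                 est.input_width())


class TestTraining:
    def test_overfits_repeated_sentence(self):
        docs = [one_sentence_doc(i) for i in range(10)]
        est = tiny_tagger(epochs=12, dropout=0.2, seed=0)
        est.fit(docs)
        assert len(est.loss_history_) == 12
        # early loss strictly decreasing, and gold recovered exactly
        assert all(a > b for a, b in zip(est.loss_history_[:5],
                                         est.loss_history_[1:6]))
        assert est.predict([one_sentence_doc()])[0] \
            == one_sentence_doc().spans

    def test_same_seed_identical_checkpoints(self, small_corpus):
        docs = small_corpus[:6]
        a = tiny_tagger(epochs=2).fit(docs)
        b = tiny_tagger(epochs=2).fit(docs)
        assert a.params_.keys() == b.params_.keys()
        for k in a.params_:
            assert np.array_equal(a.params_[k], b.params_[k]), k

    def test_zero_epochs_keeps_initialization(self, small_corpus):
        docs = small_corpus[:4]
        est = tiny_tagger(epochs=0).fit(docs)
        fresh = tiny_tagger(epochs=0)
        fresh.fit(docs)
        for k in est.params_:
            assert np.array_equal(est.params_[k], fresh.params_[k])
        assert est.loss_history_ == []

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tiny_tagger().fit([])

    def test_frozen_embeddings_do_not_move(self, small_corpus):
        docs = small_corpus[:4]
        trained = tiny_tagger(epochs=2, train_embeddings=False).fit(docs)
        init = tiny_tagger(epochs=0).fit(docs)
        assert np.array_equal(trained.params_["word_emb"],
                              init.params_["word_emb"])
        assert not np.array_equal(trained.params_["wf.Wx"],
                                  init.params_["wf.Wx"])

    def test_features_disabled_still_trains(self):
        docs = [one_sentence_doc(i) for i in range(4)]
        est = tiny_tagger(epochs=2, use_lexical=False, use_knowledge=False)
        est.fit(docs)
        assert est.input_width() == 16 + 2 * 6
        assert len(est.loss_history_) == 2


class TestPrediction:
    def test_empty_document(self, small_corpus):
        est = tiny_tagger(epochs=0).fit(small_corpus[:2])
        assert est.predict([Document("e", "")]) == [[]]

    def test_prediction_deterministic(self, small_corpus):
        est = tiny_tagger(epochs=1).fit(small_corpus[:4])
        doc = small_corpus[5]
        assert est.predict([doc]) == est.predict([doc])

    def test_predicted_spans_disjoint_and_valid(self, small_corpus):
        est = tiny_tagger(epochs=2).fit(small_corpus[:6])
        for doc, spans in zip(small_corpus[6:10],
                              est.predict(small_corpus[6:10])):
            # constructing a Document revalidates offsets and disjointness
            Document(doc.doc_id, doc.text, spans)

    def test_unseen_words_map_to_unknown(self, small_corpus):
        est = tiny_tagger(epochs=0).fit(small_corpus[:2])
        assert est._word_index("Qqqqqxyzzy") == est.vocab_["UNKNOWN"]


class TestCheckpointRoundTrip:
    def test_save_load_identical_predictions(self, tmp_path, small_corpus):
        docs = small_corpus[:5]
        est = tiny_tagger(epochs=2).fit(docs)
        est.save(tmp_path / "ckpt")
        back = PhiTagger.load(tmp_path / "ckpt")
        for k in est.params_:
            assert np.array_equal(est.params_[k], back.params_[k]), k
        assert est.predict(small_corpus[5:8]) \
            == back.predict(small_corpus[5:8])

    def test_provenance_recorded(self, tmp_path, small_corpus):
        est = tiny_tagger(epochs=1).fit(small_corpus[:3])
        assert est.provenance_["epochs_run"] == 1
        assert len(est.provenance_["corpora"]) == 1


class TestFineTuning:
    def test_zero_epoch_fine_tune_is_identity(self, small_corpus):
        est = tiny_tagger(epochs=1).fit(small_corpus[:4])
        b_docs = generate_corpus(GeneratorConfig(n_notes=3, seed=21),
                                 "site_B")
        before = est.predict(b_docs)
        tuned = copy.deepcopy(est).fine_tune(b_docs, epochs=0)
        assert tuned.predict(b_docs) == before

    def test_provenance_chains_both_corpora(self, small_corpus):
        est = tiny_tagger(epochs=1).fit(small_corpus[:3])
        b_docs = generate_corpus(GeneratorConfig(n_notes=2, seed=22),
                                 "site_B")
        est.fine_tune(b_docs, epochs=1)
        assert len(est.provenance_["corpora"]) == 2
        assert est.provenance_["epochs_run"] == 2

    def test_new_words_added_with_fresh_rows(self, small_corpus):
        est = tiny_tagger(epochs=1).fit(small_corpus[:3])
        n_before = len(est.vocab_)
        b_docs = generate_corpus(GeneratorConfig(n_notes=3, seed=23),
                                 "site_B")
        est.fine_tune(b_docs, epochs=0)
        assert len(est.vocab_) > n_before
        assert est.params_["word_emb"].shape[0] == len(est.vocab_)

    def test_alien_labels_rejected(self, small_corpus):
        est = tiny_tagger(epochs=0).fit(small_corpus[:2])
        est.tag_list_ = [t for t in est.tag_list_ if "ZIP" not in t]
        est.tag_vocab_ = {t: i for i, t in enumerate(est.tag_list_)}
        zip_doc = Document("z", "Zip code 32601 on file.\n",
                           [PhiSpan(9, 14, "ZIP", "32601")])
        with pytest.raises(ValueError, match="symmetric difference"):
            est.fine_tune([zip_doc], epochs=0)

    def test_unfitted_model_cannot_fine_tune(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            tiny_tagger().fine_tune([one_sentence_doc()])


class TestMergeCorpora:
    def test_sizes_add_up(self):
        a = [Document(f"a{i}", "x\n") for i in range(997)]
        b = [Document(f"b{i}", "y\n") for i in range(233)]
        assert len(merge_corpora(a, b)) == 1230

    def test_merge_with_empty_is_identity(self, small_corpus):
        assert merge_corpora(small_corpus, []) == list(small_corpus)

    def test_id_collision_suffixed(self):
        a = [Document("n1", "x\n")]
        b = [Document("n1", "y\n")]
        merged = merge_corpora(a, b)
        assert len(merged) == 2
        assert len({d.doc_id for d in merged}) == 2
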