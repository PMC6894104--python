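"""The BiLSTM-CRF PHI tagger and its training regimes.

Architecture, bottom to top: a character BiLSTM encodes each token's
spelling; its final states are concatenated with a word embedding and
with small dense embeddings of categorical feature streams (part of
speech, word shape, gazetteer-lookup results); a word-level BiLSTM reads
the concatenation (with dropout on its input during training) and a
linear layer produces per-tag emission scores, decoded by a linear-chain
CRF.  Optimization is pure SGD (one sentence per step) with momentum and
elementwise gradient clipping, for a fixed number of epochs with no early
stopping.

Two customization regimes for a new institution are supported: merging
its notes with the original training corpus and retraining from scratch
(:func:`merge_corpora` + ``fit``), or continuing training of an existing
model's weights on the new notes alone (``fine_tune``).

:class:`PhiTagger` follows the scikit-learn estimator protocol
(``get_params``/``set_params``, ``fit``/``predict``, fitted attributes
with a trailing underscore).
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ..corpus import Document, LabeledSequence, PhiSpan, Token
from ..embeddings import UNKNOWN, EmbeddingMatrix, lookup
from ..features import (Dictionary, fuzzy_lookup, pos_tag, word_shape)
from ..preprocess import (bio_to_spans, correct_typos, default_lexicon,
                          spans_to_bio, split_sentences, tokenize)
from . import nn
from .crf import TransitionMatrix, crf_gradients, viterbi_decode

PAD, UNK = "<pad>", "<unk>"


@dataclass
class HyperParams:
    """Trainer hyperparameters; defaults are the reference configuration."""

    word_dim: int = 300
    char_dim: int = 25
    char_lstm_out: int = 25     # per direction
    word_lstm_out: int = 100    # per direction
    semantic_feat_dim: int = 20
    lexical_feat_dim: int = 15
    lr: float = 0.005
    momentum: float = 0.9
    dropout: float = 0.5        # on the word-LSTM input, training only
    grad_clip: float = 5.0      # values clipped to [-grad_clip, grad_clip]
    epochs_scratch: int = 30
    epochs_finetune: int = 15
    seed: int = 42


@dataclass
class _Sentence:
    """One preprocessed sentence ready for encoding."""

    tokens: list[Token]            # original-text offsets
    surfaces: list[str]            # corrected-text surfaces (model input)
    feats: dict[str, list[str]]
    tags: list[str] | None = None


def merge_corpora(a: Sequence[Document],
                  b: Sequence[Document]) -> list[Document]:
    """Concatenate two corpora; colliding doc_ids in *b* get a suffix."""
    seen = {d.doc_id for d in a}
    out = list(a)
    for d in b:
        doc_id = d.doc_id
        while doc_id in seen:
            doc_id += "+"
        seen.add(doc_id)
        out.append(Document(doc_id, d.text, d.spans, d.note_type)
                   if doc_id != d.doc_id else d)
    return out


class PhiTagger(BaseEstimator):
    """BiLSTM-CRF sequence tagger for PHI spans in clinical notes.

    Parameters mirror :class:`HyperParams` plus feature wiring:

    use_lexical / use_knowledge
        enable the POS+shape and gazetteer feature streams.
    knowledge_wiring
        ``"composite"`` embeds the (category, boundary, condition) triple
        as one categorical stream; ``"separate"`` embeds the category and
        the boundary:condition pair as two streams.
    pretrained
        optional :class:`~phitag.embeddings.EmbeddingMatrix`; its rows
        initialize the (trainable) word-embedding table and fix its
        dimension.
    train_embeddings
        when False the word-embedding table is frozen (useful with large
        pretrained matrices); all other parameters always train.
    dictionaries
        gazetteers for the knowledge features; ``None`` loads the bundled
        set when ``use_knowledge`` is on.
    """

    def __init__(self, word_dim: int = 300, char_dim: int = 25,
                 char_lstm_out: int = 25, word_lstm_out: int = 100,
                 semantic_feat_dim: int = 20, lexical_feat_dim: int = 15,
                 lr: float = 0.005, momentum: float = 0.9,
                 dropout: float = 0.5, grad_clip: float = 5.0,
                 epochs: int = 30, epochs_finetune: int = 15,
                 seed: int = 42, use_lexical: bool = True,
                 use_knowledge: bool = True,
                 knowledge_wiring: str = "composite",
                 pretrained: EmbeddingMatrix | None = None,
                 train_embeddings: bool = True,
                 dictionaries: list[Dictionary] | None = None,
                 lexicon: set[str] | None = None):
        self.word_dim = word_dim
        self.char_dim = char_dim
        self.char_lstm_out = char_lstm_out
        self.word_lstm_out = word_lstm_out
        self.semantic_feat_dim = semantic_feat_dim
        self.lexical_feat_dim = lexical_feat_dim
        self.lr = lr
        self.momentum = momentum
        self.dropout = dropout
        self.grad_clip = grad_clip
        self.epochs = epochs
        self.epochs_finetune = epochs_finetune
        self.seed = seed
        self.use_lexical = use_lexical
        self.use_knowledge = use_knowledge
        self.knowledge_wiring = knowledge_wiring
        self.pretrained = pretrained
        self.train_embeddings = train_embeddings
        self.dictionaries = dictionaries
        self.lexicon = lexicon

    # --- preprocessing -------------------------------------------------------

    def _streams(self) -> list[tuple[str, int]]:
        streams: list[tuple[str, int]] = []
        if self.use_knowledge:
            if self.knowledge_wiring == "composite":
                streams.append(("kb", self.semantic_feat_dim))
            elif self.knowledge_wiring == "separate":
                streams.append(("kb_cat", self.semantic_feat_dim))
                streams.append(("kb_mc", self.semantic_feat_dim))
            else:
                raise ValueError(
                    f"unknown knowledge_wiring {self.knowledge_wiring!r}")
        if self.use_lexical:
            streams.append(("pos", self.lexical_feat_dim))
            streams.append(("shape", self.lexical_feat_dim))
        return streams

    def _active_dicts(self) -> list[Dictionary]:
        if not self.use_knowledge:
            return []
        if self.dictionaries is None:
            from ..features import load_dictionaries
            self.dictionaries = load_dictionaries()
        return self.dictionaries

    def _prepare(self, doc: Document, with_tags: bool) -> list[_Sentence]:
        corrected, omap = correct_typos(
            doc.text, self.lexicon if self.lexicon is not None
            else default_lexicon())
        dicts = self._active_dicts()
        sentences: list[_Sentence] = []
        for s_start, s_end in split_sentences(corrected):
            ctoks = tokenize(corrected[s_start:s_end], s_start)
            if not ctoks:
                continue
            tokens = [Token(t.surface, *omap.project_span(t.start, t.end))
                      for t in ctoks]
            surfaces = [t.surface for t in ctoks]
            feats: dict[str, list[str]] = {}
            if self.use_knowledge:
                kb = fuzzy_lookup(surfaces, dicts)
                if self.knowledge_wiring == "composite":
                    feats["kb"] = [k.composite() for k in kb]
                else:
                    feats["kb_cat"] = [k.category for k in kb]
                    feats["kb_mc"] = [f"{k.boundary}:{k.condition}"
                                      for k in kb]
            if self.use_lexical:
                feats["pos"] = pos_tag(surfaces)
                feats["shape"] = [word_shape(s) for s in surfaces]
            tags = None
            if with_tags:
                lo, hi = tokens[0].start, tokens[-1].end
                local = [s for s in doc.spans
                         if s.start < hi and s.end > lo]
                tags = spans_to_bio(tokens, local).tags
            sentences.append(_Sentence(tokens, surfaces, feats, tags))
        return sentences

    # --- vocabulary / parameters ---------------------------------------------

    def _build_vocabs(self, sentences: list[_Sentence]) -> None:
        words = sorted({s for sent in sentences for s in sent.surfaces})
        self.vocab_ = {w: i for i, w in enumerate([UNKNOWN] + words)}
        chars = sorted(set(string.printable)
                       | {c for sent in sentences
                          for s in sent.surfaces for c in s})
        self.char_vocab_ = {c: i for i, c in
                            enumerate([PAD, UNK] + chars)}
        self.feat_vocabs_: dict[str, dict[str, int]] = {}
        for name, _ in self._streams():
            values = sorted({v for sent in sentences
                             for v in sent.feats[name]})
            self.feat_vocabs_[name] = {v: i for i, v in
                                       enumerate([UNK] + values)}
        # full BIO tag inventory over the ten categories, independent of
        # which happen to occur in a given training sample, so a model can
        # always be fine-tuned on a corpus with a different category mix
        from ..corpus import PHI_CATEGORIES
        tags = sorted([f"{p}-{c}" for p in "BI" for c in PHI_CATEGORIES]
                      + ["O"])
        seen = {t for sent in sentences for t in (sent.tags or [])}
        if not seen <= set(tags):
            raise ValueError(f"unknown tags in corpus: {sorted(seen - set(tags))}")
        self.tag_vocab_ = {t: i for i, t in enumerate(tags)}
        self.tag_list_ = tags

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        hp = self
        p: nn.Params = {}
        d_w = (self.pretrained.dim if self.pretrained is not None
               else hp.word_dim)
        self.word_dim_ = d_w
        p["word_emb"] = nn.uniform_init(rng, (len(self.vocab_), d_w), d_w)
        if self.pretrained is not None:
            for w, i in self.vocab_.items():
                p["word_emb"][i] = lookup(w, self.pretrained)
        p["char_emb"] = nn.uniform_init(
            rng, (len(self.char_vocab_), hp.char_dim), hp.char_dim)
        p["char_emb"][0] = 0.0  # PAD
        for name, dim in self._streams():
            p[f"feat.{name}"] = nn.uniform_init(
                rng, (len(self.feat_vocabs_[name]), dim), dim)
        p.update(nn.lstm_init(rng, hp.char_dim, hp.char_lstm_out, "cf"))
        p.update(nn.lstm_init(rng, hp.char_dim, hp.char_lstm_out, "cb"))
        width = self.input_width()
        p.update(nn.lstm_init(rng, width, hp.word_lstm_out, "wf"))
        p.update(nn.lstm_init(rng, width, hp.word_lstm_out, "wb"))
        K = len(self.tag_list_)
        p["proj.W"] = nn.uniform_init(rng, (2 * hp.word_lstm_out, K),
                                      2 * hp.word_lstm_out)
        p["proj.b"] = np.zeros(K)
        p["crf"] = np.zeros((K + 2, K + 2))
        self.params_ = p

    def input_width(self) -> int:
        """Per-token input width of the word-level BiLSTM."""
        d_w = getattr(self, "word_dim_", self.word_dim)
        return (d_w + 2 * self.char_lstm_out
                + sum(dim for _, dim in self._streams()))

    # --- encoding -------------------------------------------------------------

    def _indices(self, sent: _Sentence):
        widx = np.array([self._word_index(s) for s in sent.surfaces])
        cidx = [[self.char_vocab_.get(c, 1) for c in s]
                for s in sent.surfaces]
        fidx = {name: np.array([self.feat_vocabs_[name].get(v, 0)
                                for v in sent.feats[name]])
                for name, _ in self._streams()}
        return widx, cidx, fidx

    def _word_index(self, surface: str) -> int:
        idx = self.vocab_.get(surface)
        if idx is None:
            idx = self.vocab_.get(surface.lower())
        return idx if idx is not None else self.vocab_[UNKNOWN]

    def _char_batches(self, cidx: list[list[int]]):
        T = len(cidx)
        L = max(len(c) for c in cidx)
        fwd = np.zeros((L, T), dtype=np.int64)
        bwd = np.zeros((L, T), dtype=np.int64)
        mask = np.zeros((L, T))
        for j, chars in enumerate(cidx):
            n = len(chars)
            fwd[:n, j] = chars
            bwd[:n, j] = chars[::-1]
            mask[:n, j] = 1.0
        return fwd, bwd, mask

    def encode_inputs(self, sent: _Sentence) -> np.ndarray:
        """Per-token input matrix (T, width) fed to the word BiLSTM."""
        X, _ = self._encode_forward(self._indices(sent))
        return X

    def _encode_forward(self, idx):
        widx, cidx, fidx = idx
        p = self.params_
        Xw = p["word_emb"][widx]
        fwd, bwd, mask = self._char_batches(cidx)
        Cf = p["char_emb"][fwd]
        Cb = p["char_emb"][bwd]
        Hf, cache_f = nn.lstm_forward(Cf, p, "cf", mask)
        Hb, cache_b = nn.lstm_forward(Cb, p, "cb", mask)
        parts = [Xw, Hf[-1], Hb[-1]]
        for name, _ in self._streams():
            parts.append(p[f"feat.{name}"][fidx[name]])
        X = np.concatenate(parts, axis=1)
        cache = {"widx": widx, "fidx": fidx, "fwd": fwd, "bwd": bwd,
                 "cache_f": cache_f, "cache_b": cache_b,
                 "n_char_steps": Cf.shape[0]}
        return X, cache

    def _forward(self, idx, train: bool, drop_rng: np.random.Generator):
        p = self.params_
        X, enc_cache = self._encode_forward(idx)
        if train and self.dropout > 0:
            dmask = nn.dropout_mask(drop_rng, X.shape, self.dropout)
            Xd = X * dmask
        else:
            dmask = None
            Xd = X
        Xseq = Xd[:, None, :]
        Hf, cache_wf = nn.lstm_forward(Xseq, p, "wf")
        Hb_r, cache_wb = nn.lstm_forward(Xseq[::-1], p, "wb")
        H = np.concatenate([Hf[:, 0, :], Hb_r[::-1][:, 0, :]], axis=1)
        emissions = H @ p["proj.W"] + p["proj.b"]
        cache = {"enc": enc_cache, "dmask": dmask, "H": H,
                 "cache_wf": cache_wf, "cache_wb": cache_wb, "X": X}
        return emissions, cache

    def _backward(self, d_emis: np.ndarray, cache) -> nn.Params:
        p = self.params_
        grads: nn.Params = {}
        H = cache["H"]
        grads["proj.W"] = H.T @ d_emis
        grads["proj.b"] = d_emis.sum(axis=0)
        dH = d_emis @ p["proj.W"].T
        h = self.word_lstm_out
        dHf = dH[:, :h][:, None, :]
        dHb = dH[:, h:][::-1][:, None, :]
        dX = nn.lstm_backward(dHf, cache["cache_wf"], grads)[:, 0, :]
        dX += nn.lstm_backward(dHb, cache["cache_wb"], grads)[::-1][:, 0, :]
        if cache["dmask"] is not None:
            dX = dX * cache["dmask"]
        enc = cache["enc"]
        d_w = self.word_dim_
        hc = self.char_lstm_out
        dXw = dX[:, :d_w]
        dhf = dX[:, d_w:d_w + hc]
        dhb = dX[:, d_w + hc:d_w + 2 * hc]
        off = d_w + 2 * hc
        grads["word_emb"] = np.zeros_like(p["word_emb"])
        np.add.at(grads["word_emb"], enc["widx"], dXw)
        L = enc["n_char_steps"]
        dHs_f = np.zeros((L,) + dhf.shape)
        dHs_f[-1] = dhf
        dHs_b = np.zeros((L,) + dhb.shape)
        dHs_b[-1] = dhb
        dCf = nn.lstm_backward(dHs_f, enc["cache_f"], grads)
        dCb = nn.lstm_backward(dHs_b, enc["cache_b"], grads)
        grads["char_emb"] = np.zeros_like(p["char_emb"])
        np.add.at(grads["char_emb"], enc["fwd"], dCf)
        np.add.at(grads["char_emb"], enc["bwd"], dCb)
        grads["char_emb"][0] = 0.0  # PAD stays zero
        for name, dim in self._streams():
            g = np.zeros_like(p[f"feat.{name}"])
            np.add.at(g, enc["fidx"][name], dX[:, off:off + dim])
            grads[f"feat.{name}"] = g
            off += dim
        return grads

    # --- training -------------------------------------------------------------

    def fit(self, docs: Sequence[Document], y=None) -> "PhiTagger":
        """Train from random initialization for ``epochs`` epochs."""
        docs = list(docs)
        if not docs:
            raise ValueError("cannot fit on an empty corpus")
        sentences = [s for d in docs for s in self._prepare(d, True)]
        self._build_vocabs(sentences)
        self._init_params()
        self.loss_history_ = []
        self.provenance_ = {
            "corpora": [sorted(d.doc_id for d in docs)],
            "epochs_run": 0, "seed": self.seed,
        }
        self._run_epochs(sentences, self.epochs, seed_offset=1)
        return self

    def fine_tune(self, docs: Sequence[Document],
                  epochs: int | None = None) -> "PhiTagger":
        """Continue training the fitted model on a new corpus.

        New words, characters and feature values are added to the
        vocabularies with freshly initialized rows; the new corpus must
        not introduce tags unknown to the base model.
        """
        self._require_fitted()
        docs = list(docs)
        if not docs:
            raise ValueError("cannot fine-tune on an empty corpus")
        sentences = [s for d in docs for s in self._prepare(d, True)]
        new_tags = {t for s in sentences for t in s.tags or []}
        if not new_tags <= set(self.tag_list_):
            diff = new_tags ^ set(self.tag_list_)
            raise ValueError(f"label-set mismatch; symmetric difference: "
                             f"{sorted(diff)}")
        self._extend_vocabs(sentences)
        self.provenance_["corpora"].append(sorted(d.doc_id for d in docs))
        self._run_epochs(sentences,
                         self.epochs_finetune if epochs is None else epochs,
                         seed_offset=2)
        return self

    def _extend_vocabs(self, sentences: list[_Sentence]) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 9]))
        p = self.params_

        def grow(table: dict[str, int], new: list[str], key: str,
                 dim: int) -> None:
            fresh = [v for v in sorted(set(new)) if v not in table]
            if not fresh:
                return
            rows = nn.uniform_init(rng, (len(fresh), dim), dim)
            p[key] = np.vstack([p[key], rows])
            for v in fresh:
                table[v] = len(table)

        grow(self.vocab_, [s for x in sentences for s in x.surfaces],
             "word_emb", self.word_dim_)
        grow(self.char_vocab_,
             [c for x in sentences for s in x.surfaces for c in s],
             "char_emb", self.char_dim)
        for name, dim in self._streams():
            grow(self.feat_vocabs_[name],
                 [v for x in sentences for v in x.feats[name]],
                 f"feat.{name}", dim)

    def _run_epochs(self, sentences: list[_Sentence], epochs: int,
                    seed_offset: int) -> None:
        ss = np.random.SeedSequence([self.seed, seed_offset])
        shuffle_rng, drop_rng = (np.random.default_rng(c)
                                 for c in ss.spawn(2))
        opt = nn.SGDMomentum(self.params_, self.lr, self.momentum,
                             self.grad_clip)
        encoded = [(s, self._indices(s)) for s in sentences
                   if len(s.tokens) > 0]
        tm = TransitionMatrix(self.params_["crf"])
        for _ in range(epochs):
            order = shuffle_rng.permutation(len(encoded))
            total = 0.0
            for i in order:
                sent, idx = encoded[i]
                tags = np.array([self.tag_vocab_[t] for t in sent.tags])
                emissions, cache = self._forward(idx, True, drop_rng)
                ll, d_emis, d_mat = crf_gradients(emissions, tm, tags)
                if not np.isfinite(ll):
                    raise RuntimeError(
                        f"non-finite training loss ({-ll}); "
                        "lower the learning rate")
                grads = self._backward(-d_emis, cache)
                grads["crf"] = -d_mat
                if not self.train_embeddings:
                    grads.pop("word_emb", None)
                opt.step(grads)
                total += -ll
            self.loss_history_.append(total / max(len(encoded), 1))
            self.provenance_["epochs_run"] += 1

    # --- prediction -----------------------------------------------------------

    def predict(self, docs: Sequence[Document]) -> list[list[PhiSpan]]:
        """Predicted PHI spans (original-text offsets) per document."""
        self._require_fitted()
        tm = TransitionMatrix(self.params_["crf"])
        out: list[list[PhiSpan]] = []
        for doc in docs:
            spans: list[PhiSpan] = []
            for sent in self._prepare(doc, False):
                if not sent.tokens:
                    continue
                emissions, _ = self._forward(self._indices(sent), False, None)
                path, _ = viterbi_decode(emissions, tm)
                tags = [self.tag_list_[i] for i in path]
                seq = LabeledSequence(sent.tokens, tags)
                spans.extend(bio_to_spans(seq, doc.text))
            out.append(sorted(spans))
        return out

    def predict_document(self, doc: Document) -> Document:
        """Copy of *doc* whose spans are the model's predictions."""
        return Document(doc.doc_id, doc.text, self.predict([doc])[0],
                        doc.note_type)

    def score(self, docs: Sequence[Document], y=None) -> float:
        """Strict micro F1 against the documents' own annotations."""
        from ..evaluate import evaluate_corpus
        result = evaluate_corpus(list(docs), self.predict(docs))
        return result.strict.micro_prf()[2]

    def _require_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    # --- checkpointing --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar with vocabularies,
        hyperparameters and training provenance."""
        self._require_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.params_)
        hp = {k: v for k, v in self.get_params().items()
              if k not in ("pretrained", "dictionaries", "lexicon")}
        sidecar = {
            "hyperparams": hp,
            "word_dim_": self.word_dim_,
            "vocab": self.vocab_,
            "char_vocab": self.char_vocab_,
            "feat_vocabs": self.feat_vocabs_,
            "tags": self.tag_list_,
            "loss_history": self.loss_history_,
            "provenance": self.provenance_,
            "dictionaries": [
                {"name": d.name, "category": d.target_category,
                 "entries": sorted(d.entries), "priority": d.priority,
                 "exact_only": d.exact_only}
                for d in (self.dictionaries or [])
            ] if self.use_knowledge else [],
            "lexicon": sorted(self.lexicon) if self.lexicon is not None
            else None,
        }
        (directory / "model.json").write_text(
            json.dumps(sidecar, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, directory: str | Path) -> "PhiTagger":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text(
            encoding="utf-8"))
        est = cls(**sidecar["hyperparams"])
        if sidecar["dictionaries"]:
            est.dictionaries = [
                Dictionary(d["name"], d["category"], set(d["entries"]),
                           d["priority"], d["exact_only"])
                for d in sidecar["dictionaries"]
            ]
        if sidecar["lexicon"] is not None:
            est.lexicon = set(sidecar["lexicon"])
        est.word_dim_ = sidecar["word_dim_"]
        est.vocab_ = dict(sidecar["vocab"])
        est.char_vocab_ = dict(sidecar["char_vocab"])
        est.feat_vocabs_ = {k: dict(v)
                            for k, v in sidecar["feat_vocabs"].items()}
        est.tag_list_ = list(sidecar["tags"])
        est.tag_vocab_ = {t: i for i, t in enumerate(est.tag_list_)}
        est.loss_history_ = list(sidecar["loss_history"])
        est.provenance_ = sidecar["provenance"]
        with np.load(directory / "weights.npz") as npz:
            est.params_ = {k: npz[k].copy() for k in npz.files}
        return est


# --- thin functional wrappers -------------------------------------------------

def train(corpus: Sequence[Document], hp: HyperParams | None = None,
          **kwargs) -> PhiTagger:
    """Train a tagger from scratch; *hp* supplies hyperparameters."""
    hp = hp or HyperParams()
    est = PhiTagger(word_dim=hp.word_dim, char_dim=hp.char_dim,
                    char_lstm_out=hp.char_lstm_out,
                    word_lstm_out=hp.word_lstm_out,
                    semantic_feat_dim=hp.semantic_feat_dim,
                    lexical_feat_dim=hp.lexical_feat_dim,
                    lr=hp.lr, momentum=hp.momentum, dropout=hp.dropout,
                    grad_clip=hp.grad_clip, epochs=hp.epochs_scratch,
                    epochs_finetune=hp.epochs_finetune, seed=hp.seed,
                    **kwargs)
    return est.fit(corpus)


def fine_tune(base: PhiTagger, corpus: Sequence[Document]) -> PhiTagger:
    return base.fine_tune(corpus)


def predict(model: PhiTagger, doc: Document) -> list[PhiSpan]:
    return model.predict([doc])[0]
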