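"""Reproducible miniature studies on the surrogate corpora.

Two experiment designs, both fully seeded:

* :func:`in_style_experiment` -- train on site_A notes, evaluate on
  held-out site_A notes: the single-institution setting.
* :func:`cross_style_experiment` -- train on site_A, then measure on a
  site_B test set (a) the zero-shot model, (b) the model fine-tuned on
  site_B training notes, (c) a model retrained from scratch on the merged
  site_A + site_B training corpus, and (d) a model trained on the site_B
  notes alone.  This is the cross-institute customization comparison in
  miniature.

Model dimensions and corpus sizes here are deliberately small (see
``REDUCED_DIMS``); the point of the design is the ordering of the
scores, which is insensitive to scale, not their absolute values.
"""

from __future__ import annotations

import copy
import statistics
from typing import Callable

from .corpus import Document
from .evaluate import evaluate_corpus
from .model.tagger import PhiTagger, merge_corpora
from .synthetic import GeneratorConfig, generate_corpus

#: Reduced model configuration used by the miniature studies.
REDUCED_DIMS = dict(word_dim=24, char_dim=8, char_lstm_out=8,
                    word_lstm_out=16, semantic_feat_dim=8,
                    lexical_feat_dim=6)

#: Scratch-training epochs for the miniature studies (fine-tuning keeps
#: its standard 15).
REDUCED_EPOCHS = 10


def _corpus(style: str, n: int, seed: int,
            typo_rate: float = 0.02) -> list[Document]:
    cfg = GeneratorConfig(n_notes=n, seed=seed % 2**31, typo_rate=typo_rate)
    return generate_corpus(cfg, style)


def _tagger(seed: int, epochs: int = REDUCED_EPOCHS) -> PhiTagger:
    return PhiTagger(epochs=epochs, seed=seed % 2**31, **REDUCED_DIMS)


def _strict_f1(model: PhiTagger, test: list[Document]) -> float:
    result = evaluate_corpus(test, dict(zip((d.doc_id for d in test),
                                            model.predict(test))))
    return result.strict.micro_prf()[2]


def in_style_experiment(seed: int, n_train: int = 200,
                        n_test: int = 50) -> dict[str, float]:
    """Train and test within site_A; returns strict and relax micro F1."""
    train = _corpus("site_A", n_train, 1000 * seed + 1)
    test = _corpus("site_A", n_test, 1000 * seed + 2)
    model = _tagger(seed).fit(train)
    result = evaluate_corpus(test, dict(zip((d.doc_id for d in test),
                                            model.predict(test))))
    return {"strict_f1": result.strict.micro_prf()[2],
            "relax_f1": result.relax.micro_prf()[2]}


def cross_style_experiment(seed: int, n_a: int = 120, n_b: int = 60,
                           n_test: int = 40) -> dict[str, float]:
    """Cross-institute comparison; returns strict micro F1 per regime."""
    a_train = _corpus("site_A", n_a, 1000 * seed + 11)
    b_train = _corpus("site_B", n_b, 1000 * seed + 12)
    b_test = _corpus("site_B", n_test, 1000 * seed + 13)
    a_test = _corpus("site_A", n_test, 1000 * seed + 14)

    base = _tagger(seed).fit(a_train)
    out = {
        "in_style": _strict_f1(base, a_test),
        "zero_shot": _strict_f1(base, b_test),
    }
    tuned = copy.deepcopy(base).fine_tune(b_train)
    out["fine_tuned"] = _strict_f1(tuned, b_test)
    merged = _tagger(seed).fit(merge_corpora(a_train, b_train))
    out["merged"] = _strict_f1(merged, b_test)
    b_only = _tagger(seed).fit(b_train)
    out["b_only"] = _strict_f1(b_only, b_test)
    return out


def median_over_seeds(fn: Callable[[int], dict[str, float]],
                      seeds: list[int]) -> dict[str, float]:
    """Run *fn* once per seed and take the per-key median."""
    runs = [fn(s) for s in seeds]
    return {k: statistics.median(r[k] for r in runs) for k in runs[0]}
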