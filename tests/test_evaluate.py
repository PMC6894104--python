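"""Strict/relax matching, P/R/F1 arithmetic and the error taxonomy."""

import itertools

import numpy as np
import pytest

from phitag.corpus import IntegrityError, PhiSpan
from phitag.evaluate import (classify_errors, compute_prf, evaluate_corpus,
                             f1_score, match_spans)


def span(start, end, cat="NAME"):
    return PhiSpan(start, end, cat, "x" * (end - start))


class TestMatchSpans:
    def test_identical_span_strict_tp(self):
        c = match_spans([span(0, 10)], [span(0, 10)], "strict")
        assert (c.tp["NAME"], c.fp["NAME"], c.fn["NAME"]) == (1, 0, 0)

    def test_boundary_difference_strict_vs_relax(self):
        gold, pred = [span(0, 10)], [span(0, 8)]
        strict = match_spans(gold, pred, "strict")
        assert (strict.fn["NAME"], strict.fp["NAME"]) == (1, 1)
        relax = match_spans(gold, pred, "relax")
        assert relax.tp["NAME"] == 1 and relax.micro() == (1, 0, 0)

    def test_relax_requires_same_category(self):
        c = match_spans([span(0, 10, "ID")], [span(0, 10, "PHONE")], "relax")
        assert c.tp == {} and c.fn["ID"] == 1 and c.fp["PHONE"] == 1

    def test_overlapping_input_rejected(self):
        with pytest.raises(IntegrityError):
            match_spans([span(0, 5), span(3, 8)], [], "strict")

    def test_counts_equal_optimal_assignment_on_random_sets(self):
        # relax matching must equal the best possible 1-to-1 assignment
        rng = np.random.default_rng(40)
        for _ in range(60):
            gold = _random_spans(rng)
            pred = _random_spans(rng)
            counts = match_spans(gold, pred, "relax")
            assert sum(counts.tp.values()) == _best_assignment(gold, pred)


def _random_spans(rng, n_max=5):
    spans, pos = [], 0
    for _ in range(rng.integers(0, n_max + 1)):
        pos += int(rng.integers(0, 4))
        length = int(rng.integers(1, 5))
        cat = ("NAME", "DATE")[rng.integers(0, 2)]
        spans.append(span(pos, pos + length, cat))
        pos += length
    return spans


def _best_assignment(gold, pred):
    """Maximum 1-to-1 same-category overlap matching, by brute force."""
    best = 0
    idx = range(len(pred))
    for k in range(min(len(gold), len(pred)), 0, -1):
        for g_sub in itertools.combinations(range(len(gold)), k):
            for p_sub in itertools.permutations(idx, k):
                ok = all(
                    gold[g].category == pred[p].category
                    and min(gold[g].end, pred[p].end)
                    > max(gold[g].start, pred[p].start)
                    for g, p in zip(g_sub, p_sub))
                if ok:
                    return k
    return best


class TestComputePrf:
    def test_zero_counts_convention(self):
        assert compute_prf(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_f1_from_reference_precision_recall(self):
        # customized-model operating point: P=0.9474, R=0.9109
        assert f1_score(0.9474, 0.9109) == pytest.approx(0.9288, abs=1e-4)
        # per-category DATE operating point: P=0.9807, R=0.977
        assert f1_score(0.9807, 0.977) == pytest.approx(0.9789, abs=1e-4)

    def test_micro_pools_before_dividing(self):
        p, r, f = compute_prf(8, 2, 2)
        assert p == r == 0.8
        assert f == pytest.approx(0.8)


class TestClassifyErrors:
    def test_boundary_mismatch(self):
        # prediction misses the "Jr." suffix of a name
        gold = [PhiSpan(0, 11, "NAME", "Xxx Yyy Jr.")]
        pred = [PhiSpan(0, 7, "NAME", "Xxx Yyy")]
        assert classify_errors(gold, pred)["boundary_mismatch"] == 1

    def test_wrong_category_id_vs_phone(self):
        gold = [span(0, 7, "ID")]
        pred = [span(0, 7, "PHONE")]
        out = classify_errors(gold, pred)
        assert out["wrong_category"] == 1
        assert sum(out.values()) == 1

    def test_false_positive_like_lab_value(self):
        # "1/2" in a lab result predicted as DATE with no gold overlap
        gold = []
        pred = [PhiSpan(5, 8, "DATE", "1/2")]
        assert classify_errors(gold, pred)["false_positive"] == 1

    def test_false_negative(self):
        out = classify_errors([span(0, 4)], [])
        assert out["false_negative"] == 1

    def test_each_span_in_exactly_one_class(self):
        rng = np.random.default_rng(41)
        for _ in range(40):
            gold, pred = _random_spans(rng), _random_spans(rng)
            out = classify_errors(gold, pred)
            n_correct = sum(
                1 for g in gold for p in pred
                if (g.start, g.end, g.category)
                == (p.start, p.end, p.category))
            assert (out["wrong_category"] + out["boundary_mismatch"]
                    + out["false_negative"] + n_correct) == len(gold)


class TestEvaluateCorpus:
    def _docs(self, small_corpus):
        return small_corpus[:8]

    def test_perfect_predictions(self, small_corpus):
        docs = self._docs(small_corpus)
        result = evaluate_corpus(docs, {d.doc_id: list(d.spans)
                                        for d in docs})
        assert result.strict.micro_prf() == (1.0, 1.0, 1.0)
        assert result.relax.micro_prf() == (1.0, 1.0, 1.0)
        assert all(v == 0 for v in result.errors.values())

    def test_empty_predictions(self, small_corpus):
        docs = self._docs(small_corpus)
        result = evaluate_corpus(docs, {d.doc_id: [] for d in docs})
        p, r, f = result.strict.micro_prf()
        assert (p, r, f) == (0.0, 0.0, 0.0)
        n_gold = sum(len(d.spans) for d in docs)
        assert sum(result.strict.fn.values()) == n_gold
        assert result.errors["false_negative"] == n_gold

    def test_doc_id_mismatch_rejected(self, small_corpus):
        docs = self._docs(small_corpus)
        with pytest.raises(IntegrityError, match="doc_id"):
            evaluate_corpus(docs, {"nope": []})

    def test_relax_f1_at_least_strict(self, small_corpus):
        rng = np.random.default_rng(42)
        docs = self._docs(small_corpus)
        preds = {}
        for d in docs:
            spans = []
            for s in d.spans:
                if rng.random() < 0.3:
                    continue
                end = s.end - 1 if rng.random() < 0.4 and s.end - s.start > 1 \
                    else s.end
                spans.append(PhiSpan(s.start, end, s.category,
                                     d.text[s.start:end]))
            preds[d.doc_id] = spans
        result = evaluate_corpus(docs, preds)
        assert result.relax.micro_prf()[2] >= result.strict.micro_prf()[2]

    def test_micro_f1_invariant_to_corpus_split(self, small_corpus):
        docs = self._docs(small_corpus)
        preds = {d.doc_id: list(d.spans[:-1]) for d in docs}
        whole = evaluate_corpus(docs, preds)
        part1 = evaluate_corpus(docs[:3], {d.doc_id: preds[d.doc_id]
                                           for d in docs[:3]})
        part2 = evaluate_corpus(docs[3:], {d.doc_id: preds[d.doc_id]
                                           for d in docs[3:]})
        pooled = part1.strict
        pooled.add(part2.strict)
        assert pooled.micro_prf() == whole.strict.micro_prf()

    def test_json_report_round_trips(self, tmp_path, small_corpus):
        import json
        docs = self._docs(small_corpus)
        result = evaluate_corpus(docs, {d.doc_id: list(d.spans)
                                        for d in docs})
        result.write_json(tmp_path / "r.json")
        data = json.loads((tmp_path / "r.json").read_text())
        assert data["strict"]["micro"]["f1"] == 1.0
        assert set(data["error_taxonomy"]) == {
            "boundary_mismatch", "wrong_category",
            "false_positive", "false_negative"}
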