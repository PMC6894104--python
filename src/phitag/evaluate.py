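"""Strict/relax span-matching evaluation and the four-way error taxonomy.

Scores follow the conventions of the i2b2 de-identification evaluations:

* strict -- a predicted span is a true positive only with identical
  (start, end, category);
* relax -- at least one character of overlap with a gold span of the same
  category suffices.

Matching is one-to-one: exact pairs bind first, then each gold span
(left to right) takes the overlapping prediction with the earliest end,
which for disjoint span lists equals an optimal exhaustive assignment.
Micro-averaged scores pool counts
over all categories before dividing.  Disagreements are also classified
into four error kinds: boundary mismatch (right category, wrong offsets),
wrong category (overlap, different category), false positive (prediction
overlapping no gold span) and false negative (gold span never predicted).
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import Document, IntegrityError, PhiSpan

ERROR_KINDS = ("boundary_mismatch", "wrong_category",
               "false_positive", "false_negative")


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0/0 -> 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, F1) from raw counts, with the 0/0 -> 0 convention."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, f1_score(p, r)


@dataclass
class MatchCounts:
    """Per-category tp/fp/fn counters; micro counts are their pooled sums."""

    tp: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    fp: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    fn: dict[str, int] = field(default_factory=lambda: defaultdict(int))

    def add(self, other: "MatchCounts") -> None:
        for mine, theirs in ((self.tp, other.tp), (self.fp, other.fp),
                             (self.fn, other.fn)):
            for cat, n in theirs.items():
                mine[cat] += n

    def micro(self) -> tuple[int, int, int]:
        return (sum(self.tp.values()), sum(self.fp.values()),
                sum(self.fn.values()))

    def micro_prf(self) -> tuple[float, float, float]:
        return compute_prf(*self.micro())

    def category_prf(self, cat: str) -> tuple[float, float, float]:
        return compute_prf(self.tp[cat], self.fp[cat], self.fn[cat])

    def categories(self) -> list[str]:
        return sorted(set(self.tp) | set(self.fp) | set(self.fn))


def _check_disjoint(spans: Sequence[PhiSpan], which: str) -> None:
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise IntegrityError(
                f"overlapping {which} spans [{a.start},{a.end}) and "
                f"[{b.start},{b.end})")


def _overlap(a: PhiSpan, b: PhiSpan) -> int:
    return max(0, min(a.end, b.end) - max(b.start, a.start))


def _pair_spans(gold: Sequence[PhiSpan], pred: Sequence[PhiSpan],
                same_category: bool) -> list[tuple[PhiSpan, PhiSpan]]:
    """Greedy 1-to-1 overlap pairing, left-to-right by gold start.

    Exactly coincident (same offsets and, when required, same category)
    pairs are bound first so a stray overlapping prediction cannot steal
    a gold span from its exact match; each remaining gold span then takes
    the available overlapping prediction with the smallest end offset.
    Because spans within each list are disjoint, the earliest-end choice
    achieves the maximum possible number of pairs (the classic interval
    exchange argument), so the counts equal those of an exhaustive
    optimal assignment.
    """
    taken: set[int] = set()
    pairs: list[tuple[PhiSpan, PhiSpan]] = []
    remaining: list[PhiSpan] = []
    for g in sorted(gold):
        exact = next(
            (j for j, p in enumerate(pred)
             if j not in taken and (p.start, p.end) == (g.start, g.end)
             and (not same_category or p.category == g.category)), None)
        if exact is not None:
            taken.add(exact)
            pairs.append((g, pred[exact]))
        else:
            remaining.append(g)
    for g in remaining:
        cands = [(j, p) for j, p in enumerate(pred)
                 if j not in taken and _overlap(g, p) > 0
                 and (not same_category or p.category == g.category)]
        if not cands:
            continue
        j, p = min(cands, key=lambda jp: (jp[1].end, jp[1].start))
        taken.add(j)
        pairs.append((g, p))
    return pairs


def match_spans(gold: Sequence[PhiSpan], pred: Sequence[PhiSpan],
                mode: str = "strict") -> MatchCounts:
    """Count tp/fp/fn between one document's gold and predicted spans."""
    if mode not in ("strict", "relax"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_disjoint(gold, "gold")
    _check_disjoint(pred, "predicted")
    counts = MatchCounts()
    if mode == "strict":
        matched_pred: set[int] = set()
        pred_index = {(p.start, p.end, p.category): j
                      for j, p in enumerate(pred)}
        for g in gold:
            j = pred_index.get((g.start, g.end, g.category))
            if j is not None and j not in matched_pred:
                matched_pred.add(j)
                counts.tp[g.category] += 1
            else:
                counts.fn[g.category] += 1
        for j, p in enumerate(pred):
            if j not in matched_pred:
                counts.fp[p.category] += 1
    else:
        pairs = _pair_spans(gold, pred, same_category=True)
        matched_gold = {id(g) for g, _ in pairs}
        matched_pred = {id(p) for _, p in pairs}
        for g, _ in pairs:
            counts.tp[g.category] += 1
        for g in gold:
            if id(g) not in matched_gold:
                counts.fn[g.category] += 1
        for p in pred:
            if id(p) not in matched_pred:
                counts.fp[p.category] += 1
    return counts


def classify_errors(gold: Sequence[PhiSpan],
                    pred: Sequence[PhiSpan]) -> dict[str, int]:
    """Assign every disagreement to exactly one of the four error kinds."""
    _check_disjoint(gold, "gold")
    _check_disjoint(pred, "predicted")
    out = dict.fromkeys(ERROR_KINDS, 0)
    pairs = _pair_spans(gold, pred, same_category=False)
    matched_gold = {id(g) for g, _ in pairs}
    matched_pred = {id(p) for _, p in pairs}
    for g, p in pairs:
        if g.category != p.category:
            out["wrong_category"] += 1
        elif (g.start, g.end) != (p.start, p.end):
            out["boundary_mismatch"] += 1
    for p in pred:
        if id(p) not in matched_pred:
            out["false_positive"] += 1
    for g in gold:
        if id(g) not in matched_gold:
            out["false_negative"] += 1
    return out


@dataclass
class EvalResult:
    """Corpus-level strict/relax metrics plus error-taxonomy counts."""

    strict: MatchCounts
    relax: MatchCounts
    errors: dict[str, int]

    def to_dict(self) -> dict:
        def block(counts: MatchCounts) -> dict:
            p, r, f = counts.micro_prf()
            per_cat = {}
            for cat in counts.categories():
                cp, cr, cf = counts.category_prf(cat)
                per_cat[cat] = {"precision": cp, "recall": cr, "f1": cf,
                                "tp": counts.tp[cat], "fp": counts.fp[cat],
                                "fn": counts.fn[cat]}
            return {"micro": {"precision": p, "recall": r, "f1": f},
                    "per_category": per_cat}
        return {"strict": block(self.strict), "relax": block(self.relax),
                "error_taxonomy": dict(self.errors)}

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n",
                              encoding="utf-8")


def evaluate_corpus(
        gold_docs: Sequence[Document],
        pred: Sequence[Document] | Mapping[str, Sequence[PhiSpan]],
) -> EvalResult:
    """Pool per-document counts over a doc_id-aligned corpus pair."""
    if isinstance(pred, Mapping):
        pred_spans = dict(pred)
    else:
        pred_spans = {d.doc_id: d.spans for d in pred}
    gold_ids = [d.doc_id for d in gold_docs]
    missing = set(gold_ids) ^ set(pred_spans)
    if missing:
        raise IntegrityError(
            f"gold/prediction doc_id mismatch: {sorted(missing)}")
    strict, relax = MatchCounts(), MatchCounts()
    errors = dict.fromkeys(ERROR_KINDS, 0)
    for doc in gold_docs:
        p = list(pred_spans[doc.doc_id])
        strict.add(match_spans(doc.spans, p, "strict"))
        relax.add(match_spans(doc.spans, p, "relax"))
        for kind, n in classify_errors(doc.spans, p).items():
            errors[kind] += n
    return EvalResult(strict, relax, errors)
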