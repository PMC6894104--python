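"""Text normalization, sentence splitting, tokenization and BIO conversion.

Clinical notes frequently contain run-together words where a space was
lost ("prnInsulin" for "prn Insulin").  :func:`correct_typos` repairs the
dominant pattern -- a lowercase-to-uppercase transition between two known
words -- and returns an :class:`OffsetMap` so every downstream character
offset can be projected back onto the original note text.  Annotations
therefore always live in original-text coordinates; the corrected text
exists only as the stream the tagger sees.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .corpus import LabeledSequence, PhiSpan, Token, repair_bio

logger = logging.getLogger(__name__)


@dataclass
class OffsetMap:
    """Piecewise monotone map from corrected-text to original-text offsets.

    ``to_orig[i]`` is the original offset of corrected offset ``i``, for
    ``i`` in ``[0, len(corrected)]``.  Characters inserted during
    correction map to the original offset of the following character, so
    the map is total and monotone non-decreasing.
    """

    to_orig: list[int]

    def to_original(self, offset: int) -> int:
        return self.to_orig[offset]

    def project_span(self, start: int, end: int) -> tuple[int, int]:
        return self.to_orig[start], self.to_orig[end]

    @classmethod
    def identity(cls, n: int) -> "OffsetMap":
        return cls(list(range(n + 1)))


_DEFAULT_LEXICON: set[str] | None = None


def default_lexicon() -> set[str]:
    """Known-word list bundled with the package (one word per line)."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        text = (resources.files("phitag") / "data" / "lexicon.txt").read_text(
            encoding="utf-8")
        _DEFAULT_LEXICON = {
            w.strip().lower() for w in text.splitlines() if w.strip()
        }
    return _DEFAULT_LEXICON


def load_lexicon(path: str | Path) -> set[str]:
    return {
        w.strip().lower()
        for w in Path(path).read_text(encoding="utf-8").splitlines()
        if w.strip()
    }


def correct_typos(text: str,
                  lexicon: set[str] | None = None) -> tuple[str, OffsetMap]:
    """Insert spaces at run-together word boundaries.

    A space is inserted at each lowercase-to-uppercase transition whose
    flanking alphabetic runs both have length >= 2 and at least one of
    which (case-folded) is in the known-word lexicon.  The returned
    :class:`OffsetMap` projects corrected offsets back to the original.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    out: list[str] = []
    to_orig: list[int] = []
    n = len(text)
    for i, ch in enumerate(text):
        if (0 < i and text[i - 1].islower() and ch.isupper()):
            j = i - 1
            while j > 0 and text[j - 1].isalpha():
                j -= 1
            k = i
            while k < n and text[k].isalpha():
                k += 1
            left, right = text[j:i], text[i:k]
            if (len(left) >= 2 and len(right) >= 2
                    and (left.lower() in lexicon or right.lower() in lexicon)):
                out.append(" ")
                to_orig.append(i)
        out.append(ch)
        to_orig.append(i)
    to_orig.append(n)
    return "".join(out), OffsetMap(to_orig)


_SENT_BREAK = re.compile(r"[.!?](?=\s)|\n")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return (start, end) spans of sentences, whitespace-trimmed.

    Newlines always break (clinical notes are list-heavy); sentence-final
    punctuation followed by whitespace also breaks.  The spans tile the
    non-whitespace text.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BREAK.finditer(text):
        end = m.end() if m.group() != "\n" else m.start()
        seg = _trim(text, start, end)
        if seg is not None:
            spans.append(seg)
        start = m.end()
    seg = _trim(text, start, len(text))
    if seg is not None:
        spans.append(seg)
    return spans


def _trim(text: str, start: int, end: int) -> tuple[int, int] | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return (start, end) if start < end else None


_TOKEN = re.compile(r"[^\W\d_]+|\d+|\S", re.UNICODE)


def tokenize(sentence_text: str, base_offset: int = 0) -> list[Token]:
    """Aggressive tokenization: letter runs, digit runs, single punctuation.

    Fine granularity keeps punctuation-laced PHIs (phones, IDs, dates)
    aligned with token boundaries.  Offsets are absolute in the document
    when *base_offset* is the sentence start.
    """
    return [
        Token(m.group(), base_offset + m.start(), base_offset + m.end())
        for m in _TOKEN.finditer(sentence_text)
    ]


def spans_to_bio(tokens: list[Token], spans: list[PhiSpan]) -> LabeledSequence:
    """Project character spans onto tokens as BIO tags.

    A token partially covered by a span is labeled entirely (boundary
    snapping): for de-identification it is safer to over-mask than to
    leak part of a PHI.  Spans overlapping no token are dropped with a
    warning.
    """
    tags = ["O"] * len(tokens)
    dropped = 0
    for span in spans:
        hit = [i for i, t in enumerate(tokens)
               if t.start < span.end and span.start < t.end]
        if not hit:
            dropped += 1
            continue
        tags[hit[0]] = f"B-{span.category}"
        for i in hit[1:]:
            tags[i] = f"I-{span.category}"
    if dropped:
        logger.warning("spans_to_bio: dropped %d span(s) overlapping no token",
                       dropped)
    return LabeledSequence(list(tokens), tags)


def bio_to_spans(seq: LabeledSequence, text: str) -> list[PhiSpan]:
    """Collapse maximal ``B-X (I-X)*`` runs into character spans.

    Invalid tag grammar is repaired (orphan I promoted to B) before
    conversion; *text* supplies span surfaces.
    """
    tags, _ = repair_bio(seq.tags)
    spans: list[PhiSpan] = []
    i = 0
    while i < len(tags):
        tag = tags[i]
        if tag.startswith("B-"):
            cat = tag[2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{cat}":
                j += 1
            start = seq.tokens[i].start
            end = seq.tokens[j - 1].end
            spans.append(PhiSpan(start, end, cat, text[start:end]))
            i = j
        else:
            i += 1
    return spans
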