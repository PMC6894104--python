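"""Domain types and I/O for annotated clinical notes.

A corpus is a list of :class:`Document` objects: free text plus standoff
PHI (protected health information) annotations given as character-offset
spans.  Offsets are 0-based and half-open, the usual standoff convention.
Two on-disk formats are supported:

* standoff -- the note text in one file, annotations in a tab-separated
  companion file with lines ``id<TAB>category start end<TAB>surface``;
* CoNLL -- one token per line (``surface<TAB>start<TAB>end<TAB>tag``),
  blank line between sentences, BIO tag scheme.

Ten PHI categories are admissible.  Source annotations that use the finer
2014 i2b2/UTHealth label inventory are harmonized onto this set (or
dropped) by :func:`harmonize_category`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

#: The ten admissible PHI categories.
PHI_CATEGORIES: tuple[str, ...] = (
    "DATE", "NAME", "AGE", "ID", "PHONE",
    "WEB", "INSTITUTE", "STREET", "CITY", "ZIP",
)

#: Sentinel returned by :func:`harmonize_category` for excluded labels.
DROP = "DROP"


class ParseError(ValueError):
    """A file does not conform to the expected dialect."""


class IntegrityError(ValueError):
    """An annotation violates a document invariant."""


class ConfigurationError(ValueError):
    """An unknown label or invalid configuration value."""


class Token(NamedTuple):
    surface: str
    start: int
    end: int


@dataclass(frozen=True, order=True)
class PhiSpan:
    """One annotated PHI mention: ``[start, end)`` character offsets."""

    start: int
    end: int
    category: str
    surface: str

    def __post_init__(self) -> None:
        if self.category not in PHI_CATEGORIES:
            raise ConfigurationError(
                f"unknown PHI category {self.category!r}; "
                f"admissible: {', '.join(PHI_CATEGORIES)}"
            )
        if not (0 <= self.start < self.end):
            raise IntegrityError(f"bad span offsets [{self.start}, {self.end})")

    def overlaps(self, other: "PhiSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Document:
    """A clinical note with validated, disjoint, sorted PHI spans."""

    doc_id: str
    text: str
    spans: list[PhiSpan] = field(default_factory=list)
    note_type: str = "PROGRESS NOTES"

    def __post_init__(self) -> None:
        self.spans = sorted(self.spans)
        n = len(self.text)
        prev: PhiSpan | None = None
        for s in self.spans:
            if s.end > n:
                raise IntegrityError(
                    f"{self.doc_id}: span [{s.start}, {s.end}) exceeds text length {n}"
                )
            if self.text[s.start:s.end] != s.surface:
                raise IntegrityError(
                    f"{self.doc_id}: surface mismatch at [{s.start}, {s.end}): "
                    f"annotation {s.surface!r} vs text "
                    f"{self.text[s.start:s.end]!r}"
                )
            if prev is not None and s.start < prev.end:
                raise IntegrityError(
                    f"{self.doc_id}: overlapping spans "
                    f"[{prev.start}, {prev.end}) and [{s.start}, {s.end})"
                )
            prev = s


@dataclass
class LabeledSequence:
    """One sentence of tokens with aligned BIO tags."""

    tokens: list[Token]
    tags: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise IntegrityError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def is_valid_bio(self) -> bool:
        prev = "O"
        for t in self.tags:
            if t.startswith("I-"):
                if prev not in (f"B-{t[2:]}", t):
                    return False
            prev = t
        return True


def repair_bio(tags: list[str]) -> tuple[list[str], int]:
    """Promote orphan ``I-X`` tags to ``B-X``; return (tags, n_repaired)."""
    out: list[str] = []
    n = 0
    prev = "O"
    for t in tags:
        if t.startswith("I-") and prev not in (f"B-{t[2:]}", t):
            t = "B-" + t[2:]
            n += 1
        out.append(t)
        prev = t
    return out, n


# --- category harmonization -------------------------------------------------

# Source labels of the 2014 i2b2/UTHealth guideline mapped onto the ten
# target categories: phone and fax merge to PHONE; email, URL and IP
# address merge to WEB; organization and hospital merge to INSTITUTE;
# calendar sub-kinds other than full dates, plus state and country, are
# excluded because HIPAA Safe Harbor does not require them.
HARMONIZATION: dict[str, str] = {
    **{c: c for c in PHI_CATEGORIES},
    "PATIENT": "NAME",
    "DOCTOR": "NAME",
    "USERNAME": "NAME",
    "HOSPITAL": "INSTITUTE",
    "ORGANIZATION": "INSTITUTE",
    "FAX": "PHONE",
    "EMAIL": "WEB",
    "URL": "WEB",
    "IPADDRESS": "WEB",
    "IP ADDRESS": "WEB",
    "MEDICALRECORD": "ID",
    "IDNUM": "ID",
    "DEVICE": "ID",
    "BIOID": "ID",
    "HEALTHPLAN": "ID",
    "DAY-OF-WEEK": DROP,
    "SEASON": DROP,
    "HOLIDAY": DROP,
    "STATE": DROP,
    "COUNTRY": DROP,
    "PROFESSION": DROP,
    "LOCATION-OTHER": DROP,
}


def harmonize_category(source_label: str,
                       extra: dict[str, str] | None = None) -> str:
    """Map a source annotation label onto the ten-category set.

    Returns one of :data:`PHI_CATEGORIES` or :data:`DROP` for labels that
    are excluded from the harmonized scheme.  ``extra`` lets callers
    extend the mapping for site-specific label inventories.
    """
    label = source_label.strip().upper()
    table = HARMONIZATION if extra is None else {**HARMONIZATION, **extra}
    try:
        return table[label]
    except KeyError:
        raise ConfigurationError(
            f"unknown source label {source_label!r}; admissible: "
            f"{', '.join(sorted(table))}"
        ) from None


def harmonize_document(doc: Document,
                       extra: dict[str, str] | None = None) -> Document:
    """Return a copy of *doc* with all span categories harmonized."""
    spans = []
    for s in doc.spans:
        cat = harmonize_category(s.category, extra)
        if cat is not DROP and cat != DROP:
            spans.append(PhiSpan(s.start, s.end, cat, s.surface))
    return Document(doc.doc_id, doc.text, spans, doc.note_type)


# --- standoff I/O ------------------------------------------------------------

def read_standoff(text_path: str | Path, ann_path: str | Path,
                  note_type: str = "PROGRESS NOTES") -> Document:
    """Read a note and its standoff annotation companion file.

    Annotation lines: ``id<TAB>category start end<TAB>surface``.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    text = text_path.read_text(encoding="utf-8")
    spans: list[PhiSpan] = []
    for lineno, line in enumerate(
            ann_path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{ann_path}:{lineno}: expected 3 tab-separated "
                             f"columns, got {len(parts)}")
        _, middle, surface = parts
        try:
            category, start_s, end_s = middle.rsplit(" ", 2)
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(
                f"{ann_path}:{lineno}: malformed 'category start end' field "
                f"{middle!r}") from None
        if end > len(text) or start < 0 or start >= end:
            raise ParseError(
                f"{ann_path}:{lineno}: offsets [{start}, {end}) out of range "
                f"for text of length {len(text)}")
        spans.append(PhiSpan(start, end, category, surface))
    return Document(text_path.stem, text, spans, note_type)


def write_standoff(doc: Document, text_path: str | Path,
                   ann_path: str | Path) -> None:
    Path(text_path).write_text(doc.text, encoding="utf-8")
    lines = [
        f"T{i}\t{s.category} {s.start} {s.end}\t{s.surface}"
        for i, s in enumerate(doc.spans, start=1)
    ]
    Path(ann_path).write_text(
        "".join(line + "\n" for line in lines), encoding="utf-8")


def read_corpus_dir(directory: str | Path) -> list[Document]:
    """Read every ``*.txt`` + ``*.ann`` pair under *directory*."""
    directory = Path(directory)
    docs = []
    for text_path in sorted(directory.glob("*.txt")):
        ann_path = text_path.with_suffix(".ann")
        if not ann_path.exists():
            raise ParseError(f"missing annotation file for {text_path}")
        docs.append(read_standoff(text_path, ann_path))
    return docs


def write_corpus_dir(docs: Iterable[Document], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        write_standoff(doc, directory / f"{doc.doc_id}.txt",
                       directory / f"{doc.doc_id}.ann")


# --- CoNLL I/O ----------------------------------------------------------------

def write_conll(sequences: Iterable[LabeledSequence],
                path: str | Path) -> None:
    """Write sentences in the 4-column tab-separated token dialect."""
    lines: list[str] = []
    for seq in sequences:
        for tok, tag in zip(seq.tokens, seq.tags):
            lines.append(f"{tok.surface}\t{tok.start}\t{tok.end}\t{tag}")
        lines.append("")
    try:
        Path(path).write_text(
            "".join(line + "\n" for line in lines), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write CoNLL file {path}: {exc}") from exc


def read_conll(path: str | Path) -> list[LabeledSequence]:
    """Read the dialect written by :func:`write_conll`.

    Orphan ``I-X`` tags are promoted to ``B-X`` with a logged warning so
    that third-party prediction files with sloppy tag grammar still load.
    """
    path = Path(path)
    sequences: list[LabeledSequence] = []
    tokens: list[Token] = []
    tags: list[str] = []
    repaired = 0

    def flush() -> None:
        nonlocal tokens, tags, repaired
        if tokens:
            fixed, n = repair_bio(tags)
            repaired += n
            sequences.append(LabeledSequence(tokens, fixed))
        tokens, tags = [], []

    for lineno, line in enumerate(
            path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 tab-separated columns, "
                f"got {len(parts)}")
        surface, start_s, end_s, tag = parts
        try:
            tokens.append(Token(surface, int(start_s), int(end_s)))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer offset") from None
        tags.append(tag)
    flush()
    if repaired:
        logger.warning("%s: repaired %d orphan I- tag(s)", path, repaired)
    return sequences
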