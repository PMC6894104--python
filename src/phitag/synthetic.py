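"""Seeded generator of surrogate clinical notes with PHI annotations.

Every PHI value is a surrogate drawn from invented vocabularies -- the
corpus is distributable and nothing in it refers to a real person.  Two
built-in institution styles, ``site_A`` and ``site_B``, share note
templates but differ in every date/phone/ID surface format and in their
name/city/street/institute vocabularies, emulating the distribution shift
a tagger meets when notes from a second hospital arrive.  The generator
can also inject the characteristic run-together-word typo (a deleted
space before a capitalized word) at a configurable rate, keeping the
annotations consistent with the perturbed text.

:func:`plant_prediction_errors` perturbs gold annotations into synthetic
"predictions" realizing exact requested counts of the four error kinds
(boundary mismatch, wrong category, false positive, false negative), a
closed-loop oracle for the evaluation module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import PHI_CATEGORIES, Document, PhiSpan
from .evaluate import ERROR_KINDS

_MONTHS = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
           "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


@dataclass
class StyleProfile:
    """Surface conventions and vocabularies of one institution."""

    name: str
    date_formats: list[str]          # callables keyed below
    phone_formats: list[str]         # '#' -> digit
    id_formats: list[str]            # '#' -> digit, '@' -> uppercase letter
    first_names: list[str]
    last_names: list[str]
    cities: list[str]
    street_names: list[str]
    institutes: list[str]
    zip_codes: list[str]
    web_hosts: list[str]

    def vocabulary(self) -> set[str]:
        return (set(self.first_names) | set(self.last_names)
                | set(self.cities) | set(self.street_names)
                | set(self.institutes))


SITE_A = StyleProfile(
    name="site_A",
    date_formats=["mm/dd/yyyy", "m/d/yy"],
    phone_formats=["(###) ###-####", "###-###-####"],
    id_formats=["#######", "########"],
    first_names=["Alice", "Brian", "Clara", "Daniel", "Elena", "Frank",
                 "Grace", "Henry", "Irene", "Jacob", "Karen", "Louis",
                 "Maria", "Nathan", "Olivia", "Peter", "Quinn", "Rachel",
                 "Samuel", "Teresa"],
    last_names=["Anderson", "Baxter", "Caldwell", "Dawson", "Ellison",
                "Foster", "Granger", "Holloway", "Ingram", "Jennings",
                "Keller", "Lawson", "Mercer", "Norwood", "Osborne",
                "Prescott", "Quimby", "Redding", "Sheldon", "Thornton"],
    cities=["Gainesville", "Ocala", "Alachua", "Newberry", "Micanopy",
            "Archer", "Hawthorne", "Waldo", "Starke", "Palatka"],
    street_names=["Oak Lane", "Maple Drive", "Cedar Court", "Elm Street",
                  "Pine Avenue", "Magnolia Way", "Hickory Road",
                  "Willow Terrace"],
    institutes=["Riverbend Medical Center", "North Lake Clinic",
                "Summit Care Hospital", "Westgate Health Institute",
                "Crestview Family Practice"],
    zip_codes=["32601", "32603", "32605", "32607", "32608", "32609",
               "32641", "32653", "34470", "34471"],
    web_hosts=["portal.riverbendmed.org", "results.northlakeclinic.org"],
)

SITE_B = StyleProfile(
    name="site_B",
    date_formats=["yyyy-mm-dd", "dd Mon yyyy"],
    phone_formats=["###.###.####", "+1 ### ### ####"],
    id_formats=["@@-######", "#########"],
    first_names=["Amara", "Boris", "Celeste", "Dmitri", "Esme", "Farid",
                 "Gwen", "Hiro", "Ines", "Jonas", "Katya", "Leif",
                 "Mirela", "Nadia", "Omar", "Priya", "Rohan", "Saskia",
                 "Tomas", "Ursula"],
    last_names=["Albright", "Beaumont", "Castellano", "Delacroix",
                "Eastwood", "Fairbanks", "Goldberg", "Hathaway",
                "Iverson", "Jorgensen", "Kowalski", "Lindqvist",
                "Moreau", "Novak", "Okafor", "Petrov", "Quintana",
                "Rosenberg", "Silverman", "Takahashi"],
    cities=["Lakeside", "Brookhaven", "Fairmont", "Silverton", "Eastvale",
            "Northfield", "Westbrook", "Harborview", "Stonegate",
            "Maplewood"],
    street_names=["Birch Boulevard", "Aspen Circle", "Juniper Street",
                  "Sycamore Alley", "Poplar Crescent", "Laurel Close",
                  "Chestnut Row", "Dogwood Path"],
    institutes=["Bayside Regional Hospital", "Eastern Valley Clinic",
                "Pine Grove Medical Institute", "Harbor Point Health Center",
                "South Ridge Hospital"],
    zip_codes=["45201", "45208", "45212", "45219", "45220", "45227",
               "45230", "45236", "45242", "45255"],
    web_hosts=["ehr.baysideportal.net", "chart.pinegrovemed.net"],
)

STYLES = {"site_A": SITE_A, "site_B": SITE_B}

#: Sentence templates per category; exactly one PHI slot per sentence so
#: category counts are a clean multinomial draw.
TEMPLATES: dict[str, list[str]] = {
    "DATE": ["Seen in clinic on {} for routine follow up.",
             "Patient will return to clinic on {}.",
             "Labs drawn on {} were reviewed in detail.",
             "Discharged home in good condition on {}."],
    "NAME": ["Patient {} was evaluated in the office today.",
             "Seen and examined together with {} at bedside.",
             "Care plan was discussed at length with {}.",
             "Note reviewed and cosigned by {} as attending."],
    "AGE": ["The patient is a {} year old with hypertension.",
            "This {} year old presents for annual evaluation.",
            "A pleasant {} year old seen for medication review."],
    "ID": ["Medical record number {} confirmed on file.",
           "Account number {} was verified at registration.",
           "Reference identifier {} assigned for this visit."],
    "PHONE": ["Contact number on file is {} for scheduling.",
              "Please call {} with any urgent questions.",
              "Pharmacy phone number listed as {} today."],
    "WEB": ["Results are posted at {} for review.",
            "Patient portal available at {} after discharge."],
    "INSTITUTE": ["Outside records were requested from {} this week.",
                  "Patient was transferred overnight from {}.",
                  "Imaging was performed previously at {}."],
    "STREET": ["Home address listed as {} on intake.",
               "Patient currently resides at {} alone."],
    "CITY": ["Patient lives in {} with immediate family.",
             "Relocated from {} earlier last year."],
    "ZIP": ["Mailing zip code on file is {} currently.",
            "Address zip code was updated to {} today."],
}

FILLER_SENTENCES = [
    "Vital signs are stable and within normal limits.",
    "No acute distress was noted on examination.",
    "Medications were reconciled without any change.",
    "Plan was discussed and all questions answered.",
    "Blood pressure remains well controlled on therapy.",
    "Aspirin 81 mg daily was continued without change.",
    "Review of systems is otherwise entirely negative.",
    "Will follow up as needed for new symptoms.",
]

NOTE_TYPES = ("PROGRESS NOTES", "RADIOLOGY REPORT", "H&P")

#: Table of per-category annotation totals used for the default category
#: weights (DATE-heavy, WEB vanishingly rare), matching the skew of real
#: de-identification corpora.
DEFAULT_CATEGORY_WEIGHTS: dict[str, float] = {
    "DATE": 4702, "NAME": 1983, "AGE": 408, "ID": 334, "PHONE": 125,
    "WEB": 4, "INSTITUTE": 319, "STREET": 52, "CITY": 114, "ZIP": 65,
}


@dataclass
class GeneratorConfig:
    """Knobs of the surrogate-note generator."""

    n_notes: int = 100
    note_type_mix: dict[str, float] = field(
        default_factory=lambda: {"PROGRESS NOTES": 0.5,
                                 "RADIOLOGY REPORT": 0.3, "H&P": 0.2})
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    phi_sentences: tuple[int, int] = (4, 8)    # inclusive range per note
    filler_sentences: tuple[int, int] = (2, 4)
    typo_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be non-negative")
        for cat in self.category_weights:
            if cat not in PHI_CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")


def _digits(rng: np.random.Generator, pattern: str) -> str:
    out = []
    for ch in pattern:
        if ch == "#":
            out.append(str(rng.integers(0, 10)))
        elif ch == "@":
            out.append(chr(ord("A") + rng.integers(0, 26)))
        else:
            out.append(ch)
    return "".join(out)


def _date_value(rng: np.random.Generator, style: StyleProfile) -> str:
    y = int(rng.integers(2010, 2019))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    fmt = style.date_formats[rng.integers(0, len(style.date_formats))]
    if fmt == "mm/dd/yyyy":
        return f"{m:02d}/{d:02d}/{y}"
    if fmt == "m/d/yy":
        return f"{m}/{d}/{y % 100:02d}"
    if fmt == "yyyy-mm-dd":
        return f"{y}-{m:02d}-{d:02d}"
    if fmt == "dd Mon yyyy":
        return f"{d:02d} {_MONTHS[m - 1]} {y}"
    raise ValueError(f"unknown date format {fmt!r}")


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[rng.integers(0, len(items))]


def _phi_value(rng: np.random.Generator, style: StyleProfile,
               category: str) -> str:
    if category == "DATE":
        return _date_value(rng, style)
    if category == "NAME":
        if rng.random() < 0.7:
            return f"{_pick(rng, style.first_names)} " \
                   f"{_pick(rng, style.last_names)}"
        return _pick(rng, style.last_names)
    if category == "AGE":
        return str(rng.integers(18, 96))
    if category == "ID":
        return _digits(rng, _pick(rng, style.id_formats))
    if category == "PHONE":
        return _digits(rng, _pick(rng, style.phone_formats))
    if category == "WEB":
        return f"{_pick(rng, style.web_hosts)}/r{rng.integers(100, 1000)}"
    if category == "INSTITUTE":
        return _pick(rng, style.institutes)
    if category == "STREET":
        return f"{rng.integers(100, 9900)} {_pick(rng, style.street_names)}"
    if category == "CITY":
        return _pick(rng, style.cities)
    if category == "ZIP":
        return _pick(rng, style.zip_codes)
    raise ValueError(f"unknown category {category!r}")


def _choose_weighted(rng: np.random.Generator,
                     weights: dict[str, float]) -> str:
    cats = sorted(weights)
    w = np.array([weights[c] for c in cats], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("category weights sum to zero")
    return cats[rng.choice(len(cats), p=w / total)]


def generate_note(rng: np.random.Generator, cfg: GeneratorConfig,
                  style: StyleProfile, doc_id: str) -> Document:
    for cat, w in cfg.category_weights.items():
        if w > 0 and cat == "NAME" and not style.first_names:
            raise ValueError(f"style {style.name}: empty NAME vocabulary")
    types = sorted(cfg.note_type_mix)
    tw = np.array([cfg.note_type_mix[t] for t in types], dtype=float)
    note_type = types[rng.choice(len(types), p=tw / tw.sum())]

    lo, hi = cfg.phi_sentences
    n_phi = int(rng.integers(lo, hi + 1))
    lo, hi = cfg.filler_sentences
    n_fill = int(rng.integers(lo, hi + 1))
    kinds = ["phi"] * n_phi + ["fill"] * n_fill
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]

    pieces: list[str] = [f"{note_type}\n\n"]
    pos = len(pieces[0])
    spans: list[PhiSpan] = []
    for kind in kinds:
        if kind == "fill":
            line = FILLER_SENTENCES[rng.integers(0, len(FILLER_SENTENCES))]
        else:
            cat = _choose_weighted(rng, cfg.category_weights)
            template = TEMPLATES[cat][rng.integers(0, len(TEMPLATES[cat]))]
            value = _phi_value(rng, style, cat)
            prefix, suffix = template.split("{}")
            spans.append(PhiSpan(pos + len(prefix),
                                 pos + len(prefix) + len(value), cat, value))
            line = prefix + value + suffix
        pieces.append(line + "\n")
        pos += len(line) + 1
    text = "".join(pieces)
    if cfg.typo_rate > 0:
        text, spans = _inject_typos(rng, text, spans, cfg.typo_rate)
    return Document(doc_id, text, spans, note_type)


def _inject_typos(rng: np.random.Generator, text: str,
                  spans: list[PhiSpan], rate: float
                  ) -> tuple[str, list[PhiSpan]]:
    """Delete spaces at lowercase-word / Capitalized-word boundaries.

    Only spaces outside every span are candidates, so surfaces never
    change; offsets after each deletion shift left by one.
    """
    candidates = []
    for m in re.finditer(r" ", text):
        p = m.start()
        if (p >= 2 and text[p - 1].islower() and text[p - 2].isalpha()
                and p + 2 <= len(text) - 1 and text[p + 1].isupper()
                and text[p + 2].isalpha()):
            if not any(s.start < p < s.end for s in spans):
                candidates.append(p)
    doomed = sorted(p for p in candidates if rng.random() < rate)
    if not doomed:
        return text, spans
    out_spans = []
    for s in spans:
        shift_start = sum(1 for p in doomed if p < s.start)
        shift_end = sum(1 for p in doomed if p < s.end)
        out_spans.append(PhiSpan(s.start - shift_start, s.end - shift_end,
                                 s.category, s.surface))
    chars = [c for i, c in enumerate(text) if i not in set(doomed)]
    return "".join(chars), out_spans


def generate_corpus(cfg: GeneratorConfig,
                    style: StyleProfile | str) -> list[Document]:
    """Deterministic surrogate corpus for a (config, style) pair."""
    if isinstance(style, str):
        style = STYLES[style]
    rng = np.random.default_rng(cfg.seed)
    return [generate_note(rng, cfg, style, f"{style.name}-{i:04d}")
            for i in range(cfg.n_notes)]


# --- planted-error predictions ------------------------------------------------

def plant_prediction_errors(docs: list[Document], spec: dict[str, int],
                            seed: int = 0) -> dict[str, list[PhiSpan]]:
    """Perturb gold spans into predictions with exact error counts.

    *spec* maps error kinds (subset of ``boundary_mismatch``,
    ``wrong_category``, ``false_positive``, ``false_negative``) to
    requested counts; all remaining gold spans are copied verbatim.
    Raises ``ValueError`` when the corpus cannot realize the request.
    """
    unknown = set(spec) - set(ERROR_KINDS)
    if unknown:
        raise ValueError(f"unknown error kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    preds: dict[str, list[PhiSpan]] = {d.doc_id: list(d.spans) for d in docs}
    flat = [(d, i) for d in docs for i in range(len(d.spans))]
    order = [flat[i] for i in rng.permutation(len(flat))]
    need = (spec.get("false_negative", 0) + spec.get("wrong_category", 0)
            + spec.get("boundary_mismatch", 0))
    if need > len(flat):
        raise ValueError(
            f"spec needs {need} gold spans, corpus has {len(flat)}")

    cursor = 0

    def take() -> tuple[Document, int]:
        nonlocal cursor
        d, i = order[cursor]
        cursor += 1
        return d, i

    removed: dict[str, set[int]] = {d.doc_id: set() for d in docs}
    for _ in range(spec.get("false_negative", 0)):
        d, i = take()
        removed[d.doc_id].add(i)
    for _ in range(spec.get("wrong_category", 0)):
        d, i = take()
        s = d.spans[i]
        cats = [c for c in PHI_CATEGORIES if c != s.category]
        new_cat = cats[rng.integers(0, len(cats))]
        preds[d.doc_id][i] = PhiSpan(s.start, s.end, new_cat, s.surface)
    planted_boundary = 0
    for _ in range(spec.get("boundary_mismatch", 0)):
        placed = False
        while cursor < len(order):
            d, i = take()
            s = d.spans[i]
            nxt = d.spans[i + 1].start if i + 1 < len(d.spans) else len(d.text)
            if s.end + 1 <= nxt and s.end < len(d.text):
                new = PhiSpan(s.start, s.end + 1, s.category,
                              d.text[s.start:s.end + 1])
            elif s.end - s.start >= 2:
                new = PhiSpan(s.start, s.end - 1, s.category,
                              d.text[s.start:s.end - 1])
            else:
                continue
            preds[d.doc_id][i] = new
            planted_boundary += 1
            placed = True
            break
        if not placed:
            raise ValueError("not enough gold spans for boundary mismatches")

    for doc_id, idxs in removed.items():
        preds[doc_id] = [s for i, s in enumerate(preds[doc_id])
                         if i not in idxs]

    n_fp = spec.get("false_positive", 0)
    if n_fp:
        _plant_false_positives(rng, docs, preds, n_fp)
    return preds


def _plant_false_positives(rng: np.random.Generator, docs: list[Document],
                           preds: dict[str, list[PhiSpan]],
                           n_fp: int) -> None:
    sites = []
    for d in docs:
        blocked = sorted(d.spans + preds[d.doc_id])
        for m in re.finditer(r"[A-Za-z]{4,}", d.text):
            if not any(s.start < m.end() and m.start() < s.end
                       for s in blocked):
                sites.append((d, m.start(), m.end()))
    if len(sites) < n_fp:
        raise ValueError(f"only {len(sites)} false-positive sites available, "
                         f"{n_fp} requested")
    chosen = rng.choice(len(sites), size=n_fp, replace=False)
    used: dict[str, list[tuple[int, int]]] = {}
    placed = 0
    for k in sorted(int(c) for c in chosen):
        d, a, b = sites[k]
        if any(x < b and a < y for x, y in used.get(d.doc_id, [])):
            continue
        cat = PHI_CATEGORIES[rng.integers(0, len(PHI_CATEGORIES))]
        preds[d.doc_id].append(PhiSpan(a, b, cat, d.text[a:b]))
        used.setdefault(d.doc_id, []).append((a, b))
        placed += 1
    # overlapping choices were skipped; top up from untouched sites
    if placed < n_fp:
        for j, (d, a, b) in enumerate(sites):
            if placed == n_fp:
                break
            if j in {int(c) for c in chosen}:
                continue
            if any(x < b and a < y for x, y in used.get(d.doc_id, [])):
                continue
            cat = PHI_CATEGORIES[rng.integers(0, len(PHI_CATEGORIES))]
            preds[d.doc_id].append(PhiSpan(a, b, cat, d.text[a:b]))
            used.setdefault(d.doc_id, []).append((a, b))
            placed += 1
        if placed < n_fp:
            raise ValueError("could not place all requested false positives")
    for doc_id in preds:
        preds[doc_id] = sorted(preds[doc_id])
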