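"""Per-token lexical and knowledge-based features.

The tagger consumes, besides word and character embeddings, two groups of
categorical feature streams:

* lexical -- a Penn-Treebank-style part-of-speech tag and a word-shape
  string per token;
* knowledge-based -- the result of a fuzzy dictionary (gazetteer) lookup:
  the matched semantic category, the token's position inside the match
  (BIO), and the matching condition (exact vs partial).

Each stream is categorical; the model embeds stream values in small dense
vectors, so these functions only need to emit deterministic strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .corpus import PHI_CATEGORIES, ConfigurationError

logger = logging.getLogger(__name__)


# --- word shape ---------------------------------------------------------------

def word_shape(token: str) -> str:
    """Map a token to ``full|collapsed`` shape form.

    Uppercase letters become ``A``, lowercase ``a``, digits ``0``; other
    characters are kept verbatim.  The collapsed variant squeezes runs of
    the same symbol to one occurrence: ``Smith`` -> ``Aaaaa|Aa``.
    """
    if not token:
        raise ValueError("word_shape: empty token")
    full: list[str] = []
    for ch in token:
        if ch.isupper():
            full.append("A")
        elif ch.islower():
            full.append("a")
        elif ch.isdigit():
            full.append("0")
        else:
            full.append(ch)
    collapsed = [full[0]]
    for sym in full[1:]:
        if sym != collapsed[-1]:
            collapsed.append(sym)
    return "".join(full) + "|" + "".join(collapsed)


# --- part-of-speech -----------------------------------------------------------

# Deterministic rule-based tagger over the Penn Treebank tagset: a
# closed-class lexicon plus suffix heuristics.  Coarse but stable, which
# is what a categorical feature stream needs; unknown forms fall back to
# "X".

_CLOSED_CLASS: dict[str, str] = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "no": "DT", "every": "DT", "each": "DT",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC",
    "in": "IN", "of": "IN", "on": "IN", "at": "IN", "for": "IN",
    "with": "IN", "by": "IN", "from": "IN", "as": "IN", "into": "IN",
    "per": "IN", "after": "IN", "before": "IN", "during": "IN",
    "since": "IN", "without": "IN", "via": "IN",
    "to": "TO",
    "he": "PRP", "she": "PRP", "it": "PRP", "they": "PRP", "i": "PRP",
    "we": "PRP", "you": "PRP", "him": "PRP", "her": "PRP", "them": "PRP",
    "his": "PRP$", "its": "PRP$", "their": "PRP$", "my": "PRP$",
    "our": "PRP$", "your": "PRP$",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP", "has": "VBZ", "have": "VBP",
    "had": "VBD", "do": "VBP", "does": "VBZ", "did": "VBD",
    "will": "MD", "would": "MD", "can": "MD", "could": "MD", "may": "MD",
    "might": "MD", "must": "MD", "shall": "MD", "should": "MD",
    "not": "RB", "n't": "RB", "very": "RB", "today": "NN", "who": "WP",
    "which": "WDT", "when": "WRB", "where": "WRB", "if": "IN",
    "old": "JJ", "new": "JJ", "stable": "JJ", "normal": "JJ",
}

_PUNCT_TAGS = {".": ".", "!": ".", "?": ".", ",": ",", ";": ":", ":": ":",
               "(": "(", ")": ")", '"': "''", "'": "''", "`": "``"}


def _tag_one(tok: str) -> str:
    low = tok.lower()
    if low in _CLOSED_CLASS:
        return _CLOSED_CLASS[low]
    if tok in _PUNCT_TAGS:
        return _PUNCT_TAGS[tok]
    if tok.isdigit():
        return "CD"
    if not tok.isalpha():
        return "SYM" if not any(c.isdigit() for c in tok) else "CD"
    if tok[0].isupper():
        return "NNP"
    if low.endswith("ly"):
        return "RB"
    if low.endswith("ing") and len(low) > 4:
        return "VBG"
    if low.endswith("ed") and len(low) > 3:
        return "VBD"
    if low.endswith("s") and not low.endswith("ss") and len(low) > 3:
        return "NNS"
    if low.isalpha():
        return "NN"
    return "X"


def pos_tag(tokens: list[str]) -> list[str]:
    """Tag one sentence of token surfaces; length-preserving, deterministic."""
    return [_tag_one(t) for t in tokens]


# --- dictionaries and fuzzy lookup --------------------------------------------

NONE_CATEGORY = "NONE"
EXACT, PARTIAL, NO_MATCH = "EXACT", "PARTIAL", "NONE"


@dataclass(frozen=True)
class KnowledgeFeatures:
    """Per-token gazetteer-lookup result.

    ``category == NONE`` iff ``boundary == O`` iff ``condition == NONE``.
    """

    category: str = NONE_CATEGORY
    boundary: str = "O"
    condition: str = NO_MATCH

    def __post_init__(self) -> None:
        none = (self.category == NONE_CATEGORY, self.boundary == "O",
                self.condition == NO_MATCH)
        if any(none) and not all(none):
            raise ValueError(f"inconsistent knowledge features: {self}")

    def composite(self) -> str:
        """Single categorical value coalescing the three fields."""
        return f"{self.category}:{self.boundary}:{self.condition}"


NO_FEATURES = KnowledgeFeatures()


@dataclass
class Dictionary:
    """A gazetteer: case-folded (possibly multi-word) entries for one category.

    ``priority`` ranks dictionaries when several match the same tokens
    (lower wins).  ``exact_only`` disables fuzzy matching; the default
    ZIP-code behaviour, since edit distance on short digit strings
    produces spurious partial matches.
    """

    name: str
    target_category: str
    entries: set[str]
    priority: int = 0
    exact_only: bool = False

    # entries tokenized on whitespace, indexed by word count and by the
    # first word's length (edit distance <= 1 cannot bridge a length gap
    # larger than 1, so lookup scans only three adjacent length buckets)
    _by_len: dict[int, dict[int, list[tuple[str, ...]]]] = field(
        default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.target_category not in PHI_CATEGORIES:
            raise ConfigurationError(
                f"dictionary {self.name!r}: unknown category "
                f"{self.target_category!r}")
        folded = {e.strip().lower() for e in self.entries if e.strip()}
        if not folded:
            raise ConfigurationError(f"dictionary {self.name!r} is empty")
        self.entries = folded
        for e in sorted(folded):
            words = tuple(e.split())
            buckets = self._by_len.setdefault(len(words), {})
            buckets.setdefault(len(words[0]), []).append(words)

    @classmethod
    def from_file(cls, path: str | Path, target_category: str,
                  priority: int = 0, exact_only: bool | None = None,
                  name: str | None = None) -> "Dictionary":
        path = Path(path)
        entries = set(path.read_text(encoding="utf-8").splitlines())
        if exact_only is None:
            exact_only = target_category == "ZIP"
        return cls(name or path.stem, target_category, entries,
                   priority, exact_only)


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment distance (edits + adjacent transpositions)."""
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return la or lb
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = a[i - 1] != b[j - 1]
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


#: Minimum token length for edit-distance partial matching.
FUZZY_MIN_LEN = 5
#: Maximum per-token edit distance for a PARTIAL match.
FUZZY_MAX_DIST = 1


@lru_cache(maxsize=65536)
def _token_match(tok: str, word: str) -> str | None:
    """EXACT / PARTIAL / None for one token against one entry word."""
    if tok == word:
        return EXACT
    if (len(tok) >= FUZZY_MIN_LEN and len(word) >= FUZZY_MIN_LEN
            and abs(len(tok) - len(word)) <= FUZZY_MAX_DIST
            and damerau_levenshtein(tok, word) <= FUZZY_MAX_DIST):
        return PARTIAL
    return None


def _match_at(tokens_cf: list[str], i: int, d: Dictionary):
    """Best match of any entry of *d* starting at token *i*.

    Returns (n_tokens_matched, condition) or None.  Longest entries are
    tried first; a strict exact prefix covering at least half of a
    multi-word entry also counts as PARTIAL.
    """
    best: tuple[int, str] | None = None
    first_len = len(tokens_cf[i])
    for n_words in sorted(d._by_len, reverse=True):
        if best and best[0] >= n_words:
            break
        buckets = d._by_len[n_words]
        entries = [e for ln in (first_len - 1, first_len, first_len + 1)
                   for e in buckets.get(ln, ())]
        for entry in entries:
            if i + n_words <= len(tokens_cf):
                conds = [_token_match(tokens_cf[i + k], entry[k])
                         for k in range(n_words)]
                if all(c is not None for c in conds):
                    if any(c == PARTIAL for c in conds):
                        if not d.exact_only:
                            cand = (n_words, PARTIAL)
                        else:
                            cand = None
                    else:
                        cand = (n_words, EXACT)
                    if cand and (best is None or cand[0] > best[0]
                                 or (cand[0] == best[0]
                                     and cand[1] == EXACT)):
                        best = cand
                        continue
            # strict prefix of a multi-word entry (>= half its words)
            if d.exact_only or n_words < 2:
                continue
            for k in range(n_words - 1, 0, -1):
                if 2 * k < n_words or i + k > len(tokens_cf):
                    continue
                if tuple(tokens_cf[i:i + k]) == entry[:k]:
                    if best is None or k > best[0]:
                        best = (k, PARTIAL)
                    break
    return best


def fuzzy_lookup(tokens: list[str],
                 dicts: list[Dictionary]) -> list[KnowledgeFeatures]:
    """Scan a sentence for longest leftmost gazetteer matches.

    Matched runs get the dictionary's category with B/I boundaries and an
    EXACT or PARTIAL condition; competing matches at the same position are
    resolved by lower priority rank, then longer match, then exact before
    partial.  With no dictionaries loaded, every token gets the NONE
    feature (the feature layer degrades gracefully).
    """
    out = [NO_FEATURES] * len(tokens)
    if not dicts:
        if tokens:
            logger.warning("fuzzy_lookup: no dictionaries loaded; "
                           "emitting all-NONE features")
        return out
    ranked = sorted(dicts, key=lambda d: d.priority)
    tokens_cf = [t.lower() for t in tokens]
    i = 0
    while i < len(tokens):
        best: tuple[int, int, str, Dictionary] | None = None  # (prio, -len, cond, d)
        for d in ranked:
            m = _match_at(tokens_cf, i, d)
            if m is None:
                continue
            n, cond = m
            key = (d.priority, -n, 0 if cond == EXACT else 1)
            if best is None or key < (best[0], best[1], best[2]):
                best = (d.priority, -n, 0 if cond == EXACT else 1, d)
                best_n, best_cond = n, cond
        if best is None:
            i += 1
            continue
        cat = best[3].target_category
        out[i] = KnowledgeFeatures(cat, "B", best_cond)
        for k in range(1, best_n):
            out[i + k] = KnowledgeFeatures(cat, "I", best_cond)
        i += best_n
    return out


# --- bundled gazetteers -------------------------------------------------------

#: file-name -> (category, priority) for the dictionaries shipped in
#: ``phitag/data/dicts``; ZIP is exact-only by default.
DEFAULT_MANIFEST: dict[str, tuple[str, int]] = {
    "first_names.txt": ("NAME", 0),
    "last_names.txt": ("NAME", 1),
    "provider_names.txt": ("NAME", 0),
    "cities.txt": ("CITY", 2),
    "institutes.txt": ("INSTITUTE", 2),
    "zipcodes.txt": ("ZIP", 3),
}


def load_dictionaries(directory: str | Path | None = None,
                      manifest: dict[str, tuple[str, int]] | None = None
                      ) -> list[Dictionary]:
    """Load gazetteer files; defaults to the bundled dictionary set."""
    manifest = manifest or DEFAULT_MANIFEST
    dicts = []
    for fname, (category, priority) in sorted(manifest.items()):
        if directory is None:
            ref = resources.files("phitag") / "data" / "dicts" / fname
            entries = set(ref.read_text(encoding="utf-8").splitlines())
            dicts.append(Dictionary(Path(fname).stem, category, entries,
                                    priority, category == "ZIP"))
        else:
            dicts.append(Dictionary.from_file(Path(directory) / fname,
                                              category, priority))
    return dicts
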