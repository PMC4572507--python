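"""Dictionary-based concept recognition over ontology labels and synonyms.

A deliberately simple recognizer: every term label and synonym is indexed
under a normalized form (lowercase, punctuation folded to spaces), and
abstracts are scanned with a greedy longest-match, left-to-right,
non-overlapping token window.  No stemming by default and no negation
detection — the downstream frequency/specificity filter is what absorbs
recognition noise, so the recognizer errs on the side of simplicity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .ontology import Ontology, TermId

__all__ = ["LexicalIndex", "Mention", "normalize", "build_index", "recognize"]

_NON_ALNUM = re.compile(r"[^0-9a-z]+")
_TOKEN = re.compile(r"[0-9A-Za-z]+")

DEFAULT_MAX_PHRASE_TOKENS = 7


def normalize(text: str) -> str:
    """Lowercase, replace punctuation with spaces, collapse whitespace.

    Idempotent: ``normalize(normalize(x)) == normalize(x)``.
    """
    return _NON_ALNUM.sub(" ", text.lower()).strip()


@dataclass(frozen=True)
class Mention:
    """One recognized term occurrence in an abstract.

    Offsets are 0-based character positions into the scanned text with a
    half-open end; ``surface`` is the exact substring at [start, end).
    """

    abstract_id: str
    term: TermId
    start: int
    end: int
    surface: str


@dataclass
class LexicalIndex:
    """Normalized phrase -> term-id index built from an ontology lexicon.

    A phrase shared by several terms (e.g. a common synonym) maps to the
    full set of term ids; recognition emits one mention per mapped term.
    """

    entries: dict[str, frozenset[TermId]] = field(default_factory=dict)
    max_phrase_tokens: int = DEFAULT_MAX_PHRASE_TOKENS


def build_index(
    ontology: Ontology, max_phrase_tokens: int = DEFAULT_MAX_PHRASE_TOKENS
) -> LexicalIndex:
    """Index every label and synonym under its normalized form.

    Phrases longer than ``max_phrase_tokens`` tokens are skipped: the
    scanning window cannot reach them.
    """
    entries: dict[str, set[TermId]] = {}
    for tid in ontology:
        term = ontology.term(tid)
        for phrase in (term.label, *term.synonyms):
            key = normalize(phrase)
            if not key or len(key.split()) > max_phrase_tokens:
                continue
            entries.setdefault(key, set()).add(tid)
    return LexicalIndex(
        entries={k: frozenset(v) for k, v in entries.items()},
        max_phrase_tokens=max_phrase_tokens,
    )


def recognize(index: LexicalIndex, abstract_id: str, text: str) -> list[Mention]:
    """Scan *text* and return all recognized term mentions.

    Greedy longest-match, left to right: at each token position the longest
    indexed phrase starting there wins and the scan resumes after it, so
    matches never overlap.  Ambiguous phrases yield one mention per mapped
    term at the same span.  Negated statements are matched like any other
    (no negation handling by design).
    """
    tokens = [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN.finditer(text)]
    mentions: list[Mention] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for k in range(min(index.max_phrase_tokens, n - i), 0, -1):
            phrase = " ".join(tok for tok, _, _ in tokens[i : i + k])
            term_ids = index.entries.get(phrase)
            if term_ids:
                start = tokens[i][1]
                end = tokens[i + k - 1][2]
                surface = text[start:end]
                for tid in sorted(term_ids):
                    mentions.append(
                        Mention(
                            abstract_id=abstract_id,
                            term=tid,
                            start=start,
                            end=end,
                            surface=surface,
                        )
                    )
                i += k
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def recognize_record(
    index: LexicalIndex, abstract_id: str, title: str, body: str
) -> list[Mention]:
    """Recognize mentions in both title and body of an abstract.

    The two fields are scanned separately (no phrase can straddle the
    boundary); body mentions are offset as if title and body were joined
    by a two-newline separator, so offsets index into ``title + "\\n\\n" +
    body``.
    """
    mentions = recognize(index, abstract_id, title)
    shift = len(title) + 2
    for m in recognize(index, abstract_id, body):
        mentions.append(
            Mention(
                abstract_id=m.abstract_id,
                term=m.term,
                start=m.start + shift,
                end=m.end + shift,
                surface=m.surface,
            )
        )
    return mentions


def mentions_to_tsv(mentions: Iterable[Mention], path_or_buf) -> None:
    """Write mentions as TSV: abstract_id, term_id, start, end, surface."""
    import pandas as pd

    df = pd.DataFrame(
        [(m.abstract_id, m.term, m.start, m.end, m.surface) for m in mentions],
        columns=["abstract_id", "term_id", "start", "end", "surface"],
    )
    df.to_csv(path_or_buf, sep="\t", index=False)
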