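"""TF-IDF scoring of a case's clinical terms against pattern code documents.

Each TCM pattern is represented as a code: a bag of characteristic terms with
occurrence counts. A case's pooled symptom/sign terms are scored against every
code with term frequency

    tf(t, d) = f_{t,d} / sum_{t' in d} f_{t',d}

and smoothed inverse document frequency

    idf(t) = ln(1 + N / n_t)

where N is the number of codes and n_t the number of codes containing t. The
case's score for a code is the sum of tf*idf over the terms it shares with
that code; the differentiated pattern is the top-scoring code. Natural log is
used throughout — the log base rescales every score by the same constant, so
rankings are base-invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

#: Sentinel pattern id returned when a case matches no code at all.
UNDETERMINED = "undetermined"


class KnowledgeBase:
    """Pattern codes as term-count documents, with cached document frequency."""

    def __init__(self, codes: Mapping[str, Mapping[str, int]]):
        if not codes:
            raise ValueError("knowledge base needs at least one pattern code")
        clean: dict[str, dict[str, int]] = {}
        for pid, doc in codes.items():
            if not doc:
                raise ValueError(f"pattern {pid!r} has an empty document")
            for term, count in doc.items():
                if not (isinstance(count, int) and count > 0):
                    raise ValueError(
                        f"pattern {pid!r}, term {term!r}: counts must be "
                        f"positive integers, got {count!r}"
                    )
            clean[pid] = dict(doc)
        self.codes = clean
        self.doc_freq: dict[str, int] = {}
        for doc in self.codes.values():
            for term in doc:
                self.doc_freq[term] = self.doc_freq.get(term, 0) + 1

    @property
    def N(self) -> int:
        return len(self.codes)

    def __contains__(self, term: str) -> bool:
        return term in self.doc_freq

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.codes, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "KnowledgeBase":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))


@dataclass(frozen=True)
class PatternScore:
    pattern_id: str
    score: float
    matched_terms: frozenset


def term_frequency(term: str, document: Mapping[str, int]) -> float:
    """f_{t,d} / sum of counts in d; 0.0 for a term absent from d."""
    if not document:
        raise ValueError("term frequency of an empty document is undefined")
    return document.get(term, 0) / sum(document.values())


def idf_smooth(term: str, kb: KnowledgeBase) -> float:
    """ln(1 + N/n_t); errors for a term present in no code."""
    n_t = kb.doc_freq.get(term)
    if not n_t:
        raise KeyError(f"term {term!r} occurs in no pattern code")
    return math.log(1.0 + kb.N / n_t)


def score_case(terms: Iterable[str], kb: KnowledgeBase) -> list[PatternScore]:
    """Score a term set against every code; descending, ties by pattern id.

    Terms absent from every code contribute nothing (real records contain
    findings outside the knowledge base); duplicates in ``terms`` collapse.
    """
    term_set = set(terms)
    known = term_set & kb.doc_freq.keys()
    scores = []
    for pid in sorted(kb.codes):
        doc = kb.codes[pid]
        matched = frozenset(t for t in known if t in doc)
        s = sum(term_frequency(t, doc) * idf_smooth(t, kb) for t in matched)
        scores.append(PatternScore(pattern_id=pid, score=s, matched_terms=matched))
    scores.sort(key=lambda ps: (-ps.score, ps.pattern_id))
    return scores


def top_pattern(terms: Iterable[str], kb: KnowledgeBase) -> str:
    """Top-scoring pattern id for a term set, or UNDETERMINED on all-zero."""
    ranked = score_case(terms, kb)
    if ranked[0].score == 0.0:
        return UNDETERMINED
    return ranked[0].pattern_id


def differentiate(record, kb: KnowledgeBase) -> str:
    """Differentiate a standardized record: pool the four category term sets
    and return the top pattern (or UNDETERMINED when nothing matches)."""
    return top_pattern(record.all_terms(), kb)
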