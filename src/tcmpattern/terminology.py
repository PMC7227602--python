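"""Terminology standardization: map raw term variants to canonical vocabulary.

Raw records carry free-text symptom/sign terms. A thesaurus maps each known
variant to a (canonical term, category) pair; lookup is exact after a light
normalization (trim, case-fold, collapse internal whitespace). Unmapped terms
are recorded, never fatal — they let a user extend the thesaurus.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .vocab import CATEGORIES, DEFAULT_FEATURE_CATALOG, SYNONYMS

_WS = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Trim, case-fold and collapse internal whitespace."""
    return _WS.sub(" ", raw.strip().casefold())


@dataclass
class Thesaurus:
    """Exact-match lookup from normalized variant to (canonical, category).

    Every canonical term maps to itself; a variant maps to exactly one
    canonical; categories are restricted to the four fixed ones.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for variant, (canon, cat) in self.entries.items():
            if cat not in CATEGORIES:
                raise ValueError(f"{variant!r}: unknown category {cat!r}")
        # self-mapping invariant
        for canon, cat in set(self.entries.values()):
            key = normalize_term(canon)
            if key not in self.entries:
                self.entries[key] = (canon, cat)

    @property
    def canonical_set(self) -> set[tuple[str, str]]:
        return set(self.entries.values())

    def add(self, variant: str, canonical: str, category: str) -> None:
        key = normalize_term(variant)
        existing = self.entries.get(key)
        if existing is not None and existing[0] != canonical:
            raise ValueError(
                f"variant {variant!r} already maps to {existing[0]!r}"
            )
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        self.entries[key] = (canonical, category)
        self.entries.setdefault(normalize_term(canonical), (canonical, category))

    def lookup(self, raw: str) -> tuple[str, str] | None:
        return self.entries.get(normalize_term(raw))

    def variants_of(self, canonical: str) -> list[str]:
        """All non-identity variants mapping to a canonical term."""
        canon_key = normalize_term(canonical)
        return [
            v for v, (c, _) in self.entries.items()
            if c == canonical and v != canon_key
        ]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["variant", "canonical", "category"])
            for variant in sorted(self.entries):
                canon, cat = self.entries[variant]
                w.writerow([variant, canon, cat])

    @classmethod
    def from_csv(cls, path) -> "Thesaurus":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[normalize_term(row["variant"])] = (
                    row["canonical"], row["category"],
                )
        return cls(entries)


def demo_thesaurus() -> Thesaurus:
    """The shipped ~60-entry demo lexicon: the canonical catalog plus the
    hand-curated synonym list."""
    th = Thesaurus()
    catalog = dict(DEFAULT_FEATURE_CATALOG)
    for term, cat in DEFAULT_FEATURE_CATALOG:
        th.add(term, term, cat)
    for variant, canonical in SYNONYMS.items():
        th.add(variant, canonical, catalog[canonical])
    return th


@dataclass(frozen=True)
class StandardizedRecord:
    """One case's canonical binary clinical features in the four categories."""

    case_id: str
    gender: str
    age: float | None
    symptoms: frozenset = frozenset()
    tongue_appearance: frozenset = frozenset()
    tongue_coating: frozenset = frozenset()
    pulse: frozenset = frozenset()
    unmapped: tuple = ()

    def terms_by_category(self) -> dict[str, frozenset]:
        return {
            "symptom": self.symptoms,
            "tongue_appearance": self.tongue_appearance,
            "tongue_coating": self.tongue_coating,
            "pulse": self.pulse,
        }

    def all_terms(self) -> set:
        return (
            set(self.symptoms) | set(self.tongue_appearance)
            | set(self.tongue_coating) | set(self.pulse)
        )


def standardize(record, thesaurus: Thesaurus) -> StandardizedRecord:
    """Standardize one raw record against a thesaurus.

    Each raw term is normalized and looked up; hits land in the category set
    the thesaurus assigns (duplicates collapse), misses are appended to
    ``unmapped`` in input order.
    """
    if not thesaurus.entries:
        raise ValueError("thesaurus is empty")
    sets: dict[str, set] = {c: set() for c in CATEGORIES}
    unmapped: list[str] = []
    for raw, _category in record.raw_terms:
        hit = thesaurus.lookup(raw)
        if hit is None:
            unmapped.append(raw)
        else:
            canon, cat = hit
            sets[cat].add(canon)
    return StandardizedRecord(
        case_id=record.case_id,
        gender=record.gender,
        age=record.age,
        symptoms=frozenset(sets["symptom"]),
        tongue_appearance=frozenset(sets["tongue_appearance"]),
        tongue_coating=frozenset(sets["tongue_coating"]),
        pulse=frozenset(sets["pulse"]),
        unmapped=tuple(unmapped),
    )


def filter_complete(records: Iterable[StandardizedRecord]) -> list[StandardizedRecord]:
    """Keep complete initial-visit records.

    A record survives if it has gender, age, and at least one canonical term
    in at least one category; only the first (earliest) record per case id is
    kept.
    """
    seen: set[str] = set()
    kept = []
    for r in records:
        if r.case_id in seen:
            continue
        seen.add(r.case_id)
        if not r.gender or r.age is None:
            continue
        if not r.all_terms():
            continue
        kept.append(r)
    return kept


def unmapped_term_counts(records: Iterable[StandardizedRecord]) -> Counter:
    """Counts of unmapped raw terms across records, for thesaurus curation."""
    counts: Counter = Counter()
    for r in records:
        counts.update(normalize_term(t) for t in r.unmapped)
    return counts
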