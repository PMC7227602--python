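"""P + Sx_n combination expansion and frequency-weighted pattern aggregation.

Every secondary feature of a cluster occurs there with a different frequency,
so each per-category SF list is disassembled into prefixes: Sx_n is the top-n
entries of cluster x's list, weighted by the frequency of the n-th (last)
entry. Each prefix joined with the primary features (P + Sx_n) is
differentiated to a pattern, and per cluster i the patterns are aggregated:

    f_ij          = mean anchor frequency of combinations assigned pattern j
    F_i           = sum over j of f_ij
    percentage_ij = f_ij / F_i

The overall ("ALL") table pools every cluster's combinations and re-aggregates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .pattern_engine import KnowledgeBase, UNDETERMINED, top_pattern
from .vocab import CATEGORIES


@dataclass(frozen=True)
class Combination:
    """P + Sx_n: primary features plus the top-n SF of one category in one
    cluster, weighted by the n-th SF term's frequency."""

    cluster: int
    category: str
    n: int
    terms: frozenset
    anchor_freq: float | None
    sf_terms: tuple

    @property
    def label(self) -> str:
        return f"P+S{self.cluster}_{self.n}({self.category})"


def _entry(item) -> tuple[str, float | None]:
    if isinstance(item, str):
        return item, None
    term, freq = item
    return term, float(freq)


def enumerate_combinations(
    pf: Iterable[str],
    sf: Mapping[int, Mapping[str, Sequence]],
    dedupe: bool = False,
) -> list[Combination]:
    """All P + Sx_n combinations: one per cluster, category and prefix length.

    SF entries may be (term, frequency) pairs or bare terms (frequency then
    unavailable; such combinations cannot be frequency-weighted). Lists are
    expanded as given; ``dedupe`` drops repeated terms within a list first
    (source tables may print a term twice). The total count equals the sum of
    SF list lengths.
    """
    pf_set = frozenset(pf)
    combos: list[Combination] = []
    for cluster in sorted(sf):
        by_cat = sf[cluster]
        for category in CATEGORIES:
            entries = [_entry(e) for e in by_cat.get(category, [])]
            if dedupe:
                seen: set[str] = set()
                entries = [
                    e for e in entries if not (e[0] in seen or seen.add(e[0]))
                ]
            for n in range(1, len(entries) + 1):
                prefix = entries[:n]
                combos.append(
                    Combination(
                        cluster=cluster,
                        category=category,
                        n=n,
                        terms=pf_set | {t for t, _ in prefix},
                        anchor_freq=prefix[-1][1],
                        sf_terms=tuple(t for t, _ in prefix),
                    )
                )
    if not combos:
        warnings.warn("no secondary features anywhere: empty combination list",
                      stacklevel=2)
    return combos


@dataclass(frozen=True)
class PatternAggregate:
    """Frequency-weighted pattern mix of one cluster (or the pooled "ALL")."""

    cluster: object  # cluster label, or "ALL"
    avg_frequency: dict[str, float]  # f_ij per pattern

    @property
    def total(self) -> float:  # F_i
        return sum(self.avg_frequency.values())

    @property
    def percentage(self) -> dict[str, float]:
        """Exact percentage_ij = f_ij / F_i, in percent."""
        return pattern_shares(self.avg_frequency)

    def percentage_rounded(self) -> dict[str, int]:
        return {p: round(v) for p, v in self.percentage.items()}


def pattern_shares(avg_frequency: Mapping[str, float]) -> dict[str, float]:
    """Normalize average pattern frequencies to percentages (exact)."""
    total = sum(avg_frequency.values())
    if total <= 0:
        raise ValueError("pattern frequencies sum to zero")
    return {p: 100.0 * f / total for p, f in avg_frequency.items()}


def aggregate_assigned(
    assigned: Sequence[tuple[Combination, str]]
) -> dict[object, PatternAggregate]:
    """Aggregate (combination, pattern) pairs per cluster plus pooled "ALL"."""
    out: dict[object, PatternAggregate] = {}
    groups: dict[object, list[tuple[Combination, str]]] = {"ALL": list(assigned)}
    for combo, pat in assigned:
        groups.setdefault(combo.cluster, []).append((combo, pat))
    for key, pairs in groups.items():
        freqs: dict[str, list[float]] = {}
        for combo, pat in pairs:
            if combo.anchor_freq is None:
                raise ValueError(
                    f"{combo.label}: no anchor frequency; cannot weight"
                )
            freqs.setdefault(pat, []).append(combo.anchor_freq)
        out[key] = PatternAggregate(
            cluster=key,
            avg_frequency={p: sum(v) / len(v) for p, v in sorted(freqs.items())},
        )
    return out


def aggregate(
    combinations: Sequence[Combination], kb: KnowledgeBase
) -> tuple[dict[object, PatternAggregate], list[tuple[Combination, str]]]:
    """Differentiate every combination and aggregate per cluster and overall.

    Returns (aggregates keyed by cluster label and "ALL", the per-combination
    pattern assignments for audit). Combinations matching no code are counted
    under the UNDETERMINED sentinel.
    """
    assigned = [(c, top_pattern(c.terms, kb)) for c in combinations]
    return aggregate_assigned(assigned), assigned
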