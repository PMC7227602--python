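"""Herbal prescription consumption ranking and therapeutic-category totals.

Prescriptions (single herbs or multi-herb formulas) are compared by total
consumption in grams — the number of person-days a medication was prescribed
multiplied by its average daily dose — and then aggregated by therapeutic
effect to give each principle's share of overall consumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PrescriptionRecord:
    """One herb or formula with its consumption and therapeutic category.

    Consumption is accepted either precomputed (``total_consumption`` in
    grams) or as ``person_days`` x ``avg_daily_dose``; at least one route
    must be supplied.
    """

    name: str
    kind: str  # "single_herb" | "formula"
    category: str
    person_days: float | None = None
    avg_daily_dose: float | None = None
    total_consumption: float | None = None
    label_as_printed: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in ("single_herb", "formula"):
            raise ValueError(f"unknown prescription kind: {self.kind!r}")
        if self.total_consumption is None:
            if self.person_days is None or self.avg_daily_dose is None:
                raise ValueError(
                    f"{self.name}: need total_consumption or both "
                    "person_days and avg_daily_dose"
                )
            if self.person_days <= 0 or self.avg_daily_dose <= 0:
                raise ValueError(f"{self.name}: person-days and dose must be positive")
            self.total_consumption = self.person_days * self.avg_daily_dose
        if self.total_consumption <= 0:
            raise ValueError(f"{self.name}: total consumption must be positive")


@dataclass(frozen=True)
class CategorySummary:
    """Total grams consumed under one therapeutic principle and its share."""

    category: str
    total: float
    share: float  # percent of grand total, exact (unrounded)

    @property
    def share_rounded(self) -> int:
        return round(self.share)


def rank_prescriptions(
    records: list[PrescriptionRecord],
    kind: str | None = None,
    top_k: int | None = 10,
) -> list[PrescriptionRecord]:
    """Rank prescriptions by descending total consumption, ties by name.

    ``kind`` restricts to ``"single_herb"`` or ``"formula"``; ``top_k=None``
    returns the full ranking.
    """
    if not records:
        raise ValueError("no prescription records")
    pool = [r for r in records if kind is None or r.kind == kind]
    pool.sort(key=lambda r: (-r.total_consumption, r.name))
    return pool if top_k is None else pool[:top_k]


def summarize_categories(records: list[PrescriptionRecord]) -> list[CategorySummary]:
    """Total consumption and percentage share per therapeutic category.

    Shares are exact (they sum to 100 before rounding); display rounding to
    whole percent is available via :attr:`CategorySummary.share_rounded`.
    Raises if any record lacks a category, listing the offending names.
    """
    uncategorized = [r.name for r in records if not r.category]
    if uncategorized:
        raise ValueError(f"uncategorized prescriptions: {uncategorized}")
    totals: dict[str, float] = {}
    for r in records:
        totals[r.category] = totals.get(r.category, 0.0) + r.total_consumption
    grand = sum(totals.values())
    summaries = [
        CategorySummary(category=c, total=t, share=100.0 * t / grand)
        for c, t in totals.items()
    ]
    summaries.sort(key=lambda s: (-s.total, s.category))
    return summaries
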