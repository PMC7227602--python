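"""KPI-based variable selection for clustering.

Every variable is a yes/no indicator. The KPI is a coefficient-of-variation
statistic: kpi = sqrt(n_yes / n_no), which equals the standard deviation of
the complement indicator divided by its mean. Higher values mark more evenly
split (more informative) variables. Candidate variables must appear in more
than 5% of cases, which bounds the admissible KPI below by
sqrt(0.05/0.95) ~= 0.2294. The selection threshold is swept upward from the
minimum observed KPI in steps of 0.01; the best threshold is the one whose
clustering yields the most primary features (ties go to the smallest
threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .clustering import BinaryFeatureMatrix

#: Frequency floor for admissible variables ("more than 5%").
FREQUENCY_FLOOR = 0.05


def kpi(n_yes: int, n_no: int, variant: str = "complement") -> float:
    """Evenness KPI of a binary variable from its yes/no counts.

    ``variant="complement"`` (default) is sqrt(n_yes/n_no): the sd/mean of
    the no-indicator, increasing in the yes-frequency so the 5% frequency
    floor translates to a kpi floor of sqrt(.05/.95)=0.2294.
    ``variant="literal"`` is the sd/mean of the yes-indicator,
    sqrt(n_no/n_yes).
    """
    if n_yes < 1 or n_no < 1:
        raise ValueError("kpi needs at least one case on each side")
    if variant == "complement":
        return math.sqrt(n_yes / n_no)
    if variant == "literal":
        return math.sqrt(n_no / n_yes)
    raise ValueError(f"unknown kpi variant {variant!r}")


@dataclass(frozen=True)
class KpiRecord:
    variable: str
    category: str
    n_yes: int
    n_no: int

    @property
    def frequency(self) -> float:
        return self.n_yes / (self.n_yes + self.n_no)

    def kpi(self, variant: str = "complement") -> float:
        return kpi(self.n_yes, self.n_no, variant=variant)


def kpi_table(
    matrix: BinaryFeatureMatrix, variant: str = "complement"
) -> list[KpiRecord]:
    """Per-variable yes/no counts, frequency and KPI for a cohort matrix."""
    n = len(matrix.case_ids)
    out = []
    for j, (term, cat) in enumerate(matrix.variables):
        n_yes = int(matrix.values[:, j].sum())
        out.append(KpiRecord(variable=term, category=cat, n_yes=n_yes, n_no=n - n_yes))
    return out


def select_variables(
    matrix: BinaryFeatureMatrix,
    threshold: float,
    variant: str = "complement",
    frequency_floor: float = FREQUENCY_FLOOR,
) -> list[tuple[str, str]]:
    """Variables with frequency above the floor and KPI >= threshold."""
    selected = []
    for rec in kpi_table(matrix, variant=variant):
        if rec.frequency > frequency_floor and rec.kpi(variant) >= threshold:
            selected.append((rec.variable, rec.category))
    return selected


@dataclass
class SweepResult:
    threshold: float
    selected_variables: list[tuple[str, str]]
    n_pf: int
    cluster_model: object  # ClusterModel of the winning threshold
    log: list[tuple[float, int, int]]  # (threshold, n_selected, n_pf)


def sweep(
    matrix: BinaryFeatureMatrix,
    clusterer: Callable[[BinaryFeatureMatrix], object],
    pf_rule: Callable[[BinaryFeatureMatrix, object], Sequence],
    step: float = 0.01,
    variant: str = "complement",
    frequency_floor: float = FREQUENCY_FLOOR,
) -> SweepResult:
    """Sweep KPI thresholds; return the one maximizing the PF count.

    The grid starts at the minimum KPI among variables passing the frequency
    floor and rises by ``step`` while at least two variables remain selected.
    ``clusterer`` maps a (subset) matrix to a cluster model; ``pf_rule`` maps
    (matrix, model) to the primary-feature set. Ties in PF count go to the
    smallest threshold; the full grid log is returned for audit.
    """
    table = [
        r for r in kpi_table(matrix, variant=variant)
        if r.frequency > frequency_floor
    ]
    if len(table) < 2:
        raise ValueError("fewer than two variables pass the frequency floor")
    kpis = sorted(r.kpi(variant) for r in table)
    start, stop = kpis[0], kpis[-1]
    thresholds = np.arange(start, stop + step / 2, step)

    best: SweepResult | None = None
    log: list[tuple[float, int, int]] = []
    for thr in thresholds:
        selected = select_variables(
            matrix, float(thr), variant=variant, frequency_floor=frequency_floor
        )
        if len(selected) < 2:
            break
        sub = matrix.subset(selected)
        try:
            model = clusterer(sub)
        except ValueError:
            # selection shrank below what the clusterer can split (e.g. fewer
            # distinct rows than clusters); higher thresholds only shrink it
            # further, so the grid ends here
            break
        n_pf = len(pf_rule(sub, model))
        log.append((float(thr), len(selected), n_pf))
        if best is None or n_pf > best.n_pf:
            best = SweepResult(
                threshold=float(thr),
                selected_variables=selected,
                n_pf=n_pf,
                cluster_model=model,
                log=log,
            )
    if best is None:
        raise ValueError("no threshold leaves at least two variables")
    best.log = log
    return best
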