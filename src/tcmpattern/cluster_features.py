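"""Primary/secondary feature classification across clusters.

A variable is a primary feature (PF) when it carries similar weight in every
cluster: either its yes-frequency shows no statistically significant
difference across clusters (chi-square homogeneity test) while its overall
frequency exceeds 5%, or it differs significantly but keeps a stable
within-category frequency rank everywhere (rank spread no more than 10 for
symptoms; 3 for tongue appearance and pulse; 5 for tongue coating) with more
than 5% frequency in every cluster. The remaining variables with at least 5%
within-cluster frequency form each cluster's per-category secondary-feature
(SF) list, ordered by descending frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .clustering import BinaryFeatureMatrix, ClusterModel
from .vocab import CATEGORIES

#: Maximum allowed spread between a variable's best and worst within-category
#: rank across clusters for the rank-stability PF arm.
DEFAULT_RANK_GAPS: dict[str, int] = {
    "symptom": 10,
    "tongue_appearance": 3,
    "pulse": 3,
    "tongue_coating": 5,
}

DEFAULT_ALPHA = 0.05
FREQUENCY_FLOOR = 0.05
_FREQ_DECIMALS = 4  # "more than 5%" judged on frequency rounded to 4 decimals


@dataclass(frozen=True)
class FeatureSummary:
    variable: str
    category: str
    per_cluster_freq: dict[int, float]
    per_cluster_rank: dict[int, int]
    overall_freq: float
    chi2_p: float


def homogeneity_test(yes_by_cluster: Mapping[int, int],
                     n_by_cluster: Mapping[int, int]) -> float:
    """Chi-square homogeneity p-value for a clusters x {yes,no} table.

    A table with identical proportions gives statistic 0 and p = 1. Raises
    when a margin is empty (all-yes or all-no overall), where the test is
    undefined.
    """
    clusters = sorted(n_by_cluster)
    if len(clusters) < 2:
        raise ValueError("homogeneity test needs at least two clusters")
    table = np.array(
        [[yes_by_cluster.get(c, 0), n_by_cluster[c] - yes_by_cluster.get(c, 0)]
         for c in clusters]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: empty margin")
    _, p, _, _ = chi2_contingency(table, correction=False)
    return float(p)


def summarize_features(
    matrix: BinaryFeatureMatrix, model: ClusterModel
) -> list[FeatureSummary]:
    """Per-variable per-cluster frequency, rank and homogeneity p-value.

    Ranks are within (cluster, category), 1 = most frequent, assigned by
    descending frequency with lexicographic tie-break. A variable absent from
    a cluster ranks one past the number of present variables, so it fails
    rank-gap criteria naturally.
    """
    labels = model.labels(matrix.case_ids)
    clusters = sorted(set(labels.tolist()))
    n_by_cluster = {c: int((labels == c).sum()) for c in clusters}
    n_total = len(matrix.case_ids)

    freq: dict[tuple[str, str], dict[int, float]] = {}
    yes: dict[tuple[str, str], dict[int, int]] = {}
    for j, var in enumerate(matrix.variables):
        col = matrix.values[:, j]
        yes[var] = {c: int(col[labels == c].sum()) for c in clusters}
        freq[var] = {c: yes[var][c] / n_by_cluster[c] for c in clusters}

    # dense 1..n ranks per (cluster, category) over variables present there
    rank: dict[tuple[str, str], dict[int, int]] = {v: {} for v in matrix.variables}
    for cat in CATEGORIES:
        cat_vars = [v for v in matrix.variables if v[1] == cat]
        for c in clusters:
            present = [v for v in cat_vars if freq[v][c] > 0]
            present.sort(key=lambda v: (-freq[v][c], v[0]))
            for pos, v in enumerate(present, start=1):
                rank[v][c] = pos
            for v in cat_vars:
                rank[v].setdefault(c, len(present) + 1)

    out = []
    for j, (term, cat) in enumerate(matrix.variables):
        var = (term, cat)
        out.append(
            FeatureSummary(
                variable=term,
                category=cat,
                per_cluster_freq=freq[var],
                per_cluster_rank=rank[var],
                overall_freq=sum(yes[var].values()) / n_total,
                chi2_p=homogeneity_test(yes[var], n_by_cluster),
            )
        )
    return out


def _above_floor(f: float, floor: float = FREQUENCY_FLOOR) -> bool:
    return round(f, _FREQ_DECIMALS) >= floor


def classify_pf(
    summaries: Sequence[FeatureSummary],
    alpha: float = DEFAULT_ALPHA,
    rank_gaps: Mapping[str, int] = DEFAULT_RANK_GAPS,
) -> set[str]:
    """Primary features: homogeneous-and-common, or rank-stable everywhere."""
    pf: set[str] = set()
    for s in summaries:
        if s.chi2_p >= alpha:
            if _above_floor(s.overall_freq):
                pf.add(s.variable)
        else:
            ranks = list(s.per_cluster_rank.values())
            gap_ok = max(ranks) - min(ranks) <= rank_gaps[s.category]
            freq_ok = all(_above_floor(f) for f in s.per_cluster_freq.values())
            if gap_ok and freq_ok:
                pf.add(s.variable)
    return pf


def classify_sf(
    summaries: Sequence[FeatureSummary],
    pf: set[str],
    frequency_floor: float = FREQUENCY_FLOOR,
) -> dict[int, dict[str, list[tuple[str, float]]]]:
    """Per-cluster, per-category SF lists: non-PF variables at >=5%
    within-cluster frequency, ordered by descending frequency (ties broken
    lexicographically)."""
    clusters = sorted(
        {c for s in summaries for c in s.per_cluster_freq}
    )
    sf: dict[int, dict[str, list[tuple[str, float]]]] = {
        c: {cat: [] for cat in CATEGORIES} for c in clusters
    }
    for s in summaries:
        if s.variable in pf:
            continue
        for c, f in s.per_cluster_freq.items():
            if _above_floor(f, frequency_floor):
                sf[c][s.category].append((s.variable, f))
    for c in clusters:
        for cat in CATEGORIES:
            sf[c][cat].sort(key=lambda vf: (-vf[1], vf[0]))
    return sf
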