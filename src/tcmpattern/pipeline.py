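"""End-to-end orchestration of the five-stage analysis.

Stages: (1) terminology standardization, (2) elbow cluster-count choice and
KPI threshold sweep, (3) primary/secondary feature classification, (4)
P + Sx_n combination expansion with pattern aggregation, (5) herbal
prescription category comparison. Every stage writes its tabular output under
the configured directory, and a manifest records the seed and parameters so
any output is re-derivable from the manifest alone.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .aggregation import aggregate, enumerate_combinations
from .cluster_features import (
    DEFAULT_ALPHA, DEFAULT_RANK_GAPS, classify_pf, classify_sf,
    summarize_features,
)
from .clustering import build_feature_matrix, choose_k, kmeans
from .feature_selection import FREQUENCY_FLOOR, kpi_table, sweep
from .herbal import rank_prescriptions, summarize_categories
from .pattern_engine import KnowledgeBase, score_case
from .synthetic import (
    GeneratorConfig, generate_cohort, generate_knowledge_base,
    generate_prescriptions, read_cohort_csv, read_prescriptions_csv,
    write_cohort_csv, write_prescriptions_csv,
)
from .terminology import (
    Thesaurus, demo_thesaurus, filter_complete, standardize,
    unmapped_term_counts,
)
from .vocab import CATEGORIES

log = logging.getLogger("tcmpattern")


@dataclass
class PipelineConfig:
    outdir: str = "tcmpattern-run"
    seed: int = 0
    n_cases: int = 2000
    # optional external inputs; generated synthetically when None
    cohort_path: str | None = None
    thesaurus_path: str | None = None
    kb_path: str | None = None
    prescriptions_path: str | None = None
    # analysis parameters
    k_range: tuple = (2, 8)
    drop_threshold: float = 0.10
    restarts: int = 25
    alpha: float = DEFAULT_ALPHA
    frequency_floor: float = FREQUENCY_FLOOR
    kpi_step: float = 0.01
    kpi_variant: str = "complement"
    rank_gaps: dict = field(default_factory=lambda: dict(DEFAULT_RANK_GAPS))

    def __post_init__(self) -> None:
        if not (0 < self.drop_threshold < 1 and 0 < self.alpha < 1
                and 0 <= self.frequency_floor < 1 and self.kpi_step > 0):
            raise ValueError("numeric parameter out of range")
        for path in (self.cohort_path, self.thesaurus_path,
                     self.kb_path, self.prescriptions_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"missing input: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


@dataclass
class PipelineResult:
    outdir: Path
    n_raw: int
    n_complete: int
    k: int
    wss_by_k: dict
    best_kpi: float
    selected_variables: list
    pf: set
    sf: dict
    n_combinations: int
    aggregates: dict
    herb_categories: list


def _write_csv(path: Path, header, rows) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage; returns the in-memory results and writes all tables."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if config.cohort_path:
        raw = read_cohort_csv(config.cohort_path)
    else:
        gen = GeneratorConfig(n_cases=config.n_cases, seed=config.seed)
        raw = generate_cohort(gen)
        write_cohort_csv(raw, out / "cohort.csv", out / "cohort_labels.csv")
    thesaurus = (
        Thesaurus.from_csv(config.thesaurus_path)
        if config.thesaurus_path else demo_thesaurus()
    )
    kb = (
        KnowledgeBase.from_json(config.kb_path)
        if config.kb_path else generate_knowledge_base()
    )
    prescriptions = (
        read_prescriptions_csv(config.prescriptions_path)
        if config.prescriptions_path
        else generate_prescriptions(seed=config.seed)
    )
    log.info("inputs: %d raw records", len(raw))

    # --- stage 1: standardization ----------------------------------------
    standardized = [standardize(r, thesaurus) for r in raw]
    complete = filter_complete(standardized)
    log.info("standardized: %d complete of %d", len(complete), len(standardized))
    _write_csv(
        out / "standardized.csv",
        ["case_id", "gender", "age", *CATEGORIES, "unmapped"],
        [
            [r.case_id, r.gender, r.age]
            + ["|".join(sorted(r.terms_by_category()[c])) for c in CATEGORIES]
            + ["|".join(r.unmapped)]
            for r in complete
        ],
    )
    _write_csv(
        out / "unmapped_terms.csv", ["term", "count"],
        sorted(unmapped_term_counts(standardized).items()),
    )

    # per-case pattern differentiation
    diag_rows = []
    for r in complete:
        ranked = score_case(r.all_terms(), kb)
        top, second = ranked[0], ranked[1]
        top_id = top.pattern_id if top.score > 0 else "undetermined"
        diag_rows.append(
            [r.case_id, top_id, f"{top.score:.6f}",
             second.pattern_id, f"{top.score - second.score:.6f}"]
        )
    _write_csv(out / "diagnoses.csv",
               ["case_id", "top_pattern", "score", "second_pattern", "margin"],
               diag_rows)

    # --- stage 2: cluster count, KPI sweep, clustering --------------------
    matrix = build_feature_matrix(complete)
    k, wss = choose_k(
        matrix, range(config.k_range[0], config.k_range[1] + 1),
        drop_threshold=config.drop_threshold, seed=config.seed,
        restarts=config.restarts,
    )
    log.info("elbow selected k=%d", k)
    _write_csv(out / "elbow.csv", ["k", "total_wss"],
               [[kk, f"{w:.6f}"] for kk, w in sorted(wss.items())])
    _write_csv(
        out / "kpi_table.csv",
        ["variable", "category", "n_yes", "n_no", "frequency", "kpi"],
        [
            [r.variable, r.category, r.n_yes, r.n_no,
             f"{r.frequency:.6f}", f"{r.kpi(config.kpi_variant):.6f}"]
            for r in kpi_table(matrix, variant=config.kpi_variant)
        ],
    )

    def clusterer(m):
        return kmeans(m, k, seed=config.seed, restarts=config.restarts)

    def pf_rule(m, model):
        return classify_pf(
            summarize_features(m, model),
            alpha=config.alpha, rank_gaps=config.rank_gaps,
        )

    best = sweep(
        matrix, clusterer, pf_rule,
        step=config.kpi_step, variant=config.kpi_variant,
        frequency_floor=config.frequency_floor,
    )
    log.info("best KPI threshold %.4f: %d variables, %d PF",
             best.threshold, len(best.selected_variables), best.n_pf)
    _write_csv(out / "kpi_sweep.csv", ["threshold", "n_selected", "n_pf"],
               [[f"{t:.4f}", ns, np_] for t, ns, np_ in best.log])
    model = best.cluster_model
    sub = matrix.subset(best.selected_variables)
    _write_csv(out / "assignments.csv", ["case_id", "cluster"],
               sorted(model.assignments.items()))

    # --- stage 3: PF / SF --------------------------------------------------
    summaries = summarize_features(sub, model)
    pf = classify_pf(summaries, alpha=config.alpha, rank_gaps=config.rank_gaps)
    sf = classify_sf(summaries, pf, frequency_floor=config.frequency_floor)
    with open(out / "pf_sf.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "pf": sorted(pf),
                "clusters": {
                    str(c): {
                        cat: [[t, round(f, 6)] for t, f in lst]
                        for cat, lst in by_cat.items()
                    }
                    for c, by_cat in sf.items()
                },
            },
            fh, indent=1,
        )

    # --- stage 4: combinations and pattern aggregation ---------------------
    combos = enumerate_combinations(pf, sf)
    aggregates, assigned = aggregate(combos, kb)
    log.info("%d P+Sx_n combinations", len(combos))
    with open(out / "combinations.json", "w", encoding="utf-8") as fh:
        json.dump(
            [
                {"label": c.label, "cluster": c.cluster, "category": c.category,
                 "n": c.n, "anchor_freq": c.anchor_freq,
                 "sf_terms": list(c.sf_terms), "pattern": pat}
                for c, pat in assigned
            ],
            fh, indent=1,
        )
    agg_rows = []
    for key in ["ALL"] + sorted(kk for kk in aggregates if kk != "ALL"):
        agg = aggregates[key]
        pct = agg.percentage
        for pat in sorted(agg.avg_frequency, key=lambda p: -agg.avg_frequency[p]):
            agg_rows.append(
                [key, pat, f"{agg.avg_frequency[pat]:.6f}", f"{pct[pat]:.4f}"]
            )
    _write_csv(out / "pattern_aggregates.csv",
               ["cluster", "pattern", "avg_frequency", "percentage"], agg_rows)

    # --- stage 5: herbal prescriptions -------------------------------------
    if not config.prescriptions_path:
        write_prescriptions_csv(prescriptions, out / "prescriptions.csv")
    ranked = rank_prescriptions(prescriptions, kind=None, top_k=None)
    _write_csv(out / "herb_ranking.csv",
               ["name", "kind", "total_consumption", "category"],
               [[r.name, r.kind, f"{r.total_consumption:.1f}", r.category]
                for r in ranked])
    categories = summarize_categories(prescriptions)
    _write_csv(out / "herb_categories.csv",
               ["category", "total_g", "share_pct"],
               [[s.category, f"{s.total:.1f}", s.share_rounded]
                for s in categories])

    # --- manifest and summary ----------------------------------------------
    manifest = {"version": __version__, "config": asdict(config)}
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    top_all = max(
        aggregates["ALL"].avg_frequency,
        key=lambda p: aggregates["ALL"].percentage[p],
    )
    summary = [
        f"records: {len(raw)} raw, {len(complete)} complete",
        f"clusters: k={k} (elbow on WSS curve)",
        f"best KPI threshold: {best.threshold:.4f} "
        f"({len(best.selected_variables)} variables, {best.n_pf} PF)",
        f"primary features: {', '.join(sorted(pf))}",
        f"combinations: {len(combos)}",
        f"leading overall pattern: {top_all} "
        f"({aggregates['ALL'].percentage[top_all]:.0f}%)",
        f"top therapeutic category: {categories[0].category} "
        f"({categories[0].share_rounded}%)",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n", encoding="utf-8")

    return PipelineResult(
        outdir=out,
        n_raw=len(raw),
        n_complete=len(complete),
        k=k,
        wss_by_k=wss,
        best_kpi=best.threshold,
        selected_variables=best.selected_variables,
        pf=pf,
        sf=sf,
        n_combinations=len(combos),
        aggregates=aggregates,
        herb_categories=categories,
    )
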