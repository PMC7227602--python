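"""Synthetic EMR cohort, knowledge base and prescription generators.

Real TCM outpatient records are rarely shareable, so every pipeline input can
be generated here: raw visit records with planted cluster structure, a demo
thesaurus already provided by :mod:`tcmpattern.terminology`, a toy pattern
knowledge base, and a prescription table.

The cohort is a finite Bernoulli mixture: each case belongs to one of five
latent subgroups, and each binary clinical feature is present independently
with the subgroup's profile probability. Twelve shared features (the
primary-feature analogue) keep a common, cohort-wide marginal taken from the
published frequency table; the remaining features are split into per-subgroup
signature sets that are frequent (0.80) inside their subgroup and rare (0.05)
elsewhere — a well-separated regime in which k-means is expected to recover
the planted labels. True labels are carried outside the pipeline input and
used only for validation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .pattern_engine import KnowledgeBase
from .herbal import PrescriptionRecord
from .vocab import CATEGORIES, DEFAULT_FEATURE_CATALOG, SYNONYMS

# ---------------------------------------------------------------------------
# default mixture: marginals and signature structure

#: Cohort-wide presence probability of the shared (PF-analogue) features.
SHARED_FEATURE_MARGINALS: dict[str, float] = {
    "insomnia": 0.387,
    "dry mouth": 0.315,
    "lack of strength": 0.171,
    "dizziness": 0.144,
    "loss of appetite": 0.138,
    "abdominal distention": 0.100,
    "bitter taste of mouth": 0.085,
    "headache": 0.069,
    "loose stool": 0.070,
    "nausea": 0.066,
    "slippery pulse": 0.190,
    "rapid pulse": 0.120,
}

#: Per-subgroup signature features (disjoint across subgroups). Smaller
#: subgroups get more signature features so that every pair of subgroups is
#: separated well enough for the planted five-group structure to register as
#: an elbow in the within-cluster sum-of-squares curve.
CLUSTER_SIGNATURES: dict[int, tuple[str, ...]] = {
    0: ("profuse dreaming", "pale red tongue", "slimy coating",
        "sunken pulse"),
    1: ("absence of thirst", "acid regurgitation", "nocturia",
        "afraid of cold", "red tongue", "dry tongue", "white coating",
        "string-like pulse"),
    2: ("lumbago", "soreness", "teeth-marked tongue", "thin coating",
        "fine pulse"),
    3: ("back pain", "dry eyes", "dark red tongue",
        "thin and white coating", "weak pulse"),
    4: ("cough", "abdominal pain", "enlarged tongue", "thick coating",
        "moderate pulse", "rough pulse", "floating pulse"),
}

SIGNATURE_PRESENT = 0.80
SIGNATURE_ABSENT = 0.05

#: Subgroup mixing weights, proportional to the published cluster sizes.
DEFAULT_CLUSTER_WEIGHTS = (975 / 2738, 290 / 2738, 634 / 2738,
                           501 / 2738, 338 / 2738)


def default_profiles(
    feature_catalog=DEFAULT_FEATURE_CATALOG, n_clusters: int = 5
) -> np.ndarray:
    """n_clusters x n_features presence-probability matrix (default mixture)."""
    profiles = np.full((n_clusters, len(feature_catalog)), SIGNATURE_ABSENT)
    for j, (term, _cat) in enumerate(feature_catalog):
        if term in SHARED_FEATURE_MARGINALS:
            profiles[:, j] = SHARED_FEATURE_MARGINALS[term]
        else:
            for c in range(n_clusters):
                if term in CLUSTER_SIGNATURES.get(c, ()):
                    profiles[c, j] = SIGNATURE_PRESENT
    return profiles


@dataclass
class GeneratorConfig:
    """Cohort generator settings; defaults give the well-separated 5-subgroup
    mixture described in the module docstring."""

    n_cases: int = 2000
    n_clusters: int = 5
    cluster_weights: tuple = DEFAULT_CLUSTER_WEIGHTS
    feature_catalog: tuple = DEFAULT_FEATURE_CATALOG
    bernoulli_profiles: np.ndarray | None = None
    synonym_rate: float = 0.15
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_clusters < 1:
            raise ValueError("n_cases and n_clusters must be positive")
        w = np.asarray(self.cluster_weights, dtype=float)
        if w.shape != (self.n_clusters,):
            raise ValueError("cluster_weights length must equal n_clusters")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_weights must be a probability vector")
        if self.bernoulli_profiles is None:
            self.bernoulli_profiles = default_profiles(
                self.feature_catalog, self.n_clusters
            )
        self.bernoulli_profiles = np.asarray(self.bernoulli_profiles, dtype=float)
        expected = (self.n_clusters, len(self.feature_catalog))
        if self.bernoulli_profiles.shape != expected:
            raise ValueError(f"profiles must have shape {expected}")
        for p, name in ((self.bernoulli_profiles, "profiles"),
                        (np.array([self.synonym_rate, self.missing_rate]), "rates")):
            if (np.asarray(p) < 0).any() or (np.asarray(p) > 1).any():
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class RawRecord:
    """One raw visit record; ``true_cluster`` is held out from the pipeline."""

    case_id: str
    gender: str
    age: float
    raw_terms: list = field(default_factory=list)  # (free-text term, category)
    true_cluster: int = 0


#: Inverse synonym map: canonical term -> its free-text variants.
_VARIANTS: dict[str, list[str]] = {}
for _v, _c in SYNONYMS.items():
    _VARIANTS.setdefault(_c, []).append(_v)


def _emit_term(term: str, rng: np.random.Generator) -> str:
    """A raw surface form: hand-list synonym or a decorated spelling."""
    options = list(_VARIANTS.get(term, ()))
    options += [term.upper(), f"  {term} ", term.title()]
    return options[rng.integers(len(options))]


def generate_cohort(config: GeneratorConfig) -> list[RawRecord]:
    """Draw the cohort; deterministic for a fixed config seed.

    Feature presence is Bernoulli per the profile row of the case's sampled
    subgroup; with probability ``synonym_rate`` a present term is emitted as
    a raw variant instead of its canonical spelling; with probability
    ``missing_rate`` one whole category is dropped from the record.
    """
    rng = np.random.default_rng(config.seed)
    clusters = rng.choice(
        config.n_clusters, size=config.n_cases, p=np.asarray(config.cluster_weights)
    )
    records = []
    width = len(str(config.n_cases))
    for i in range(config.n_cases):
        c = int(clusters[i])
        present = rng.random(len(config.feature_catalog)) < config.bernoulli_profiles[c]
        raw_terms = []
        for j, (term, cat) in enumerate(config.feature_catalog):
            if not present[j]:
                continue
            emitted = (
                _emit_term(term, rng)
                if rng.random() < config.synonym_rate else term
            )
            raw_terms.append((emitted, cat))
        if rng.random() < config.missing_rate and raw_terms:
            dropped = CATEGORIES[rng.integers(len(CATEGORIES))]
            raw_terms = [(t, cat) for t, cat in raw_terms if cat != dropped]
        gender = "F" if rng.random() < 0.99 else "M"
        age = float(np.clip(round(rng.normal(52.0, 10.0)), 20, 90))
        records.append(
            RawRecord(
                case_id=f"case-{i + 1:0{width}d}",
                gender=gender,
                age=age,
                raw_terms=raw_terms,
                true_cluster=c,
            )
        )
    return records


def write_cohort_csv(records, path, labels_path=None) -> None:
    """Cohort CSV (pipe-joined raw terms per category) and an optional side
    file with the held-out true labels."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["case_id", "gender", "age", *CATEGORIES])
        for r in records:
            by_cat = {c: [] for c in CATEGORIES}
            for term, cat in r.raw_terms:
                by_cat[cat].append(term)
            w.writerow(
                [r.case_id, r.gender, r.age]
                + ["|".join(by_cat[c]) for c in CATEGORIES]
            )
    if labels_path is not None:
        with open(labels_path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["case_id", "true_cluster"])
            for r in records:
                w.writerow([r.case_id, r.true_cluster])


def read_cohort_csv(path) -> list[RawRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            raw_terms = []
            for cat in CATEGORIES:
                raw_terms.extend(
                    (t, cat) for t in row[cat].split("|") if t
                )
            records.append(
                RawRecord(
                    case_id=row["case_id"],
                    gender=row["gender"],
                    age=float(row["age"]),
                    raw_terms=raw_terms,
                    true_cluster=-1,
                )
            )
    return records


# ---------------------------------------------------------------------------
# knowledge base

#: Hand-authored demo pattern documents over the canonical catalog, following
#: standard pattern semantics (e.g. liver-gallbladder dampness-heat is marked
#: by bitter taste, slimy/thick coating, slippery and rapid pulse).
DEFAULT_PATTERN_DOCS: dict[str, dict[str, int]] = {
    "LGDH": {  # liver-gallbladder dampness-heat
        "bitter taste of mouth": 3, "slippery pulse": 3, "rapid pulse": 3,
        "slimy coating": 3, "dry mouth": 2, "red tongue": 2,
        "thick coating": 2, "string-like pulse": 2, "nausea": 1,
        "headache": 1, "insomnia": 1, "dark red tongue": 1,
    },
    "DLTF": {  # depressed liver qi transforming into fire
        "insomnia": 3, "red tongue": 3, "string-like pulse": 3,
        "profuse dreaming": 2, "bitter taste of mouth": 2, "headache": 2,
        "dry eyes": 2, "rapid pulse": 2, "acid regurgitation": 1,
        "dry tongue": 1, "dizziness": 1,
    },
    "RDT": {  # retained dampness-toxin
        "slimy coating": 3, "thick coating": 3, "dark red tongue": 2,
        "nausea": 2, "loss of appetite": 2, "abdominal distention": 2,
        "slippery pulse": 2, "soreness": 1, "enlarged tongue": 1,
    },
    "LKYD": {  # liver-kidney yin deficiency
        "lumbago": 3, "fine pulse": 3, "dry eyes": 2, "dry mouth": 2,
        "dizziness": 2, "nocturia": 2, "dry tongue": 2, "red tongue": 1,
        "rapid pulse": 1, "soreness": 1, "back pain": 1, "cough": 1,
    },
    "LDSD": {  # liver depression and spleen deficiency
        "abdominal distention": 3, "loose stool": 3, "string-like pulse": 2,
        "loss of appetite": 2, "lack of strength": 2, "teeth-marked tongue": 2,
        "weak pulse": 1, "pale red tongue": 1, "thin coating": 1,
        "abdominal pain": 1, "thin and white coating": 1,
    },
    "SSQD": {  # spleen-stomach qi deficiency
        "lack of strength": 3, "loss of appetite": 3, "weak pulse": 3,
        "loose stool": 2, "pale red tongue": 2, "teeth-marked tongue": 2,
        "abdominal distention": 1, "nausea": 1, "enlarged tongue": 1,
        "moderate pulse": 1, "white coating": 1, "absence of thirst": 1,
        "afraid of cold": 1,
    },
    "RDH": {  # retained dampness-heat
        "slimy coating": 3, "slippery pulse": 3, "thick coating": 2,
        "red tongue": 1, "rapid pulse": 1, "loose stool": 1,
        "abdominal distention": 1, "nausea": 1, "headache": 1,
        "floating pulse": 1,
    },
    "QDBS": {  # qi deficiency with blood stasis
        "lack of strength": 3, "dark red tongue": 3, "rough pulse": 3,
        "soreness": 2, "fine pulse": 1, "lumbago": 1, "back pain": 1,
        "dizziness": 1, "sunken pulse": 1,
    },
}


def generate_knowledge_base(
    patterns=None,
    feature_catalog=DEFAULT_FEATURE_CATALOG,
    seed: int = 0,
    terms_per_pattern: int = 10,
) -> KnowledgeBase:
    """Demo knowledge base.

    With no ``patterns`` argument the hand-authored eight-pattern library is
    returned. A custom pattern list gets random documents: each pattern draws
    ``terms_per_pattern`` characteristic terms (counts 1-3) and every catalog
    term is guaranteed to land in at least one document. Deterministic for a
    fixed seed.
    """
    if patterns is None:
        return KnowledgeBase(DEFAULT_PATTERN_DOCS)
    patterns = list(patterns)
    if len(patterns) < 2:
        raise ValueError("need at least two patterns")
    terms = [t for t, _ in feature_catalog]
    if terms_per_pattern < 3:
        raise ValueError("each pattern needs at least three characteristic terms")
    rng = np.random.default_rng(seed)
    docs: dict[str, dict[str, int]] = {}
    for pid in patterns:
        chosen = rng.choice(len(terms), size=min(terms_per_pattern, len(terms)),
                            replace=False)
        docs[pid] = {terms[j]: int(rng.integers(1, 4)) for j in chosen}
    covered = {t for d in docs.values() for t in d}
    for t in terms:
        if t not in covered:
            pid = patterns[int(rng.integers(len(patterns)))]
            docs[pid][t] = 1
    return KnowledgeBase(docs)


# ---------------------------------------------------------------------------
# prescriptions

_HERB_POOL = [
    ("Herba A", "single_herb"), ("Herba B", "single_herb"),
    ("Radix C", "single_herb"), ("Radix D", "single_herb"),
    ("Fructus E", "single_herb"), ("Rhizoma F", "single_herb"),
    ("Formula G", "formula"), ("Formula H", "formula"),
    ("Formula I", "formula"), ("Formula J", "formula"),
    ("Formula K", "formula"), ("Formula L", "formula"),
]

_CATEGORY_POOL = [
    "Clear heat, drain dampness and detoxify",
    "Harmonize the liver and spleen",
    "Tonify qi",
    "Nourish the heart to tranquilize",
    "Activate blood and resolve stasis",
    "Tonify yin",
]


def generate_prescriptions(seed: int = 0, n: int = 12) -> list[PrescriptionRecord]:
    """Random prescription table: >=10 records, both kinds, >=4 categories,
    positive person-days and daily dose. Deterministic for a fixed seed.

    For the published top-10 table itself use
    :func:`tcmpattern.reference.reference_prescriptions`.
    """
    n = max(n, 10)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        name, kind = _HERB_POOL[i % len(_HERB_POOL)]
        category = _CATEGORY_POOL[i % len(_CATEGORY_POOL)]
        records.append(
            PrescriptionRecord(
                name=name if i < len(_HERB_POOL) else f"{name} #{i}",
                kind=kind,
                category=category,
                person_days=float(rng.integers(100, 20000)),
                avg_daily_dose=float(np.round(rng.uniform(1.0, 15.0), 1)),
            )
        )
    return records


def write_prescriptions_csv(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "kind", "person_days", "avg_daily_dose",
                    "total_consumption", "category"])
        for r in records:
            w.writerow([r.name, r.kind,
                        "" if r.person_days is None else r.person_days,
                        "" if r.avg_daily_dose is None else r.avg_daily_dose,
                        r.total_consumption, r.category])


def read_prescriptions_csv(path) -> list[PrescriptionRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                PrescriptionRecord(
                    name=row["name"],
                    kind=row["kind"],
                    category=row["category"],
                    person_days=float(row["person_days"]) if row["person_days"] else None,
                    avg_daily_dose=(
                        float(row["avg_daily_dose"]) if row["avg_daily_dose"] else None
                    ),
                    total_consumption=(
                        float(row["total_consumption"])
                        if row["total_consumption"] else None
                    ),
                )
            )
    return records
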