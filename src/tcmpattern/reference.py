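"""Published reference tables for the breast-cancer TCM cohort.

These are the printed summary tables of the source study (N = 2,738 complete
initial-visit records from a single medical center): term frequencies, the
primary-feature (PF) list and per-cluster secondary-feature (SF) lists, the
per-cluster average pattern frequencies, and the top-10 herbal prescriptions.
They serve as inputs for the arithmetic the pipeline re-derives (frequency
percentages, the P+Sx_n combination count, pattern shares, and therapeutic
category totals) and as regression fixtures for the analysis modules.
"""

from __future__ import annotations

from .herbal import PrescriptionRecord

#: Cohort size behind the frequency tables.
COHORT_N = 2738

#: Term -> case count among the 2,738 records (top-20 symptoms, top-5 signs).
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "symptom": {
        "insomnia": 1060,
        "dry mouth": 863,
        "lack of strength": 467,
        "dizziness": 395,
        "loss of appetite": 377,
        "abdominal distention": 273,
        "profuse dreaming": 266,
        "bitter taste of mouth": 234,
        "lumbago": 231,
        "back pain": 199,
        "afraid of cold": 194,
        "loose stool": 192,
        "headache": 189,
        "nausea": 181,
        "absence of thirst": 175,
        "cough": 175,
        "acid regurgitation": 170,
        "soreness": 143,
        "nocturia": 139,
        "dry eyes": 136,
    },
    "tongue_appearance": {
        "pale red tongue": 516,
        "red tongue": 460,
        "teeth-marked tongue": 241,
        "dark red tongue": 137,
        "dry tongue": 120,
    },
    "tongue_coating": {
        "white coating": 1163,
        "thin coating": 804,
        "thin and white coating": 634,
        "slimy coating": 368,
        "thick coating": 213,
    },
    "pulse": {
        "string-like pulse": 865,
        "slippery pulse": 520,
        "fine pulse": 443,
        "weak pulse": 369,
        "sunken pulse": 333,
    },
}

#: The twelve primary features shared across all five clusters.
PRIMARY_FEATURES: tuple[str, ...] = (
    "insomnia",
    "dry mouth",
    "lack of strength",
    "dizziness",
    "loss of appetite",
    "bitter taste of mouth",
    "abdominal distention",
    "headache",
    "loose stool",
    "nausea",
    "slippery pulse",
    "rapid pulse",
)

#: Cases per cluster (amount of people, clusters 1..5).
CLUSTER_SIZES: dict[int, int] = {1: 975, 2: 290, 3: 634, 4: 501, 5: 338}

#: Secondary features per cluster and category, ordered by within-cluster
#: frequency as printed. The cluster-5 pulse list contains "fine pulse" twice
#: as printed in the source table; the published 87-combination total counts
#: entries as printed (86 after deduplication).
SECONDARY_FEATURES: dict[int, dict[str, list[str]]] = {
    1: {
        "symptom": [
            "profuse dreaming", "lumbago", "afraid of cold", "backache",
            "acid regurgitation", "nocturia", "cough", "soreness",
        ],
        "pulse": ["sunken pulse", "weak pulse", "fine pulse"],
        "tongue_appearance": ["pale red tongue"],
        "tongue_coating": ["slimy coating", "thin coating"],
    },
    2: {
        "symptom": [
            "profuse dreaming", "nocturia", "afraid of cold",
            "absence of thirst", "acid regurgitation",
        ],
        "pulse": [
            "string-like pulse", "sunken pulse", "weak pulse", "fine pulse",
        ],
        "tongue_appearance": ["red tongue", "dry tongue"],
        "tongue_coating": [
            "slimy coating", "thin coating", "white coating", "thick coating",
        ],
    },
    3: {
        "symptom": [
            "profuse dreaming", "lumbago", "absence of thirst", "soreness",
            "backache", "acid regurgitation", "abdominal pain", "cough",
        ],
        "pulse": [
            "string-like pulse", "fine pulse", "weak pulse", "moderate pulse",
            "sunken pulse", "rough pulse",
        ],
        "tongue_appearance": [
            "pale red tongue", "red tongue", "teeth-marked tongue",
            "dark red tongue", "dry tongue", "enlarged tongue",
        ],
        "tongue_coating": ["thin coating"],
    },
    4: {
        "symptom": [
            "lumbago", "backache", "soreness", "profuse dreaming",
            "dry eyes", "afraid of cold", "cough",
        ],
        "pulse": [
            "string-like pulse", "fine pulse", "weak pulse", "sunken pulse",
            "rough pulse", "floating pulse",
        ],
        "tongue_appearance": [
            "pale red tongue", "teeth-marked tongue", "red tongue",
            "dark red tongue",
        ],
        "tongue_coating": ["white coating", "slimy coating", "thin coating"],
    },
    5: {
        "symptom": [
            "absence of thirst", "cough", "lumbago", "backache",
            "afraid of cold",
        ],
        "pulse": [
            "moderate pulse", "sunken pulse", "fine pulse", "weak pulse",
            "fine pulse", "rough pulse",
        ],
        "tongue_appearance": [
            "pale red tongue", "teeth-marked tongue", "red tongue",
        ],
        "tongue_coating": ["white coating", "thick coating", "slimy coating"],
    },
}

#: The eight pattern codes of the study.
PATTERN_CODES = ("LGDH", "DLTF", "RDT", "LKYD", "LDSD", "SSQD", "RDH", "QDBS")

#: Printed average pattern frequency per cluster (fractions of 1; the source
#: prints percents). Keys: cluster label 1..5 plus "ALL" pooled.
PATTERN_AVG_FREQUENCIES: dict[object, dict[str, float]] = {
    "ALL": {"LGDH": 0.85, "DLTF": 0.38, "RDT": 0.22, "LKYD": 0.11,
            "LDSD": 0.11, "SSQD": 0.11, "RDH": 0.10, "QDBS": 0.07},
    1: {"DLTF": 0.12, "RDH": 0.10, "LDSD": 0.08, "SSQD": 0.04},
    2: {"LGDH": 0.70, "DLTF": 0.22, "LDSD": 0.09},
    3: {"DLTF": 0.71, "LDSD": 0.13, "LKYD": 0.06, "QDBS": 0.06},
    4: {"LGDH": 0.99, "DLTF": 0.33, "LDSD": 0.15, "LKYD": 0.12, "QDBS": 0.08},
    5: {"LGDH": 0.99, "RDT": 0.22, "SSQD": 0.17, "LDSD": 0.10, "QDBS": 0.06},
}

# Top-10 single herbs and formulas with total consumption in grams
# (person-days x average daily dose) and therapeutic-effect category.
# The Zizyphus jujuba row is printed as "Nourish the yin to tranquilize";
# the published category totals only balance when it is pooled with
# "Nourish the heart to tranquilize", so the mapped category does that and
# the printed label is preserved alongside.
_TABLE4_ROWS = [
    # (name, kind, total_g, category as printed)
    ("Hedyotis diffusa Willd.", "single_herb", 553153.5,
     "Clear heat, drain dampness and detoxify"),
    ("Scutellaria barbata D. Don", "single_herb", 498634.0,
     "Clear heat, drain dampness and detoxify"),
    ("Taraxacum mongolicum Hand.-Mazz.", "single_herb", 442880.6,
     "Clear heat, drain dampness and detoxify"),
    ("Spatholobus suberectus Dunn", "single_herb", 277550.5,
     "Activate blood and resolve stasis"),
    ("Zizyphus jujuba Mill var. spinosa", "single_herb", 236498.7,
     "Nourish the yin to tranquilize"),
    ("Salvia miltiorrhiza Bge.", "single_herb", 220686.4,
     "Activate blood and resolve stasis"),
    ("Astragalus membranaceus (Fisch.) Bunge", "single_herb", 209072.8,
     "Tonify qi"),
    ("Polygonum multiflorum Thunb.", "single_herb", 154919.8,
     "Nourish the heart to tranquilize"),
    ("Fritillaria thunbergii Miq.", "single_herb", 148233.0,
     "Clear heat and resolve phlegm"),
    ("Rheum palmatum L.", "single_herb", 66898.8, "Offensive purgative"),
    ("Jia-Wei-Xiao-Yao-San", "formula", 1604612.1,
     "Harmonize the liver and spleen"),
    ("San-Zhong-Kui-Jian-Tang", "formula", 523792.8,
     "Clear heat, drain dampness and detoxify"),
    ("Xue-Fu-Zhu-Yu-Tang", "formula", 517921.8,
     "Activate blood and resolve stasis"),
    ("Xiang-Sha-Liu-Jun-Zi-Tang", "formula", 517717.2, "Tonify qi"),
    ("Gui-Pi-Tang", "formula", 464660.0, "Nourish the heart to tranquilize"),
    ("Bu-Zhong-Yi-Qi-Tang", "formula", 403355.6, "Tonify qi"),
    ("Suan-Zao-Ren-Tang", "formula", 402041.9,
     "Nourish the heart to tranquilize"),
    ("Zhen-Ren-Huo-Ming-Yin", "formula", 388555.2,
     "Clear heat, drain dampness and detoxify"),
    ("Zhi-Bai-Di-Huang-Wan", "formula", 367875.0, "Tonify yin"),
    ("Sheng-Mai-Yin", "formula", 336522.3, "Tonify qi"),
]

#: Printed labels that are pooled into a different category for aggregation.
CATEGORY_POOLING = {
    "Nourish the yin to tranquilize": "Nourish the heart to tranquilize",
}


def reference_prescriptions(pool_categories: bool = True) -> list[PrescriptionRecord]:
    """The top-10 herbs and top-10 formulas with total consumption in grams.

    With ``pool_categories`` (default), printed category labels listed in
    :data:`CATEGORY_POOLING` are mapped to the category the published
    therapeutic-effect totals aggregate them under.
    """
    records = []
    for name, kind, total, label in _TABLE4_ROWS:
        category = CATEGORY_POOLING.get(label, label) if pool_categories else label
        records.append(
            PrescriptionRecord(
                name=name, kind=kind, category=category,
                total_consumption=total, label_as_printed=label,
            )
        )
    return records
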