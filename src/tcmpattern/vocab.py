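"""Canonical clinical vocabulary for the demo pipeline.

The four feature categories follow TCM practice: patient-reported symptoms,
and three practitioner-observed sign categories (tongue appearance, tongue
coating, pulse quality). The catalog covers the vocabulary of the published
frequency tables for the breast-cancer cohort plus the handful of extra signs
that appear only in the per-cluster secondary-feature lists.
"""

from __future__ import annotations

CATEGORIES = ("symptom", "tongue_appearance", "tongue_coating", "pulse")

SYMPTOMS = (
    "insomnia",
    "dry mouth",
    "lack of strength",
    "dizziness",
    "loss of appetite",
    "abdominal distention",
    "profuse dreaming",
    "bitter taste of mouth",
    "lumbago",
    "back pain",
    "afraid of cold",
    "loose stool",
    "headache",
    "nausea",
    "absence of thirst",
    "cough",
    "acid regurgitation",
    "soreness",
    "nocturia",
    "dry eyes",
    "abdominal pain",
)

TONGUE_APPEARANCES = (
    "pale red tongue",
    "red tongue",
    "teeth-marked tongue",
    "dark red tongue",
    "dry tongue",
    "enlarged tongue",
)

TONGUE_COATINGS = (
    "white coating",
    "thin coating",
    "thin and white coating",
    "slimy coating",
    "thick coating",
)

PULSES = (
    "string-like pulse",
    "slippery pulse",
    "fine pulse",
    "weak pulse",
    "sunken pulse",
    "rapid pulse",
    "moderate pulse",
    "rough pulse",
    "floating pulse",
)

#: Every canonical (term, category) pair the demo pipeline knows about.
DEFAULT_FEATURE_CATALOG: tuple[tuple[str, str], ...] = (
    tuple((t, "symptom") for t in SYMPTOMS)
    + tuple((t, "tongue_appearance") for t in TONGUE_APPEARANCES)
    + tuple((t, "tongue_coating") for t in TONGUE_COATINGS)
    + tuple((t, "pulse") for t in PULSES)
)

#: Hand-curated synonym list: raw variant -> canonical term. The real-world
#: equivalent is a proprietary 20,000-term thesaurus; this demo list covers
#: common English variants of the catalog vocabulary.
SYNONYMS: dict[str, str] = {
    "xerostomia": "dry mouth",
    "thirsty mouth": "dry mouth",
    "sleeplessness": "insomnia",
    "difficulty sleeping": "insomnia",
    "fatigue": "lack of strength",
    "weakness": "lack of strength",
    "tiredness": "lack of strength",
    "vertigo": "dizziness",
    "light-headedness": "dizziness",
    "poor appetite": "loss of appetite",
    "anorexia": "loss of appetite",
    "bloating": "abdominal distention",
    "abdominal fullness": "abdominal distention",
    "frequent dreams": "profuse dreaming",
    "dream-disturbed sleep": "profuse dreaming",
    "bitter taste": "bitter taste of mouth",
    "low back pain": "lumbago",
    "backache": "back pain",
    "chills": "afraid of cold",
    "aversion to cold": "afraid of cold",
    "diarrhea": "loose stool",
    "soft stool": "loose stool",
    "cephalalgia": "headache",
    "queasiness": "nausea",
    "no desire to drink": "absence of thirst",
    "acid reflux": "acid regurgitation",
    "heartburn": "acid regurgitation",
    "body aches": "soreness",
    "night urination": "nocturia",
    "ocular dryness": "dry eyes",
    "stomach ache": "abdominal pain",
    "wiry pulse": "string-like pulse",
    "taut pulse": "string-like pulse",
    "thready pulse": "fine pulse",
    "deep pulse": "sunken pulse",
    "fast pulse": "rapid pulse",
    "choppy pulse": "rough pulse",
    "greasy coating": "slimy coating",
    "scalloped tongue": "teeth-marked tongue",
    "crimson tongue": "dark red tongue",
    "swollen tongue": "enlarged tongue",
}


def category_of(term: str) -> str:
    """Category of a canonical catalog term; KeyError if unknown."""
    for t, c in DEFAULT_FEATURE_CATALOG:
        if t == term:
            return c
    raise KeyError(term)
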