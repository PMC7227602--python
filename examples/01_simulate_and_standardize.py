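"""Generate a synthetic outpatient cohort and standardize its terminology.

The generator plants a 5-subgroup Bernoulli mixture over ~40 binary clinical
features and emits some terms as raw variants ("xerostomia", "WIRY PULSE").
Standardization maps every variant back to the canonical vocabulary.
"""

from tcmpattern import (
    GeneratorConfig, demo_thesaurus, filter_complete, generate_cohort,
    standardize,
)

config = GeneratorConfig(n_cases=500, seed=42)
raw = generate_cohort(config)
thesaurus = demo_thesaurus()
records = filter_complete([standardize(r, thesaurus) for r in raw])

print(f"raw records:       {len(raw)}")
print(f"complete records:  {len(records)}")
example = next(r for r in raw if any(t != t.lower().strip() for t, _ in r.raw_terms))
std = standardize(example, thesaurus)
print(f"\ncase {example.case_id} raw terms:   {[t for t, _ in example.raw_terms]}")
print(f"case {example.case_id} standardized: {sorted(std.all_terms())}")
# Every raw surface form (synonym, odd casing, stray spaces) has been mapped
# to one canonical term per category; records lacking gender, age or any
# term would have been dropped as incomplete.
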