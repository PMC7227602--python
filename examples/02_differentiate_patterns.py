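"""Score a case's terms against the demo pattern knowledge base.

Each of the eight TCM pattern codes is a bag of characteristic terms. A case
is scored per code by summing tf*idf over shared terms; the top code is the
differentiated pattern.
"""

from tcmpattern import generate_knowledge_base, score_case, term_frequency, idf_smooth

kb = generate_knowledge_base()  # the hand-authored 8-pattern demo library

terms = {"bitter taste of mouth", "slimy coating", "slippery pulse",
         "rapid pulse", "insomnia"}
print(f"case terms: {sorted(terms)}\n")
for ps in score_case(terms, kb)[:4]:
    print(f"  {ps.pattern_id}: score={ps.score:.4f} "
          f"matched={sorted(ps.matched_terms)}")

# The top pattern is the differentiation result; the margin to the runner-up
# indicates how decisive the evidence is. Individual weights are exposed:
t = "bitter taste of mouth"
print(f"\ntf({t!r} | LGDH) = {term_frequency(t, kb.codes['LGDH']):.4f}")
print(f"idf({t!r})        = {idf_smooth(t, kb):.4f}  (ln(1 + N/n_t))")
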