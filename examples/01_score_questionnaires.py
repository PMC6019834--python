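"""Score CAT/CCQ/SGRQ-style questionnaires and standardise to 0-100.

Builds item responses by hand, scores them under each instrument's
rule, and shows the common 0-100 standardisation that makes change
scores comparable across instruments.
"""
from mcidkit import CAT, CCQ, score_instrument, standardize, synthetic_sgrq

# CAT: 8 items 0-5, total = sum (0-40)
cat = score_instrument(CAT, {0: 3, 1: 2, 2: 4, 3: 1, 4: 3, 5: 2, 6: 3, 7: 2})
print(f"CAT total {cat.total:.0f}/40  -> standardized {cat.standardized:.1f}")

# CCQ: 10 items 0-6, total = mean of items, with named domains
ccq = score_instrument(CCQ, dict(enumerate([4, 4, 1, 1, 4, 4, 2, 2, 2, 2])))
print(f"CCQ total {ccq.total:.1f}/6   -> standardized {ccq.standardized:.1f}")
print(f"    domains: {ccq.domain_scores}")

# SGRQ-shaped weighted instrument (synthetic weights; the licensed
# weights would be loaded from config in a real analysis)
sgrq = synthetic_sgrq()
responses = {i: (1 if i % 3 == 0 else 0) for i in range(sgrq.n_items)}
rec = score_instrument(sgrq, responses)
print(f"SGRQ-like weighted total {rec.total:.1f}/100")

# a change score standardises linearly: the classic -3.1-point CAT
# improvement at discharge is -7.75 on the 0-100 scale
print(f"CAT change -3.1 -> standardized {standardize(CAT, -3.1):.2f}")
# Negative change = improvement on all three instruments.
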