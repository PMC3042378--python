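"""Decompose total effects into direct and mediated components.

Indirect effects along continuous-mediator pathways are products of the edge
coefficients; total effects sum the direct path and all quantifiable
products.  Sex-moderated paths resolve to female-reference or male
(reference + offset) coefficients.  Natural-unit conversions divide by the
predictor SD: exp(b/SD) is the odds ratio per measurement unit.
"""

from pthpath import (
    build_final_model,
    male_effect,
    reference_coefficients,
    reference_male_offsets,
    total_effect,
    unstandardize_linear,
    unstandardize_logistic,
)

model = build_final_model()
coeffs = reference_coefficients()
offsets = reference_male_offsets()

est = total_effect(model, coeffs, "phosphate", "PTH", male_offsets=offsets)
print("total effect of phosphate on PTH (standardized):")
print(f"  direct -0.26 + calcium route (-0.09)(0.27) = {est.value:.4f} ~ {est.value:.2f}")

est = total_effect(model, coeffs, "magnesium", "MS", male_offsets=offsets)
print("\ntotal effect of magnesium on MS (log-odds, women):")
print(f"  quantifiable part via PTH: {est.value:.4f}")
for p in est.excluded_pathways:
    print(f"  excluded: {p} (binary mediator - no meaningful product)")

print("\nmale coefficients on moderated MS paths (reference + offset):")
for pair in (("PTH", "MS"), ("phosphate", "MS")):
    m = male_effect(coeffs[pair], offsets[pair])
    print(f"  {pair[0]} -> MS: {coeffs[pair]:+.2f} {offsets[pair]:+.2f} = {m:+.2f}")

print("\nnatural-unit conversions (population SDs: PTH 2.3 pmol/l, age 12 y, vitD 22 nmol/l):")
print(f"  MS odds ratio per pmol/l PTH: {unstandardize_logistic(coeffs[('PTH','MS')], 2.3):.2f}")
print(f"  MS odds ratio per year of age: {unstandardize_logistic(coeffs[('age','MS')], 12):.2f}")
print(f"  PTH change per nmol/l vitD: {unstandardize_linear(coeffs[('vitD','PTH')], 22, 2.3):.3f} pmol/l")
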