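"""Build the hypothesized and final path models and enumerate mediation routes.

The path model links metabolic syndrome (MS) to seven explanatory variables
— age, type 2 diabetes, PTH, vitamin D, magnesium, calcium, phosphate — with
parathyroid hormone (PTH) as the hypothesized mediator.  Each endogenous
node (MS, PTH, calcium, T2DM) carries one regression equation.
"""

from pthpath import build_final_model, build_initial_model, enumerate_pathways, validate_model

initial = build_initial_model()
final = build_final_model()

print("initial model:", len(initial.edges), "edges,",
      len(initial.endogenous), "equations; valid:", validate_model(initial).ok)
print("final model:  ", len(final.edges), "edges;",
      "sex-moderated paths:", ", ".join(str(e) for e in final.moderated_edges))

print("\nhow phosphate reaches PTH (direct plus a calcium-mediated route):")
for p in enumerate_pathways(final, "phosphate", "PTH"):
    print(f"  {p}  quantifiable={p.quantifiable}")

print("\nhow magnesium reaches MS:")
for p in enumerate_pathways(final, "magnesium", "MS"):
    note = "" if p.quantifiable else "  (binary mediator: coefficients cannot be multiplied)"
    print(f"  {p}  quantifiable={p.quantifiable}{note}")
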