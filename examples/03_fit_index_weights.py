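"""Learn tier weights from synthetic carts and build the 0-100 index.

Generates compositions calibrated to the study conditions, fits the three
estimators (ridge with BIC penalty, ridge with cross-validated penalty,
OLS), and transforms the best fit into the three-weight index formula.
"""
from cfni import CompositionParams, fit_model, generate_compositions, to_index_formula

comp = generate_compositions(CompositionParams(seed=7))
hei = comp.rename(columns={"hei": "total"})[["cart_id", "total"]]

print(f"{'method':18s} {'%green':>8s} {'%red':>8s} {'constant':>9s} {'lambda':>9s}")
for method in ("model1", "model2", "model3"):
    m = fit_model(comp, hei, method, seed=7)
    print(f"{m.method:18s} {m.coef_green:8.3f} {m.coef_red:8.3f} "
          f"{m.constant:9.2f} {m.penalty:9.3g}")

model = fit_model(comp, hei, "model1", seed=7)
f = to_index_formula(model)
print(
    f"\nindex = (({f.coef_green_3v:.4f}*G + {f.coef_yellow_3v:.4f}*Y "
    f"+ {f.coef_red_3v:.4f}*R) - {f.offset:.2f}) / {f.scale:.2f} * 100"
)
# Ridge shrinks the green/red coefficients toward zero relative to OLS;
# the transform spreads the fitted constant over all three tiers and
# rescales so an all-green cart scores 100 and an all-red cart scores 0.
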