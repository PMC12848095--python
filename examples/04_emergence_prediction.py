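"""Predict which not-yet-observed karyotypes will emerge in the next passage.

Using the smooth-GRF fixture: the fitted landscape supplies candidate
karyotypes (those with fitness estimates that were never observed), features
are the landscape fitness f and the fractions d1..d5 of the current
population 1..5 missegregations away, and the label is whether the candidate
actually appears in the held-out future sample. A logistic model quantifies
which features predict emergence.
"""

from alfak import (
    InferenceConfig,
    emergence_features,
    fit_emergence_model,
    fit_landscape,
    generate_fixture,
)
from alfak.forecasting import distribution_from_counts

fx = generate_fixture("smooth_grf", seed=11)
config = InferenceConfig(min_obs=45, p=fx.manifest["sim"]["p"])
fitted = fit_landscape(fx.counts, config)

zeta = distribution_from_counts(fx.counts.tables[-1])
zeta = {k: v for k, v in zeta.items() if k in fitted.lut}  # observed, in Theta
psi = {k for k in fx.held_out if k in fitted.lut}  # present in the future

feats = emergence_features(fitted.lut, zeta, psi)
n_pos = sum(ft.emerged for ft in feats)
print(f"candidates (in the landscape, not yet observed): {len(feats)}; "
      f"{n_pos} of them emerge in the future sample")

model = fit_emergence_model(feats)
print("coefficient  estimate   Wald p")
for name in ("f", "d1", "d2", "d3", "d4", "d5"):
    print(f"   {name:<8} {model.coefficients[name]: 9.3f}   "
          f"{model.p_values[name]:.3g}")
print("a positive, significant d1 coefficient says candidates adjacent to "
      "abundant clones emerge preferentially; a positive f coefficient says "
      "the fitness estimate itself carries predictive signal")
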