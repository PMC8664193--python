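"""Model socio-spatial disparities in access with NB2 regression.

Fits the disparity models for RT: the base model, the model with a
rural x older-adults interaction, and the model restricted to the 5th
(most underserviced) quintile.
"""

from ehc_access import (
    ModelSpec,
    RegionConfig,
    TimeConstants,
    areas_frame,
    fit_disparity_models,
    generate_region,
)
from ehc_access.pipeline import compute_access

region = generate_region(RegionConfig(seed=1))
access = compute_access(region, TimeConstants())
areas = areas_frame(region.areas)

for spec in (ModelSpec("rt"), ModelSpec("rt", with_interaction=True),
             ModelSpec("rt", subset="quintile5")):
    res = fit_disparity_models(areas, access, spec)
    print(f"\n=== {res.label}  (n={res.n}, alpha={res.alpha:.3f}, "
          f"AIC={res.aic:.1f}, BIC={res.bic:.1f}) ===")
    print(res.frame().round(4).to_string(index=False))
# Coefficients are on the log scale: exp(estimate) multiplies expected
# waiting minutes. A positive rural estimate means rural areas wait
# longer even after adjusting for demographics; has_station < 0 means
# areas whose municipality hosts a station are reached faster.
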