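"""Generate a synthetic study region and inspect its structure.

Builds a seeded region at the default study conditions — a 100 km square
with 500 DeSO-like analysis areas, 24 ambulance stations and 5 emergency
departments — and prints how its municipalities and areas were classified.
"""

from collections import Counter

from ehc_access import RegionConfig, generate_region, write_region

config = RegionConfig(seed=1)
region = generate_region(config)

print(f"network: {region.network.n_nodes} junctions, {region.network.n_edges} road segments")
print(f"facilities: {len(region.stations)} stations, {len(region.hospitals)} emergency departments")
print(f"total population: {region.truth['total_population']:,.0f}")

types = Counter(a.area_type for a in region.areas)
print("area types:", dict(types))
# The mix should resemble a mixed urban/rural region: roughly a quarter of
# areas urban, half densely populated and a fifth rural.

cov = region.covariate_frame()
print(cov.groupby("area_type")[["older_share", "high_edu_share", "median_income"]]
      .mean().round(3))
# Rural areas carry older populations and lower education/income -- the
# gradient the disparity models later try to detect.

paths = write_region(region, "scratch/example_region")
print(f"wrote {len(paths)} files to scratch/example_region/")
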