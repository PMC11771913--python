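"""Simulate a synthetic older-driver crash table with known ground truth.

Two crash hotspots are planted in a 10 km x 10 km study area, covariates
follow the coded category structure of the Nevada older-driver summary,
and the binary injury outcome is drawn from a spatial lag probit latent
field with rho = 0.5.
"""

import crashspat as cs

config = cs.SyntheticConfig(
    hotspots=[cs.Hotspot(2000, 2000, 150, 150),
              cs.Hotspot(7000, 6500, 150, 150)],
    background_count=400,
    bounding_box=(0, 0, 10_000, 10_000),
    rho=0.5,
    seed=11,
)

table, truth = cs.generate_crash_table(config)

print(f"records: {len(table)}")
print(f"columns: {list(table.columns)}")
print(f"injury share: {table['severity'].mean():.3f}  "
      "(fraction of crashes with injury or fatality)")
print(f"true rho: {truth.true_rho}  (spatial dependence of the latent field)")
print(f"planted hotspot sizes: "
      f"{[(truth.true_cluster == i).sum() for i in range(2)]}")
print()
print(table.head().to_string())
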