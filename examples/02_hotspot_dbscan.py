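"""Identify crash hotspots by density clustering with a parameter sweep.

Runs DBSCAN over the simulated crash locations for a grid of radii (eps)
and density thresholds (min_pts) — the calibration protocol for choosing
hotspot parameters — then clusters at one chosen setting and reports the
convex-hull footprint of each hotspot.
"""

import crashspat as cs

config = cs.SyntheticConfig(
    hotspots=[cs.Hotspot(2000, 2000, 150, 150),
              cs.Hotspot(7000, 6500, 150, 150)],
    background_count=400,
    bounding_box=(0, 0, 10_000, 10_000),
    rho=0.0, seed=11,
)
table, truth = cs.generate_crash_table(config)
points = cs.PointSet.from_dataframe(table)

sweep = cs.sensitivity_sweep(points, eps_values=[100.0, 150.0, 200.0],
                             min_pts_values=[5, 10, 15])
print("sensitivity sweep (one DBSCAN run per cell):")
print(sweep.to_string(index=False))
print()

result = cs.dbscan(points, cs.DBSCANParams(eps=150.0, min_pts=10))
print(f"chosen (eps=150, min_pts=10): {result.n_clusters} hotspot(s), "
      f"{result.core_count} core points, {result.noise_count} noise points")
for hull in cs.cluster_hulls(points, result):
    print(f"  hotspot {hull.cluster_id}: {hull.member_count} crashes, "
          f"hull area {hull.area:,.0f} square units"
          + ("  [degenerate]" if hull.degenerate else ""))
print()
print("Each hotspot is a maximal density-connected set of crash points; "
      "the hull is its polygon footprint for mapping.")
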