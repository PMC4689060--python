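"""Ego-centered network-distance neighborhoods for one residence.

The home is privacy-blurred, snapped to the nearest street edge, and the
network reachable within each of the six study distances is cut at exact
residual lengths and buffered into the neighborhood polygon A with area
ν(A).
"""

import moveability as mv

cfg = mv.CityConfig(seed=7)
network = mv.generate_street_network(cfg)
density = mv.generate_density_raster(cfg)

home = (1400.0, 1100.0)
blurred = mv.blur_residence(home, density, mv.BlurSpec(seed=3), cfg.window)
print(f"home {home} -> blurred ({blurred[0]:.0f}, {blurred[1]:.0f}) "
      f"[displacement {((blurred[0]-home[0])**2 + (blurred[1]-home[1])**2)**0.5:.0f} m]")

snap = mv.snap_to_network(blurred, network)
print(f"snapped to edge {snap.edge_id} at {snap.snap_distance_m:.0f} m")

open_space = mv.generate_point_layer("open_space", density, network, cfg)
print(f"{'distance':>9s} {'reached km':>10s} {'area km²':>9s} "
      f"{'simple /km²':>11s} {'R_A /km²':>9s}")
for d in (500, 750, 1000, 1250, 1500, 2000):
    sa = mv.service_area(network, snap, d, buffer_m=25.0)
    simple = mv.simple_intensity(open_space, sa.polygon)
    R_A = mv.residential_density_in(sa, density)
    print(f"{d:7d} m {sa.reached_length_m / 1000:10.2f} {sa.area_km2:9.3f} "
          f"{simple:11.1f} {R_A:9.0f}")

# Reached length, polygon area and R_A all grow with distance; the simple
# intensity (count per area) is noisiest in the smallest neighborhood.
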