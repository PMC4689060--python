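"""Generate a synthetic study region and look at what it contains.

The city is a street lattice with random edge dropout, an elliptical
residential-density gradient, and three point layers of urban
characteristics: intersections (street nodes of degree ≥ 3), public
transit stations and public open spaces, the latter two placed
proportionally to residential density.
"""

import moveability as mv

cfg = mv.CityConfig(seed=7)
network = mv.generate_street_network(cfg)
density = mv.generate_density_raster(cfg)

print(f"window: {cfg.window_width_m:.0f} m x {cfg.window_height_m:.0f} m "
      f"({cfg.window.area_km2:.1f} km²)")
print(f"street network: {network.n_nodes} nodes, {network.n_edges} edges, "
      f"{network.total_length_m() / 1000:.1f} km of streets")
print(f"residents: {density.total_residents:.0f} "
      f"(density {density.values.min():.0f}-{density.values.max():.0f} /km²)")

for kind in ("intersections", "transit", "open_space"):
    layer = mv.generate_point_layer(kind, density, network, cfg)
    print(f"{kind:>14s}: {layer.n:4d} points "
          f"({layer.n / cfg.window.area_km2:.1f} per km²)")

# The per-km² figures are the city-wide simple intensities; the analysis
# pipeline evaluates the same quantities inside each child's own
# network-distance neighborhood instead.
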