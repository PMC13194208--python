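"""Measure the four fragmentation metrics inside a circular landscape.

Builds a small synthetic forest map, cuts a 250-m circular landscape
around its center, and prints the class metrics for that window.
"""

from forestfrag import compute_metrics, delineate_landscape, gen_fractal_landscape

# a 40x40 grid of 30-m cells (1.2 km on a side), 60% forest, aggregated
grid = gen_fractal_landscape(n=40, cell_size=30.0, p=0.6, roughness=2.0, seed=11)
window = delineate_landscape(grid, center=(600.0, 600.0), radius_m=250.0)
m = compute_metrics(window, connectivity=8)

print(f"landscape area:   {m.landscape_area_ha:7.2f} ha "
      f"({window.n_inside} cells inside the 250-m circle)")
print(f"forest proportion:{m.p_habitat:8.3f}")
print(f"patch number:     {m.n_patches:5d}")
print(f"edge density:     {m.edge_density:8.1f} m/ha")
print(f"mean patch size:  {m.mean_patch_size:8.3f} ha")

# The conservation identity ties the four measures together:
# patches x mean size == proportion x area.
lhs = m.n_patches * m.mean_patch_size
rhs = m.p_habitat * m.landscape_area_ha
print(f"conservation:     {lhs:.6f} ha == {rhs:.6f} ha")
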