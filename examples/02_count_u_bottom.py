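"""Cell counting in a U-bottom well via prolate-spheroid colony geometry.

In a U-shaped well (lower half of a prolate spheroid, top radius R = 750 µm,
depth c = 248 µm) settled cells pile into a central 3-D colony, so the count
comes from the colony volume rather than the projected area: the segmented
cluster areas are summed into one equivalent circular colony of radius r,
the colony height follows from the spheroid surface, and the volume is
divided by the single-cell volume (15 µm sphere, 1767.15 µm³).
"""

import math

import wellquant as wq

spec = wq.WellSpec(shape="u_bottom", top_radius_um=750.0, depth_um=248.0)
cell = wq.make_cell_model(15.0)
print(f"single cell: projected area {cell.projected_area_um2:.2f} µm², "
      f"volume {cell.volume_um3:.2f} µm³")

# a colony covering half the well radius (area = pi * 375^2)
estimate = wq.count_u_bottom([math.pi * 375.0**2], spec, cell)
print(f"colony radius r        = {estimate.r_um:.1f} µm")
print(f"gap height   h'        = {estimate.h_prime_um:.3f} µm")
print(f"colony height h        = {estimate.h_um:.3f} µm")
print(f"colony volume V_cells  = {estimate.v_cells_um3:.4g} µm³")
print(f"estimated cell count   = {estimate.n_cells_est:.0f}")

# the same area in a flat-bottom well would read as a monolayer:
flat_count = wq.count_flat(math.pi * 375.0**2, cell)
print(f"(the same area counted as a flat monolayer: {flat_count:.0f} cells — "
      "the U-bottom geometry accounts for cells stacked in depth)")
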