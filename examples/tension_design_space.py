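"""Map the membrane-tension design space for tip size versus cell size.

At the ~133.3 Pa operating suction, how close does an aspirated cell come
to the rupture-tension band (800-5000, median 3700) reported for clinical
tumor cells?  The sweep shows the whole practical tip range is far below
the minimum rupture threshold — the physical basis of the viability claim.
"""

import numpy as np

from sct import CellModel, assess_safety, design_grid, membrane_tension

DP = 133.3  # Pa, on/off operating suction

# scalar check: 2.0 um tip I.D. holding a 12 um cell
tau = membrane_tension(DP, 1e-6, 6e-6)
a = assess_safety(tau, CellModel(cell_radius=6e-6))
print(f"2.0 um tip, 12 um cell: tension = {tau:6.2f}  "
      f"[{a.classification}], margin to rupture min = {a.margin_to_min:.0f}")

grid = design_grid(DP)
print(f"\ngrid: tip I.D. {grid.tip_inner_diameters_um[0]}-"
      f"{grid.tip_inner_diameters_um[-1]} um x cell diameter "
      f"{grid.cell_diameters_um[0]}-{grid.cell_diameters_um[-1]} um")
print(f"max tension on grid : {grid.max_tension:7.1f}")
print(f"rupture minimum     :   800.0")
print(f"fraction safe       : {grid.fraction_safe:7.1%}")

print("\ntension matrix (rows = tip I.D. um, cols = cell diameter um):")
header = "      " + "".join(f"{c:7.0f}" for c in grid.cell_diameters_um)
print(header)
for tid, row in zip(grid.tip_inner_diameters_um[::4], grid.tension[::4]):
    cells = "".join("      -" if np.isnan(v) else f"{v:7.1f}" for v in row)
    print(f"{tid:5.2f} {cells}")
print("\nEvery admissible pairing sits below the 800 rupture minimum:")
print("aspiration at the on/off suction does not endanger the cell.")
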