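"""Virtual cross-section through a cracked shell, as cut through a CT-like stack.

After a growth run the deformed outer sheet is sampled along a straight cut
together with interpolated intermediate sheets; cracked outer sheets show
gaps of about one mesh spacing while the innermost sheets stay continuous
(the deeper, more hydrated stratum corneum does not crack).
"""

import numpy as np

from pachyshell.mesh import TriMesh, make_triangular_grid
from pachyshell.substrate import Substrate
from pachyshell.shell import ShellParams
from pachyshell.simulate import SimConfig, run_growth, virtual_section

spacing, amplitude = 2.0, 0.6
sub = Substrate(
    lambda xy: amplitude * np.cos(2 * np.pi * xy[:, 0] / spacing),
    amplitude=amplitude,
    fd_step=0.01,
)
grid = make_triangular_grid(23, 14, 0.18)
mesh = TriMesh(sub.project(grid.vertices), grid.faces)

result = run_growth(sub, mesh, ShellParams(), SimConfig(h_max=spacing / 6, break_target=0.02))

y_mid = mesh.vertices[:, 1].mean()
section = virtual_section(result, sub, ((0.2, y_mid), (3.8, y_mid)), n_sheets=5)

print(f"cut length: {section['s'][-1]:.2f} mm, {len(section['sheets'])} sheets")
print(f"crack gaps crossed by the cut: {len(section['gaps'])}")
for lo, hi in section["gaps"]:
    print(f"  gap from {lo:.2f} to {hi:.2f} mm (width {hi - lo:.2f} mm ~ mesh spacing)")
outer = section["sheets"][-1]
print(f"outer sheet: {np.isnan(outer).sum()} of {len(outer)} samples inside gaps")
print(f"innermost sheet continuous: {not np.isnan(section['sheets'][0]).any()}")
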