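"""PCA free-energy landscape of Cα fluctuations.

Superposes the frames of a hinge-driven synthetic ensemble, diagonalizes the
Cα covariance matrix, projects each frame onto the first two principal
components and converts bin populations to free energies,
G_i = -k_B T ln(N_i/N_m).  The hinge oscillation shows up as the dominant
eigenvalue; the landscape minimum (G = 0) marks the most visited state.
"""

import numpy as np

from lspnet import default_two_lobe_spec, generate_ensemble
from lspnet.pipeline import run_fel

spec = default_two_lobe_spec(seed=3, n_frames=400, stride_ns=0.1)  # 40 ns demo
ens = generate_ensemble(spec)
coords = np.stack([f.anchors for f in ens.frames])

result = run_fel(coords, bins=25, temperature_K=300.0)
ev = result.model.eigenvalues
print(f"leading eigenvalues (Å²): {ev[:4].round(2)}")
print(f"PC1 captures {100 * ev[0] / result.model.covariance_trace:.0f}% of the Cα fluctuation variance")
print(f"free-energy range: 0 to {np.nanmax(result.grid.free_energy):.2f} kcal/mol")
print(f"basins (persistence > 0.75 kcal/mol): {result.n_basins}")
print()
print("The hinge's slow opening/closing dominates PC1; the single deep basin")
print("says the ensemble oscillates around one conformational state.")
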