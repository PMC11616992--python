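"""Wild-type vs mutant protein residue networks on a synthetic two-lobe system.

Generates a bilobal ensemble (two rigid lobes, a flexible linker loop, a
catalytic-interface contact decohered by hinge motion) plus a "mutant" that
rigidifies the loop and loosens the active-site patch.  The LSP pipeline
(windowed all-to-all Cα-Cβ pattern comparison → weighted adjacency →
degree/betweenness centrality) recovers the planted story: communication
shifts from the catalytic interface to the rigidified loop.
"""

import numpy as np

from lspnet import (
    apply_mutant,
    default_mutant_edit,
    default_two_lobe_spec,
    generate_ensemble,
)
from lspnet.pipeline import run_compare, run_prn
from lspnet.synthetic import recovery_tolerances

spec = default_two_lobe_spec(seed=1, n_frames=200, stride_ns=0.1)  # 20 ns, small demo
wt = generate_ensemble(spec)
mut = generate_ensemble(apply_mutant(spec, default_mutant_edit()))

windows = dict(window_starts=(0.0, 10.0), window_length=10.0, stride=0.1)
tol = recovery_tolerances()
wt_res = run_prn(wt.frames, tolerances=tol, **windows)
mut_res = run_prn(mut.frames, tolerances=tol, **windows)
delta = run_compare(wt_res, mut_res)

linker = slice(50, 58)
active = slice(108, 120)
print(f"wild-type top-BC node: {np.argmax(wt_res.profile.bc_mean)} "
      f"(active-site patch = nodes 108-119, its lobe-1 contact = node 0)")
print(f"mutant top-8 BC nodes: {sorted(int(i) for i in np.argsort(mut_res.profile.bc_mean)[::-1][:8])} "
      f"(linker = nodes 50-57)")
print(f"mean linker  ΔBC: {delta.delta_bc[linker].mean():+9.0f}   ΔDC: {delta.delta_dc[linker].mean():+6.2f}")
print(f"mean active  ΔBC: {delta.delta_bc[active].mean():+9.0f}   ΔDC: {delta.delta_dc[active].mean():+6.2f}")
print()
print("Positive linker ΔBC/ΔDC with negative active-site ΔDC is the centrality")
print("signature of a mutation that turns a flexible inter-lobe loop into the")
print("dominant connector while destabilizing the catalytic region.")
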