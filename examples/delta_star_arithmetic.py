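"""Normalized fractional volume change (delta*) arithmetic.

delta* = J * (V_f / V_r) - 1 measures how much a voxel's contribution to
global lung volume changed between two inspiratory scans: J is the local
reference-to-floating volume ratio from the registration Jacobian, and
V_f / V_r normalizes away the global lung-volume difference.
"""

import numpy as np

from lungmech import delta_star_map

# A region whose local-to-global contribution grew by 50%, realized three
# ways: purely locally, split between local and global, purely globally.
for J, ratio in [(1.5, 1.0), (1.2, 1.25), (1.0, 1.5)]:
    d = delta_star_map(np.array([J]), Vf=ratio * 1000.0, Vr=1000.0)[0]
    print(f"J = {J:4.2f}, Vf/Vr = {ratio:4.2f}  ->  delta* = {d:.3f}")

# Uniform inflation: every voxel expands exactly as the whole lung does,
# so the normalized change vanishes.
Vr, Vf = 6.2e6, 5.4e6  # mm^3, a typical TLC pair
J_uniform = np.full(5, Vr / Vf)
print("uniform inflation delta*:", delta_star_map(J_uniform, Vf, Vr))
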