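"""Interlobe rotation angle and helix-axis geometry between two states.

Aligns the small lobe of two synthetic conformations and measures the
residual rigid rotation of the large lobe — the standard two-stage
decomposition used to report statements like "the large lobe rotates
16 degrees away from the small lobe".  Also shows helix-axis fitting.
"""

from conformap import Selection, helix_axis, interlobe_rotation
from conformap.synth import TwoLobeParams, make_helix, make_two_lobe

ALIGN = Selection(ranges=((1, 60),))    # small lobe
MOVING = Selection(ranges=((61, 180),))  # large lobe

closed, _ = make_two_lobe(TwoLobeParams(theta_open=0.0))
open_, _ = make_two_lobe(TwoLobeParams(theta_open=16.0))

rot = interlobe_rotation(closed, open_, ALIGN, MOVING)
print(f"interlobe rotation : {rot.angle:.2f} deg "
      f"(axis {rot.axis.round(3).tolist()})")
print(f"fit used {rot.n_align} alignment and {rot.n_moving} moving CA atoms")
print("A noise-free rigid opening is recovered exactly; the axis is the")
print("generator's hinge axis (y).")

helix = make_helix(20, axis=(0, 0, 1))
ax = helix_axis(helix, (1, 20))
print(f"\nideal 20-residue helix axis: {ax.direction.round(4).tolist()} "
      "(unit vector, N-to-C; dot with z ~ 1)")
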