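"""Compute the four kinetic parameters for a hand-built trajectory.

A zigzag track sampled at 30 fps: the curvilinear path is longer than the
straight-line displacement, so VCL > VSL, LIN < 1, and SWR compares the
4 µm displacement with the 1 µm-wide band the track sweeps sideways.
"""

from spermwall import Spot, Trajectory, compute_all

zigzag = Trajectory(id="demo", spots=[
    Spot(frame=f, x=float(x), y=float(y))
    for f, (x, y) in enumerate([(0, 0), (1, 1), (2, 0), (3, 1), (4, 0)])])

k = compute_all(zigzag, fps=30.0)
print(f"VCL = {k.vcl:.3f} um/s   (total path {k.total_path_um:.3f} um "
      f"over {k.duration_s:.4f} s)")
print(f"VSL = {k.vsl:.3f} um/s   (displacement {k.displacement_um:.3f} um)")
print(f"LIN = {k.lin:.4f}        (VSL/VCL; 1 = perfectly straight)")
print(f"SWR = {k.swr:.3f}        (displacement / {k.max_sideward_um:.3f} um "
      "max sideward movement)")
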