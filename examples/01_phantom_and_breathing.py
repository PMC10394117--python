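"""Build the synthetic liver phantom and its breathing cycle.

Prints the anatomy inventory and the per-phase liver motion amplitudes:
the superior-inferior (SI) component dominates, as respiratory liver motion
does, and phase 0% (end of inhale) is the motionless reference.
"""

import numpy as np

from livertrack import (GridSpec, MotionParams, PhantomConfig,
                        make_breathing_phases, make_phantom)

phantom = make_phantom(PhantomConfig(grid=GridSpec.centered(32, 8.0)), seed=7)
print(f"body mesh:  {phantom.body_mesh.n_nodes} nodes")
print(f"liver mesh: {phantom.liver_mesh.n_nodes} nodes "
      f"(fixed across phases: node correspondence)")
print(f"tumor mesh: {phantom.tumor_mesh.n_nodes} nodes, "
      f"attenuation {phantom.config.mu_tumor / phantom.config.mu_liver - 1:+.1%} "
      f"vs liver (low contrast)")
print(f"grid: {phantom.grid.shape} voxels at {phantom.grid.spacing[0]} mm")

phases = make_breathing_phases(phantom, 10, MotionParams(), seed=3)
print("\nphase   max |LR|   max |AP|   max |SI|  (mm, liver boundary)")
for label, b in zip(phases.phases, phases.boundary_dvfs):
    amp = np.abs(b.d).max(axis=0)
    print(f"{label:>5}   {amp[0]:8.2f}   {amp[1]:8.2f}   {amp[2]:8.2f}")
print("\nThe 0% row is exactly zero; the SI peak matches the configured "
      "15 mm amplitude.")
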