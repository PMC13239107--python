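"""Carbon reference radiation from a flat 6 cm SOBP at 21 cm range.

Generates a mini machine with energy layers spanning the reference SOBP,
optimizes a flat biological-effect SOBP in depth and returns the
mixed-field (alpha_ref, beta_ref) at the midpoint for both RBE models --
the radiation quality every RBE in this package is expressed against.
Takes a couple of minutes.
"""

import numpy as np

from mkmplan import calibrate_reference
from mkmplan.base_data import generate_mini_machine

machine = generate_mini_machine(ranges_cm=np.arange(14.6, 21.6, 0.25))
print(f"machine: {len(machine.entries)} layers, ranges "
      f"{machine.ranges_cm.min():.1f}-{machine.ranges_cm.max():.1f} cm")

for model in ("mmkm", "mcf_mkm"):
    ref = calibrate_reference(machine, model, sobp_width_cm=6.0, range_cm=21.0)
    print(
        f"{model:8s} alpha_ref = {ref.alpha_ref:.4f} Gy^-1,"
        f" beta_ref = {ref.beta_ref:.4f} Gy^-2"
    )

print(
    "\nThe mMKM beta_ref equals beta0 = 0.0615 exactly (constant-beta model)."
    "\nBoth alpha_ref values sit well below the published carbon references"
    "\n(0.7554 and 1.019 Gy^-1): the synthetic Bragg curves deliver a smaller"
    "\nstopping-carbon dose share at the SOBP midpoint than the measured"
    "\nbeams behind those numbers.  Internally the calibration is consistent:"
    "\nRBE = 1 at the midpoint quality for each model by construction."
)
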