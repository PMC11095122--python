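"""Fluorescent-bead validation: star-like smearing and its correction.

Reproduces the character of a bead-in-agarose measurement: a cylinder of
tiny fluorescent beads imaged in a silicone-oil medium (RI 1.422) that does
not match the aqueous specimen (RI 1.335). Off-center beads smear into
star-like shapes without correction; rearrangement restores them to circles.
Writes reconstructions and red/green composites to bead_demo_out/.
"""

import numpy as np

from slotsim.experiments import end_to_end_bead_demo

res = end_to_end_bead_demo(seed=5, n_medium=1.422, n_sample=1.335,
                           outdir="bead_demo_out")

centers = res["centers"]
off_center = centers[:, 2] >= 0.6
print("bead axis ratios (1.0 = perfectly circular):")
for name, ratios in res["ratios"].items():
    print(f"  {name:11s} max {ratios.max():.2f}   "
          f"off-center mean {ratios[off_center].mean():.2f}")
print("the mismatched off-center beads smear to ratios >= 2 (star-like); "
      "matched and corrected beads stay below 1.3")
print("images written to bead_demo_out/ — in the composites the matched "
      "reconstruction is red, the comparison green; overlap shows yellow")
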