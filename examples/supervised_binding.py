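"""Run one supervised binding replica on the toy funnel receptor.

Builds the pocketed bead receptor, places a designed binder fragment 50 A
from the cleft, and runs the supervised loop: short Brownian-dynamics steps
are kept only when the fragment-site distance d_cm trends downward, so the
fragment is funnelled from bulk placement into the cleft without any bias
force.  Prints the outcome, the step bookkeeping and the distance profile.
"""

import numpy as np

from htsumd.engine import SuMDConfig, run_sumd
from htsumd.synth import make_planted_library, make_toy_receptor
from htsumd.systems import place_fragment

receptor, site = make_toy_receptor()
library = make_planted_library(n=40, binder_fraction=0.125, seed=1)
fragment = library.fragments[0]          # a designed binder

system = place_fragment(receptor, fragment, site, min_separation=50.0,
                        seed=1)
trajectory = run_sumd(system, site, SuMDConfig(base_seed=1))

print(f"fragment {fragment.fragment_id}: outcome = {trajectory.outcome}")
print(f"accepted steps: {trajectory.accepted_steps}, "
      f"attempted: {trajectory.attempted_steps} "
      f"(rejected steps are re-simulated with fresh noise)")
print(f"frames stored: {len(trajectory.frames)}")
d = trajectory.d_cm
print("d_cm profile (A), every 50th frame:", np.round(d[::50], 1))
print(f"final d_cm = {d[-1]:.1f} A; best interaction energy "
      f"{np.nanmin(trajectory.energies):.1f} kcal/mol")
# A 'bound' outcome means d_cm dropped below 5 A: the fragment entered the
# cleft; the energy minimum shows how well it fits the sub-pockets there.
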