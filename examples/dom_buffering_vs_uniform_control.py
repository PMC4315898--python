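"""DOM C:N buffering by functional diversity vs the one-group control.

Runs the three-group community and the uniform population at two litter
stoichiometries on a small grid and compares their late-decay DOM C:N.
Functional diversity buffers the DOM C:N (similar values across litter
C:N); the uniform population's DOM C:N stays coupled to the litter.
"""

import dataclasses

from microstoich import (
    build_three_group_model,
    build_uniform_population_model,
    default_params,
    run_scenario,
)
from microstoich.observables import late_mean

params = dataclasses.replace(default_params(), grid_size=30, steps_max=8000)

for label, build in (("three-group", build_three_group_model),
                     ("uniform    ", build_uniform_population_model)):
    values = {}
    for litter_cn in (45.0, 75.0):
        rec = run_scenario(build(litter_cn, params=params, seed=2)).records
        values[litter_cn] = late_mean(rec, "dom_cn")
    spread = values[75.0] - values[45.0]
    print(f"{label}: late DOM C:N {values[45.0]:5.1f} @ litter 45, "
          f"{values[75.0]:5.1f} @ litter 75   (difference {spread:+.1f})")
print("\nA smaller difference in the three-group community is the "
      "buffering signature: remains degraders recycle N-rich necromass "
      "faster when litter N is scarce.")
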