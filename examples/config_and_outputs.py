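"""Round-tripping configuration and writing run outputs.

Dumps the shipped defaults (with the three-group trait table) to YAML,
reloads and validates them, runs a very short simulation and writes the
tidy records table, metadata sidecar and a grid snapshot to ./example_out.
"""

import dataclasses
from pathlib import Path

from microstoich import default_params, dump_config, load_config, run_scenario
from microstoich.experiments import build_three_group_model, three_groups
from microstoich import io as mio

out = Path("example_out")
out.mkdir(exist_ok=True)

dump_config(default_params(), out / "params.yaml", groups=list(three_groups()))
params, groups = load_config(out / "params.yaml")
print(f"reloaded config: grid {params.grid_size}x{params.grid_size}, "
      f"step {params.step_hours} h, groups {[g.name for g in groups]}")

params = dataclasses.replace(params, grid_size=15, steps_max=50, mass_loss_stop=1.0)
scenario = build_three_group_model(55.0, params=params, seed=0)
result = run_scenario(scenario)
mio.write_outputs(result, out, snapshots={"final": result.state})
print(f"wrote {len(result.records)} record rows and a final snapshot to {out}/")
occ = mio.read_snapshot(out / "snapshot_final_occupancy.txt")
print(f"occupancy map: {(occ >= 0).sum()} of {occ.size} microsites occupied "
      f"(group index per site, -1 = empty)")
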