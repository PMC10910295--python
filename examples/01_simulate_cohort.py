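"""Simulate a small treatment x hemisphere cohort and write it to disk.

Each unit responds to contralateral, ipsilateral and bilateral flash
stimulation with an inhomogeneous-Poisson spike train: constant baseline plus
Gaussian ON/OFF transients whose amplitudes depend on the stimulation
condition and the unit's archetype.
"""

from pathlib import Path

from entolat import default_cohort_config, simulate_cohort, write_spike_table
from entolat.spikeio import write_protocol, write_unit_meta

config = default_cohort_config(n_units_per_cell=5, seed=7)
dataset = simulate_cohort(config)

out = Path("example_cohort")
out.mkdir(exist_ok=True)
write_spike_table(dataset, out / "spikes.csv", meta_path=out / "units.csv")
write_protocol(dataset.protocol, out / "protocol.yaml")

n_spikes = sum(t.size for t in dataset.spikes.values())
print(f"simulated {len(dataset.units)} units, {n_spikes} spikes -> {out}/")
for u in dataset.units[:5]:
    print(f"  {u.unit_id}: {u.treatment}/{u.hemisphere}, archetype={u.ground_truth}")
# Archetype labels are the ground truth later recovery tests compare against.
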