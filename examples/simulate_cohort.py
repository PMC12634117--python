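"""Simulate a linked ECG-echocardiogram cohort and write it to disk.

Builds a 150-patient cohort with the default study conditions (per-valve
prevalence 3-6%, morphology-coupled progression hazards, roughly annual
echo surveillance), writes WFDB records plus CSV manifests, and summarizes
what was generated.
"""

import tempfile
from pathlib import Path

import numpy as np

from ecgsurv import SimulationConfig, simulate_cohort, write_cohort
from ecgsurv.datatypes import VALVES

config = SimulationConfig(n_patients=150, seed=7)
patients, ecgs, echos = simulate_cohort(config)

out_dir = Path(tempfile.mkdtemp()) / "cohort"
write_cohort(patients, ecgs, echos, out_dir)

print(f"patients: {len(patients)}   ECGs: {len(ecgs)}   echo reports: {len(echos)}")
for valve in VALVES:
    prevalent = np.mean([p.prevalent[valve] for p in patients])
    events_5y = np.mean([0 < p.true_event_time[valve] <= 5 for p in patients])
    print(f"  {valve.upper()}: prevalent at entry {prevalent:.1%}, "
          f"true progression within 5 y {events_5y:.1%}")
qrs = [p.morphology['qrs_width_ms'] for p in patients]
eta = [p.log_hazard for p in patients]
rho = np.corrcoef(np.argsort(np.argsort(eta)), np.argsort(np.argsort(qrs)))[0, 1]
print(f"rank correlation of baseline QRS width with true log-hazard: {rho:.2f}")
print(f"cohort written to {out_dir}")
print("Higher-hazard patients carry broader QRS and smaller P waves; the "
      "written CSVs and WFDB records are what the cohort builder consumes.")
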