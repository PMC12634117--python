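"""Run one ECG through the preprocessing chain and extract its median beat.

Shows the filter contract: a 10-s, 500 Hz recording becomes exactly 4096
samples at 400 Hz; 60 Hz mains interference is suppressed by >20 dB while
in-band (10 Hz) content passes essentially unchanged.
"""

import numpy as np

from ecgsurv import SimulationConfig, extract_median_beat, preprocess, simulate_cohort
from ecgsurv.preprocessing import preprocess_array

_, ecgs, _ = simulate_cohort(SimulationConfig(n_patients=1, seed=3))
ecg = ecgs[0]
clean = preprocess(ecg)
print(f"input:  {ecg.samples.shape[1]} samples at {ecg.fs:g} Hz")
print(f"output: {clean.samples.shape[1]} samples at {clean.fs:g} Hz "
      f"(last 96 are zero padding: {np.all(clean.samples[:, 4000:] == 0)})")

t = np.arange(5000) / 500.0
for freq in (60.0, 10.0):
    sine = np.sin(2 * np.pi * freq * t)[None, :]
    out = preprocess_array(sine, fs=500.0)
    db = 20 * np.log10(np.sqrt(np.mean(out[:, 400:3600] ** 2))
                       / np.sqrt(np.mean(sine ** 2)))
    print(f"{freq:5.0f} Hz sine -> {db:+.1f} dB")

beat = extract_median_beat(clean)
print(f"median beat: {beat.samples.shape[1]} samples over {beat.window_ms:g} ms, "
      f"from {beat.beats_used} aligned beats, R peak at sample {beat.r_index}")
print("The negative dB at 60 Hz is the mains notch; the ~0 dB at 10 Hz shows "
      "the passband is preserved. The median beat is the input unit for the "
      "explainability analyses.")
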