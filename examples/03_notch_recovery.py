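"""Remove a pedaling-cadence artifact with the 100 BPM notch filter.

Pedaling at 50 RPM induces a narrowband motion artifact near 100 BPM (two
pedal strokes per revolution).  When it rivals the pulse in amplitude, the
spectrogram shows two lines and per-frame argmax tracking locks onto the
wrong one.  The band-stop notch (100 +/- 25 BPM) removes it and recovers
the true HR in every frame.
"""

import numpy as np

from roma_ppg import (ConstantHR, PipelineConfig, SynthConfig, generate,
                      process_record)

synth = generate(SynthConfig(duration_s=300.0, hr_trajectory=ConstantHR(130.0),
                             cadence_bpm=100.0, cadence_amp=0.8, seed=21))

for label, cfg in [("without notch", PipelineConfig()),
                   ("with notch   ", PipelineConfig(notch=True))]:
    result = process_record(synth.record, cfg)
    dev = np.abs(result.track.peak_hr - 130.0)
    captured = int(np.sum(np.abs(result.track.peak_hr - 100.0) < 10.0))
    print(f"{label}: {captured:2d}/{result.track.n_frames} frames captured by the "
          f"artifact, max |peak HR - 130| = {dev.max():5.2f} BPM, "
          f"agreement MAE = {result.agreement.mae:.2f} BPM")

print("\nTrue HR is 130 BPM. The notch restores every spectrogram frame to the")
print("heart-rate line and the agreement error collapses accordingly.")
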