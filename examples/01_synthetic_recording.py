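"""Build a synthetic EEG session and condition it like a real recording.

Generates a 14-channel, 256 Hz recording with 1/f background, a strong
alpha rhythm, and one artifact-laden channel; then band-passes it to
1-45 Hz, rereferences to the channel average, rejects the bad channel,
and cuts 2-s epochs with 75% overlap.
"""

import numpy as np

import eegbico as eb

spec = eb.SynthSpec(
    n_channels=14, fs=256.0, duration=30.0, background_slope=1.0,
    background_rms=10.0,
    band_components=[(10.0, 3.0, 6.0, None)],  # alpha rhythm on every channel
    seed=0,
)
rec = eb.build_recording(spec)
# in-band movement artifact: 3 mV at 7 Hz survives the band-pass and trips
# the peak-to-peak criterion (default limit 1 mV)
rec.data[5] += 3000.0 * np.sin(2 * np.pi * 7.0 * np.arange(rec.n_samples) / rec.fs)

filtered = eb.bandpass(rec, 1, 45)
reref = eb.rereference_average(filtered)
clean, report = eb.reject_channels(reref)
epochs = eb.make_epochs(clean, length=2.0, overlap=0.75)

print(f"channels kept: {clean.n_channels}/{rec.n_channels}")
for label, reason in report.removed.items():
    print(f"rejected {label}: {reason}")
print(f"epochs: {epochs.n_epochs} x {epochs.samples_per_epoch} samples")
# The rejected channel is the one with the injected 5 mV drift; the epoch
# count follows floor((N - L)/step) + 1 with a 0.5 s step.
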