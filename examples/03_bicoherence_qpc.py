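"""Detect quadratic phase coupling with wavelet bicoherence.

Two recordings share the same 6, 9 and 15 Hz components; in one the 15 Hz
phase is locked to the sum of the others (full QPC), in the other it is
randomized every 2 s. Only the coupled recording shows bicoherence near 1
at (9, 6); surrogate filtering then zeroes everything but that
neighborhood.
"""

import numpy as np

import eegbico as eb

n = 512 + 199 * 128  # 200 epochs at 2 s / 75% overlap
grid = eb.BifrequencyGrid(1, 20, 1, 2)

for strength, label in [(1.0, "coupled"), (0.0, "uncoupled")]:
    spec = eb.SynthSpec(
        n_channels=1, fs=256.0, duration=n / 256.0, background_slope=0.0,
        background_rms=0.5, qpc_triplets=[(6.0, 9.0, strength, 1.0)], seed=11,
    )
    epochs = eb.make_epochs(eb.build_recording(spec))
    bic = eb.wavelet_bicoherence(epochs, epochs.labels[0], grid)
    print(f"{label:10s} b2(9,6) = {bic.at(9, 6):.3f}")
    if strength == 1.0:
        thr = eb.surrogate_threshold(epochs, epochs.labels[0], grid,
                                     n_surrogates=40, seed=5)
        fiwbic = eb.filter_bicoherence(bic, thr)
        survivors = int(np.sum(np.nan_to_num(fiwbic.values) > 0))
        print(f"           cells surviving the surrogate filter: {survivors} "
              f"of {int(bic.domain.sum())}")
        print(f"           theta-alpha total coupling: "
              f"{eb.total_band_coupling(fiwbic, 'theta', 'alpha'):.3f}")
# The coupled run gives b2 ~ 0.98, the uncoupled ~ 0.01-0.03; after
# filtering, the surviving coupling mass sits at (9 Hz, 6 Hz) and the
# theta-alpha band-pair total is dominated by it.
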