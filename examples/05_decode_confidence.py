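"""Decode confidence reports from simulated multi-frequency power spectra.

For each subject, pre-question power at 7-40 Hz carries the observer's
confidence only in the beta band (15-30 Hz); noisy confidence reports
(calibrated to correlate 0.23 with the observer's confidence) are then
predicted with a 20-fold interleaved cross-validated ridge regression
(penalty 0.01).
"""

import numpy as np

from cwlearn import TaskConfig, run_decoding_experiment

config = TaskConfig()  # full scale: 24 subjects x 4 sessions
table, weights = run_decoding_experiment(config, master_seed=5)
print(table.round(4).to_string(index=False))

freqs = np.arange(7.0, 41.0)
band = (freqs >= 15) & (freqs <= 30)
print(f"\nmean ridge weight inside 15-30 Hz : {weights[band].mean():+.4f}")
print(f"mean ridge weight outside         : {weights[~band].mean():+.4f}")
print()
print(
    "rho_mean is the group-average out-of-sample correlation between\n"
    "predicted and actual reports; it is small and positive — the reports\n"
    "are deliberately noisy readouts, so even perfect decoding of the\n"
    "observer's confidence caps the attainable accuracy — and the full-data\n"
    "ridge weights recover the planted beta-band loading."
)
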