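"""Shared measurement noise, trial binning and the power -> ERF regression.

Simulates single-trial beta power (coupled to confidence, with autocorrelated
noise) and evoked-response amplitude (coupled to surprise and power), both
corrupted by one common fast measurement noise per trial.  The common noise
biases the single-trial estimate of the power -> ERF coupling; averaging
consecutive trials into bins suppresses it while the slower, confidence-
mediated true coupling (beta3 = 0.5) survives.
"""

from cwlearn import NeuroSimParams, TaskConfig, run_binning_experiment

config = TaskConfig(n_subjects=12, n_sessions=2)
table = run_binning_experiment(config, bin_sizes=(1, 2, 3, 5, 10), master_seed=4)
print("with shared measurement noise:")
print(table.round(3).to_string(index=False))

clean = run_binning_experiment(
    config, NeuroSimParams(sd_eps=0.0), bin_sizes=(1, 10), master_seed=4
)
print("\nwithout shared noise (artifact-free):")
print(clean.round(3).to_string(index=False))
print()
print(
    "The group t of the power coefficient rises with bin size: at bin 1 the\n"
    "artifact dominates (sign opposite to the true coupling), by bin 10 the\n"
    "true positive coupling shows through.  With no shared noise the\n"
    "coefficient equals the generative coupling 0.5 at every bin size."
)
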