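"""Run the Bayes-optimal ideal observer on a simulated session.

The observer tracks the joint posterior over (p(A|A), p(B|B)) on a 20 x 20
grid with a hidden-Markov forward recursion that allows for change points
(probability 1/75 per trial), and emits per trial its prediction of the next
tone, the Shannon surprise of what it then hears, the log-precision
confidence of its prediction, and the KL divergence quantifying how much the
observation moved its beliefs.
"""

from cwlearn import TaskConfig, generate_sequence, run_observer

config = TaskConfig()
seq = generate_sequence(config, seed=1)
trace = run_observer(seq, config)

df = trace.to_frame()
cols = ["trial", "tone", "prediction", "surprise_bits", "confidence", "kl_update"]
around_cp = seq.changepoints[0]
print(f"first change point at trial {around_cp}\n")
print(df.loc[around_cp - 3 : around_cp + 5, cols].round(3).to_string(index=False))
print()
print(
    "Around the change point the observer's prediction is briefly wrong:\n"
    "surprise jumps (bits of information the tone carried), confidence\n"
    "(-log posterior variance) drops as old evidence is discounted, and the\n"
    "KL update spikes while the posterior re-adapts."
)
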