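"""Generate one session of the volatile transition-probability task.

Builds a 380-trial binary tone sequence whose transition probabilities
p(A|A) and p(B|B) are resampled at rare change points (probability 1/75 per
trial) on [0.1, 0.9] under a 4-fold odds-change constraint, plus the
schedule of occasional probe questions.
"""

import numpy as np

from cwlearn import TaskConfig, generate_question_schedule, generate_sequence

config = TaskConfig()
seq = generate_sequence(config, seed=1)
questions = generate_question_schedule(config, seed=2)

print(f"trials            : {len(seq)}")
print(f"change points     : {seq.changepoints.tolist()}")
print(f"segment lengths   : {np.diff(np.r_[0, seq.changepoints, len(seq)]).tolist()}")
print(f"theta on trial 0  : p(A|A)={seq.theta_true[0, 0]:.3f}, p(B|B)={seq.theta_true[0, 1]:.3f}")
print(f"questions at      : {questions.question_trials.tolist()}")
print(f"median gap        : {np.median(np.diff(np.r_[0, questions.question_trials])):.1f} trials")
print()
print(seq.to_frame().head(8).to_string(index=False))
print()
print(
    "Each row is one tone (0=A, 1=B) with the transition probabilities in\n"
    "force on that trial and the number of observations since the last\n"
    "change point; segments last 75 trials on average."
)
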