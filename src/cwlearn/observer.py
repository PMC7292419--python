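"""Bayes-optimal ideal observer for volatile transition probabilities.

The observer inverts the task's generative model with a hidden-Markov forward
recursion over a discretized joint grid of the two transition probabilities
``theta = (p(A|A), p(B|B))``.  Between consecutive observations the belief is
passed through the change-point kernel

    b'(theta) = (1 - p_c) * b(theta) + p_c * uniform(theta),

reflecting the assumption that at a change point both probabilities are
resampled jointly from a flat prior over the full unit square (the observer is
not told about the experimenter's 0.1-0.9 truncation or fold-change rule).
The belief is then multiplied by the likelihood of the new tone given the
previous one and renormalized.

Per trial the observer emits, before observing the tone:

- ``prediction`` -- mean of the relevant marginal of the previous trial's
  posterior, mapped to the probability that the next tone is A;
- ``surprise`` -- Shannon surprise of the observed tone, in bits;
- ``confidence`` -- log-precision, ``-log(var)`` (natural log), of the
  relevant marginal of the previous trial's posterior;

and ``kl_update``, the Kullback-Leibler divergence (nats) between the
pre-observation belief (by default the belief after the change-point kernel,
i.e. what the observer holds just before the likelihood) and the
post-observation posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TONE_A, TaskConfig, ToneSequence

__all__ = [
    "PosteriorGrid",
    "ObserverTrace",
    "make_prior",
    "transition_kernel",
    "likelihood_grid",
    "hmm_step",
    "predict_next",
    "surprise_bits",
    "confidence_logprec",
    "kl_update",
    "run_observer",
]

_NORM_TOL = 1e-12


@dataclass
class PosteriorGrid:
    """Joint distribution over ``(p(A|A), p(B|B))`` on a square grid.

    ``grid`` holds the ``grid_n`` midpoint values ``(i - 0.5) / grid_n``,
    strictly inside (0, 1); ``joint`` is the ``grid_n x grid_n`` array of
    probability masses (axis 0 indexes ``p(A|A)``, axis 1 ``p(B|B)``).
    """

    grid: np.ndarray
    joint: np.ndarray

    def normalize(self) -> "PosteriorGrid":
        total = self.joint.sum()
        if total <= 0.0:
            raise FloatingPointError("posterior mass underflowed to zero")
        self.joint = self.joint / total
        return self

    def marginal(self, axis: int) -> np.ndarray:
        """Marginal mass over ``p(A|A)`` (axis=0) or ``p(B|B)`` (axis=1)."""
        return self.joint.sum(axis=1 - axis)

    def marginal_moments(self, axis: int) -> tuple[float, float]:
        """Mean and variance of the requested marginal."""
        m = self.marginal(axis)
        mean = float(m @ self.grid)
        var = float(m @ (self.grid - mean) ** 2)
        return mean, var

    def copy(self) -> "PosteriorGrid":
        return PosteriorGrid(grid=self.grid, joint=self.joint.copy())


def make_prior(grid_n: int) -> PosteriorGrid:
    """Flat prior over the joint grid of transition probabilities."""
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    grid = (np.arange(grid_n) + 0.5) / grid_n
    joint = np.full((grid_n, grid_n), 1.0 / grid_n**2)
    return PosteriorGrid(grid=grid, joint=joint)


def transition_kernel(post: PosteriorGrid, p_change: float) -> PosteriorGrid:
    """Apply the change-point kernel: mix the belief with the flat prior."""
    if not 0.0 <= p_change <= 1.0:
        raise ValueError("p_change must lie in [0, 1]")
    total = post.joint.sum()
    flat = total / post.joint.size
    return PosteriorGrid(
        grid=post.grid, joint=(1.0 - p_change) * post.joint + p_change * flat
    )


def likelihood_grid(grid: np.ndarray, prev_tone: int, new_tone: int) -> np.ndarray:
    """Likelihood of ``new_tone`` given ``prev_tone`` at every grid cell."""
    n = len(grid)
    if prev_tone == TONE_A:
        col = grid if new_tone == TONE_A else 1.0 - grid
        return np.repeat(col[:, None], n, axis=1)
    col = grid if new_tone != TONE_A else 1.0 - grid
    return np.repeat(col[None, :], n, axis=0)


def hmm_step(
    post: PosteriorGrid, prev_tone: int, new_tone: int, p_change: float
) -> PosteriorGrid:
    """One forward step: change-point kernel, likelihood, renormalization."""
    pre = transition_kernel(post, p_change)
    pre.joint = pre.joint * likelihood_grid(pre.grid, prev_tone, new_tone)
    return pre.normalize()


def predict_next(post: PosteriorGrid, prev_tone: int) -> float:
    """Probability that the next tone is A: ``E[p(A|A)]`` after an A,
    ``1 - E[p(B|B)]`` after a B."""
    mean, _ = post.marginal_moments(0 if prev_tone == TONE_A else 1)
    return mean if prev_tone == TONE_A else 1.0 - mean


def surprise_bits(prediction: float, observed: int) -> float:
    """Shannon surprise ``-log2 p(observed)`` of the observed tone."""
    p = prediction if observed == TONE_A else 1.0 - prediction
    if not 0.0 < p < 1.0:
        raise ValueError("prediction must lie strictly inside (0, 1)")
    return -np.log2(p)


def confidence_logprec(post: PosteriorGrid, prev_tone: int) -> float:
    """Log-precision ``-log(var)`` of the relevant marginal (natural log)."""
    _, var = post.marginal_moments(0 if prev_tone == TONE_A else 1)
    if var <= 0.0:
        raise FloatingPointError("degenerate posterior: zero variance")
    return -np.log(var)


def kl_update(prior_grid: PosteriorGrid, posterior_grid: PosteriorGrid) -> float:
    """KL divergence (nats) ``sum q log(q/p)`` from belief ``p`` to ``q``.

    ``q`` is the post-observation posterior, ``p`` the pre-observation belief.
    Cells with ``q = 0`` contribute nothing; ``p = 0`` where ``q > 0`` is a
    support mismatch.
    """
    q = posterior_grid.joint.ravel()
    p = prior_grid.joint.ravel()
    pos = q > 0.0
    if np.any(p[pos] <= 0.0):
        raise ValueError("support mismatch: prior has zero mass where posterior > 0")
    return float(np.sum(q[pos] * (np.log(q[pos]) - np.log(p[pos]))))


@dataclass
class ObserverTrace:
    """Per-trial latent variables emitted by the ideal observer.

    Trial 0 has no predecessor: its prediction is fixed at 0.5, surprise is
    1 bit, and confidence / KL update are NaN with ``flag_first`` set.
    """

    tones: np.ndarray
    prediction: np.ndarray
    surprise: np.ndarray
    confidence: np.ndarray
    kl_update: np.ndarray
    posterior_mean_rel: np.ndarray
    posterior_var_rel: np.ndarray
    flag_first: np.ndarray
    trials_since_cp: np.ndarray

    def __len__(self) -> int:
        return len(self.tones)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.tones)),
                "tone": self.tones,
                "prediction": self.prediction,
                "surprise_bits": self.surprise,
                "confidence": self.confidence,
                "kl_update": self.kl_update,
                "posterior_mean_rel": self.posterior_mean_rel,
                "posterior_var_rel": self.posterior_var_rel,
                "flag_first": self.flag_first,
                "trials_since_cp": self.trials_since_cp,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_observer(
    seq: ToneSequence,
    config: TaskConfig,
    kl_prior: str = "post_transition",
) -> ObserverTrace:
    """Run the HMM forward recursion over a tone sequence.

    Parameters
    ----------
    seq:
        The session to process.
    config:
        Supplies ``p_change`` and ``grid_n`` (the observer's assumptions).
    kl_prior:
        Reference belief for the KL update: ``"post_transition"`` (default)
        compares the posterior with the belief after the change-point kernel,
        ``"pre_transition"`` with the previous trial's raw posterior.
    """
    if kl_prior not in ("post_transition", "pre_transition"):
        raise ValueError(f"unknown kl_prior {kl_prior!r}")
    n = len(seq)
    pred = np.full(n, np.nan)
    surp = np.full(n, np.nan)
    conf = np.full(n, np.nan)
    kl = np.full(n, np.nan)
    mean_rel = np.full(n, np.nan)
    var_rel = np.full(n, np.nan)
    flag = np.zeros(n, dtype=bool)

    post = make_prior(config.grid_n)
    if n > 0:
        # first tone is uninformative about transition probabilities
        flag[0] = True
        pred[0] = 0.5
        surp[0] = 1.0

    for t in range(1, n):
        prev, new = int(seq.tones[t - 1]), int(seq.tones[t])
        axis = 0 if prev == TONE_A else 1
        # latent variables come from the posterior carried over from trial t-1
        m, v = post.marginal_moments(axis)
        pred[t] = m if prev == TONE_A else 1.0 - m
        mean_rel[t] = m
        var_rel[t] = v
        conf[t] = -np.log(v)
        surp[t] = surprise_bits(pred[t], new)
        pre = transition_kernel(post, config.p_change)
        ref = pre.copy() if kl_prior == "post_transition" else post
        pre.joint = pre.joint * likelihood_grid(pre.grid, prev, new)
        post_new = pre.normalize()
        kl[t] = kl_update(ref, post_new)
        post = post_new

    return ObserverTrace(
        tones=np.asarray(seq.tones),
        prediction=pred,
        surprise=surp,
        confidence=conf,
        kl_update=kl,
        posterior_mean_rel=mean_rel,
        posterior_var_rel=var_rel,
        flag_first=flag,
        trials_since_cp=np.asarray(seq.trials_since_cp),
    )
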