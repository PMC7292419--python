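"""Synthetic single-trial neural and pupil signals.

Generates per-trial measurements whose statistical structure mirrors what the
downstream analyses assume about real recordings:

- beta-band power linearly reflects the observer's confidence and carries
  trial-to-trial autocorrelated noise;
- the evoked response (ERF) linearly reflects surprise (negatively) and power
  (positively, sign-flipped by the negative deflection), with white noise;
- both measured signals share one common measurement-noise realization per
  trial, creating the fast spurious power-ERF coupling that trial binning is
  designed to disrupt;
- tonic pupil size reflects confidence negatively with strongly
  autocorrelated noise; phasic pupil dilation reflects surprise with white
  noise;
- confidence reports on question trials are a noisy squashed readout of the
  observer's confidence, calibrated to a target correlation.

The generative equations for power and ERF are, with CONF and SURP the
z-scored confidence and surprise::

    power_neural = beta1 * CONF + eta_power          (AR(1) noise)
    erf_neural   = -(beta2 * SURP - beta3 * power_neural) + eps_erf
    power_meas   = power_neural + eps_common
    erf_meas     = erf_neural   - eps_common         (same realization)

with ``beta1 = 0.25``, ``beta2 = 0.25``, ``beta3 = 0.5``, eta_power of unit
SD and lag-1 autocorrelation 0.5, and unit-SD white eps noises by default.
These couplings are illustrative defaults, not fits to data.

The single common noise realization per trial stands for trial-to-trial
recording gain (breathing, motion, sensor noise): a stronger recording
inflates measured power and deepens the negative evoked deflection, so the
shared noise loads on the two measured signals with opposite signs and the
spurious power-ERF coupling it creates *opposes* the true, positive
``beta3`` coupling.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import zscore
from .task import QuestionSchedule

__all__ = ["NeuroSimParams", "TrialSignals", "simulate_power_erf", "simulate_pupil", "simulate_reports"]


@dataclass(frozen=True)
class NeuroSimParams:
    """Couplings and noise parameters of the signal simulators.

    ``beta1`` couples confidence to neural beta power, ``beta2`` surprise to
    the evoked response, ``beta3`` power to the evoked response.  ``sd_eta``
    and ``rho_eta`` parameterize the AR(1) power noise (stationary SD and
    lag-1 autocorrelation); ``sd_eps`` is the SD of both white measurement
    noises.  Pupil gains are sign-constrained only (confidence lowers tonic
    size, surprise raises phasic dilation); ``pupil_rho`` is the target
    trial-to-trial autocorrelation of the tonic level.  ``report_rho`` is the
    target correlation of simulated confidence reports with the observer's
    confidence.
    """

    beta1: float = 0.25
    beta2: float = 0.25
    beta3: float = 0.5
    sd_eta: float = 1.0
    rho_eta: float = 0.5
    sd_eps: float = 1.0
    pupil_conf_gain: float = -0.1
    pupil_surprise_gain: float = 0.2
    pupil_rho: float = 0.75
    report_rho: float = 0.23

    def __post_init__(self) -> None:
        if min(self.sd_eta, self.sd_eps) < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (abs(self.rho_eta) < 1 and abs(self.pupil_rho) < 1):
            raise ValueError("autocorrelations must lie in (-1, 1)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NeuroSimParams":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TrialSignals:
    """Per-trial synthetic measurements aligned with a tone sequence.

    ``report_confidence`` is NaN outside question trials.
    """

    power_neural: np.ndarray | None = None
    power_meas: np.ndarray | None = None
    erf_neural: np.ndarray | None = None
    erf_meas: np.ndarray | None = None
    pupil_tonic: np.ndarray | None = None
    pupil_phasic: np.ndarray | None = None
    report_confidence: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = {
            k: v
            for k, v in self.__dict__.items()
            if v is not None
        }
        return pd.DataFrame(cols)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with lag-1 autocorrelation ``rho`` and SD ``sd``."""
    x = np.empty(n)
    if n == 0:
        return x
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho**2), size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def _zscored_latents(trace) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored confidence and surprise; flagged trials are set to 0 (the mean)."""
    df = trace if isinstance(trace, pd.DataFrame) else trace.to_frame()
    conf = df["confidence"].to_numpy(dtype=float)
    surp = df["surprise_bits"].to_numpy(dtype=float)
    ok = ~(np.isnan(conf) | np.isnan(surp))
    zc = np.zeros(len(df))
    zs = np.zeros(len(df))
    zc[ok] = zscore(conf[ok])
    zs[ok] = zscore(surp[ok])
    return zc, zs


def simulate_power_erf(trace, params: NeuroSimParams, seed) -> TrialSignals:
    """Simulate coupled single-trial beta power and evoked-response amplitude.

    The same white common-noise realization enters both measured signals
    (with opposite sign on the ERF, see the module docstring), so at the
    single-trial level ``power_meas`` and ``erf_meas`` share variance that
    has nothing to do with the neural coupling ``beta3`` and biases its
    estimate downward; averaging consecutive trials into bins suppresses
    this fast shared noise while preserving the slower confidence-driven
    coupling.
    """
    rng = np.random.default_rng(seed)
    conf, surp = _zscored_latents(trace)
    n = len(conf)
    eta = _ar1(rng, n, params.rho_eta, params.sd_eta)
    eps_erf = rng.normal(0.0, params.sd_eps, size=n)
    eps_common = rng.normal(0.0, params.sd_eps, size=n)
    power_neural = params.beta1 * conf + eta
    erf_neural = -(params.beta2 * surp - params.beta3 * power_neural) + eps_erf
    return TrialSignals(
        power_neural=power_neural,
        power_meas=power_neural + eps_common,
        erf_neural=erf_neural,
        erf_meas=erf_neural - eps_common,
    )


def simulate_pupil(trace, params: NeuroSimParams, seed) -> TrialSignals:
    """Simulate tonic and phasic pupil levels (z-units).

    Tonic level couples negatively to confidence with strongly autocorrelated
    noise; phasic dilation couples positively to surprise with white noise;
    the two noise processes are independent.
    """
    rng = np.random.default_rng(seed)
    conf, surp = _zscored_latents(trace)
    n = len(conf)
    tonic = params.pupil_conf_gain * conf + _ar1(rng, n, params.pupil_rho, 1.0)
    phasic = params.pupil_surprise_gain * surp + rng.normal(0.0, 1.0, size=n)
    return TrialSignals(pupil_tonic=tonic, pupil_phasic=phasic)


def _squash_attenuation() -> float:
    """Correlation of logistic(X) with X for standard-normal X (Gauss-Hermite)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    w = weights / weights.sum()
    g = 1.0 / (1.0 + np.exp(-nodes))
    mg = w @ g
    cov = w @ (nodes * (g - mg))
    var_g = w @ (g - mg) ** 2
    return float(cov / np.sqrt(var_g))


def simulate_reports(
    trace, schedule: QuestionSchedule, params: NeuroSimParams, seed
) -> TrialSignals:
    """Simulate noisy confidence reports on question trials.

    The report is a logistic squash of a noisy linear readout of the
    observer's z-scored confidence.  The pre-squash correlation is corrected
    for the squash's attenuation so that the report-confidence correlation
    approximates ``params.report_rho``.
    """
    rng = np.random.default_rng(seed)
    conf, _ = _zscored_latents(trace)
    n = len(conf)
    if not 0.0 <= params.report_rho <= 1.0:
        raise ValueError("report_rho must lie in [0, 1]")
    # the squash caps the attainable correlation; saturate at a noiseless readout
    r = min(params.report_rho / _squash_attenuation(), 1.0)
    reports = np.full(n, np.nan)
    q = np.asarray(schedule.question_trials, dtype=int)
    if np.any(q >= n):
        raise ValueError("question schedule exceeds trace length")
    noise = rng.normal(0.0, 1.0, size=q.size)
    pre = r * conf[q] + np.sqrt(1.0 - r**2) * noise
    reports[q] = 1.0 / (1.0 + np.exp(-pre))
    return TrialSignals(report_confidence=reports)
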