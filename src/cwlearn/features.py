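"""Derived regressors and summary statistics on ideal-observer traces.

This module builds the quantities the downstream analyses regress on:
residual confidence (confidence with all prediction-related components
linearly removed), z-scored design matrices, within-session trial bins,
lagged predictors, and the regression batteries relating confidence to the
prediction, to the previous trial's surprise and to the number of
observations accumulated since the last change point.

Conventions
-----------
All regressions include a constant and z-scored predictors.  Outcome
standardization is configurable: coefficients can be reported with the
outcome z-scored within subject (``standardize_outcome=True``) or in the
outcome's natural units (log-precision); the surprise and
trials-since-change-point effects are, by default, estimated on the
*residual* confidence in natural units, the convention under which their
group-level weights are directly comparable across analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .observer import ObserverTrace

__all__ = [
    "DesignMatrix",
    "zscore",
    "residual_confidence",
    "adjacent_correlation",
    "bin_trials",
    "update_regression_r",
    "confidence_regressions",
    "summarize_coefficients",
]


def zscore(x) -> np.ndarray:
    """Z-score a vector; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class DesignMatrix:
    """Named regressors with a constant and per-column z-scoring.

    ``columns`` maps names to 1-D vectors over included trials; z-scoring is
    applied per column on construction unless the name appears in
    ``no_zscore``.
    """

    columns: dict[str, np.ndarray]
    intercept: bool = True
    no_zscore: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.columns.values()}
        if len(lengths) > 1:
            raise ValueError("all design columns must have equal length")
        for name, v in self.columns.items():
            v = np.asarray(v, dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"design column {name!r} contains missing values")
            self.columns[name] = v if name in self.no_zscore else zscore(v)

    @property
    def names(self) -> list[str]:
        return (["intercept"] if self.intercept else []) + list(self.columns)

    def matrix(self) -> np.ndarray:
        cols = list(self.columns.values())
        n = len(cols[0]) if cols else 0
        if self.intercept:
            cols = [np.ones(n)] + cols
        return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit; returns (coefficients, fitted values)."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, X @ beta


def residual_confidence(trace) -> np.ndarray:
    """Confidence with all prediction-related components regressed out.

    Fits confidence on ``[1, p, p^2, log(p), log(1-p)]`` by least squares and
    returns the residuals, aligned with the input trials (NaN where the trace
    is flagged).  The residuals are orthogonal to each predictor, so they
    carry the part of confidence not explained by the prediction itself.

    Parameters
    ----------
    trace:
        An :class:`~cwlearn.observer.ObserverTrace` or a DataFrame with
        ``prediction``, ``confidence`` and ``flag_first`` columns.
    """
    df = trace.to_frame() if isinstance(trace, ObserverTrace) else trace
    p = df["prediction"].to_numpy(dtype=float)
    c = df["confidence"].to_numpy(dtype=float)
    valid = ~(df["flag_first"].to_numpy(dtype=bool) | np.isnan(c))
    pv, cv = p[valid], c[valid]
    if np.ptp(pv) == 0.0:
        raise ValueError("degenerate trace: constant prediction")
    X = np.column_stack([np.ones(pv.size), pv, pv**2, np.log(pv), np.log1p(-pv)])
    _, fitted = _ols(X, cv)
    out = np.full(len(df), np.nan)
    out[valid] = cv - fitted
    return out


def adjacent_correlation(x, sessions=None) -> float:
    """Pearson correlation between values on consecutive trials.

    Pairs ``(x[t], x[t+1])`` are formed within session only (no pair spans a
    session boundary); NaN entries drop the pairs they touch.
    """
    x = np.asarray(x, dtype=float)
    if sessions is None:
        sessions = np.zeros(len(x), dtype=int)
    sessions = np.asarray(sessions)
    a_parts, b_parts = [], []
    for s in pd.unique(sessions):
        xs = x[sessions == s]
        a_parts.append(xs[:-1])
        b_parts.append(xs[1:])
    a = np.concatenate(a_parts)
    b = np.concatenate(b_parts)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 within-session pairs")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("constant input has no defined correlation")
    return float(np.corrcoef(a, b)[0, 1])


def bin_trials(signals, bin_size: int, sessions=None) -> np.ndarray:
    """Average consecutive non-overlapping bins of trials within session.

    Each output row is the mean of ``bin_size`` consecutive input rows; a
    trailing partial bin is dropped so every bin averages the same number of
    trials.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    X = np.asarray(signals, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    if sessions is None:
        sessions = np.zeros(len(X), dtype=int)
    sessions = np.asarray(sessions)
    out = []
    for s in pd.unique(sessions):
        Xs = X[sessions == s]
        n_bins = len(Xs) // bin_size
        if n_bins == 0:
            continue
        out.append(Xs[: n_bins * bin_size].reshape(n_bins, bin_size, -1).mean(axis=1))
    if not out:
        raise ValueError("bin_size exceeds every session length")
    res = np.concatenate(out)
    return res[:, 0] if squeeze else res


def _valid_trials(traces: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("confidence", "kl_update", "surprise_bits") if c in traces]
    mask = ~traces["flag_first"].to_numpy(dtype=bool)
    for c in cols:
        mask &= ~traces[c].isna().to_numpy()
    return traces[mask]


def update_regression_r(traces: pd.DataFrame, include_interaction: bool = False) -> float:
    """Pearson correlation between fitted and actual belief update.

    One pooled OLS of the KL update on z-scored surprise and confidence
    (plus, optionally, their product) with an intercept, over all valid
    trials of all subjects and sessions.
    """
    d = _valid_trials(traces)
    if len(d) < 100:
        raise ValueError("need at least 100 valid trials")
    s = zscore(d["surprise_bits"])
    c = zscore(d["confidence"])
    cols = [np.ones(len(d)), s, c]
    if include_interaction:
        cols.append(s * c)
    X = np.column_stack(cols)
    y = d["kl_update"].to_numpy(dtype=float)
    _, fitted = _ols(X, y)
    return float(np.corrcoef(fitted, y)[0, 1])


def _lagged_within_session(df: pd.DataFrame, col: str, lag: int = 1) -> pd.Series:
    parts = []
    for _, g in df.groupby("session", sort=False):
        parts.append(g[col].shift(lag))
    return pd.concat(parts)


def confidence_regressions(
    traces: pd.DataFrame,
    standardize_outcome: bool = True,
    center_square: bool = True,
    residual_outcome_for_history: bool = True,
) -> pd.DataFrame:
    """Per-subject battery of confidence effects.

    For each subject the battery computes

    - ``beta_p2``: weight of the squared prediction in a multiple regression
      of confidence on ``p`` and ``p^2`` (the U-shape of confidence in the
      predictability of the next tone);
    - ``beta_prev_surprise``: weight of the previous trial's surprise in a
      single-predictor regression of confidence (within session);
    - ``beta_log_tsc``: weight of the log number of observations since the
      last generative change point;
    - ``corr_conf_p``: plain Pearson correlation between confidence and the
      prediction (expected near zero);
    - ``adj_corr_resid_conf``: within-session adjacent-trial correlation of
      residual confidence.

    Parameters
    ----------
    traces:
        Long DataFrame of observer traces with ``subject``, ``session``
        columns (see :func:`cwlearn.pipeline.simulate_cohort`).
    standardize_outcome:
        If True the outcome of the ``p^2`` regression is z-scored confidence;
        otherwise confidence in natural (log-precision) units.
    center_square:
        If True the square regressor is the square of the z-scored
        prediction, i.e. the squared deviation of ``p`` from its mean — a
        U-shape regressor nearly orthogonal to ``p`` itself.  If False the
        raw ``p^2`` is used (then heavily collinear with ``p``).
    residual_outcome_for_history:
        If True (default) the surprise and trials-since-change-point effects
        are estimated on residual confidence in natural units, isolating the
        history effects from the prediction-driven component; if False they
        are estimated on (z-scored) raw confidence.
    """
    rows = []
    for subject, g in traces.groupby("subject", sort=False):
        g = _valid_trials(g)
        if len(g) < 10:
            raise ValueError(f"subject {subject}: fewer than 10 valid trials")
        p = g["prediction"].to_numpy(dtype=float)
        c = g["confidence"].to_numpy(dtype=float)
        resid = residual_confidence(g.assign(flag_first=False))

        # (a) U-shape: confidence ~ p + p^2
        zp = zscore(p)
        sq = zp**2 if center_square else p**2
        X = np.column_stack([np.ones(len(g)), zp, zscore(sq)])
        y = zscore(c) if standardize_outcome else c
        beta_p2 = _ols(X, y)[0][2]

        # (b) previous-trial surprise -> confidence, within session
        prev_s = _lagged_within_session(g, "surprise_bits").to_numpy(dtype=float)
        ok = ~np.isnan(prev_s)
        hist_outcome = resid if residual_outcome_for_history else zscore(c)
        Xs = np.column_stack([np.ones(ok.sum()), zscore(prev_s[ok])])
        beta_prev = _ols(Xs, hist_outcome[ok])[0][1]

        # (c) log number of observations since the last change point
        log_tsc = np.log(g["trials_since_cp"].to_numpy(dtype=float))
        Xt = np.column_stack([np.ones(len(g)), zscore(log_tsc)])
        beta_tsc = _ols(Xt, hist_outcome)[0][1]

        # (d) linear relation between confidence and the prediction
        corr_cp = float(np.corrcoef(c, p)[0, 1])

        # (e) adjacent-trial correlation of residual confidence
        adj = adjacent_correlation(resid, g["session"].to_numpy())

        rows.append(
            {
                "subject": subject,
                "beta_p2": float(beta_p2),
                "beta_prev_surprise": float(beta_prev),
                "beta_log_tsc": float(beta_tsc),
                "corr_conf_p": corr_cp,
                "adj_corr_resid_conf": adj,
            }
        )
    return pd.DataFrame(rows)


def summarize_coefficients(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Group-level summary (mean, s.e.m., 95% CI, Cohen's d, t, p) per column."""
    rows = []
    for col in per_subject.columns:
        if col == "subject":
            continue
        v = per_subject[col].to_numpy(dtype=float)
        n = v.size
        mean = v.mean()
        sd = v.std(ddof=1)
        sem = sd / np.sqrt(n)
        t, p = sps.ttest_1samp(v, 0.0)
        ci = sps.t.interval(0.95, n - 1, loc=mean, scale=sem)
        rows.append(
            {
                "coefficient": col,
                "mean": mean,
                "sem": sem,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "cohen_d": mean / sd,
                "t": float(t),
                "p": float(p),
                "n": n,
            }
        )
    return pd.DataFrame(rows).set_index("coefficient")
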