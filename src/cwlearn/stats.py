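"""Group-level inferential machinery.

Mass-univariate multiple regression across timepoints, a one-dimensional
cluster-based permutation test (sign-flipping of whole subjects, maximal
summed-t cluster statistic), a cross-subject shuffle control that absorbs
shared temporal profiles, interleaved cross-validated ridge decoding, and
one-sample group t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import Ridge

from .features import DesignMatrix

__all__ = [
    "Cluster",
    "ClusterResult",
    "RidgeCVResult",
    "ShuffleControlResult",
    "GroupTTestResult",
    "mass_univariate_regression",
    "cluster_permutation_1d",
    "shuffle_control_z",
    "ridge_cv",
    "group_ttest",
]


# ---------------------------------------------------------------------------
# mass-univariate regression


def mass_univariate_regression(Y: np.ndarray, X) -> tuple[np.ndarray, np.ndarray]:
    """Independent OLS of each timepoint of ``Y`` on the design ``X``.

    Parameters
    ----------
    Y:
        ``trials x timepoints`` signal array (a 1-D array is treated as one
        timepoint).
    X:
        A :class:`~cwlearn.features.DesignMatrix` or a plain ``trials x k``
        array used as-is (callers z-score themselves in that case).

    Returns
    -------
    betas, tvals:
        ``k x timepoints`` arrays of coefficients and t-values.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    M = X.matrix() if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    n, k = M.shape
    if np.linalg.matrix_rank(M) < k:
        raise np.linalg.LinAlgError("collinear design matrix")
    if n != Y.shape[0]:
        raise ValueError("design and signal have different trial counts")
    xtx_inv = np.linalg.inv(M.T @ M)
    betas = xtx_inv @ M.T @ Y  # k x T
    resid = Y - M @ betas
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = betas / se
    return betas, tvals


# ---------------------------------------------------------------------------
# 1-D cluster-based permutation test


@dataclass
class Cluster:
    start: int
    stop: int  # exclusive
    mass: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    n_perm: int
    tail: str
    t_obs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


def _group_t(data: np.ndarray) -> np.ndarray:
    """One-sample t across subjects (axis 0) per timepoint."""
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return m / (sd / np.sqrt(n))


def _find_clusters(t: np.ndarray, threshold: float, tail: str) -> list[tuple[int, int, float]]:
    """Contiguous supra-threshold runs with sign-consistent mass."""
    if tail == "two":
        above = np.abs(t) > threshold
        signs = np.sign(t)
    else:
        above = t > threshold
        signs = np.ones_like(t)
    clusters = []
    i = 0
    T = len(t)
    while i < T:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < T and above[j] and signs[j] == signs[i]:
            j += 1
        clusters.append((i, j, float(t[i:j].sum())))
        i = j
    return clusters


def cluster_permutation_1d(
    subject_stats: np.ndarray,
    cluster_forming_p: float = 0.05,
    n_perm: int = 1000,
    tail: str = "two",
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-based permutation test over one dimension (e.g. time).

    A group-level one-sample t-statistic is computed per timepoint across
    subjects; contiguous runs exceeding the cluster-forming threshold form
    clusters scored by their summed t.  The null distribution of the maximal
    cluster mass is built by randomly sign-flipping whole subjects ``n_perm``
    times; each observed cluster's p-value is the fraction of null maxima at
    least as large (with the +1 correction so p > 0).
    """
    data = np.asarray(subject_stats, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a subjects x timepoints array with >= 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    S, T = data.shape
    dof = S - 1
    q = cluster_forming_p / 2 if tail == "two" else cluster_forming_p
    threshold = float(sps.t.ppf(1 - q, dof))

    t_obs = _group_t(data)
    observed = _find_clusters(t_obs, threshold, tail)

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, S))
    # sign flips leave per-subject squares unchanged: var from fixed E[x^2]
    sq_mean = (data**2).mean(axis=0)  # T
    m_perm = flips @ data / S  # n_perm x T
    var_perm = (sq_mean[None, :] - m_perm**2) * S / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = m_perm / np.sqrt(var_perm / S)

    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        cl = _find_clusters(t_perm[i], threshold, tail)
        if cl:
            masses = [abs(m) if tail == "two" else m for *_, m in cl]
            null_max[i] = max(masses)

    clusters = []
    for start, stop, mass in observed:
        ref = abs(mass) if tail == "two" else mass
        p = (np.sum(null_max >= ref) + 1.0) / (n_perm + 1.0)
        clusters.append(Cluster(start=start, stop=stop, mass=mass, p_value=float(p)))
    return ClusterResult(
        clusters=clusters, threshold=threshold, n_perm=n_perm, tail=tail, t_obs=t_obs
    )


# ---------------------------------------------------------------------------
# cross-subject shuffle control


@dataclass
class ShuffleControlResult:
    observed: np.ndarray
    z: np.ndarray
    t: float
    p: float


def shuffle_control_z(
    signal_per_subject: list[np.ndarray],
    regressor_per_subject: list[np.ndarray],
    n_shuffle: int = 1000,
    seed: int | None = None,
) -> ShuffleControlResult:
    """Control for a shared temporal profile via cross-subject shuffling.

    The observed statistic is each subject's correlation between their signal
    and their own regressor time-course.  The null pairs each subject's
    signal with regressors drawn from *other* subjects (truncating to the
    shorter series), so any component shared across subjects — a generic
    within-session profile — survives in the null and is absorbed by the
    Z-normalization ``(observed - null mean) / null SD``.  A one-sample
    t-test on the per-subject Z values gives the group-level test.
    """
    n_sub = len(signal_per_subject)
    if n_sub < 3 or len(regressor_per_subject) != n_sub:
        raise ValueError("need >= 3 subjects with matching signal/regressor lists")
    rng = np.random.default_rng(seed)

    def corr(a, b):
        k = min(len(a), len(b))
        return float(np.corrcoef(a[:k], b[:k])[0, 1])

    observed = np.array(
        [corr(signal_per_subject[i], regressor_per_subject[i]) for i in range(n_sub)]
    )
    null = np.empty((n_shuffle, n_sub))
    others = [[j for j in range(n_sub) if j != i] for i in range(n_sub)]
    for s in range(n_shuffle):
        for i in range(n_sub):
            j = others[i][rng.integers(len(others[i]))]
            null[s, i] = corr(signal_per_subject[i], regressor_per_subject[j])
    z = (observed - null.mean(axis=0)) / null.std(axis=0, ddof=1)
    t, p = sps.ttest_1samp(z, 0.0)
    return ShuffleControlResult(observed=observed, z=z, t=float(t), p=float(p))


# ---------------------------------------------------------------------------
# cross-validated ridge decoding


@dataclass
class RidgeCVResult:
    predictions: np.ndarray
    rho: float
    weights: np.ndarray
    fold_of_row: np.ndarray


def ridge_cv(
    features: np.ndarray,
    target: np.ndarray,
    penalty: float = 0.01,
    n_folds: int = 20,
    seed: int | None = None,
) -> RidgeCVResult:
    """Interleaved k-fold cross-validated ridge regression.

    Features are z-scored across rows; row ``i`` belongs to fold
    ``i mod n_folds`` (interleaved assignment, deterministic; ``seed`` is
    accepted for interface symmetry but unused).  Each fold's predictions
    come from a ridge fit (penalty on the slopes, intercept unpenalized) on
    the remaining folds.  ``rho`` is the Pearson correlation between
    out-of-sample predictions and the target; ``weights`` are from a fit on
    all rows.
    """
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError("need at least n_folds rows")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    folds = np.arange(n) % n_folds
    preds = np.empty(n)
    for k in range(n_folds):
        test = folds == k
        model = Ridge(alpha=penalty).fit(X[~test], y[~test])
        preds[test] = model.predict(X[test])
    rho = float(np.corrcoef(preds, y)[0, 1])
    weights = Ridge(alpha=penalty).fit(X, y).coef_
    return RidgeCVResult(predictions=preds, rho=rho, weights=weights, fold_of_row=folds)


# ---------------------------------------------------------------------------
# group-level t-test


@dataclass
class GroupTTestResult:
    t: float
    p: float
    mean: float
    sem: float
    cohen_d: float
    ci_low: float
    ci_high: float
    n: int
    degenerate: bool = False


def group_ttest(values) -> GroupTTestResult:
    """One-sample t-test of per-subject scalars against zero.

    Returns t, p, mean, s.e.m., Cohen's d (mean/SD) and the 95% CI.  A
    zero-variance input is flagged degenerate with infinite t.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    # values identical to machine precision: the t statistic is not meaningful
    if sd <= 1e-12 * max(1.0, abs(mean)):
        inf_t = float(np.inf) * np.sign(mean) if mean != 0 else 0.0
        return GroupTTestResult(
            t=inf_t, p=0.0 if mean != 0 else 1.0, mean=mean, sem=0.0,
            cohen_d=float(np.inf) * np.sign(mean) if mean != 0 else 0.0,
            ci_low=mean, ci_high=mean, n=n, degenerate=True,
        )
    sem = sd / np.sqrt(n)
    t, p = sps.ttest_1samp(v, 0.0)
    ci = sps.t.interval(0.95, n - 1, loc=mean, scale=sem)
    return GroupTTestResult(
        t=float(t), p=float(p), mean=mean, sem=float(sem), cohen_d=mean / sd,
        ci_low=float(ci[0]), ci_high=float(ci[1]), n=n,
    )
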