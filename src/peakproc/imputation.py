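"""Missing-value imputation: SV, mean, median, feature-KNN, BPCA, random forest.

Every imputer returns a table with no missing cells and leaves observed
cells bit-identical.  The module also houses the NRMSE assessment harness:
mask a known fraction of a complete matrix at random, impute, and report the
root mean squared error over the masked cells normalised by the mean of the
complete matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import PeakTable
from .normalisation import normalise_sum
from .synthetic_data import inject_missing

__all__ = [
    "ImputationAssessment",
    "impute",
    "impute_small_value",
    "impute_mean",
    "impute_median",
    "impute_knn",
    "impute_bpca",
    "impute_rf",
    "assess_mvi",
]


def _values(table: PeakTable) -> np.ndarray:
    return np.where(table.missing, np.nan, table.intensities)


def _complete(table: PeakTable, filled: np.ndarray) -> PeakTable:
    values = table.intensities.copy()
    values[table.missing] = filled[table.missing]
    return table.with_values(values, np.zeros_like(table.missing))


def _feature_means(v: np.ndarray) -> np.ndarray:
    counts = np.sum(~np.isnan(v), axis=0)
    if np.any(counts == 0):
        raise ValueError("feature with no observed values cannot be imputed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(v, axis=0)


def impute_small_value(table: PeakTable) -> PeakTable:
    """Replace every missing cell by half the global minimum observed intensity."""
    if not table.observed.any():
        raise ValueError("no observed values in table")
    v = _values(table)
    fill = 0.5 * np.nanmin(v)
    return _complete(table, np.full_like(v, fill))


def impute_mean(table: PeakTable) -> PeakTable:
    """Replace missing cells by the per-feature mean over observed cells."""
    v = _values(table)
    return _complete(table, np.broadcast_to(_feature_means(v), v.shape))


def impute_median(table: PeakTable) -> PeakTable:
    """Replace missing cells by the per-feature median over observed cells."""
    v = _values(table)
    counts = np.sum(~np.isnan(v), axis=0)
    if np.any(counts == 0):
        raise ValueError("feature with no observed values cannot be imputed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(v, axis=0)
    return _complete(table, np.broadcast_to(med, v.shape))


# -- K nearest neighbour features --------------------------------------------------

def pairwise_feature_distances(v: np.ndarray) -> np.ndarray:
    """Euclidean distances between features over jointly observed samples.

    Distances are computed over the samples where both features are observed
    and rescaled by ``sqrt(n_samples / n_joint)`` to the full-length
    equivalent, so features with few joint observations are not favoured.
    Pairs with no joint sample get an infinite distance.
    """
    n = v.shape[0]
    m = (~np.isnan(v)).astype(float)
    z = np.where(np.isnan(v), 0.0, v)
    c = z.T @ z
    d = (z**2).T @ m
    joint = m.T @ m
    sq = d + d.T - 2.0 * c
    np.maximum(sq, 0.0, out=sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        sq *= n / joint
    sq[joint == 0] = np.inf
    return np.sqrt(sq)


def impute_knn(table: PeakTable, k: int = 10) -> PeakTable:
    """Impute each missing cell from the k nearest features.

    Neighbours are *features* ranked by Euclidean distance of their responses
    across samples (pairwise-complete, rescaled).  A missing cell
    (feature f, sample s) becomes the unweighted mean of the values at s
    among the k nearest features of f observed at s; when none of the k
    neighbours is observed at s the per-feature mean is used instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= table.n_features:
        raise ValueError("k must be smaller than the number of features")
    v = _values(table)
    feat_means = _feature_means(v)
    dist = pairwise_feature_distances(v)
    np.fill_diagonal(dist, np.inf)

    filled = v.copy()
    for f in np.flatnonzero(table.missing.any(axis=0)):
        order = np.argpartition(dist[f], k)[:k]
        rows = np.flatnonzero(table.missing[:, f])
        neigh = v[np.ix_(rows, order)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            est = np.nanmean(neigh, axis=1)
        est = np.where(np.isnan(est), feat_means[f], est)
        filled[rows, f] = est
    return _complete(table, filled)


# -- Bayesian PCA ------------------------------------------------------------------

def impute_bpca(
    table: PeakTable,
    n_axes: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> PeakTable:
    """Probabilistic-PCA imputation with automatic relevance determination.

    Variational Bayes probabilistic PCA with automatic-relevance priors on
    the loading axes.  The latent-score posterior for each sample is built
    from its *observed* coordinates only (so a missing cell never predicts
    itself); the loading posterior keeps a shared row covariance which both
    regularises the scores and feeds the ARD precisions, letting the model
    switch superfluous axes off even when the noise variance is small.
    Missing cells are replaced by the model expectation at every sweep.
    Deterministic: initialised from the eigendecomposition of the
    mean-imputed matrix.  Converged when the largest relative change of an
    imputed cell drops below ``tol``.
    """
    n, p = table.intensities.shape
    q_max = min(n, p) - 1
    q = q_max if n_axes is None else int(n_axes)
    if q > q_max:
        raise ValueError(f"n_axes must be <= min(n_samples, n_features) - 1 = {q_max}")
    if q == 0:
        return impute_mean(table)

    v = _values(table)
    miss = table.missing
    obs = ~miss
    n_obs = int(obs.sum())
    mu = _feature_means(v)
    xc = np.where(miss, mu, v)
    missing_cols = [np.flatnonzero(miss[i]) for i in range(n)]
    obs_counts = obs.sum(axis=1).astype(float)

    # initial loadings from the SVD of the mean-imputed, centred matrix
    y0 = xc - mu
    _, s, vt = np.linalg.svd(y0, full_matrices=False)
    w = vt[:q].T * (s[:q] / np.sqrt(n))  # p x q principal axes
    mean_var = float(np.sum(s**2)) / (n * p)
    sigma2 = max(float(np.sum(s[q:] ** 2)) / (n * max(p - q, 1)), 1e-3 * mean_var)
    sig_w = np.zeros((q, q))  # shared posterior covariance of a loading row
    alpha = p / (np.sum(w**2, axis=0) + np.finfo(float).eps)

    eps = np.finfo(float).eps
    prev_miss = xc[miss]
    converged = False
    eye_q = np.eye(q)
    for _ in range(max_iter):
        # mean from the completed matrix keeps the centring consistent with
        # the model (an observed-only mean de-ranks exactly low-rank data)
        mu = xc.mean(axis=0)
        y_obs0 = np.where(obs, v - mu, 0.0)  # observed residuals, zero-filled

        # E-step: score posterior per sample from its observed coordinates;
        # the loading-row covariance adds |obs_i| * sig_w of extra precision
        wtw = w.T @ w
        b = y_obs0 @ w
        z = np.empty((n, q))
        s_x = np.zeros((q, q))  # sum of score second moments
        resid_extra = 0.0
        for i in range(n):
            cols = missing_cols[i]
            a_i = wtw + obs_counts[i] * sig_w + sigma2 * eye_q
            if cols.size:
                wm = w[cols]
                a_i = a_i - wm.T @ wm - cols.size * sig_w
            inv_a = np.linalg.inv(a_i)
            z[i] = inv_a @ b[i]
            cov_z = sigma2 * inv_a
            s_x += cov_z
            # E[||W_o (x - xbar)||^2] contribution to the noise update
            resid_extra += float(np.sum((wtw + obs_counts[i] * sig_w) * cov_z))
        s_x += z.T @ z
        recon = z @ w.T
        xc = np.where(miss, mu + recon, v)

        # M-step: loading posterior with ARD prior; sig_w is its shared
        # row covariance and keeps the ARD denominators away from zero
        y = xc - mu
        p_mat = s_x + sigma2 * np.diag(alpha)
        p_inv = np.linalg.inv(p_mat)
        w = y.T @ z @ p_inv
        sig_w = sigma2 * p_inv
        alpha = p / (np.sum(w**2, axis=0) + p * np.diag(sig_w) + eps)

        resid = np.where(obs, y - z @ w.T, 0.0)
        sigma2 = max(float((np.sum(resid**2) + resid_extra) / n_obs), 1e-12)

        cur_miss = xc[miss]
        delta = (
            np.max(np.abs(cur_miss - prev_miss) / (np.abs(prev_miss) + eps))
            if cur_miss.size
            else 0.0
        )
        prev_miss = cur_miss
        if delta < tol:
            converged = True
            break
    if not converged and miss.any():
        warnings.warn("BPCA imputation did not converge; returning best iterate")
    return _complete(table, xc)


# -- missForest-style random forest ------------------------------------------------

def impute_rf(
    table: PeakTable,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int | None = None,
) -> PeakTable:
    """Iterative random-forest imputation (missForest scheme).

    Missing cells start at the feature mean; features are visited in order
    of ascending missing count, each regressed on all other features with a
    random forest fitted on the rows where it is observed, and its missing
    cells replaced by forest predictions.  Sweeps repeat until the
    normalised squared difference between successive imputations first
    increases, returning the previous iterate, or until ``max_iter``.
    Stochastic but reproducible for a fixed seed.
    """
    from sklearn.ensemble import RandomForestRegressor

    v = _values(table)
    if not table.missing.any():
        return _complete(table, v)
    feat_means = _feature_means(v)
    rng = np.random.default_rng(seed)
    xc = np.where(table.missing, feat_means, v)

    missing_counts = table.missing.sum(axis=0)
    todo = np.flatnonzero(missing_counts > 0)
    todo = todo[np.argsort(missing_counts[todo], kind="stable")]

    prev_diff = np.inf
    prev_xc = xc.copy()
    for _ in range(max_iter):
        for f in todo:
            obs_rows = np.flatnonzero(~table.missing[:, f])
            mis_rows = np.flatnonzero(table.missing[:, f])
            predictors = np.delete(xc, f, axis=1)
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(predictors[obs_rows], xc[obs_rows, f])
            xc[mis_rows, f] = forest.predict(predictors[mis_rows])
        num = float(np.sum((xc[table.missing] - prev_xc[table.missing]) ** 2))
        den = float(np.sum(xc[table.missing] ** 2)) or 1.0
        diff = num / den
        if diff >= prev_diff:
            xc = prev_xc  # last sweep made things worse: keep previous iterate
            break
        prev_diff = diff
        prev_xc = xc.copy()
    return _complete(table, xc)


# -- dispatch and assessment -------------------------------------------------------

_METHODS = {
    "SV": lambda t, seed: impute_small_value(t),
    "MN": lambda t, seed: impute_mean(t),
    "MD": lambda t, seed: impute_median(t),
    "KNN": lambda t, seed: impute_knn(t),
    "BPCA": lambda t, seed: impute_bpca(t),
    "RF": lambda t, seed: impute_rf(t, seed=seed),
}


def impute(table: PeakTable, method: str, seed: int | None = None) -> PeakTable:
    """Run one of the named imputation methods (``none`` returns a copy)."""
    if method == "none":
        return table.copy()
    try:
        fn = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown imputation method {method!r}") from None
    return fn(table, seed)


@dataclass
class ImputationAssessment:
    """NRMSE of one imputation method on one masked dataset."""

    method: str
    nrmse: float
    n_masked: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.nrmse < 0:
            raise ValueError("NRMSE cannot be negative")


def assess_mvi(
    table_complete: PeakTable,
    methods: Sequence[str] = ("SV", "MN", "MD", "KNN", "BPCA", "RF"),
    rate: float = 0.10,
    seed: int | None = None,
    *,
    sum_normalise: bool = True,
) -> list[ImputationAssessment]:
    """Mask a complete table at random and score each imputer by NRMSE.

    The table is SUM-normalised first (the convention of the assessment this
    harness mirrors), then ``floor(rate x cells)`` cells are masked uniformly
    at random (MCAR) and each method imputes them.  NRMSE is the root mean
    squared error over the *masked* cells divided by the mean of the
    complete matrix.
    """
    if table_complete.missing.any():
        raise ValueError("assessment requires a complete table; filter features first")
    base = normalise_sum(table_complete).table if sum_normalise else table_complete
    truth = base.intensities
    masked = inject_missing(base, rate, mnar_weight=0.0, seed=seed)
    cells = masked.missing
    matrix_mean = float(truth.mean())

    results = []
    for method in methods:
        imputed = impute(masked, method, seed=seed)
        err = imputed.intensities[cells] - truth[cells]
        nrmse = float(np.sqrt(np.mean(err**2)) / matrix_mean)
        results.append(
            ImputationAssessment(method=method, nrmse=nrmse, n_masked=int(cells.sum()), seed=seed)
        )
    return results
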