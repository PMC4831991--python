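"""Statistical engines: normality, two-group screens with BH-FDR, NIPALS PCA
tolerant of missing values, and PLS-DA with tenfold cross-validation.

The univariate screen runs a vectorised tie-corrected Mann-Whitney U (or
pooled-variance Student's t) per feature on observed cells only, excludes QC
samples, and adjusts with Benjamini-Hochberg over the features that could be
tested.  PCA uses the NIPALS algorithm with inner products restricted to
observed cells, so tables with residual missing values remain analysable;
PLS-DA requires a complete matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import PeakTable

__all__ = [
    "UnivariateResult",
    "PcaModel",
    "PlsdaModel",
    "test_normality",
    "univariate_screen",
    "fit_pca_nipals",
    "fit_plsda",
]


def test_normality(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one vector (3 <= n <= 5000)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3 or values.size > 5000:
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(values) == 0:
        raise ValueError("normality test undefined for a constant vector")
    res = stats.shapiro(values)
    return float(res.statistic), float(res.pvalue)


# -- two-group screens -------------------------------------------------------------

def _tie_term(column: np.ndarray) -> float:
    """Sum of t^3 - t over tied groups of the observed values of one column."""
    vals = column[~np.isnan(column)]
    _, counts = np.unique(vals, return_counts=True)
    counts = counts[counts > 1]
    return float(np.sum(counts**3 - counts))


def _mannwhitney_columns(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    """Two-sided tie-corrected Mann-Whitney p per column; NaN = missing.

    Asymptotic normal approximation with continuity correction; columns with
    fewer than 8 observations in either group are routed through the exact
    (scipy) computation.
    """
    n_a, p = va.shape
    v = np.vstack([va, vb])
    obs = ~np.isnan(v)
    na = obs[:n_a].sum(axis=0).astype(float)
    nb = obs[n_a:].sum(axis=0).astype(float)
    n = na + nb

    ranks = stats.rankdata(v, axis=0, nan_policy="omit")
    ra = np.nansum(ranks[:n_a], axis=0)
    u = ra - na * (na + 1) / 2.0
    mean_u = na * nb / 2.0

    # tie correction needs per-column multiplicities; only bother where ties exist
    tie = np.zeros(p)
    sorted_v = np.sort(v, axis=0)
    has_ties = np.any(np.diff(sorted_v, axis=0) == 0.0, axis=0)
    for j in np.flatnonzero(has_ties):
        tie[j] = _tie_term(v[:, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        var_u = na * nb / 12.0 * ((n + 1.0) - tie / (n * (n - 1.0)))
        z = (np.abs(u - mean_u) - 0.5) / np.sqrt(var_u)
    pvals = np.clip(2.0 * stats.norm.sf(z), 0.0, 1.0)
    pvals[var_u <= 0] = 1.0  # all values tied: no rank separation

    small = (na < 8) | (nb < 8)
    for j in np.flatnonzero(small):
        a = va[:, j][~np.isnan(va[:, j])]
        b = vb[:, j][~np.isnan(vb[:, j])]
        pvals[j] = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    return pvals


def _ttest_columns(va: np.ndarray, vb: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance Student's t per column; NaN = missing."""
    na = np.sum(~np.isnan(va), axis=0).astype(float)
    nb = np.sum(~np.isnan(vb), axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(va, axis=0), np.nanmean(vb, axis=0)
        sa = np.nanvar(va, axis=0, ddof=1)
        sb = np.nanvar(vb, axis=0, ddof=1)
    df = na + nb - 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = ((na - 1.0) * sa + (nb - 1.0) * sb) / df
        t = (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[~np.isfinite(t)] = 1.0  # zero pooled variance with equal means etc.
    return pvals


@dataclass
class UnivariateResult:
    """Per-feature p/q values of a two-group screen with BH-FDR flags."""

    per_feature: pd.DataFrame  # columns: p, q, significant (indexed by feature_id)
    test: str
    alpha: float
    n_tested: int

    @property
    def significant_features(self) -> list[str]:
        flags = self.per_feature["significant"].fillna(False).astype(bool)
        return list(self.per_feature.index[flags])

    @property
    def n_significant(self) -> int:
        return int(self.per_feature["significant"].fillna(False).astype(bool).sum())


def univariate_screen(
    table: PeakTable,
    class_a: str = "A",
    class_b: str = "B",
    test: str = "mann-whitney",
    alpha: float = 0.05,
    *,
    min_per_class: int = 3,
) -> UnivariateResult:
    """Two-sided per-feature screen between two classes with BH adjustment.

    QC samples are removed first.  Features with fewer than ``min_per_class``
    observed values in either class get p = NaN and are excluded from the BH
    family rather than imputed.
    """
    rows_a = np.flatnonzero(table.class_mask(class_a))
    rows_b = np.flatnonzero(table.class_mask(class_b))
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValueError(f"empty class: {class_a!r} has {rows_a.size}, {class_b!r} has {rows_b.size}")
    v = np.where(table.missing, np.nan, table.intensities)
    va, vb = v[rows_a], v[rows_b]

    enough = (np.sum(~np.isnan(va), axis=0) >= min_per_class) & (
        np.sum(~np.isnan(vb), axis=0) >= min_per_class
    )
    p = np.full(table.n_features, np.nan)
    if enough.any():
        if test == "mann-whitney":
            p[enough] = _mannwhitney_columns(va[:, enough], vb[:, enough])
        elif test == "t":
            p[enough] = _ttest_columns(va[:, enough], vb[:, enough])
        else:
            raise ValueError(f"unknown test {test!r}")

    q = np.full_like(p, np.nan)
    sig = np.zeros(table.n_features, dtype=bool)
    tested = ~np.isnan(p)
    if tested.any():
        reject, q_adj, _, _ = multipletests(p[tested], alpha=alpha, method="fdr_bh")
        q[tested] = q_adj
        sig[tested] = reject
    sig_col = pd.array(sig, dtype="boolean")
    sig_col[~tested] = pd.NA
    frame = pd.DataFrame({"p": p, "q": q, "significant": sig_col}, index=table.feature_ids)
    return UnivariateResult(per_feature=frame, test=test, alpha=alpha, n_tested=int(tested.sum()))


# -- PCA (NIPALS with missing data) ------------------------------------------------

@dataclass
class PcaModel:
    """NIPALS PCA scores/loadings with class-separation diagnostics."""

    scores: np.ndarray  # n_samples x n_comp
    loadings: np.ndarray  # n_features x n_comp, unit-norm columns
    explained_variance_pct: np.ndarray
    score_p_values: np.ndarray  # per component, class separation on biological samples
    score_tests: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _separation_test(scores: np.ndarray, labels: np.ndarray) -> tuple[float, str]:
    """t-test when both class score vectors pass Shapiro-Wilk, else Mann-Whitney."""
    groups = [scores[labels == c] for c in pd.unique(labels)]
    if len(groups) != 2 or min(len(g) for g in groups) < 3:
        return float("nan"), "none"
    normal = True
    for g in groups:
        if np.ptp(g) == 0:
            normal = False
            break
        normal &= stats.shapiro(g).pvalue >= 0.05
    if normal:
        return float(stats.ttest_ind(groups[0], groups[1], equal_var=True).pvalue), "t"
    return (
        float(stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue),
        "mann-whitney",
    )


def fit_pca_nipals(
    table: PeakTable,
    n_comp: int = 2,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> PcaModel:
    """NIPALS PCA with inner products over observed cells only.

    Features are mean-centred over their observed cells.  After each
    component the observed cells are deflated; explained variance per
    component is the drop in observed sum of squares, as a percentage of the
    total observed (centred) sum of squares.  QC samples enter the model but
    are excluded from the per-component class-separation test.
    """
    if n_comp > min(table.n_samples, table.n_features):
        raise ValueError("n_comp exceeds matrix rank bound")
    v = np.where(table.missing, np.nan, table.intensities)
    obs = ~np.isnan(v)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(v, axis=0)
    x = np.where(obs, v - mu, 0.0)  # residuals; zeros at missing drop out of sums
    total_ss = float(np.sum(x**2))

    scores, loadings, var_pct = [], [], []
    for _ in range(n_comp):
        ss_before = float(np.sum(x**2))
        if ss_before == 0:
            break
        t = x[:, int(np.argmax(np.sum(x**2, axis=0)))].copy()
        converged = False
        for _ in range(max_iter):
            # loadings: regression of each feature on t over observed cells
            denom_p = obs.T @ (t**2)
            p_vec = x.T @ t / np.where(denom_p > 0, denom_p, 1.0)
            norm = np.linalg.norm(p_vec)
            if norm == 0:
                break
            p_vec /= norm
            denom_t = obs @ (p_vec**2)
            t_new = x @ p_vec / np.where(denom_t > 0, denom_t, 1.0)
            if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-30):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            warnings.warn("NIPALS component did not converge; truncating model")
            break
        x = np.where(obs, x - np.outer(t, p_vec), 0.0)
        scores.append(t)
        loadings.append(p_vec)
        var_pct.append(100.0 * (ss_before - float(np.sum(x**2))) / total_ss)

    score_mat = np.column_stack(scores) if scores else np.empty((table.n_samples, 0))
    load_mat = np.column_stack(loadings) if loadings else np.empty((table.n_features, 0))

    labels = table.class_labels.to_numpy(dtype=object)
    bio = ~table.is_qc & ~pd.isna(labels)
    p_values, tests = [], []
    for j in range(score_mat.shape[1]):
        pj, test_name = _separation_test(score_mat[bio, j], labels[bio])
        p_values.append(pj)
        tests.append(test_name)
    return PcaModel(
        scores=score_mat,
        loadings=load_mat,
        explained_variance_pct=np.asarray(var_pct),
        score_p_values=np.asarray(p_values),
        score_tests=tests,
    )


# -- PLS-DA ------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """PLS1 discriminant model with tenfold cross-validated Q2."""

    n_components: int
    r2: float
    q2: float
    scores: np.ndarray
    loadings: np.ndarray
    weights: np.ndarray
    r2_per_component: np.ndarray
    q2_per_component: np.ndarray


def _pls1_fit(x: np.ndarray, y: np.ndarray, n_comp: int):
    """NIPALS PLS1 on centred data; returns weights, x-loadings, y-loadings, scores."""
    xr = x.copy()
    yr = y.copy()
    w_list, p_list, q_list, t_list = [], [], [], []
    for _ in range(n_comp):
        w = xr.T @ yr
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        t = xr @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p = xr.T @ t / tt
        q = float(yr @ t) / tt
        xr -= np.outer(t, p)
        yr = yr - q * t
        w_list.append(w)
        p_list.append(p)
        q_list.append(q)
        t_list.append(t)
    return (
        np.column_stack(w_list) if w_list else np.empty((x.shape[1], 0)),
        np.column_stack(p_list) if p_list else np.empty((x.shape[1], 0)),
        np.asarray(q_list),
        np.column_stack(t_list) if t_list else np.empty((x.shape[0], 0)),
    )


def _pls1_predict(x: np.ndarray, w: np.ndarray, p: np.ndarray, q: np.ndarray, n_comp: int) -> np.ndarray:
    xr = x.copy()
    yhat = np.zeros(x.shape[0])
    for a in range(min(n_comp, w.shape[1])):
        t = xr @ w[:, a]
        yhat += q[a] * t
        xr -= np.outer(t, p[:, a])
    return yhat


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in pd.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for i, sample in enumerate(idx):
            folds[i % n_folds].append(int(sample))
    return [np.asarray(sorted(f)) for f in folds]


def fit_plsda(
    table: PeakTable,
    class_a: str = "A",
    class_b: str = "B",
    max_comp: int = 5,
    n_folds: int = 10,
    seed: int | None = None,
) -> PlsdaModel:
    """PLS1 discriminant analysis with stratified tenfold cross-validation.

    Requires a complete matrix (cross-validation is ill-defined with missing
    cells).  QC samples are excluded.  R2 is the in-model fraction of the
    centred class-indicator variance explained; Q2(A) = 1 - PRESS/TSS over
    seeded, class-stratified folds.  The component count maximising Q2 over
    ``1..max_comp`` is selected.
    """
    if table.missing.any():
        raise ValueError("PLS-DA requires a complete table (no missing values)")
    bio = table.class_mask(class_a) | table.class_mask(class_b)
    x_all = table.intensities[bio]
    lab = table.class_labels.to_numpy(dtype=object)[bio]
    if min(np.sum(lab == class_a), np.sum(lab == class_b)) < n_folds / 2:
        raise ValueError("each class needs enough members for stratified folds")
    y_all = (lab == class_a).astype(float)

    x_mu, y_mu = x_all.mean(axis=0), y_all.mean()
    xc, yc = x_all - x_mu, y_all - y_mu
    tss = float(np.sum(yc**2))

    w, p, q, t = _pls1_fit(xc, yc, max_comp)
    n_fit = w.shape[1]
    r2_per = np.array(
        [1.0 - np.sum((yc - _pls1_predict(xc, w, p, q, a + 1)) ** 2) / tss for a in range(n_fit)]
    )

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(lab, n_folds, rng)
    press = np.zeros(n_fit)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(lab)), test_idx)
        xm, ym = x_all[train].mean(axis=0), y_all[train].mean()
        wf, pf, qf, _ = _pls1_fit(x_all[train] - xm, y_all[train] - ym, n_fit)
        for a in range(n_fit):
            yhat = ym + _pls1_predict(x_all[test_idx] - xm, wf, pf, qf, a + 1)
            press[a] += float(np.sum((y_all[test_idx] - yhat) ** 2))
    q2_per = 1.0 - press / tss
    best = int(np.argmax(q2_per)) + 1 if n_fit else 0
    return PlsdaModel(
        n_components=best,
        r2=float(r2_per[best - 1]) if best else 0.0,
        q2=float(q2_per[best - 1]) if best else float("-inf"),
        scores=t[:, :best],
        loadings=p[:, :best],
        weights=w[:, :best],
        r2_per_component=r2_per,
        q2_per_component=q2_per,
    )
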