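"""Feature/sample filtering and missingness-structure diagnostics.

Two filtering rules are applied before any downstream processing: features
fully missing in exactly one class (but observed elsewhere) are filled with
half the global minimum observed intensity, then features and samples with
more than a threshold fraction (default 20 %) of missing values are removed.
Diagnostics correlate per-feature missing counts with m/z, retention time
and mean response to probe whether missingness is structured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PeakTable

__all__ = [
    "MissingnessDiagnostics",
    "FilterReport",
    "fill_class_absent",
    "filter_by_missing",
    "diagnose_missingness",
]


def fill_class_absent(table: PeakTable) -> PeakTable:
    """Fill features fully missing in one class with 0.5 x global minimum.

    For every feature observed in at least one class but fully missing in
    one (or more) other class(es), the missing cells of each fully-missing
    class are set to half the minimum observed intensity of the whole
    matrix.  Sporadically missing cells are untouched.  QC samples are
    ignored both when deciding and when filling.
    """
    observed = table.observed
    if not observed.any():
        raise ValueError("table has no observed values at all")
    fill_value = 0.5 * np.nanmin(table.intensities)

    bio = ~table.is_qc
    labels = table.class_labels
    classes = [c for c in pd.unique(labels[bio]) if not pd.isna(c)]
    values = table.intensities.copy()
    missing = table.missing.copy()
    for cls in classes:
        in_class = table.class_mask(cls)
        rows = np.flatnonzero(in_class)
        other_rows = np.flatnonzero(bio & ~in_class & labels.notna().to_numpy())
        if rows.size == 0 or other_rows.size == 0:
            continue
        all_missing_here = missing[rows].all(axis=0)
        observed_elsewhere = (~missing[other_rows]).any(axis=0)
        cols = np.flatnonzero(all_missing_here & observed_elsewhere)
        if cols.size:
            values[np.ix_(rows, cols)] = fill_value
            missing[np.ix_(rows, cols)] = False
    return table.with_values(values, missing)


@dataclass
class FilterReport:
    """What the missingness filter removed, and why."""

    removed: pd.DataFrame  # columns: id, kind, missing_fraction
    missing_before_pct: float
    missing_after_pct: float

    def to_csv(self, path) -> None:
        self.removed.to_csv(path, index=False)


def filter_by_missing(
    table: PeakTable, threshold: float = 0.20
) -> tuple[PeakTable, FilterReport]:
    """Drop features, then samples, with more than ``threshold`` missing.

    The inequality is strict ("more than"), so a feature with exactly the
    threshold fraction missing is retained.  Features are filtered before
    samples; fractions are computed over all samples/features present at the
    time of each step (QC samples included).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    pct_before = 100.0 * table.missing.mean()

    feat_frac = table.missing.mean(axis=0)
    keep_features = feat_frac <= threshold
    if not keep_features.any():
        raise ValueError("missingness filter would remove every feature")
    removed = [
        {"id": fid, "kind": "feature", "missing_fraction": float(frac)}
        for fid, frac in zip(table.feature_ids[~keep_features], feat_frac[~keep_features])
    ]
    out = table.subset_features(np.flatnonzero(keep_features))

    samp_frac = out.missing.mean(axis=1)
    keep_samples = samp_frac <= threshold
    if not keep_samples.any():
        raise ValueError("missingness filter would remove every sample")
    removed += [
        {"id": sid, "kind": "sample", "missing_fraction": float(frac)}
        for sid, frac in zip(out.sample_ids[~keep_samples], samp_frac[~keep_samples])
    ]
    out = out.subset_samples(np.flatnonzero(keep_samples))

    report = FilterReport(
        removed=pd.DataFrame(removed, columns=["id", "kind", "missing_fraction"]),
        missing_before_pct=float(pct_before),
        missing_after_pct=float(100.0 * out.missing.mean()),
    )
    return out, report


@dataclass
class MissingnessDiagnostics:
    """Pearson correlations of per-feature missing counts with feature properties."""

    missing_counts: pd.Series
    r_mz: float
    r_rt: float
    r_mean_response: float
    missing_pct: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": [
                    "missing_pct",
                    "pearson_missing_vs_mz",
                    "pearson_missing_vs_rt",
                    "pearson_missing_vs_mean_response",
                ],
                "value": [self.missing_pct, self.r_mz, self.r_rt, self.r_mean_response],
            }
        )


def _safe_pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(f"Pearson correlation undefined for {what} (zero variance)")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def diagnose_missingness(table: PeakTable) -> MissingnessDiagnostics:
    """Correlate per-feature missing counts with m/z, RT and mean response.

    Mean response per feature is computed over observed cells only; features
    with no observed cell contribute NaN and are excluded pairwise from the
    mean-response correlation.
    """
    if table.n_features < 3:
        raise ValueError("need at least 3 features for missingness diagnostics")
    counts = table.missing.sum(axis=0).astype(float)
    mz = table.feature_meta["mz"].to_numpy(dtype=float)
    rt = table.feature_meta["rt"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_resp = np.nanmean(np.where(table.missing, np.nan, table.intensities), axis=0)
    ok = np.isfinite(mean_resp)
    return MissingnessDiagnostics(
        missing_counts=pd.Series(counts, index=table.feature_ids, name="n_missing"),
        r_mz=_safe_pearson(mz, counts, "missing vs m/z"),
        r_rt=_safe_pearson(rt, counts, "missing vs retention time"),
        r_mean_response=_safe_pearson(mean_resp[ok], counts[ok], "missing vs mean response"),
        missing_pct=float(100.0 * table.missing.mean()),
    )
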