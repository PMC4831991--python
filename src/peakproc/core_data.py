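"""Central data model and I/O for XCMS-style peak tables.

A peak table couples a samples x features intensity matrix with an explicit
boolean missing mask, per-feature metadata (m/z, retention time) and
per-sample metadata (class label, QC flag).  The on-disk convention is the
XCMS one -- features as rows, one column per sample -- while the in-memory
matrix keeps samples in rows so that normalisation is row-wise and scaling
is column-wise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PeakTable",
    "ProcessingPermutation",
    "PeakTableError",
    "DEFAULT_VOCABULARIES",
    "read_peak_table",
    "write_peak_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "enumerate_grid",
]


class PeakTableError(ValueError):
    """Malformed peak-table input (bad header, duplicate ids, negative values...)."""


# Closed per-stage vocabularies for the processing grid, in canonical order.
DEFAULT_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "normalisation": ("SUM", "PQN"),
    "mvi": ("none", "SV", "MN", "MD", "KNN", "BPCA", "RF"),
    "transformation": ("none", "glog", "nlog", "IHS"),
    "scaling": ("none", "auto", "pareto", "range", "vast"),
}


@dataclass(frozen=True)
class ProcessingPermutation:
    """One choice of method per pipeline stage.

    Stages apply in the fixed order normalisation -> missing-value imputation
    -> transformation -> scaling; ``none`` skips a stage where the grid
    allows it.
    """

    normalisation: str
    mvi: str
    transformation: str
    scaling: str

    def __post_init__(self) -> None:
        for stage in ("normalisation", "mvi", "transformation", "scaling"):
            value = getattr(self, stage)
            vocab = DEFAULT_VOCABULARIES[stage]
            if value not in vocab:
                raise ValueError(
                    f"unknown {stage} method {value!r}; expected one of {vocab}"
                )

    def label(self) -> str:
        return f"{self.normalisation}/{self.mvi}/{self.transformation}/{self.scaling}"


@dataclass
class PeakTable:
    """Samples x features intensity matrix with explicit missingness.

    Parameters
    ----------
    intensities
        Float array of shape ``(n_samples, n_features)``.  Cells flagged in
        ``missing`` hold NaN; observed cells are finite.  Raw (untransformed)
        intensities are non-negative; transformed/scaled tables may hold any
        real value.
    missing
        Boolean array, same shape; True marks a cell with no observed value.
    feature_meta
        DataFrame indexed by unique ``feature_id`` with columns ``mz`` (Da)
        and ``rt`` (seconds).
    sample_meta
        DataFrame indexed by unique ``sample_id`` with columns
        ``class_label`` (may be missing for QC samples) and ``is_qc`` (bool).
    """

    intensities: np.ndarray
    missing: np.ndarray
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.intensities.ndim != 2:
            raise PeakTableError("intensities must be a 2-D samples x features array")
        if self.missing.shape != self.intensities.shape:
            raise PeakTableError("missing mask shape differs from intensity shape")
        n_samples, n_features = self.intensities.shape
        if len(self.sample_meta) != n_samples:
            raise PeakTableError("sample_meta length differs from matrix rows")
        if len(self.feature_meta) != n_features:
            raise PeakTableError("feature_meta length differs from matrix columns")
        if self.sample_meta.index.has_duplicates:
            raise PeakTableError("duplicate sample ids")
        if self.feature_meta.index.has_duplicates:
            raise PeakTableError("duplicate feature ids")
        # keep mask and storage consistent: masked cells carry NaN
        self.intensities = self.intensities.copy()
        self.intensities[self.missing] = np.nan
        observed = self.intensities[~self.missing]
        if observed.size and not np.all(np.isfinite(observed)):
            raise PeakTableError("observed intensities must be finite")

    # -- shape / metadata helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> pd.Index:
        return self.sample_meta.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.feature_meta.index

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing

    @property
    def is_qc(self) -> np.ndarray:
        return self.sample_meta["is_qc"].to_numpy(dtype=bool)

    @property
    def class_labels(self) -> pd.Series:
        return self.sample_meta["class_label"]

    def class_mask(self, label: str, *, exclude_qc: bool = True) -> np.ndarray:
        """Boolean sample mask for one class; samples without a label are False."""
        lab = self.sample_meta["class_label"]
        mask = (lab == label).fillna(False).to_numpy(dtype=bool)
        if exclude_qc:
            mask &= ~self.is_qc
        return mask

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.intensities.copy(),
            self.missing.copy(),
            self.feature_meta.copy(),
            self.sample_meta.copy(),
        )

    def with_values(self, values: np.ndarray, missing: np.ndarray | None = None) -> "PeakTable":
        """Return a table sharing this table's metadata but new cell values."""
        return PeakTable(
            np.asarray(values, dtype=float),
            self.missing.copy() if missing is None else np.asarray(missing, dtype=bool),
            self.feature_meta.copy(),
            self.sample_meta.copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "PeakTable":
        keep = np.asarray(keep)
        return PeakTable(
            self.intensities[keep],
            self.missing[keep],
            self.feature_meta.copy(),
            self.sample_meta.iloc[keep].copy() if keep.dtype != bool else self.sample_meta.loc[keep].copy(),
        )

    def subset_features(self, keep: np.ndarray) -> "PeakTable":
        keep = np.asarray(keep)
        fmeta = self.feature_meta.loc[keep] if keep.dtype == bool else self.feature_meta.iloc[keep]
        return PeakTable(
            self.intensities[:, keep],
            self.missing[:, keep],
            fmeta.copy(),
            self.sample_meta.copy(),
        )

    def validate_raw(self) -> None:
        """Assert the invariant of an untransformed table: observed cells >= 0."""
        observed = self.intensities[~self.missing]
        if observed.size and np.any(observed < 0):
            raise PeakTableError("negative intensity in an untransformed peak table")


# -- I/O ---------------------------------------------------------------------------

_META_COLUMNS = ("feature_id", "mz", "rt")


def read_peak_table(
    path: str | Path,
    sample_meta: pd.DataFrame | str | Path | None = None,
    *,
    sep: str | None = None,
    zeros_as_missing: bool = True,
) -> PeakTable:
    """Read an XCMS-style peak table (features as rows).

    The first three columns must be ``feature_id, mz, rt``; every further
    column is a sample.  Empty cells and ``NA`` denote missing values; zeros
    are also mapped to missing when ``zeros_as_missing`` is set (XCMS reports
    unfilled peaks as zero or NA depending on settings).

    ``sample_meta`` may be a DataFrame or a path to a CSV with columns
    ``sample_id,class,is_qc``; when omitted, all samples are treated as
    non-QC with no class label.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(
        path, sep=sep, na_values=["NA"], keep_default_na=True, float_precision="round_trip"
    )
    if tuple(df.columns[:3]) != _META_COLUMNS:
        raise PeakTableError(
            f"malformed header: expected leading columns {_META_COLUMNS}, got {tuple(df.columns[:3])}"
        )
    if df["feature_id"].duplicated().any():
        raise PeakTableError("duplicate feature ids in peak table")
    sample_ids = list(df.columns[3:])
    if len(sample_ids) != len(set(sample_ids)):
        raise PeakTableError("duplicate sample ids in peak table header")
    values = df[sample_ids].to_numpy(dtype=float).T  # samples x features
    missing = np.isnan(values)
    if zeros_as_missing:
        missing |= values == 0.0
    if np.any(values[~missing] < 0):
        raise PeakTableError("negative intensity in peak table")

    feature_meta = df[["feature_id", "mz", "rt"]].set_index("feature_id")
    feature_meta.index = feature_meta.index.astype(str)

    if sample_meta is None:
        smeta = pd.DataFrame(
            {"class_label": pd.Series([pd.NA] * len(sample_ids), dtype=object),
             "is_qc": False},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    else:
        if not isinstance(sample_meta, pd.DataFrame):
            sample_meta = read_sample_metadata(sample_meta)
        try:
            smeta = sample_meta.loc[sample_ids]
        except KeyError as exc:
            raise PeakTableError(f"sample metadata missing entries: {exc}") from exc
    table = PeakTable(values, missing, feature_meta, smeta)
    table.validate_raw()
    return table


def write_peak_table(table: PeakTable, path: str | Path, *, sep: str | None = None) -> None:
    """Write a peak table in the features-as-rows convention; missing as NA."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.DataFrame(table.intensities.T, columns=table.sample_ids)
    df.insert(0, "rt", table.feature_meta["rt"].to_numpy())
    df.insert(0, "mz", table.feature_meta["mz"].to_numpy())
    df.insert(0, "feature_id", table.feature_ids)
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.17g")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read ``sample_id,class,is_qc`` CSV into the internal sample_meta frame."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "class", "is_qc"}
    if not required.issubset(df.columns):
        raise PeakTableError(f"sample metadata must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise PeakTableError("duplicate sample ids in metadata")
    is_qc = df["is_qc"].map(lambda v: str(v).strip().lower() in {"true", "1", "yes"})
    out = pd.DataFrame(
        {
            "class_label": df["class"].astype(object).where(df["class"].notna(), pd.NA),
            "is_qc": is_qc.to_numpy(dtype=bool),
        },
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    return out


def write_sample_metadata(table: PeakTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "class": table.sample_meta["class_label"].to_numpy(),
            "is_qc": table.is_qc,
        }
    )
    out.to_csv(path, index=False)


# -- processing grid ---------------------------------------------------------------

def enumerate_grid(
    options: Mapping[str, Sequence[str]] | None = None,
) -> list[ProcessingPermutation]:
    """Cartesian product of the per-stage vocabularies.

    Order is deterministic: stages iterate in the fixed pipeline order and
    each stage follows its canonical vocabulary order, independent of the
    order methods were supplied in.  The default grid has
    2 x 7 x 4 x 5 = 280 members.
    """
    vocab = dict(DEFAULT_VOCABULARIES)
    if options:
        for stage, methods in options.items():
            if stage not in vocab:
                raise ValueError(f"unknown pipeline stage {stage!r}")
            methods = list(methods)
            if not methods:
                raise ValueError(f"empty vocabulary for stage {stage!r}")
            for m in methods:
                if m not in DEFAULT_VOCABULARIES[stage]:
                    raise ValueError(f"unknown {stage} method {m!r}")
            # canonical order regardless of input order, no duplicates
            vocab[stage] = tuple(m for m in DEFAULT_VOCABULARIES[stage] if m in set(methods))
    return [
        ProcessingPermutation(n, i, t, s)
        for n, i, t, s in itertools.product(
            vocab["normalisation"], vocab["mvi"], vocab["transformation"], vocab["scaling"]
        )
    ]
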