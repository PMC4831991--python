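"""Shared fixtures: hand-built peak tables of known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from peakproc.core_data import PeakTable


def make_table(
    values: np.ndarray,
    missing: np.ndarray | None = None,
    classes: list | None = None,
    qc: list[bool] | None = None,
    mz: np.ndarray | None = None,
    rt: np.ndarray | None = None,
) -> PeakTable:
    """Build a PeakTable from a samples x features array with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if missing is None:
        missing = np.isnan(values)
    if classes is None:
        half = n // 2
        classes = ["A"] * half + ["B"] * (n - half)
    if qc is None:
        qc = [False] * n
    classes = [pd.NA if c is None else c for c in classes]
    fmeta = pd.DataFrame(
        {
            "mz": np.arange(p, dtype=float) + 100.0 if mz is None else np.asarray(mz, float),
            "rt": np.arange(p, dtype=float) * 10.0 + 60.0 if rt is None else np.asarray(rt, float),
        },
        index=pd.Index([f"F{i + 1:03d}" for i in range(p)], name="feature_id"),
    )
    smeta = pd.DataFrame(
        {"class_label": classes, "is_qc": qc},
        index=pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id"),
    )
    return PeakTable(values, np.asarray(missing, bool), fmeta, smeta)


@pytest.fixture
def small_table() -> PeakTable:
    """4 samples x 3 features, one missing cell, no QC."""
    x = np.array(
        [
            [10.0, 200.0, 3000.0],
            [12.0, np.nan, 2800.0],
            [9.0, 210.0, 3100.0],
            [11.0, 190.0, 2900.0],
        ]
    )
    return make_table(x)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
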