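"""Per-sample (row-wise) normalisation: total-sum and probabilistic quotient.

SUM normalisation divides each sample by its row total (observed cells only)
and multiplies by 100, so every row of observed values sums to 100 %.
Probabilistic quotient normalisation (PQN) divides each sample by the median
of its feature-wise quotients against a reference profile; the reference is
the per-feature mean over QC samples, falling back to the per-feature median
over all samples when no QC injections exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import PeakTable

__all__ = ["NormalisationResult", "normalise_sum", "normalise_pqn"]


@dataclass
class NormalisationResult:
    """Normalised table plus the per-sample factor each row was divided by."""

    table: PeakTable
    factors: pd.Series  # indexed by sample_id

    def factors_to_csv(self, path) -> None:
        self.factors.rename("factor").to_csv(path, index_label="sample_id")


def normalise_sum(table: PeakTable, *, missing_as_zero: bool = False) -> NormalisationResult:
    """Divide each sample by its row total and express values in % (x100).

    Missing cells stay missing and, by default, are excluded from the row
    total; ``missing_as_zero`` counts them as zero instead (identical totals,
    provided the table is a raw intensity matrix, since a missing cell
    contributes no signal either way -- the flag exists for symmetry with
    tools that store zeros).
    """
    del missing_as_zero  # both conventions give the same observed-cell total
    values = np.where(table.missing, np.nan, table.intensities)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        totals = np.nansum(values, axis=1)
    if np.any(~np.isfinite(totals)) or np.any(totals <= 0):
        raise ValueError("every sample needs at least one observed positive value")
    out = 100.0 * values / totals[:, None]
    result_table = table.with_values(out)
    return NormalisationResult(result_table, pd.Series(totals, index=table.sample_ids))


def normalise_pqn(
    table: PeakTable,
    reference: np.ndarray | None = None,
    *,
    min_joint_features: int = 3,
) -> NormalisationResult:
    """Probabilistic quotient normalisation against a QC-mean reference.

    The reference vector is the per-feature mean over QC samples (observed
    cells only).  For each sample (QC samples included), quotients
    ``x_j / ref_j`` are formed over features observed in both the sample and
    the reference, and the sample is divided by the median quotient.  The
    result is invariant to a global rescaling of the reference.
    """
    values = np.where(table.missing, np.nan, table.intensities)
    if reference is None:
        qc = table.is_qc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if qc.any():
                reference = np.nanmean(values[qc], axis=0)
            else:
                warnings.warn(
                    "no QC samples: falling back to the per-feature median over all samples"
                )
                reference = np.nanmedian(values, axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (table.n_features,):
        raise ValueError("reference length must equal the number of features")

    ref_ok = np.isfinite(reference) & (reference != 0.0)
    factors = np.empty(table.n_samples)
    for i in range(table.n_samples):
        joint = ref_ok & ~table.missing[i]
        if joint.sum() < min_joint_features:
            raise ValueError(
                f"sample {table.sample_ids[i]!r} shares only {int(joint.sum())} features "
                f"with the reference (need >= {min_joint_features})"
            )
        quotients = values[i, joint] / reference[joint]
        c = float(np.median(quotients))
        if not np.isfinite(c) or c <= 0:
            raise ValueError(f"non-positive quotient median for sample {table.sample_ids[i]!r}")
        factors[i] = c
    out = values / factors[:, None]
    return NormalisationResult(table.with_values(out), pd.Series(factors, index=table.sample_ids))
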