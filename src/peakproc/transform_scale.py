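"""Element-wise transformations and feature-wise scalings.

Transformations: the generalised logarithm ``z = ln(y + sqrt(y^2 + lambda))``
with a technical-replicate-estimated lambda, the natural logarithm, and the
inverse hyperbolic sine (identical to glog at lambda = 1).  Scalings: auto
(unit variance), Pareto (sqrt of the standard deviation), range, and VAST
(autoscale divided by the coefficient of variation).  Transformations act on
observed cells only and always precede scaling in a pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import optimize

from .core_data import PeakTable

__all__ = ["GlogParams", "optimize_lambda", "glog", "transform", "scale"]

TRANSFORMATIONS = ("glog", "nlog", "IHS")
SCALINGS = ("auto", "pareto", "range", "vast")


def glog(y: np.ndarray | float, lam: float) -> np.ndarray | float:
    """Generalised logarithm ``ln(y + sqrt(y^2 + lambda))``."""
    return np.log(y + np.sqrt(np.square(y) + lam))


@dataclass
class GlogParams:
    """Fitted glog parameter lambda with the optimisation diagnostics."""

    lam: float
    objective: float
    trace: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"lambda": float(self.lam), "objective": float(self.objective)}, fh)

    @classmethod
    def from_yaml(cls, path) -> "GlogParams":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(lam=float(data["lambda"]), objective=float(data.get("objective", np.nan)))


def _glog_objective(log10_lam: float, y: np.ndarray) -> float:
    """Jacobian-normalised replicate-variance objective J(lambda).

    J = SSE / GM^2 where SSE pools the within-feature sums of squared
    deviations of the transformed technical replicates and GM is the
    geometric mean over cells of the transform derivative 1/sqrt(y^2+lam).
    The raw SSE alone is degenerate (it vanishes as lambda grows and the
    transform flattens); dividing by the squared geometric-mean derivative
    makes the objective scale-invariant, following the maximum-likelihood
    treatment of the generalised logarithm.
    """
    lam = 10.0**log10_lam
    z = glog(y, lam)
    sse = float(np.sum((z - z.mean(axis=0)) ** 2))
    # log of geometric mean of dz/dy = -0.5 * mean(log(y^2 + lam))
    log_gm = -0.5 * float(np.mean(np.log(np.square(y) + lam)))
    return np.log(sse) - 2.0 * log_gm if sse > 0 else -np.inf


def optimize_lambda(qc_table: PeakTable, *, min_qc: int = 3) -> GlogParams:
    """Estimate lambda from QC technical replicates.

    Uses the QC samples of ``qc_table`` (or all samples when none are
    flagged), requires every QC cell observed, and minimises the
    scale-invariant objective by bounded search on log10(lambda) over
    ``[min(y)^2 * 1e-4, max(y)^2 * 1e4]``.
    """
    qc = qc_table.is_qc
    rows = np.flatnonzero(qc) if qc.any() else np.arange(qc_table.n_samples)
    if rows.size < min_qc:
        raise ValueError(f"need at least {min_qc} QC samples to estimate lambda")
    if qc_table.missing[rows].any():
        raise ValueError("QC cells must be observed; impute or drop features first")
    y = qc_table.intensities[rows]

    if float(np.sum((y - y.mean(axis=0)) ** 2)) == 0.0:
        warnings.warn("QC replicates have zero technical variance; lambda is undetermined")
        return GlogParams(lam=float(np.min(np.square(y)) * 1e-4), objective=0.0)

    y_pos = np.abs(y[y != 0])
    lo = np.log10(float(np.min(y_pos)) ** 2) - 4.0 if y_pos.size else -8.0
    hi = np.log10(float(np.max(np.abs(y)))) * 2 + 4.0
    trace: list[tuple[float, float]] = []

    def objective(log10_lam: float) -> float:
        val = _glog_objective(log10_lam, y)
        trace.append((10.0**log10_lam, val))
        return val

    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    return GlogParams(lam=float(10.0**res.x), objective=float(res.fun), trace=trace)


def transform(table: PeakTable, method: str, params: GlogParams | float | None = None) -> PeakTable:
    """Apply an element-wise transformation to the observed cells.

    ``glog`` needs ``params`` (a GlogParams or a bare lambda); ``nlog``
    requires all observed values strictly positive; ``IHS`` is glog with
    lambda fixed at 1.  Missing cells stay missing.
    """
    if method == "none":
        return table.copy()
    v = np.where(table.missing, np.nan, table.intensities)
    if method == "glog":
        if params is None:
            raise ValueError("glog transformation needs a fitted lambda")
        lam = params.lam if isinstance(params, GlogParams) else float(params)
        out = glog(v, lam)
    elif method == "IHS":
        out = glog(v, 1.0)
    elif method == "nlog":
        if np.any(v[~table.missing] <= 0):
            raise ValueError("natural log requires strictly positive observed values")
        out = np.log(v)
    else:
        raise ValueError(f"unknown transformation {method!r}")
    return table.with_values(out)


def scale(table: PeakTable, method: str, *, ddof: int = 1) -> PeakTable:
    """Apply a feature-wise scaling over observed cells.

    auto: (x - m)/s; pareto: (x - m)/sqrt(s); range: (x - m)/(max - min);
    vast: ((x - m)/s) * (m/s).  Standard deviations use n-1.  A feature with
    zero spread is set to all-zero with a warning; VAST with a zero mean is
    an error.  Missing cells stay missing.
    """
    if method == "none":
        return table.copy()
    if method not in SCALINGS:
        raise ValueError(f"unknown scaling {method!r}")
    v = np.where(table.missing, np.nan, table.intensities)
    counts = np.sum(~np.isnan(v), axis=0)
    if np.any(counts < 2):
        raise ValueError("every feature needs at least 2 observed values to scale")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(v, axis=0)
        s = np.nanstd(v, axis=0, ddof=ddof)
        spread = np.nanmax(v, axis=0) - np.nanmin(v, axis=0)

    centred = v - m
    if method == "range":
        denom = spread
    elif method == "auto":
        denom = s
    elif method == "pareto":
        denom = np.sqrt(s)
    else:  # vast
        if np.any(m == 0):
            raise ValueError("VAST scaling undefined for a feature with zero mean")
        denom = s * (s / m)

    degenerate = spread == 0
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} zero-spread feature(s) set to all-zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = centred / denom
    out[:, degenerate] = 0.0
    out[np.isnan(v)] = np.nan
    return table.with_values(out)
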