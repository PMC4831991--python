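"""Synthetic two-class UHPLC-MS peak tables with QC replicates and spike-ins.

The generator emulates the structure of a non-targeted serum feature matrix:
heavy-tailed base abundances spanning several decades, a low-rank latent
biological covariance shared across features, multiplicative technical noise
at QC-replicate level, per-sample injection/sensitivity scale drift, MCAR
(optionally abundance-dependent MNAR) missingness, and a spike-in
constructor that multiplies chosen features of one class by known fold
factors to create ground-truth positives.

Class labels on the null table are re-randomised until a Mann-Whitney U
screen on the SUM-normalised biological samples finds no feature with raw
p < 0.05, reproducing the construction of the benchmark dataset this
generator emulates; the unconditioned null remains available via
``null_condition="none"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PeakTable

__all__ = [
    "GeneratorConfig",
    "SpikePlan",
    "default_factor_grid",
    "generate_null_table",
    "inject_missing",
    "construct_modified_dataset",
    "generate_spiked_benchmark",
]

TERTILE_NAMES = ("low", "medium", "high")


def default_factor_grid() -> np.ndarray:
    """Spike fold-factor grid: 0.1..2.0 step 0.1 plus 2.5..10.0 step 0.5 (36 values)."""
    fine = np.round(np.arange(1, 21) * 0.1, 10)
    coarse = np.round(np.arange(5, 21) * 0.5, 10)
    return np.concatenate([fine, coarse])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults render the benchmark dataset at desk scale: 22 + 24 biological
    samples, 18 pooled-QC injections and 3000 features so the 96 spiked
    features stay a small fraction of the matrix (as in the dataset this
    emulates).  ``base_log_mean_range`` is in log10 intensity units;
    ``biological_sd`` and ``sample_scale_sd`` are natural-log standard
    deviations; ``qc_cv`` is the technical coefficient of variation.
    """

    n_samples_per_class: tuple[int, int] = (22, 24)
    n_qc: int = 18
    n_features: int = 3000
    latent_rank: int = 3
    base_log_mean_range: tuple[float, float] = (4.0, 8.0)
    biological_sd: float = 0.16
    sample_scale_sd: float = 0.15
    qc_cv: float = 0.08
    missing_rate: float = 0.078
    mnar_weight: float = 0.0
    class_names: tuple[str, str] = ("A", "B")
    null_condition: str = "raw"  # "raw" | "bh" | "none"
    max_label_tries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        n_a, n_b = self.n_samples_per_class
        if min(n_a, n_b) < 1 or self.n_qc < 0 or self.n_features < 1:
            raise ValueError("sample/feature counts must be positive")
        if not (0.0 <= self.missing_rate < 1.0 and 0.0 <= self.mnar_weight <= 1.0):
            raise ValueError("missing_rate must be in [0,1) and mnar_weight in [0,1]")
        if self.latent_rank < 0:
            raise ValueError("latent_rank must be >= 0")
        if self.biological_sd > 0 and self.qc_cv >= _cv_from_lnsd(self.biological_sd):
            raise ValueError("qc_cv must stay below the biological CV")
        if self.null_condition not in {"raw", "bh", "none"}:
            raise ValueError("null_condition must be 'raw', 'bh' or 'none'")


def _cv_from_lnsd(sd: float) -> float:
    return float(np.sqrt(np.exp(sd**2) - 1.0))


def _lnsd_from_cv(cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + cv**2)))


def _sum_normalise_rows(x: np.ndarray) -> np.ndarray:
    return 100.0 * x / x.sum(axis=1, keepdims=True)


def _mw_pvalues(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per feature (columns), asymptotic with ties."""
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", axis=0, method="asymptotic")
    return np.asarray(res.pvalue)


def generate_null_table(config: GeneratorConfig) -> PeakTable:
    """Generate a complete (no-missing) two-class table with QC replicates.

    Intensities are ``exp(base + latent + technical noise) * sample scale``;
    QC samples are technical replicates of the pooled mean profile
    ``exp(base)``.  Class labels carry no induced effect and, by default, are
    re-randomised until no feature is raw-significant (p < 0.05,
    Mann-Whitney on SUM-normalised biological samples).
    """
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_samples_per_class
    n_bio = n_a + n_b
    n = n_bio + config.n_qc
    p = config.n_features

    lo10, hi10 = config.base_log_mean_range
    base = rng.uniform(lo10, hi10, size=p) * np.log(10.0)

    if config.latent_rank > 0 and config.biological_sd > 0:
        loadings = rng.standard_normal((p, config.latent_rank))
        loadings *= config.biological_sd / np.linalg.norm(loadings, axis=1, keepdims=True)
        scores = rng.standard_normal((n_bio, config.latent_rank))
        biological = scores @ loadings.T
    else:
        biological = np.zeros((n_bio, p))

    tech_sd = _lnsd_from_cv(config.qc_cv) if config.qc_cv > 0 else 0.0
    log_bio = base + biological + rng.normal(0.0, tech_sd, size=(n_bio, p)) if tech_sd else base + biological
    log_qc = base + rng.normal(0.0, tech_sd, size=(config.n_qc, p)) if tech_sd else np.tile(base, (config.n_qc, 1))

    log_x = np.vstack([log_bio, log_qc])
    if config.sample_scale_sd > 0:
        log_x = log_x + rng.normal(0.0, config.sample_scale_sd, size=(n, 1))
    x = np.exp(log_x)

    labels = _assign_null_labels(x[:n_bio], n_a, n_b, config, rng)

    sample_ids = (
        [f"S{i + 1:03d}" for i in range(n_bio)]
        + [f"QC{i + 1:02d}" for i in range(config.n_qc)]
    )
    sample_meta = pd.DataFrame(
        {
            "class_label": list(labels) + [pd.NA] * config.n_qc,
            "is_qc": [False] * n_bio + [True] * config.n_qc,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    feature_meta = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(100.0, 1000.0, size=p), 4),
            "rt": np.round(rng.uniform(30.0, 900.0, size=p), 2),
        },
        index=pd.Index([f"F{i + 1:05d}" for i in range(p)], name="feature_id"),
    )
    return PeakTable(x, np.zeros_like(x, dtype=bool), feature_meta, sample_meta)


def _assign_null_labels(
    x_bio: np.ndarray, n_a: int, n_b: int, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    name_a, name_b = config.class_names
    base_labels = np.array([name_a] * n_a + [name_b] * n_b, dtype=object)
    if config.null_condition == "none":
        return rng.permutation(base_labels)
    x_norm = _sum_normalise_rows(x_bio)
    for _ in range(config.max_label_tries):
        labels = rng.permutation(base_labels)
        pvals = _mw_pvalues(x_norm[labels == name_a], x_norm[labels == name_b])
        if config.null_condition == "raw":
            clean = float(np.min(pvals)) >= 0.05
        else:  # "bh"
            m = pvals.size
            order = np.sort(pvals)
            clean = not np.any(order <= 0.05 * np.arange(1, m + 1) / m)
        if clean:
            return labels
    raise RuntimeError(
        f"could not find a null class assignment in {config.max_label_tries} tries"
    )


def inject_missing(
    table: PeakTable,
    rate: float,
    mnar_weight: float = 0.0,
    seed: int | None = None,
    *,
    allow_empty: bool = False,
) -> PeakTable:
    """Mask ``floor(rate * n_cells)`` additional cells.

    With ``mnar_weight=0`` the selection is uniform over currently observed
    cells (MCAR).  A positive ``mnar_weight`` routes that fraction of the
    masked cells through an abundance-dependent draw whose probability
    decreases with intensity, emulating below-limit-of-detection losses.
    Cells already missing are never re-selected.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if not 0.0 <= mnar_weight <= 1.0:
        raise ValueError("mnar_weight must be in [0, 1]")
    n_cells = table.intensities.size
    n_mask = int(np.floor(rate * n_cells))
    if n_mask == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    eligible = np.flatnonzero(~table.missing.ravel())
    if n_mask > eligible.size:
        raise ValueError("not enough observed cells to reach the requested rate")

    n_mnar = int(round(mnar_weight * n_mask))
    chosen: list[np.ndarray] = []
    if n_mnar > 0:
        values = table.intensities.ravel()[eligible]
        # linear-in-rank weight: smallest intensity most likely to vanish
        ranks = stats.rankdata(values, method="ordinal")
        weights = (eligible.size - ranks + 1).astype(float)
        weights /= weights.sum()
        mnar_cells = rng.choice(eligible, size=n_mnar, replace=False, p=weights)
        chosen.append(mnar_cells)
        eligible = np.setdiff1d(eligible, mnar_cells, assume_unique=False)
    n_mcar = n_mask - n_mnar
    if n_mcar > 0:
        chosen.append(rng.choice(eligible, size=n_mcar, replace=False))
    cells = np.concatenate(chosen)

    missing = table.missing.copy()
    missing.ravel()[cells] = True
    if not allow_empty:
        if np.any(missing.all(axis=1)):
            raise ValueError("injection would leave a sample fully missing")
        if np.any(missing.all(axis=0)):
            raise ValueError("injection would leave a feature fully missing")
    values = table.intensities.copy()
    values[missing] = np.nan
    return table.with_values(values, missing)


@dataclass
class SpikePlan:
    """Record of the spike-in modification: which features, tertile, factor."""

    entries: pd.DataFrame  # columns: feature_id, tertile, factor, target_class

    def __post_init__(self) -> None:
        required = {"feature_id", "tertile", "factor", "target_class"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"SpikePlan entries need columns {sorted(required)}")
        if self.entries["feature_id"].duplicated().any():
            raise ValueError("spiked features must be distinct")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.entries["feature_id"])

    def strong_features(self, low: float = 0.5, high: float = 2.0) -> list[str]:
        """Features whose fold factor is at most ``low`` or at least ``high``."""
        e = self.entries
        sel = (e["factor"] <= low) | (e["factor"] >= high)
        return list(e.loc[sel, "feature_id"])

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpikePlan":
        return cls(pd.read_csv(path, dtype={"feature_id": str}))


def construct_modified_dataset(
    table: PeakTable,
    n_per_tertile: int = 32,
    factor_grid: Sequence[float] | None = None,
    target_class: str = "A",
    seed: int | None = None,
    *,
    tertile_mode: str = "rank",
) -> tuple[PeakTable, SpikePlan]:
    """Spike known fold changes into one class to create ground-truth positives.

    Features are partitioned into low/medium/high abundance tertiles by their
    mean response over all samples (rank-based thirds by default;
    ``tertile_mode="range"`` splits the numeric range of means instead).
    ``n_per_tertile`` features per tertile are drawn uniformly without
    replacement and their intensities in ``target_class`` samples are
    multiplied by factors drawn without replacement from ``factor_grid``
    (with replacement only if the grid is smaller than ``n_per_tertile``).
    All other cells are returned bit-identical.
    """
    if tertile_mode not in {"rank", "range"}:
        raise ValueError("tertile_mode must be 'rank' or 'range'")
    grid = np.asarray(default_factor_grid() if factor_grid is None else factor_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("factor grid must contain positive factors")
    target_rows = np.flatnonzero(table.class_mask(target_class))
    if target_rows.size == 0:
        raise ValueError(f"no samples in target class {target_class!r}")

    means = np.nanmean(np.where(table.missing, np.nan, table.intensities), axis=0)
    if np.any(np.isnan(means)):
        raise ValueError("every feature needs at least one observed value")

    if tertile_mode == "rank":
        order = np.argsort(means, kind="stable")
        tertiles = np.array_split(order, 3)
    else:
        lo, hi = means.min(), means.max()
        edges = [lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0]
        bins = np.digitize(means, edges)
        tertiles = [np.flatnonzero(bins == k) for k in range(3)]
    for name, block in zip(TERTILE_NAMES, tertiles):
        if block.size < n_per_tertile:
            raise ValueError(
                f"tertile {name!r} has {block.size} features, fewer than n_per_tertile={n_per_tertile}"
            )

    rng = np.random.default_rng(seed)
    values = table.intensities.copy()
    records = []
    for name, block in zip(TERTILE_NAMES, tertiles):
        feats = rng.choice(block, size=n_per_tertile, replace=False)
        factors = rng.choice(grid, size=n_per_tertile, replace=n_per_tertile > grid.size)
        for f_idx, factor in zip(feats, factors):
            values[target_rows, f_idx] *= factor
            records.append(
                {
                    "feature_id": table.feature_ids[f_idx],
                    "tertile": name,
                    "factor": float(factor),
                    "target_class": target_class,
                }
            )
    plan = SpikePlan(pd.DataFrame.from_records(records))
    return table.with_values(values), plan


def generate_spiked_benchmark(
    config: GeneratorConfig,
    n_per_tertile: int = 32,
    factor_grid: Sequence[float] | None = None,
) -> tuple[PeakTable, SpikePlan]:
    """Null table -> spike-in -> missingness, with sub-seeds derived from config.seed.

    Spiking is applied to the complete table before missingness is injected,
    so ground-truth factors act on fully observed intensities.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    spike_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    miss_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    table = generate_null_table(config)
    spiked, plan = construct_modified_dataset(
        table,
        n_per_tertile=n_per_tertile,
        factor_grid=factor_grid,
        target_class=config.class_names[0],
        seed=spike_seed,
    )
    if config.missing_rate > 0:
        spiked = inject_missing(spiked, config.missing_rate, config.mnar_weight, miss_seed)
    return spiked, plan
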