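"""Grid evaluation of processing permutations against spike-in ground truth.

Each processing permutation (normalisation -> missing-value imputation ->
transformation -> scaling, in that fixed order) is applied to a spiked peak
table and scored three ways: a univariate true/false-positive count against
the spike plan, a PCA outcome (explained variance, PC1 score separation,
loading ranks of the spiked features, fold-change and abundance-effect
flags), and a PLS-DA outcome (R2, Q2, component count).  Rankings mirror
the evaluation protocol: univariate by TP then FP, PCA by PC1 p-value among
permutations driven by fold change but not abundance, PLS-DA by R2 among
models with R2 - Q2 below 0.20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import PeakTable, ProcessingPermutation
from .imputation import impute
from .normalisation import normalise_pqn, normalise_sum
from .stats_analysis import fit_pca_nipals, fit_plsda, univariate_screen
from .synthetic_data import SpikePlan
from .transform_scale import GlogParams, optimize_lambda, scale, transform

__all__ = [
    "PermutationError",
    "UnivariateOutcome",
    "MultivariateOutcome",
    "run_permutation",
    "estimate_glog_lambda",
    "score_univariate",
    "score_pca",
    "score_plsda",
    "rank_permutations",
    "evaluate_grid",
]


class PermutationError(RuntimeError):
    """A pipeline stage failed; carries the permutation it happened in."""

    def __init__(self, permutation: ProcessingPermutation, stage: str, cause: Exception):
        self.permutation = permutation
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{permutation.label()}] stage {stage!r} failed: {cause}")


def estimate_glog_lambda(table: PeakTable) -> GlogParams:
    """Fit the glog lambda on QC rows, dropping features with missing QC cells."""
    qc_rows = np.flatnonzero(table.is_qc)
    if qc_rows.size == 0:
        raise ValueError("glog lambda estimation needs QC samples")
    complete_qc = ~table.missing[qc_rows].any(axis=0)
    if not complete_qc.any():
        raise ValueError("no feature is fully observed across QC samples")
    return optimize_lambda(table.subset_features(np.flatnonzero(complete_qc)))


def run_permutation(
    table: PeakTable,
    perm: ProcessingPermutation,
    glog_params: GlogParams | None = None,
    seed: int | None = None,
) -> PeakTable:
    """Apply one permutation's stages in fixed order; "none" stages are skipped.

    The glog lambda is estimated on the post-normalisation, post-imputation
    QC rows when not supplied.  Stage errors re-raise as PermutationError
    with the permutation attached.
    """
    stage = "normalisation"
    try:
        if perm.normalisation == "SUM":
            out = normalise_sum(table).table
        else:
            out = normalise_pqn(table).table
        stage = "mvi"
        out = impute(out, perm.mvi, seed=seed)
        stage = "transformation"
        if perm.transformation == "glog":
            params = glog_params if glog_params is not None else estimate_glog_lambda(out)
            out = transform(out, "glog", params)
        else:
            out = transform(out, perm.transformation)
        stage = "scaling"
        out = scale(out, perm.scaling)
    except Exception as exc:  # noqa: BLE001 - converted into a typed error
        raise PermutationError(perm, stage, exc) from exc
    return out


@dataclass
class UnivariateOutcome:
    """True/false-positive counts of one permutation's univariate screen."""

    permutation: ProcessingPermutation
    total_significant: int
    true_positives: int

    @property
    def false_positives(self) -> int:
        return self.total_significant - self.true_positives


def score_univariate(
    processed: PeakTable,
    plan: SpikePlan,
    perm: ProcessingPermutation | None = None,
    test: str = "mann-whitney",
    alpha: float = 0.05,
    class_a: str = "A",
    class_b: str = "B",
) -> UnivariateOutcome:
    """Count significant features (q < alpha) and intersect with the spike plan."""
    result = univariate_screen(processed, class_a, class_b, test=test, alpha=alpha)
    significant = set(result.significant_features)
    tp = len(significant & set(plan.feature_ids))
    return UnivariateOutcome(
        permutation=perm if perm is not None else ProcessingPermutation("SUM", "none", "none", "none"),
        total_significant=len(significant),
        true_positives=tp,
    )


@dataclass
class MultivariateOutcome:
    """PCA and PLS-DA summaries for one permutation."""

    permutation: ProcessingPermutation
    # PCA block
    pc1_variance_pct: float = float("nan")
    pc2_variance_pct: float = float("nan")
    pc1_score_p: float = float("nan")
    spiked_rank_range_pc1: tuple[int, int] | None = None
    spiked_rank_range_pc2: tuple[int, int] | None = None
    spiked_rank_range_combined: tuple[int, int] | None = None
    fold_change_effect: bool = False
    abundance_effect: bool = False
    # PLS-DA block
    r2: float = float("nan")
    q2: float = float("nan")
    n_components: int = 0
    evaluable: bool = True

    @property
    def r2_q2_gap(self) -> float:
        return self.r2 - self.q2


def _loading_ranks(loadings_abs: np.ndarray) -> np.ndarray:
    """Rank 1 = largest absolute loading, computed among all features."""
    order = np.argsort(-loadings_abs, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, loadings_abs.size + 1)
    return ranks


def score_pca(
    processed: PeakTable,
    plan: SpikePlan,
    perm: ProcessingPermutation | None = None,
    abundance: np.ndarray | None = None,
    *,
    top_n: int = 10,
    spearman_alpha: float = 0.05,
) -> MultivariateOutcome:
    """Two-component PCA outcome: variances, PC1 separation, loading ranks, flags.

    The fold-change-effect flag is set when |ln factor| of the spiked
    features correlates positively (Spearman, p < alpha) with their combined
    |loading|.  The abundance-effect flag is set when the top-``top_n``
    spiked features by combined loading fail to cover all three abundance
    tertiles, or when mean feature abundance correlates with the combined
    loading over the spiked set.
    """
    model = fit_pca_nipals(processed, n_comp=2)
    out = MultivariateOutcome(
        permutation=perm if perm is not None else ProcessingPermutation("SUM", "none", "none", "none")
    )
    if model.n_components < 2:
        out.evaluable = False
        return out
    out.pc1_variance_pct = float(model.explained_variance_pct[0])
    out.pc2_variance_pct = float(model.explained_variance_pct[1])
    out.pc1_score_p = float(model.score_p_values[0])

    abs_l1 = np.abs(model.loadings[:, 0])
    abs_l2 = np.abs(model.loadings[:, 1])
    combined = np.sqrt(abs_l1**2 + abs_l2**2)
    feature_index = pd.Index(processed.feature_ids)
    spike_pos = feature_index.get_indexer(plan.feature_ids)
    spike_pos = spike_pos[spike_pos >= 0]
    if spike_pos.size == 0:
        return out

    for attr, vec in (
        ("spiked_rank_range_pc1", abs_l1),
        ("spiked_rank_range_pc2", abs_l2),
        ("spiked_rank_range_combined", combined),
    ):
        ranks = _loading_ranks(vec)[spike_pos]
        setattr(out, attr, (int(ranks.min()), int(ranks.max())))

    entries = plan.entries.set_index("feature_id").loc[feature_index[spike_pos]]
    log_factor = np.abs(np.log(entries["factor"].to_numpy(dtype=float)))
    spike_combined = combined[spike_pos]
    if np.ptp(log_factor) > 0 and np.ptp(spike_combined) > 0:
        rho = stats.spearmanr(log_factor, spike_combined)
        out.fold_change_effect = bool(rho.statistic > 0 and rho.pvalue < spearman_alpha)

    top = entries.iloc[np.argsort(-spike_combined, kind="stable")[:top_n]]
    tertile_gap = len(set(top["tertile"])) < 3
    abundance_corr = False
    if abundance is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            abundance = np.nanmean(
                np.where(processed.missing, np.nan, processed.intensities), axis=0
            )
    spike_abundance = np.asarray(abundance, dtype=float)[spike_pos]
    if np.ptp(spike_abundance) > 0 and np.ptp(spike_combined) > 0:
        rho = stats.spearmanr(spike_abundance, spike_combined)
        abundance_corr = bool(rho.pvalue < spearman_alpha)
    out.abundance_effect = bool(tertile_gap or abundance_corr)
    return out


def score_plsda(
    processed: PeakTable,
    plan: SpikePlan,
    perm: ProcessingPermutation | None = None,
    max_comp: int = 5,
    n_folds: int = 10,
    seed: int | None = None,
    outcome: MultivariateOutcome | None = None,
) -> MultivariateOutcome:
    """PLS-DA outcome: R2, Q2, component count; non-evaluable if missing remain."""
    del plan  # the spike plan is used by the PCA block; kept for interface symmetry
    out = outcome if outcome is not None else MultivariateOutcome(
        permutation=perm if perm is not None else ProcessingPermutation("SUM", "none", "none", "none")
    )
    if processed.missing.any():
        out.evaluable = False
        return out
    model = fit_plsda(processed, max_comp=max_comp, n_folds=n_folds, seed=seed)
    out.r2 = model.r2
    out.q2 = model.q2
    out.n_components = model.n_components
    return out


def rank_permutations(
    outcomes: Sequence[UnivariateOutcome | MultivariateOutcome],
    mode: str,
    *,
    r2_q2_bound: float = 0.20,
) -> pd.DataFrame:
    """Order permutations the way the evaluation protocol prescribes.

    univariate: TP descending, then FP ascending.  pca: keep rows with a
    fold-change effect and no abundance effect, sort by PC1 p ascending then
    PC1+PC2 variance descending.  plsda: keep evaluable rows with
    R2 - Q2 < bound, sort by R2 descending.  Ties always break on the
    permutation's lexicographic label, making the order total and stable.
    """
    if mode == "univariate":
        rows = [
            {
                "permutation": o.permutation.label(),
                "true_positives": o.true_positives,
                "false_positives": o.false_positives,
                "total_significant": o.total_significant,
            }
            for o in outcomes
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["true_positives", "false_positives", "permutation"],
            ascending=[False, True, True],
        ).reset_index(drop=True)

    rows = []
    for o in outcomes:
        rows.append(
            {
                "permutation": o.permutation.label(),
                "pc1_variance_pct": o.pc1_variance_pct,
                "pc2_variance_pct": o.pc2_variance_pct,
                "pc1_pc2_variance_pct": o.pc1_variance_pct + o.pc2_variance_pct,
                "pc1_score_p": o.pc1_score_p,
                "fold_change_effect": o.fold_change_effect,
                "abundance_effect": o.abundance_effect,
                "r2": o.r2,
                "q2": o.q2,
                "r2_q2_gap": o.r2_q2_gap,
                "n_components": o.n_components,
                "evaluable": o.evaluable,
            }
        )
    df = pd.DataFrame(rows)
    if mode == "pca":
        keep = df["evaluable"] & df["fold_change_effect"] & ~df["abundance_effect"]
        return (
            df[keep]
            .sort_values(
                ["pc1_score_p", "pc1_pc2_variance_pct", "permutation"],
                ascending=[True, False, True],
            )
            .reset_index(drop=True)
        )
    if mode == "plsda":
        keep = df["evaluable"] & (df["r2_q2_gap"] < r2_q2_bound) & df["r2"].notna()
        return (
            df[keep]
            .sort_values(["r2", "permutation"], ascending=[False, True])
            .reset_index(drop=True)
        )
    raise ValueError(f"unknown ranking mode {mode!r}")


@dataclass
class GridResult:
    """Everything a grid run produced: per-permutation outcomes and failures."""

    univariate: list[UnivariateOutcome] = field(default_factory=list)
    multivariate: list[MultivariateOutcome] = field(default_factory=list)
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)


def _checkpoint_record(
    perm: ProcessingPermutation,
    uni: UnivariateOutcome | None,
    multi: MultivariateOutcome | None,
    failure: str | None,
) -> dict:
    rec: dict = {"permutation": list(
        (perm.normalisation, perm.mvi, perm.transformation, perm.scaling)
    )}
    if failure is not None:
        rec["failure"] = failure
    if uni is not None:
        rec["univariate"] = {
            "total_significant": uni.total_significant,
            "true_positives": uni.true_positives,
        }
    if multi is not None:
        rec["multivariate"] = {
            k: getattr(multi, k)
            for k in (
                "pc1_variance_pct", "pc2_variance_pct", "pc1_score_p",
                "spiked_rank_range_pc1", "spiked_rank_range_pc2",
                "spiked_rank_range_combined", "fold_change_effect",
                "abundance_effect", "r2", "q2", "n_components", "evaluable",
            )
        }
    return rec


def _restore_from_record(rec: dict, result: "GridResult", failures: list) -> None:
    perm = ProcessingPermutation(*rec["permutation"])
    if "failure" in rec:
        failures.append({"permutation": perm.label(), "error": rec["failure"]})
    if "univariate" in rec:
        result.univariate.append(UnivariateOutcome(permutation=perm, **rec["univariate"]))
    if "multivariate" in rec:
        fields = dict(rec["multivariate"])
        for key in ("spiked_rank_range_pc1", "spiked_rank_range_pc2", "spiked_rank_range_combined"):
            if fields.get(key) is not None:
                fields[key] = tuple(fields[key])
        result.multivariate.append(MultivariateOutcome(permutation=perm, **fields))


def evaluate_grid(
    table: PeakTable,
    plan: SpikePlan,
    permutations: Iterable[ProcessingPermutation],
    seed: int | None = None,
    *,
    test: str = "mann-whitney",
    alpha: float = 0.05,
    max_comp: int = 5,
    n_folds: int = 10,
    run_univariate: bool = True,
    run_multivariate: bool = True,
    progress: bool = False,
    checkpoint: "str | None" = None,
) -> GridResult:
    """Run every permutation through the pipeline and score it.

    Imputed tables are cached per (normalisation, mvi) pair since the later
    stages do not feed back.  Failing permutations (for example nlog on a
    table containing zeros) are recorded as non-evaluable rows, never
    aborting the run.  Raw per-feature mean abundance is computed once on
    the input table and reused for the PCA abundance-effect flag.

    When ``checkpoint`` names a file, one JSON line is appended per scored
    permutation; an interrupted run restarted with the same checkpoint file
    restores those rows instead of recomputing them.
    """
    import json
    from pathlib import Path

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        abundance = np.nanmean(np.where(table.missing, np.nan, table.intensities), axis=0)

    done: dict[str, dict] = {}
    ckpt_path = Path(checkpoint) if checkpoint else None
    if ckpt_path is not None and ckpt_path.exists():
        for line in ckpt_path.read_text().splitlines():
            if line.strip():
                rec = json.loads(line)
                done["/".join(rec["permutation"])] = rec

    norm_cache: dict[str, PeakTable] = {}
    imputed_cache: dict[tuple[str, str], PeakTable] = {}
    lambda_cache: dict[tuple[str, str], GlogParams] = {}
    failures: list[dict] = []
    result = GridResult()

    def finish(perm, uni, multi, failure):
        if failure is not None:
            failures.append({"permutation": perm.label(), "error": failure})
        if uni is not None:
            result.univariate.append(uni)
        if multi is not None:
            result.multivariate.append(multi)
        if ckpt_path is not None:
            with ckpt_path.open("a") as fh:
                fh.write(json.dumps(_checkpoint_record(perm, uni, multi, failure)) + "\n")

    for i, perm in enumerate(permutations):
        if perm.label() in done:
            _restore_from_record(done[perm.label()], result, failures)
            if progress:
                print(f"[{i + 1}] {perm.label()} restored from checkpoint")
            continue
        try:
            if perm.normalisation not in norm_cache:
                norm_cache[perm.normalisation] = (
                    normalise_sum(table).table
                    if perm.normalisation == "SUM"
                    else normalise_pqn(table).table
                )
            key = (perm.normalisation, perm.mvi)
            if key not in imputed_cache:
                imputed_cache[key] = impute(norm_cache[perm.normalisation], perm.mvi, seed=seed)
            base = imputed_cache[key]
            if perm.transformation == "glog":
                if key not in lambda_cache:
                    lambda_cache[key] = estimate_glog_lambda(base)
                processed = transform(base, "glog", lambda_cache[key])
            else:
                processed = transform(base, perm.transformation)
            processed = scale(processed, perm.scaling)
        except Exception as exc:  # noqa: BLE001 - failures become report rows
            multi = (
                MultivariateOutcome(permutation=perm, evaluable=False)
                if run_multivariate
                else None
            )
            finish(perm, None, multi, str(exc))
            continue
        try:
            uni = (
                score_univariate(processed, plan, perm, test=test, alpha=alpha)
                if run_univariate
                else None
            )
            multi = None
            if run_multivariate:
                multi = score_pca(processed, plan, perm, abundance=abundance)
                multi = score_plsda(
                    processed, plan, perm, max_comp=max_comp, n_folds=n_folds, seed=seed,
                    outcome=multi,
                )
            finish(perm, uni, multi, None)
        except Exception as exc:  # noqa: BLE001
            multi = (
                MultivariateOutcome(permutation=perm, evaluable=False)
                if run_multivariate
                else None
            )
            finish(perm, None, multi, str(exc))
        if progress:
            print(f"[{i + 1}] {perm.label()} done")
    result.failures = pd.DataFrame(failures, columns=["permutation", "error"])
    return result
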