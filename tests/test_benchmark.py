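"""Pipeline permutations, spike scoring, and ranking rules."""

import numpy as np
import pandas as pd
import pytest

from peakproc.benchmark import (
    MultivariateOutcome,
    PermutationError,
    UnivariateOutcome,
    evaluate_grid,
    rank_permutations,
    run_permutation,
    score_pca,
    score_univariate,
)
from peakproc.core_data import ProcessingPermutation, enumerate_grid
from peakproc.normalisation import normalise_sum
from peakproc.synthetic_data import (
    GeneratorConfig,
    SpikePlan,
    construct_modified_dataset,
    generate_null_table,
    generate_spiked_benchmark,
)

from conftest import make_table


def tiny_benchmark(seed=1, n_features=80, n_per_tertile=4):
    cfg = GeneratorConfig(
        n_samples_per_class=(10, 10), n_qc=5, n_features=n_features, seed=seed
    )
    return generate_spiked_benchmark(cfg, n_per_tertile=n_per_tertile)


def empty_plan():
    return SpikePlan(
        pd.DataFrame(columns=["feature_id", "tertile", "factor", "target_class"])
    )


class TestRunPermutation:
    def test_single_active_stage_equals_normalise_sum(self):
        table, _ = tiny_benchmark()
        perm = ProcessingPermutation("SUM", "none", "none", "none")
        out = run_permutation(table, perm)
        ref = normalise_sum(table).table
        np.testing.assert_array_equal(out.intensities[~out.missing], ref.intensities[~ref.missing])

    def test_deterministic_for_fixed_seed(self):
        table, _ = tiny_benchmark()
        perm = ProcessingPermutation("PQN", "RF", "glog", "none")
        a = run_permutation(table, perm, seed=3)
        b = run_permutation(table, perm, seed=3)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_stage_error_carries_permutation_id(self):
        t = make_table(np.array([[0.0, 2.0], [1.0, 3.0]]), missing=np.zeros((2, 2), bool))
        perm = ProcessingPermutation("SUM", "none", "nlog", "none")
        with pytest.raises(PermutationError) as err:
            run_permutation(t, perm)
        assert err.value.permutation == perm
        assert err.value.stage == "transformation"


class TestScoring:
    def test_tp_fp_conservation(self):
        table, plan = tiny_benchmark()
        perm = ProcessingPermutation("PQN", "none", "none", "none")
        out = score_univariate(run_permutation(table, perm), plan, perm)
        assert out.true_positives + out.false_positives == out.total_significant
        assert out.true_positives <= len(plan)

    def test_empty_plan_makes_every_hit_a_false_positive(self):
        table, _ = tiny_benchmark()
        perm = ProcessingPermutation("PQN", "none", "none", "none")
        out = score_univariate(run_permutation(table, perm), empty_plan(), perm)
        assert out.true_positives == 0
        assert out.false_positives == out.total_significant

    def test_null_table_without_spikes_has_no_discoveries(self):
        cfg = GeneratorConfig(n_samples_per_class=(10, 10), n_qc=5, n_features=100, seed=4)
        table = generate_null_table(cfg)
        perm = ProcessingPermutation("SUM", "none", "none", "none")
        out = score_univariate(run_permutation(table, perm), empty_plan(), perm)
        assert out.total_significant == 0

    def test_single_dominant_spike_ranks_first_on_combined_loading(self):
        cfg = GeneratorConfig(
            n_samples_per_class=(10, 10), n_qc=5, n_features=60,
            seed=8, missing_rate=0.0,
        )
        table = generate_null_table(cfg)
        values = table.intensities.copy()
        values[table.class_mask("A"), 30] *= 10.0  # one spiked feature, rest null
        spiked = table.with_values(values)
        plan = SpikePlan(
            pd.DataFrame(
                [{"feature_id": table.feature_ids[30], "tertile": "medium",
                  "factor": 10.0, "target_class": "A"}]
            )
        )
        proc = run_permutation(spiked, ProcessingPermutation("SUM", "none", "nlog", "none"))
        outcome = score_pca(proc, plan)
        assert outcome.spiked_rank_range_combined[0] == 1

    def test_no_spiking_fold_change_flag_false(self):
        cfg = GeneratorConfig(n_samples_per_class=(10, 10), n_qc=5, n_features=60, seed=9)
        table = generate_null_table(cfg)
        proc = run_permutation(table, ProcessingPermutation("SUM", "none", "nlog", "none"))
        outcome = score_pca(proc, empty_plan())
        assert not outcome.fold_change_effect

    def test_untransformed_data_shows_abundance_effect(self):
        table, plan = tiny_benchmark(seed=3, n_features=120, n_per_tertile=6)
        proc = run_permutation(table, ProcessingPermutation("SUM", "MN", "none", "none"))
        outcome = score_pca(proc, plan)
        # raw-scale variance tracks abundance: top loadings are high-tertile only
        assert outcome.abundance_effect


class TestRanking:
    def _uni(self, label, tp, fp):
        perm = ProcessingPermutation(*label.split("/"))
        return UnivariateOutcome(perm, total_significant=tp + fp, true_positives=tp)

    def test_univariate_lower_fp_ranks_first_on_tp_tie(self):
        a = self._uni("SUM/none/none/none", 80, 3)
        b = self._uni("PQN/none/none/none", 80, 0)
        ranked = rank_permutations([a, b], "univariate")
        assert ranked.iloc[0]["permutation"] == "PQN/none/none/none"

    def test_univariate_tp_dominates(self):
        a = self._uni("SUM/none/none/none", 90, 5)
        b = self._uni("PQN/none/none/none", 80, 0)
        assert rank_permutations([a, b], "univariate").iloc[0]["true_positives"] == 90

    def _mv(self, label, **kw):
        perm = ProcessingPermutation(*label.split("/"))
        return MultivariateOutcome(permutation=perm, **kw)

    def test_pca_mode_excludes_abundance_effect_rows(self):
        keep = self._mv("SUM/RF/glog/none", fold_change_effect=True, abundance_effect=False,
                        pc1_score_p=1e-8, pc1_variance_pct=40, pc2_variance_pct=20)
        drop = self._mv("SUM/SV/glog/none", fold_change_effect=True, abundance_effect=True,
                        pc1_score_p=1e-12, pc1_variance_pct=50, pc2_variance_pct=20)
        ranked = rank_permutations([keep, drop], "pca")
        assert list(ranked["permutation"]) == ["SUM/RF/glog/none"]

    def test_plsda_mode_filters_gap_and_sorts_r2(self):
        good = self._mv("PQN/KNN/glog/none", r2=0.61, q2=0.46)
        better_r2_overfit = self._mv("SUM/SV/glog/none", r2=0.90, q2=0.30)
        lower = self._mv("SUM/KNN/glog/none", r2=0.59, q2=0.51)
        ranked = rank_permutations([good, better_r2_overfit, lower], "plsda")
        assert list(ranked["permutation"]) == ["PQN/KNN/glog/none", "SUM/KNN/glog/none"]

    def test_ranking_deterministic_total_order(self):
        rows = [self._uni(f"SUM/{m}/none/none", 10, 1) for m in ("none", "SV", "MN")]
        a = rank_permutations(rows, "univariate")
        b = rank_permutations(list(reversed(rows)), "univariate")
        assert list(a["permutation"]) == list(b["permutation"])


class TestEvaluateGrid:
    def test_failures_recorded_not_raised(self):
        # a zero intensity makes nlog fail; the grid run must survive
        x = np.exp(np.random.default_rng(0).normal(5, 0.5, (12, 20)))
        x[0, 0] = 0.0
        t = make_table(x, missing=np.zeros_like(x, bool),
                       classes=["A"] * 6 + ["B"] * 6)
        grid = [
            ProcessingPermutation("SUM", "none", "nlog", "none"),
            ProcessingPermutation("SUM", "none", "none", "none"),
        ]
        res = evaluate_grid(t, empty_plan(), grid, seed=1, run_multivariate=False)
        assert len(res.failures) == 1
        assert "nlog" in res.failures.iloc[0]["permutation"]
        assert len(res.univariate) == 1

    def test_full_small_grid_row_count(self):
        table, plan = tiny_benchmark(seed=2)
        grid = enumerate_grid(
            {"mvi": ["none", "MN"], "transformation": ["none", "IHS"], "scaling": ["none", "pareto"]}
        )
        res = evaluate_grid(table, plan, grid, seed=2, run_multivariate=False)
        assert len(res.univariate) + len(res.failures) == len(grid) == 16

    def test_checkpoint_restores_interrupted_run(self, tmp_path, monkeypatch):
        table, plan = tiny_benchmark(seed=5)
        grid = enumerate_grid(
            {"mvi": ["none", "MN"], "transformation": ["none"], "scaling": ["none", "auto"]}
        )
        ckpt = tmp_path / "checkpoint.jsonl"
        # "interrupted" first run covers only half the grid
        first = evaluate_grid(table, plan, grid[:4], seed=5, checkpoint=str(ckpt))
        assert ckpt.exists() and len(ckpt.read_text().splitlines()) == 4

        # resumed run must not recompute the checkpointed permutations: poison
        # the imputer for the (norm, mvi) pairs already covered
        import peakproc.benchmark as bench

        real_impute = bench.impute
        calls = []

        def counting_impute(t, method, seed=None):
            calls.append(method)
            return real_impute(t, method, seed=seed)

        monkeypatch.setattr(bench, "impute", counting_impute)
        full = evaluate_grid(table, plan, grid, seed=5, checkpoint=str(ckpt))
        assert len(full.univariate) + len(full.failures) == len(grid)
        # only the second half's (norm, mvi) combinations were computed
        assert len(calls) <= 2
        fresh = evaluate_grid(table, plan, grid, seed=5)
        got = {o.permutation.label(): (o.true_positives, o.false_positives) for o in full.univariate}
        want = {o.permutation.label(): (o.true_positives, o.false_positives) for o in fresh.univariate}
        assert got == want
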