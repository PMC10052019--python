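"""Tests for repeated-split evaluation, leakage guard and reporting."""

import numpy as np
import pandas as pd
import pytest

from zotrad import (
    FeatureTable,
    GAConfig,
    LeakageGuardError,
    ProcedureResult,
    SplitConfig,
    TableSpec,
    evolve,
    generate_feature_table,
    leakage_gap,
    run_procedure_a,
    run_procedure_b,
    selection_rates,
    stratified_split,
    summarize,
)
from zotrad._seeds import derive_seed
from zotrad.evaluation import RepeatOutcome, _fit_and_score, _guarded_selection

SMALL_GA = GAConfig(population_size=8, generations=4)


@pytest.fixture
def separator_table(rng):
    """20-row table whose first column equals the label exactly."""
    y = np.array([0, 1] * 10)
    X = np.column_stack([y.astype(float), rng.standard_normal((20, 4))])
    names = ["firstorder_Label", "firstorder_N1", "firstorder_N2", "firstorder_N3", "firstorder_N4"]
    return FeatureTable(pd.DataFrame(X, columns=names), pd.Series(y))


class TestStratifiedSplit:
    def test_balanced_ten_rows(self, rng):
        t = FeatureTable(
            pd.DataFrame(rng.standard_normal((10, 2)), columns=["firstorder_A", "firstorder_B"]),
            pd.Series([0] * 5 + [1] * 5),
        )
        tr, te = stratified_split(t, 0.8, seed=0)
        y = t.labels()
        assert len(tr) == 8 and len(te) == 2
        assert y[tr].sum() == 4 and y[te].sum() == 1

    def test_cohort_shape_proportions(self):
        t = generate_feature_table(TableSpec(n_samples=77, n_features=5, seed=1))
        tr, te = stratified_split(t, 0.8, seed=3)
        y = t.labels()
        assert len(tr) in (61, 62)
        frac_tr = y[tr].mean()
        assert abs(frac_tr - 0.61) <= 1 / len(tr)  # within one sample of 61%

    def test_partition_properties(self, rng):
        t = generate_feature_table(TableSpec(n_samples=33, n_features=4, seed=2))
        tr, te = stratified_split(t, 0.8, seed=9)
        assert len(set(tr) & set(te)) == 0
        assert sorted(np.concatenate([tr, te])) == list(range(33))

    def test_deterministic_per_seed(self):
        t = generate_feature_table(TableSpec(n_samples=30, n_features=3, seed=0))
        assert (stratified_split(t, 0.8, 5)[0] == stratified_split(t, 0.8, 5)[0]).all()
        assert not (stratified_split(t, 0.8, 5)[0] == stratified_split(t, 0.8, 6)[0]).all()

    def test_empty_test_share_rejected(self, rng):
        t = FeatureTable(
            pd.DataFrame(rng.standard_normal((6, 2)), columns=["firstorder_A", "firstorder_B"]),
            pd.Series([0, 0, 0, 0, 0, 1]),
        )
        with pytest.raises(ValueError):
            stratified_split(t, 0.8, seed=0)


class TestProcedures:
    def test_perfect_separator_all_repeats_auc_one(self, separator_table):
        ga = GAConfig(population_size=10, generations=6, cv_folds=5)
        res = run_procedure_a(separator_table, ga, SplitConfig(n_repeats=3, master_seed=1))
        assert res.aucs().tolist() == [1.0, 1.0, 1.0]

    def test_single_repeat_reproduces_manual_composition(self, separator_table):
        """n_repeats=1 equals one manual GA + split + fit run with derived seeds."""
        sp = SplitConfig(n_repeats=1, master_seed=4)
        res = run_procedure_a(separator_table, SMALL_GA, sp)

        split_seed = derive_seed(4, "split", 0)
        ga_seed = derive_seed(4, "ga", 0)
        tree_seed = derive_seed(4, "tree", 0)
        from dataclasses import replace

        manual_sel = evolve(separator_table, replace(SMALL_GA, seed=ga_seed))
        tr, te = stratified_split(separator_table, 0.8, split_seed)
        manual_auc = _fit_and_score(separator_table, tr, te, manual_sel.selected_names, tree_seed)
        assert res.per_repeat[0].selected_names == manual_sel.selected_names
        assert res.per_repeat[0].test_auc == manual_auc

    def test_procedures_share_split_sequence(self, separator_table):
        sp = SplitConfig(n_repeats=2, master_seed=8)
        ra = run_procedure_a(separator_table, SMALL_GA, sp)
        rb = run_procedure_b(separator_table, SMALL_GA, sp)
        assert [r.split_seed for r in ra.per_repeat] == [r.split_seed for r in rb.per_repeat]

    def test_guard_trips_on_full_table(self, separator_table):
        tr, _ = stratified_split(separator_table, 0.8, 0)
        train_ids = [separator_table.row_ids[i] for i in tr]
        with pytest.raises(LeakageGuardError):
            _guarded_selection(separator_table, train_ids, SMALL_GA)

    def test_procedure_b_test_set_isolation(self, separator_table):
        """Permuting test-row feature values does not change B's selections."""
        sp = SplitConfig(n_repeats=2, master_seed=3)
        rb1 = run_procedure_b(separator_table, SMALL_GA, sp)
        # scramble the test rows of every repeat's split (recompute them)
        X2 = separator_table.X.copy()
        rng = np.random.default_rng(0)
        for r in range(sp.n_repeats):
            _, te = stratified_split(separator_table, 0.8, derive_seed(3, "split", r))
            noise_cols = [c for c in X2.columns if c != "firstorder_Label"]
            X2.iloc[te, [X2.columns.get_loc(c) for c in noise_cols]] = rng.standard_normal(
                (len(te), len(noise_cols))
            )
        t2 = FeatureTable(X2, separator_table.y)
        rb2 = run_procedure_b(t2, SMALL_GA, sp)
        for a, b in zip(rb1.per_repeat, rb2.per_repeat):
            assert a.selected_names == b.selected_names

    def test_full_pipeline_reproducible(self, separator_table):
        sp = SplitConfig(n_repeats=2, master_seed=6)
        r1 = run_procedure_b(separator_table, SMALL_GA, sp)
        r2 = run_procedure_b(separator_table, SMALL_GA, sp)
        assert r1.to_json() == r2.to_json()


class TestLeakageGap:
    def test_identical_results_zero_gap(self, separator_table):
        sp = SplitConfig(n_repeats=2, master_seed=1)
        ra = run_procedure_a(separator_table, SMALL_GA, sp)
        assert leakage_gap(ra, ra) == 0.0

    def test_gap_is_difference_of_recomputed_means(self, separator_table):
        sp = SplitConfig(n_repeats=3, master_seed=2)
        ra = run_procedure_a(separator_table, SMALL_GA, sp)
        rb = run_procedure_b(separator_table, SMALL_GA, sp)
        assert leakage_gap(ra, rb) == pytest.approx(
            np.mean([r.test_auc for r in ra.per_repeat])
            - np.mean([r.test_auc for r in rb.per_repeat])
        )

    def test_mismatched_provenance_rejected(self, separator_table, rng):
        sp = SplitConfig(n_repeats=2, master_seed=1)
        ra = run_procedure_a(separator_table, SMALL_GA, sp)
        other = FeatureTable(
            pd.DataFrame(rng.standard_normal((20, 2)), columns=["firstorder_A", "firstorder_B"]),
            pd.Series([0, 1] * 10),
        )
        rb = run_procedure_b(other, SMALL_GA, sp)
        with pytest.raises(ValueError):
            leakage_gap(ra, rb)


class TestSelectionRates:
    def _result(self, names, selections):
        per = [RepeatOutcome(0.5, sel, i) for i, sel in enumerate(selections)]
        return ProcedureResult("B", per, names, "h")

    def test_always_and_never_selected(self):
        names = ["firstorder_A", "firstorder_B (ZOT)", "W-LLH1-firstorder_C"]
        res = self._result(names, [["firstorder_A"], ["firstorder_A"]])
        rep = selection_rates(res)
        assert rep.rates["firstorder_A"] == 100.0
        assert rep.rates["firstorder_B (ZOT)"] == 0.0

    def test_annotation_and_tie_order(self):
        names = ["firstorder_B (ZOT)", "firstorder_A", "L-2-firstorder_C (ZOT)"]
        res = self._result(names, [names, names])  # all tied at 100%
        rep = selection_rates(res, top_k=3)
        assert rep.top["feature"].tolist() == sorted(names)
        zot_rows = rep.top[rep.top["region"] == "ZOT"]
        assert set(zot_rows["feature"]) == {"firstorder_B (ZOT)", "L-2-firstorder_C (ZOT)"}
        assert rep.top.loc[rep.top["feature"] == "L-2-firstorder_C (ZOT)", "filter"].item() == "laplacian"

    def test_rates_survive_serialization(self, separator_table):
        sp = SplitConfig(n_repeats=3, master_seed=5)
        rb = run_procedure_b(separator_table, SMALL_GA, sp)
        back = ProcedureResult.from_json(rb.to_json())
        assert selection_rates(back).rates.equals(selection_rates(rb).rates)


class TestSummarize:
    def test_constant_aucs_zero_sd(self):
        per = [RepeatOutcome(0.75, [], i) for i in range(4)]
        res = ProcedureResult("A", per, ["firstorder_A"], "h")
        s = summarize(res)
        assert s["sd_auc"] == 0.0 and s["mean_auc"] == 0.75
        assert "kde" not in s

    def test_moments_match_direct_recomputation(self):
        aucs = [0.5, 0.6, 0.7, 0.9]
        per = [RepeatOutcome(a, [], i) for i, a in enumerate(aucs)]
        res = ProcedureResult("B", per, ["firstorder_A"], "h")
        s = summarize(res)
        assert s["mean_auc"] == pytest.approx(np.mean(aucs))
        assert s["sd_auc"] == pytest.approx(np.std(aucs, ddof=1))

    def test_density_normalized(self):
        rng = np.random.default_rng(3)
        per = [RepeatOutcome(a, [], i) for i, a in enumerate(rng.uniform(0.4, 0.9, 40))]
        res = ProcedureResult("A", per, ["firstorder_A"], "h")
        s = summarize(res)
        grid = np.array(s["kde"]["grid"])
        dens = np.array(s["kde"]["density"])
        assert abs(np.trapezoid(dens, grid) - 1.0) < 1e-6
        hist = np.array(s["histogram"]["density"])
        edges = np.array(s["histogram"]["edges"])
        assert abs((hist * np.diff(edges)).sum() - 1.0) < 1e-9
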