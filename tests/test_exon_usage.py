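"""DEU/DGE model behavior: no-signal cases, symmetry, covariate
invariance, permutation oracle, filtering rules."""

import numpy as np
import pandas as pd
import pytest

from splicedyn.counts import ExonCountTable
from splicedyn.exon_usage import filter_testable, usage_coefficients
from splicedyn.exon_usage import test_exon_usage as deu_test
from splicedyn.exon_usage import test_gene_expression as dge_test
from splicedyn.simulate import SimParams, StudyDesign, simulate_counts


class TestFilterTestable:
    def test_all_zero_exon_untested(self, tiny_count_table):
        t = tiny_count_table
        t.counts.loc["G1:E002"] = 0
        out = filter_testable(t, min_total=10)
        assert not out.testable["G1:E002"]
        assert out.testable["G1:E001"]

    def test_min_total_zero_keeps_multi_exon_genes(self, tiny_count_table):
        out = filter_testable(tiny_count_table, min_total=0)
        assert out.testable.all()

    def test_single_exon_gene_untestable(self, tiny_count_table):
        t = tiny_count_table
        extra = t.counts.iloc[:1].copy()
        extra.index = ["G9:E001"]
        counts = pd.concat([t.counts, extra])
        gene_ids = pd.concat([t.gene_ids, pd.Series({"G9:E001": "G9"})])
        t2 = ExonCountTable(counts=counts, gene_ids=gene_ids, samples=t.samples)
        out = filter_testable(t2, min_total=0)
        assert not out.testable["G9:E001"]


class TestExonUsage:
    def test_no_signal_exon_exact_flat(self):
        # exon:rest = 100:900 in every sample -> lfc 0, p ~ 1
        meta = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(8)],
                "cohort": ["lean"] * 8,
                "timepoint": ["confluence"] * 4 + ["day3"] * 4,
                "subject": [f"p{i}" for i in range(8)],
                "run": ["run1", "run2"] * 4,
            }
        )
        counts = pd.DataFrame(
            {s: [100, 900] for s in meta["sample"]},
            index=pd.Index(["G1:E001", "G1:E002"], name="exon_id"),
        )
        t = ExonCountTable(
            counts=counts,
            gene_ids=pd.Series(["G1", "G1"], index=counts.index),
            samples=meta,
        )
        res = deu_test(filter_testable(t, 0), "lean", ("confluence", "day3"))
        tested = res.table[res.table["tested"]]
        assert np.abs(tested["log2fc"]).max() < 1e-4
        assert tested["pvalue"].min() > 0.99

    def test_direction_swap_negates_lfc_keeps_p(self, null_table):
        table, _ = null_table
        table = filter_testable(table)
        fwd = deu_test(table, "lean", ("confluence", "day3"))
        rev = deu_test(table, "lean", ("day3", "confluence"))
        f = fwd.table[fwd.table["tested"]]
        r = rev.table.loc[f.index]
        assert np.allclose(f["log2fc"], -r["log2fc"], atol=1e-5)
        assert np.allclose(f["pvalue"], r["pvalue"], atol=1e-6)

    def test_pure_run_library_effect_changes_no_call(self, null_table):
        table, _ = null_table
        table = filter_testable(table)
        base = deu_test(table, "obese", ("confluence", "day3"))
        doubled = table.counts.copy()
        run2 = table.samples.loc[table.samples["run"] == "run2", "sample"]
        doubled[run2] = doubled[run2] * 2
        t2 = ExonCountTable(
            counts=doubled, gene_ids=table.gene_ids,
            samples=table.samples, testable=table.testable,
        )
        pert = deu_test(t2, "obese", ("confluence", "day3"))
        b = base.table[base.table["tested"]]["significant"]
        p = pert.table.loc[b.index]["significant"]
        assert (b == p).all()

    def test_qvalues_monotone_in_pvalues(self, null_table):
        table, _ = null_table
        res = deu_test(filter_testable(table), "lean", ("day3", "day15"))
        t = res.table[res.table["tested"]].sort_values("pvalue")
        assert (np.diff(t["qvalue"]) >= -1e-12).all()
        assert t["qvalue"].between(0, 1).all()
        assert np.all(np.sign(t["z"]) == np.sign(t["log2fc"]))

    def test_missing_timepoint_is_design_error(self, tiny_count_table):
        with pytest.raises(ValueError):
            deu_test(
                filter_testable(tiny_count_table, 0), "lean", ("confluence", "day15")
            )

    def test_permutation_oracle_on_tiny_dataset(self, tiny_count_table):
        """GLM p-values agree with a condition-label permutation null."""
        table = filter_testable(tiny_count_table, 0)
        obs = deu_test(table, "lean", ("confluence", "day3"))
        obs_t = obs.table[obs.table["tested"]]
        rng = np.random.default_rng(1)
        n_perm = 200
        meta = table.samples
        stats = {eid: [] for eid in obs_t.index}
        for _ in range(n_perm):
            perm = meta.copy()
            perm["timepoint"] = rng.permutation(perm["timepoint"].to_numpy())
            tp = ExonCountTable(
                counts=table.counts, gene_ids=table.gene_ids,
                samples=perm, testable=table.testable,
            )
            r = deu_test(tp, "lean", ("confluence", "day3"))
            for eid in stats:
                stats[eid].append(abs(r.table.loc[eid, "z"]))
        for eid in stats:
            p_perm = (
                1 + sum(s >= abs(obs_t.loc[eid, "z"]) for s in stats[eid])
            ) / (1 + n_perm)
            p_glm = obs_t.loc[eid, "pvalue"]
            # both should call the exon unremarkable; agree within a wide band
            assert abs(p_glm - p_perm) < 0.35


class TestUsageCoefficients:
    def test_shape_and_constant_exon_flat(self, null_table):
        table, _ = null_table
        table = filter_testable(table)
        co = usage_coefficients(table, "lean")
        assert list(co.columns) == ["confluence", "day3", "day15"]
        # under the null, trajectories are flat up to fit noise
        spread = co.max(axis=1) - co.min(axis=1)
        assert np.median(spread) < 0.25

    def test_planted_monotone_increase_is_monotone_in_expectation(self, small_models):
        hits = 0
        n = 20
        for s in range(n):
            params = SimParams(ds_fraction=0.05, ds_effect=1.0, shared_fraction=1.0)
            table, truth = simulate_counts(small_models[:60], params=params,
                                           seed=900 + s)
            table = filter_testable(table)
            co = usage_coefficients(table, "lean")
            key = ("lean", ("confluence", "day3"))
            ups = [e for e, d in truth.ds_exons[key].items()
                   if d > 0 and e in co.index]
            if not ups:
                continue
            diffs = co.loc[ups, "day3"] - co.loc[ups, "confluence"]
            hits += (diffs > 0).mean() > 0.9
        assert hits >= 0.9 * n


class TestGeneExpression:
    def test_low_fold_change_never_flagged(self, null_table):
        table, _ = null_table
        res = dge_test(table, "lean", ("confluence", "day3"))
        weak = res.table[np.abs(res.table["log2fc"]) < np.log2(1.25)]
        assert not weak["significant"].any()

    def test_planted_fold_change_recovered(self, small_models):
        wins = 0
        for s in range(10):
            params = SimParams(de_fraction=0.1, de_effect=1.0, shared_fraction=1.0)
            table, truth = simulate_counts(small_models, params=params, seed=50 + s)
            res = dge_test(table, "obese", ("day3", "day15"))
            planted = set(truth.de_genes[("obese", ("day3", "day15"))])
            called = set(res.significant_genes)
            wins += len(called & planted) / len(planted) >= 0.8
        assert wins >= 8

    def test_null_realized_fdr(self, small_models):
        flagged_false = total_flagged = 0
        for s in range(10):
            table, _ = simulate_counts(small_models, params=SimParams(), seed=70 + s)
            res = dge_test(table, "lean", ("confluence", "day3"))
            total_flagged += len(res.significant_genes)
            flagged_false += len(res.significant_genes)
        # all flags are false positives under the null
        assert flagged_false <= max(1, 0.10 * 200 * 10 * 0.05 * 10)
        # and there should be very few of them at all
        assert total_flagged <= 10
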