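import numpy as np
import pandas as pd
import pytest

import factorscan as fs
from factorscan.cohort import ModuleAssignment


def _toy_assignment(labels: dict[str, int], k: int) -> ModuleAssignment:
    s = pd.Series(labels, name="module")
    return ModuleAssignment(
        k=k, labels=s, centers=pd.DataFrame(), cost=0.0, cost_history=(0.0,)
    )


class TestPreprocessCohort:
    def _cohort(self, rng, n_probes=40, n_samples=10):
        probes = [f"p{i}" for i in range(n_probes)]
        expr = pd.DataFrame(
            rng.lognormal(2, 0.3, (n_probes, n_samples)),
            index=probes,
            columns=[f"s{j}" for j in range(n_samples)],
        )
        det = pd.DataFrame(
            rng.uniform(0, 0.04, (n_probes, n_samples)), index=probes, columns=expr.columns
        )
        symbols = pd.Series([f"G{i // 2}" for i in range(n_probes)], index=probes)
        return expr, det, symbols

    def test_detection_fraction_boundary(self, rng):
        n = 100
        samples = [f"s{j}" for j in range(n)]
        probes = ["p0", "p1", "p2", "p3"]
        expr = pd.DataFrame(
            {
                "p0": rng.lognormal(2, 1.5, n),  # high-variance, should be gone anyway
                "p1": rng.lognormal(2, 1.0, n),  # high-variance, passes detection
                "p2": rng.lognormal(2, 0.01, n),
                "p3": rng.lognormal(2, 0.01, n),
            }
        ).T
        expr.columns = samples
        det = pd.DataFrame(1.0, index=probes, columns=samples)
        det.loc["p0", samples[:19]] = 0.01  # 19% < 20% -> probe dropped
        det.loc["p1", samples[:20]] = 0.01  # exactly 20% -> probe kept
        det.loc[["p2", "p3"]] = 0.01
        symbols = pd.Series(["G0", "G1", "G2", "G3"], index=probes)
        out = fs.preprocess_cohort(expr, det, symbols)
        assert "G0" not in out.index
        assert "G1" in out.index  # most variable surviving gene passes the CV cut

    def test_probe_median_collapse(self):
        expr = pd.DataFrame(
            {"s1": [4.0, 6.0, 5.0, 5.0], "s2": [20.0, 20.0, 5.0, 5.0]},
            index=["pA", "pB", "pC", "pD"],
        )
        det = expr * 0.0
        symbols = pd.Series(["G", "G", "H", "Z"], index=expr.index)
        out = fs.preprocess_cohort(expr, det, symbols, variability="variance")
        # G collapses to median(4,6)=5 and median(20,20)=20; sample medians
        # are 5 and 5, so the retained (most variable) gene G reads (1, 4)
        assert out.loc["G", "s1"] == pytest.approx(1.0)
        assert out.loc["G", "s2"] == pytest.approx(4.0)

    def test_pipeline_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(9)
        truth = fs.default_truth(9, n_genes=500, n_factors=4, n_targets=50)
        probe_expr, det, symbols, _ = fs.generate_expression(
            truth, 500, design="cohort", n_samples=30
        )
        out = fs.preprocess_cohort(probe_expr, det, symbols)

        keep = (det.to_numpy() < 0.05).mean(axis=1) >= 0.2
        kept = probe_expr.loc[keep]
        genes = {}
        for g in sorted(set(symbols[kept.index])):
            rows = kept.loc[symbols[kept.index] == g]
            genes[g] = rows.median(axis=0)
        gene_df = pd.DataFrame(genes).T
        gene_df = gene_df / gene_df.median(axis=0)
        cv = gene_df.std(axis=1, ddof=1) / gene_df.mean(axis=1).abs()
        expected = gene_df.loc[cv > cv.median()]
        assert set(out.index) == set(expected.index)
        np.testing.assert_allclose(out.to_numpy(), expected.loc[out.index].to_numpy())

    def test_misaligned_matrices_rejected(self, rng):
        expr, det, symbols = self._cohort(rng)
        with pytest.raises(ValueError, match="aligned"):
            fs.preprocess_cohort(expr, det.iloc[:-1], symbols)


class TestKmedians:
    def test_k1_center_is_median(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (30, 4)))
        out = fs.kmedians(expr, k=1, seed=0, restarts=2)
        np.testing.assert_allclose(out.centers.iloc[0], expr.median(axis=0))
        assert set(out.labels) == {1}

    def test_planted_blobs_recovered_exactly(self, rng):
        a = rng.normal(3.0, 0.2, (25, 6))
        b = rng.normal(-3.0, 0.2, (25, 6))
        expr = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(50)])
        out = fs.kmedians(expr, k=2, seed=1, restarts=5)
        first = set(out.labels.iloc[:25])
        second = set(out.labels.iloc[25:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_duplicate_genes_share_a_module(self, rng):
        base = rng.normal(0, 1, (20, 5))
        expr = pd.DataFrame(np.vstack([base, base[:1]]), index=[f"g{i}" for i in range(21)])
        out = fs.kmedians(expr, k=3, seed=2)
        assert out.labels.iloc[0] == out.labels.iloc[20]

    def test_cost_monotone_and_restarts_never_worse(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (80, 5)))
        best = fs.kmedians(expr, k=4, seed=3, restarts=8)
        diffs = np.diff(best.cost_history)
        assert (diffs <= 1e-9).all()
        single = fs.kmedians(expr, k=4, seed=3, restarts=1)
        assert best.cost <= single.cost + 1e-9

    def test_deterministic_for_fixed_seed(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (40, 5)))
        a = fs.kmedians(expr, k=3, seed=7)
        b = fs.kmedians(expr, k=3, seed=7)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_invalid_k_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (5, 3)))
        with pytest.raises(ValueError):
            fs.kmedians(expr, k=0, seed=0)
        with pytest.raises(ValueError):
            fs.kmedians(expr, k=6, seed=0)


class TestModuleFactorScreen:
    def test_planted_module_recovers_planted_factor(self, synth):
        truth = synth["truth"]
        matrix = synth["matrix"]
        module1 = [g for g in truth.target_genes if g in matrix.index]
        rest = [g for g in matrix.index[:150] if g not in set(module1)]
        labels = {g: 1 for g in module1} | {g: 2 for g in rest}
        tables = fs.module_factor_screen(
            matrix, _toy_assignment(labels, k=2), synth["background"]
        )
        kept = tables[1][~tables[1]["triaged"]]
        assert kept.index[0] == truth.planted_factor

    def test_small_module_skipped_with_warning(self, synth):
        genes = list(synth["matrix"].index[:40])
        labels = {g: 1 for g in genes[:3]} | {g: 2 for g in genes[3:]}
        with pytest.warns(RuntimeWarning, match="skipped"):
            tables = fs.module_factor_screen(
                synth["matrix"], _toy_assignment(labels, k=2), synth["background"]
            )
        assert set(tables) == {2}

    def test_random_modules_rarely_score_any_factor(self, synth):
        rng = np.random.default_rng(0)
        flagged = 0
        draws = 50
        genes = np.array(synth["background"])
        for _ in range(draws):
            module = list(rng.choice(genes, 100, replace=False))
            labels = {g: 1 for g in module}
            tables = fs.module_factor_screen(
                synth["matrix"], _toy_assignment(labels, k=1), synth["background"]
            )
            pc = tables[1]["p_corr"].dropna()
            flagged += bool((pc < 0.05).any())
        assert flagged <= 0.1 * draws


class TestFactorPresenceClustering:
    def test_identical_call_patterns_are_adjacent_at_zero_distance(self):
        fdrs = {
            "rat_d1": pd.Series({"EZH2": 0.001, "SUZ12": 0.01, "STAT3": 0.9}),
            "rat_d10": pd.Series({"EZH2": 0.002, "SUZ12": 0.04, "STAT3": 0.8}),
            "M-2": pd.Series({"EZH2": 0.9, "SUZ12": 0.7, "STAT3": 0.01}),
        }
        out = fs.factor_presence_clustering(fdrs)
        assert set(out.matrix.to_numpy().ravel()) <= {0, 1}
        i = out.column_order.index("rat_d1")
        assert out.column_order[i - 1] == "rat_d10" or (
            i + 1 < 3 and out.column_order[i + 1] == "rat_d10"
        )
        assert out.linkage[0, 2] == pytest.approx(0.0)

    def test_anticomplementary_columns_are_maximally_distant(self):
        fdrs = {
            "L1": pd.Series({"A": 0.01, "B": 0.01, "C": 0.9, "D": 0.9}),
            "L2": pd.Series({"A": 0.9, "B": 0.9, "C": 0.01, "D": 0.01}),
        }
        out = fs.factor_presence_clustering(fdrs)
        assert out.linkage[-1, 2] == pytest.approx(2.0)

    def test_planted_families_cosegregate(self, rng):
        factors = [f"F{i}" for i in range(12)]
        human_sig = factors[:5]
        rodent_sig = factors[5:10]
        fdrs = {}
        for name, sig in [("M-1", human_sig), ("M-3", human_sig), ("down_d1", rodent_sig), ("down_d10", rodent_sig)]:
            vals = {f: (0.01 if f in sig else 0.5) for f in factors}
            flip = rng.choice(factors[10:], 1)[0]  # sprinkle one stray call
            vals[flip] = 0.01
            fdrs[name] = pd.Series(vals)
        out = fs.factor_presence_clustering(fdrs)
        order = out.column_order
        assert abs(order.index("M-1") - order.index("M-3")) == 1
        assert abs(order.index("down_d1") - order.index("down_d10")) == 1

    def test_row_order_invariance(self):
        fdrs = {
            "L1": pd.Series({"A": 0.01, "B": 0.5, "C": 0.01}),
            "L2": pd.Series({"C": 0.02, "A": 0.3, "B": 0.01}),
        }
        rev = {k: s.iloc[::-1] for k, s in fdrs.items()}
        pd.testing.assert_frame_equal(
            fs.factor_presence_clustering(fdrs).matrix,
            fs.factor_presence_clustering(rev).matrix,
        )


class TestModuleExpressionTest:
    def _cohorts(self, rng, shift=0.0, n_genes=100, n_samples=20):
        genes = [f"g{i}" for i in range(n_genes)]
        a = pd.DataFrame(rng.normal(8, 0.5, (n_genes, n_samples)), index=genes)
        b = pd.DataFrame(rng.normal(8, 0.5, (n_genes, n_samples)), index=genes) + shift
        return genes, a, b

    def test_identical_cohorts(self, rng):
        genes, a, _ = self._cohorts(rng)
        res = fs.module_expression_test(genes, a, a.copy())
        assert res.p == pytest.approx(1.0)
        assert res.direction == "none"

    def test_planted_shift_detected(self, rng):
        genes, a, b = self._cohorts(rng, shift=-1.0)
        res = fs.module_expression_test(genes, a, b)
        assert res.direction == "higher_in_a"
        assert res.p < 1e-10

    def test_label_swap_flips_direction_only(self, rng):
        genes, a, b = self._cohorts(rng, shift=-1.0)
        fwd = fs.module_expression_test(genes, a, b)
        rev = fs.module_expression_test(genes, b, a)
        assert fwd.p == pytest.approx(rev.p)
        assert {fwd.direction, rev.direction} == {"higher_in_a", "higher_in_b"}

    def test_gene_order_invariance(self, rng):
        genes, a, b = self._cohorts(rng, shift=-0.3)
        fwd = fs.module_expression_test(genes, a, b)
        rev = fs.module_expression_test(list(reversed(genes)), a, b)
        assert fwd.p == pytest.approx(rev.p)

    def test_disjoint_cohorts_rejected(self, rng):
        genes, a, b = self._cohorts(rng)
        b.index = [f"x{i}" for i in range(len(b))]
        with pytest.raises(ValueError, match="shared"):
            fs.module_expression_test(genes, a, b)
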