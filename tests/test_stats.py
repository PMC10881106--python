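"""Group comparisons, correlation diagnostics, trajectory peaks, calibration."""
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import evoindex as ev
from evoindex.errors import ValidationError
from evoindex.io_qc import GROUP_SEP

from conftest import CAL_REGIONS, student_t_by_hand, welch_t_by_hand


def eri_table(values_by_region, lineage="L1"):
    return pd.DataFrame(
        {
            "group": list(values_by_region),
            "lineage": lineage,
            "index_kind": "ERI",
            "value": list(values_by_region.values()),
            "n_genes_used": 10,
        }
    )


class TestCompareRegionClasses:
    def test_hand_checkable_2v2_fixture(self):
        """values 1,2 (cortical) vs 3,4 (non-cortical) against the textbook
        Welch and Student formulas."""
        table = eri_table({"c1": 1.0, "c2": 2.0, "n1": 3.0, "n2": 4.0})
        cmap = {"c1": "cortical", "c2": "cortical", "n1": "non_cortical", "n2": "non_cortical"}
        for method, oracle in (("welch", welch_t_by_hand), ("student", student_t_by_hand)):
            res = ev.compare_region_classes(table, cmap, method=method).iloc[0]
            t, df, p = oracle([3.0, 4.0], [1.0, 2.0])
            assert res["t_statistic"] == pytest.approx(t, abs=1e-10)
            assert res["degrees_of_freedom"] == pytest.approx(df, abs=1e-10)
            assert res["p_value"] == pytest.approx(p, abs=1e-10)

    def test_matches_closed_form_on_random_fixtures(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            na, nb = rng.integers(2, 12, size=2)
            nc = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), na)
            c = rng.normal(0, 1, nb)
            table = eri_table(
                {f"n{i}": v for i, v in enumerate(nc)} | {f"c{i}": v for i, v in enumerate(c)}
            )
            cmap = {f"n{i}": "non_cortical" for i in range(na)} | {
                f"c{i}": "cortical" for i in range(nb)
            }
            for method, oracle in (("welch", welch_t_by_hand), ("student", student_t_by_hand)):
                res = ev.compare_region_classes(table, cmap, method=method).iloc[0]
                t, df, p = oracle(nc, c)
                assert res["t_statistic"] == pytest.approx(t, abs=1e-10)
                assert res["p_value"] == pytest.approx(p, abs=1e-10)

    def test_identical_values_degenerate(self):
        table = eri_table({"c1": 1.0, "c2": 1.0, "n1": 1.0, "n2": 1.0})
        cmap = {"c1": "cortical", "c2": "cortical", "n1": "non_cortical", "n2": "non_cortical"}
        res = ev.compare_region_classes(table, cmap).iloc[0]
        assert res["t_statistic"] == 0.0 and res["p_value"] == 1.0

    def test_other_class_excluded_and_small_class_rejected(self):
        table = eri_table({"c1": 1.0, "c2": 2.0, "n1": 3.0, "n2": 4.0, "x": 9.0})
        cmap = {
            "c1": "cortical", "c2": "cortical",
            "n1": "non_cortical", "n2": "non_cortical", "x": "other",
        }
        res = ev.compare_region_classes(table, cmap).iloc[0]
        assert res["n_noncortical"] == 2 and res["n_cortical"] == 2
        with pytest.raises(ValidationError, match=">=2 regions"):
            ev.compare_region_classes(
                eri_table({"c1": 1.0, "n1": 3.0, "n2": 4.0}),
                {"c1": "cortical", "n1": "non_cortical", "n2": "non_cortical"},
            )

    def test_directional_alternative(self):
        table = eri_table({"c1": 1.0, "c2": 2.0, "n1": 3.0, "n2": 4.0})
        cmap = {"c1": "cortical", "c2": "cortical", "n1": "non_cortical", "n2": "non_cortical"}
        two = ev.compare_region_classes(table, cmap, sidedness="two_sided").iloc[0]
        one = ev.compare_region_classes(table, cmap, sidedness="greater").iloc[0]
        assert one["p_value"] == pytest.approx(two["p_value"] / 2)

    def test_power_with_planted_effect(self):
        """coupling_delta=0.5, 20 non-cortical + 25 cortical regions: p<0.05
        in >=90% of 200 replicates, every lineage."""
        regions = tuple((f"N{i}", "non_cortical") for i in range(20)) + tuple(
            (f"C{i}", "cortical") for i in range(25)
        )
        cfg = ev.SimConfig(
            n_genes=400, regions=regions, n_samples_per_region=4, coupling_delta=0.5, seed=77
        )
        rates = ev.rejection_rates(cfg, n_reps=200, alpha=0.05)
        assert min(rates["per_lineage_rate"].values()) >= 0.90


class TestCorrelation:
    def test_perfect_linearity(self, toy_gene_evo):
        dnds = toy_gene_evo.data["L2"]
        expr = ev.ExpressionMatrix(pd.DataFrame({"grp": 3.0 * dnds}))
        res = ev.dnds_expression_correlation(toy_gene_evo, expr)
        row = res[(res["lineage"] == "L2") & (res["group"] == "grp")].iloc[0]
        assert row["pearson_r"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_expression_flagged_not_crashed(self, toy_gene_evo):
        expr = ev.ExpressionMatrix(
            pd.DataFrame({"grp": [2.0, 2.0, 2.0]}, index=["gA", "gB", "gC"])
        )
        res = ev.dnds_expression_correlation(toy_gene_evo, expr)
        assert res["undefined"].all()
        assert res["pearson_r"].isna().all()

    def test_null_correlation_is_small(self):
        """Independent dN/dS and expression at n_genes=5000: |r| < 0.05 in
        >=95% of replicates."""
        rng = np.random.default_rng(31)
        ok = 0
        n_reps = 200
        for _ in range(n_reps):
            n = 5000
            ge = ev.GeneEvoTable(
                pd.DataFrame(
                    {"L1": rng.gamma(0.5, 0.4, n), "age": rng.uniform(0, 70, n)},
                    index=[f"g{i}" for i in range(n)],
                ),
                lineages=("L1",),
            )
            expr = ev.ExpressionMatrix(
                pd.DataFrame({"grp": rng.lognormal(0, 1, n)}, index=ge.gene_ids)
            )
            r = ev.dnds_expression_correlation(ge, expr)["pearson_r"].iloc[0]
            ok += int(abs(r) < 0.05)
        assert ok >= 0.95 * n_reps

    def test_log1p_transform_changes_r(self, small_config):
        ge = ev.simulate_gene_evo(small_config)
        expr, meta, _ = ev.simulate_expression_study(ge, small_config)
        grouped = ev.aggregate_expression(expr, meta, "region")
        ident = ev.dnds_expression_correlation(ge, grouped, "identity")
        logd = ev.dnds_expression_correlation(ge, grouped, "log1p")
        assert not np.allclose(ident["pearson_r"], logd["pearson_r"])


def region_window_table(values, kind="ERI", region="AMY", lineage="L1"):
    return pd.DataFrame(
        {
            "group": [f"{region}{GROUP_SEP}{w}" for w in values],
            "lineage": lineage if kind == "ERI" else pd.NA,
            "index_kind": kind,
            "value": list(values.values()),
            "n_genes_used": 5,
        }
    )


class TestPeakStage:
    WINDOWS = ("w1", "w2", "w3")

    def test_monotone_increasing_peaks_at_last_window(self):
        tbl = region_window_table({"w1": 0.1, "w2": 0.2, "w3": 0.3})
        res = ev.peak_stage(tbl, self.WINDOWS)
        assert res["window"].iloc[0] == "w3" and res["direction"].iloc[0] == "peak"

    def test_tie_breaks_toward_earliest_window(self):
        tbl = region_window_table({"w1": 0.1, "w2": 0.5, "w3": 0.5})
        assert ev.peak_stage(tbl, self.WINDOWS)["window"].iloc[0] == "w2"

    def test_tai_reports_trough(self):
        tbl = region_window_table({"w1": 30.0, "w2": 10.0, "w3": 20.0}, kind="TAI")
        res = ev.peak_stage(tbl, self.WINDOWS)
        assert res["window"].iloc[0] == "w2" and res["direction"].iloc[0] == "trough"

    def test_invariant_to_constant_shift(self):
        vals = {"w1": 0.4, "w2": 0.9, "w3": 0.6}
        a = ev.peak_stage(region_window_table(vals), self.WINDOWS)
        b = ev.peak_stage(
            region_window_table({w: v + 17.0 for w, v in vals.items()}), self.WINDOWS
        )
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_window_label_rejected(self):
        tbl = region_window_table({"w1": 0.1, "weird": 0.2})
        with pytest.raises(ValidationError, match="weird"):
            ev.peak_stage(tbl, self.WINDOWS)

    def test_planted_peak_recovered_from_simulation(self, small_config):
        cfg = replace(small_config, n_samples_per_region=16, n_genes=500)
        ge = ev.simulate_gene_evo(cfg)
        expr, meta, truth = ev.simulate_expression_study(ge, cfg)
        grouped = ev.aggregate_expression(expr, meta, "region_window")
        peaks = ev.peak_stage(ev.compute_eri_table(ge, grouped), cfg.windows)
        assert (peaks["window"] == truth.true_peak_window).mean() >= 0.9


class TestCalibration:
    def test_alpha_one_rejects_always_and_determinism(self, small_config):
        cfg = ev.null_config(replace(small_config, n_genes=60, seed=5))
        r1 = ev.run_null_calibration(cfg, n_reps=100, alpha=1.0)
        assert r1["mean_rate"] == 1.0 and r1["any_lineage_rate"] == 1.0
        r2 = ev.run_null_calibration(cfg, n_reps=100, alpha=1.0)
        assert r1 == r2

    def test_requires_null_config_and_min_reps(self, small_config):
        with pytest.raises(ValidationError, match="coupling_delta"):
            ev.run_null_calibration(small_config, n_reps=100)
        with pytest.raises(ValidationError, match="n_reps"):
            ev.run_null_calibration(ev.null_config(small_config), n_reps=10)

    def test_permuting_region_classes_destroys_planted_effect(self):
        """With the class labels randomly permuted across regions, the
        per-lineage rejection rate returns to the nominal level (binomial
        tolerance at 200 replicates) despite coupling_delta=0.5."""
        rng = np.random.default_rng(55)
        n_reps, hits = 200, 0.0
        for rep in range(n_reps):
            cfg = ev.SimConfig(
                n_genes=250, regions=CAL_REGIONS, n_samples_per_region=2,
                coupling_delta=0.5, seed=4000 + rep,
            )
            ge = ev.simulate_gene_evo(cfg)
            expr, meta, _ = ev.simulate_expression_study(ge, cfg)
            eri = ev.compute_eri_table(ge, ev.aggregate_expression(expr, meta, "region"))
            perm = rng.permutation([c for _, c in cfg.regions])
            cmap = {r: c for (r, _), c in zip(cfg.regions, perm)}
            comp = ev.compare_region_classes(eri, cmap)
            hits += (comp["p_value"].to_numpy() < 0.05).mean()
        rate = hits / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - 3 * se <= rate <= 0.05 + 3 * se
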