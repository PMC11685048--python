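"""Integrated table, Kruskal-Wallis/Dunn, semi-log fit, selection, outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gcmab.panel import load_cell_mabs
from gcmab.stats import (
    build_integrated_table,
    detect_outliers,
    kruskal_dunn,
    select_clonotypes,
    semilog_fit,
    summarize_clonotypes,
)


def meta(ids):
    return pd.DataFrame({"cell_id": ids, "sample": "d10p"}).set_index("cell_id")


class TestIntegratedTable:
    def test_left_join_and_report(self):
        base = meta(["a", "b", "c"])
        extra = pd.DataFrame({"cell_id": ["a", "b"], "x": [1, 2]})
        table, report = build_integrated_table(base, extra)
        assert len(table) == 3
        assert table.loc["a", "x"] == 1 and np.isnan(table.loc["c", "x"])
        assert report["source_1"] == {"matched": 2, "unmatched": 0}

    def test_disjoint_source_fully_unmatched(self):
        table, report = build_integrated_table(
            meta(["a"]), pd.DataFrame({"cell_id": ["z"], "x": [1]})
        )
        assert report["source_1"]["unmatched"] == 1

    def test_duplicate_keys_rejected(self):
        dup = pd.DataFrame({"cell_id": ["a", "a"], "x": [1, 2]})
        with pytest.raises(ValueError, match="duplicate"):
            build_integrated_table(meta(["a"]), dup)

    def test_empty_source_is_fine(self):
        table, _ = build_integrated_table(
            meta(["a"]), pd.DataFrame(columns=["cell_id", "threshold_ng"])
        )
        assert "threshold_ng" in table.columns and table["threshold_ng"].isna().all()


class TestKruskalDunn:
    def test_identical_groups_are_null(self):
        res = kruskal_dunn({"a": [1, 1, 1], "b": [1, 1], "c": [1, 1]})
        assert res["H"] == 0 and res["p"] == 1
        assert (res["pairwise"]["p_adjusted"] == 1).all()

    def test_hand_computed_h(self):
        res = kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert res["H"] == pytest.approx(7.2)

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="< 2"):
            kruskal_dunn({"a": [1], "b": [2, 3]})

    def test_adjusted_p_bounds(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abcd")}
        res = kruskal_dunn(groups)
        pw = res["pairwise"]
        assert (pw["p_adjusted"] >= pw["p_raw"] - 1e-15).all()
        assert (pw["p_adjusted"] <= 1).all()
        holm = kruskal_dunn(groups, adjustment="holm")["pairwise"]
        assert (holm["p_adjusted"] <= pw["p_adjusted"] + 1e-12).all()

    def test_h_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 1, 7) for i, k in enumerate("abc")}
        res1 = kruskal_dunn(groups)
        res2 = kruskal_dunn({k: np.exp(v) for k, v in groups.items()})
        assert res1["H"] == pytest.approx(res2["H"])

    def test_matches_scipy_omnibus_with_ties(self):
        groups = {"a": [1, 2, 2, 3], "b": [2, 4, 4, 5], "c": [5, 5, 6, 7]}
        res = kruskal_dunn(groups)
        H, p = sps.kruskal(*groups.values())
        assert res["H"] == pytest.approx(H) and res["p"] == pytest.approx(p)

    def test_graded_groups_rank_smallest_extreme_pair(self):
        rng = np.random.default_rng(2)
        groups = {
            s: rng.poisson(lam, 40)
            for s, lam in zip(["d10p", "d20p", "d10s", "d20s"], [2, 4, 6, 10])
        }
        res = kruskal_dunn(groups)
        assert res["p"] < 1e-6
        pw = res["pairwise"].set_index(["group_a", "group_b"])
        extreme = pw.loc[("d10p", "d20s"), "p_adjusted"]
        assert extreme == pw["p_adjusted"].min()


class TestSemilogFit:
    def test_perfect_line_gives_r2_one(self):
        x = np.array([1, 10, 100, 1000], float)
        y = 2.0 - 0.5 * np.log10(x)
        res = semilog_fit(x, y)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(-0.5)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 1000, 30)
        y = 1 - 0.4 * np.log10(x) + rng.normal(0, 0.3, 30)
        res = semilog_fit(x, y)
        r = np.corrcoef(np.log10(x), y)[0, 1]
        assert res["r_squared"] == pytest.approx(r**2, rel=1e-9)

    def test_r2_invariant_to_affine_rescaling_of_y(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 1000, 20)
        y = rng.uniform(0, 2, 20)
        a = semilog_fit(x, y)["r_squared"]
        b = semilog_fit(x, 3.5 * y - 1.2)["r_squared"]
        assert a == pytest.approx(b, rel=1e-9)

    def test_censor_policies(self):
        df = load_cell_mabs()
        cap = semilog_fit(df["threshold_ng"], df["asinh_OVA-AF647"], df["censored"], "cap")
        exc = semilog_fit(
            df["threshold_ng"], df["asinh_OVA-AF647"], df["censored"], "exclude"
        )
        assert cap["n"] == 32 and exc["n"] == 32 - int(df["censored"].sum())
        with pytest.raises(ValueError, match="censor_policy"):
            semilog_fit(df["threshold_ng"], df["asinh_OVA-AF647"], df["censored"], "drop")

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="usable points"):
            semilog_fit([1, 10], [0.1, 0.2])
        with pytest.raises(ValueError, match="> 0"):
            semilog_fit([0, 10, 100], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="variance"):
            semilog_fit([1, 10, 100], [0.5, 0.5, 0.5])


def summary_frame():
    return pd.DataFrame(
        {
            "clonotype_id": ["c1", "c2", "c3", "c4"],
            "size": [6, 4, 6, 9],
            "mean_binding": [1.5, 2.0, 0.2, 0.9],
            "n_above_background": [3, 4, 0, 1],
        }
    )


class TestSelection:
    def test_size_and_binding_gates(self):
        hits = select_clonotypes(summary_frame())
        assert hits == ["c1", "c4"]  # c2 too small, c3 all below background

    def test_seeded_subsample(self):
        hits = select_clonotypes(summary_frame(), k=1, seed=0)
        assert len(hits) == 1 and hits[0] in {"c1", "c4"}

    def test_empty_result_allowed(self):
        assert select_clonotypes(summary_frame(), min_size=100) == []

    def test_summarize_counts_members_and_binding(self, bundle_noisefree):
        truth = bundle_noisefree.truth
        facs = bundle_noisefree.index_sort.merge(
            bundle_noisefree.well_map, on=["plate", "well"]
        ).set_index("cell_id")
        clean = truth.cells[truth.cells["qc_violation"] == ""]
        table = clean.join(
            np.arcsinh(facs[["OVA-AF647"]] / 100).rename(
                columns={"OVA-AF647": "asinh_OVA-AF647"}
            )
        )
        summary = summarize_clonotypes(table)
        qualifying = set(select_clonotypes(summary))
        planted = {
            cid
            for cid, grp in clean.join(table[["asinh_OVA-AF647"]]).groupby("clonotype_id")
            if len(grp) >= 5 and (grp["asinh_OVA-AF647"] > 1).any()
        }
        assert qualifying == planted
        assert set(truth.selected_clonotypes) <= qualifying


class TestOutliers:
    def test_table_rows_inside_window(self):
        df = load_cell_mabs()
        out = detect_outliers(df)
        assert len(out) == 5

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["asinh_OVA-AF647", "threshold_ng", "censored"])
        assert len(detect_outliers(empty)) == 0

    def test_monotone_in_binding_cutoff(self):
        df = load_cell_mabs()
        lo = set(detect_outliers(df, binding_cutoff=0.5).index)
        hi = set(detect_outliers(df, binding_cutoff=1.5).index)
        assert lo <= hi

    def test_censored_thresholds_never_qualify(self):
        df = load_cell_mabs().copy()
        df.loc[df["censored"], "threshold_ng"] = 50  # inside window but censored
        out = detect_outliers(df)
        assert not out.index.isin(df.index[df["censored"]]).any()
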