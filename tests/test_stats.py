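import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restalpha.errors import DegenerateDataError, ParameterError
from restalpha.montage import ROI_ELECTRODES
from restalpha.stats import (bh_fdr, cohort_demographics, compare_groups,
                             iaf_comparison, kruskal_wallis, ks_normality,
                             mann_whitney, percentage, round_half_up)
from restalpha.synth import CohortSpec, draw_cohort_manifest

# --------------------------------------------------------------------------
# independent oracles


def brute_force_bh(p):
    """Step-up definition, implemented directly from first principles."""
    p = list(p)
    n = len(p)
    idx = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = idx[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj


def enumeration_mwu_p(x, y):
    """Exact two-sided MWU p by exhaustive enumeration over rank subsets."""
    n_x, n_y = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks_x = [pooled.index(v) + 1 for v in x]
    u_obs = sum(ranks_x) - n_x * (n_x + 1) / 2
    mu = n_x * n_y / 2.0
    count = total = 0
    for subset in itertools.combinations(range(1, n_x + n_y + 1), n_x):
        u = sum(subset) - n_x * (n_x + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


# --------------------------------------------------------------------------
# mann_whitney


class TestMannWhitney:
    def test_separated_samples_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=9)
        _, p1 = mann_whitney(x, y)
        _, p2 = mann_whitney(y, x)
        assert p1 == pytest.approx(p2)

    def test_identical_samples_tie_corrected(self):
        u, p = mann_whitney([5, 7, 9], [5, 7, 9])
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n_x,n_y", [(2, 3), (3, 3), (4, 4), (3, 5), (5, 5)])
    def test_exact_branch_matches_enumeration(self, n_x, n_y):
        rng = np.random.default_rng(n_x * 10 + n_y)
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n_x + n_y + 1.0))
            x, y = list(vals[:n_x]), list(vals[n_x:])
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(enumeration_mwu_p(x, y), abs=1e-12)

    def test_exact_branch_all_u_values(self):
        # every achievable U for a 4-vs-4 design
        n = 4
        base = list(range(1, 2 * n + 1))
        for subset in itertools.combinations(base, n):
            x = [float(v) for v in subset]
            y = [float(v) for v in base if v not in subset]
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(enumeration_mwu_p(x, y), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(1.0, 1.0, 30)
        _, p = mann_whitney(x, y)
        from scipy.stats import mannwhitneyu
        ref = mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


# --------------------------------------------------------------------------
# kruskal_wallis


class TestKruskalWallis:
    def test_hand_computed_h(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=5e-4)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_equal_mean_ranks(self):
        h, p = kruskal_wallis([[1, 5], [2, 3, 4]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=7), rng.normal(0.4, 1, 9), rng.normal(size=5)]
        from scipy.stats import kruskal
        h, p = kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_two_group_equivalence_with_mwu_no_cc(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=8)
            y = rng.normal(0.5, 1.0, size=9)
            _, p_kw = kruskal_wallis([x, y])
            _, p_mwu = mann_whitney(x, y, continuity=False,
                                    exact_max_n=0)
            assert abs(p_kw - p_mwu) < 1e-6

    def test_degenerate_input(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ParameterError):
            kruskal_wallis([[1.0, 2.0]])


# --------------------------------------------------------------------------
# bh_fdr


TABLE3_RAW = {"O1": 0.128, "O2": 0.064, "P3": 0.015, "Pz": 0.024,
              "P4": 0.014, "P10": 0.009, "P9": 0.222, "T4": 0.026,
              "T3": 0.021, "T5": 0.187, "T6": 0.076}
TABLE3_ADJ = {"O1": 0.156, "O2": 0.101, "P3": 0.048, "Pz": 0.048,
              "P4": 0.048, "P10": 0.048, "P9": 0.222, "T4": 0.048,
              "T3": 0.048, "T5": 0.206, "T6": 0.105}


class TestBhFdr:
    def test_published_worked_example(self):
        order = list(TABLE3_RAW)
        adj = bh_fdr([TABLE3_RAW[e] for e in order])
        for e, a in zip(order, adj):
            assert round_half_up(a, 3) == TABLE3_ADJ[e], e

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_uniform_ladder(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ParameterError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, p):
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_dominates_raw(self, p):
        adj = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


# --------------------------------------------------------------------------
# ks_normality


class TestKsNormality:
    def test_statistic_in_unit_interval(self):
        rng = np.random.default_rng(4)
        stat, p, _ = ks_normality(rng.normal(size=100))
        assert 0.0 <= stat <= 1.0
        assert 0.0 <= p <= 1.0

    def test_accepts_normal_data(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            _, _, ok = ks_normality(rng.normal(size=1000))
            hits += ok
        assert hits >= 45

    def test_rejects_lognormal_data(self):
        rejects = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            _, _, ok = ks_normality(rng.lognormal(0.0, 1.0, size=1000))
            rejects += not ok
        assert rejects >= 48

    def test_constant_input(self):
        with pytest.raises(DegenerateDataError):
            ks_normality([2.0] * 10)

    def test_tiny_sample(self):
        with pytest.raises(ParameterError):
            ks_normality([1.0, 2.0])


# --------------------------------------------------------------------------
# compare_groups


def make_mwu_sample(n: int, u: int) -> tuple[np.ndarray, np.ndarray]:
    """Tie-free samples (x, y), n each, with #(x_i > y_j) exactly u."""
    assert 0 <= u <= n * n
    y = np.arange(1.0, n + 1.0)
    q, r = divmod(u, n)
    x = []
    x += [n + 10.0 + i for i in range(q)]          # above all y
    if q < n and r > 0:
        x.append(r + 0.5)                           # above exactly r of y
    while len(x) < n:
        x.append(-1.0 - len(x) / 7.0)               # below all y
    return np.asarray(x[:n]), y


# U values (case side, 300 vs 300) whose normal-approximation p-values round
# to the 11 published uncorrected p-values at 3 decimals and whose BH
# adjustment reproduces the published FDR column at 3 decimals.
TABLE3_U = {"O1": 41764, "O2": 41067, "P3": 39810, "Pz": 40191, "P4": 39755,
            "P10": 39413, "P9": 42404, "T4": 40271, "T3": 40081, "T5": 42195,
            "T6": 41233}
TABLE3_ADJ_PRINTED = {**TABLE3_ADJ, "T5": 0.205}


def _table3_fixture() -> pd.DataFrame:
    rows = []
    n = 300
    samples = {e: make_mwu_sample(n, u) for e, u in TABLE3_U.items()}
    for i in range(n):
        row = {"subject_id": f"V{i}", "group": "case", "migraine": False,
               "age": 30.0, "sex": "m"}
        for e in ROI_ELECTRODES:
            row[f"alpha_psd_{e}"] = samples[e][0][i]
        rows.append(row)
    for i in range(n):
        row = {"subject_id": f"C{i}", "group": "control", "migraine": False,
               "age": 30.0, "sex": "m"}
        for e in ROI_ELECTRODES:
            row[f"alpha_psd_{e}"] = samples[e][1][i]
        rows.append(row)
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(5)
        vals = {e: rng.lognormal(-2.0, 0.8, 21) for e in ROI_ELECTRODES}
        rows = []
        for g, prefix in (("case", "V"), ("control", "C")):
            for i in range(21):
                row = {"subject_id": f"{prefix}{i}", "group": g,
                       "migraine": False, "age": 30.0, "sex": "m"}
                for e in ROI_ELECTRODES:
                    row[f"alpha_psd_{e}"] = vals[e][i]
                rows.append(row)
        res = compare_groups(pd.DataFrame(rows))
        assert (res.table["p_raw"] >= 0.9).all()
        assert not res.table["significant"].any()
        assert res.table.loc["O1", "median_case"] == \
            res.table.loc["O1", "median_control"]

    def test_reproduces_table3_pvalues_and_fdr(self):
        res = compare_groups(_table3_fixture())
        for e in ROI_ELECTRODES:
            assert round_half_up(res.table.loc[e, "p_raw"], 3) == \
                TABLE3_RAW[e], e
            assert round_half_up(res.table.loc[e, "p_fdr"], 3) == \
                TABLE3_ADJ_PRINTED[e], e
        fmt = res.formatted()
        assert fmt.loc["P10", "p_fdr"] == 0.048
        sig = set(res.table.index[res.table["significant"]])
        assert sig == {"P3", "Pz", "P4", "P10", "T4", "T3"}

    def test_invariant_to_row_order_and_rescaling(self):
        table = _table3_fixture()
        res1 = compare_groups(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = compare_groups(shuffled)
        assert np.allclose(res1.table["p_raw"], res2.table["p_raw"])
        scaled = table.copy()
        for e in ROI_ELECTRODES:
            scaled[f"alpha_psd_{e}"] *= 37.5
        res3 = compare_groups(scaled)
        assert np.allclose(res1.table["p_raw"], res3.table["p_raw"])
        assert np.allclose(res1.table["p_fdr"], res3.table["p_fdr"])

    def test_fdr_dominates_raw_and_monotone(self):
        res = compare_groups(_table3_fixture())
        t = res.table
        assert (t["p_fdr"] >= t["p_raw"] - 1e-15).all()
        ranked = t.sort_values("p_raw")
        assert (np.diff(ranked["p_fdr"]) >= -1e-15).all()

    def test_missing_column_rejected(self):
        table = _table3_fixture().drop(columns=["alpha_psd_O1"])
        with pytest.raises(ParameterError):
            compare_groups(table)


# --------------------------------------------------------------------------
# iaf_comparison


def _iaf_table_from_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    out = manifest[["subject_id", "group", "age", "sex", "migraine"]].copy()
    out["iaf_O1"] = manifest["iaf_true"]
    out["iaf_O2"] = manifest["iaf_true"]
    return out


class TestIafComparison:
    def test_directional_pattern_without_migraine(self):
        hits = 0
        for seed in range(20):
            spec = CohortSpec(n_per_group=21, duration=160.0, seed=seed)
            _, manifest = draw_cohort_manifest(spec)
            table = _iaf_table_from_manifest(manifest)
            res = iaf_comparison(table, electrodes=("O1",))
            row = res[(res["electrode"] == "O1")
                      & (res["stratum"] == "no_migraine")].iloc[0]
            hits += row["median_case"] > row["median_control"]
        assert hits >= 16

    def test_migraine_strata_wider_spread(self):
        hits = 0
        for seed in range(20):
            spec = CohortSpec(n_per_group=21, duration=160.0, seed=100 + seed)
            _, manifest = draw_cohort_manifest(spec)
            table = _iaf_table_from_manifest(manifest)
            res = iaf_comparison(table, electrodes=("O1",))
            mig = res[(res["stratum"] == "migraine")].iloc[0]
            nomig = res[(res["stratum"] == "no_migraine")].iloc[0]
            hits += mig["iqr_case"] > nomig["iqr_case"]
        assert hits >= 16

    def test_null_omnibus_gates_posthoc(self):
        nonsig = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            rows = []
            for g, prefix in (("case", "V"), ("control", "C")):
                for i in range(21):
                    rows.append({"subject_id": f"{prefix}{i}", "group": g,
                                 "migraine": i < 14, "age": 30.0, "sex": "m",
                                 "iaf_O1": rng.normal(10.2, 0.5),
                                 "iaf_O2": rng.normal(10.2, 0.5)})
            res = iaf_comparison(pd.DataFrame(rows))
            p_omni = res["p_omnibus"].iloc[0]
            if p_omni >= 0.05:
                nonsig += 1
                assert res[res["electrode"] == "O1"]["p_posthoc"].isna().all()
        assert nonsig >= 45

    def test_degenerate_stratum_flagged(self):
        rng = np.random.default_rng(6)
        rows = []
        for g, prefix in (("case", "V"), ("control", "C")):
            for i in range(10):
                rows.append({"subject_id": f"{prefix}{i}", "group": g,
                             "migraine": True, "age": 30.0, "sex": "m",
                             "iaf_O1": rng.normal(10.2, 0.5),
                             "iaf_O2": rng.normal(10.2, 0.5)})
        res = iaf_comparison(pd.DataFrame(rows))
        empty = res[(res["electrode"] == "O1")
                    & (res["stratum"] == "no_migraine")].iloc[0]
        assert empty["skipped"]
        assert empty["n_case"] == 0 and empty["n_control"] == 0


# --------------------------------------------------------------------------
# cohort_demographics


class TestDemographics:
    def test_percentage_formatting(self):
        assert percentage(14, 21, "half_up") == 66.7
        assert percentage(14, 21, "truncate") == 66.6
        assert percentage(20, 21, "half_up") == 95.2
        assert percentage(13, 21, "half_up") == 61.9

    def test_identical_age_vectors(self):
        ages = [25.0, 30.0, 35.0, 40.0, 45.0]
        rows = []
        for g, prefix in (("case", "V"), ("control", "C")):
            for i, a in enumerate(ages):
                rows.append({"subject_id": f"{prefix}{i}", "group": g,
                             "age": a, "sex": "m", "migraine": False})
        out = cohort_demographics(pd.DataFrame(rows))
        assert out["age_t"] == pytest.approx(0.0, abs=1e-12)
        assert out["age_p"] == pytest.approx(1.0)
        lo, hi = out["age_ci95"]
        assert lo == pytest.approx(-hi, abs=1e-9)
        assert out["age_df"] == 8

    def test_counts_and_means(self):
        spec = CohortSpec(n_per_group=21, duration=160.0, seed=13)
        _, manifest = draw_cohort_manifest(spec)
        out = cohort_demographics(manifest)
        assert out["n_case"] == 21 and out["n_control"] == 21
        assert out["migraine_n_case"] == 14
        assert out["migraine_pct_case"] == 66.7
        assert out["male_pct_case"] == 61.9
        assert out["age_mean_case"] == pytest.approx(out["age_mean_control"])
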