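"""Nonparametric case-control statistics.

Pipeline: Lilliefors-corrected Kolmogorov-Smirnov normality check, a single
Kruskal-Wallis omnibus test on the per-subject ROI-mean alpha PSD, a
per-electrode two-sided Wilcoxon-Mann-Whitney post-hoc, and Benjamini-
Hochberg step-up FDR adjustment across exactly the ROI electrodes.

``mann_whitney`` reports U from the first sample's side (number of (x, y)
pairs with x > y, plus half the ties).  The exact two-sided p-value is used
for small tie-free samples (total n <= 12), computed from the full
permutation distribution of U by a rank-sum counting recursion; otherwise
the normal approximation with tie and continuity corrections applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ParameterError
from .montage import ROI_ELECTRODES

__all__ = ["ks_normality", "mann_whitney", "kruskal_wallis", "bh_fdr",
           "GroupComparison", "compare_groups", "iaf_comparison",
           "cohort_demographics", "round_half_up"]

GROUP_LEVELS = ("case", "control")


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal round-half-up (the table-formatting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# elementary tests


def ks_normality(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample KS test of normality with estimated parameters (Lilliefors)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise ParameterError("need a 1-D sample with n >= 5")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample has no distribution shape")
    from statsmodels.stats.diagnostic import lilliefors
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p), bool(p >= alpha)


@lru_cache(maxsize=None)
def _rank_sum_counts(n_total: int, n_x: int) -> tuple[int, ...]:
    """counts[s] = number of n_x-subsets of ranks 1..n_total with rank sum
    s + n_x(n_x+1)/2 (i.e. indexed by U = s - min_sum)."""
    max_u = n_x * (n_total - n_x)
    # dp over ranks: dp[k][u] = ways to pick k ranks with U-excess u
    dp = np.zeros((n_x + 1, max_u + 1), dtype=object)
    dp[0][0] = 1
    for r in range(1, n_total + 1):
        for k in range(min(r, n_x), 0, -1):
            # adding rank r as the k-th smallest contributes r - k to U
            add = r - k
            if add > max_u:
                continue
            dp[k][add:] = dp[k][add:] + dp[k - 1][:max_u + 1 - add]
    return tuple(int(v) for v in dp[n_x])


def mann_whitney(x, y, continuity: bool = True, exact_max_n: int = 12
                 ) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Returns ``(U, p)`` with U counted from x's side (pairs with x > y plus
    half the ties).  Exact enumeration when the pooled sample is tie-free
    with n <= ``exact_max_n``; otherwise normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n_x].sum()
    u = r_x - n_x * (n_x + 1) / 2.0  # = #(x > y) + ties/2

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if not has_ties and n_x + n_y <= exact_max_n:
        counts = np.array(_rank_sum_counts(n_x + n_y, n_x), dtype=float)
        total = counts.sum()
        mu = n_x * n_y / 2.0
        dev = abs(u - mu)
        us = np.arange(len(counts))
        p = counts[np.abs(us - mu) >= dev - 1e-12].sum() / total
        return float(u), float(min(p, 1.0))

    n = n_x + n_y
    mu = n_x * n_y / 2.0
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 1.0
    d = u - mu
    if continuity and d != 0:
        d -= 0.5 * np.sign(d)
    z = d / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(u), float(min(p, 1.0))


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected mid-ranks) with chi-squared p-value."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ParameterError("need >= 2 non-empty groups")
    n = sum(a.size for a in arrs)
    if n < 5:
        raise ParameterError("need total n >= 5")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrs:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    h = h / correction
    p = float(sps.chi2.sf(h, len(arrs) - 1))
    return float(h), p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# table-level operations


@dataclass
class GroupComparison:
    """Per-electrode case/control comparison (the Table-3 analogue)."""

    table: pd.DataFrame  # indexed by electrode
    h_omnibus: float
    p_omnibus: float
    alpha_level: float = 0.05
    electrode_order: tuple[str, ...] = ROI_ELECTRODES
    confirmatory: bool = True

    def formatted(self, ndigits: int = 3) -> pd.DataFrame:
        """Table with p-values rounded half-up, for reporting only."""
        out = self.table.copy()
        for col in ("p_raw", "p_fdr"):
            out[col] = [round_half_up(v, ndigits) for v in out[col]]
        return out

    def to_json_dict(self) -> dict:
        return {
            "omnibus": {"H": self.h_omnibus, "p": self.p_omnibus,
                        "confirmatory": self.confirmatory},
            "alpha_level": self.alpha_level,
            "electrodes": self.table.reset_index().to_dict(orient="records"),
        }


def _split_groups(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    levels = sorted(table["group"].unique())
    if len(levels) != 2:
        raise ParameterError(f"expected exactly two group levels, got {levels}")
    if set(levels) == set(GROUP_LEVELS):
        case_lab, ctrl_lab = "case", "control"
    else:
        case_lab, ctrl_lab = levels
    return table[table["group"] == case_lab], table[table["group"] == ctrl_lab]


def _iqr(v: np.ndarray) -> float:
    q1, q3 = np.percentile(v, [25, 75])
    return float(q3 - q1)


def compare_groups(metric_table: pd.DataFrame,
                   roi: Sequence[str] = ROI_ELECTRODES,
                   value_prefix: str = "alpha_psd_",
                   alpha_level: float = 0.05) -> GroupComparison:
    """Medians/IQRs, per-electrode MWU with BH-FDR over the ROI, KW omnibus.

    The omnibus is a two-group Kruskal-Wallis on each subject's mean alpha
    PSD over the ROI; post-hoc tests are reported regardless but flagged
    non-confirmatory when the omnibus is not significant.
    """
    case, ctrl = _split_groups(metric_table)
    if case.empty or ctrl.empty:
        raise ParameterError("both groups must be non-empty")
    cols = [f"{value_prefix}{e}" for e in roi]
    missing = [c for c in cols if c not in metric_table.columns]
    if missing:
        raise ParameterError(f"metric table lacks columns: {missing}")

    omni_case = case[cols].mean(axis=1).to_numpy()
    omni_ctrl = ctrl[cols].mean(axis=1).to_numpy()
    h, p_omni = kruskal_wallis([omni_case, omni_ctrl])

    rows = []
    for e, col in zip(roi, cols):
        xv = case[col].to_numpy(dtype=float)
        yv = ctrl[col].to_numpy(dtype=float)
        if np.isnan(xv).any() or np.isnan(yv).any():
            raise ParameterError(f"missing values in column {col}")
        u, p = mann_whitney(xv, yv)
        rows.append({
            "electrode": e,
            "median_case": float(np.median(xv)),
            "median_control": float(np.median(yv)),
            "iqr_case": _iqr(xv),
            "iqr_control": _iqr(yv),
            "U": u,
            "p_raw": p,
        })
    table = pd.DataFrame(rows).set_index("electrode")
    table["p_fdr"] = bh_fdr(table["p_raw"].to_numpy())
    table["significant"] = table["p_fdr"] < alpha_level
    return GroupComparison(table=table, h_omnibus=h, p_omnibus=p_omni,
                           alpha_level=alpha_level,
                           electrode_order=tuple(roi),
                           confirmatory=bool(p_omni < alpha_level))


def iaf_comparison(metric_table: pd.DataFrame,
                   electrodes: Sequence[str] = ("O1", "O2"),
                   stratify_by_migraine: bool = True,
                   alpha_level: float = 0.05) -> pd.DataFrame:
    """Group comparison of IAF per electrode, optionally migraine-stratified.

    Per electrode an omnibus Kruskal-Wallis runs across the (stratified)
    groups; per-stratum Mann-Whitney post-hocs are computed only when the
    omnibus is significant.  Strata with n < 2 in either group are flagged
    and their tests skipped.
    """
    case, ctrl = _split_groups(metric_table)
    rows = []
    for e in electrodes:
        col = f"iaf_{e}"
        if col not in metric_table.columns:
            raise ParameterError(f"metric table lacks column {col}")
        strata = [(True,), (False,)] if stratify_by_migraine else [(None,)]

        groups, labels = [], []
        for (mig,) in strata:
            for name, df in (("case", case), ("control", ctrl)):
                sub = df if mig is None else df[df["migraine"] == mig]
                v = sub[col].to_numpy(dtype=float)
                if len(v) > 0:
                    groups.append(v)
                    labels.append((mig, name))
        try:
            _, p_omni = kruskal_wallis([g for g in groups if len(g) > 0])
        except (ParameterError, DegenerateDataError):
            p_omni = np.nan

        for (mig,) in strata:
            sub_case = case if mig is None else case[case["migraine"] == mig]
            sub_ctrl = ctrl if mig is None else ctrl[ctrl["migraine"] == mig]
            cv = sub_case[col].to_numpy(dtype=float)
            kv = sub_ctrl[col].to_numpy(dtype=float)
            degenerate = len(cv) < 2 or len(kv) < 2
            p_post = np.nan
            if (not degenerate and np.isfinite(p_omni)
                    and p_omni < alpha_level):
                _, p_post = mann_whitney(cv, kv)
            rows.append({
                "electrode": e,
                "stratum": ("all" if mig is None
                            else ("migraine" if mig else "no_migraine")),
                "n_case": len(cv), "n_control": len(kv),
                "median_case": float(np.median(cv)) if len(cv) else np.nan,
                "median_control": float(np.median(kv)) if len(kv) else np.nan,
                "iqr_case": _iqr(cv) if len(cv) >= 2 else np.nan,
                "iqr_control": _iqr(kv) if len(kv) >= 2 else np.nan,
                "min_case": float(cv.min()) if len(cv) else np.nan,
                "max_case": float(cv.max()) if len(cv) else np.nan,
                "min_control": float(kv.min()) if len(kv) else np.nan,
                "max_control": float(kv.max()) if len(kv) else np.nan,
                "p_omnibus": p_omni,
                "p_posthoc": p_post,
                "skipped": degenerate,
            })
    return pd.DataFrame(rows)


def _percentage(count: int, denom: int, mode: str = "half_up") -> float:
    pct = 100.0 * count / denom
    if mode == "half_up":
        return round_half_up(pct, 1)
    if mode == "truncate":
        return float(int(pct * 10) / 10.0)
    raise ParameterError(f"unknown percentage mode {mode!r}")


def cohort_demographics(manifest: pd.DataFrame,
                        percent_mode: str = "half_up") -> dict:
    """Counts, percentages, age mean±sd and a two-sample t-test on age."""
    case, ctrl = _split_groups(manifest)
    out: dict = {"n_case": len(case), "n_control": len(ctrl),
                 "percent_mode": percent_mode}
    for name, df in (("case", case), ("control", ctrl)):
        n = len(df)
        out[f"age_mean_{name}"] = float(df["age"].mean())
        out[f"age_sd_{name}"] = float(df["age"].std(ddof=1))
        if "migraine" in df.columns:
            m = int(df["migraine"].sum())
            out[f"migraine_n_{name}"] = m
            out[f"migraine_pct_{name}"] = _percentage(m, n, percent_mode)
        if "sex" in df.columns:
            k = int((df["sex"] == "m").sum())
            out[f"male_n_{name}"] = k
            out[f"male_pct_{name}"] = _percentage(k, n, percent_mode)

    a = case["age"].to_numpy(dtype=float)
    b = ctrl["age"].to_numpy(dtype=float)
    res = sps.ttest_ind(a, b)
    df_t = len(a) + len(b) - 2
    if np.ptp(np.concatenate([a, b])) == 0:
        t_stat, p_val, ci = 0.0, 1.0, (0.0, 0.0)
    else:
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        lo, hi = res.confidence_interval(0.95)
        ci = (float(lo), float(hi))
    out.update({"age_t": t_stat, "age_p": p_val, "age_ci95": ci,
                "age_df": int(df_t)})
    return out


def percentage(count: int, denom: int, mode: str = "half_up") -> float:
    """Public percentage formatter (1 decimal; half-up or truncating)."""
    return _percentage(count, denom, mode)
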