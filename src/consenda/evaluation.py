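"""Tool-concordance metrics, depth-confound controls, ground-truth
benchmarking, and cohort summary tables.

The concordance metrics quantify, per engine and dataset: (a) what fraction
of the engine's calls are consensus calls (a proxy for precision), (b) what
fraction of all consensus calls the engine finds (a proxy for recall), and
(c) the engine's total call count min-max normalised within the dataset.
Datasets without any consensus call are excluded from aggregation.
"""
from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import exact_test_2x2
from .io_profiles import SampleMetadata
from .synthetic_data import SimTruth

log = logging.getLogger(__name__)

__all__ = [
    "tool_metrics", "aggregate_metrics", "benchmark_vs_truth",
    "depth_group_test", "depth_matched_subset", "cohort_summary",
    "format_percent",
]


def tool_metrics(engine_results: dict[str, pd.DataFrame],
                 consensus_df: pd.DataFrame, dataset_id: str) -> pd.DataFrame:
    """Per-engine concordance with the consensus set of one dataset.

    ``pct_calls_consensus`` is NaN (undefined) when the engine made no
    calls; ``n_calls_normalized`` is min-max over engines within the
    dataset (constant counts normalise to 0).
    """
    cset = set(consensus_df.loc[consensus_df["consensus"], "feature_id"])
    calls = {e: set(df.loc[df["significant"], "feature_id"])
             for e, df in engine_results.items()}
    counts = {e: len(c) for e, c in calls.items()}
    lo, hi = min(counts.values()), max(counts.values())
    rows = []
    for e in sorted(engine_results):
        c = calls[e]
        rows.append({
            "engine": e,
            "dataset_id": dataset_id,
            "n_calls": counts[e],
            "pct_calls_consensus": 100.0 * len(c & cset) / len(c) if c else np.nan,
            "pct_consensus_found": 100.0 * len(c & cset) / len(cset) if cset else np.nan,
            "n_calls_normalized": (counts[e] - lo) / (hi - lo) if hi > lo else 0.0,
            "has_consensus": bool(cset),
        })
    return pd.DataFrame(rows)


def aggregate_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Median (IQR) of each concordance metric per engine across datasets,
    dropping datasets without consensus calls."""
    if records.empty:
        return records
    usable = records[records["has_consensus"]]
    out = []
    for engine, sub in usable.groupby("engine"):
        row = {"engine": engine, "n_datasets": len(sub)}
        for col in ("pct_calls_consensus", "pct_consensus_found", "n_calls_normalized"):
            vals = sub[col].dropna()
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row[f"{col}_median"] = med
                row[f"{col}_iqr"] = f"{q1:.1f}-{q3:.1f}"
            else:
                row[f"{col}_median"] = np.nan
                row[f"{col}_iqr"] = ""
        out.append(row)
    return pd.DataFrame(out)


def benchmark_vs_truth(calls, truth: SimTruth, universe=None) -> dict:
    """Sensitivity, observed FDR, and sign accuracy against implanted truth.

    ``calls`` is either a DAResult frame, a consensus frame, or an iterable
    of feature ids; sign accuracy needs a frame with directions and is NaN
    otherwise (or when there are no true positives).
    """
    true_set = set(truth.diff_features)
    directions = {}
    if isinstance(calls, pd.DataFrame):
        if "consensus" in calls.columns:
            called = calls[calls["consensus"]]
            directions = dict(zip(called["feature_id"], called["majority_direction"]))
        else:
            called = calls[calls["significant"]]
            directions = dict(zip(called["feature_id"], called["direction"]))
        call_set = set(called["feature_id"])
    else:
        call_set = set(calls)
    if universe is not None and not true_set <= set(universe):
        missing = true_set - set(universe)
        raise ValueError(f"truth features outside the feature universe: {sorted(missing)}")
    tp = call_set & true_set
    sensitivity = len(tp) / len(true_set) if true_set else np.nan
    fdr = len(call_set - true_set) / max(1, len(call_set))
    if directions and tp:
        ok = sum(1 for f in tp
                 if np.sign(truth.diff_features[f]) == np.sign(directions.get(f, 0)))
        sign_acc = ok / len(tp)
    else:
        sign_acc = np.nan
    return {"sensitivity": sensitivity, "observed_fdr": fdr,
            "sign_accuracy": sign_acc, "n_calls": len(call_set),
            "n_true": len(true_set)}


def depth_group_test(meta: SampleMetadata, group_col: str = "group") -> dict:
    """Rank-sum test of library size by group — the depth-confound check."""
    df = meta.data
    groups = df[group_col].unique()
    if len(groups) != 2:
        raise ValueError("depth test requires exactly two groups")
    a = df.loc[df[group_col] == groups[0], "library_size"].to_numpy(dtype=float)
    b = df.loc[df[group_col] == groups[1], "library_size"].to_numpy(dtype=float)
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least two samples per group")
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {"p": p, "medians": {str(groups[0]): float(np.median(a)),
                                str(groups[1]): float(np.median(b))}}


def depth_matched_subset(meta: SampleMetadata, mode: str = "min_threshold",
                         k: int | None = None, group_col: str = "group",
                         case_level: str = "case") -> list[str]:
    """Select a depth-matched sample subset.

    ``min_threshold`` keeps every case sample plus controls whose library
    size is at least the shallowest case sample; ``top_k`` keeps the k
    deepest samples of each group. Ties break deterministically by
    sample id.
    """
    df = meta.data
    case = df[df[group_col] == case_level]
    ctrl = df[df[group_col] != case_level]
    if case.empty or ctrl.empty:
        raise ValueError("both groups must be non-empty")
    if mode == "min_threshold":
        cut = case["library_size"].min()
        keep = list(case.index) + [s for s in ctrl.index
                                   if ctrl.loc[s, "library_size"] >= cut]
    elif mode == "top_k":
        if k is None:
            raise ValueError("top_k mode requires k")
        keep = []
        for sub in (ctrl, case):
            if k > len(sub):
                raise ValueError(f"k={k} exceeds group size {len(sub)}")
            ordered = sub.assign(_sid=sub.index.astype(str)).sort_values(
                ["library_size", "_sid"], ascending=[False, True])
            keep.extend(ordered.index[:k])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return sorted(keep, key=list(df.index).index)


def format_percent(numerator: float, denominator: float) -> str:
    """Percentage at one decimal, rounded half away from zero, with a
    trailing '.0' stripped (the printed style of clinical summary tables:
    10/28 -> '35.7', 14/28 -> '50')."""
    pct = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    s = str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return s[:-2] if s.endswith(".0") else s


def _is_normal(values: np.ndarray, strict: bool = False) -> bool:
    """Normality gate. Default: one omnibus test at alpha = 0.05. Strict
    mode requires unanimous passes from four tests (omnibus, Shapiro-Wilk,
    Lilliefors-style KS, Anderson-Darling)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 8 or np.ptp(v) == 0:
        return False
    if not strict:
        return bool(stats.normaltest(v).pvalue >= 0.05)
    ks = stats.kstest((v - v.mean()) / v.std(ddof=1), "norm").pvalue
    ad = stats.anderson(v, "norm")
    ad_ok = ad.statistic < ad.critical_values[list(ad.significance_level).index(5.0)]
    return bool(stats.normaltest(v).pvalue >= 0.05
                and stats.shapiro(v).pvalue >= 0.05
                and ks >= 0.05 and ad_ok)


def cohort_summary(clinical: pd.DataFrame, types: dict[str, str],
                   group_col: str = "group", strict_normality: bool = False) -> pd.DataFrame:
    """Clinical characteristics table: per variable, a per-group summary and
    a between-group p-value.

    Continuous variables pass a normality gate in both groups: normal ->
    mean+/-sd with a t-test, otherwise median (IQR, linear interpolation)
    with a rank-sum test. Categorical variables: 2x2 -> exact hypergeometric
    test with odds ratio, larger tables -> chi-square. All-missing
    variables are skipped with a log entry.
    """
    groups = list(pd.unique(clinical[group_col]))
    if len(groups) != 2:
        raise ValueError("cohort summary requires exactly two groups")
    rows = []
    for var, kind in types.items():
        sub = clinical[[group_col, var]].dropna()
        if sub.empty:
            log.warning("cohort_summary: variable %r has no data; skipped", var)
            continue
        a = sub.loc[sub[group_col] == groups[0], var]
        b = sub.loc[sub[group_col] == groups[1], var]
        if kind == "continuous":
            a, b = a.astype(float), b.astype(float)
            normal = _is_normal(a, strict_normality) and _is_normal(b, strict_normality)
            if normal:
                summ = [f"{v.mean():.1f}±{v.std(ddof=1):.1f}" for v in (a, b)]
                p = float(stats.ttest_ind(a, b).pvalue)
                test = "t"
            else:
                summ = []
                for v in (a, b):
                    q1, med, q3 = np.percentile(v, [25, 50, 75])
                    summ.append(f"{med:.1f} ({q1:.1f}-{q3:.1f})")
                p = (float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                     if np.ptp(np.concatenate([a, b])) > 0 else 1.0)
                test = "ranksum"
        elif kind == "categorical":
            tab = pd.crosstab(sub[var], sub[group_col]).reindex(columns=groups, fill_value=0)
            if tab.shape == (2, 2):
                _, p = exact_test_2x2(tab.to_numpy().T)
                test = "exact"
            else:
                p = float(stats.chi2_contingency(tab.to_numpy())[1])
                test = "chi2"
            summ = []
            for g in groups:
                col = tab[g]
                top = col.index[np.argmax(col.to_numpy())]
                summ.append(f"{col[top]} ({format_percent(col[top], col.sum())}%)")
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        rows.append({"variable": var, str(groups[0]): summ[0],
                     str(groups[1]): summ[1], "p": p, "test": test})
    return pd.DataFrame(rows)
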