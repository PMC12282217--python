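"""Majority-vote consensus across differential-abundance engines.

A feature is a *consensus* call at a level when at least half of the
engines that ran (>= 3 of 6 by default) flag it significant at q < 0.05.
Features flagged by only one or two engines form the supplementary tier.
Direction is the sign consensus among significant engines; disagreement in
sign is reported via a discordance flag rather than suppressed.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = ["min_votes", "vote", "consensus_across_levels", "compare_methods"]


def min_votes(n_engines: int, threshold: float = 0.5) -> int:
    """Smallest k with k / n_engines >= threshold (simple majority by
    default: 6 engines -> 3)."""
    if n_engines < 1:
        raise ValueError("need at least one engine")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    return math.ceil(threshold * n_engines)


def vote(results: dict[str, pd.DataFrame], threshold: float = 0.5,
         level: str | None = None) -> pd.DataFrame:
    """Aggregate per-engine result frames for one level into consensus calls.

    ``results`` maps engine id -> DAResult frame; all frames must cover the
    same feature set (engines that failed should simply be absent, which
    shrinks the vote denominator).
    """
    if not results:
        raise ValueError("no engine results to vote on")
    engine_ids = sorted(results)
    universes = [frozenset(df["feature_id"]) for df in results.values()]
    if len(set(universes)) != 1:
        raise ValueError("engines report on different feature sets")
    features = list(results[engine_ids[0]]["feature_id"])
    need = min_votes(len(engine_ids), threshold)
    sig = pd.DataFrame({e: results[e].set_index("feature_id")["significant"]
                        for e in engine_ids}).loc[features]
    direction = pd.DataFrame({e: results[e].set_index("feature_id")["direction"]
                              for e in engine_ids}).loc[features]
    rows = []
    for f in features:
        s = sig.loc[f].to_numpy(dtype=bool)
        d = direction.loc[f].to_numpy(dtype=int)
        n_sig = int(s.sum())
        signs = d[s]
        majority = int(np.sign(signs.sum())) if n_sig else 0
        discordant = bool((signs > 0).any() and (signs < 0).any())
        rows.append({
            "feature_id": f,
            "level": level,
            "n_engines_run": len(engine_ids),
            "n_significant": n_sig,
            "consensus": n_sig >= need,
            "majority_direction": majority,
            "discordant": discordant,
            "votes": ",".join(e for e, flag in zip(engine_ids, s) if flag),
        })
    return pd.DataFrame(rows)


def consensus_across_levels(all_results: dict[tuple[str, str], pd.DataFrame],
                            threshold: float = 0.5) -> pd.DataFrame:
    """Apply :func:`vote` independently per level; no cross-level
    aggregation. ``all_results`` maps (level, engine) -> DAResult frame."""
    levels = sorted({lv for lv, _ in all_results})
    frames = []
    for lv in levels:
        per_engine = {e: df for (l, e), df in all_results.items() if l == lv}
        frames.append(vote(per_engine, threshold, level=lv))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def split_tiers(consensus_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main tier (consensus calls) and supplementary tier (1-2 votes)."""
    main = consensus_df[consensus_df["consensus"]]
    supp = consensus_df[(~consensus_df["consensus"]) & (consensus_df["n_significant"] > 0)]
    return main.reset_index(drop=True), supp.reset_index(drop=True)


def compare_methods(consensus_m1: pd.DataFrame, consensus_m2: pd.DataFrame) -> dict:
    """Set algebra on consensus calls from the proportion-input (method 1)
    and count-input (method 2) runs, stratified by vote count."""
    key = ["level", "feature_id"]
    u1 = set(map(tuple, consensus_m1[key].itertuples(index=False)))
    u2 = set(map(tuple, consensus_m2[key].itertuples(index=False)))
    if u1 != u2:
        raise ValueError("method runs cover different feature universes")
    c1 = set(map(tuple, consensus_m1.loc[consensus_m1["consensus"], key]
                 .itertuples(index=False)))
    c2 = set(map(tuple, consensus_m2.loc[consensus_m2["consensus"], key]
                 .itertuples(index=False)))
    votes1 = consensus_m1.set_index(key)["n_significant"]
    tiers = {}
    for v in (3, 4, 5, 6):
        tier1 = {k for k in c1 if votes1.loc[k] == v}
        tiers[v] = {"n_m1": len(tier1),
                    "n_shared": len(tier1 & c2),
                    "frac_shared": len(tier1 & c2) / len(tier1) if tier1 else float("nan")}
    return {"shared": sorted(c1 & c2), "only_m1": sorted(c1 - c2),
            "only_m2": sorted(c2 - c1), "by_votes": tiers}
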