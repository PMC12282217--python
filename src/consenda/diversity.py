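"""Alpha diversity on rarefied counts, Aitchison beta diversity, and
permutation tests.

Alpha diversity is computed on equal-depth (rarefied) samples: Shannon index
in nats, richness as the count of detected features, and Pielou's evenness
shannon / ln(richness). Beta diversity is the Aitchison distance — Euclidean
distance between CLR-transformed samples — with group location tested by
PERMANOVA (pseudo-F, free or within-subject-restricted permutations) gated
by a PERMDISP homogeneity-of-dispersions test: the location test is only
trusted when dispersions do not differ.

Both permutation tests support exhaustive enumeration of all label
permutations for small n, which the test suite uses as its oracle.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io_profiles import FeatureTable, SampleMetadata, clr_transform

log = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix", "alpha_diversity", "aitchison", "permanova",
    "permdisp", "matched_unmatched", "matched_by_group", "depth_richness_corr",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(v, v.T, atol=1e-9) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def loc(self, a: str, b: str) -> float:
        ia, ib = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def alpha_diversity(rarefied: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), richness, and Pielou's evenness.

    Requires equal row sums (i.e. rarefied input); evenness is defined as 0
    for single-feature samples.
    """
    counts = rarefied.values()
    sums = counts.sum(axis=1)
    if not np.allclose(sums, sums[0]):
        raise ValueError("alpha diversity requires rarefied (equal-sum) samples")
    records = []
    for sid, row in zip(rarefied.sample_ids, counts):
        p = row[row > 0] / row.sum()
        shannon = float(-(p * np.log(p)).sum())
        richness = int((row > 0).sum())
        evenness = shannon / np.log(richness) if richness > 1 else 0.0
        records.append({"sample_id": sid, "shannon": shannon,
                        "richness": richness, "evenness": evenness})
    return pd.DataFrame(records).set_index("sample_id")


def observed_richness(table: FeatureTable) -> pd.Series:
    """Richness without rarefaction (used for depth-confound diagnostics)."""
    return pd.Series((table.values() > 0).sum(axis=1), index=table.sample_ids,
                     name="richness")


def aitchison(table: FeatureTable, pseudo: float) -> DistanceMatrix:
    """Euclidean distances between CLR-transformed samples."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    clr = clr_transform(table, pseudo)
    return DistanceMatrix(table.sample_ids, squareform(pdist(clr)))


# ---------------------------------------------------------------------------
# PERMANOVA / PERMDISP
# ---------------------------------------------------------------------------

def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes)
    if len(uniques) < 2 or (sizes == 0).any():
        raise ValueError("need at least two non-empty groups")
    return codes, len(uniques)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, g: int) -> float:
    """PERMANOVA pseudo-F from squared distances and group codes."""
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for k in range(g):
        idx = np.flatnonzero(codes == k)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _permutations(n: int, n_perm: int, rng, strata=None, exhaustive=False):
    """Yield permutation index arrays; exhaustive mode enumerates all
    distinct rearrangements (within strata when given)."""
    idx = np.arange(n)
    if exhaustive:
        if strata is None:
            yield from (np.asarray(p) for p in itertools.permutations(idx))
        else:
            groups = [np.flatnonzero(np.asarray(strata) == s)
                      for s in pd.unique(np.asarray(strata))]
            pools = [list(itertools.permutations(g)) for g in groups]
            for combo in itertools.product(*pools):
                perm = idx.copy()
                for g, p in zip(groups, combo):
                    perm[g] = p
                yield perm
    else:
        for _ in range(n_perm):
            if strata is None:
                yield rng.permutation(idx)
            else:
                perm = idx.copy()
                for s in pd.unique(np.asarray(strata)):
                    g = np.flatnonzero(np.asarray(strata) == s)
                    perm[g] = g[rng.permutation(len(g))]
                yield perm


def permanova(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=0,
              strata=None, exhaustive: bool = False) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns pseudo_F, R2 and the add-one permutation p-value. ``strata``
    restricts permutations to within-stratum swaps (the within-subject
    scheme used for time-point contrasts); ``exhaustive`` enumerates every
    permutation instead of sampling.
    """
    codes, g = _group_codes(groups)
    d2 = dm.values ** 2
    n = len(codes)
    obs = _pseudo_f(d2, codes, g)
    ss_total = d2.sum() / (2 * n)
    r2 = obs * (g - 1) / (obs * (g - 1) + (n - g))
    rng = np.random.default_rng(seed)
    count, total = 0, 0
    for perm in _permutations(n, n_perm, rng, strata=strata, exhaustive=exhaustive):
        total += 1
        if _pseudo_f(d2, codes[perm], g) >= obs - 1e-12:
            count += 1
    if exhaustive:
        p = count / total
    else:
        p = (1 + count) / (1 + total)
    return {"pseudo_F": float(obs), "R2": float(r2), "p": float(p),
            "n_permutations": total}


def _dispersion_distances(dm: DistanceMatrix, codes: np.ndarray, g: int) -> np.ndarray:
    """Distance of each sample to its group centroid in principal-coordinate
    space, retaining negative-eigenvalue axes with the usual sign correction."""
    n = len(codes)
    a = -0.5 * dm.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    gram = j @ a @ j
    eigval, eigvec = np.linalg.eigh((gram + gram.T) / 2)
    keep = np.abs(eigval) > 1e-10
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 0
    z = np.empty(n)
    for k in range(g):
        idx = codes == k
        c = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - c) ** 2
        d2 = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, g: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_b = sum((z[codes == k].mean() - grand) ** 2 * (codes == k).sum()
               for k in range(g))
    ss_w = sum(((z[codes == k] - z[codes == k].mean()) ** 2).sum()
               for k in range(g))
    if ss_w <= 1e-30:
        return np.inf if ss_b > 1e-30 else 0.0
    return (ss_b / (g - 1)) / (ss_w / (n - g))


def permdisp(dm: DistanceMatrix, groups, n_perm: int = 9999, seed=0,
             exhaustive: bool = False) -> dict:
    """Homogeneity-of-dispersions test (distances to group centroids,
    permutation F). Returns the p-value and the gate flag: a PERMANOVA
    report is suppressed when dispersions differ (p < 0.05)."""
    codes, g = _group_codes(groups)
    z = _dispersion_distances(dm, codes, g)
    obs = _anova_f(z, codes, g)
    rng = np.random.default_rng(seed)
    count, total = 0, 0
    for perm in _permutations(len(codes), n_perm, rng, exhaustive=exhaustive):
        total += 1
        if _anova_f(z[perm], codes, g) >= obs - 1e-12:
            count += 1
    p = count / total if exhaustive else (1 + count) / (1 + total)
    return {"F": float(obs), "p": float(p), "homogeneous": bool(p >= 0.05)}


# ---------------------------------------------------------------------------
# matched / unmatched stability
# ---------------------------------------------------------------------------

def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p; all-tied inputs give p = 1 by convention."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _pairs(meta: SampleMetadata) -> dict[str, tuple[str, str]]:
    df = meta.data
    out = {}
    for subject, sub in df.groupby("subject_id"):
        tps = set(sub["timepoint"])
        if {"early", "late"} <= tps:
            early = sub.index[sub["timepoint"] == "early"][0]
            late = sub.index[sub["timepoint"] == "late"][0]
            out[subject] = (early, late)
    return out


def matched_unmatched(dm: DistanceMatrix, meta: SampleMetadata) -> dict:
    """Within-subject (matched) early-late distances vs all cross-subject
    early-late distances, with a two-sided rank-sum test."""
    pairs = _pairs(meta)
    if not pairs:
        raise ValueError("no subject has both time points")
    df = meta.data
    early_ids = [s for s in dm.sample_ids if df.loc[s, "timepoint"] == "early"]
    late_ids = [s for s in dm.sample_ids if df.loc[s, "timepoint"] == "late"]
    matched = np.array([dm.loc(e, l) for e, l in pairs.values()])
    unmatched = np.array([dm.loc(e, l) for e in early_ids for l in late_ids
                          if df.loc[e, "subject_id"] != df.loc[l, "subject_id"]])
    return {"matched": matched, "unmatched": unmatched,
            "p": _ranksum_p(matched, unmatched)}


def matched_by_group(dm: DistanceMatrix, meta: SampleMetadata,
                     test: str = "auto") -> dict:
    """Compare within-subject early-late distances between groups
    (microbiome stability). ``test``: 'ranksum', 't', or 'auto' (normality
    gate on both groups chooses; the selection is logged)."""
    pairs = _pairs(meta)
    df = meta.data
    by_group: dict[str, list[float]] = {}
    for subject, (e, l) in pairs.items():
        by_group.setdefault(df.loc[e, "group"], []).append(dm.loc(e, l))
    if len(by_group) != 2:
        raise ValueError("need matched pairs in exactly two groups")
    (ga, da), (gb, db) = [(g, np.asarray(v)) for g, v in sorted(by_group.items())]
    if min(len(da), len(db)) < 2:
        raise ValueError("need at least two matched pairs per group for a test")
    chosen = test
    if test == "auto":
        normal = all(len(v) >= 8 and stats.normaltest(v).pvalue >= 0.05
                     for v in (da, db))
        chosen = "t" if normal else "ranksum"
        log.info("matched_by_group: auto-selected %s test", chosen)
    if chosen == "t":
        p = float(stats.ttest_ind(da, db).pvalue)
    else:
        p = _ranksum_p(da, db)
    return {"groups": (ga, gb), "distances": {ga: da, gb: db},
            "p": p, "test": chosen}


def depth_richness_corr(meta: SampleMetadata, alpha: pd.DataFrame) -> dict:
    """Spearman correlation of library size with pre-rarefaction richness —
    the depth-sensitivity diagnostic motivating rarefaction."""
    rich = alpha["richness"].astype(float)
    depth = meta.data.loc[rich.index, "library_size"].astype(float)
    if rich.nunique() <= 1 or depth.nunique() <= 1:
        return {"rho": 0.0, "p": 1.0, "undefined": True}
    rho, p = stats.spearmanr(depth, rich)
    return {"rho": float(rho), "p": float(p), "undefined": False}
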