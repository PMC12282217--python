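"""Synthetic metagenomic cohorts with known ground truth.

Emulates the structure of a paired two-group pregnancy cohort profiled by
shotgun metagenomics: sparse, strongly uneven compositions over a few
hundred features; log-normal library sizes with an optional multiplicative
depth confound on the case group; paired subjects sampled at an early and a
late time point with subject-level autocorrelation; and group effects
implanted on a chosen number of features as signed log2 fold changes,
recorded as ground truth for benchmarking.

The count layer is multinomial given each sample's closed composition;
biological overdispersion enters through log-normal noise on the abundance
scale, which keeps sampling and biological variance separable for oracle
checks.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_profiles import FeatureTable, SampleMetadata

__all__ = [
    "SimConfig", "SimTruth", "study_roster", "roster_from_config",
    "simulate_baseline", "simulate_cohort", "implant_signal",
]

#: default library-size log-mean, matching a post-QC mean depth of ~375,000
#: paired reads reported for buccal swab profiles
DEFAULT_DEPTH_LOGMEAN = float(np.log(375_199))


@dataclass
class SimConfig:
    """Parameters of the cohort generator.

    ``depth_group_shift`` multiplies case-group library sizes (1 = no
    confound). ``log2_fold_changes`` gives the signed implanted effects; if
    None, ``n_diff`` features get +3 (8-fold increase in cases).
    ``subject_sd`` and ``noise_sd`` are log-scale standard deviations of the
    per-subject (time-stable) and per-sample feature effects.
    """

    n_features: int = 300
    n_subjects_per_group: int = 20
    paired_fraction: float = 1.0
    depth_logmean: float = DEFAULT_DEPTH_LOGMEAN
    depth_logsd: float = 0.5
    depth_group_shift: float = 1.0
    n_diff: int = 0
    log2_fold_changes: tuple[float, ...] | None = None
    subject_sd: float = 0.6
    noise_sd: float = 0.6
    bmi_effect: float = 0.0
    n_bmi_features: int = 0
    baseline_logsd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_diff > self.n_features:
            raise ValueError("n_diff cannot exceed n_features")
        if min(self.subject_sd, self.noise_sd, self.depth_logsd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.depth_group_shift <= 0:
            raise ValueError("depth_group_shift must be positive")
        if not (0 <= self.paired_fraction <= 1):
            raise ValueError("paired_fraction must lie in [0, 1]")
        if self.log2_fold_changes is not None and len(self.log2_fold_changes) != self.n_diff:
            raise ValueError("log2_fold_changes length must equal n_diff")


@dataclass
class SimTruth:
    """Ground-truth differential features with signed log2 fold changes."""

    diff_features: dict[str, float] = field(default_factory=dict)
    bmi_features: tuple[str, ...] = ()

    def __post_init__(self):
        if any(fc == 0 for fc in self.diff_features.values()):
            raise ValueError("ground-truth fold changes must be non-zero")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"diff_features": self.diff_features,
                       "bmi_features": list(self.bmi_features)}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(diff_features=d["diff_features"],
                   bmi_features=tuple(d["bmi_features"]))


def study_roster() -> list[tuple[str, str, tuple[str, ...]]]:
    """The cohort layout of the motivating study: 24 paired + 3 early-only +
    1 late-only control subjects, 9 paired + 2 early-only case subjects.

    Returns (subject_id, group, timepoints) triples; 27 control samples at
    the early time point and 25 at the late one.
    """
    roster = []
    for i in range(24):
        roster.append((f"C{i+1:02d}", "control", ("early", "late")))
    for i in range(24, 27):
        roster.append((f"C{i+1:02d}", "control", ("early",)))
    roster.append(("C28", "control", ("late",)))
    for i in range(9):
        roster.append((f"T{i+1:02d}", "case", ("early", "late")))
    for i in range(9, 11):
        roster.append((f"T{i+1:02d}", "case", ("early",)))
    return roster


def roster_from_config(config: SimConfig) -> list[tuple[str, str, tuple[str, ...]]]:
    """Build a roster from n_subjects_per_group and paired_fraction: the
    first round(fraction * n) subjects of each group are paired, the rest
    appear at the early time point only."""
    roster = []
    n = config.n_subjects_per_group
    n_paired = int(round(config.paired_fraction * n))
    for prefix, group in (("C", "control"), ("T", "case")):
        for i in range(n):
            tps = ("early", "late") if i < n_paired else ("early",)
            roster.append((f"{prefix}{i+1:03d}", group, tps))
    return roster


def simulate_baseline(n_features: int, seed) -> np.ndarray:
    """A strongly uneven baseline composition: normal log-abundances with a
    wide spread, closed to sum one. Deterministic given the seed."""
    if n_features < 2:
        raise ValueError("need at least two features")
    rng = np.random.default_rng(seed)
    log_lam = rng.normal(0.0, 2.0, size=n_features)
    p = np.exp(log_lam - log_lam.max())
    return p / p.sum()


def _pick_diff_features(log_lam: np.ndarray, n_diff: int, rng) -> np.ndarray:
    """Implant effects on low- but not vanishing-abundance features: the
    55th-90th percentile band of baseline log-abundance, mirroring the
    sub-percent prevalence of real differential taxa."""
    lo, hi = np.quantile(log_lam, [0.55, 0.90])
    eligible = np.flatnonzero((log_lam >= lo) & (log_lam <= hi))
    if len(eligible) < n_diff:
        eligible = np.argsort(log_lam)[-max(n_diff, 1):]
    return rng.choice(eligible, size=n_diff, replace=False)


def simulate_cohort(config: SimConfig,
                    roster: list[tuple[str, str, tuple[str, ...]]] | None = None
                    ) -> tuple[FeatureTable, SampleMetadata, SimTruth]:
    """Generate (count table, metadata, ground truth) for one cohort.

    Per subject i in group g at time t, feature f:
        log a = lam_f + 1[g=case] * delta_f + beta_bmi * (bmi_i - 27) * 1[f in B]
                + u_{i,f} + eps_{s,f}
    closed by softmax to a composition, then counts ~ multinomial(depth_s).
    Subject effects u are shared across a subject's time points, which is
    what makes matched samples more similar than unmatched ones.
    """
    rng = np.random.default_rng(config.seed)
    roster = roster if roster is not None else roster_from_config(config)
    m = config.n_features
    feature_ids = [f"F{j+1:04d}" for j in range(m)]
    log_lam = np.log(simulate_baseline(m, rng.integers(2**31)))

    delta = np.zeros(m)
    truth_map: dict[str, float] = {}
    if config.n_diff > 0:
        idx = _pick_diff_features(log_lam, config.n_diff, rng)
        l2fc = (config.log2_fold_changes if config.log2_fold_changes is not None
                else (3.0,) * config.n_diff)
        for j, fc in zip(idx, l2fc):
            delta[j] = fc * np.log(2.0)
            truth_map[feature_ids[j]] = float(fc)

    bmi_idx = np.array([], dtype=int)
    if config.n_bmi_features > 0:
        candidates = np.setdiff1d(np.arange(m), np.flatnonzero(delta))
        bmi_idx = rng.choice(candidates, size=config.n_bmi_features, replace=False)

    rows, meta_rows, index = [], [], []
    for subject, group, timepoints in roster:
        u = rng.normal(0.0, config.subject_sd, size=m)
        bmi = float(np.clip(rng.normal(30.0 if group == "case" else 26.0, 4.0), 16, 55))
        for tp in timepoints:
            eps = rng.normal(0.0, config.noise_sd, size=m)
            log_a = log_lam + u + eps
            if group == "case":
                log_a = log_a + delta
            if config.bmi_effect != 0 and len(bmi_idx):
                log_a[bmi_idx] += config.bmi_effect * (bmi - 27.0)
            comp = np.exp(log_a - log_a.max())
            comp /= comp.sum()
            depth = rng.lognormal(config.depth_logmean, config.depth_logsd)
            if group == "case":
                depth *= config.depth_group_shift
            depth = max(int(round(depth)), 100)
            counts = rng.multinomial(depth, comp)
            sid = f"{subject}_{'E' if tp == 'early' else 'L'}"
            index.append(sid)
            rows.append(counts)
            meta_rows.append({"subject_id": subject, "group": group,
                              "timepoint": tp, "bmi": bmi,
                              "library_size": depth})
    table = FeatureTable(pd.DataFrame(np.asarray(rows), index=index,
                                      columns=feature_ids),
                         unit="count", level="sgb")
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=pd.Index(index, name="sample_id")))
    truth = SimTruth(diff_features=truth_map,
                     bmi_features=tuple(feature_ids[j] for j in bmi_idx))
    return table, meta, truth


def implant_signal(table: FeatureTable, feature_ids, fold_changes,
                   target_group: str, meta: SampleMetadata
                   ) -> tuple[FeatureTable, SampleMetadata, SimTruth]:
    """Multiply chosen features' counts in target-group samples by known
    fold changes (re-rounded), leaving every other cell untouched.

    Library sizes are updated to the new row sums. Returns the spiked table,
    updated metadata, and the ground truth with log2 fold changes.
    """
    feature_ids = list(feature_ids)
    fold_changes = np.asarray(fold_changes, dtype=float)
    if (fold_changes <= 0).any():
        raise ValueError("fold changes must be positive")
    unknown = [f for f in feature_ids if f not in table.data.columns]
    if unknown:
        raise KeyError(f"unknown feature ids: {unknown}")
    aligned = meta.for_table(table)
    mask = (aligned["group"] == target_group).to_numpy()
    data = table.data.copy()
    block = data.loc[mask, feature_ids].to_numpy(dtype=float) * fold_changes
    data.loc[mask, feature_ids] = np.rint(block)
    new_meta = meta.data.copy()
    new_meta.loc[data.index, "library_size"] = data.sum(axis=1).astype(np.int64)
    truth = SimTruth(diff_features={f: float(np.log2(fc))
                                    for f, fc in zip(feature_ids, fold_changes)
                                    if fc != 1.0})
    return (FeatureTable(data, unit=table.unit, level=table.level),
            SampleMetadata(new_meta), truth)
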