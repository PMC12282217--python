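"""Six differential-abundance engine families behind one interface.

Each engine maps (feature table, metadata, design) to a per-feature result
frame with an effect estimate, raw p, FDR-adjusted q, significance at
q < alpha, and direction. The families mirror the six methodological
archetypes commonly combined in consensus DA analysis:

``ast_lm``
    Linear model on arcsine-square-root proportions (or CLR-transformed
    counts in count mode); t-test; BH.
``clr_lm_bias``
    Linear model on CLR values with a compositional bias correction: the
    median of all raw group effects is treated as the compositional shift
    and subtracted before testing; BH.
``loglinear_bias``
    Log-linear model with iteratively estimated sample-specific offsets
    (sampling-fraction bias) shared across features; Wald test;
    Holm-Bonferroni.
``dirichlet_mc``
    Monte-Carlo Dirichlet instances of the underlying proportions, CLR with
    per-sample scale noise, Wilcoxon rank-sum per instance; expected
    (instance-averaged) p and BH q.
``negbin_wald``
    Negative-binomial GLM per feature with positive-counts median-of-ratios
    size factors and trend-shrunk moment dispersions; Wald test; BH.
``reference_perm``
    Reference-taxa ratio test: low-evidence features form a reference set,
    each feature is tested as the sqrt ratio to the reference total with a
    reduced-model residual-permutation F-test and permutation-based FDR.

These are engine *families*, not re-implementations of any published tool;
every simplification is fixed and covered by oracle tests.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fdr_adjust, ols_fit_matrix, ranksum_matrix
from .io_profiles import (FeatureTable, SampleMetadata, TransformParams,
                          clr_transform, ast_transform, prevalence_filter,
                          to_approximate_counts, to_proportions)

log = logging.getLogger(__name__)

ENGINE_IDS = ("ast_lm", "clr_lm_bias", "loglinear_bias", "dirichlet_mc",
              "negbin_wald", "reference_perm")
#: engines whose input can be switched between proportions and counts
#: (the method-1 / method-2 axis); the rest always take counts
SWITCHABLE_ENGINES = ("ast_lm", "clr_lm_bias", "reference_perm")


@dataclass
class Design:
    """Group contrast (case vs control) with optional covariates/pairing.

    ``effect > 0`` always means higher in ``contrast[0]``. ``pairing``
    names the subject column for paired (time-point-style) contrasts where
    the contrast varies within subject; it enters linear engines as subject
    fixed effects.
    """

    contrast: tuple[str, str] = ("case", "control")
    group_col: str = "group"
    covariates: tuple[str, ...] = ()
    pairing: str | None = None
    alpha: float = 0.05


@dataclass
class EngineConfig:
    """Engine tuning shared across the run."""

    mc_samples: int = 1000
    scale_noise_gamma: float = 0.25
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self):
        if self.mc_samples < 2:
            raise ValueError("mc_samples must be at least 2")
        if self.scale_noise_gamma < 0:
            raise ValueError("scale_noise_gamma must be non-negative")


def _design_matrix(meta_df: pd.DataFrame, design: Design) -> tuple[np.ndarray, int, list[str]]:
    """Build (X, group column index, column names). Intercept first, group
    indicator second, then covariates, then subject dummies if paired."""
    n = len(meta_df)
    cols = [np.ones(n)]
    names = ["intercept"]
    grp = meta_df[design.group_col].astype(str)
    levels = set(grp)
    if not set(design.contrast) <= levels:
        raise ValueError(f"contrast groups {design.contrast} not all present in data")
    cols.append((grp == design.contrast[0]).to_numpy(dtype=float))
    names.append(f"{design.group_col}[{design.contrast[0]}]")
    for cov in design.covariates:
        v = meta_df[cov].astype(float)
        if v.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        cols.append(v.to_numpy())
        names.append(cov)
    if design.pairing is not None:
        subjects = meta_df[design.pairing].astype(str)
        counts = subjects.value_counts()
        if (subjects.map(counts) > 2).any():
            raise ValueError("pairing requires at most one sample per condition level")
        dummies = pd.get_dummies(subjects, drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(f"subject[{c}]")
    X = np.column_stack(cols)
    return X, 1, names


def _results_frame(feature_ids, effect, p, q, alpha, engine_id) -> pd.DataFrame:
    effect = np.asarray(effect, dtype=float)
    q = np.clip(np.asarray(q, dtype=float), 0.0, 1.0)
    df = pd.DataFrame({
        "feature_id": list(feature_ids),
        "effect": effect,
        "p": np.asarray(p, dtype=float),
        "q": q,
        "significant": q < alpha,
        "direction": np.sign(effect).astype(int),
        "engine": engine_id,
    })
    return df


def _require_counts(table: FeatureTable, engine: str) -> np.ndarray:
    if table.unit != "count":
        raise ValueError(f"{engine} requires a count table, got {table.unit!r}")
    return table.values()


# ---------------------------------------------------------------------------
# engine 1: linear model on AST proportions / CLR counts
# ---------------------------------------------------------------------------

def engine_ast_lm(table: FeatureTable, meta: SampleMetadata, design: Design,
                  cfg: EngineConfig | None = None) -> pd.DataFrame:
    """OLS per feature on arcsine-sqrt proportions (proportion input) or
    CLR-transformed counts with a half-count pseudo (count input); two-sided
    t-test on the group coefficient; BH."""
    meta_df = meta.for_table(table)
    X, gi, _ = _design_matrix(meta_df, design)
    if table.unit in ("proportion", "relative_percent"):
        prop = table.values() / (100.0 if table.unit == "relative_percent" else 1.0)
        Y = ast_transform(prop)
    elif table.unit == "count":
        Y = clr_transform(table.values(), pseudo=0.5)
    else:
        raise ValueError(f"ast_lm cannot handle unit {table.unit!r}")
    fit = ols_fit_matrix(X, Y)
    p = fit["p"][gi]
    q = fdr_adjust(p, "bh")
    return _results_frame(table.feature_ids, fit["beta"][gi], p, q,
                          design.alpha, "ast_lm")


# ---------------------------------------------------------------------------
# engine 2: CLR linear model with compositional bias term
# ---------------------------------------------------------------------------

def _impute_zeros_by_depth(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Replace zero counts with library-size-scaled half-minima of each
    feature's nonzero proportions (so imputed mass scales with depth)."""
    prop = counts / lib[:, None]
    out = counts.astype(float).copy()
    for j in range(counts.shape[1]):
        zero = counts[:, j] == 0
        if zero.any():
            nz = prop[~zero, j]
            fill = 0.5 * (nz.min() if nz.size else 1.0 / lib.max())
            out[zero, j] = fill * lib[zero]
    return out


def engine_clr_lm_bias(table: FeatureTable, meta: SampleMetadata, design: Design,
                       cfg: EngineConfig | None = None) -> pd.DataFrame:
    """CLR linear model with compositional bias correction: the median of
    all raw group effects estimates the shared compositional shift and is
    subtracted before the t-test (standard errors unchanged); BH."""
    meta_df = meta.for_table(table)
    X, gi, _ = _design_matrix(meta_df, design)
    if table.unit in ("proportion", "relative_percent"):
        prop = table.values() / (100.0 if table.unit == "relative_percent" else 1.0)
        positive = prop[prop > 0]
        pseudo = 0.5 * positive.min() if positive.size else 1e-6
        Y = clr_transform(prop, pseudo=pseudo)
    elif table.unit == "count":
        lib = meta_df["library_size"].to_numpy(dtype=float)
        imputed = _impute_zeros_by_depth(table.values(), lib)
        logx = np.log(imputed)
        Y = logx - logx.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"clr_lm_bias cannot handle unit {table.unit!r}")
    fit = ols_fit_matrix(X, Y)
    raw = fit["beta"][gi]
    bias = float(np.median(raw))
    corrected = raw - bias
    se = fit["se"][gi]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, corrected / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), fit["df"])
    p = np.where(se > 0, p, np.where(np.abs(corrected) < 1e-12, 1.0, 0.0))
    q = fdr_adjust(p, "bh")
    return _results_frame(table.feature_ids, corrected, p, q,
                          design.alpha, "clr_lm_bias")


# ---------------------------------------------------------------------------
# engine 3: log-linear model with sample-specific bias offsets
# ---------------------------------------------------------------------------

def engine_loglinear_bias(table: FeatureTable, meta: SampleMetadata,
                          design: Design, cfg: EngineConfig | None = None,
                          tol: float = 1e-8, max_iter: int = 100) -> pd.DataFrame:
    """Log-linear model with iteratively estimated per-sample offsets.

    y = log(count + 1); alternate (a) per-feature OLS of y minus the current
    offsets on the design and (b) offset <- mean residual per sample, until
    the offsets move less than ``tol``. Offsets are centred each pass (gauge
    freedom). Wald test on the group coefficient; Holm-Bonferroni.
    """
    counts = _require_counts(table, "loglinear_bias")
    if table.n_features < 2:
        raise ValueError("sample offsets are unidentifiable with a single feature")
    meta_df = meta.for_table(table)
    X, gi, _ = _design_matrix(meta_df, design)
    Y = np.log(counts + 1.0)
    offsets = np.zeros(table.n_samples)
    fit = None
    for _ in range(max_iter):
        fit = ols_fit_matrix(X, Y - offsets[:, None])
        resid = fit["resid"]
        new = offsets + resid.mean(axis=1)
        new -= new.mean()
        if np.max(np.abs(new - offsets)) < tol:
            offsets = new
            break
        offsets = new
    fit = ols_fit_matrix(X, Y - offsets[:, None])
    # The offsets are only identified up to the design projection, so the
    # group contrast of the true sample biases leaks into every feature's
    # coefficient as one shared shift; recentre by the median (the
    # taxa-specific bias identification step) before the Wald test.
    raw = fit["beta"][gi]
    bias = float(np.median(raw))
    corrected = raw - bias
    se = fit["se"][gi]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, corrected / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), fit["df"])
    p = np.where(se > 0, p, np.where(np.abs(corrected) < 1e-12, 1.0, 0.0))
    q = fdr_adjust(p, "holm")
    res = _results_frame(table.feature_ids, corrected, p, q,
                         design.alpha, "loglinear_bias")
    # the group component attributed to sample bias belongs in the offsets
    full_offsets = offsets + X[:, gi] * bias
    full_offsets -= full_offsets.mean()
    res.attrs["sample_offsets"] = pd.Series(full_offsets, index=table.sample_ids)
    return res


# ---------------------------------------------------------------------------
# engine 4: Dirichlet Monte-Carlo instances + rank-sum
# ---------------------------------------------------------------------------

def engine_dirichlet_mc(table: FeatureTable, meta: SampleMetadata,
                        design: Design, cfg: EngineConfig | None = None) -> pd.DataFrame:
    """Monte-Carlo Dirichlet instances of the underlying proportions.

    For each instance, proportions ~ Dirichlet(counts + 0.5) per sample are
    CLR transformed and perturbed by per-sample scale noise N(0, gamma^2);
    a two-sided Wilcoxon rank-sum is run per feature (per-instance OLS on
    CLR when covariates or pairing are present). Reported p/q are instance
    averages; the effect is the median standardized between-group
    difference.
    """
    cfg = cfg or EngineConfig()
    counts = _require_counts(table, "dirichlet_mc")
    meta_df = meta.for_table(table)
    rng = np.random.default_rng(cfg.seed)
    grp = meta_df[design.group_col].astype(str)
    mask_a = (grp == design.contrast[0]).to_numpy()
    mask_b = (grp == design.contrast[1]).to_numpy()
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both contrast groups must be present")
    use_lm = bool(design.covariates) or design.pairing is not None
    if use_lm:
        X, gi, _ = _design_matrix(meta_df, design)
        log.info("dirichlet_mc: covariate design, using per-instance OLS on CLR")
    n, m = counts.shape
    alpha_post = counts + 0.5
    p_sum = np.zeros(m)
    q_sum = np.zeros(m)
    effects = np.empty((cfg.mc_samples, m))
    for it in range(cfg.mc_samples):
        gam = rng.gamma(alpha_post)
        prop = gam / gam.sum(axis=1, keepdims=True)
        logx = np.log(prop)
        clr = logx - logx.mean(axis=1, keepdims=True)
        if cfg.scale_noise_gamma > 0:
            # gamma is conventionally stated in log2 units; CLR here is in nats
            sd = cfg.scale_noise_gamma * np.log(2.0)
            clr = clr + rng.normal(0.0, sd, size=n)[:, None]
        if use_lm:
            fit = ols_fit_matrix(X, clr)
            p_it = fit["p"][gi]
            diff = fit["beta"][gi]
            spread = np.sqrt(np.maximum(fit["resid"].var(axis=0), 1e-30))
        else:
            p_it = ranksum_matrix(clr, mask_a)
            diff = clr[mask_a].mean(axis=0) - clr[mask_b].mean(axis=0)
            spread = np.maximum(clr[mask_a].std(axis=0, ddof=1),
                                clr[mask_b].std(axis=0, ddof=1))
        p_sum += p_it
        q_sum += fdr_adjust(p_it, "bh")
        effects[it] = diff / np.maximum(spread, 1e-12)
    p = p_sum / cfg.mc_samples
    q = q_sum / cfg.mc_samples
    effect = np.median(effects, axis=0)
    return _results_frame(table.feature_ids, effect, p, q,
                          design.alpha, "dirichlet_mc")


# ---------------------------------------------------------------------------
# engine 5: negative-binomial Wald
# ---------------------------------------------------------------------------

def poscounts_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors using only positive counts per feature
    for the geometric-mean reference; normalised to geometric mean one."""
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("a sample has all-zero counts; size factors undefined")
    n, m = counts.shape
    with np.errstate(divide="ignore"):
        logc = np.where(counts > 0, np.log(counts), np.nan)
    log_geo = np.nanmean(logc, axis=0)          # per-feature, positive counts only
    usable = ~np.isnan(log_geo)
    ratios = np.where(counts[:, usable] > 0,
                      logc[:, usable] - log_geo[usable], np.nan)
    sf = np.exp(np.nanmedian(ratios, axis=1))
    if np.isnan(sf).any():
        raise ValueError("a sample shares no positive feature with the reference")
    return sf / np.exp(np.mean(np.log(sf)))


def _nb_dispersions(norm_counts: np.ndarray, X: np.ndarray,
                    floor: float = 1e-8, shrink_weight: float = 0.5) -> np.ndarray:
    """Per-feature method-of-moments NB dispersions on normalised counts,
    shrunk toward a log-linear mean trend with weight ``shrink_weight``.

    The per-feature log-dispersion is first debiased for the chi-square
    sampling bias of the residual variance. The half-weight shrinkage
    deliberately keeps part of each feature's own (noisy) estimate, which
    is what makes this family the least conservative of the six: features
    whose dispersion is underestimated by chance are called more readily.
    """
    from scipy.special import digamma

    fit = ols_fit_matrix(X, norm_counts)
    mu = np.maximum(norm_counts.mean(axis=0), 1e-8)
    df = max(fit["df"], 1)
    resid_var = np.einsum("nm,nm->m", fit["resid"], fit["resid"]) / df
    raw = np.maximum((resid_var - mu) / mu**2, floor)
    # E[log s^2] - log sigma^2 = digamma(df/2) - log(df/2): debias
    logd = np.log(raw) - (digamma(df / 2.0) - np.log(df / 2.0))
    logm = np.log(mu)
    informative = raw > floor * 10
    if informative.sum() >= 5:
        A = np.column_stack([np.ones(int(informative.sum())), logm[informative]])
        coef, *_ = np.linalg.lstsq(A, logd[informative], rcond=None)
        log_trend = coef[0] + coef[1] * logm
    else:
        log_trend = np.full_like(raw, np.mean(logd))
    shrunk = np.exp((1 - shrink_weight) * logd + shrink_weight * log_trend)
    return np.maximum(shrunk, floor)


def _nb_irls(counts: np.ndarray, X: np.ndarray, offsets: np.ndarray,
             disp: np.ndarray, max_iter: int = 60, tol: float = 1e-8):
    """Vectorised IRLS for per-feature NB GLMs with a shared design.

    log mu = offset + X beta; weights w = mu / (1 + disp * mu). Returns
    (beta, covariance diagonals) with shapes (p, m) and (p, m).
    """
    n, m = counts.shape
    p = X.shape[1]
    init = np.log((counts + 0.5) / np.exp(offsets)[:, None])
    beta = np.linalg.lstsq(X, init, rcond=None)[0]
    for _ in range(max_iter):
        eta = offsets[:, None] + X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + disp[None, :] * mu)
        z = (eta - offsets[:, None]) + (counts - mu) / mu
        a = np.einsum("np,nm,nq->mpq", X, w, X)
        b = np.einsum("np,nm,nm->mp", X, w, z)
        a += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(a, b[..., None])[..., 0].T   # (p, m)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = offsets[:, None] + X @ beta
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + disp[None, :] * mu)
    a = np.einsum("np,nm,nq->mpq", X, w, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(a)
    var = np.einsum("mpp->mp", cov).T              # (p, m)
    return beta, np.maximum(var, 0.0)


def engine_negbin_wald(table: FeatureTable, meta: SampleMetadata, design: Design,
                       cfg: EngineConfig | None = None) -> pd.DataFrame:
    """Negative-binomial GLM per feature with poscounts size-factor offsets
    and trend-shrunk moment dispersions; Wald z on the group coefficient; BH."""
    counts = np.rint(_require_counts(table, "negbin_wald"))
    meta_df = meta.for_table(table)
    X, gi, _ = _design_matrix(meta_df, design)
    sf = poscounts_size_factors(counts)
    disp = _nb_dispersions(counts / sf[:, None], X)
    beta, var = _nb_irls(counts, X, np.log(sf), disp)
    se = np.sqrt(var[gi])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta[gi] / np.where(se > 0, se, 1.0), 0.0)
    # Wald statistic referred to t(n - p): at the cohort sizes this engine
    # sees (tens of samples) the normal reference is visibly anticonservative
    p = 2.0 * stats.t.sf(np.abs(z), max(counts.shape[0] - X.shape[1], 1))
    q = fdr_adjust(p, "bh")
    res = _results_frame(table.feature_ids, beta[gi], p, q,
                         design.alpha, "negbin_wald")
    res.attrs["size_factors"] = pd.Series(sf, index=table.sample_ids)
    res.attrs["dispersions"] = pd.Series(disp, index=table.feature_ids)
    return res


# ---------------------------------------------------------------------------
# engine 6: reference-taxa ratio with permutation FDR
# ---------------------------------------------------------------------------

def _f_statistics(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray) -> np.ndarray:
    """Per-column F statistics comparing the full model to the reduced one."""
    n = Y.shape[0]
    q = X_full.shape[1] - X_red.shape[1]
    df2 = n - X_full.shape[1]
    h_full = X_full @ np.linalg.pinv(X_full)
    h_red = X_red @ np.linalg.pinv(X_red)
    rss_full = np.einsum("nm,nm->m", Y - h_full @ Y, Y - h_full @ Y)
    rss_red = np.einsum("nm,nm->m", Y - h_red @ Y, Y - h_red @ Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / q) / np.maximum(rss_full / df2, 1e-30)
    return np.maximum(f, 0.0)


def engine_reference_perm(table: FeatureTable, meta: SampleMetadata,
                          design: Design, cfg: EngineConfig | None = None,
                          exhaustive: bool = False) -> pd.DataFrame:
    """Reference-taxa ratio test with residual permutation and permutation
    FDR.

    Stage 1 screens each sqrt-proportion feature with a reduced-model
    residual-permutation F test; the half of features with the weakest
    evidence (largest p) becomes the reference set. Stage 2 tests each
    feature as sqrt(proportion / reference total) with the same permutation
    scheme. q-values are the permutation FDR: expected null exceedances over
    observed exceedances at each feature's F, monotonized.
    """
    cfg = cfg or EngineConfig()
    if table.unit == "count":
        counts = table.values()
        prop = (counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True)
    elif table.unit in ("proportion", "relative_percent"):
        prop = table.values() / (100.0 if table.unit == "relative_percent" else 1.0)
    else:
        raise ValueError(f"reference_perm cannot handle unit {table.unit!r}")
    meta_df = meta.for_table(table)
    X_full, gi, _ = _design_matrix(meta_df, design)
    X_red = np.delete(X_full, gi, axis=1)
    n, m = prop.shape
    rng = np.random.default_rng(cfg.seed)
    if exhaustive:
        import itertools
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(cfg.n_perm)]

    def perm_f(Y):
        h_red = X_red @ np.linalg.pinv(X_red)
        fitted = h_red @ Y
        resid = Y - fitted
        obs = _f_statistics(Y, X_full, X_red)
        null = np.empty((len(perms), Y.shape[1]))
        for b, perm in enumerate(perms):
            null[b] = _f_statistics(fitted + resid[perm], X_full, X_red)
        return obs, null

    # stage 1: screen on sqrt proportions
    f1, null1 = perm_f(np.sqrt(prop))
    p1 = (1 + (null1 >= f1[None, :] - 1e-12).sum(axis=0)) / (1 + len(perms))
    order = np.argsort(p1)
    n_ref = m - m // 2                      # weaker-evidence half (larger p)
    ref_idx = order[m - n_ref:]
    if len(ref_idx) == 0:
        raise ValueError("reference set is empty")
    ref_total = prop[:, ref_idx].sum(axis=1)
    if (ref_total <= 0).any():
        raise ValueError("reference total is zero for some sample")

    # stage 2: ratios to the reference total
    Y2 = np.sqrt(prop / ref_total[:, None])
    f2, null2 = perm_f(Y2)
    p2 = (1 + (null2 >= f2[None, :] - 1e-12).sum(axis=0)) / (1 + len(perms))
    # permutation FDR, monotonized along decreasing F
    exceed_null = (null2[:, :, None] >= f2[None, None, :] - 1e-12).sum(axis=1).mean(axis=0)
    exceed_obs = (f2[:, None] >= f2[None, :] - 1e-12).sum(axis=0)
    q = np.clip(exceed_null / np.maximum(exceed_obs, 1), 0.0, 1.0)
    order_desc = np.argsort(-f2)
    q_sorted = np.maximum.accumulate(q[order_desc])
    q_mono = np.empty_like(q)
    q_mono[order_desc] = q_sorted
    # effect: group coefficient of the stage-2 full model
    beta = np.linalg.pinv(X_full) @ Y2
    res = _results_frame(table.feature_ids, beta[gi], p2, q_mono,
                         design.alpha, "reference_perm")
    res.attrs["f_observed"] = f2
    res.attrs["f_null"] = null2
    res.attrs["reference_features"] = [table.feature_ids[i] for i in ref_idx]
    return res


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_ENGINE_FUNCS = {
    "ast_lm": engine_ast_lm,
    "clr_lm_bias": engine_clr_lm_bias,
    "loglinear_bias": engine_loglinear_bias,
    "dirichlet_mc": engine_dirichlet_mc,
    "negbin_wald": engine_negbin_wald,
    "reference_perm": engine_reference_perm,
}


def run_all_engines(tables: dict[str, FeatureTable], meta: SampleMetadata,
                    design: Design, input_mode: str = "proportions",
                    cfg: EngineConfig | None = None,
                    params: TransformParams | None = None,
                    engines: tuple[str, ...] = ENGINE_IDS) -> dict:
    """Run every engine on every level with one shared prevalence filter.

    ``input_mode='proportions'`` (method 1) feeds relative abundances to the
    switchable engines and approximate counts to the rest;
    ``input_mode='counts'`` (method 2) feeds approximate counts to all six.
    A failing engine is recorded in the audit and does not abort the run.

    Returns {"results": {(level, engine): DataFrame}, "audit": [...]}.
    """
    if input_mode not in ("proportions", "counts"):
        raise ValueError("input_mode must be 'proportions' or 'counts'")
    cfg = cfg or EngineConfig()
    params = params or TransformParams()
    results: dict[tuple[str, str], pd.DataFrame] = {}
    audit: list[dict] = []
    for li, (level, table) in enumerate(sorted(tables.items())):
        filtered = prevalence_filter(table, params)
        if filtered.unit == "count":
            count_tab = filtered
            prop_tab = to_proportions(filtered) if filtered.n_features else filtered
        else:
            prop_tab = to_proportions(filtered) if filtered.n_features else filtered
            count_tab = to_approximate_counts(prop_tab, meta, round_to_int=True)
        for ei, engine in enumerate(engines):
            wants_prop = engine in SWITCHABLE_ENGINES and input_mode == "proportions"
            tab = prop_tab if wants_prop else count_tab
            sub_seed = int(np.random.SeedSequence([cfg.seed, li, ei]).generate_state(1)[0]
                           % 2**31)
            sub_cfg = EngineConfig(mc_samples=cfg.mc_samples,
                                   scale_noise_gamma=cfg.scale_noise_gamma,
                                   n_perm=cfg.n_perm, seed=sub_seed)
            entry = {"level": level, "engine": engine, "unit": tab.unit,
                     "n_features": tab.n_features, "status": "ok"}
            try:
                results[(level, engine)] = _ENGINE_FUNCS[engine](tab, meta, design, sub_cfg)
            except Exception as exc:  # noqa: BLE001 — isolate engine failures
                entry["status"] = f"error: {exc}"
                log.warning("engine %s failed on level %s: %s", engine, level, exc)
            audit.append(entry)
    return {"results": results, "audit": audit}
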