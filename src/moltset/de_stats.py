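"""Per-feature two-state ANOVA with a shrinkage F statistic and
residual-permutation p-values.

The model per feature is the one-way fixed-effect decomposition
``Y = mu + STATE + eps``. Each developmental-state contrast (e.g. L4
lethargus vs late L4) is fit separately. Significance uses Fs, a modified F
whose denominator variance is shrunk across features by a positive-part
James-Stein estimator on log variances (Cui-style shrinkage): with
``X_g = ln(RSS_g / nu)``,

    sigma2_g = exp( Xbar + c * (X_g - Xbar) ) * B,
    c        = max(0, 1 - (G - 3) * V_nu / sum((X_g - Xbar)^2)),

where ``V_nu = trigamma(nu/2)`` is the sampling variance of the log of a
scaled chi-square with nu degrees of freedom and ``B = exp(-(digamma(nu/2)
+ ln 2 - ln nu))`` removes the mean bias of the log-scale estimate.

P-values come from permuting the residuals of the null (grand-mean) model
across the contrast's samples — equivalently, permuting the observed sample
values — with one shared permutation index vector per round applied to every
feature, and the shrinkage re-estimated inside each round. By default the
permuted Fs values from all features are pooled into one null distribution
(feasible because the shrunk denominator puts features on a common scale,
and necessary with few replicates, where per-feature permutation p-values
are coarsely discrete); per-feature counting is available via ``pool=False``.
The reported p is the smoothed exceedance fraction; in exhaustive mode every
permutation is enumerated and p is the exact proportion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .matrix import ExpressionMatrix

__all__ = [
    "StageDesign",
    "StageModelFit",
    "fit_stage_model",
    "shrink_variances",
    "fs_statistics",
    "permutation_pvalues",
    "fold_changes",
    "run_de",
]

logger = logging.getLogger(__name__)

#: floor applied to per-feature variances before taking logs, so that
#: zero-residual features survive the shrinkage step
VARIANCE_FLOOR = 1e-8

#: refuse exhaustive enumeration beyond this many permutations
_EXHAUSTIVE_CAP = 50_000


@dataclass(frozen=True)
class StageDesign:
    """One two-group developmental-state contrast.

    ``group_a`` is the state of interest (lethargus, by convention: fold
    changes are reported as A minus B on log2 scale); ``group_b`` the
    reference state. Groups must be disjoint and each hold >= 2 samples.
    """

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError(
                f"contrast {self.name!r}: each group needs >= 2 samples "
                "(within-group variance is undefined otherwise)"
            )
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name!r}: groups overlap")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group_a + self.group_b


@dataclass(frozen=True)
class StageModelFit:
    """Per-feature one-way fit of ``Y = mu + STATE + eps`` for one contrast."""

    design: StageDesign
    feature_ids: pd.Index
    mean_a: np.ndarray
    mean_b: np.ndarray
    grand_mean: np.ndarray
    between_ss: np.ndarray
    rss: np.ndarray
    residuals: np.ndarray  # features x (n_a + n_b), sample order a then b

    @property
    def nu(self) -> int:
        """Residual degrees of freedom: n_samples - n_groups."""
        return len(self.design.samples) - 2

    @property
    def q(self) -> int:
        """Between-groups degrees of freedom: n_groups - 1."""
        return 1


def _group_values(matrix: ExpressionMatrix, design: StageDesign) -> tuple[np.ndarray, int]:
    missing = [s for s in design.samples if s not in matrix.values.columns]
    if missing:
        raise ValueError(f"contrast {design.name!r}: samples not in matrix: {missing}")
    vals = matrix.values[list(design.samples)].to_numpy(dtype=float)
    return vals, len(design.group_a)


def _anova_parts(vals: np.ndarray, n_a: int) -> tuple[np.ndarray, ...]:
    """Vectorized one-way decomposition for a features x samples block.

    All sums are taken group-wise (and the grand mean is formed from the
    group means), so the result is invariant to the order of samples within
    a group — permutations that only relabel within groups reproduce the
    observed statistics bitwise.
    """
    n = vals.shape[1]
    n_b = n - n_a
    a, b = vals[:, :n_a], vals[:, n_a:]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    grand = (n_a * mean_a + n_b * mean_b) / n
    between = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    resid_a = a - mean_a[:, None]
    resid_b = b - mean_b[:, None]
    rss = (resid_a**2).sum(axis=1) + (resid_b**2).sum(axis=1)
    resid = np.concatenate([resid_a, resid_b], axis=1)
    return mean_a, mean_b, grand, between, rss, resid


def fit_stage_model(matrix: ExpressionMatrix, design: StageDesign) -> StageModelFit:
    """Fit the one-way state model per feature for one contrast.

    Group means are sample means per state; RSS is the within-group sum of
    squared deviations on ``nu = n - 2`` degrees of freedom; the between-group
    sum of squares is ``sum_g n_g (mean_g - grand)^2``.
    """
    if matrix.scale != "log2":
        raise ValueError("fit_stage_model expects a log2-scale matrix")
    vals, n_a = _group_values(matrix, design)
    mean_a, mean_b, grand, between, rss, resid = _anova_parts(vals, n_a)
    return StageModelFit(
        design=design,
        feature_ids=matrix.values.index,
        mean_a=mean_a,
        mean_b=mean_b,
        grand_mean=grand,
        between_ss=between,
        rss=rss,
        residuals=resid,
    )


def _log_chisq_moments(nu: int) -> tuple[float, float]:
    """Mean bias and variance of ``ln(RSS/nu)`` when ``RSS ~ sigma^2 chi^2_nu``.

    ``ln(chi^2_nu / nu)`` has mean ``digamma(nu/2) + ln 2 - ln nu`` and
    variance ``trigamma(nu/2)``.
    """
    m = float(digamma(nu / 2.0) + math.log(2.0) - math.log(nu))
    v = float(polygamma(1, nu / 2.0))
    return m, v


def shrink_variances(
    rss: np.ndarray, nu: int, *, floor: float = VARIANCE_FLOOR
) -> np.ndarray:
    """Positive-part James-Stein shrinkage of per-feature variances.

    Operates on ``X_g = ln(max(RSS_g/nu, floor))``: each X is pulled toward
    the across-feature mean by the factor ``c`` (0 = complete pooling,
    1 = no shrinkage), then mapped back with the log-scale bias correction
    ``B``. With fewer than 4 features the James-Stein factor is undefined
    (G - 3 <= 0) and the raw bias-corrected estimates are returned with a
    warning.
    """
    rss = np.asarray(rss, dtype=float)
    if nu < 1:
        raise ValueError("shrink_variances requires nu >= 1")
    m, v_nu = _log_chisq_moments(nu)
    bias_correction = math.exp(-m)
    x = np.log(np.maximum(rss / nu, floor))
    n_features = x.size
    if n_features <= 3:
        logger.warning(
            "shrinkage needs > 3 features (got %d); returning unshrunk variances",
            n_features,
        )
        return np.exp(x) * bias_correction
    x_bar = x.mean()
    ss = ((x - x_bar) ** 2).sum()
    if ss == 0.0:
        # all variances identical: full pooling is exact
        return np.exp(x) * bias_correction
    c = max(0.0, 1.0 - (n_features - 3) * v_nu / ss)
    return np.exp(x_bar + c * (x - x_bar)) * bias_correction


def fs_statistics(fit: StageModelFit, sigma2: np.ndarray) -> np.ndarray:
    """Fs per feature: between-group mean square over the shrunk variance."""
    sigma2 = np.asarray(sigma2, dtype=float)
    assert (sigma2 > 0).all(), "shrunk variances must be positive"
    return (fit.between_ss / fit.q) / sigma2


def _fs_for_block(vals: np.ndarray, n_a: int, *, shrink: bool, sigma2_frozen=None) -> np.ndarray:
    _, _, _, between, rss, _ = _anova_parts(vals, n_a)
    nu = vals.shape[1] - 2
    if sigma2_frozen is not None:
        sigma2 = sigma2_frozen
    elif shrink:
        sigma2 = shrink_variances(rss, nu)
    else:
        sigma2 = np.maximum(rss / nu, VARIANCE_FLOOR)
    return between / sigma2


def _pooled_exceedances(fs_obs: np.ndarray, fs_perm: np.ndarray) -> np.ndarray:
    """#{permuted Fs values >= each observed Fs}, counted across all features."""
    pool = np.sort(fs_perm, axis=None)
    return pool.size - np.searchsorted(pool, fs_obs, side="left")


def permutation_pvalues(
    matrix: ExpressionMatrix,
    design: StageDesign,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    shrink: bool = True,
    pool: bool = True,
    exhaustive: bool = False,
    scope: str = "shared",
    recompute_shrinkage: bool = True,
) -> np.ndarray:
    """Residual-permutation p-values for Fs under one contrast.

    Residuals of the null (grand-mean) model are permuted across the
    contrast's samples and Fs recomputed each round; since the per-feature
    grand mean is permutation-invariant this amounts to permuting the sample
    values themselves. By default one permutation index vector is shared by
    all features within a round, preserving between-feature correlation;
    ``scope="per_feature"`` draws an independent permutation per feature.

    With ``pool=True`` (default) the null distribution is the pool of
    permuted Fs values across ALL features, so p for feature g is the
    smoothed fraction of pooled values at or above its observed Fs. Pooling
    is what makes small-replicate designs usable: a two-group 3v3 layout has
    only 20 label partitions, so a per-feature permutation p can never fall
    below 0.1, whereas the pooled null has ``n_perm * G`` draws. Shrinking
    the denominator variance across features is what puts the per-feature
    Fs values on a common scale and justifies pooling. ``pool=False``
    counts exceedances within each feature's own rounds.

    Parameters
    ----------
    n_perm
        Number of sampled rounds; p = (1 + exceedances) / (1 + #null draws).
        Ignored when ``exhaustive`` is set.
    exhaustive
        Enumerate every permutation of the contrast's samples (identity
        included) and return the exact proportion of null draws with
        Fs* >= Fs observed (no smoothing term).
    recompute_shrinkage
        Re-estimate the shrunk variances inside each round (default); when
        off, the observed-data variances are frozen across rounds.
    """
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("shared", "per_feature"):
        raise ValueError(f"unknown permutation scope {scope!r}")
    vals, n_a = _group_values(matrix, design)
    n = vals.shape[1]
    n_features = vals.shape[0]

    sigma2_frozen = None
    if not recompute_shrinkage:
        _, _, _, _, rss, _ = _anova_parts(vals, n_a)
        nu = n - 2
        sigma2_frozen = (
            shrink_variances(rss, nu) if shrink else np.maximum(rss / nu, VARIANCE_FLOOR)
        )

    fs_obs = _fs_for_block(vals, n_a, shrink=shrink, sigma2_frozen=sigma2_frozen)
    count = np.zeros(n_features, dtype=np.int64)

    if exhaustive:
        total = math.comb(n, n_a)
        if total > _EXHAUSTIVE_CAP:
            raise ValueError(
                f"exhaustive enumeration over {total} group assignments exceeds "
                f"the cap ({_EXHAUSTIVE_CAP}); use sampled permutations"
            )
        # enumerate distinct group-A assignments: within-group order does not
        # affect F, so this is the full permutation null without redundancy
        all_cols = set(range(n))
        for combo in _combinations(range(n), n_a):
            perm = list(combo) + sorted(all_cols - set(combo))
            fs_perm = _fs_for_block(vals[:, perm], n_a, shrink=shrink, sigma2_frozen=sigma2_frozen)
            if pool:
                count += _pooled_exceedances(fs_obs, fs_perm)
            else:
                count += fs_perm >= fs_obs
        n_null = total * (n_features if pool else 1)
        return count / n_null

    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        if scope == "shared":
            # canonicalize within-group order: F depends only on the group
            # assignment, and sorting makes partition ties bitwise exact
            perm = rng.permutation(n)
            perm = np.concatenate([np.sort(perm[:n_a]), np.sort(perm[n_a:])])
            permuted = vals[:, perm]
        else:
            idx = np.argsort(rng.random(vals.shape), axis=1)
            permuted = np.take_along_axis(vals, idx, axis=1)
        fs_perm = _fs_for_block(permuted, n_a, shrink=shrink, sigma2_frozen=sigma2_frozen)
        if pool:
            count += _pooled_exceedances(fs_obs, fs_perm)
        else:
            count += fs_perm >= fs_obs
    n_null = n_perm * (n_features if pool else 1)
    return (1 + count) / (1 + n_null)


def fold_changes(fit: StageModelFit) -> pd.DataFrame:
    """Log2 fold change (state-of-interest minus reference) and direction.

    Returns a DataFrame with ``log2fc``, ``fold`` (= 2^|log2fc|, the linear
    fold change) and ``direction`` ('up' if higher in group A else 'down').
    """
    log2fc = fit.mean_a - fit.mean_b
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold": np.exp2(np.abs(log2fc)),
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=fit.feature_ids,
    )


def run_de(
    matrix: ExpressionMatrix,
    design: StageDesign,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    shrink: bool = True,
    pool: bool = True,
    exhaustive: bool = False,
    scope: str = "shared",
    recompute_shrinkage: bool = True,
) -> pd.DataFrame:
    """Full differential-expression summary for one contrast.

    Columns: ``Fs``, ``p_raw`` (permutation), ``log2fc``, ``fold``,
    ``direction``, ``sigma2_shrunk``, ``mean_a``, ``mean_b``. Doubling and
    BH adjustment are applied downstream when sets are built.
    """
    fit = fit_stage_model(matrix, design)
    if shrink:
        sigma2 = shrink_variances(fit.rss, fit.nu)
    else:
        sigma2 = np.maximum(fit.rss / fit.nu, VARIANCE_FLOOR)
    fs = fs_statistics(fit, sigma2)
    p_raw = permutation_pvalues(
        matrix,
        design,
        n_perm,
        seed,
        shrink=shrink,
        pool=pool,
        exhaustive=exhaustive,
        scope=scope,
        recompute_shrinkage=recompute_shrinkage,
    )
    fc = fold_changes(fit)
    out = pd.DataFrame(
        {
            "Fs": fs,
            "p_raw": p_raw,
            "log2fc": fc["log2fc"],
            "fold": fc["fold"],
            "direction": fc["direction"],
            "sigma2_shrunk": sigma2,
            "mean_a": fit.mean_a,
            "mean_b": fit.mean_b,
        },
        index=fit.feature_ids,
    )
    out.index.name = "feature"
    return out
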