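"""Permutation-based ANCOVA with nuisance covariates, and FDR correction.

Group effects on network measures are tested with a partial F statistic:
the full linear model contains an intercept, the covariates (age, sex)
and group indicator columns; the reduced model drops the group columns.

    F = ((RSS_reduced - RSS_full) / (g - 1)) / (RSS_full / (n - g - q))

Significance comes from Freedman-Lane residual permutation: the reduced
(covariates-only) model is fitted once, its residuals are permuted and
added back to the reduced fit, and the partial F is recomputed on each
reconstructed outcome. This respects the nuisance covariates under
permutation; with no covariates it reduces to plain label permutation.
p-values use the add-one convention p = (1 + #{F* >= F_obs}) / (1 + P),
so the smallest attainable p is 1/(P+1).

Multiple-comparison correction is Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, CohortDataset
from .metrics import GLOBAL_MEASURES, NODAL_MEASURES, global_metrics_table, \
    nodal_metrics_arrays

__all__ = [
    "AncovaResult",
    "partial_f",
    "permutation_ancova",
    "freedman_lane_f",
    "fdr_adjust",
    "compare_global",
    "compare_nodal",
    "group_pairs",
]

_RANK_TOL = 1e-10
# numerator sums of squares below this fraction of total SS are treated
# as exactly zero signal (guards 0/0 when the model fits perfectly)
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class AncovaResult:
    statistic: float
    p_perm: float
    group_adjusted_means: dict[str, float]
    df: tuple[int, int]
    n_used: int
    n_permutations: int


def _design_matrices(groups: np.ndarray, covariates: np.ndarray | None):
    """Full (intercept + covariates + group dummies) and reduced
    (intercept + covariates) design matrices, plus group level order."""
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = [(groups == lv).sum() for lv in levels]
    if min(counts) < 2:
        raise ValueError("every group needs at least 2 subjects")
    n = groups.shape[0]
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if covariates.shape[0] != n:
        raise ValueError("covariates and groups length mismatch")
    z = np.column_stack([np.ones(n), covariates])
    dummies = np.column_stack([(groups == lv).astype(float) for lv in levels[1:]])
    x = np.column_stack([z, dummies])
    return x, z, levels


def _orth(m: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space; errors on rank deficiency."""
    q, r = np.linalg.qr(m)
    diag = np.abs(np.diag(r))
    if np.any(diag < _RANK_TOL * max(diag.max(), 1.0)):
        raise ValueError("singular design matrix (collinear columns)")
    return q

def _f_from_projections(tot, proj_x_ss, proj_z_ss, df1, df2):
    rss_full = np.maximum(tot - proj_x_ss, 0.0)
    rss_red = np.maximum(tot - proj_z_ss, 0.0)
    num = np.maximum(rss_red - rss_full, 0.0)
    scale = np.maximum(tot, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (num / df1) / (rss_full / df2)
    f = np.where(num <= _ZERO_TOL * scale, 0.0, f)
    return np.where(np.isnan(f), 0.0, f)


def _batch_f(y: np.ndarray, qx: np.ndarray, qz: np.ndarray, df1: int, df2: int):
    """Partial F per column of y (shape (n, m))."""
    tot = (y ** 2).sum(axis=0)
    px = ((qx.T @ y) ** 2).sum(axis=0)
    pz = ((qz.T @ y) ** 2).sum(axis=0)
    return _f_from_projections(tot, px, pz, df1, df2)


def _dfs(n: int, g: int, q: int) -> tuple[int, int]:
    df1, df2 = g - 1, n - g - q
    if df2 <= 0:
        raise ValueError(f"not enough subjects (n={n}) for g={g} groups, {q} covariates")
    return df1, df2


def partial_f(y: np.ndarray, groups: np.ndarray,
              covariates: np.ndarray | None = None):
    """Partial F for the group factor, adjusted for covariates.

    Returns (F, (df_num, df_den)).
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains missing or non-finite values")
    x, z, levels = _design_matrices(groups, covariates)
    df1, df2 = _dfs(y.shape[0], len(levels), z.shape[1] - 1)
    f = _batch_f(y[:, None], _orth(x), _orth(z), df1, df2)
    return float(f[0]), (df1, df2)


def _perm_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def freedman_lane_f(y: np.ndarray, groups: np.ndarray,
                    covariates: np.ndarray | None, n_perm: int,
                    rng: np.random.Generator):
    """Observed and permutation partial-F values under the Freedman-Lane
    scheme.

    ``y`` may be a vector (one outcome) or an (n, m) matrix of m outcomes
    sharing one design; a single permutation stream drives all columns.
    Returns (F_obs (m,), F_perm (n_perm, m), (df1, df2)).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if np.any(~np.isfinite(y)):
        raise ValueError("y contains missing or non-finite values")
    x, z, levels = _design_matrices(groups, covariates)
    n, m = y.shape
    df1, df2 = _dfs(n, len(levels), z.shape[1] - 1)
    qx, qz = _orth(x), _orth(z)

    f_obs = _batch_f(y, qx, qz, df1, df2)
    fitted = qz @ (qz.T @ y)
    resid = y - fitted
    idx = _perm_indices(rng, n_perm, n)

    if m == 1:
        # vectorized: all permuted outcomes at once, shape (n_perm, n)
        ystar = fitted[:, 0][None, :] + resid[:, 0][idx]
        tot = (ystar ** 2).sum(axis=1)
        px = ((ystar @ qx) ** 2).sum(axis=1)
        pz = ((ystar @ qz) ** 2).sum(axis=1)
        f_perm = _f_from_projections(tot, px, pz, df1, df2)[:, None]
    else:
        f_perm = np.empty((n_perm, m))
        for p in range(n_perm):
            ystar = fitted + resid[idx[p]]
            f_perm[p] = _batch_f(ystar, qx, qz, df1, df2)
    return f_obs, f_perm, (df1, df2)


def _adjusted_means(y, groups, covariates, levels):
    """Covariate-adjusted group means: model predictions per group at the
    grand covariate means."""
    x, _, _ = _design_matrices(groups, covariates)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    q = x.shape[1] - (len(levels) - 1)  # 1 + n_cov
    cov_part = beta[0] + (
        0.0 if q == 1 else
        float(np.asarray(covariates, dtype=float).reshape(len(y), -1).mean(axis=0) @ beta[1:q])
    )
    means = {levels[0]: cov_part}
    for j, lv in enumerate(levels[1:]):
        means[lv] = cov_part + float(beta[q + j])
    return means


def permutation_ancova(y: np.ndarray, groups: np.ndarray,
                       covariates: np.ndarray | None, n_perm: int,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None) -> AncovaResult:
    """Permutation-based ANCOVA for a single outcome."""
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    f_obs, f_perm, df = freedman_lane_f(y, groups, covariates, n_perm, rng)
    p = float((1 + (f_perm[:, 0] >= f_obs[0]).sum()) / (1 + n_perm))
    _, _, levels = _design_matrices(groups, covariates)
    means = _adjusted_means(y, groups, covariates, levels)
    return AncovaResult(float(f_obs[0]), p, means, df, len(y), n_perm)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_pairs(cohort: CohortDataset) -> list[tuple[str, str]]:
    """Post-hoc pairs: each disease group vs control, then disease pairs."""
    ctrl = cohort.control_group
    disease = [g for g in cohort.groups if g != ctrl]
    return [(d, ctrl) for d in disease] + list(combinations(disease, 2))


def _direction_label(a: str, b: str, means: dict[str, float]) -> str:
    if means[a] < means[b]:
        return f"{a} < {b}"
    if means[a] > means[b]:
        return f"{a} > {b}"
    return f"{a} = {b}"


def _pairwise_posthoc(y, groups, covariates, pairs, n_perm, rng):
    """Three (or k) pairwise permutation ANCOVAs, refit per pair; returns
    raw p, FDR-adjusted p (across the pairs) and direction labels."""
    raw, dirs = [], []
    for a, b in pairs:
        keep = (groups == a) | (groups == b)
        res = permutation_ancova(y[keep], groups[keep],
                                 covariates[keep] if covariates is not None else None,
                                 n_perm, rng=rng)
        raw.append(res.p_perm)
        dirs.append(_direction_label(a, b, res.group_adjusted_means))
    return np.array(raw), fdr_adjust(raw), dirs


def compare_global(cohort: CohortDataset, config: AnalysisConfig,
                   metrics_df: pd.DataFrame | None = None,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Global three-group comparison table.

    One row per global measure: per-group mean +/- SD, omnibus
    permutation-ANCOVA p, and for each post-hoc pair the raw and
    FDR-adjusted p (corrected across the pairs) with direction labels.
    """
    if metrics_df is None:
        metrics_df = global_metrics_table(cohort)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = cohort.group_labels()
    cov = cohort.covariates()
    pairs = group_pairs(cohort)

    rows = []
    for measure in GLOBAL_MEASURES:
        y = metrics_df[measure].to_numpy(dtype=float)
        omni = permutation_ancova(y, groups, cov, config.n_permutations, rng=rng)
        raw, adj, dirs = _pairwise_posthoc(y, groups, cov, pairs,
                                           config.n_permutations, rng)
        row = {"measure": measure}
        for g in cohort.groups:
            sel = groups == g
            row[f"mean_{g}"] = float(y[sel].mean())
            row[f"sd_{g}"] = float(y[sel].std(ddof=1))
        row["p_omnibus"] = omni.p_perm
        for (a, b), pr, pa, d in zip(pairs, raw, adj, dirs):
            row[f"p_{a}_vs_{b}"] = pr
            row[f"p_fdr_{a}_vs_{b}"] = pa
            row[f"direction_{a}_vs_{b}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


def compare_nodal(cohort: CohortDataset, config: AnalysisConfig,
                  measure_names=NODAL_MEASURES,
                  nodal_arrays: dict[str, np.ndarray] | None = None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Nodal comparison table.

    Per nodal measure, an omnibus permutation-ANCOVA p at every node,
    FDR-corrected across the nodes; nodes surviving FDR at
    ``config.alpha`` receive the pairwise post-hoc tests (FDR across the
    pairs). Long format: one row per (measure, node).
    """
    if nodal_arrays is None:
        nodal_arrays = nodal_metrics_arrays(cohort, measure_names)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    groups = cohort.group_labels()
    cov = cohort.covariates()
    pairs = group_pairs(cohort)
    labels = list(cohort.labels)

    rows = []
    for measure in measure_names:
        y_all = nodal_arrays[measure]  # (n_subj, n_nodes)
        f_obs, f_perm, _ = freedman_lane_f(y_all, groups, cov,
                                           config.n_permutations, rng)
        p_omni = (1 + (f_perm >= f_obs[None, :]).sum(axis=0)) / (1 + config.n_permutations)
        p_fdr = fdr_adjust(p_omni)
        for j, node in enumerate(labels):
            row = {
                "measure": measure,
                "node": node,
                "F": float(f_obs[j]),
                "p_omnibus": float(p_omni[j]),
                "p_omnibus_fdr": float(p_fdr[j]),
                "significant": bool(p_fdr[j] < config.alpha),
            }
            if row["significant"]:
                raw, adj, dirs = _pairwise_posthoc(
                    y_all[:, j], groups, cov, pairs, config.n_permutations, rng)
                for (a, b), pr, pa, d in zip(pairs, raw, adj, dirs):
                    row[f"p_{a}_vs_{b}"] = pr
                    row[f"p_fdr_{a}_vs_{b}"] = pa
                    row[f"direction_{a}_vs_{b}"] = d
            else:
                for a, b in pairs:
                    row[f"p_{a}_vs_{b}"] = np.nan
                    row[f"p_fdr_{a}_vs_{b}"] = np.nan
                    row[f"direction_{a}_vs_{b}"] = ""
            rows.append(row)
    return pd.DataFrame(rows)
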