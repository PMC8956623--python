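"""Associations between network measures and clinical variables.

Within one disease group at a time, the clinical score is regressed on a
network measure with age and sex controlled:

    clinical = b0 + b1 * measure + b2 * age + b3 * sex + error

fitted by ordinary least squares. The reported significance is that of
b1 (the measure term): by default the analytic partial-F p-value (for a
single coefficient this equals the two-sided t-test), with a
Freedman-Lane permutation alternative available. Subjects with missing
clinical values are dropped pairwise; groups in which a clinical
variable is entirely missing (e.g. EDSS in healthy controls) are skipped
with a notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import CohortDataset
from .metrics import GLOBAL_MEASURES, global_metrics_table
from .permstats import freedman_lane_f

__all__ = ["GlmFit", "fit_association", "association_table"]

logger = logging.getLogger(__name__)

MIN_SUBJECTS = 5


@dataclass(frozen=True)
class GlmFit:
    clinical_name: str
    measure_name: str
    group: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    p_beta1: float
    beta1_ci: tuple[float, float]  # 95% confidence interval
    n_used: int


def fit_association(cohort: CohortDataset, measure: np.ndarray,
                    clinical_name: str, group: str,
                    measure_name: str = "measure",
                    permutation: bool = False, n_perm: int = 10_000,
                    rng: np.random.Generator | None = None) -> GlmFit:
    """OLS fit of clinical ~ measure + age + sex within one group.

    ``measure`` is aligned with ``cohort.subjects``; rows outside
    ``group`` or with missing clinical values are dropped.
    """
    measure = np.asarray(measure, dtype=float)
    if measure.shape[0] != len(cohort.subjects):
        raise ValueError("measure not aligned with cohort subjects")
    groups = cohort.group_labels()
    clin = np.array([s.clinical.get(clinical_name, np.nan)
                     for s in cohort.subjects], dtype=float)
    keep = (groups == group) & np.isfinite(clin) & np.isfinite(measure)
    n_used = int(keep.sum())
    if n_used < MIN_SUBJECTS:
        raise ValueError(
            f"group '{group}': only {n_used} subjects with complete "
            f"'{clinical_name}' data (minimum {MIN_SUBJECTS})")
    cov = cohort.covariates()[keep]
    x = np.column_stack([measure[keep], cov])  # measure, age, sex
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"collinear/degenerate design for ({group}, {measure_name}, "
            f"{clinical_name})")
    fit = sm.OLS(clin[keep], design).fit()
    b0, b1, b2, b3 = fit.params
    ci = fit.conf_int(alpha=0.05)[1]

    if permutation:
        if rng is None:
            rng = np.random.default_rng(0)
        p1 = _permutation_p_beta1(clin[keep], measure[keep], cov, n_perm, rng)
    else:
        p1 = float(fit.pvalues[1])  # t-test == partial F for one term
    return GlmFit(clinical_name, measure_name, group,
                  float(b0), float(b1), float(b2), float(b3), p1,
                  (float(ci[0]), float(ci[1])), n_used)


def _permutation_p_beta1(clin, measure, cov, n_perm, rng):
    """Freedman-Lane permutation p for the measure term: nuisance model
    is intercept + age + sex, the tested factor is the measure."""
    # reuse the group-factor engine by treating the continuous measure as
    # the column of interest: full = [1, cov, measure], reduced = [1, cov]
    from .permstats import _batch_f, _orth
    n = len(clin)
    z = np.column_stack([np.ones(n), cov])
    x = np.column_stack([z, measure])
    qz, qx = _orth(z), _orth(x)
    df1, df2 = 1, n - x.shape[1]
    y = np.asarray(clin, dtype=float)[:, None]
    f_obs = _batch_f(y, qx, qz, df1, df2)[0]
    fitted = qz @ (qz.T @ y)
    resid = y - fitted
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    ystar = fitted[:, 0][None, :] + resid[:, 0][idx]
    tot = (ystar ** 2).sum(axis=1)
    px = ((ystar @ qx) ** 2).sum(axis=1)
    pz = ((ystar @ qz) ** 2).sum(axis=1)
    from .permstats import _f_from_projections
    f_perm = _f_from_projections(tot, px, pz, df1, df2)
    return float((1 + (f_perm >= f_obs).sum()) / (1 + n_perm))


def association_table(cohort: CohortDataset,
                      metrics_df: pd.DataFrame | None = None,
                      clinical_names: tuple[str, ...] = ("disease_duration", "edss"),
                      measure_names: tuple[str, ...] = GLOBAL_MEASURES,
                      groups: tuple[str, ...] | None = None,
                      permutation: bool = False, n_perm: int = 10_000,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per (group, measure, clinical variable) with the b1
    coefficient (unstandardized, on the raw measurement scale) and its
    p-value. Disease groups only by default; groups with a clinical
    variable entirely missing are skipped with a logged notice."""
    if metrics_df is None:
        metrics_df = global_metrics_table(cohort)
    if groups is None:
        groups = tuple(g for g in cohort.groups if g != cohort.control_group)
    glabels = cohort.group_labels()
    rows = []
    for group in groups:
        for clinical_name in clinical_names:
            clin = np.array([s.clinical.get(clinical_name, np.nan)
                             for s in cohort.subjects], dtype=float)
            if not np.isfinite(clin[glabels == group]).any():
                logger.info("group %s: clinical '%s' entirely missing; skipped",
                            group, clinical_name)
                continue
            for measure_name in measure_names:
                fit = fit_association(
                    cohort, metrics_df[measure_name].to_numpy(dtype=float),
                    clinical_name, group, measure_name=measure_name,
                    permutation=permutation, n_perm=n_perm, rng=rng)
                rows.append({
                    "group": group,
                    "clinical": clinical_name,
                    "measure": measure_name,
                    "beta": fit.beta1,
                    "p_value": fit.p_beta1,
                    "beta0": fit.beta0,
                    "beta_age": fit.beta2,
                    "beta_sex": fit.beta3,
                    "n_used": fit.n_used,
                })
    return pd.DataFrame(rows)
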