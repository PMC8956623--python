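"""Prevalence-based edge screening against tractography false positives.

Tractography-derived connectivity matrices contain spurious connections
(false positives) and missed connections (false negatives). Screening
estimates, for every node pair, the prevalence of the connection among
control subjects — the fraction of controls in which the edge weight is
strictly positive. A group threshold tau declares edges with prevalence
>= tau "existing". For a candidate tau, each control subject then
contributes false negatives (existing edges it lacks) and false
positives (non-existing edges it has). As tau rises the existing set
shrinks, so FN falls and FP grows; the optimal threshold balances the
two by minimizing max(FP, FN), with ties broken toward the smaller tau
(retaining more edges). The resulting edge mask, derived from controls
only, is applied to every subject in the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CohortDataset, Subject

__all__ = [
    "ScreeningResult",
    "prevalence_rates",
    "fp_fn_curves",
    "optimal_threshold",
    "apply_mask",
    "screen_cohort",
]


@dataclass(frozen=True)
class ScreeningResult:
    prevalence: np.ndarray           # (n, n) symmetric, in [0, 1]
    candidate_thresholds: np.ndarray
    fp_counts: np.ndarray
    fn_counts: np.ndarray
    chosen_threshold: float
    mask: np.ndarray                 # (n, n) boolean, symmetric

    @property
    def n_edges_retained(self) -> int:
        return int(self.mask[np.triu_indices(self.mask.shape[0], k=1)].sum())


def _control_stack(cohort: CohortDataset) -> np.ndarray:
    ctrl = [s.network.weights for s in cohort.subjects
            if s.group == cohort.control_group]
    if not ctrl:
        raise ValueError(f"no subjects in control group '{cohort.control_group}'")
    return np.stack(ctrl)


def prevalence_rates(cohort: CohortDataset) -> np.ndarray:
    """Per-edge fraction of control subjects in which the edge exists
    (weight strictly > 0). Symmetric, zero diagonal."""
    stack = _control_stack(cohort)
    prev = (stack > 0).mean(axis=0)
    np.fill_diagonal(prev, 0.0)
    return prev


def fp_fn_curves(cohort: CohortDataset, prevalence: np.ndarray,
                 grid: np.ndarray):
    """Total false-positive and false-negative connection counts across
    control subjects, for each candidate group threshold.

    At threshold tau the existing edge set is {prevalence >= tau}; a
    control subject's missing existing edge is a false negative, and its
    observed non-existing edge is a false positive.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid values must lie in [0, 1]")
    stack = _control_stack(cohort)
    n = stack.shape[1]
    iu = np.triu_indices(n, k=1)
    prev = np.asarray(prevalence)[iu]                  # (m,)
    present = (stack > 0)[:, iu[0], iu[1]].sum(axis=0)  # controls having edge
    n_ctrl = stack.shape[0]
    existing = prev[None, :] >= grid[:, None]           # (t, m)
    fn = np.where(existing, n_ctrl - present[None, :], 0).sum(axis=1)
    fp = np.where(~existing, present[None, :], 0).sum(axis=1)
    return fp.astype(int), fn.astype(int)


def optimal_threshold(fp_counts: np.ndarray, fn_counts: np.ndarray,
                      grid: np.ndarray) -> float:
    """Grid threshold minimizing max(FP, FN); ties go to the smaller
    threshold so that more edges are retained."""
    fp = np.asarray(fp_counts)
    fn = np.asarray(fn_counts)
    grid = np.asarray(grid, dtype=float)
    if not (fp.shape == fn.shape == grid.shape):
        raise ValueError("curves and grid must be aligned")
    worst = np.maximum(fp, fn)
    return float(grid[int(np.argmin(worst))])  # argmin takes first = smallest tau


def apply_mask(cohort: CohortDataset, mask: np.ndarray) -> CohortDataset:
    """Zero every subject's weights outside the (symmetric) edge mask;
    returns a new cohort, the input is untouched."""
    mask = np.asarray(mask, dtype=bool)
    n = cohort.n_nodes
    if mask.shape != (n, n):
        raise ValueError(f"mask shape {mask.shape} does not match n={n}")
    if not np.array_equal(mask, mask.T):
        raise ValueError("mask must be symmetric")
    subjects = []
    for s in cohort.subjects:
        w = np.where(mask, s.network.weights, 0.0)
        np.fill_diagonal(w, 0.0)
        subjects.append(Subject(s.subject_id, s.group, s.age, s.sex,
                                dict(s.clinical), s.network.with_weights(w)))
    return CohortDataset(tuple(subjects), control_group=cohort.control_group)


def screen_cohort(cohort: CohortDataset,
                  grid_step: float = 0.01) -> tuple[CohortDataset, ScreeningResult]:
    """Full screening pass: prevalence, FP/FN curves over the grid
    {0, grid_step, ..., 1}, optimal threshold, mask, masked cohort."""
    prev = prevalence_rates(cohort)
    n_steps = int(round(1.0 / grid_step))
    grid = np.round(np.arange(n_steps + 1) * grid_step, 10)
    fp, fn = fp_fn_curves(cohort, prev, grid)
    tau = optimal_threshold(fp, fn, grid)
    mask = prev >= tau
    np.fill_diagonal(mask, False)
    result = ScreeningResult(prev, grid, fp, fn, tau, mask)
    return apply_mask(cohort, mask), result
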