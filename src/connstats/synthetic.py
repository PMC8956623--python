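"""Synthetic three-group cohorts of FA-weighted connectomes.

The generator emulates the structure of a DTI case-control study of two
demyelinating diseases (MS, NMOSD) against healthy controls (HC):

* a shared population template network (Erdos-Renyi topology at a target
  density, resampled until connected) with truncated-normal FA-like
  weights in [0.2, 0.7];
* a per-group multiplicative attenuation of all weights (global
  disconnection; control fixed at 1);
* a planted, connected subnetwork of edges further attenuated in the
  disease groups (the ground truth that NBS should recover);
* linear age and sex effects on mean edge weight;
* subject-level noise: a global multiplicative factor and additive
  per-edge Gaussian noise, clipped at zero; edges absent from the
  template stay absent;
* clinical scores (EDSS-like, disease-duration-like) generated from a
  linear model on the subject's own realized network measures plus age
  and sex, for the disease groups only (missing in controls).

Everything is a pure function of (spec, truth, seed).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.stats import truncnorm

from .io import CohortDataset, Subject, WeightedNetwork, write_network

__all__ = [
    "CohortSpec",
    "ClinicalModel",
    "GroundTruth",
    "make_template",
    "default_ground_truth",
    "simulate_cohort",
    "null_cohort",
    "save_cohort",
]

# study-condition defaults: 68 MS / 50 NMOSD / 26 HC, ~80% female,
# HC and MS aged ~N(35, 9), NMOSD ~N(44, 12)
DEFAULT_GROUP_SIZES = {"MS": 68, "NMOSD": 50, "HC": 26}
DEFAULT_AGE_DIST = {"MS": (35.0, 9.0), "NMOSD": (44.0, 12.0), "HC": (35.0, 9.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling conditions for a synthetic cohort."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_nodes: int = 90
    density: float = 0.6
    weight_mean: float = 0.45
    weight_sd: float = 0.10
    weight_bounds: tuple[float, float] = (0.2, 0.7)
    edge_noise_sd: float = 0.03
    subject_scale_sd: float = 0.05
    age_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DIST))
    sex_p_female: float = 0.8
    control_group: str = "HC"

    def __post_init__(self):
        if self.density * self.n_nodes * (self.n_nodes - 1) / 2 < 1:
            raise ValueError("density too low: fewer than one edge")
        if self.weight_bounds[0] < 0:
            raise ValueError("weight bounds must keep weights >= 0")
        if self.control_group not in self.n_per_group:
            raise ValueError(f"no size for control group '{self.control_group}'")
        missing = set(self.n_per_group) - set(self.age_dist)
        if missing:
            raise ValueError(f"no age distribution for groups {sorted(missing)}")

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)

    @property
    def mean_age(self) -> float:
        """Expected cohort-wide age (centering point for covariate effects)."""
        total = sum(self.n_per_group.values())
        return sum(n * self.age_dist[g][0]
                   for g, n in self.n_per_group.items()) / total


@dataclass(frozen=True)
class ClinicalModel:
    """clinical = b0 + b1*measure + b2*age + b3*sex + N(0, noise_sd),
    generated for the listed groups only."""

    measure: str = "total_strength"
    betas: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 0.0)
    noise_sd: float = 0.0
    groups: tuple[str, ...] = ("MS", "NMOSD")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator plants, so tests can score recovery."""

    template: WeightedNetwork
    planted_edges: tuple[tuple[int, int], ...]
    planted_deltas: dict[str, float]      # multiplicative: w *= (1 + delta)
    group_scale: dict[str, float]
    covariate_betas: tuple[float, float]  # (age, sex) effect on mean weight
    clinical_models: dict[str, ClinicalModel] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        w = self.template.weights
        edges = tuple(tuple(sorted((int(i), int(j))))
                      for i, j in self.planted_edges)
        object.__setattr__(self, "planted_edges", edges)
        for i, j in edges:
            if w[i, j] <= 0:
                raise ValueError(f"planted edge ({i},{j}) absent from template")
        if edges and not _edges_connected(edges):
            raise ValueError("planted edges do not form a connected subnetwork")
        for g, s in self.group_scale.items():
            if s <= 0:
                raise ValueError(f"group_scale[{g}] must be > 0")

    def planted_mask(self) -> np.ndarray:
        m = np.zeros_like(self.template.weights, dtype=bool)
        for i, j in self.planted_edges:
            m[i, j] = m[j, i] = True
        return m


def _edges_connected(edges) -> bool:
    g = nx.Graph()
    g.add_edges_from(edges)
    return nx.is_connected(g)


def make_template(n_nodes: int, density: float,
                  weight_params: tuple[float, float, float, float] = (0.45, 0.10, 0.2, 0.7),
                  seed: int = 0) -> WeightedNetwork:
    """Connected Erdos-Renyi template with truncated-normal weights.

    Exactly round(density * n(n-1)/2) edges; resampled (up to 100 times)
    until connected. ``weight_params`` is (mean, sd, low, high).
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if density < 2.0 / n_nodes:
        warnings.warn(
            f"density {density} < 2/n_nodes: connectivity unlikely",
            stacklevel=2)
    m = int(round(density * n_nodes * (n_nodes - 1) / 2))
    rng = np.random.default_rng(seed)
    graph = None
    for _ in range(100):
        cand = nx.gnm_random_graph(n_nodes, m,
                                   seed=int(rng.integers(2 ** 31)))
        if nx.is_connected(cand):
            graph = cand
            break
    if graph is None:
        raise RuntimeError(
            f"no connected graph with n={n_nodes}, density={density} "
            "after 100 attempts")
    mean, sd, lo, hi = weight_params
    a, b = (lo - mean) / sd, (hi - mean) / sd
    w = np.zeros((n_nodes, n_nodes))
    edges = np.array(sorted(graph.edges()))
    vals = truncnorm.rvs(a, b, loc=mean, scale=sd, size=len(edges),
                         random_state=rng)
    w[edges[:, 0], edges[:, 1]] = vals
    w[edges[:, 1], edges[:, 0]] = vals
    labels = tuple(f"node_{i:03d}" for i in range(n_nodes))
    return WeightedNetwork(labels, w)


def _grow_connected_edge_set(template: WeightedNetwork, n_edges: int,
                             rng: np.random.Generator):
    """Random connected edge set grown from a random template edge."""
    w = template.weights
    iu = np.triu_indices(template.n, k=1)
    all_edges = [(int(i), int(j)) for i, j in zip(*iu) if w[i, j] > 0]
    start = all_edges[int(rng.integers(len(all_edges)))]
    chosen = {start}
    nodes = set(start)
    while len(chosen) < n_edges:
        frontier = [e for e in all_edges
                    if e not in chosen and (e[0] in nodes or e[1] in nodes)]
        if not frontier:
            raise RuntimeError("cannot grow connected edge set in template")
        e = frontier[int(rng.integers(len(frontier)))]
        chosen.add(e)
        nodes.update(e)
    return tuple(sorted(chosen))


def default_ground_truth(spec: CohortSpec, seed: int,
                         n_planted: int = 8,
                         planted_deltas: dict[str, float] | None = None,
                         group_scale: dict[str, float] | None = None,
                         covariate_betas: tuple[float, float] = (-0.001, 0.005),
                         with_clinical: bool = True) -> GroundTruth:
    """Study-like ground truth: global attenuation of both disease
    groups, a planted connected subnetwork hit harder in MS, and clinical
    scores negatively linked to total strength."""
    rng = np.random.default_rng(seed)
    template = make_template(
        spec.n_nodes, spec.density,
        (spec.weight_mean, spec.weight_sd, *spec.weight_bounds),
        seed=int(rng.integers(2 ** 31)))
    planted = _grow_connected_edge_set(template, n_planted, rng) \
        if n_planted else ()
    disease = [g for g in spec.groups if g != spec.control_group]
    if planted_deltas is None:
        planted_deltas = {g: d for g, d in zip(disease, (-0.25, -0.12))}
    if group_scale is None:
        group_scale = {g: (1.0 if g == spec.control_group else 0.92)
                       for g in spec.groups}
    clinical = {}
    if with_clinical and disease:
        # scaled so that a strength drop of study size moves the scores by
        # a clinically visible amount
        exp_total = 2 * spec.density * spec.n_nodes * (spec.n_nodes - 1) / 2 \
            * spec.weight_mean * 0.92
        clinical = {
            "edss": ClinicalModel(
                "total_strength",
                (2.0 + 0.06 * exp_total, -0.06, 0.02, 0.2), 0.8,
                tuple(disease)),
            "disease_duration": ClinicalModel(
                "total_strength",
                (4.0 + 0.07 * exp_total, -0.07, 0.0, 0.0), 2.0,
                tuple(disease)),
        }
    return GroundTruth(template, planted, planted_deltas, group_scale,
                       covariate_betas, clinical,
                       seed=int(rng.integers(2 ** 31)))


def _subject_measure(weights: np.ndarray, name: str) -> float:
    if name == "total_strength":
        return float(weights.sum())
    from . import metrics
    from .io import WeightedNetwork as WN
    labels = tuple(f"node_{i:03d}" for i in range(weights.shape[0]))
    return metrics.compute_all(WN(labels, weights)).global_[name]


def simulate_cohort(spec: CohortSpec, truth: GroundTruth
                    ) -> tuple[CohortDataset, GroundTruth]:
    """Draw a cohort from the generative model; pure in (spec, truth)."""
    if truth.template.n != spec.n_nodes:
        raise ValueError(
            f"truth template has n={truth.template.n}, spec n_nodes={spec.n_nodes}")
    if abs(truth.group_scale.get(spec.control_group, 1.0) - 1.0) > 1e-12:
        raise ValueError("control group scale must be 1")
    rng = np.random.default_rng(truth.seed)
    tw = truth.template.weights
    support = tw > 0
    planted = truth.planted_mask()
    beta_age, beta_sex = truth.covariate_betas
    mean_age = spec.mean_age
    labels = truth.template.labels

    subjects = []
    sid = 0
    for group in spec.groups:
        mu_age, sd_age = spec.age_dist[group]
        base = tw * truth.group_scale.get(group, 1.0)
        delta = truth.planted_deltas.get(group, 0.0)
        base = np.where(planted, base * (1.0 + delta), base)
        for _ in range(spec.n_per_group[group]):
            sid += 1
            age = float(np.clip(rng.normal(mu_age, sd_age), 18.0, 90.0))
            sex = int(rng.random() < spec.sex_p_female)
            w = base.copy()
            shift = beta_age * (age - mean_age) + beta_sex * sex
            if spec.subject_scale_sd > 0:
                w = w * max(rng.normal(1.0, spec.subject_scale_sd), 0.0)
            w = np.where(support, w + shift, 0.0)
            if spec.edge_noise_sd > 0:
                noise = rng.normal(0.0, spec.edge_noise_sd,
                                   size=w.shape)
                noise = np.triu(noise, k=1)
                noise = noise + noise.T
                w = np.where(support, w + noise, 0.0)
            w = np.clip(w, 0.0, None)
            np.fill_diagonal(w, 0.0)
            net = WeightedNetwork(labels, w)
            clinical = {}
            for name, model in truth.clinical_models.items():
                if group in model.groups:
                    b0, b1, b2, b3 = model.betas
                    val = (b0 + b1 * _subject_measure(w, model.measure)
                           + b2 * age + b3 * sex)
                    if model.noise_sd > 0:
                        val += rng.normal(0.0, model.noise_sd)
                    clinical[name] = float(val)
                else:
                    clinical[name] = float("nan")
            subjects.append(Subject(f"sub-{sid:04d}", group, age, sex,
                                    clinical, net))
    cohort = CohortDataset(tuple(subjects),
                           control_group=spec.control_group)
    return cohort, truth


def null_cohort(spec: CohortSpec, seed: int) -> CohortDataset:
    """Cohort in which group labels carry no information: identical
    generating distribution (template, scale 1, shared age/sex
    distributions) for all three groups."""
    ctrl_age = spec.age_dist[spec.control_group]
    null_spec = dataclasses.replace(
        spec, age_dist={g: ctrl_age for g in spec.groups})
    rng = np.random.default_rng(seed)
    template = make_template(
        spec.n_nodes, spec.density,
        (spec.weight_mean, spec.weight_sd, *spec.weight_bounds),
        seed=int(rng.integers(2 ** 31)))
    truth = GroundTruth(
        template, (), {}, {g: 1.0 for g in spec.groups},
        covariate_betas=(-0.001, 0.005), clinical_models={},
        seed=int(rng.integers(2 ** 31)))
    cohort, _ = simulate_cohort(null_spec, truth)
    return cohort


def save_cohort(cohort: CohortDataset, out_dir: str | Path,
                truth: GroundTruth | None = None) -> Path:
    """Write matrices + manifest (and ground truth JSON) in the layout
    read_cohort consumes; returns the manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    clinical_names = sorted({k for s in cohort.subjects for k in s.clinical})
    for s in cohort.subjects:
        fname = f"{s.subject_id}.csv"
        write_network(s.network, mat_dir / fname)
        row = {"subject_id": s.subject_id, "group": s.group,
               "age": s.age, "sex": s.sex,
               "matrix_file": f"matrices/{fname}"}
        for c in clinical_names:
            row[c] = s.clinical.get(c, float("nan"))
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if truth is not None:
        info = {
            "seed": truth.seed,
            "planted_edges": [list(e) for e in truth.planted_edges],
            "planted_deltas": truth.planted_deltas,
            "group_scale": truth.group_scale,
            "covariate_betas": list(truth.covariate_betas),
            "clinical_models": {
                name: {"measure": m.measure, "betas": list(m.betas),
                       "noise_sd": m.noise_sd, "groups": list(m.groups)}
                for name, m in truth.clinical_models.items()},
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(info, indent=2))
        write_network(truth.template, out_dir / "template.csv")
    return manifest
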