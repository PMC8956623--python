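"""Input/output and validation for connectome group analysis.

Connectivity matrices are dense square delimited text files (CSV/TSV),
optionally carrying region labels as a header row (and matching index
column). A cohort is described by a manifest CSV with columns
``subject_id, group, age, sex, matrix_file`` plus optional clinical
columns (e.g. ``edss``, ``disease_duration``); missing clinical values
are preserved as NaN and excluded pairwise downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WeightedNetwork",
    "Subject",
    "CohortDataset",
    "AnalysisConfig",
    "read_network",
    "read_cohort",
    "write_report",
    "load_config",
    "aal90_labels",
]

#: symmetry tolerance: larger asymmetries are treated as data errors
SYMMETRY_TOL = 1e-8

#: recognised clinical group labels; the control group anchors screening
DEFAULT_CONTROL_GROUP = "HC"

#: sex coding used throughout (configurable in read_cohort)
FEMALE_CODE = 1


def aal90_labels() -> list[str]:
    """Region names of the 90-region AAL parcellation (78 cortical + 12
    subcortical, cerebellum excluded), in standard atlas order."""
    text = resources.files("connstats.data").joinpath("aal90_labels.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class WeightedNetwork:
    """One subject's symmetric weighted adjacency with region labels.

    Edge weights are dimensionless mean-FA values (>= 0, zero meaning no
    connection); the diagonal is zero. The binary adjacency is derived,
    never stored: ``a_ij = 1`` iff ``w_ij > 0``.
    """

    labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if n < 2:
            raise ValueError(f"network needs at least 2 regions, got {n}")
        if w.ndim != 2 or w.shape != (n, n):
            raise ValueError(
                f"weight matrix shape {w.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain NaN or infinite entries")
        if np.any(w < 0):
            raise ValueError("weights contain negative entries")
        if not np.allclose(w, w.T, rtol=0.0, atol=SYMMETRY_TOL):
            raise ValueError("weight matrix is not symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix has nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def adjacency(self) -> np.ndarray:
        """Derived binary adjacency (w > 0)."""
        return (self.weights > 0).astype(int)

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        return WeightedNetwork(self.labels, weights)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    age: float
    sex: int
    clinical: dict = field(default_factory=dict)
    network: WeightedNetwork | None = None

    def __post_init__(self):
        if not (self.age > 0):
            raise ValueError(f"subject {self.subject_id}: age must be > 0")
        for name, value in self.clinical.items():
            if value is not None and not np.isnan(value) and not np.isfinite(value):
                raise ValueError(
                    f"subject {self.subject_id}: clinical '{name}' not finite"
                )


@dataclass(frozen=True)
class CohortDataset:
    """Cohort of subjects with aligned networks, group labels, covariates
    and (possibly missing) clinical scores."""

    subjects: tuple[Subject, ...]
    control_group: str = DEFAULT_CONTROL_GROUP

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if not self.subjects:
            raise ValueError("cohort is empty")
        nets = [s.network for s in self.subjects]
        if any(net is None for net in nets):
            raise ValueError("every subject needs a network")
        first = nets[0]
        for s in self.subjects[1:]:
            if s.network.n != first.n:
                raise ValueError(
                    "inconsistent dimensions: subject "
                    f"{s.subject_id} has n={s.network.n}, expected {first.n}"
                )
            if s.network.labels != first.labels:
                raise ValueError(
                    f"subject {s.subject_id}: region labels differ from cohort"
                )
        if self.control_group not in {s.group for s in self.subjects}:
            raise ValueError(
                f"control group '{self.control_group}' has no subjects"
            )

    @property
    def n_nodes(self) -> int:
        return self.subjects[0].network.n

    @property
    def labels(self) -> tuple[str, ...]:
        return self.subjects[0].network.labels

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, control last, others in first-seen order."""
        seen: list[str] = []
        for s in self.subjects:
            if s.group not in seen and s.group != self.control_group:
                seen.append(s.group)
        return seen + [self.control_group]

    def group_labels(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def covariates(self) -> np.ndarray:
        """(n_subjects, 2) array of (age, sex)."""
        return np.array([[s.age, s.sex] for s in self.subjects], dtype=float)

    def stacked_weights(self) -> np.ndarray:
        """(n_subjects, n, n) stacked weight matrices."""
        return np.stack([s.network.weights for s in self.subjects])

    def subset(self, keep: np.ndarray | list) -> "CohortDataset":
        subs = tuple(s for s, k in zip(self.subjects, keep) if k)
        if not subs:
            raise ValueError("subset selects no subjects")
        groups = {s.group for s in subs}
        ctrl = self.control_group if self.control_group in groups else subs[0].group
        return CohortDataset(subs, control_group=ctrl)


@dataclass
class AnalysisConfig:
    """Analysis parameters: cluster-forming threshold, permutation count,
    significance level, FDR method, seed, screening grid resolution."""

    nbs_threshold: float = 3.0
    n_permutations: int = 10_000
    alpha: float = 0.05
    fdr_method: str = "bh"
    seed: int = 0
    screening_grid_step: float = 0.01

    def __post_init__(self):
        if not self.nbs_threshold > 0:
            raise ValueError("nbs_threshold must be > 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.screening_grid_step < 1:
            raise ValueError("screening_grid_step must be in (0, 1)")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# matrix files
# ---------------------------------------------------------------------------

def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except (TypeError, ValueError):
        return False


def read_network(path: str | Path, labels: list[str] | None = None) -> WeightedNetwork:
    """Read a square connectivity matrix from delimited text.

    Accepts plain numeric matrices, matrices with a label header row, and
    matrices with both header row and index column. Asymmetries within
    1e-8 are symmetrized by averaging; larger asymmetry is an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str,
                      skip_blank_lines=True)
    raw = raw.map(lambda x: x.strip() if isinstance(x, str) else x)

    file_labels = None
    first_row = raw.iloc[0].tolist()
    header = not all(_is_number(t) for t in first_row if t is not None and t == t)
    if header:
        body = raw.iloc[1:]
        first_col = body.iloc[:, 0].tolist()
        if not all(_is_number(t) for t in first_col):
            # header row + index column
            file_labels = [str(t) for t in body.iloc[:, 0]]
            body = body.iloc[:, 1:]
        else:
            file_labels = [str(t) for t in raw.iloc[0] if t == t]
        raw = body
    try:
        w = raw.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entries: {exc}") from None

    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square, shape {w.shape}")
    if not np.all(np.isfinite(w)):
        raise ValueError(f"{path}: matrix contains NaN or infinite entries")
    if np.any(w < 0):
        raise ValueError(f"{path}: matrix contains negative entries")

    asym = np.abs(w - w.T).max()
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"{path}: matrix asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
        )
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)

    if labels is not None:
        use = list(labels)
    elif file_labels is not None:
        use = file_labels
    else:
        use = [f"node_{i:03d}" for i in range(w.shape[0])]
    if len(use) != w.shape[0]:
        raise ValueError(
            f"{path}: {len(use)} labels for a {w.shape[0]}-node matrix"
        )
    return WeightedNetwork(tuple(use), w)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write a matrix with label header+index, at full float precision."""
    df = pd.DataFrame(net.weights, index=net.labels, columns=net.labels)
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# cohort manifests
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ["subject_id", "group", "age", "sex", "matrix_file"]

_SEX_ALIASES = {"f": 1, "female": 1, "m": 0, "male": 0}


def _parse_sex(value, female_code: int) -> int:
    if isinstance(value, str) and value.strip().lower() in _SEX_ALIASES:
        female = _SEX_ALIASES[value.strip().lower()]
        return female_code if female else 1 - female_code
    iv = int(float(value))
    if iv not in (0, 1):
        raise ValueError(f"sex code must be 0/1 or F/M, got {value!r}")
    return iv


def read_cohort(
    manifest_path: str | Path,
    matrix_dir: str | Path | None = None,
    labels: list[str] | None = None,
    control_group: str = DEFAULT_CONTROL_GROUP,
    known_groups: tuple[str, ...] | None = None,
    female_code: int = FEMALE_CODE,
) -> CohortDataset:
    """Load a cohort manifest and all its connectivity matrices.

    ``matrix_dir`` defaults to the manifest's directory; ``matrix_file``
    entries are resolved relative to it. Extra manifest columns are
    treated as clinical variables, with empty cells kept as missing.
    """
    manifest_path = Path(manifest_path)
    base = Path(matrix_dir) if matrix_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    clinical_cols = [c for c in df.columns if c not in _MANIFEST_REQUIRED]

    subjects = []
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        group = str(row["group"])
        if known_groups is not None and group not in known_groups:
            raise ValueError(f"subject {sid}: unknown group label '{group}'")
        mpath = base / str(row["matrix_file"])
        if not mpath.exists():
            raise FileNotFoundError(
                f"subject {sid}: matrix file not found: {mpath}"
            )
        net = read_network(mpath, labels=labels)
        clinical = {
            c: (float(row[c]) if pd.notna(row[c]) else float("nan"))
            for c in clinical_cols
        }
        subjects.append(
            Subject(
                subject_id=sid,
                group=group,
                age=float(row["age"]),
                sex=_parse_sex(row["sex"], female_code),
                clinical=clinical,
                network=net,
            )
        )
    return CohortDataset(tuple(subjects), control_group=control_group)


def write_report(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                 float_precision: int = 6) -> list[Path]:
    """Write result tables as CSV with deterministic column order and
    fixed float precision; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format=f"%.{float_precision}f",
                     lineterminator="\n")
        written.append(path)
    return written
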