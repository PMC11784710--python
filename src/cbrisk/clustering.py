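"""Per-subject K-means over (time, signal) points and the pattern taxonomy.

Each subject's minute series is clustered independently on standardized
(time, value) pairs — or (time, RR, HR) triples for the combined variable —
with K=6 by default.  The labels at the three post-hyperoxia minutes form a
triple whose *equality structure* is named:

====  =================  ==========================
name  structure          reading
====  =================  ==========================
DU    (a, a, b)          double-up: change at the third minute
DD    (a, b, b)          double-down: change at the second minute
DUD   (a, b, a)          excursion and return
S     (a, a, a)          stable, no change
T     (a, b, c)          three distinct clusters
====  =================  ==========================

These five classes are exactly the set partitions of three items, so every
triple receives one name and the naming is invariant under any relabeling of
the arbitrary K-means cluster indices.  The group-level *variability* index
is the percentage of subjects whose triple is not constant (pattern != S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .cohort import PatientMatrix, StimulusProtocol, VariableKind

__all__ = [
    "PATTERN_NAMES",
    "PATTERN_CODES",
    "ClusterLabels",
    "PostOxygenTriple",
    "VariabilityResult",
    "standardize_columns",
    "cluster_subject_series",
    "cluster_group",
    "extract_postoxygen",
    "pattern_name",
    "pattern_code",
    "variability",
    "wcss_curve",
    "suggest_k",
]

#: Fixed pattern-name order and their conventional integer codes.
PATTERN_NAMES: tuple[str, ...] = ("DU", "DD", "DUD", "S", "T")
PATTERN_CODES: dict[str, int] = {name: i + 1 for i, name in enumerate(PATTERN_NAMES)}

#: Default number of clusters (chosen by the WCSS elbow on this protocol).
DEFAULT_K = 6
#: Default seed for the K-means initialisation, for reproducibility.
DEFAULT_SEED = 13
#: k-means++ restarts; lowest-WCSS solution is kept.
N_INIT = 10


@dataclass(frozen=True)
class ClusterLabels:
    """Cluster label per minute for one subject and one variable."""

    subject_id: str
    variable: VariableKind
    labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and self.labels.max() >= self.k:
            raise ValueError(
                f"label {int(self.labels.max())} out of range for k={self.k}"
            )


@dataclass(frozen=True)
class PostOxygenTriple:
    """Labels at the post-hyperoxia window minutes (default 11, 12, 13)."""

    subject_id: str
    variable: VariableKind
    labels3: tuple[int, ...]

    @property
    def is_constant(self) -> bool:
        return len(set(self.labels3)) == 1

    @property
    def pattern(self) -> str:
        return pattern_name(self.labels3)


@dataclass(frozen=True)
class VariabilityResult:
    """Eq.-style variability index: share of subjects with a non-constant triple."""

    c_d: int
    n_s: int

    @property
    def percent(self) -> float:
        return 100.0 * self.c_d / self.n_s


def standardize_columns(points: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance transform of each column.

    A zero-variance column (including the single-row case) maps to zeros.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 1:
        raise ValueError("points must be a non-empty 2-D array")
    mean = points.mean(axis=0)
    std = points.std(axis=0)
    out = np.zeros_like(points)
    nz = std > 0
    out[:, nz] = (points[:, nz] - mean[nz]) / std[nz]
    return out


def cluster_subject_series(
    points: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = DEFAULT_SEED,
    *,
    subject_id: str = "",
    variable: VariableKind | int | str = VariableKind.HR,
) -> ClusterLabels:
    """K-means over one subject's standardized (time, value...) points.

    Uses k-means++ initialisation with ``N_INIT`` restarts keeping the
    lowest-inertia solution; identical seed yields identical labels.
    """
    variable = VariableKind.from_any(variable)
    points = np.asarray(points, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    z = standardize_columns(points)
    n_distinct = np.unique(z, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct standardized points"
        )
    km = KMeans(n_clusters=k, init="k-means++", n_init=N_INIT, random_state=seed)
    labels = km.fit_predict(z)
    return ClusterLabels(
        subject_id=subject_id, variable=variable, labels=labels, k=k, seed=seed
    )


def cluster_group(
    matrix: PatientMatrix, k: int = DEFAULT_K, seed: int = DEFAULT_SEED
) -> list[ClusterLabels]:
    """Cluster every subject of a variable matrix independently."""
    return [
        cluster_subject_series(
            matrix.subject_points(sid),
            k=k,
            seed=seed,
            subject_id=sid,
            variable=matrix.variable,
        )
        for sid in matrix.subject_ids
    ]


def extract_postoxygen(
    labels: ClusterLabels, protocol: StimulusProtocol | None = None
) -> PostOxygenTriple:
    """Slice out the labels at the post-hyperoxia window minutes."""
    protocol = protocol or StimulusProtocol()
    lo, hi = protocol.postoxygen_window
    if not (1 <= lo <= hi <= labels.labels.size):
        raise ValueError(
            f"post-oxygen window {protocol.postoxygen_window} outside the "
            f"1..{labels.labels.size} minute grid"
        )
    # minute m lives at index m-1
    window = tuple(int(v) for v in labels.labels[lo - 1 : hi])
    return PostOxygenTriple(
        subject_id=labels.subject_id, variable=labels.variable, labels3=window
    )


def pattern_name(labels3: Sequence[int], orientation: str = "aab_is_du") -> str:
    """Name a label triple by its equality structure.

    (a,a,a) -> S; (a,a,b) -> DU; (a,b,b) -> DD; (a,b,a) -> DUD; all distinct
    -> T.  Invariant under any permutation of the label alphabet.  The
    ``orientation`` switch flips the DU/DD reading of the two two-cluster
    change patterns, should the convention ever be read the other way.
    """
    if len(labels3) != 3:
        raise ValueError(f"expected a label triple, got length {len(labels3)}")
    if orientation not in ("aab_is_du", "aab_is_dd"):
        raise ValueError(f"unknown orientation {orientation!r}")
    a, b, c = labels3
    if a == b == c:
        return "S"
    if a == b:  # (a, a, b)
        return "DU" if orientation == "aab_is_du" else "DD"
    if b == c:  # (a, b, b)
        return "DD" if orientation == "aab_is_du" else "DU"
    if a == c:  # (a, b, a)
        return "DUD"
    return "T"


def pattern_code(name: str) -> int:
    """Conventional integer code of a pattern name (DU=1 .. T=5)."""
    try:
        return PATTERN_CODES[name]
    except KeyError:
        raise ValueError(f"unknown pattern name {name!r}") from None


def variability(triples: Iterable[PostOxygenTriple]) -> VariabilityResult:
    """Percentage of subjects whose post-oxygen triple is not constant."""
    triples = list(triples)
    if not triples:
        raise ValueError("variability needs at least one subject triple")
    c_d = sum(1 for t in triples if not t.is_constant)
    return VariabilityResult(c_d=c_d, n_s=len(triples))


def wcss_curve(
    points: np.ndarray,
    k_range: Iterable[int],
    seed: int = DEFAULT_SEED,
) -> list[tuple[int, float]]:
    """Within-cluster sum of squares over a range of K, on standardized points.

    Infeasible K values (exceeding the number of distinct points) are skipped
    with a warning.  With best-of-``N_INIT`` restarts the curve is
    non-increasing up to numerical tolerance.
    """
    z = standardize_columns(np.asarray(points, dtype=float))
    n_distinct = np.unique(z, axis=0).shape[0]
    curve: list[tuple[int, float]] = []
    for k in k_range:
        if k < 1 or k > n_distinct:
            warnings.warn(f"skipping infeasible k={k}", stacklevel=2)
            continue
        km = KMeans(n_clusters=k, init="k-means++", n_init=N_INIT, random_state=seed)
        km.fit(z)
        curve.append((int(k), float(km.inertia_)))
    return curve


def suggest_k(curve: Sequence[tuple[int, float]]) -> int:
    """Elbow of a WCSS curve: the K maximizing the discrete second difference.

    Ties break toward the smallest K.  Needs at least three curve points.
    """
    if len(curve) < 3:
        raise ValueError("need at least three (k, wcss) points to locate an elbow")
    ks = [k for k, _ in curve]
    ws = [w for _, w in curve]
    best_k, best_curv = ks[1], -np.inf
    for i in range(1, len(curve) - 1):
        curvature = ws[i - 1] - 2.0 * ws[i] + ws[i + 1]
        if curvature > best_curv + 1e-12:
            best_k, best_curv = ks[i], curvature
    return int(best_k)
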