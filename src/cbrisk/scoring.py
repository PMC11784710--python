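"""Training of the glucose-weighted risk score.

Each training subject (prediabetes group, glucose required) contributes a
*weight* W derived from a severity level SL of their interstitial-glucose
series:

    SL = (sum_{j=1..t_g} g_j) / t_g  +  (sum_{j=T_g..80} g_j) / (T_g - t_g)
    W  = SL / 100

with t_g=34 and T_g=55 by default — the interval over which the group mean
glucose trajectories diverge.  Note the second term's denominator: the
printed formula divides the 26-sample tail sum by T_g - t_g = 21.  The
default ``as_printed`` mode keeps that literal form; ``window_mean`` divides
by the actual sample count instead.

The association table Δ pairs each subject's weight with its three cluster
patterns (HR, RR, RRxHR).  The score matrix Ψ (pattern × variable) sums the
weights of subjects showing each pattern in each variable; the maximum risk
χ is the sum of column maxima, and the Low/Medium/High bands split [0, χ]
at χ/3 and 2χ/3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering
from .cohort import Cohort, Group, StimulusProtocol, VariableKind, VARIABLES
from .clustering import PATTERN_NAMES, pattern_code

__all__ = [
    "GlucoseWindows",
    "AssociationRow",
    "ScoreMatrix",
    "RiskModel",
    "TrainingConfig",
    "severity_level",
    "weight",
    "subject_patterns",
    "build_association",
    "score_matrix",
    "max_risk",
    "risk_table",
    "train",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

RISK_LEVELS = ("Low", "Medium", "High")


@dataclass(frozen=True)
class GlucoseWindows:
    """Severity-level windows: baseline end t_g and tail start T_g (minutes)."""

    t_g: int = 34
    T_g: int = 55

    def __post_init__(self) -> None:
        if not 1 <= self.t_g < self.T_g:
            raise ValueError(
                f"require 1 <= t_g < T_g, got t_g={self.t_g}, T_g={self.T_g}"
            )


def severity_level(
    glucose: np.ndarray,
    windows: GlucoseWindows = GlucoseWindows(),
    mode: str = "as_printed",
) -> float:
    """Severity level of a minute-indexed glucose series (mg/dL).

    ``as_printed`` divides the minute-T_g..80 sum by (T_g - t_g);
    ``window_mean`` uses the arithmetic mean of that tail window.
    """
    if glucose is None:
        raise ValueError(
            "severity level requires a glucose series; training subjects "
            "must carry glucose"
        )
    g = np.asarray(glucose, dtype=float)
    t_g, T_g = windows.t_g, windows.T_g
    if T_g > g.size:
        raise ValueError(
            f"glucose windows ({t_g}, {T_g}) exceed the {g.size}-minute grid"
        )
    # minute m is index m-1; both windows are inclusive
    head = float(g[:t_g].sum()) / t_g
    tail_sum = float(g[T_g - 1 :].sum())
    if mode == "as_printed":
        tail = tail_sum / (T_g - t_g)
    elif mode == "window_mean":
        tail = tail_sum / (g.size - T_g + 1)
    else:
        raise ValueError(f"unknown severity-level mode {mode!r}")
    return head + tail


def weight(sl: float) -> float:
    """Training weight W = SL / 100 (nominally in the 1..10 range)."""
    if sl < 0:
        raise ValueError(f"severity level must be non-negative, got {sl}")
    return sl / 100.0


@dataclass(frozen=True)
class AssociationRow:
    """One subject's row of the association table Δ: weight plus patterns."""

    subject_id: str
    weight: float
    patterns: dict[str, str]  # variable name -> pattern name

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(
                f"subject {self.subject_id}: weight must be positive"
            )
        expected = {v.name for v in VARIABLES}
        if set(self.patterns) != expected:
            raise ValueError(
                f"subject {self.subject_id}: patterns must cover {sorted(expected)}"
            )
        for var, name in self.patterns.items():
            if name not in PATTERN_NAMES:
                raise ValueError(
                    f"subject {self.subject_id}: unknown pattern {name!r} for {var}"
                )

    @property
    def pattern_codes(self) -> dict[str, int]:
        return {var: pattern_code(name) for var, name in self.patterns.items()}


@dataclass(frozen=True)
class ScoreMatrix:
    """Pattern-by-variable score table Ψ.

    Rows are ordered (DU, DD, DUD, S, T), columns (HR, RR, RRxHR).  Each
    column sums to the training cohort's total weight: every subject shows
    exactly one pattern per variable.
    """

    values: np.ndarray  # shape (5, 3)

    row_names = PATTERN_NAMES
    col_names = tuple(v.name for v in VARIABLES)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(self.row_names), len(self.col_names)):
            raise ValueError(
                f"score matrix must be {len(self.row_names)}x{len(self.col_names)}, "
                f"got {arr.shape}"
            )
        if np.any(arr < 0):
            raise ValueError("score matrix entries must be non-negative")
        object.__setattr__(self, "values", arr)

    def cell(self, pattern: str, variable: VariableKind | str) -> float:
        variable = VariableKind.from_any(variable)
        if pattern not in self.row_names:
            raise ValueError(f"unknown pattern name {pattern!r}")
        i = self.row_names.index(pattern)
        j = self.col_names.index(variable.name)
        return float(self.values[i, j])

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.row_names), columns=list(self.col_names)
        )


def subject_patterns(
    subject,
    protocol: StimulusProtocol,
    k: int = clustering.DEFAULT_K,
    seed: int = clustering.DEFAULT_SEED,
    orientation: str = "aab_is_du",
) -> dict[str, str]:
    """Cluster one subject on all three variables and name the window triples."""
    t = protocol.minutes.astype(float)
    point_sets = {
        "HR": np.column_stack([t, subject.hr]),
        "RR": np.column_stack([t, subject.rr]),
        "RRxHR": np.column_stack([t, subject.rr, subject.hr]),
    }
    out: dict[str, str] = {}
    for var, points in point_sets.items():
        labels = clustering.cluster_subject_series(
            points, k=k, seed=seed, subject_id=subject.subject_id, variable=var
        )
        triple = clustering.extract_postoxygen(labels, protocol)
        out[var] = clustering.pattern_name(triple.labels3, orientation)
    return out


@dataclass(frozen=True)
class TrainingConfig:
    """Snapshot of every knob that shapes a trained model."""

    k: int = clustering.DEFAULT_K
    seed: int = clustering.DEFAULT_SEED
    windows: GlucoseWindows = field(default_factory=GlucoseWindows)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    sl_mode: str = "as_printed"
    pattern_orientation: str = "aab_is_du"

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "t_g": self.windows.t_g,
            "T_g": self.windows.T_g,
            "protocol": {
                "baseline_end_minute": self.protocol.baseline_end_minute,
                "postoxygen_window": list(self.protocol.postoxygen_window),
                "meal_minute": self.protocol.meal_minute,
                "total_minutes": self.protocol.total_minutes,
            },
            "sl_mode": self.sl_mode,
            "pattern_orientation": self.pattern_orientation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        proto = d.get("protocol", {})
        return cls(
            k=int(d["k"]),
            seed=int(d["seed"]),
            windows=GlucoseWindows(t_g=int(d["t_g"]), T_g=int(d["T_g"])),
            protocol=StimulusProtocol(
                baseline_end_minute=int(proto["baseline_end_minute"]),
                postoxygen_window=tuple(proto["postoxygen_window"]),
                meal_minute=int(proto["meal_minute"]),
                total_minutes=int(proto["total_minutes"]),
            ),
            sl_mode=str(d["sl_mode"]),
            pattern_orientation=str(d["pattern_orientation"]),
        )


def build_association(
    cohort: Cohort, config: TrainingConfig = TrainingConfig()
) -> list[AssociationRow]:
    """Build Δ for a training cohort: one (weight, patterns) row per subject.

    All subjects must belong to the prediabetes group and carry glucose.
    """
    rows: list[AssociationRow] = []
    for s in cohort:
        if s.group is not Group.PREDIABETES:
            raise ValueError(
                f"training cohort must be prediabetes-only; subject "
                f"{s.subject_id} is {s.group.value}"
            )
        if not s.has_glucose:
            raise ValueError(
                f"subject {s.subject_id} has no glucose series; training "
                "requires glucose for every subject"
            )
        sl = severity_level(s.glucose, config.windows, config.sl_mode)
        rows.append(
            AssociationRow(
                subject_id=s.subject_id,
                weight=weight(sl),
                patterns=subject_patterns(
                    s,
                    config.protocol,
                    k=config.k,
                    seed=config.seed,
                    orientation=config.pattern_orientation,
                ),
            )
        )
    return rows


def score_matrix(delta: list[AssociationRow]) -> ScoreMatrix:
    """Sum, per (pattern, variable) cell, the weights of matching subjects."""
    if not delta:
        raise ValueError("association table is empty")
    values = np.zeros((len(PATTERN_NAMES), len(VARIABLES)))
    for row in delta:
        for j, var in enumerate(VARIABLES):
            i = PATTERN_NAMES.index(row.patterns[var.name])
            values[i, j] += row.weight
    return ScoreMatrix(values=values)


def max_risk(psi: ScoreMatrix) -> float:
    """Maximum achievable score χ: sum of the column-wise maxima of Ψ."""
    return float(psi.values.max(axis=0).sum())


def risk_table(chi: float) -> list[tuple[float, float, str]]:
    """The three risk bands over [0, χ], split at χ/3 and 2χ/3.

    Lower bounds are inclusive, upper bounds exclusive, except the top
    band which includes χ itself.
    """
    if chi <= 0:
        raise ValueError(f"maximum risk must be positive, got {chi}")
    return [
        (0.0, chi / 3.0, "Low"),
        (chi / 3.0, 2.0 * chi / 3.0, "Medium"),
        (2.0 * chi / 3.0, chi, "High"),
    ]


@dataclass(frozen=True)
class RiskModel:
    """A trained risk model: score matrix, maximum risk, bands, provenance."""

    psi: ScoreMatrix
    chi: float
    config: TrainingConfig
    version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.chi <= 0:
            raise ValueError("degenerate model: maximum risk must be positive")
        expected = max_risk(self.psi)
        if not np.isclose(self.chi, expected):
            raise ValueError(
                f"inconsistent model: chi={self.chi} but column maxima sum to "
                f"{expected}"
            )

    @property
    def thresholds(self) -> tuple[float, float]:
        return (self.chi / 3.0, 2.0 * self.chi / 3.0)

    @property
    def bands(self) -> list[tuple[float, float, str]]:
        return risk_table(self.chi)


def train(cohort: Cohort, config: TrainingConfig = TrainingConfig()) -> RiskModel:
    """End-to-end training: Δ from the cohort, then Ψ, χ and the bands."""
    training = [s for s in cohort if s.group is Group.PREDIABETES]
    if len(training) < 2:
        raise ValueError(
            f"training needs at least 2 prediabetes subjects, got {len(training)}"
        )
    delta = build_association(
        Cohort(subjects=tuple(training), protocol=cohort.protocol), config
    )
    psi = score_matrix(delta)
    return RiskModel(psi=psi, chi=max_risk(psi), config=config)


def save_model(model: RiskModel, path: str | Path) -> Path:
    """Persist a model as JSON (score matrix with labels, χ, config)."""
    path = Path(path)
    payload = {
        "version": model.version,
        "psi": {
            "rows": list(ScoreMatrix.row_names),
            "cols": list(ScoreMatrix.col_names),
            "values": model.psi.values.tolist(),
        },
        "chi": model.chi,
        "thresholds": list(model.thresholds),
        "config": model.config.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_model(path: str | Path) -> RiskModel:
    """Load a model saved by :func:`save_model`; validates version and labels."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} not supported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    psi_spec = payload["psi"]
    if tuple(psi_spec["rows"]) != ScoreMatrix.row_names:
        raise ValueError(
            f"unknown pattern rows {psi_spec['rows']} in model file"
        )
    if tuple(psi_spec["cols"]) != ScoreMatrix.col_names:
        raise ValueError(f"unknown variable columns {psi_spec['cols']} in model file")
    return RiskModel(
        psi=ScoreMatrix(values=np.asarray(psi_spec["values"], dtype=float)),
        chi=float(payload["chi"]),
        config=TrainingConfig.from_dict(payload["config"]),
        version=int(version),
    )
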