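"""Risk banding of new subjects — the non-invasive, fit/predict surface.

A trained model scores a subject from HR and RR alone: the subject's three
post-hyperoxia cluster patterns select one Ψ cell per variable, the cells
are summed, and the sum falls into one of the Low/Medium/High bands.

:class:`RiskBandClassifier` packages the whole pipeline as a scikit-learn
style estimator.  ``X`` is an ``(n_subjects, 2*T)`` array holding each
subject's HR minutes followed by RR minutes; ``fit`` additionally needs the
training glucose series, passed as ``y`` with shape ``(n_subjects, T)``.
``predict`` returns the band names.  The cohort-level :func:`classify_subject`
and :func:`classify_cohort` helpers stay thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import clustering, scoring
from .cohort import Cohort, Group, StimulusProtocol, SubjectRecord, VARIABLES
from .scoring import (
    GlucoseWindows,
    RiskModel,
    ScoreMatrix,
    TrainingConfig,
    risk_table,
    subject_patterns,
)

__all__ = [
    "RiskResult",
    "RiskBandClassifier",
    "score_patterns",
    "classify_score",
    "classify_subject",
    "classify_cohort",
]


@dataclass(frozen=True)
class RiskResult:
    """Classification outcome for one subject."""

    subject_id: str
    patterns: dict[str, str]
    score: float
    level: str

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "patterns": dict(self.patterns),
            "score": self.score,
            "level": self.level,
        }


def score_patterns(patterns: dict[str, str], psi: ScoreMatrix) -> float:
    """Sum the Ψ cells selected by one pattern per variable."""
    missing = [v.name for v in VARIABLES if v.name not in patterns]
    if missing:
        raise ValueError(f"patterns missing for variables {missing}")
    return float(sum(psi.cell(patterns[v.name], v) for v in VARIABLES))


def classify_score(score: float, model: RiskModel) -> str:
    """Band a score: Low below χ/3, Medium below 2χ/3, High up to χ.

    Lower bounds are inclusive; a score above χ (only reachable by mixing
    models) clamps to High with a warning.
    """
    if score < 0:
        raise ValueError(f"score must be non-negative, got {score}")
    low_hi, med_hi = model.thresholds
    if score > model.chi:
        warnings.warn(
            f"score {score:.4g} exceeds the model's maximum risk "
            f"{model.chi:.4g}; clamping to High",
            stacklevel=2,
        )
        return "High"
    if score < low_hi:
        return "Low"
    if score < med_hi:
        return "Medium"
    return "High"


def classify_subject(subject: SubjectRecord, model: RiskModel) -> RiskResult:
    """Score and band one subject from HR and RR only (glucose is ignored)."""
    cfg = model.config
    if subject.n_minutes != cfg.protocol.total_minutes:
        raise ValueError(
            f"subject {subject.subject_id}: {subject.n_minutes} minutes, the "
            f"model's protocol expects {cfg.protocol.total_minutes}"
        )
    patterns = subject_patterns(
        subject,
        cfg.protocol,
        k=cfg.k,
        seed=cfg.seed,
        orientation=cfg.pattern_orientation,
    )
    score = score_patterns(patterns, model.psi)
    return RiskResult(
        subject_id=subject.subject_id,
        patterns=patterns,
        score=score,
        level=classify_score(score, model),
    )


def classify_cohort(cohort: Cohort, model: RiskModel) -> list[RiskResult]:
    return [classify_subject(s, model) for s in cohort]


class RiskBandClassifier(BaseEstimator):
    """Unsupervised three-band risk classifier over stimulus-response series.

    Parameters
    ----------
    k : int, default=6
        Number of K-means clusters per subject and variable.
    random_state : int, default=13
        Seed for the k-means++ initialisation; classification of a given
        subject under a fitted model is fully deterministic.
    t_g, T_g : int, defaults 34 and 55
        Glucose severity-level window boundaries (minutes).
    sl_mode : {'as_printed', 'window_mean'}
        Denominator convention of the severity level's second term.
    pattern_orientation : {'aab_is_du', 'aab_is_dd'}
        Which of the two two-cluster change structures is called DU.
    protocol : StimulusProtocol, optional
        Stimulus timing; defaults to the standard 80-minute run.

    Attributes
    ----------
    psi_ : ScoreMatrix
        Trained pattern-by-variable score matrix.
    chi_ : float
        Maximum risk (sum of Ψ column maxima).
    thresholds_ : tuple of float
        The (χ/3, 2χ/3) band boundaries.
    model_ : RiskModel
        Full trained model, also usable with the functional API.
    classes_ : ndarray of str
        The three band names.
    """

    def __init__(
        self,
        k: int = clustering.DEFAULT_K,
        random_state: int = clustering.DEFAULT_SEED,
        t_g: int = 34,
        T_g: int = 55,
        sl_mode: str = "as_printed",
        pattern_orientation: str = "aab_is_du",
        protocol: StimulusProtocol | None = None,
    ) -> None:
        self.k = k
        self.random_state = random_state
        self.t_g = t_g
        self.T_g = T_g
        self.sl_mode = sl_mode
        self.pattern_orientation = pattern_orientation
        self.protocol = protocol

    # -- helpers ----------------------------------------------------------
    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            k=self.k,
            seed=self.random_state,
            windows=GlucoseWindows(t_g=self.t_g, T_g=self.T_g),
            protocol=self.protocol or StimulusProtocol(),
            sl_mode=self.sl_mode,
            pattern_orientation=self.pattern_orientation,
        )

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        T = (self.protocol or StimulusProtocol()).total_minutes
        if X.ndim != 2 or X.shape[1] != 2 * T:
            raise ValueError(
                f"X must be (n_subjects, {2 * T}): HR minutes then RR minutes"
            )
        if not np.all(np.isfinite(X)) or np.any(X <= 0):
            raise ValueError("HR/RR values must be finite and strictly positive")
        return X

    def _subjects(self, X: np.ndarray, ids=None, glucose=None, group=Group.CONTROL):
        T = (self.protocol or StimulusProtocol()).total_minutes
        minutes = np.arange(1, T + 1)
        out = []
        for i, row in enumerate(X):
            out.append(
                SubjectRecord(
                    subject_id=str(ids[i]) if ids is not None else f"subject-{i}",
                    group=group,
                    minutes=minutes,
                    hr=row[:T],
                    rr=row[T:],
                    glucose=None if glucose is None else np.asarray(glucose)[i],
                )
            )
        return out

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, subject_ids=None):
        """Train the score matrix from stimulus-response and glucose series.

        Parameters
        ----------
        X : array-like of shape (n_subjects, 2*T)
            Training subjects' HR then RR minute series (prediabetes group).
        y : array-like of shape (n_subjects, T)
            Matching interstitial-glucose series, mg/dL per minute.
        """
        X = self._check_X(X)
        T = (self.protocol or StimulusProtocol()).total_minutes
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0], T):
            raise ValueError(
                f"y must carry one {T}-minute glucose series per subject; "
                f"got {y.shape}"
            )
        subjects = self._subjects(
            X, ids=subject_ids, glucose=y, group=Group.PREDIABETES
        )
        cohort = Cohort(
            subjects=tuple(subjects), protocol=self.protocol or StimulusProtocol()
        )
        self.model_ = scoring.train(cohort, self._config())
        self.psi_ = self.model_.psi
        self.chi_ = self.model_.chi
        self.thresholds_ = self.model_.thresholds
        self.classes_ = np.asarray(scoring.RISK_LEVELS)
        return self

    @classmethod
    def from_model(cls, model: RiskModel) -> "RiskBandClassifier":
        """Wrap an already-trained :class:`RiskModel` as a fitted estimator."""
        cfg = model.config
        est = cls(
            k=cfg.k,
            random_state=cfg.seed,
            t_g=cfg.windows.t_g,
            T_g=cfg.windows.T_g,
            sl_mode=cfg.sl_mode,
            pattern_orientation=cfg.pattern_orientation,
            protocol=cfg.protocol,
        )
        est.model_ = model
        est.psi_ = model.psi
        est.chi_ = model.chi
        est.thresholds_ = model.thresholds
        est.classes_ = np.asarray(scoring.RISK_LEVELS)
        return est

    def decision_function(self, X) -> np.ndarray:
        """Risk score of each subject (higher = closer to the training group)."""
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        return np.asarray(
            [
                classify_subject(s, self.model_).score
                for s in self._subjects(X)
            ]
        )

    def predict(self, X) -> np.ndarray:
        """Low/Medium/High band for each subject."""
        check_is_fitted(self, "model_")
        X = self._check_X(X)
        return np.asarray(
            [classify_subject(s, self.model_).level for s in self._subjects(X)]
        )

    @staticmethod
    def pack(hr: np.ndarray, rr: np.ndarray) -> np.ndarray:
        """Stack per-subject HR and RR series into the estimator's X layout."""
        hr = np.atleast_2d(np.asarray(hr, dtype=float))
        rr = np.atleast_2d(np.asarray(rr, dtype=float))
        return np.hstack([hr, rr])
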