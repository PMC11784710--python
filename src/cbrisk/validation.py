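"""Validation harness: ADASYN augmentation, four-fold CV, metrics.

The classifier is validated as a binary screening test: subjects banded High
count as predicted prediabetes, Low as predicted healthy, and Medium — the
deliberately cautious middle band — as a *successful* classification for the
subject's true class.  Because only 8 prediabetes subjects are available
against 25 controls, the prediabetes test pool is topped up with ADASYN
synthetic series before each evaluation round.

ADASYN (adaptive synthetic sampling) oversamples the minority class by
interpolating each minority point toward randomly chosen minority
neighbours, allocating more synthetic points to minority samples whose
neighbourhoods are dominated by the majority class.  The implementation here
produces exactly the class gap (majority - minority) of synthetic vectors,
allocating per-point budgets by largest remainder so the count is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.neighbors import NearestNeighbors

from . import scoring
from .classifier import classify_subject
from .cohort import Cohort, Group, StimulusProtocol, SubjectRecord
from .scoring import RiskModel, TrainingConfig

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "RoundResult",
    "ValidationReport",
    "TABLE_FOLD_TEST_PAIRS",
    "subject_feature_vector",
    "vector_to_subject",
    "adasyn_augment",
    "make_fold_plan",
    "evaluate_round",
    "confusion_metrics",
    "run_cross_validation",
    "rank_sum_test",
    "compare_postoxygen_rr",
]

#: The published four-round fold assignment for the 8-subject training group:
#: each round holds out one fixed pair for testing.
TABLE_FOLD_TEST_PAIRS: tuple[tuple[str, str], ...] = (
    ("20180101008", "20180101001"),
    ("20180101002", "20180101006"),
    ("20180101005", "20180101004"),
    ("20180101007", "20180101003"),
)


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint test pairs covering every training subject exactly once."""

    rounds: tuple[dict, ...]  # each {"test_ids": [...], "train_ids": [...]}
    seed: int | None = None

    def __post_init__(self) -> None:
        tested = [sid for r in self.rounds for sid in r["test_ids"]]
        if len(set(tested)) != len(tested):
            raise ValueError("fold plan tests some subject more than once")
        for r in self.rounds:
            if set(r["test_ids"]) & set(r["train_ids"]):
                raise ValueError("fold plan overlaps test and train ids")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = prediabetes."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    A zero denominator yields 0 for that metric, with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} denominator is zero; reporting 0", stacklevel=3)
            return 0.0
        return num / den

    accuracy = (cm.tp + cm.tn) / cm.total
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision + recall == 0:
        warnings.warn("F1 denominator is zero; reporting 0", stacklevel=2)
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


# ---------------------------------------------------------------------------
# ADASYN
# ---------------------------------------------------------------------------


def _standardizer(reference: np.ndarray):
    mean = reference.mean(axis=0)
    sd = reference.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda a: (a - mean) / sd


def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares``, exact sum."""
    if shares.sum() <= 0:
        shares = np.ones_like(shares)
    quota = shares / shares.sum() * total
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def adasyn_augment(
    minority: np.ndarray,
    majority_count: int,
    k_neighbors: int = 5,
    seed: int = 0,
    majority: np.ndarray | None = None,
) -> np.ndarray:
    """Generate ADASYN synthetic minority vectors to close the class gap.

    Exactly ``majority_count - len(minority)`` vectors are produced.  When
    the ``majority`` feature vectors are supplied, each minority point's
    generation budget is proportional to the fraction of majority points
    among its ``k_neighbors`` nearest neighbours (the adaptive part);
    otherwise the budget is uniform.  Each synthetic vector is a convex
    combination of a minority point and one of its nearest minority
    neighbours.  ``k_neighbors`` silently shrinks to ``len(minority) - 1``
    when necessary.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or minority.shape[0] < 2:
        raise ValueError("ADASYN needs at least 2 minority samples")
    n_min = minority.shape[0]
    gap = majority_count - n_min
    if gap <= 0:
        return np.empty((0, minority.shape[1]))

    rng = np.random.default_rng(seed)
    k = min(k_neighbors, n_min - 1)

    # difficulty ratios from the mixed-class neighbourhood, if available
    if majority is not None and len(majority) > 0:
        majority = np.asarray(majority, dtype=float)
        both = np.vstack([minority, majority])
        z = _standardizer(both)
        k_mixed = min(k_neighbors, both.shape[0] - 1)
        nn = NearestNeighbors(n_neighbors=k_mixed + 1).fit(z(both))
        _, idx = nn.kneighbors(z(minority))
        # column 0 is the point itself
        ratios = (idx[:, 1:] >= n_min).mean(axis=1)
    else:
        ratios = np.ones(n_min)

    counts = _largest_remainder(ratios, gap)

    z_min = _standardizer(minority)
    nn_min = NearestNeighbors(n_neighbors=k + 1).fit(z_min(minority))
    _, min_idx = nn_min.kneighbors(z_min(minority))

    synthetic = np.empty((gap, minority.shape[1]))
    pos = 0
    for i, g_i in enumerate(counts):
        for _ in range(g_i):
            z_choice = min_idx[i, 1 + rng.integers(k)]
            lam = rng.random()
            synthetic[pos] = minority[i] + lam * (minority[z_choice] - minority[i])
            pos += 1
    return synthetic


def subject_feature_vector(subject: SubjectRecord) -> np.ndarray:
    """Concatenated HR then RR minute series — the ADASYN feature space."""
    return np.concatenate([subject.hr, subject.rr])


def vector_to_subject(
    vector: np.ndarray,
    subject_id: str,
    group: Group,
    protocol: StimulusProtocol,
) -> SubjectRecord:
    """Split a feature vector back into an HR/RR subject record."""
    T = protocol.total_minutes
    vector = np.asarray(vector, dtype=float)
    if vector.size != 2 * T:
        raise ValueError(f"expected a {2 * T}-long vector, got {vector.size}")
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        minutes=protocol.minutes,
        hr=np.clip(vector[:T], 1e-6, None),
        rr=np.clip(vector[T:], 1e-6, None),
    )


# ---------------------------------------------------------------------------
# Folds and rounds
# ---------------------------------------------------------------------------


def make_fold_plan(
    ids: list[str], seed: int | None = None, preset: str | None = None
) -> FoldPlan:
    """Pair the training ids into held-out test pairs, one pair per round.

    ``preset='table'`` reproduces the published fixed assignment (valid only
    for the original eight subject ids); otherwise the pairing is a seeded
    random partition.
    """
    ids = list(ids)
    if preset == "table":
        expected = {sid for pair in TABLE_FOLD_TEST_PAIRS for sid in pair}
        if set(ids) != expected:
            raise ValueError(
                "the published fold preset applies only to the original "
                f"training ids {sorted(expected)}"
            )
        rounds = tuple(
            {
                "test_ids": list(pair),
                "train_ids": [sid for sid in ids if sid not in pair],
            }
            for pair in TABLE_FOLD_TEST_PAIRS
        )
        return FoldPlan(rounds=rounds, seed=None)
    if len(ids) % 2 != 0 or not ids:
        raise ValueError(f"need an even, positive number of ids, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    rounds = tuple(
        {
            "test_ids": order[i : i + 2],
            "train_ids": [sid for sid in ids if sid not in order[i : i + 2]],
        }
        for i in range(0, len(order), 2)
    )
    return FoldPlan(rounds=rounds, seed=seed)


@dataclass(frozen=True)
class RoundResult:
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    test_ids: tuple[str, ...]
    control_ids: tuple[str, ...]


@dataclass(frozen=True)
class ValidationReport:
    rounds: tuple[RoundResult, ...]
    averages: dict[str, float]
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {
                    "confusion": r.confusion.to_dict(),
                    "metrics": r.metrics,
                    "test_ids": list(r.test_ids),
                    "control_ids": list(r.control_ids),
                }
                for r in self.rounds
            ],
            "averages": self.averages,
            "config": self.config,
        }


def _tally(level: str, is_prediabetes: bool, counts: dict) -> None:
    # Medium counts as a correct call for the subject's true class
    if level == "Medium":
        counts["tp" if is_prediabetes else "tn"] += 1
    elif level == "High":
        counts["tp" if is_prediabetes else "fp"] += 1
    else:  # Low
        counts["fn" if is_prediabetes else "tn"] += 1


def evaluate_round(
    cohort: Cohort,
    round_entry: dict,
    config: TrainingConfig = TrainingConfig(),
    *,
    synthetic_subjects: list[SubjectRecord] | None = None,
    n_controls: int = 19,
    control_seed: int = 0,
) -> RoundResult:
    """Train on the round's training subjects; score held-out + synthetic +
    sampled controls.

    Held-out prediabetes data never reaches the trained model: the model is
    fit on the ``train_ids`` subjects only.
    """
    controls = cohort.group_subjects(Group.CONTROL)
    if len(controls) < n_controls:
        raise ValueError(
            f"round needs {n_controls} controls, cohort has {len(controls)}"
        )
    model = scoring.train(cohort.subset(round_entry["train_ids"]), config)

    rng = np.random.default_rng(control_seed)
    picked = [controls[i] for i in rng.choice(len(controls), n_controls, replace=False)]

    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for sid in round_entry["test_ids"]:
        _tally(classify_subject(cohort.subject(sid), model).level, True, counts)
    for s in synthetic_subjects or []:
        _tally(classify_subject(s, model).level, True, counts)
    for s in picked:
        _tally(classify_subject(s, model).level, False, counts)

    cm = ConfusionMatrix(**counts)
    return RoundResult(
        confusion=cm,
        metrics=confusion_metrics(cm),
        test_ids=tuple(round_entry["test_ids"]),
        control_ids=tuple(s.subject_id for s in picked),
    )


def run_cross_validation(
    cohort: Cohort,
    config: TrainingConfig = TrainingConfig(),
    *,
    folds: str = "random",
    seed: int = 7,
    adasyn_k: int = 5,
    n_controls: int = 19,
    no_leak: bool = False,
) -> ValidationReport:
    """Four-fold cross-validation with ADASYN-augmented test rounds.

    The synthetic prediabetes pool (class gap vs. the controls) is generated
    once per run from all training subjects, as the published protocol's
    counts imply; ``no_leak=True`` instead regenerates it per round from the
    held-out pair only, so no training subject's geometry appears among the
    test items.
    """
    pre = cohort.group_subjects(Group.PREDIABETES)
    controls = cohort.group_subjects(Group.CONTROL)
    pre_ids = [s.subject_id for s in pre]
    plan = make_fold_plan(
        pre_ids,
        seed=seed,
        preset="table" if folds in ("table", "table6") else None,
    )

    majority_vectors = np.asarray([subject_feature_vector(s) for s in controls])

    def _synthesize(source: list[SubjectRecord], gen_seed: int, tag: str):
        vectors = np.asarray([subject_feature_vector(s) for s in source])
        target = len(source) + (len(controls) - len(pre))
        synth = adasyn_augment(
            vectors,
            majority_count=target,
            k_neighbors=adasyn_k,
            seed=gen_seed,
            majority=majority_vectors,
        )
        return [
            vector_to_subject(
                v, f"adasyn-{tag}-{i + 1:03d}", Group.PREDIABETES, cohort.protocol
            )
            for i, v in enumerate(synth)
        ]

    shared_pool = None if no_leak else _synthesize(pre, seed, "all")

    rounds = []
    for r, entry in enumerate(plan.rounds):
        pool = (
            _synthesize(
                [cohort.subject(sid) for sid in entry["test_ids"]],
                seed + 1000 + r,
                f"r{r + 1}",
            )
            if no_leak
            else shared_pool
        )
        rounds.append(
            evaluate_round(
                cohort,
                entry,
                config,
                synthetic_subjects=pool,
                n_controls=n_controls,
                control_seed=seed + 2000 + r,
            )
        )

    averages = {
        name: float(np.mean([r.metrics[name] for r in rounds]))
        for name in ("accuracy", "precision", "recall", "f1")
    }
    return ValidationReport(
        rounds=tuple(rounds),
        averages=averages,
        config={
            "folds": folds,
            "seed": seed,
            "adasyn_k": adasyn_k,
            "n_controls": n_controls,
            "no_leak": no_leak,
            "training": config.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# Rank-sum comparison
# ---------------------------------------------------------------------------


def rank_sum_test(x, y) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the smaller sample has at most 8
    observations and there are no ties, and the normal approximation with
    tie correction otherwise.  Returns ``{"U": ..., "p_two_sided": ...}``
    with U computed for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"U": float(res.statistic), "p_two_sided": float(min(res.pvalue, 1.0))}


def compare_postoxygen_rr(cohort: Cohort) -> dict[str, float]:
    """Rank-sum comparison of the groups' mean RR over the post-oxygen window.

    One interpretation of the published group comparison: each subject is
    summarised by their mean respiratory rate over the post-hyperoxia
    minutes, and the prediabetes and control summaries are compared.
    """
    idx = cohort.protocol.window_minutes - 1
    pre = [s.rr[idx].mean() for s in cohort.group_subjects(Group.PREDIABETES)]
    ctl = [s.rr[idx].mean() for s in cohort.group_subjects(Group.CONTROL)]
    return rank_sum_test(pre, ctl)
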