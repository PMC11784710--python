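"""Synthetic reference-cohort fixture.

:func:`reference_cohort` builds a deterministic eight-subject prediabetes
cohort *engineered by inverse construction* so that the full training path
reproduces the reference association table of :mod:`cbrisk.reference`:

* each subject's glucose series is piecewise linear with head/tail plateaus
  chosen so the severity-level arithmetic yields exactly the reference
  weight;
* each subject's HR and RR series are piecewise-constant block layouts
  designed — and verified, by running the actual clustering path — so that
  K-means at K=6 places the post-stimulus minutes in clusters realizing the
  reference pattern triple for all three variables.

The layouts are frozen; the companion test suite asserts the realization,
so any change to the clustering path that breaks it fails loudly.  The
cohort is synthetic: only its *derived* association table matches the
reference example.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, Group, StimulusProtocol, SubjectRecord
from .reference import REFERENCE_DELTA
from .scoring import AssociationRow

__all__ = ["reference_cohort"]

_T = 80

# Per-subject piecewise-constant layouts, (first_minute, last_minute, value).
# Segment order matters: later segments override earlier ones.  The window
# minutes (11-13) realize the reference patterns through block boundaries
# (DU/DD), single-minute excursions with a time-adjacent home block (DUD),
# singleton combos (T), and — for the (DU, DD) -> DUD subject — an
# intermediate-level block that captures minutes 11 and 13 jointly in 3-D.
_LAYOUTS: dict[str, dict[str, list[tuple[int, int, float]]]] = {
    "20180101001": dict(  # DU, DUD, T
        hr=[(1, 12, 72), (13, 13, 125), (14, 40, 60), (41, 60, 84), (61, 80, 108)],
        rr=[(1, 11, 18), (12, 12, 30), (13, 13, 18), (14, 40, 14), (41, 60, 22),
            (61, 80, 26)],
    ),
    "20180101002": dict(  # DU, DD, DUD
        hr=[(1, 12, 84), (13, 13, 102), (14, 26, 93), (27, 40, 60), (41, 54, 72),
            (55, 67, 114), (68, 80, 126)],
        rr=[(1, 10, 20), (11, 11, 28), (12, 13, 20), (14, 26, 24), (27, 40, 12),
            (41, 54, 16), (55, 67, 32), (68, 80, 35)],
    ),
    "20180101003": dict(  # DU, DD, T
        hr=[(1, 12, 72), (13, 30, 96), (31, 48, 60), (49, 64, 84), (65, 80, 108)],
        rr=[(1, 11, 18), (12, 30, 26), (31, 48, 12), (49, 64, 22), (65, 80, 30)],
    ),
    "20180101004": dict(  # S, DUD, DUD
        hr=[(1, 16, 84), (17, 40, 60), (41, 60, 100), (61, 80, 70)],
        rr=[(1, 11, 18), (12, 12, 26), (13, 13, 18), (14, 24, 26), (25, 40, 12),
            (41, 60, 22), (61, 80, 31)],
    ),
    "20180101005": dict(  # DUD, DD, DUD
        hr=[(1, 14, 84), (12, 12, 108), (15, 26, 108), (27, 44, 60), (45, 62, 96),
            (63, 80, 72)],
        rr=[(1, 11, 20), (12, 26, 23), (27, 44, 12), (45, 62, 16), (63, 80, 29)],
    ),
    "20180101006": dict(  # DD, DU, T
        hr=[(1, 11, 72), (12, 30, 96), (31, 48, 60), (49, 64, 84), (65, 80, 108)],
        rr=[(1, 12, 18), (13, 30, 26), (31, 48, 12), (49, 64, 22), (65, 80, 30)],
    ),
    "20180101007": dict(  # DU, DUD, DU
        hr=[(1, 12, 84), (13, 26, 108), (27, 44, 60), (45, 62, 96), (63, 80, 72)],
        rr=[(1, 11, 20), (12, 12, 23), (13, 13, 20), (14, 26, 23), (27, 44, 12),
            (45, 62, 16), (63, 80, 29)],
    ),
    "20180101008": dict(  # DD, DUD, DUD
        hr=[(1, 11, 84), (12, 26, 88), (27, 44, 60), (45, 62, 104), (63, 80, 72)],
        rr=[(1, 11, 20), (12, 12, 32), (13, 14, 20), (15, 26, 32), (27, 44, 12),
            (45, 62, 16), (63, 80, 26)],
    ),
}

# Head-plateau glucose (mg/dL) per subject; the first subject echoes the
# worked severity-level example (head term exactly 93).
_GLUCOSE_HEAD = {sid: 90.0 for sid in _LAYOUTS}
_GLUCOSE_HEAD["20180101001"] = 93.0


def _series(segments: list[tuple[int, int, float]]) -> np.ndarray:
    arr = np.zeros(_T)
    for lo, hi, v in segments:
        arr[lo - 1 : hi] = v
    return arr


def _glucose_for_weight(target_w: float, head: float, t_g: int = 34, T_g: int = 55
                        ) -> np.ndarray:
    """Invert the severity-level arithmetic: constant head and tail plateaus
    with a linear ramp between, such that SL = 100 * target_w exactly."""
    tail = (T_g - t_g) * (100.0 * target_w - head) / (_T - T_g + 1)
    g = np.empty(_T)
    g[:t_g] = head
    g[T_g - 1 :] = tail
    ramp = np.linspace(head, tail, T_g - t_g + 1)  # minutes t_g .. T_g
    g[t_g - 1 : T_g] = ramp
    return g


def reference_cohort() -> tuple[Cohort, tuple[AssociationRow, ...]]:
    """The engineered training cohort and the association table it realizes.

    Training this cohort with the default configuration (K=6, seed 13)
    reproduces the reference score matrix and maximum risk.
    """
    subjects = []
    for row in REFERENCE_DELTA:
        lay = _LAYOUTS[row.subject_id]
        subjects.append(
            SubjectRecord(
                subject_id=row.subject_id,
                group=Group.PREDIABETES,
                minutes=np.arange(1, _T + 1),
                hr=_series(lay["hr"]),
                rr=_series(lay["rr"]),
                glucose=_glucose_for_weight(
                    row.weight, _GLUCOSE_HEAD[row.subject_id]
                ),
            )
        )
    return Cohort(subjects=tuple(subjects), protocol=StimulusProtocol()), REFERENCE_DELTA
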