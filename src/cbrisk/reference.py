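"""Reference worked example of the training arithmetic.

These constants hold the worked example used throughout the documentation
and tests: an eight-subject training group's association table (weights and
cluster patterns), the score matrix derived from it, and the resulting
maximum risk and band boundaries.  The score-matrix and maximum-risk values
are quoted to two decimals as conventionally printed (truncated, not
rounded); recomputing them from the association rows at full precision is
what the tests do.
"""

from __future__ import annotations

import numpy as np

from .scoring import AssociationRow, ScoreMatrix

__all__ = [
    "REFERENCE_DELTA",
    "REFERENCE_PSI",
    "REFERENCE_CHI",
    "REFERENCE_THRESHOLDS",
    "REFERENCE_TOTAL_WEIGHT",
]

#: Association table Δ of the reference training group: one row per subject
#: with the glucose-derived weight and the HR / RR / RRxHR window patterns.
REFERENCE_DELTA: tuple[AssociationRow, ...] = tuple(
    AssociationRow(subject_id=sid, weight=w, patterns={"HR": p1, "RR": p2, "RRxHR": p3})
    for sid, w, p1, p2, p3 in [
        ("20180101001", 2.1815, "DU", "DUD", "T"),
        ("20180101002", 2.8356, "DU", "DD", "DUD"),
        ("20180101003", 2.476, "DU", "DD", "T"),
        ("20180101004", 2.175, "S", "DUD", "DUD"),
        ("20180101005", 1.5246, "DUD", "DD", "DUD"),
        ("20180101006", 1.6958, "DD", "DU", "T"),
        ("20180101007", 2.1543, "DU", "DUD", "DU"),
        ("20180101008", 2.8676, "DD", "DUD", "DUD"),
    ]
)

#: Score matrix of the reference example, two-decimal figures as printed.
#: Rows (DU, DD, DUD, S, T) x columns (HR, RR, RRxHR).
REFERENCE_PSI = ScoreMatrix(
    values=np.array(
        [
            [9.64, 1.69, 2.15],
            [4.56, 6.83, 0.0],
            [1.52, 9.37, 9.4],
            [2.175, 0.0, 0.0],
            [0.0, 0.0, 6.35],
        ]
    )
)

#: Maximum risk of the reference score matrix (sum of column maxima).
REFERENCE_CHI = 28.41

#: The Low/Medium and Medium/High boundaries at χ/3 and 2χ/3.
REFERENCE_THRESHOLDS = (9.47, 18.94)

#: Sum of the eight reference weights.
REFERENCE_TOTAL_WEIGHT = 17.9104
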