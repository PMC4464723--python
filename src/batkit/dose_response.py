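"""The basophil allergen threshold sensitivity statistic (BAT AC50).

For each subject x allergen, activation (%CD63+) is measured over a serial
dilution series and plotted against the log10 dilution factor *d*.  The AC50
is the lowest allergen concentration — i.e. the *largest* *d* — at which the
piecewise-linear interpolant of the response reaches half of the activation
measured in the stimulation control.  Larger AC50 means the subject reacts to
more dilute allergen: greater sensitivity.

Censoring and non-response:

* activation still at or above threshold at the most dilute tested point:
  right-censored at ``d_max`` (the true threshold lies beyond the range);
* activation below threshold at every tested point: ``non_responder`` for
  this statistic (no value);
* ``left_censored_at_min_dilution`` is reserved for curves whose only
  threshold contact would lie below the tested range; with node-anchored
  linear interpolation this cannot arise from measured points, but the status
  is part of the result vocabulary for completeness.

Non-monotone (hook-effect) curves may cross the threshold several times; the
"lowest concentration able to activate" reading selects the most dilute
(largest *d*) crossing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .dilution import DilutionSeries
from .gating import ActivationMeasurement, QCStatus

__all__ = [
    "AC50Status",
    "DoseResponseCurve",
    "AC50Result",
    "build_curve",
    "ac50",
    "ac50_cohort",
    "scores_for_ranks",
]

logger = logging.getLogger(__name__)


class AC50Status(str, Enum):
    INTERPOLATED = "interpolated"
    RIGHT_CENSORED = "right_censored_at_max_dilution"
    LEFT_CENSORED = "left_censored_at_min_dilution"
    NON_RESPONDER = "non_responder"


@dataclass
class DoseResponseCurve:
    """Ordered (d, activation) points for one subject x allergen."""

    subject_id: str
    allergen: str
    d: np.ndarray
    activation: np.ndarray
    positive_control_activation: float

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.activation = np.asarray(self.activation, dtype=float)
        if self.d.size != self.activation.size:
            raise ValueError("d and activation lengths differ")
        if self.d.size < 2:
            raise ValueError("a dose-response curve needs at least 2 points")
        if not np.all(np.diff(self.d) > 0):
            raise ValueError("d must be strictly increasing")
        if np.any(self.activation < 0) or np.any(self.activation > 100):
            raise ValueError("activation must be in [0, 100]")


@dataclass
class AC50Result:
    """AC50 for one subject x allergen, with censoring status.

    ``value`` is in log10 dilution units and is ``None`` exactly when
    ``status`` is ``non_responder``.  ``threshold_used`` is half the
    positive-control activation, in percent.
    """

    subject_id: str
    allergen: str
    value: float | None
    status: AC50Status
    threshold_used: float


def build_curve(
    measurements: list[ActivationMeasurement],
    series: DilutionSeries,
    positive_control_activation: float,
) -> DoseResponseCurve:
    """Assemble a subject's dose-response curve from per-tube measurements.

    All measurements must belong to one subject and to ``series.allergen``;
    steps are mapped to *d* by the series' convention and sorted increasing.
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 measurements to build a curve")
    subjects = {m.subject_id for m in measurements}
    if len(subjects) != 1:
        raise ValueError(f"measurements span several subjects: {sorted(subjects)}")
    stimuli = {m.stimulus for m in measurements}
    if stimuli != {series.allergen}:
        raise ValueError(
            f"measurements are for {sorted(stimuli)}, series is {series.allergen!r}"
        )
    steps = [m.dilution_step for m in measurements]
    if len(set(steps)) != len(steps):
        raise ValueError(f"duplicate dilution steps: {sorted(steps)}")
    order = np.argsort(steps)
    d = series.log10_dilution(np.asarray(steps, dtype=float)[order])
    act = np.asarray([m.percent_cd63_positive for m in measurements])[order]
    return DoseResponseCurve(
        subject_id=measurements[0].subject_id,
        allergen=series.allergen,
        d=d,
        activation=act,
        positive_control_activation=float(positive_control_activation),
    )


def ac50(curve: DoseResponseCurve) -> AC50Result:
    """AC50 by linear interpolation at half the stimulation-control response.

    The threshold is ``T = positive_control_activation / 2``.  Scanning the
    piecewise-linear curve, the crossing at the largest *d* is returned
    (status ``interpolated``); if the most dilute point is still at or above
    *T* the result is right-censored at ``d_max``; if no point reaches *T*
    the subject is a non-responder for this statistic.  A node lying exactly
    on *T* at the boundary of the most dilute exceedance yields that node's
    *d* exactly.
    """
    pc = curve.positive_control_activation
    if pc <= 0:
        raise ValueError(
            f"positive-control activation must be > 0, got {pc} "
            f"(subject {curve.subject_id!r} should have been QC-excluded)"
        )
    T = 0.5 * pc
    a = curve.activation
    d = curve.d
    common = dict(
        subject_id=curve.subject_id, allergen=curve.allergen, threshold_used=T
    )
    if a[-1] >= T:
        return AC50Result(
            value=float(d[-1]), status=AC50Status.RIGHT_CENSORED, **common
        )
    if np.all(a < T):
        return AC50Result(value=None, status=AC50Status.NON_RESPONDER, **common)
    # a[-1] < T and some a[i] >= T: the largest-d threshold contact is a
    # downward crossing on the last segment whose left node is >= T.
    i = int(np.max(np.nonzero(a >= T)[0]))
    value = d[i] + (a[i] - T) / (a[i] - a[i + 1]) * (d[i + 1] - d[i])
    return AC50Result(value=float(value), status=AC50Status.INTERPOLATED, **common)


def ac50_cohort(
    curves: list[DoseResponseCurve],
    qc: list[QCStatus],
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """AC50 for every curve of QC-included subjects.

    QC-excluded subjects are dropped (and counted in the log); non-responders
    are carried as rows with status ``non_responder`` and a missing value so
    downstream statistics can choose their handling.  Right-censored values
    enter at ``d_max`` with a logged warning.

    Returns a DataFrame with columns subject_id, group, allergen, ac50,
    status, threshold_used.
    """
    included = {s.subject_id for s in qc if s.included}
    n_excluded = sum(1 for c in curves if c.subject_id not in included)
    if n_excluded:
        logger.info("ac50_cohort: dropping %d curve(s) of QC-excluded subjects",
                    n_excluded)
    rows = []
    for c in curves:
        if c.subject_id not in included:
            continue
        r = ac50(c)
        if r.status is AC50Status.RIGHT_CENSORED:
            logger.warning(
                "AC50 right-censored at d_max=%.3f for subject %s / %s",
                r.value, r.subject_id, r.allergen,
            )
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": (groups or {}).get(r.subject_id, ""),
                "allergen": r.allergen,
                "ac50": np.nan if r.value is None else r.value,
                "status": r.status.value,
                "threshold_used": r.threshold_used,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "allergen", "ac50", "status",
                 "threshold_used"],
    )


def scores_for_ranks(
    table: pd.DataFrame, non_responder_policy: str = "zero"
) -> pd.DataFrame:
    """Scores for rank-based statistics (group tests, ROC) from an AC50 table.

    ``non_responder_policy``: ``"zero"`` (default) assigns non-responders the
    minimal sensitivity 0; ``"exclude"`` drops them.  Censored values always
    enter at their censoring bound.
    """
    if non_responder_policy not in ("zero", "exclude"):
        raise ValueError(f"unknown non_responder_policy {non_responder_policy!r}")
    out = table.copy()
    nr = out["status"] == AC50Status.NON_RESPONDER.value
    if non_responder_policy == "zero":
        out.loc[nr, "ac50"] = 0.0
    else:
        out = out[~nr]
    return out
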