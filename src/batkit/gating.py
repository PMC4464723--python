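"""Basophil gating, CD63 positivity and subject-level quality control.

The gating strategy mirrors routine BAT practice: basophils are identified as
CD203c-positive, SSC-low events; the CD63 positivity threshold is set once per
subject from that subject's negative-control tube and reused for every tube of
the same subject; activation is the percentage of gated basophils whose CD63
exceeds that threshold.

Quality control (subject level):

* spontaneous activation above 10 % of basophils in the negative control
  excludes the subject;
* a positive-control response below the responder floor (default 10 %)
  excludes the subject as a stimulation-control non-responder;
* per allergen, a subject is a *responder* when the maximal %CD63+ across the
  dilution series reaches the 15 % positivity cutoff (boundary inclusive).

Threshold rules
---------------
Where a human operator places gates by eye, this module uses reproducible
surrogates.  The CD203c basophil gate is an Otsu-style between-class-variance
split on the log scale, guarded by a separation ratio: if the two putative
components are not separated by at least ``min_separation`` pooled
within-class standard deviations the population is treated as unimodal (all
events pass, or an absolute ``cd203c_min`` floor applies if configured).  The
SSC cut is taken relative to the CD203c-high population and only applies when
a CD203c split was actually found; this makes gating idempotent.

The CD63 threshold is a parametric upper quantile of the resting
(non-activated) negative-control population: location and scale are estimated
robustly on the log scale (median, and lower-half spread), so spontaneously
activated cells — the very thing the 10 % QC rule must detect — cannot drag
the threshold upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EventTable",
    "GatingConfig",
    "BasophilGate",
    "ActivationMeasurement",
    "QCStatus",
    "InsufficientEventsError",
    "gate_basophils",
    "set_cd63_threshold",
    "percent_activated",
    "qc_subject",
    "measure_cohort",
]


class InsufficientEventsError(RuntimeError):
    """Too few basophil events to compute a subject-level quantity."""


@dataclass
class EventTable:
    """Per-tube flow-cytometry events (one entry per event).

    Channels are arbitrary positive fluorescence/scatter units.  The optional
    ``truth_*`` masks are generator ground truth used by tests; they survive
    subsetting but are never written to event CSVs.
    """

    ssc: np.ndarray
    cd203c: np.ndarray
    cd63: np.ndarray
    subject_id: str = ""
    stimulus: str = ""
    dilution_step: int | None = None
    truth_basophil: np.ndarray | None = None
    truth_activated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ssc = np.asarray(self.ssc, dtype=float)
        self.cd203c = np.asarray(self.cd203c, dtype=float)
        self.cd63 = np.asarray(self.cd63, dtype=float)
        n = self.ssc.size
        if n < 1:
            raise ValueError("EventTable requires at least one event")
        if self.cd203c.size != n or self.cd63.size != n:
            raise ValueError("EventTable channel lengths differ")
        for name in ("ssc", "cd203c", "cd63"):
            x = getattr(self, name)
            if not np.all(np.isfinite(x)) or np.any(x <= 0):
                raise ValueError(f"EventTable.{name} must be finite and positive")

    @property
    def n_events(self) -> int:
        return int(self.ssc.size)

    def subset(self, mask: np.ndarray) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        return EventTable(
            ssc=self.ssc[mask],
            cd203c=self.cd203c[mask],
            cd63=self.cd63[mask],
            subject_id=self.subject_id,
            stimulus=self.stimulus,
            dilution_step=self.dilution_step,
            truth_basophil=None
            if self.truth_basophil is None
            else self.truth_basophil[mask],
            truth_activated=None
            if self.truth_activated is None
            else self.truth_activated[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ssc": self.ssc, "cd203c": self.cd203c, "cd63": self.cd63}
        )

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, subject_id="", stimulus="", dilution_step=None
    ) -> "EventTable":
        return cls(
            ssc=df["ssc"].to_numpy(),
            cd203c=df["cd203c"].to_numpy(),
            cd63=df["cd63"].to_numpy(),
            subject_id=subject_id,
            stimulus=stimulus,
            dilution_step=dilution_step,
        )


@dataclass(frozen=True)
class GatingConfig:
    """Tunable gating and QC parameters (defaults are the study rules)."""

    #: Quantile of the resting negative-control CD63 distribution that defines
    #: the positivity threshold.
    cd63_baseline_quantile: float = 0.995
    #: %CD63+ at or above which a test is positive / a subject responds.
    positive_test_cutoff: float = 15.0
    #: Negative-control %CD63+ strictly above this excludes the subject.
    spontaneous_exclusion_cutoff: float = 10.0
    #: Positive-control %CD63+ strictly below this marks a stimulation-control
    #: non-responder (the quantitative floor is a package choice).
    posctrl_responder_floor: float = 10.0
    min_basophils: int = 200
    #: SSC quantile of the CD203c-high population below which events are kept.
    ssc_quantile: float = 0.995
    #: Minimal CD203c between-component separation (pooled within-sd units)
    #: for the split to be accepted as bimodal.
    min_separation: float = 4.0
    #: Optional absolute CD203c floor used when no bimodal split is found.
    cd203c_min: float | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.cd63_baseline_quantile < 1.0:
            raise ValueError(
                "cd63_baseline_quantile must be in (0.5, 1), got "
                f"{self.cd63_baseline_quantile}"
            )
        for name in ("positive_test_cutoff", "spontaneous_exclusion_cutoff",
                     "posctrl_responder_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must be in (0, 100), got {v}")
        if self.min_basophils < 1:
            raise ValueError(f"min_basophils must be >= 1, got {self.min_basophils}")


@dataclass
class BasophilGate:
    """A gated tube: the basophil subset plus the thresholds used.

    ``cd203c_threshold`` is ``-inf`` when the population was unimodal and no
    absolute floor applied; ``ssc_threshold`` is ``+inf`` when no SSC cut was
    applied.  ``insufficient_events`` flags tubes whose gated count fell below
    the configured minimum — the tube is flagged, never silently dropped.
    ``basophils`` is ``None`` only when no event passed the gate at all.
    """

    basophils: EventTable | None
    cd203c_threshold: float
    ssc_threshold: float
    insufficient_events: bool

    @property
    def n_basophils(self) -> int:
        return self.basophils.n_events if self.basophils is not None else 0


def _otsu_split(x: np.ndarray) -> tuple[float, float]:
    """Best two-class split of 1-D data by between-class variance.

    Returns ``(threshold, separation)`` where *threshold* is the midpoint
    between the two classes' adjacent order statistics and *separation* is the
    distance between class means in pooled within-class-sd units.
    """
    xs = np.sort(x)
    n = xs.size
    if n < 2 or xs[0] == xs[-1]:
        return float(xs[0]), 0.0
    c1 = np.cumsum(xs)
    c2 = np.cumsum(xs**2)
    k = np.arange(1, n)  # lower class = first k order statistics
    m1 = c1[k - 1] / k
    m2 = (c1[-1] - c1[k - 1]) / (n - k)
    w1 = k / n
    between = w1 * (1 - w1) * (m1 - m2) ** 2
    # forbid splits between tied values (zero-width boundary)
    between[xs[k] == xs[k - 1]] = -np.inf
    i = int(np.argmax(between))
    kk = i + 1
    v1 = c2[kk - 1] / kk - m1[i] ** 2
    v2 = (c2[-1] - c2[kk - 1]) / (n - kk) - m2[i] ** 2
    pooled = np.sqrt(max((kk * v1 + (n - kk) * v2) / n, 1e-30))
    sep = (m2[i] - m1[i]) / pooled
    thr = 0.5 * (xs[kk - 1] + xs[kk])
    return float(thr), float(sep)


def gate_basophils(
    events: EventTable,
    config: GatingConfig = GatingConfig(),
    gate: BasophilGate | None = None,
) -> BasophilGate:
    """Select the basophil population (CD203c-positive, SSC-low).

    When ``gate`` is given its thresholds are re-applied unchanged — used to
    keep the gate identical across all tubes of one subject.  Otherwise the
    CD203c threshold is estimated by the Otsu-style split (see module notes)
    and the SSC threshold as the configured quantile of the CD203c-high
    population's SSC.
    """
    if gate is not None:
        t203, t_ssc = gate.cd203c_threshold, gate.ssc_threshold
    else:
        log203 = np.log(events.cd203c)
        thr_log, sep = _otsu_split(log203)
        if sep >= config.min_separation:
            t203 = float(np.exp(thr_log))
            high = events.cd203c > t203
            t_ssc = float(
                np.quantile(events.ssc[high], config.ssc_quantile, method="higher")
            )
        elif config.cd203c_min is not None:
            t203 = float(config.cd203c_min)
            t_ssc = np.inf
        else:
            # unimodal, no floor configured: treat everything as candidate
            # basophils (the tube is a pre-gated or single-population sample)
            t203, t_ssc = -np.inf, np.inf
    mask = (events.cd203c > t203) & (events.ssc <= t_ssc)
    n_gated = int(mask.sum())
    return BasophilGate(
        basophils=events.subset(mask) if n_gated else None,
        cd203c_threshold=t203,
        ssc_threshold=t_ssc,
        insufficient_events=n_gated < config.min_basophils,
    )


def set_cd63_threshold(
    negctrl_basophils: EventTable, config: GatingConfig = GatingConfig()
) -> float:
    """CD63 positivity threshold from a subject's negative-control basophils.

    Parametric ``cd63_baseline_quantile`` of the resting population: on the
    log scale, location = median and scale = (median - Q25) / z(0.75), both
    insensitive to an upper tail of spontaneously activated cells.  For a
    point-mass distribution the threshold equals that constant.
    """
    if negctrl_basophils.n_events < config.min_basophils:
        raise InsufficientEventsError(
            f"negative control of subject {negctrl_basophils.subject_id!r} has "
            f"{negctrl_basophils.n_events} basophils "
            f"(minimum {config.min_basophils})"
        )
    logx = np.log(negctrl_basophils.cd63)
    mu = float(np.median(logx))
    spread = mu - float(np.quantile(logx, 0.25))
    sigma = spread / sps.norm.ppf(0.75)
    z = sps.norm.ppf(config.cd63_baseline_quantile)
    return float(np.exp(mu + z * sigma))


@dataclass
class ActivationMeasurement:
    """%CD63+ of gated basophils in one tube, with the threshold used."""

    subject_id: str
    stimulus: str
    dilution_step: int | None
    n_basophils: int
    percent_cd63_positive: float
    cd63_threshold: float
    insufficient_events: bool = False


def percent_activated(
    basophils: EventTable, threshold: float
) -> ActivationMeasurement:
    """Percentage of basophils with CD63 strictly above the threshold."""
    n = basophils.n_events
    pct = 100.0 * float(np.count_nonzero(basophils.cd63 > threshold)) / n
    return ActivationMeasurement(
        subject_id=basophils.subject_id,
        stimulus=basophils.stimulus,
        dilution_step=basophils.dilution_step,
        n_basophils=n,
        percent_cd63_positive=pct,
        cd63_threshold=float(threshold),
    )


@dataclass
class QCStatus:
    """Subject-level exclusion flags and per-allergen responder flags."""

    subject_id: str
    excluded_spontaneous: bool
    excluded_posctrl_nonresponder: bool
    responder: dict[str, bool] = field(default_factory=dict)
    negctrl_percent: float = float("nan")
    posctrl_percent: float = float("nan")
    excluded_insufficient_events: bool = False

    @property
    def included(self) -> bool:
        return not (
            self.excluded_spontaneous
            or self.excluded_posctrl_nonresponder
            or self.excluded_insufficient_events
        )

    @property
    def exclusion_reasons(self) -> list[str]:
        reasons = []
        if self.excluded_spontaneous:
            reasons.append("spontaneous_activation")
        if self.excluded_posctrl_nonresponder:
            reasons.append("posctrl_nonresponder")
        if self.excluded_insufficient_events:
            reasons.append("insufficient_events")
        return reasons


def qc_subject(
    measurements: list[ActivationMeasurement],
    config: GatingConfig = GatingConfig(),
) -> QCStatus:
    """Apply the subject-level QC rules to one subject's measurements.

    Requires the negative- and positive-control measurements to be present.
    Exclusion for spontaneous activation is strict (> cutoff); the responder
    flag per allergen is boundary-inclusive (>= positivity cutoff).
    """
    subject_ids = {m.subject_id for m in measurements}
    if len(subject_ids) != 1:
        raise ValueError(f"measurements span several subjects: {sorted(subject_ids)}")
    by_stim: dict[str, list[ActivationMeasurement]] = {}
    for m in measurements:
        by_stim.setdefault(m.stimulus, []).append(m)
    if "negctrl" not in by_stim or "posctrl" not in by_stim:
        raise ValueError(
            f"subject {subject_ids.pop()!r}: control tubes missing "
            f"(have {sorted(by_stim)})"
        )
    neg = by_stim["negctrl"][0]
    pos = by_stim["posctrl"][0]
    status = QCStatus(
        subject_id=neg.subject_id,
        excluded_spontaneous=neg.percent_cd63_positive
        > config.spontaneous_exclusion_cutoff,
        excluded_posctrl_nonresponder=pos.percent_cd63_positive
        < config.posctrl_responder_floor,
        negctrl_percent=neg.percent_cd63_positive,
        posctrl_percent=pos.percent_cd63_positive,
        excluded_insufficient_events=any(
            m.insufficient_events for m in (neg, pos)
        ),
    )
    for stimulus, ms in by_stim.items():
        if stimulus in ("negctrl", "posctrl"):
            continue
        status.responder[stimulus] = (
            max(m.percent_cd63_positive for m in ms) >= config.positive_test_cutoff
        )
    return status


def measure_cohort(
    cohort,
    config: GatingConfig = GatingConfig(),
) -> tuple[list[ActivationMeasurement], list[QCStatus]]:
    """Gate and measure every tube of a cohort, then QC every subject.

    The basophil gate and the CD63 threshold are estimated once per subject
    from the negative-control tube and reused for all of that subject's tubes.
    Subjects whose negative control has too few basophils are excluded with an
    ``insufficient_events`` flag rather than aborting the run.
    """
    measurements: list[ActivationMeasurement] = []
    statuses: list[QCStatus] = []
    manifest = cohort.manifest
    for subject_id, tubes in manifest.groupby("subject_id", sort=False):
        neg_rows = tubes[tubes["stimulus"] == "negctrl"]
        if neg_rows.empty:
            raise ValueError(f"subject {subject_id!r} has no negative-control tube")
        neg_events = cohort.events[neg_rows.iloc[0]["tube_id"]]
        gate = gate_basophils(neg_events, config)
        try:
            if gate.insufficient_events:
                raise InsufficientEventsError(
                    f"negative control of subject {subject_id!r} has "
                    f"{gate.n_basophils} basophils"
                )
            threshold = set_cd63_threshold(gate.basophils, config)
        except InsufficientEventsError:
            statuses.append(
                QCStatus(
                    subject_id=str(subject_id),
                    excluded_spontaneous=False,
                    excluded_posctrl_nonresponder=False,
                    excluded_insufficient_events=True,
                )
            )
            continue
        subject_measurements = []
        for _, row in tubes.iterrows():
            ev = cohort.events[row["tube_id"]]
            g = gate_basophils(ev, config, gate=gate)
            m = percent_activated(g.basophils, threshold)
            m.insufficient_events = g.insufficient_events
            subject_measurements.append(m)
        measurements.extend(subject_measurements)
        statuses.append(qc_subject(subject_measurements, config))
    return measurements, statuses
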