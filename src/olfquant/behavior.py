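"""Behavioral statistics for odor-port investigation experiments.

The raw behavioral readout is a stream of infrared beam-break intervals at an
odor port, recorded against a schedule of air and odor epochs.  From these the
module computes the statistics used to score innate preference, habituation /
dishabituation, detection thresholds, and operant task performance:

* ``epoch_durations`` — per-epoch investigation time (T), event counts, and the
  air baseline average ``TAve.Air = ΣTAir / N``.
* ``preference_index`` — ``PI = 100 · (TOdor1 + TOdor2 − 2·TAir) / (4·TAve.Air)``,
  contrasting the first two odor epochs against the last baseline air epoch.
  Positive values indicate attraction, negative aversion.
* ``npi`` / ``delta_npi`` — normalized port investigation (T / TAve.Air) and the
  novel-vs-habituated difference ``ΔNPI = 100 · (TOdor2.1 − TOdor1.5) / TAve.Air``.
* ``dishabituation_threshold_scan`` — per-concentration paired comparison of
  odor NPI against flanking-air NPI, reporting the lowest concentration whose
  p-value drops below α.
* success rates for the two-alternative-choice and Go/No-Go operant tasks.
* spike-train inter-spike-interval (ISI) statistics with a one-way ANOVA on the
  per-train mean log ISI (olfactory sensory neuron ISIs are well described by a
  lognormal distribution, so log ISI is the natural scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScheduleError",
    "BaselineError",
    "Epoch",
    "EpochSchedule",
    "EventStream",
    "EpochSummary",
    "PreferenceResult",
    "ThresholdScanResult",
    "SpikeTrain",
    "IsiStatsResult",
    "AnovaResult",
    "preference_schedule",
    "cross_habituation_schedule",
    "dishabituation_schedule",
    "epoch_durations",
    "preference_index",
    "npi",
    "delta_npi",
    "cross_habituation_delta_npi",
    "dishabituation_threshold_scan",
    "success_rate_two_choice",
    "success_rate_go_nogo",
    "isi_statistics",
    "group_anova",
]


class ScheduleError(ValueError):
    """Raised for invalid epoch schedules (empty, unordered, overlapping)."""


class BaselineError(ValueError):
    """Raised when a statistic needs a positive air baseline and has none."""


# ---------------------------------------------------------------------------
# Epoch schedules and event streams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    """One scored presentation window.

    ``kind`` is ``"air"`` or ``"odor"``; ``concentration`` is in the units the
    experiment used (v/v dilution or mol/l) and is ``None`` for air.
    """

    kind: str
    start_s: float
    end_s: float
    odor_id: str | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("air", "odor"):
            raise ScheduleError(f"epoch kind must be 'air' or 'odor', got {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ScheduleError(
                f"epoch must have end_s > start_s, got [{self.start_s}, {self.end_s}]"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EpochSchedule:
    """Ordered, non-overlapping epochs; gaps between epochs are unscored."""

    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ScheduleError("schedule has no epochs")
        object.__setattr__(self, "epochs", tuple(self.epochs))
        starts = [e.start_s for e in self.epochs]
        if sorted(starts) != starts:
            raise ScheduleError("epochs must be sorted by start time")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_s < a.end_s:
                raise ScheduleError(
                    f"epochs overlap: [{a.start_s},{a.end_s}] and [{b.start_s},{b.end_s}]"
                )

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def end_s(self) -> float:
        return self.epochs[-1].end_s


def _block(kind: str, n: int, start: float, epoch_s: float, gap_s: float,
           odor_id: str | None = None, concentration: float | None = None
           ) -> tuple[list[Epoch], float]:
    epochs = []
    t = start
    for _ in range(n):
        epochs.append(Epoch(kind, t, t + epoch_s, odor_id, concentration))
        t += epoch_s + gap_s
    return epochs, t


def preference_schedule(odor_id: str = "odor", concentration: float = 1e-4,
                        n_air: int = 4, n_odor: int = 4,
                        epoch_s: float = 300.0, gap_s: float = 300.0) -> EpochSchedule:
    """Innate-preference layout: 5-min epochs with 5-min intervals, four air
    presentations followed by four presentations of the test odor."""
    air, t = _block("air", n_air, 0.0, epoch_s, gap_s)
    odor, _ = _block("odor", n_odor, t, epoch_s, gap_s, odor_id, concentration)
    return EpochSchedule(tuple(air + odor))


def cross_habituation_schedule(habituated_odor: str = "odor1", novel_odor: str = "odor2",
                               n_air: int = 8, n_habituated: int = 5, n_novel: int = 3,
                               concentration: float = 1e-4,
                               epoch_s: float = 60.0, gap_s: float = 240.0) -> EpochSchedule:
    """Cross-habituation layout: 1-min presentations with 4-min carrier-air
    intervals; eight air trials, five of the habituating odor, then the novel
    odor."""
    air, t = _block("air", n_air, 0.0, epoch_s, gap_s)
    hab, t = _block("odor", n_habituated, t, epoch_s, gap_s, habituated_odor, concentration)
    nov, _ = _block("odor", n_novel, t, epoch_s, gap_s, novel_odor, concentration)
    return EpochSchedule(tuple(air + hab + nov))


def dishabituation_schedule(concentrations: Sequence[float], odor_id: str = "odor",
                            n_initial_air: int = 8,
                            epoch_s: float = 60.0, gap_s: float = 240.0) -> EpochSchedule:
    """Threshold-determination layout: eight initial air presentations, then the
    odor at the lowest concentration, with two air presentations interleaved
    before each subsequent (increasing) concentration."""
    concentrations = list(concentrations)
    if any(c <= 0 for c in concentrations):
        raise ScheduleError("concentrations must be positive")
    if sorted(concentrations) != concentrations:
        raise ScheduleError("concentrations must be strictly increasing")
    epochs, t = _block("air", n_initial_air, 0.0, epoch_s, gap_s)
    for i, c in enumerate(concentrations):
        if i > 0:
            air, t = _block("air", 2, t, epoch_s, gap_s)
            epochs += air
        odor, t = _block("odor", 1, t, epoch_s, gap_s, odor_id, c)
        epochs += odor
    return EpochSchedule(tuple(epochs))


@dataclass(frozen=True)
class EventStream:
    """Beam-break intervals for one session: sorted, non-overlapping
    ``(onset_s, offset_s)`` pairs.  ``truth`` carries generator ground truth
    when the stream is synthetic."""

    intervals: np.ndarray
    subject_id: str = "subject"
    session_id: str = "session"
    truth: dict | None = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "intervals", iv)
        if len(iv):
            if not np.all(iv[:, 1] > iv[:, 0]):
                raise ValueError("every interval needs offset > onset")
            if not np.all(iv[1:, 0] >= iv[:-1, 1]):
                raise ValueError("intervals must be sorted and non-overlapping")

    @property
    def total_time_s(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0])) if len(self.intervals) else 0.0


# ---------------------------------------------------------------------------
# Epoch summaries
# ---------------------------------------------------------------------------

@dataclass
class EpochSummary:
    """Per-epoch investigation summary.

    ``per_epoch`` has one row per scheduled epoch with columns ``kind``,
    ``odor_id``, ``concentration``, ``start_s``, ``end_s``, ``T`` (seconds of
    beam-break overlap, boundary-spanning bouts clipped), ``n_events`` and
    ``n_long_events`` (clipped bouts strictly longer than ``long_event_s``).  The air
    baseline is the block of air epochs preceding the first odor epoch (all air
    epochs when there is no odor), and ``t_ave_air`` is the arithmetic mean of
    their T values.
    """

    per_epoch: pd.DataFrame
    subject_id: str = "subject"
    baseline_indices: tuple[int, ...] = field(default_factory=tuple)

    @property
    def t_ave_air(self) -> float:
        if not self.baseline_indices:
            return float("nan")
        return float(self.per_epoch.loc[list(self.baseline_indices), "T"].mean())

    def odor_rows(self) -> pd.DataFrame:
        return self.per_epoch[self.per_epoch["kind"] == "odor"]


def epoch_durations(stream: EventStream, schedule: EpochSchedule,
                    long_event_s: float = 1.0) -> EpochSummary:
    """Clip beam-break intervals to each epoch window and total them.

    A bout spanning an epoch boundary contributes its overlap to each side.
    ``n_long_events`` counts clipped-in bouts strictly longer than
    ``long_event_s`` (1 s by default, the raster-plot convention separating
    investigative bouts from brief port checks).
    """
    iv = stream.intervals
    rows = []
    for ep in schedule:
        if len(iv):
            ov = np.minimum(iv[:, 1], ep.end_s) - np.maximum(iv[:, 0], ep.start_s)
            ov = ov[ov > 0]
        else:
            ov = np.empty(0)
        rows.append({
            "kind": ep.kind, "odor_id": ep.odor_id, "concentration": ep.concentration,
            "start_s": ep.start_s, "end_s": ep.end_s,
            "T": float(ov.sum()), "n_events": int(len(ov)),
            "n_long_events": int(np.sum(ov > long_event_s)),
        })
    per_epoch = pd.DataFrame(rows)
    if len(iv) and per_epoch["n_events"].sum() == 0:
        warnings.warn("event stream lies entirely outside the schedule; summary is all zero")
    kinds = per_epoch["kind"].tolist()
    first_odor = kinds.index("odor") if "odor" in kinds else len(kinds)
    baseline = tuple(i for i in range(first_odor) if kinds[i] == "air")
    if not baseline:
        baseline = tuple(i for i, k in enumerate(kinds) if k == "air")
    return EpochSummary(per_epoch=per_epoch, subject_id=stream.subject_id,
                        baseline_indices=baseline)


# ---------------------------------------------------------------------------
# Preference and habituation statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreferenceResult:
    """Preference index and its ingredients (all times in seconds)."""

    pi: float
    t_odor1: float
    t_odor2: float
    t_air_last: float
    t_ave_air: float


def preference_index(summary: EpochSummary) -> PreferenceResult:
    """PI = 100 · (TOdor1 + TOdor2 − 2·TAir) / (4 · TAve.Air).

    TOdor1/TOdor2 are the first two odor epochs, TAir the last baseline air
    epoch.  Positive PI means the odor drew more investigation than habituated
    air (attraction); negative means less (aversion).
    """
    odor = summary.odor_rows()
    if len(odor) < 2:
        raise ScheduleError("preference index needs at least two odor epochs")
    if not summary.baseline_indices:
        raise BaselineError("preference index needs at least one baseline air epoch")
    t_ave = summary.t_ave_air
    if not t_ave > 0:
        raise BaselineError("TAve.Air must be positive to normalize the preference index")
    t1, t2 = (float(t) for t in odor["T"].iloc[:2])
    t_air = float(summary.per_epoch.loc[summary.baseline_indices[-1], "T"])
    pi = 100.0 * (t1 + t2 - 2.0 * t_air) / (4.0 * t_ave)
    return PreferenceResult(pi=pi, t_odor1=t1, t_odor2=t2, t_air_last=t_air, t_ave_air=t_ave)


def npi(t: float, t_ave_air: float) -> float:
    """Normalized port investigation: epoch time over the air-baseline mean."""
    if not t_ave_air > 0:
        raise BaselineError("TAve.Air must be positive to normalize")
    return float(t) / float(t_ave_air)


def delta_npi(summary: EpochSummary, novel_epoch: int, habituated_epoch: int) -> float:
    """ΔNPI = 100 · (T_novel − T_habituated) / TAve.Air, the dishabituation score.

    ``novel_epoch`` and ``habituated_epoch`` index rows of ``summary.per_epoch``
    (typically the first presentation of the test odor and the last presentation
    of the habituating odor).
    """
    per = summary.per_epoch
    for idx in (novel_epoch, habituated_epoch):
        if idx not in per.index:
            raise ScheduleError(f"epoch index {idx} not in summary")
    t_ave = summary.t_ave_air
    if not t_ave > 0:
        raise BaselineError("TAve.Air must be positive to normalize")
    return 100.0 * (float(per.loc[novel_epoch, "T"]) - float(per.loc[habituated_epoch, "T"])) / t_ave


def cross_habituation_delta_npi(summary: EpochSummary) -> float:
    """ΔNPI for a standard cross-habituation session: first presentation of the
    second odor minus last presentation of the first odor."""
    odor = summary.odor_rows()
    ids = odor["odor_id"].tolist()
    distinct = list(dict.fromkeys(ids))
    if len(distinct) < 2:
        raise ScheduleError("cross-habituation needs two distinct odors")
    novel_id = distinct[1]
    novel_idx = odor.index[odor["odor_id"] == novel_id][0]
    hab_idx = odor.index[odor["odor_id"] == distinct[0]][-1]
    return delta_npi(summary, int(novel_idx), int(hab_idx))


# ---------------------------------------------------------------------------
# Dishabituation threshold scan
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScanResult:
    """Per-concentration ΔNPI means and paired-test p-values.

    ``table`` columns: ``concentration``, ``mean_delta_npi``, ``sem_delta_npi``,
    ``p_value`` (NaN with a single subject).  ``threshold_concentration`` is the
    lowest concentration with p < α, or None if no concentration reaches it.
    """

    table: pd.DataFrame
    threshold_concentration: float | None
    alpha: float
    n_subjects: int


def _scan_table_from_summaries(summaries: Sequence[EpochSummary]) -> pd.DataFrame:
    """Tidy (subject, concentration, npi_odor, npi_air) rows from dishabituation
    sessions.  The flanking air for each odor presentation is the pair of air
    epochs immediately preceding it."""
    rows = []
    for s, summary in enumerate(summaries):
        t_ave = summary.t_ave_air
        per = summary.per_epoch
        for idx in per.index[per["kind"] == "odor"]:
            air_before = per.index[(per["kind"] == "air") & (per.index < idx)]
            flank = air_before[-2:]
            rows.append({
                "subject_id": summary.subject_id if summary.subject_id != "subject" else f"s{s}",
                "concentration": float(per.loc[idx, "concentration"]),
                "npi_odor": npi(per.loc[idx, "T"], t_ave),
                "npi_air": npi(float(per.loc[flank, "T"].mean()), t_ave),
            })
    return pd.DataFrame(rows)


def dishabituation_threshold_scan(
    group: Sequence[EpochSummary] | pd.DataFrame,
    alpha: float = 0.05,
) -> ThresholdScanResult:
    """Scan increasing odor concentrations for the detection threshold.

    For each concentration the odor-epoch NPI is compared with the flanking-air
    NPI by a paired t-test across subjects; the detection threshold is reported
    as the lowest concentration with p < ``alpha`` (no multiplicity correction —
    each concentration is its own test).  The mean ΔNPI sequence is returned for
    psychometric fitting.  With a single subject only means are reported.

    ``group`` is either a list of per-subject :class:`EpochSummary` from
    dishabituation sessions, or a tidy frame with columns ``subject_id``,
    ``concentration``, ``npi_odor``, ``npi_air``.
    """
    if isinstance(group, pd.DataFrame):
        tidy = group
    else:
        tidy = _scan_table_from_summaries(group)
    if tidy.empty:
        raise ScheduleError("no odor presentations found in the scan input")
    n_subjects = tidy["subject_id"].nunique()
    rows = []
    for conc, sub in tidy.groupby("concentration", sort=True):
        d = 100.0 * (sub["npi_odor"].to_numpy() - sub["npi_air"].to_numpy())
        if n_subjects >= 2 and len(d) >= 2:
            p = float(sps.ttest_rel(sub["npi_odor"], sub["npi_air"]).pvalue)
            sem = float(sps.sem(d))
        else:
            p, sem = float("nan"), float("nan")
        rows.append({"concentration": float(conc), "mean_delta_npi": float(np.mean(d)),
                     "sem_delta_npi": sem, "p_value": p})
    table = pd.DataFrame(rows).sort_values("concentration", ignore_index=True)
    sig = table[table["p_value"] < alpha]
    threshold = float(sig["concentration"].iloc[0]) if len(sig) else None
    return ThresholdScanResult(table=table, threshold_concentration=threshold,
                               alpha=alpha, n_subjects=int(n_subjects))


# ---------------------------------------------------------------------------
# Operant task success rates
# ---------------------------------------------------------------------------

def success_rate_two_choice(trials: pd.DataFrame) -> float:
    """SR = 100 · (P[A/A] + P[B/B]) / Ptotal for the two-alternative choice task.

    ``trials`` needs ``stimulus`` (``"A"``/``"B"``), ``action`` (``"portA"``/
    ``"portB"``) columns; correct pokes are those matching the stimulus.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = {"A": "portA", "B": "portB"}
    hits = sum(correct[s] == a for s, a in zip(trials["stimulus"], trials["action"]))
    return 100.0 * hits / len(trials)


def success_rate_go_nogo(trials: pd.DataFrame) -> float:
    """SR = 100 · (PCS+ + NPCS−) / (PCS+ + NPCS+ + PCS− + NPCS−).

    Licks to the rewarded CS+ odor and withheld licks to the punished CS−
    both count as successes.  ``trials`` needs ``stimulus`` (``"CS+"``/``"CS-"``)
    and ``action`` (``"lick"``/``"no-lick"``).
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    stim = trials["stimulus"].to_numpy()
    act = trials["action"].to_numpy()
    hits = int(np.sum((stim == "CS+") & (act == "lick")))
    rejections = int(np.sum((stim == "CS-") & (act == "no-lick")))
    return 100.0 * (hits + rejections) / len(trials)


# ---------------------------------------------------------------------------
# Spike trains and ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTrain:
    """Spike times in seconds, strictly increasing, within [0, duration_s]."""

    times_s: np.ndarray
    duration_s: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float).ravel()
        object.__setattr__(self, "times_s", t)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")

    @property
    def isi(self) -> np.ndarray:
        return np.diff(self.times_s)

    @property
    def firing_rate_hz(self) -> float:
        return len(self.times_s) / self.duration_s


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA outcome with optional Tukey-HSD post-hoc table."""

    f: float
    p: float
    df_between: int
    df_within: int
    posthoc: pd.DataFrame | None = None


@dataclass
class IsiStatsResult:
    per_train: pd.DataFrame
    anova: AnovaResult | None


def isi_statistics(trains: Sequence[SpikeTrain],
                   group_labels: Sequence[str] | None = None) -> IsiStatsResult:
    """Per-train firing rate and mean log ISI, plus a one-way ANOVA on mean
    log ISI across groups (the group comparison used for spontaneous activity).

    Trains with fewer than two spikes carry no ISI and are excluded with a
    warning.
    """
    if group_labels is None:
        group_labels = ["all"] * len(trains)
    rows = []
    for i, (train, label) in enumerate(zip(trains, group_labels)):
        if len(train.times_s) < 2:
            warnings.warn(f"train {i} has < 2 spikes; excluded from ISI statistics")
            continue
        rows.append({
            "train": i, "group": label, "n_spikes": len(train.times_s),
            "firing_rate_hz": train.firing_rate_hz,
            "mean_log_isi": float(np.mean(np.log(train.isi))),
        })
    per_train = pd.DataFrame(rows)
    anova = None
    if len(per_train) and per_train["group"].nunique() >= 2:
        groups = [g["mean_log_isi"].to_numpy() for _, g in per_train.groupby("group")]
        if all(len(g) >= 2 for g in groups):
            anova = group_anova(per_train["mean_log_isi"], per_train["group"])
    return IsiStatsResult(per_train=per_train, anova=anova)


def group_anova(values: Iterable[float], group_labels: Iterable[str],
                posthoc: bool = False) -> AnovaResult:
    """Classical one-way ANOVA with an optional Tukey HSD post-hoc.

    When the between-group sum of squares is exactly zero (all group means
    identical) the result is reported as F = 0, p = 1 rather than NaN.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(group_labels))
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == u] for u in uniq]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    dfb, dfw = len(uniq) - 1, len(values) - len(uniq)
    if ssb == 0.0:
        f, p = 0.0, 1.0
    elif ssw == 0.0:
        f, p = float("inf"), 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f, dfb, dfw))
    table = None
    if posthoc:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        hsd = pairwise_tukeyhsd(values, labels)
        table = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return AnovaResult(f=float(f), p=float(p), df_between=dfb, df_within=dfw, posthoc=table)
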