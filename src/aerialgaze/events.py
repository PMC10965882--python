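"""Oculomotor event containers, tabular I/O, and the trial/fixation/saccade
screening procedure.

Events are taken as produced by an eye-tracker's event parser: fixations and
saccades with millisecond onsets relative to stimulus onset and positions in
image pixel coordinates (origin top-left, x rightward, y downward). Recording
starts 100 ms before stimulus onset, so pre-stimulus events carry negative
onsets and are never valid.

Screening proceeds in the order: drop the first recorded fixation of every
trial -> trial-level rules -> participant-level rule -> fixation filters ->
saccade filters. The stages are idempotent: re-screening screened data
removes nothing.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: default column names for delimited event tables
DEFAULT_COLUMNS = {
    "participant": "participant",
    "image": "image",
    "category": "category",
    "event_type": "event_type",
    "onset_ms": "onset_ms",
    "offset_ms": "offset_ms",
    "x_px": "x_px",
    "y_px": "y_px",
    "end_x_px": "end_x_px",
    "end_y_px": "end_y_px",
    "amplitude_dva": "amplitude_dva",
    "correct": "correct",
    "blink": "blink",
}


class FormatError(ValueError):
    """Raised when an event table is missing required columns."""


class ParseError(ValueError):
    """Raised when a cell of an event table cannot be interpreted."""


@dataclass(frozen=True)
class FixationEvent:
    participant_id: str
    image_id: str
    onset_ms: float
    offset_ms: float
    x_px: float
    y_px: float
    is_first: bool = False  # first recorded fixation of the trial

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError(
                f"fixation offset ({self.offset_ms}) must exceed onset "
                f"({self.onset_ms})"
            )

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class SaccadeEvent:
    participant_id: str
    image_id: str
    onset_ms: float
    start_x_px: float
    start_y_px: float
    end_x_px: float
    end_y_px: float
    amplitude_dva: float

    def __post_init__(self):
        if self.amplitude_dva < 0:
            raise ValueError("saccade amplitude must be nonnegative")


@dataclass
class Trial:
    """One participant x image presentation."""

    participant_id: str
    image_id: str
    category: str | None = None
    correct: bool | None = None
    fixations: list[FixationEvent] = field(default_factory=list)
    saccades: list[SaccadeEvent] = field(default_factory=list)
    #: (start_ms, end_ms, is_blink) gaps where the tracker lost the eye
    trackloss_segments: list[tuple[float, float, bool]] = field(default_factory=list)
    viewing_ms: float = 3000.0
    #: set once the recorded first fixation has been discarded, so that
    #: re-screening never drops the (new) earliest surviving fixation
    first_fixation_removed: bool = False

    def __post_init__(self):
        self.fixations = sorted(self.fixations, key=lambda f: f.onset_ms)
        self.saccades = sorted(self.saccades, key=lambda s: s.onset_ms)
        for ev in list(self.fixations) + list(self.saccades):
            if (ev.participant_id, ev.image_id) != (self.participant_id, self.image_id):
                raise ValueError(
                    "all events of a trial must reference the trial's "
                    "participant and image"
                )


@dataclass
class ScreeningConfig:
    image_size_px: tuple[int, int] = (600, 600)  # (width, height)
    min_fixation_ms: float = 100.0
    duration_sd_cutoff: float = 2.0
    #: apply the SD cutoff on raw milliseconds ("ms") or log-duration ("log")
    duration_sd_scale: str = "ms"
    #: compute grand mean/SD after removing sub-threshold fixations
    sd_after_short_removal: bool = True
    min_valid_fixations: int = 3  # "larger than two"
    trackloss_gap_ms: float = 100.0
    max_participant_trackloss: float = 0.25
    max_participant_excluded_trials: float = 0.25
    saccade_min_onset_ms: float = 75.0


@dataclass
class ScreeningReport:
    """Per-rule exclusion bookkeeping.

    ``rules`` maps rule name -> {"excluded": int, "total": int, "pct": float}.
    """

    rules: dict = field(default_factory=dict)
    participant_trackloss: dict = field(default_factory=dict)
    excluded_participants: list = field(default_factory=list)

    def record(self, rule: str, excluded: int, total: int) -> None:
        pct = 100.0 * excluded / total if total else 0.0
        self.rules[rule] = {"excluded": int(excluded), "total": int(total), "pct": pct}

    def merge(self, other: "ScreeningReport") -> "ScreeningReport":
        merged = ScreeningReport(
            rules={**self.rules, **other.rules},
            participant_trackloss={
                **self.participant_trackloss,
                **other.participant_trackloss,
            },
            excluded_participants=self.excluded_participants
            + other.excluded_participants,
        )
        return merged

    def to_json(self) -> str:
        return json.dumps(
            {
                "rules": self.rules,
                "participant_trackloss": self.participant_trackloss,
                "excluded_participants": self.excluded_participants,
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = []
        for rule, d in self.rules.items():
            lines.append(
                f"{rule}: excluded {d['excluded']}/{d['total']} ({d['pct']:.2f}%)"
            )
        if self.excluded_participants:
            lines.append(f"excluded participants: {self.excluded_participants}")
        return "\n".join(lines)


def in_image_region(x: float, y: float, size_px: tuple[int, int]) -> bool:
    """Half-open pixel rectangle [0, W) x [0, H): pixel W-1 is inside,
    coordinate W is outside."""
    w, h = size_px
    return 0 <= x < w and 0 <= y < h


def _parse_float(value, row_idx: int, column: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row_idx}: non-numeric value {value!r} in column {column!r}"
        ) from None


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "t", "yes", "y"}


def load_events(path, dialect: dict | None = None, viewing_ms: float = 3000.0) -> list[Trial]:
    """Read a delimited event table into Trials.

    One row per event. Rows with ``event_type`` of ``fixation``, ``saccade``
    or ``trackloss`` are grouped by (participant, image); the earliest-onset
    fixation of each trial is flagged as the recorded first fixation (it is
    discarded by screening). The ``dialect`` argument maps the canonical
    column names of :data:`DEFAULT_COLUMNS` to the file's actual headers.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)

    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if not sample.strip():
            logger.warning("empty event table %s", path)
            return []
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        required = [cols[k] for k in ("participant", "image", "event_type", "onset_ms")]
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"missing required columns: {missing}")

        trials: dict[tuple[str, str], Trial] = {}
        for idx, row in enumerate(reader):
            pid = str(row[cols["participant"]])
            img = str(row[cols["image"]])
            key = (pid, img)
            if key not in trials:
                trials[key] = Trial(
                    participant_id=pid,
                    image_id=img,
                    category=row.get(cols["category"]) or None,
                    correct=(
                        _parse_bool(row[cols["correct"]])
                        if row.get(cols["correct"]) not in (None, "")
                        else None
                    ),
                    viewing_ms=viewing_ms,
                )
            trial = trials[key]
            etype = str(row[cols["event_type"]]).strip().lower()
            onset = _parse_float(row[cols["onset_ms"]], idx, cols["onset_ms"])
            if etype == "fixation":
                trial.fixations.append(
                    FixationEvent(
                        participant_id=pid,
                        image_id=img,
                        onset_ms=onset,
                        offset_ms=_parse_float(row[cols["offset_ms"]], idx, cols["offset_ms"]),
                        x_px=_parse_float(row[cols["x_px"]], idx, cols["x_px"]),
                        y_px=_parse_float(row[cols["y_px"]], idx, cols["y_px"]),
                    )
                )
            elif etype == "saccade":
                trial.saccades.append(
                    SaccadeEvent(
                        participant_id=pid,
                        image_id=img,
                        onset_ms=onset,
                        start_x_px=_parse_float(row[cols["x_px"]], idx, cols["x_px"]),
                        start_y_px=_parse_float(row[cols["y_px"]], idx, cols["y_px"]),
                        end_x_px=_parse_float(row[cols["end_x_px"]], idx, cols["end_x_px"]),
                        end_y_px=_parse_float(row[cols["end_y_px"]], idx, cols["end_y_px"]),
                        amplitude_dva=_parse_float(
                            row[cols["amplitude_dva"]], idx, cols["amplitude_dva"]
                        ),
                    )
                )
            elif etype == "trackloss":
                trial.trackloss_segments.append(
                    (
                        onset,
                        _parse_float(row[cols["offset_ms"]], idx, cols["offset_ms"]),
                        _parse_bool(row.get(cols["blink"], "")),
                    )
                )
            else:
                raise ParseError(f"row {idx}: unknown event type {etype!r}")

    out = []
    for trial in trials.values():
        trial.fixations.sort(key=lambda f: f.onset_ms)
        trial.saccades.sort(key=lambda s: s.onset_ms)
        out.append(flag_first_fixation(trial))
    out.sort(key=lambda t: (t.participant_id, t.image_id))
    return out


def flag_first_fixation(trial: Trial) -> Trial:
    """Mark the earliest-onset fixation as the recorded first fixation."""
    if (
        trial.first_fixation_removed
        or not trial.fixations
        or trial.fixations[0].is_first
    ):
        return trial
    fixations = [replace(trial.fixations[0], is_first=True)] + trial.fixations[1:]
    trial.fixations = fixations
    return trial


def drop_first_fixations(trial: Trial) -> Trial:
    fixations = [f for f in trial.fixations if not f.is_first]
    return Trial(
        participant_id=trial.participant_id,
        image_id=trial.image_id,
        category=trial.category,
        correct=trial.correct,
        fixations=fixations,
        saccades=list(trial.saccades),
        trackloss_segments=list(trial.trackloss_segments),
        viewing_ms=trial.viewing_ms,
        first_fixation_removed=True,
    )


def _fixation_locally_valid(f: FixationEvent, cfg: ScreeningConfig) -> bool:
    """Per-fixation validity used when counting a trial's valid fixations:
    inside the image, at least the minimum duration, not pre-stimulus."""
    return (
        not f.is_first
        and f.onset_ms >= 0
        and f.duration_ms >= cfg.min_fixation_ms
        and in_image_region(f.x_px, f.y_px, cfg.image_size_px)
    )


def screen_trials(
    trials: list[Trial], cfg: ScreeningConfig | None = None
) -> tuple[list[Trial], ScreeningReport]:
    """Apply the trial-level and participant-level screening rules.

    Rules, in order: (1) incorrect categorization; (2) not more than two
    valid fixations after removal of the recorded first fixation; (3) a
    non-blink track-loss gap longer than the threshold; (4) exclusion of any
    participant whose track loss exceeds 25% of viewing time or whose
    excluded-trial fraction exceeds 25%.
    """
    cfg = cfg or ScreeningConfig()
    report = ScreeningReport()
    n_in = len(trials)

    for t in trials:
        if t.correct is None:
            raise ValueError(
                f"trial ({t.participant_id}, {t.image_id}) lacks a correctness flag"
            )

    trials = [drop_first_fixations(flag_first_fixation(t)) for t in trials]

    surviving, excluded_by = [], {"incorrect": 0, "too_few_fixations": 0, "trackloss_gap": 0}
    per_participant_excl: dict[str, int] = {}
    per_participant_total: dict[str, int] = {}
    for t in trials:
        per_participant_total[t.participant_id] = (
            per_participant_total.get(t.participant_id, 0) + 1
        )
        if not t.correct:
            rule = "incorrect"
        elif sum(_fixation_locally_valid(f, cfg) for f in t.fixations) < cfg.min_valid_fixations:
            rule = "too_few_fixations"
        elif any(
            (end - start) > cfg.trackloss_gap_ms and not is_blink
            for start, end, is_blink in t.trackloss_segments
        ):
            rule = "trackloss_gap"
        else:
            surviving.append(t)
            continue
        excluded_by[rule] += 1
        per_participant_excl[t.participant_id] = (
            per_participant_excl.get(t.participant_id, 0) + 1
        )

    report.record("trials_incorrect", excluded_by["incorrect"], n_in)
    report.record("trials_too_few_fixations", excluded_by["too_few_fixations"], n_in)
    report.record("trials_trackloss_gap", excluded_by["trackloss_gap"], n_in)

    # participant rule: total trackloss time fraction or excluded-trial fraction
    bad_participants = []
    for pid, total in per_participant_total.items():
        p_trials = [t for t in trials if t.participant_id == pid]
        viewing = sum(t.viewing_ms for t in p_trials)
        lost = sum(
            max(0.0, min(end, t.viewing_ms) - max(start, 0.0))
            for t in p_trials
            for start, end, _ in t.trackloss_segments
        )
        frac_lost = lost / viewing if viewing else 0.0
        frac_excl = per_participant_excl.get(pid, 0) / total
        report.participant_trackloss[pid] = frac_lost
        if (
            frac_lost > cfg.max_participant_trackloss
            or frac_excl > cfg.max_participant_excluded_trials
        ):
            bad_participants.append(pid)

    if bad_participants:
        n_before = len(surviving)
        surviving = [t for t in surviving if t.participant_id not in bad_participants]
        report.record("participant_exclusion", n_before - len(surviving), n_before)
        report.excluded_participants = sorted(bad_participants)
    else:
        report.record("participant_exclusion", 0, len(surviving))

    report.record("trials_total_excluded", n_in - len(surviving), n_in)
    return surviving, report


def screen_fixations(
    trials: list[Trial],
    cfg: ScreeningConfig | None = None,
    duration_cutoff_ms: float | None = None,
) -> tuple[list[FixationEvent], ScreeningReport]:
    """Filter fixations of trial-screened data.

    Removes, in order: fixations outside the image region; fixations shorter
    than the minimum duration (pre-stimulus fixations count as invalid);
    fixations longer than grand_mean + k*grand_SD of the surviving fixation
    durations of the whole dataset. Percentages are relative to all
    fixations from valid trials (first recorded fixations excluded).

    The upper-duration cutoff is a dataset-level parameter: it is estimated
    once from the data being screened unless ``duration_cutoff_ms`` pins it
    (re-applying screening with the estimated cutoff is then a no-op).
    The estimated cutoff is stored in the report under
    ``report.rules["fixations_too_long"]["cutoff_ms"]``.
    """
    cfg = cfg or ScreeningConfig()
    report = ScreeningReport()
    pool = [f for t in trials for f in t.fixations if not f.is_first]
    n_all = len(pool)

    in_region = [f for f in pool if in_image_region(f.x_px, f.y_px, cfg.image_size_px)]
    report.record("fixations_out_of_region", n_all - len(in_region), n_all)

    long_enough = [
        f for f in in_region if f.onset_ms >= 0 and f.duration_ms >= cfg.min_fixation_ms
    ]
    report.record("fixations_too_short", len(in_region) - len(long_enough), n_all)

    if duration_cutoff_ms is not None:
        cutoff = float(duration_cutoff_ms)
    else:
        basis = long_enough if cfg.sd_after_short_removal else in_region
        if len(basis) > 1:
            durations = np.array([f.duration_ms for f in basis], dtype=float)
            if cfg.duration_sd_scale == "log":
                logd = np.log(durations)
                cutoff = float(
                    np.exp(logd.mean() + cfg.duration_sd_cutoff * logd.std(ddof=1))
                )
            else:
                cutoff = float(
                    durations.mean() + cfg.duration_sd_cutoff * durations.std(ddof=1)
                )
        else:
            cutoff = np.inf
    surviving = [f for f in long_enough if f.duration_ms <= cutoff]
    report.record("fixations_too_long", len(long_enough) - len(surviving), n_all)
    report.rules["fixations_too_long"]["cutoff_ms"] = cutoff
    report.record("fixations_total_excluded", n_all - len(surviving), n_all)
    return surviving, report


def screen_saccades(
    trials: list[Trial], cfg: ScreeningConfig | None = None
) -> tuple[list[SaccadeEvent], ScreeningReport]:
    """Filter saccades of trial-screened data.

    The first recorded saccade is retained. Saccades with onset before the
    anticipation threshold (including pre-stimulus onsets) are removed, as
    are saccades whose start or end point lies outside the image region.
    """
    cfg = cfg or ScreeningConfig()
    report = ScreeningReport()
    pool = [s for t in trials for s in t.saccades]
    n_all = len(pool)

    late_enough = [s for s in pool if s.onset_ms >= cfg.saccade_min_onset_ms]
    report.record("saccades_anticipatory", n_all - len(late_enough), n_all)

    surviving = [
        s
        for s in late_enough
        if in_image_region(s.start_x_px, s.start_y_px, cfg.image_size_px)
        and in_image_region(s.end_x_px, s.end_y_px, cfg.image_size_px)
    ]
    report.record("saccades_out_of_region", len(late_enough) - len(surviving), n_all)
    report.record("saccades_total_excluded", n_all - len(surviving), n_all)
    return surviving, report


@dataclass
class ScreenedDataset:
    """Outcome of the full screening cascade, with per-trial filtered events."""

    trials: list[Trial]
    report: ScreeningReport
    duration_cutoff_ms: float = np.inf


def apply_screening(
    trials: list[Trial],
    cfg: ScreeningConfig | None = None,
    duration_cutoff_ms: float | None = None,
) -> ScreenedDataset:
    """Run the full cascade and return trials whose event lists contain only
    surviving fixations and saccades."""
    cfg = cfg or ScreeningConfig()
    valid_trials, trial_report = screen_trials(trials, cfg)
    fixations, fix_report = screen_fixations(valid_trials, cfg, duration_cutoff_ms)
    saccades, sac_report = screen_saccades(valid_trials, cfg)
    fix_keep = set(map(id, fixations))
    sac_keep = set(map(id, saccades))
    screened = []
    for t in valid_trials:
        screened.append(
            Trial(
                participant_id=t.participant_id,
                image_id=t.image_id,
                category=t.category,
                correct=t.correct,
                fixations=[f for f in t.fixations if id(f) in fix_keep],
                saccades=[s for s in t.saccades if id(s) in sac_keep],
                trackloss_segments=list(t.trackloss_segments),
                viewing_ms=t.viewing_ms,
                first_fixation_removed=True,
            )
        )
    report = trial_report.merge(fix_report).merge(sac_report)
    return ScreenedDataset(
        trials=screened,
        report=report,
        duration_cutoff_ms=fix_report.rules["fixations_too_long"]["cutoff_ms"],
    )
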