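"""Two-day cardiopulmonary exercise test (CPET) deterioration metrics.

In a two-day maximum repeated-effort protocol, a failure to reproduce
day-one performance on day two is read as objective evidence of
post-exertional malaise.  Given per-participant, per-day CPET parameters
(maximum heart rate, maximum workload, VO2 peak, respiratory exchange
ratio, and the workload at the anaerobic threshold), this module derives
the day-two deterioration flags and the cohort counts: each flag is a
strict inequality on the printed values — equality sets no flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class CPETRecord:
    participant_id: str
    group: str  # case | control
    day: int  # 1 | 2
    max_hr: float  # beats/min
    max_workload: float  # watts
    vo2_peak: float  # mL/kg/min
    rer: float  # VCO2/VO2
    at_workload: float  # watts at the anaerobic threshold

    def __post_init__(self) -> None:
        if self.day not in (1, 2):
            raise ValueError(f"{self.participant_id}: day must be 1 or 2")
        for name in ("max_hr", "max_workload", "vo2_peak", "rer", "at_workload"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.participant_id}: {name} must be positive")
        if not 0.7 <= self.rer <= 1.4:
            warnings.warn(
                f"{self.participant_id} day {self.day}: RER {self.rer} outside "
                "the typical 0.7-1.4 range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class Day2Flags:
    """Strict day-two-vs-day-one comparisons for one participant."""

    lower_max_hr: bool
    lower_max_workload: bool
    lower_vo2_peak: bool
    at_lower_workload: bool
    at_higher_workload: bool

    def __post_init__(self) -> None:
        if self.at_lower_workload and self.at_higher_workload:
            raise ValueError("AT cannot be both lower and higher on day two")


def flag_day2(day1: CPETRecord, day2: CPETRecord) -> Day2Flags:
    """Derive deterioration flags; equality on any parameter sets no flag."""
    if day1.participant_id != day2.participant_id:
        raise ValueError(
            f"participant mismatch: {day1.participant_id} vs {day2.participant_id}"
        )
    if (day1.day, day2.day) != (1, 2):
        raise ValueError("records must be (day 1, day 2)")
    return Day2Flags(
        lower_max_hr=day2.max_hr < day1.max_hr,
        lower_max_workload=day2.max_workload < day1.max_workload,
        lower_vo2_peak=day2.vo2_peak < day1.vo2_peak,
        at_lower_workload=day2.at_workload < day1.at_workload,
        at_higher_workload=day2.at_workload > day1.at_workload,
    )


def cohort_counts(records: list[CPETRecord], group: str) -> dict[str, int]:
    """Per-flag participant counts for one group, plus the compound count
    (lower max HR AND lower max workload) and the count whose anaerobic
    threshold occurred at the same or a greater workload on day two."""
    by_participant: dict[str, dict[int, CPETRecord]] = {}
    for r in records:
        if r.group != group:
            continue
        by_participant.setdefault(r.participant_id, {})[r.day] = r
    if not by_participant:
        raise ValueError(f"no participants in group {group!r}")
    counts = {
        "n": 0,
        "lower_max_hr": 0,
        "lower_max_workload": 0,
        "lower_vo2_peak": 0,
        "at_lower_workload": 0,
        "at_higher_workload": 0,
        "at_same_or_greater_workload": 0,
        "lower_hr_and_workload": 0,
    }
    for pid, days in sorted(by_participant.items()):
        if set(days) != {1, 2}:
            raise ValueError(f"participant {pid} lacks both CPET days")
        flags = flag_day2(days[1], days[2])
        counts["n"] += 1
        counts["lower_max_hr"] += flags.lower_max_hr
        counts["lower_max_workload"] += flags.lower_max_workload
        counts["lower_vo2_peak"] += flags.lower_vo2_peak
        counts["at_lower_workload"] += flags.at_lower_workload
        counts["at_higher_workload"] += flags.at_higher_workload
        counts["at_same_or_greater_workload"] += not flags.at_lower_workload
        counts["lower_hr_and_workload"] += flags.lower_max_hr and flags.lower_max_workload
    return {k: int(v) for k, v in counts.items()}


def read_cpet_csv(path: str | Path) -> list[CPETRecord]:
    """CSV columns: participant, group, day, max_hr, max_workload,
    vo2_peak, rer, at_workload."""
    df = pd.read_csv(path)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[CPETRecord]:
    return [
        CPETRecord(
            str(r["participant"]),
            str(r["group"]),
            int(r["day"]),
            float(r["max_hr"]),
            float(r["max_workload"]),
            float(r["vo2_peak"]),
            float(r["rer"]),
            float(r["at_workload"]),
        )
        for _, r in df.iterrows()
    ]


def flags_frame(records: list[CPETRecord]) -> pd.DataFrame:
    """One row of flags per participant with both days present."""
    by_participant: dict[str, dict[int, CPETRecord]] = {}
    for r in records:
        by_participant.setdefault(r.participant_id, {})[r.day] = r
    rows = []
    for pid, days in sorted(by_participant.items()):
        if set(days) != {1, 2}:
            raise ValueError(f"participant {pid} lacks both CPET days")
        f = flag_day2(days[1], days[2])
        rows.append(
            {
                "participant": pid,
                "group": days[1].group,
                "lower_max_hr": f.lower_max_hr,
                "lower_max_workload": f.lower_max_workload,
                "lower_vo2_peak": f.lower_vo2_peak,
                "at_lower_workload": f.at_lower_workload,
                "at_higher_workload": f.at_higher_workload,
            }
        )
    return pd.DataFrame(rows)


def load_study_cpet() -> list[CPETRecord]:
    """Packaged fixture: the study cohort's two-day CPET parameter table."""
    with resources.files("rrbsdmf.data").joinpath("cpet_two_day.csv").open() as fh:
        return records_from_frame(pd.read_csv(fh))
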