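"""Classification of three-timepoint methylation trajectories.

A promoter (or any fragment) trajectory (m0, m24, m48) is classified by
shape and direction into the temporal taxonomy the longitudinal design
exposes: continuous, early, transient or late change, each either
hypermethylation or hypomethylation — eight informative classes — plus a
ninth "flat" class for trajectories whose largest excursion falls below
a floor (it cannot occur on records that already passed a >=10-point
delta filter with the default floor of 5).

The rule set is a small decision list on the interval deltas
d1 = m24 - m0, d2 = m48 - m24, d3 = m48 - m0:

0. flat         if max(|d1|, |d2|, |d3|) < flat_floor;
1. continuous   if d1 and d2 share a nonzero sign and |d2| >= kappa;
2. late         if |d1| < epsilon (direction = sign of d2);
3. otherwise direction = sign(d1); transient if the trajectory then
   reverses past baseline (sign(d2) = sign(d3) = -direction), else early.

The defaults epsilon=4.5 and kappa=5 are the values that best reproduce
published class assignments computed from rounded integer means; both
are configurable, and per-patient (unrounded) trajectories can be
averaged before classification when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SHAPES = ("continuous", "early", "transient", "late", "flat")
HYPER, HYPO, NONE = "hyper", "hypo", "none"


@dataclass(frozen=True)
class Trajectory:
    """Mean methylation percentages at 0 h, 24 h and 48 h."""

    m0: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        for m in (self.m0, self.m1, self.m2):
            if not 0 <= m <= 100:
                raise ValueError(f"methylation percentage {m} outside [0, 100]")

    @property
    def d1(self) -> float:
        return self.m1 - self.m0

    @property
    def d2(self) -> float:
        return self.m2 - self.m1

    @property
    def d3(self) -> float:
        return self.m2 - self.m0


@dataclass(frozen=True)
class PatternClass:
    shape: str
    direction: str

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if (self.shape == "flat") != (self.direction == NONE):
            raise ValueError("flat <=> direction none")

    @property
    def label(self) -> str:
        if self.shape == "flat":
            return "flat"
        suffix = "hypermethylation" if self.direction == HYPER else "hypomethylation"
        return f"{self.shape} {suffix}"


@dataclass(frozen=True)
class ClassifierParams:
    epsilon: float = 4.5  # |d1| below this => the change is late
    kappa: float = 5.0  # |d2| at least this (same sign as d1) => continuous
    flat_floor: float = 5.0  # largest excursion below this => flat

    def __post_init__(self) -> None:
        if min(self.epsilon, self.kappa, self.flat_floor) < 0:
            raise ValueError("classifier thresholds must be non-negative")


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def classify_trajectory(
    t: Trajectory, params: ClassifierParams | None = None
) -> PatternClass:
    """Classify one trajectory; total on its domain (always returns a class)."""
    p = params or ClassifierParams()
    d1, d2, d3 = t.d1, t.d2, t.d3
    if max(abs(d1), abs(d2), abs(d3)) < p.flat_floor:
        return PatternClass("flat", NONE)
    s1, s2 = _sign(d1), _sign(d2)
    if s1 != 0 and s2 == s1 and abs(d2) >= p.kappa:
        return PatternClass("continuous", HYPER if s1 > 0 else HYPO)
    if abs(d1) < p.epsilon:
        return PatternClass("late", HYPER if s2 > 0 else HYPO)
    direction = s1
    if s2 == -direction and _sign(d3) == -direction:
        return PatternClass("transient", HYPER if direction > 0 else HYPO)
    return PatternClass("early", HYPER if direction > 0 else HYPO)


def classify_means(
    m0: float, m1: float, m2: float, params: ClassifierParams | None = None
) -> PatternClass:
    return classify_trajectory(Trajectory(m0, m1, m2), params)


def classify_patient_trajectories(
    per_patient: Sequence[tuple[float, float, float]],
    params: ClassifierParams | None = None,
) -> PatternClass:
    """Classify the mean of unrounded per-patient trajectories."""
    arr = np.asarray(per_patient, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("per-patient trajectories must be (n, 3)")
    m = arr.mean(axis=0)
    return classify_means(m[0], m[1], m[2], params)


def classify_table(
    table: pd.DataFrame,
    params: ClassifierParams | None = None,
    mean_cols: Sequence[str] = ("mean_0h", "mean_24h", "mean_48h"),
) -> pd.DataFrame:
    """Append shape, direction and class_label columns to a mean table."""
    out = table.copy()
    classes = [
        classify_means(row[mean_cols[0]], row[mean_cols[1]], row[mean_cols[2]], params)
        for _, row in table.iterrows()
    ]
    out["shape"] = [c.shape for c in classes]
    out["direction"] = [c.direction for c in classes]
    out["class_label"] = [c.label for c in classes]
    return out


def summarize_patterns(classes: Iterable[PatternClass]) -> dict[str, dict[str, int]]:
    """Counts per class label, per shape and per direction."""
    classes = list(classes)
    by_class: dict[str, int] = {}
    by_shape: dict[str, int] = {s: 0 for s in SHAPES}
    by_direction: dict[str, int] = {HYPER: 0, HYPO: 0, NONE: 0}
    for c in classes:
        by_class[c.label] = by_class.get(c.label, 0) + 1
        by_shape[c.shape] += 1
        by_direction[c.direction] += 1
    return {
        "by_class": by_class,
        "by_shape": by_shape,
        "by_direction": by_direction,
        "total": {"total": len(classes)},
    }


def load_promoter_table() -> pd.DataFrame:
    """Packaged fixture: the 24 case-specific promoter DMFs with their
    per-timepoint mean methylation percentages, linked genes, functional
    categories and the published pattern assignment."""
    with resources.files("rrbsdmf.data").joinpath("promoter_dmfs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
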