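"""Differentially methylated fragment (DMF) calling across timepoints.

The pipeline identifies fragments whose methylation changes through an
ordered series of timepoints within a participant group:

1. complete-case filtering — keep only fragments measured in every
   participant of the group at every timepoint;
2. one-way fixed-effects ANOVA treating timepoints as groups and
   participants as replicates, with a raw p < alpha cut (no multiplicity
   correction by default — a deliberate low-n choice, BH optional);
3. biological-relevance filtering — require a change of more than a
   threshold number of percentage points in at least one of the three
   pairwise timepoint comparisons, which simultaneously categorises each
   fragment as an early (t0->t1), late (t1->t2) and/or gradual (t0->t2)
   response;
4. de-duplication with earliest-first precedence (early > late > gradual)
   so each fragment carries a single assigned category;
5. specificity subtraction — case DMFs also present in the control DMF
   set are flagged non-specific and removed from the specific-only view.

Methylation levels are fractions in [0, 1] internally; group means and
deltas are reported in percent / percentage points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("early", "late", "gradual")


@dataclass(frozen=True)
class MethMatrix:
    """Fragments x samples methylation matrix with sample descriptors.

    ``values``: DataFrame indexed by fragment_id with a (participant,
    timepoint) column MultiIndex; entries are fractions in [0, 1], NaN
    where a fragment was not measured for that sample.
    ``groups``: participant -> "case" | "control".
    ``timepoint_order``: the temporal ordering of the timepoint labels.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    timepoint_order: tuple[str, ...]

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.nlevels != 2:
            raise ValueError("values must have (participant, timepoint) columns")
        if cols.duplicated().any():
            raise ValueError("duplicate (participant, timepoint) columns")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = self.values.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("methylation values must lie in [0, 1]")
        unknown = {p for p, _ in cols} - set(self.groups)
        if unknown:
            raise ValueError(f"participants without group labels: {sorted(unknown)}")

    def participants(self, group: str) -> list[str]:
        present = {p for p, _ in self.values.columns}
        return sorted(p for p in present if self.groups[p] == group)

    def subset(self, group: str) -> "MethMatrix":
        """Columns restricted to one group (all timepoints)."""
        parts = self.participants(group)
        if not parts:
            raise ValueError(f"no participants in group {group!r}")
        cols = [c for c in self.values.columns if c[0] in parts]
        return MethMatrix(self.values[cols], self.groups, self.timepoint_order)

    @staticmethod
    def from_long(
        frame: pd.DataFrame,
        samples: pd.DataFrame,
        timepoint_order: Sequence[str],
        value_col: str = "meth_level",
    ) -> "MethMatrix":
        """Build from a long fragment-methylation table plus a sample sheet.

        ``frame`` needs columns fragment_id, sample_id, timepoint and
        ``value_col``; ``samples`` maps sample_id -> (participant, group).
        """
        meta = samples[["sample_id", "participant", "group"]].drop_duplicates()
        if meta["sample_id"].duplicated().any():
            raise ValueError("sample sheet maps a sample_id to conflicting metadata")
        meta = meta.set_index("sample_id")
        frame = frame.assign(
            participant=frame["sample_id"].map(meta["participant"]),
        )
        wide = frame.pivot_table(
            index="fragment_id",
            columns=["participant", "timepoint"],
            values=value_col,
            aggfunc="first",
        )
        groups = dict(zip(meta["participant"], meta["group"]))
        return MethMatrix(wide, groups, tuple(timepoint_order))


@dataclass(frozen=True)
class DMFRecord:
    """One retained fragment after ANOVA + delta filtering."""

    fragment_id: str
    p_value: float
    f_statistic: float
    mean_t0: float  # percent
    mean_t1: float
    mean_t2: float
    delta_early: float  # percentage points, t1 - t0
    delta_late: float  # t2 - t1
    delta_gradual: float  # t2 - t0
    categories: frozenset[str]
    assigned_category: str
    specific: bool | None = None


@dataclass(frozen=True)
class PipelineConfig:
    alpha: float = 0.05
    fdr: bool = False  # Benjamini-Hochberg on the raw p-values if True
    delta_threshold: float = 10.0  # percentage points
    strict_delta: bool = True  # > threshold when True, >= otherwise
    control_comparison: str = "filtered"  # or "anova": subtract pre-delta set
    min_participants: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.delta_threshold < 0:
            raise ValueError("delta threshold must be non-negative")
        if self.control_comparison not in ("filtered", "anova"):
            raise ValueError("control_comparison must be 'filtered' or 'anova'")


def complete_case_filter(matrix: MethMatrix, group: str) -> MethMatrix:
    """Retain fragments measured in every participant of ``group`` at every
    timepoint."""
    parts = matrix.participants(group)
    if not parts:
        raise ValueError(f"no participants in group {group!r}")
    cols = [
        (p, t)
        for p in parts
        for t in matrix.timepoint_order
        if (p, t) in matrix.values.columns
    ]
    expected = len(parts) * len(matrix.timepoint_order)
    if len(cols) < expected:
        missing = {
            (p, t)
            for p in parts
            for t in matrix.timepoint_order
        } - set(cols)
        raise ValueError(f"sample sheet lacks columns for {sorted(missing)}")
    sub = matrix.values[cols]
    keep = sub.notna().all(axis=1)
    return MethMatrix(sub.loc[keep], matrix.groups, matrix.timepoint_order)


def _group_arrays(matrix: MethMatrix) -> tuple[np.ndarray, list[str]]:
    """(fragments, timepoints, participants) array for one group's matrix."""
    parts = sorted({p for p, _ in matrix.values.columns})
    tps = matrix.timepoint_order
    arr = np.stack(
        [
            matrix.values[[(p, t) for p in parts]].to_numpy(dtype=float)
            for t in tps
        ],
        axis=1,
    )
    return arr, parts


def anova_timepoints(matrix: MethMatrix) -> pd.DataFrame:
    """Per-fragment one-way fixed-effects ANOVA across timepoints.

    Timepoints are the factor levels and participants the replicates:
    F = MS_between / MS_within with df (k-1, k(n-1)).  Fragments with no
    within-timepoint variance get F=0, p=1 when the timepoint means agree
    and a p=0 sentinel (with a warning) when they differ.  Requires a
    complete-case matrix.
    """
    arr, parts = _group_arrays(matrix)
    n_frag, k, n = arr.shape
    if k < 2:
        raise ValueError("need >= 2 timepoints")
    if n < 2:
        raise ValueError("need >= 2 participants per timepoint (variance undefined)")
    if np.isnan(arr).any():
        raise ValueError("anova_timepoints requires complete cases (run the filter)")
    grand = arr.mean(axis=(1, 2), keepdims=True)
    tmean = arr.mean(axis=2, keepdims=True)
    ss_between = (n * (tmean - grand) ** 2).sum(axis=(1, 2))
    ss_within = ((arr - tmean) ** 2).sum(axis=(1, 2))
    df_b, df_w = k - 1, k * (n - 1)
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
        p = stats.f.sf(f, df_b, df_w)
    degenerate = ms_within == 0
    flat = degenerate & np.isclose(ms_between, 0.0)
    jump = degenerate & ~flat
    f = np.where(flat, 0.0, f)
    p = np.where(flat, 1.0, p)
    if jump.any():
        warnings.warn(
            f"{int(jump.sum())} fragments have zero within-timepoint variance "
            "with unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        f = np.where(jump, np.inf, f)
        p = np.where(jump, 0.0, p)
    return pd.DataFrame(
        {"f_statistic": f, "p_value": p}, index=matrix.values.index
    )


def significance_filter(
    records: pd.DataFrame, alpha: float = 0.05, fdr: bool = False
) -> pd.DataFrame:
    """Retain rows with p strictly below ``alpha``.

    With ``fdr=True`` the cut is applied to Benjamini-Hochberg adjusted
    p-values instead (off by default: raw p-values deliberately retain
    true positives at low n).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    p = records["p_value"].to_numpy(dtype=float)
    if fdr:
        p = stats.false_discovery_control(p, method="bh")
    return records.loc[p < alpha]


def timepoint_means(matrix: MethMatrix) -> pd.DataFrame:
    """Per-fragment group mean methylation at each timepoint, in percent."""
    arr, _ = _group_arrays(matrix)
    means = 100.0 * arr.mean(axis=2)
    return pd.DataFrame(
        means,
        index=matrix.values.index,
        columns=[f"mean_{t}" for t in matrix.timepoint_order],
    )


def categorize_deltas(
    records: pd.DataFrame,
    threshold: float = 10.0,
    strict: bool = True,
) -> pd.DataFrame:
    """Apply the pairwise-delta relevance filter and response categories.

    ``records`` must carry three ``mean_<tp>`` columns (percent) in
    temporal order.  Adds delta_early (t1-t0), delta_late (t2-t1),
    delta_gradual (t2-t0) and boolean cat_early/cat_late/cat_gradual
    columns (|delta| > threshold, or >= when ``strict=False``); rows
    passing no comparison are dropped.
    """
    if threshold < 0:
        raise ValueError("delta threshold must be non-negative")
    mean_cols = [c for c in records.columns if c.startswith("mean_")]
    if len(mean_cols) != 3:
        raise ValueError(f"expected 3 mean_<timepoint> columns, got {mean_cols}")
    m0, m1, m2 = (records[c].to_numpy(dtype=float) for c in mean_cols)
    out = records.copy()
    out["delta_early"] = m1 - m0
    out["delta_late"] = m2 - m1
    # defined as the sum so the identity d_gradual = d_early + d_late is
    # exact in floating point (mathematically equal to m2 - m0)
    out["delta_gradual"] = out["delta_early"] + out["delta_late"]
    for cat, col in zip(CATEGORY_ORDER, ("delta_early", "delta_late", "delta_gradual")):
        mag = out[col].abs()
        out[f"cat_{cat}"] = mag > threshold if strict else mag >= threshold
    keep = out[[f"cat_{c}" for c in CATEGORY_ORDER]].any(axis=1)
    return out.loc[keep]


def dedupe_combine(records: pd.DataFrame) -> pd.DataFrame:
    """Assign each fragment its earliest applicable category.

    Mirrors combining the early/late/gradual lists and dropping
    duplicates already recorded at an earlier comparison: the assigned
    category is the first of (early, late, gradual) present.
    """
    cats = np.select(
        [records[f"cat_{c}"].to_numpy(dtype=bool) for c in CATEGORY_ORDER],
        CATEGORY_ORDER,
        default="",
    )
    if (cats == "").any():
        raise ValueError("records with empty category sets must be dropped first")
    out = records.copy()
    out["assigned_category"] = cats
    return out


def category_counts(records: pd.DataFrame) -> dict[str, int]:
    counts = {
        cat: int(records[f"cat_{cat}"].sum()) for cat in CATEGORY_ORDER
    }
    counts["combined"] = len(records)
    return counts


def subtract_control_dmfs(
    case_records: pd.DataFrame, control_ids: Iterable[str]
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Flag case DMFs present in the control set and drop them from the
    specific-only view.  Returns (flagged, specific_view, n_removed)."""
    control = set(control_ids)
    flagged = case_records.copy()
    flagged["specific"] = [fid not in control for fid in flagged.index]
    specific = flagged.loc[flagged["specific"]]
    n_removed = len(flagged) - len(specific)
    logger.info("specificity subtraction removed %d shared fragments", n_removed)
    return flagged, specific, n_removed


@dataclass(frozen=True)
class DMFResult:
    case: pd.DataFrame
    control: pd.DataFrame
    specific: pd.DataFrame
    stage_counts: pd.DataFrame
    config: PipelineConfig = field(default_factory=PipelineConfig)


def _run_group(
    matrix: MethMatrix, group: str, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """complete-case -> ANOVA -> significance -> deltas -> dedupe for one group."""
    sub = matrix.subset(group)
    counts: dict[str, int] = {"input": len(sub.values)}
    complete = complete_case_filter(sub, group)
    counts["complete_case"] = len(complete.values)
    anova = anova_timepoints(complete)
    sig = significance_filter(anova, config.alpha, config.fdr)
    counts["significant"] = len(sig)
    means = timepoint_means(complete).loc[sig.index]
    cat = categorize_deltas(
        sig.join(means), config.delta_threshold, config.strict_delta
    )
    cc = category_counts(cat)
    counts.update({f"delta_{k}": v for k, v in cc.items() if k != "combined"})
    counts["combined"] = cc["combined"]
    return dedupe_combine(cat), sig, counts


def run_dmf_pipeline(matrix: MethMatrix, config: PipelineConfig | None = None) -> DMFResult:
    """Run the full per-group pipeline and the case-vs-control subtraction.

    The stage-count report lists fragment counts for both groups at every
    stage (input, complete-case, ANOVA-significant, per-category delta
    counts, combined after dedup) plus the case-specific count after
    removing fragments shared with the control DMF set.
    """
    config = config or PipelineConfig()
    case, case_sig, case_counts = _run_group(matrix, "case", config)
    control, control_sig, control_counts = _run_group(matrix, "control", config)
    if config.control_comparison == "filtered":
        control_ids = control.index
    else:
        control_ids = control_sig.index
    case_flagged, specific, n_removed = subtract_control_dmfs(case, control_ids)
    case_counts["specific"] = len(specific)
    control_counts["specific"] = np.nan
    stage_counts = pd.DataFrame({"case": case_counts, "control": control_counts})
    stage_counts.index.name = "stage"
    return DMFResult(case_flagged, control, specific, stage_counts, config)


def dmf_records(frame: pd.DataFrame) -> list[DMFRecord]:
    """Materialise pipeline rows as :class:`DMFRecord` objects."""
    mean_cols = [c for c in frame.columns if c.startswith("mean_")]
    out = []
    for fid, row in frame.iterrows():
        cats = frozenset(c for c in CATEGORY_ORDER if row[f"cat_{c}"])
        out.append(
            DMFRecord(
                fragment_id=str(fid),
                p_value=float(row["p_value"]),
                f_statistic=float(row["f_statistic"]),
                mean_t0=float(row[mean_cols[0]]),
                mean_t1=float(row[mean_cols[1]]),
                mean_t2=float(row[mean_cols[2]]),
                delta_early=float(row["delta_early"]),
                delta_late=float(row["delta_late"]),
                delta_gradual=float(row["delta_gradual"]),
                categories=cats,
                assigned_category=str(row["assigned_category"]),
                specific=bool(row["specific"]) if "specific" in row else None,
            )
        )
    return out
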