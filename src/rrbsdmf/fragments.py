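"""MspI fragment construction and fragment-level methylation aggregation.

RRBS measures methylation on MspI restriction fragments: the enzyme cuts
C^CGG, and library size selection retains fragments of roughly 40-220 bp,
enriching for CpG-dense regions.  This module digests a reference sequence
in silico, size-selects the resulting fragments, parses per-CpG methylation
calls from Bismark-coverage-style TSV files, and pools the calls into one
methylation level per fragment per sample.

Coordinate conventions: 0-based half-open internally; Bismark coverage
files use 1-based inclusive positions and are converted on read/write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MSPI_SITE = "CCGG"
#: MspI cleaves between the first C and CGG (C^CGG), i.e. 1 base into the site.
MSPI_CUT_OFFSET = 1

#: RRBS library size-selection window in bp (inclusive on both ends).
DEFAULT_MIN_LEN = 40
DEFAULT_MAX_LEN = 220


@dataclass(frozen=True)
class FragmentInterval:
    """An MspI fragment on the forward strand, 0-based half-open."""

    chrom: str
    start: int
    end: int
    cpg_count: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid fragment interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fragment_id(self) -> str:
        """Stable coordinate identity, shared across samples and groups."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class CpGCall:
    """Counts for one CpG (forward-strand C, 0-based) in one sample/timepoint."""

    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int
    sample_id: str = ""
    timepoint: str = ""

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclass(frozen=True)
class FragmentMethylation:
    """Pooled methylation of one fragment in one sample at one timepoint."""

    fragment_id: str
    sample_id: str
    timepoint: str
    meth_level: float
    total_reads: int
    cpgs_observed: int


def count_cpgs(sequence: str) -> int:
    """Number of CG dinucleotides on the forward strand."""
    return sequence.upper().count("CG")


def mspi_digest(sequence: str, chrom: str = "chr1") -> list[FragmentInterval]:
    """Digest ``sequence`` at every CCGG site (cutting C^CGG).

    Returns fragments that tile the sequence without gaps or overlaps, each
    annotated with its forward-strand CpG count.  An empty sequence yields
    an empty list; a sequence without CCGG yields one fragment.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    if not seq:
        return []
    cuts = [0]
    i = seq.find(MSPI_SITE)
    while i != -1:
        cuts.append(i + MSPI_CUT_OFFSET)
        i = seq.find(MSPI_SITE, i + 1)
    cuts.append(len(seq))
    return [
        FragmentInterval(chrom, a, b, cpg_count=count_cpgs(seq[a:b]))
        for a, b in zip(cuts[:-1], cuts[1:])
        if b > a
    ]


def size_select(
    fragments: Iterable[FragmentInterval],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[FragmentInterval]:
    """Retain fragments with ``min_len <= length <= max_len`` (both inclusive)."""
    if min_len < 0 or max_len < 0:
        raise ValueError("size-selection bounds must be non-negative")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [f for f in fragments if min_len <= f.length <= max_len]


def read_coverage_file(
    path: str | Path,
    sample_id: str = "",
    timepoint: str = "",
    merge_strands: bool = False,
) -> list[CpGCall]:
    """Parse a Bismark-coverage-style TSV into :class:`CpGCall` records.

    Expected columns: chrom, start (1-based), end, methylation %, count
    methylated, count unmethylated.  File positions are converted to
    0-based.  With ``merge_strands=True``, a record at pos+1 on the same
    chromosome (the reverse-strand C of the same CpG) is summed into the
    forward-strand call.
    """
    path = Path(path)
    calls: list[CpGCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                pos1 = int(parts[1])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable line: {line!r}") from exc
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: 1-based coordinate < 1")
            calls.append(
                CpGCall(parts[0], pos1 - 1, meth, unmeth, sample_id, timepoint)
            )
    if merge_strands:
        calls = merge_strand_calls(calls)
    return calls


def merge_strand_calls(calls: Sequence[CpGCall]) -> list[CpGCall]:
    """Sum a reverse-strand record at pos+1 into the forward CpG at pos.

    A call is treated as the reverse-strand mate of the immediately
    preceding position when both exist on the same chromosome.
    """
    by_pos = {(c.chrom, c.pos): c for c in calls}
    merged: list[CpGCall] = []
    consumed: set[tuple[str, int]] = set()
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
        key = (c.chrom, c.pos)
        if key in consumed:
            continue
        mate = by_pos.get((c.chrom, c.pos + 1))
        if mate is not None:
            consumed.add((c.chrom, c.pos + 1))
            merged.append(
                CpGCall(
                    c.chrom,
                    c.pos,
                    c.meth_count + mate.meth_count,
                    c.unmeth_count + mate.unmeth_count,
                    c.sample_id,
                    c.timepoint,
                )
            )
        else:
            merged.append(c)
    return merged


def write_coverage_file(calls: Iterable[CpGCall], path: str | Path) -> None:
    """Write calls as Bismark-coverage TSV (1-based inclusive positions)."""
    with open(path, "w") as fh:
        for c in calls:
            total = c.coverage
            pct = 100.0 * c.meth_count / total if total else 0.0
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t{c.pos + 1}\t{pct:.6g}\t"
                f"{c.meth_count}\t{c.unmeth_count}\n"
            )


def _check_non_overlapping(fragments: Sequence[FragmentInterval]) -> list[FragmentInterval]:
    frags = sorted(fragments, key=lambda f: (f.chrom, f.start))
    for a, b in zip(frags[:-1], frags[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(
                f"overlapping fragments: {a.fragment_id} and {b.fragment_id}"
            )
    return frags


def aggregate_to_fragments(
    calls: Sequence[CpGCall],
    fragments: Sequence[FragmentInterval],
    min_cpgs: int = 2,
    min_reads: int = 10,
    pooling: str = "reads",
) -> list[FragmentMethylation]:
    """Pool per-CpG calls into per-fragment methylation levels.

    Each call is assigned to the unique fragment containing its position.
    With ``pooling="reads"`` (default) the fragment level is the
    read-weighted pooled fraction sum(meth)/sum(meth+unmeth); with
    ``pooling="mean"`` it is the unweighted mean of per-CpG fractions.
    A fragment is emitted for a (sample, timepoint) only when at least
    ``min_cpgs`` CpGs were observed and the pooled read total reaches
    ``min_reads``; otherwise it is absent, which downstream complete-case
    filtering treats as missing data.  Calls outside every fragment are
    dropped (count logged).
    """
    if pooling not in ("reads", "mean"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    frags = _check_non_overlapping(fragments)
    if not calls:
        return []

    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    ids: dict[str, list[str]] = {}
    for f in frags:
        ids.setdefault(f.chrom, []).append(f.fragment_id)
    by_chrom: dict[str, list[FragmentInterval]] = {}
    for f in frags:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, fl in by_chrom.items():
        starts[chrom] = np.array([f.start for f in fl])
        ends[chrom] = np.array([f.end for f in fl])

    # accumulate per (fragment, sample, timepoint)
    acc: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    dropped = 0
    for c in calls:
        fl = by_chrom.get(c.chrom)
        if fl is None:
            dropped += 1
            continue
        j = int(np.searchsorted(starts[c.chrom], c.pos, side="right")) - 1
        if j < 0 or c.pos >= ends[c.chrom][j]:
            dropped += 1
            continue
        key = (fl[j].fragment_id, c.sample_id, c.timepoint)
        acc.setdefault(key, []).append((c.meth_count, c.unmeth_count))
    if dropped:
        logger.info("aggregate_to_fragments: %d calls outside all fragments", dropped)

    out: list[FragmentMethylation] = []
    for (frag_id, sample, tp), pairs in acc.items():
        meth = sum(m for m, _ in pairs)
        unmeth = sum(u for _, u in pairs)
        total = meth + unmeth
        n_cpg = len(pairs)
        if n_cpg < min_cpgs or total < min_reads:
            continue
        if pooling == "reads":
            level = meth / total
        else:
            fracs = [m / (m + u) for m, u in pairs if (m + u) > 0]
            level = float(np.mean(fracs)) if fracs else 0.0
        out.append(FragmentMethylation(frag_id, sample, tp, level, total, n_cpg))
    out.sort(key=lambda r: (r.fragment_id, r.sample_id, r.timepoint))
    return out


def fragments_to_bed(fragments: Iterable[FragmentInterval], path: str | Path) -> None:
    """Write fragments as BED4 (name = fragment_id, score = CpG count)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.fragment_id}\t{f.cpg_count}\n")


def methylation_to_frame(records: Iterable[FragmentMethylation]) -> pd.DataFrame:
    """Long-format table: fragment_id, sample_id, timepoint, meth_level, reads, cpgs."""
    return pd.DataFrame(
        [
            {
                "fragment_id": r.fragment_id,
                "sample_id": r.sample_id,
                "timepoint": r.timepoint,
                "meth_level": r.meth_level,
                "total_reads": r.total_reads,
                "cpgs_observed": r.cpgs_observed,
            }
            for r in records
        ],
        columns=[
            "fragment_id",
            "sample_id",
            "timepoint",
            "meth_level",
            "total_reads",
            "cpgs_observed",
        ],
    )
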