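"""Ground-truthed synthetic RRBS datasets for the longitudinal design.

The generator emulates the study layout the pipeline assumes: a small
case cohort and a smaller control cohort, each sampled at three
timepoints (0 h, 24 h, 48 h), with fragment-level methylation effects
planted as early (change over the first 24 h, then held), late (change
over the second 24 h only) or gradual (split across both intervals)
responses, in either direction (hyper/hypo), optionally shared with the
controls.  Reads are simulated per CpG as binomial draws at a
shifted-Poisson coverage, so every downstream stage — digestion,
aggregation, complete-case filtering, ANOVA, delta categorisation,
specificity subtraction, annotation — can be tested against known truth
without any external data.

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning: genome construction, truth
planting and count simulation consume independent child streams, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, write_gene_models_bed12
from .fragments import CpGCall, FragmentInterval, write_coverage_file

TIMEPOINTS = ("0h", "24h", "48h")
RESPONSES = ("early", "late", "gradual")
DIRECTIONS = ("hyper", "hypo")

#: long uncut spacers between measured fragments; excluded by size selection
#: and wide enough to host promoter windows and gene bodies without touching
#: neighbouring measured fragments.
SPACER_LEN = 8000

_FEATURES = ("promoter", "exon", "intron", "boundary", "intergenic")


class SimConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass(frozen=True)
class PlantedClass:
    """A block of fragments sharing one planted temporal response."""

    response: str  # early | late | gradual
    direction: str  # hyper | hypo
    effect_size: float  # percentage points
    count: int

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise SimConfigError(f"unknown response class {self.response!r}")
        if self.direction not in DIRECTIONS:
            raise SimConfigError(f"unknown direction {self.direction!r}")
        if self.effect_size <= 0:
            raise SimConfigError("effect sizes must be positive")
        if self.count < 0:
            raise SimConfigError("planted counts must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for one synthetic dataset.

    Defaults mirror the longitudinal design the pipeline targets: five
    cases, two controls, three timepoints, a 40-220 bp size window, and a
    bimodal Beta(0.8, 0.8) baseline methylation profile.
    """

    n_patients: int = 5
    n_controls: int = 2
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_fragments: int = 1000
    frac_null: float | None = None  # derived from planted counts when None
    planted_classes: tuple[PlantedClass, ...] = (
        PlantedClass("early", "hyper", 20.0, 25),
        PlantedClass("early", "hypo", 20.0, 25),
        PlantedClass("late", "hyper", 20.0, 25),
        PlantedClass("late", "hypo", 20.0, 25),
        PlantedClass("gradual", "hyper", 20.0, 25),
        PlantedClass("gradual", "hypo", 20.0, 25),
    )
    frac_shared_with_controls: float = 0.0
    baseline_alpha: float = 0.8
    baseline_beta: float = 0.8
    patient_sd: float = 3.0  # percentage points; per (patient, fragment)
    mean_coverage: float = 50.0
    coverage_model: str = "poisson"  # or "nbinom"
    coverage_dispersion: float = 5.0  # nbinom shape, used when coverage_model="nbinom"
    cpgs_per_fragment_range: tuple[int, int] = (3, 8)
    min_len: int = 40
    max_len: int = 220
    feature_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.2,
            "exon": 0.2,
            "intron": 0.2,
            "boundary": 0.1,
            "intergenic": 0.3,
        }
    )
    chrom: str = "chrS1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments <= 0:
            raise SimConfigError("n_fragments must be positive")
        if self.n_patients < 2 or self.n_controls < 1:
            raise SimConfigError("need >= 2 patients and >= 1 control")
        if len(self.timepoints) < 2:
            raise SimConfigError("need >= 2 timepoints")
        lo, hi = self.cpgs_per_fragment_range
        if lo < 1 or hi < lo:
            raise SimConfigError("cpgs_per_fragment_range must satisfy 1 <= lo <= hi")
        # every measured fragment carries a leading CGG plus a trailing C
        # from the MspI sites, so a c-CpG fragment needs >= 2(c-1) + 4 bases
        if self.min_len - 4 < 2 * (hi - 1):
            raise SimConfigError(
                f"fragment of length {self.min_len} cannot host {hi} CpGs"
            )
        if self.min_len > self.max_len or self.min_len < 0:
            raise SimConfigError("invalid size-selection window")
        if not 0 <= self.frac_shared_with_controls <= 1:
            raise SimConfigError("frac_shared_with_controls must be in [0, 1]")
        total_planted = sum(c.count for c in self.planted_classes)
        if total_planted > self.n_fragments:
            raise SimConfigError(
                f"{total_planted} planted fragments exceed n_fragments={self.n_fragments}"
            )
        derived_null = 1.0 - total_planted / self.n_fragments
        if self.frac_null is None:
            object.__setattr__(self, "frac_null", derived_null)
        elif abs(self.frac_null - derived_null) > 1e-9:
            raise SimConfigError(
                f"frac_null={self.frac_null} inconsistent with planted counts "
                f"(implies {derived_null})"
            )
        fr = self.feature_fractions
        if any(k not in _FEATURES for k in fr):
            raise SimConfigError(f"unknown feature keys in {sorted(fr)}")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise SimConfigError("feature_fractions must sum to 1")

    @property
    def participants(self) -> list[tuple[str, str]]:
        """(participant_id, group) pairs, cases first."""
        cases = [(f"ME{i + 1:03d}", "case") for i in range(self.n_patients)]
        ctrls = [(f"CO{i + 1:03d}", "control") for i in range(self.n_controls)]
        return cases + ctrls


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one fragment (case-group true means)."""

    fragment_id: str
    response_class: str  # null | early | late | gradual
    direction: str  # none | hyper | hypo
    effect_size: float  # percentage points; 0 for null
    shared_with_controls: bool
    means: tuple[float, ...]  # per-timepoint true means, fractions in [0, 1]

    def __post_init__(self) -> None:
        if (self.response_class == "null") != (self.direction == "none") or (
            self.response_class == "null"
        ) != (self.effect_size == 0):
            raise SimConfigError("null <=> direction none <=> effect_size 0")
        if any(not 0 <= m <= 1 for m in self.means):
            raise SimConfigError("true means must lie in [0, 1]")

    def control_means(self) -> tuple[float, ...]:
        """True means in the control group: baseline unless shared."""
        if self.shared_with_controls:
            return self.means
        return (self.means[0],) * len(self.means)


@dataclass(frozen=True)
class SimGenome:
    chrom: str
    sequence: str
    fragments: tuple[FragmentInterval, ...]  # measured (size-window) fragments
    gene_models: tuple[GeneModel, ...]
    planted_features: dict[str, str]  # fragment_id -> intended feature class

    def cpg_positions(self, fragment: FragmentInterval) -> list[int]:
        seq = self.sequence[fragment.start : fragment.end]
        return [
            fragment.start + i
            for i in range(len(seq) - 1)
            if seq[i : i + 2] == "CG"
        ]


def _fragment_body(length: int, n_cpgs: int, rng: np.random.Generator) -> str:
    """Interior of a measured fragment: 'CGG' + body + 'C' of given length.

    The leading CGG contributes one CpG; the body carries the remaining
    n_cpgs - 1 as isolated CG dinucleotides in an A/T filler, which by
    construction cannot create CCGG or extra CpGs.
    """
    body_len = length - 4
    k = n_cpgs - 1
    if body_len < 2 * k:
        raise SimConfigError(
            f"fragment of length {length} cannot host {n_cpgs} CpGs"
        )
    n_filler = body_len - 2 * k
    tokens = ["CG"] * k + list(rng.choice(["A", "T"], size=n_filler))
    rng.shuffle(tokens)
    return "CGG" + "".join(tokens) + "C"


def _spacer(rng: np.random.Generator, length: int = SPACER_LEN) -> str:
    return "CGG" + "".join(rng.choice(["A", "T"], size=length - 4)) + "C"


def _make_gene(
    gene_id: str,
    chrom: str,
    frag: FragmentInterval,
    feature: str,
    strand: str,
) -> GeneModel | None:
    """Plant a gene so that ``frag`` falls in the requested feature class.

    Geometry relies on >= 8 kb spacers flanking each measured fragment, so
    promoter windows (-5 kb/+1 kb) and gene bodies never reach a
    neighbouring measured fragment.
    """
    if feature == "intergenic":
        return None
    if feature == "promoter":
        if strand == "+":
            tss = frag.end + 200
            exons = ((tss, tss + 150), (tss + 300, tss + 450))
        else:
            tss = frag.start - 200
            exons = ((tss - 450, tss - 300), (tss - 150, tss + 1))
        return GeneModel(gene_id, chrom, strand, tss, exons)
    # gene-body classes: TSS planted 1.5 kb upstream so the promoter window
    # [-5 kb, +1 kb) ends 500 bp before the fragment
    tss = frag.start - 1500
    first = (tss, tss + 100)
    if feature == "exon":
        exons = (first, (frag.start - 20, frag.end + 20))
    elif feature == "intron":
        exons = (first, (frag.end + 200, frag.end + 300))
    elif feature == "boundary":
        mid = frag.start + frag.length // 2
        exons = (first, (frag.start - 20, mid), (frag.end + 200, frag.end + 300))
    else:
        raise SimConfigError(f"unknown feature {feature!r}")
    return GeneModel(gene_id, chrom, "+", tss, exons)


def build_sim_genome(config: SimConfig) -> SimGenome:
    """Construct a reference in which exactly ``n_fragments`` size-window
    MspI fragments exist, separated by long spacer fragments, plus gene
    models placing configured fractions of fragments into promoter, exon,
    intron, exon/intron-boundary and intergenic space."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    lo, hi = config.cpgs_per_fragment_range
    lengths = rng.integers(config.min_len, config.max_len + 1, size=config.n_fragments)
    cpgs = rng.integers(lo, hi + 1, size=config.n_fragments)

    feats = list(config.feature_fractions)
    probs = np.array([config.feature_fractions[f] for f in feats])
    feat_choice = rng.choice(len(feats), size=config.n_fragments, p=probs)

    pieces: list[str] = []
    pos = 0
    sp = _spacer(rng)
    pieces.append(sp)
    pos += len(sp)
    fragments: list[FragmentInterval] = []
    for i in range(config.n_fragments):
        body = _fragment_body(int(lengths[i]), int(cpgs[i]), rng)
        fragments.append(
            FragmentInterval(config.chrom, pos, pos + len(body), cpg_count=int(cpgs[i]))
        )
        pieces.append(body)
        pos += len(body)
        sp = _spacer(rng)
        pieces.append(sp)
        pos += len(sp)
    sequence = "".join(pieces)

    genes: list[GeneModel] = []
    planted: dict[str, str] = {}
    for i, frag in enumerate(fragments):
        feature = feats[feat_choice[i]]
        planted[frag.fragment_id] = feature
        strand = "+" if i % 2 == 0 else "-"
        if feature != "promoter":
            strand = "+"
        gene = _make_gene(f"G{i + 1:05d}", config.chrom, frag, feature, strand)
        if gene is not None:
            genes.append(gene)
    return SimGenome(config.chrom, sequence, tuple(fragments), tuple(genes), planted)


def _feasible_baseline(
    rng: np.random.Generator,
    config: SimConfig,
    direction: str,
    effect: float,
) -> float:
    """Baseline draw restricted so the full planted effect fits in [0.02, 0.98].

    Keeps the planted-class geometry exact (|delta| equals the nominal
    effect in true means) instead of letting clipping shrink it.
    """
    e = effect / 100.0
    lo, hi = (0.02, 0.98 - e) if direction == "hyper" else (0.02 + e, 0.98)
    if lo >= hi:
        raise SimConfigError(f"effect of {effect} points cannot fit in [0.02, 0.98]")
    for _ in range(10000):
        b = rng.beta(config.baseline_alpha, config.baseline_beta)
        if lo <= b <= hi:
            return float(b)
    return float(rng.uniform(lo, hi))  # pragma: no cover - beta covers (0,1)


def _class_means(base: float, response: str, direction: str, effect: float) -> tuple[float, ...]:
    e = effect / 100.0
    if direction == "hypo":
        e = -e
    if response == "early":
        means = (base, base + e, base + e)
    elif response == "late":
        means = (base, base, base + e)
    else:  # gradual
        means = (base, base + e / 2.0, base + e)
    return tuple(float(np.clip(m, 0.02, 0.98)) for m in means)


def plant_truth(
    config: SimConfig, fragments: Sequence[FragmentInterval]
) -> list[TruthRecord]:
    """Assign each fragment a response class and true per-timepoint means."""
    if not fragments:
        raise SimConfigError("plant_truth requires a non-empty fragment list")
    total_planted = sum(c.count for c in config.planted_classes)
    if total_planted > len(fragments):
        raise SimConfigError(
            f"{total_planted} planted fragments exceed {len(fragments)} available"
        )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    order = rng.permutation(len(fragments))
    records: dict[int, TruthRecord] = {}
    cursor = 0
    for cls in config.planted_classes:
        for _ in range(cls.count):
            idx = int(order[cursor])
            cursor += 1
            base = _feasible_baseline(rng, config, cls.direction, cls.effect_size)
            shared = bool(rng.random() < config.frac_shared_with_controls)
            means = _class_means(base, cls.response, cls.direction, cls.effect_size)
            records[idx] = TruthRecord(
                fragments[idx].fragment_id,
                cls.response,
                cls.direction,
                cls.effect_size,
                shared,
                means,
            )
    k = len(config.timepoints)
    for idx in range(len(fragments)):
        if idx in records:
            continue
        base = float(
            np.clip(rng.beta(config.baseline_alpha, config.baseline_beta), 0.02, 0.98)
        )
        records[idx] = TruthRecord(
            fragments[idx].fragment_id, "null", "none", 0.0, False, (base,) * k
        )
    return [records[i] for i in range(len(fragments))]


def _draw_coverage(
    rng: np.random.Generator, config: SimConfig, size: int
) -> np.ndarray:
    """Per-CpG read depths with mean ``mean_coverage`` and a minimum of 1."""
    mu = config.mean_coverage - 1.0
    if mu < 0:
        raise SimConfigError("mean_coverage must be >= 1")
    if config.coverage_model == "poisson":
        return 1 + rng.poisson(mu, size=size)
    if config.coverage_model == "nbinom":
        shape = config.coverage_dispersion
        p = shape / (shape + mu) if mu > 0 else 1.0
        return 1 + rng.negative_binomial(shape, p, size=size)
    raise SimConfigError(f"unknown coverage_model {config.coverage_model!r}")


def simulate_counts(
    truth: Sequence[TruthRecord],
    genome: SimGenome,
    config: SimConfig,
) -> dict[tuple[str, str], list[CpGCall]]:
    """Binomial read counts per CpG for every (participant, timepoint).

    The per-CpG success probability is the fragment's true mean for the
    participant's group at that timepoint plus a Gaussian per-(patient,
    fragment) offset (sd ``patient_sd`` points), clipped to [0, 1].
    """
    by_id = {t.fragment_id: t for t in truth}
    missing = [f.fragment_id for f in genome.fragments if f.fragment_id not in by_id]
    if missing:
        raise SimConfigError(f"truth does not cover fragments: {missing[:3]} ...")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    tps = list(config.timepoints)
    out: dict[tuple[str, str], list[CpGCall]] = {}
    cpg_pos = {f.fragment_id: genome.cpg_positions(f) for f in genome.fragments}
    for participant, group in config.participants:
        offsets = rng.normal(0.0, config.patient_sd / 100.0, size=len(genome.fragments))
        for ti, tp in enumerate(tps):
            calls: list[CpGCall] = []
            for fi, frag in enumerate(genome.fragments):
                rec = by_id[frag.fragment_id]
                means = rec.means if group == "case" else rec.control_means()
                p = float(np.clip(means[ti] + offsets[fi], 0.0, 1.0))
                positions = cpg_pos[frag.fragment_id]
                cov = _draw_coverage(rng, config, len(positions))
                meth = rng.binomial(cov, p)
                for pos, c, m in zip(positions, cov, meth):
                    calls.append(
                        CpGCall(genome.chrom, pos, int(m), int(c - m), participant, tp)
                    )
            out[(participant, tp)] = calls
    return out


def truth_to_frame(truth: Iterable[TruthRecord], timepoints: Sequence[str] = TIMEPOINTS) -> pd.DataFrame:
    rows = []
    for t in truth:
        row = {
            "fragment_id": t.fragment_id,
            "response_class": t.response_class,
            "direction": t.direction,
            "effect_size": t.effect_size,
            "shared_with_controls": t.shared_with_controls,
        }
        for tp, m in zip(timepoints, t.means):
            row[f"true_mean_{tp}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(
    genome: SimGenome,
    calls: dict[tuple[str, str], list[CpGCall]],
    truth: Sequence[TruthRecord],
    out_dir: str | Path,
    config: SimConfig,
) -> pd.DataFrame:
    """Write FASTA, BED12 gene models, per-sample coverage TSVs, the truth
    table and a manifest; returns the manifest frame."""
    if not truth:
        raise SimConfigError("refusing to write a dataset with empty truth")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    groups = dict(config.participants)

    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{genome.chrom}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    bed = out / "genes.bed"
    write_gene_models_bed12(genome.gene_models, bed)
    truth_path = out / "truth.tsv"
    truth_to_frame(truth, config.timepoints).to_csv(truth_path, sep="\t", index=False)

    rows = [
        {"file": fasta.name, "kind": "reference", "participant": "", "group": "", "timepoint": ""},
        {"file": bed.name, "kind": "gene_models", "participant": "", "group": "", "timepoint": ""},
        {"file": truth_path.name, "kind": "truth", "participant": "", "group": "", "timepoint": ""},
    ]
    for (participant, tp), sample_calls in sorted(calls.items()):
        name = f"{participant}_{tp}.cov.tsv"
        write_coverage_file(sample_calls, out / name)
        rows.append(
            {
                "file": name,
                "kind": "coverage",
                "participant": participant,
                "group": groups.get(participant, ""),
                "timepoint": tp,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def generate_dataset(config: SimConfig, out_dir: str | Path | None = None):
    """Convenience end-to-end generation; returns (genome, truth, calls[, manifest])."""
    genome = build_sim_genome(config)
    truth = plant_truth(config, genome.fragments)
    calls = simulate_counts(truth, genome, config)
    if out_dir is None:
        return genome, truth, calls
    manifest = write_dataset(genome, calls, truth, out_dir, config)
    return genome, truth, calls, manifest


__all__ = [
    "SimConfig",
    "SimConfigError",
    "PlantedClass",
    "TruthRecord",
    "SimGenome",
    "build_sim_genome",
    "plant_truth",
    "simulate_counts",
    "write_dataset",
    "generate_dataset",
    "truth_to_frame",
    "replace",
]
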