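"""Genomic feature annotation of MspI fragments.

Each fragment is assigned one feature class — promoter, exon/intron
boundary, exon, intron, or intergenic — and, except for intergenic
fragments, a linked gene.  Promoters are defined as the window from 5 kb
upstream to 1 kb downstream of the transcriptional start site (TSS),
strand-aware.  When a fragment overlaps several features the precedence
is promoter > exon/intron boundary > exon > intron; when several genes
offer the same feature class, the gene whose TSS is nearest wins.

Coordinates are 0-based half-open internally.  BED12 input is native;
GFF3 (1-based inclusive) is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .fragments import FragmentInterval

logger = logging.getLogger(__name__)

PROMOTER_UP = 5000
PROMOTER_DOWN = 1000

FEATURE_PROMOTER = "promoter"
FEATURE_BOUNDARY = "exon/intron boundary"
FEATURE_EXON = "exon"
FEATURE_INTRON = "intron"
FEATURE_INTERGENIC = "intergenic"

#: higher value = higher precedence
_PRECEDENCE = {
    FEATURE_PROMOTER: 4,
    FEATURE_BOUNDARY: 3,
    FEATURE_EXON: 2,
    FEATURE_INTRON: 1,
}


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, TSS and exon structure (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"{self.gene_id}: gene model requires at least one exon")
        for (a, b) in exons:
            if not (0 <= a < b):
                raise ValueError(f"{self.gene_id}: invalid exon [{a}, {b})")
        for (a1, b1), (a2, b2) in zip(exons[:-1], exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
        expected_tss = exons[0][0] if self.strand == "+" else exons[-1][1] - 1
        if self.tss != expected_tss:
            raise ValueError(
                f"{self.gene_id}: tss {self.tss} does not match first-exon "
                f"boundary {expected_tss} on strand {self.strand}"
            )

    @property
    def body(self) -> tuple[int, int]:
        """Gene body span from first to last exon."""
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class FeatureAnnotation:
    fragment_id: str
    feature: str
    gene_id: str | None
    distance_to_tss: int | None


def promoter_window(
    gene: GeneModel, up: int = PROMOTER_UP, down: int = PROMOTER_DOWN
) -> tuple[int, int]:
    """Strand-aware promoter interval (-up .. +down around the TSS), clipped at 0."""
    if gene.strand == "+":
        lo, hi = gene.tss - up, gene.tss + down
    else:
        lo, hi = gene.tss - down, gene.tss + up
    return (max(0, lo), max(0, hi))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _tss_distance(fragment: FragmentInterval, gene: GeneModel) -> int:
    """Signed distance from fragment midpoint to TSS; positive = downstream."""
    mid = (fragment.start + fragment.end) // 2
    d = mid - gene.tss
    return d if gene.strand == "+" else -d


def _classify_for_gene(
    fragment: FragmentInterval,
    gene: GeneModel,
    up: int,
    down: int,
) -> str | None:
    """Best feature this one gene offers for the fragment, or None."""
    span = (fragment.start, fragment.end)
    if _overlaps(span, promoter_window(gene, up, down)):
        return FEATURE_PROMOTER
    if not _overlaps(span, gene.body):
        return None
    in_exon = any(_overlaps(span, e) for e in gene.exons)
    introns = [
        (b1, a2) for (_, b1), (a2, _) in zip(gene.exons[:-1], gene.exons[1:]) if a2 > b1
    ]
    in_intron = any(_overlaps(span, i) for i in introns)
    if in_exon and in_intron:
        return FEATURE_BOUNDARY
    if in_exon:
        return FEATURE_EXON
    return FEATURE_INTRON


class GeneIndex:
    """Per-chromosome interval index over gene extents (body + promoter)."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        up: int = PROMOTER_UP,
        down: int = PROMOTER_DOWN,
    ) -> None:
        self.up = up
        self.down = down
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            win = promoter_window(g, up, down)
            lo = min(win[0], g.body[0])
            hi = max(win[1], g.body[1])
            self._trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)

    def candidates(self, fragment: FragmentInterval) -> list[GeneModel]:
        tree = self._trees.get(fragment.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(fragment.start, fragment.end)]


def annotate_fragment(
    fragment: FragmentInterval,
    genes: GeneIndex | Sequence[GeneModel],
    up: int = PROMOTER_UP,
    down: int = PROMOTER_DOWN,
) -> FeatureAnnotation:
    """Assign one feature class and (unless intergenic) a linked gene."""
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes, up, down)
    cands = genes.candidates(fragment)
    if not cands and fragment.chrom not in genes._trees:
        logger.warning(
            "fragment %s on chromosome absent from gene models; intergenic",
            fragment.fragment_id,
        )
    best: tuple[int, int, str, GeneModel] | None = None
    for g in cands:
        feat = _classify_for_gene(fragment, g, genes.up, genes.down)
        if feat is None:
            continue
        key = (_PRECEDENCE[feat], -abs(_tss_distance(fragment, g)))
        # deterministic final tie-break on gene_id
        if best is None or key > (best[0], best[1]) or (
            key == (best[0], best[1]) and g.gene_id < best[3].gene_id
        ):
            best = (key[0], key[1], feat, g)
    if best is None:
        return FeatureAnnotation(fragment.fragment_id, FEATURE_INTERGENIC, None, None)
    _, _, feat, gene = best
    return FeatureAnnotation(
        fragment.fragment_id, feat, gene.gene_id, _tss_distance(fragment, gene)
    )


def annotate_fragments(
    fragments: Sequence[FragmentInterval],
    genes: Iterable[GeneModel],
    up: int = PROMOTER_UP,
    down: int = PROMOTER_DOWN,
) -> list[FeatureAnnotation]:
    index = GeneIndex(genes, up, down)
    return [annotate_fragment(f, index) for f in fragments]


# ---------------------------------------------------------------------------
# Gene model I/O


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.body
            sizes = ",".join(str(b - a) for a, b in g.exons)
            offsets = ",".join(str(a - start) for a, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{start}\t{end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, _end, name, _score, strand = parts[:6]
            start = int(start)
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {name!r}")
            seen.add(name)
            tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
            genes.append(GeneModel(name, chrom, strand, tss, exons))
    return genes


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("ID", [g.id])[0]
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(g, featuretype="exon")
        )
        if not exons:
            exons = [(g.start - 1, g.end)]
        tss = exons[0][0] if g.strand == "+" else exons[-1][1] - 1
        genes.append(GeneModel(gid, g.seqid, g.strand, tss, tuple(exons)))
    return genes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3 (detected by extension/content).

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open; the TSS is the strand-appropriate end of the first exon.
    Duplicate gene ids are rejected.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".bed", ".bed12"):
        return _read_bed12(path)
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path)
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                if len(line.split("\t")) == 9:
                    return _read_gff3(path)
                return _read_bed12(path)
    return []
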