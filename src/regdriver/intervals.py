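"""Genomic interval algebra and per-gene regulatory spaces.

All coordinates are 0-based half-open throughout the package; 1-based input
formats (MAF/VCF/CADD tables) are converted at the reader boundary.

A gene's *regulatory space* is the union of its enhancer intervals, each
padded on both sides, with every annotated coding interval (of any gene)
subtracted, merged into sorted disjoint segments.  Genes whose space ends up
empty are dropped.  *Flanking regions* of a space are the +/- ``flank`` bp
around each segment with all enhancers (any gene) and all coding intervals
removed -- the neighbourhood used to estimate the local background mutation
frequency free of selection on regulatory elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "EnhancerGeneLink",
    "RegulatorySpace",
    "merge_intervals",
    "subtract_intervals",
    "build_regulatory_space",
    "flanking_regions",
    "exclude_immunoglobulin_proximal",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneAnnotation:
    """Gene with TSS anchor and (merged) coding intervals."""

    gene_id: str
    gene_type: str  # protein_coding / lncRNA / immunoglobulin / other
    strand: str
    chrom: str
    tss: int
    coding_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.coding_intervals = merge_intervals(self.coding_intervals)

    @property
    def body(self) -> GenomicInterval:
        """Span from TSS to the furthest coding base (gene body interval)."""
        points = [self.tss, self.tss + 1]
        for iv in self.coding_intervals:
            points.extend((iv.start, iv.end))
        return GenomicInterval(self.chrom, min(points), max(points))


@dataclass(frozen=True)
class EnhancerGeneLink:
    """One enhancer -> target gene prediction in one tissue."""

    enhancer: GenomicInterval
    gene_id: str
    tissue: str
    base_activity: float

    def __post_init__(self) -> None:
        if self.base_activity < 0:
            raise ValueError("base_activity must be non-negative")


@dataclass
class RegulatorySpace:
    """Merged non-coding intervals regulating one gene in one tissue."""

    gene_id: str
    tissue: str
    segments: list[GenomicInterval]
    mean_base_activity: float

    @property
    def total_length(self) -> int:
        return sum(len(seg) for seg in self.segments)

    @property
    def chroms(self) -> list[str]:
        return sorted({seg.chrom for seg in self.segments})


# ---------------------------------------------------------------------------
# interval algebra (arrays of [start, end) per chromosome)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}


def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Merge a (n, 2) array of sorted-by-start intervals into disjoint cover."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


def _subtract_array(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b for merged interval arrays on one chromosome."""
    if len(a) == 0:
        return a.reshape(0, 2)
    if len(b) == 0:
        return a
    out: list[tuple[int, int]] = []
    for start, end in a:
        cur = start
        # b intervals overlapping [start, end)
        for bs, be in b:
            if be <= cur:
                continue
            if bs >= end:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= end:
                break
        if cur < end:
            out.append((cur, end))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted disjoint cover of the union; per-chromosome; idempotent."""
    result: list[GenomicInterval] = []
    for chrom in sorted(_by_chrom(intervals)):
        for start, end in _merge_array(_by_chrom(intervals)[chrom]):
            result.append(GenomicInterval(chrom, int(start), int(end)))
    result.sort()
    return result


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases covered by ``a`` but not by ``b`` (both merged first)."""
    a_chrom = {c: _merge_array(v) for c, v in _by_chrom(a).items()}
    b_chrom = {c: _merge_array(v) for c, v in _by_chrom(b).items()}
    result: list[GenomicInterval] = []
    for chrom in sorted(a_chrom):
        diff = _subtract_array(a_chrom[chrom], b_chrom.get(chrom, np.empty((0, 2))))
        for start, end in diff:
            result.append(GenomicInterval(chrom, int(start), int(end)))
    result.sort()
    return result


# ---------------------------------------------------------------------------
# regulatory spaces


def _clip(start: int, end: int, chrom: str, chrom_sizes: Mapping[str, int] | None):
    start = max(0, start)
    if chrom_sizes is not None and chrom in chrom_sizes:
        end = min(end, chrom_sizes[chrom])
    if end <= start:
        return None
    return start, end


def build_regulatory_space(
    links: Sequence[EnhancerGeneLink],
    genes: Mapping[str, GeneAnnotation],
    pad: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, RegulatorySpace]:
    """Pool each gene's padded enhancers and subtract all coding intervals.

    Each enhancer is extended by ``pad`` bp both upstream and downstream
    (clipped at chromosome bounds), then the coding intervals of *all*
    annotated genes are removed and the remainder merged.  Genes whose space
    is empty after coding exclusion are omitted.  One enhancer may contribute
    to multiple genes' spaces.  ``mean_base_activity`` is the
    enhancer-length-weighted mean of the link activities.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    tissues = {link.tissue for link in links}
    if len(tissues) > 1:
        raise ValueError(f"links span multiple tissues: {sorted(tissues)}")
    coding_all = [iv for g in genes.values() for iv in g.coding_intervals]

    per_gene: dict[str, list[EnhancerGeneLink]] = {}
    for link in links:
        if link.gene_id not in genes:
            logger.warning("link targets unknown gene %s; skipped", link.gene_id)
            continue
        per_gene.setdefault(link.gene_id, []).append(link)

    spaces: dict[str, RegulatorySpace] = {}
    for gene_id, gene_links in per_gene.items():
        padded = []
        for link in gene_links:
            enh = link.enhancer
            clipped = _clip(enh.start - pad, enh.end + pad, enh.chrom, chrom_sizes)
            if clipped is not None:
                padded.append(GenomicInterval(enh.chrom, *clipped))
        segments = subtract_intervals(padded, coding_all)
        if not segments:
            continue
        weights = np.array([len(l.enhancer) for l in gene_links], dtype=float)
        acts = np.array([l.base_activity for l in gene_links], dtype=float)
        spaces[gene_id] = RegulatorySpace(
            gene_id=gene_id,
            tissue=next(iter(tissues)) if tissues else "",
            segments=segments,
            mean_base_activity=float(np.average(acts, weights=weights)),
        )
    return spaces


def flanking_regions(
    space: RegulatorySpace,
    all_enhancers: Iterable[GenomicInterval],
    coding: Iterable[GenomicInterval],
    flank: int = 50_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Pooled +/- ``flank`` bp around each segment, minus enhancers and coding.

    Every enhancer interval of the map in use (any target gene) is excluded,
    as are all coding intervals, so the flanks sample non-coding
    non-regulatory sequence only.  May be empty when the flanks are fully
    covered; callers must handle the zero-length denominator.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    raw: list[GenomicInterval] = []
    for seg in space.segments:
        left = _clip(seg.start - flank, seg.start, seg.chrom, chrom_sizes)
        if left is not None:
            raw.append(GenomicInterval(seg.chrom, *left))
        right = _clip(seg.end, seg.end + flank, seg.chrom, chrom_sizes)
        if right is not None:
            raw.append(GenomicInterval(seg.chrom, *right))
    exclusions = list(all_enhancers) + list(coding)
    return subtract_intervals(raw, exclusions)


def exclude_immunoglobulin_proximal(
    mutations,
    genes: Mapping[str, GeneAnnotation],
    distance: int = 10_000,
):
    """Drop mutations within ``distance`` bp of an immunoglobulin gene body.

    Immunoglobulin loci are the on-target substrate of AID-driven somatic
    hypermutation; mutations near them confound driver inference in B-cell
    cancers.  Distance is to the gene body (TSS-to-end span), boundary
    inclusive: a mutation exactly ``distance`` bp away is removed.

    ``mutations`` is a DataFrame with ``chrom`` and ``pos`` columns; the
    filtered DataFrame is returned.
    """
    ig = [g for g in genes.values() if g.gene_type == "immunoglobulin"]
    if not ig:
        logger.info("no immunoglobulin genes annotated; filter is a no-op")
        return mutations
    keep = np.ones(len(mutations), dtype=bool)
    pos = mutations["pos"].to_numpy()
    chrom = mutations["chrom"].to_numpy()
    for g in ig:
        body = g.body
        dist = np.where(
            pos < body.start, body.start - pos,
            np.where(pos >= body.end, pos - (body.end - 1), 0),
        )
        keep &= ~((chrom == body.chrom) & (dist <= distance))
    return mutations.loc[keep]
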