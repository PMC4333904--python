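"""Basal-plus-extension region-to-gene association (GREAT-style).

Each gene gets a basal promoter domain around its TSS (5 kb upstream, 1 kb
downstream by default, strand-oriented) extended in both directions up to
``max_ext`` nt beyond the basal edge, stopping early at the nearest
neighboring gene's basal domain. A genomic region is associated with every
gene whose extended domain it overlaps by at least 1 nt; the association
distance is signed midpoint-to-TSS (upstream of the gene negative).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .model import GeneAnnotation, GenomicInterval, ValidationError

__all__ = [
    "RegulatoryDomain",
    "build_domains",
    "GeneAssociation",
    "RegionGeneAssignment",
    "associate",
    "regulated_fraction",
    "DistanceHistogram",
    "distance_to_gene_distribution",
]


@dataclass(frozen=True)
class RegulatoryDomain:
    gene: GeneAnnotation
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValidationError(f"basal domain not contained in extension ({self.gene.gene})")


def build_domains(
    genes: Iterable[GeneAnnotation],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[RegulatoryDomain]:
    """Build basal-plus-extension regulatory domains for a gene list.

    Basal: ``[tss - basal_up, tss + basal_down)`` on the + strand, mirrored
    on the - strand, clipped to the chromosome. Extension: up to ``max_ext``
    nt beyond each basal edge, truncated at the nearest neighboring basal
    domain so an extension never overlaps another gene's basal domain.
    """
    genes = list(genes)
    symbols = [g.gene for g in genes]
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValidationError(f"duplicate gene symbols: {dupes}")

    def clip(chrom: str, pos: int) -> int:
        pos = max(pos, 0)
        if chrom_sizes and chrom in chrom_sizes:
            pos = min(pos, chrom_sizes[chrom])
        return pos

    basal: dict[str, GenomicInterval] = {}
    for g in genes:
        if g.strand == "+":
            s, e = g.tss - basal_up, g.tss + basal_down
        else:
            s, e = g.tss - basal_down, g.tss + basal_up
        basal[g.gene] = GenomicInterval(g.chrom, clip(g.chrom, s), clip(g.chrom, e))

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains = []
    for chrom, chrom_genes in by_chrom.items():
        chrom_genes.sort(key=lambda g: (basal[g.gene].start, basal[g.gene].end, g.gene))
        n = len(chrom_genes)
        # running max of basal ends among genes to the left (by basal start)
        prefix_max_end = [0] * n
        running = -1
        for i, g in enumerate(chrom_genes):
            prefix_max_end[i] = running
            running = max(running, basal[g.gene].end)
        suffix_min_start = [-1] * n
        running = -1
        for i in range(n - 1, -1, -1):
            suffix_min_start[i] = running
            running = (
                basal[chrom_genes[i].gene].start
                if running == -1
                else min(running, basal[chrom_genes[i].gene].start)
            )
        for i, g in enumerate(chrom_genes):
            b = basal[g.gene]
            left_block = prefix_max_end[i]  # -1 when no left neighbor
            ext_start = max(b.start - max_ext, 0)
            if left_block >= 0:
                # stop at the neighbor's basal edge; an overlapping neighbor
                # suppresses the extension entirely on this side
                ext_start = max(ext_start, min(left_block, b.start))
            right_block = suffix_min_start[i]
            ext_end = b.end + max_ext
            if right_block >= 0:
                ext_end = min(ext_end, max(right_block, b.end))
            ext_start = clip(chrom, ext_start)
            ext_end = clip(chrom, ext_end)
            domains.append(
                RegulatoryDomain(g, b, GenomicInterval(chrom, ext_start, ext_end))
            )
    domains.sort(key=lambda d: (d.gene.chrom, d.extended.start, d.gene.gene))
    return domains


class GeneAssociation(NamedTuple):
    gene: str
    distance: int  # signed midpoint-to-TSS, upstream of the gene negative


@dataclass
class RegionGeneAssignment:
    """Per-region associated genes, aligned with the input region list."""

    regions: list[GenomicInterval]
    assignments: list[list[GeneAssociation]]

    def genes_for(self, i: int) -> set[str]:
        return {a.gene for a in self.assignments[i]}

    def min_abs_distance(self, i: int) -> float:
        if not self.assignments[i]:
            return math.inf
        return float(min(abs(a.distance) for a in self.assignments[i]))


def _signed_distance(region: GenomicInterval, gene: GeneAnnotation) -> int:
    mid = region.midpoint
    return mid - gene.tss if gene.strand == "+" else gene.tss - mid


def associate(
    regions: Sequence[GenomicInterval], domains: Sequence[RegulatoryDomain]
) -> RegionGeneAssignment:
    """Associate each region with every gene whose extended domain overlaps it."""
    regions = list(regions)
    assignments: list[list[GeneAssociation]] = [[] for _ in regions]
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    starts_by_chrom = {
        chrom: np.array([regions[i].start for i in idxs], dtype=np.int64)
        for chrom, idxs in by_chrom.items()
    }
    maxw_by_chrom = {
        chrom: max(regions[i].width for i in idxs) for chrom, idxs in by_chrom.items()
    }
    order = {
        chrom: np.argsort(starts, kind="stable")
        for chrom, starts in starts_by_chrom.items()
    }
    for domain in domains:
        chrom = domain.gene.chrom
        if chrom not in by_chrom:
            continue
        idxs = by_chrom[chrom]
        starts = starts_by_chrom[chrom][order[chrom]]
        maxw = maxw_by_chrom[chrom]
        ext = domain.extended
        lo = np.searchsorted(starts, ext.start - maxw + 1, "left")
        hi = np.searchsorted(starts, ext.end, "left")
        for j in range(lo, hi):
            ri = idxs[int(order[chrom][j])]
            if regions[ri].overlaps(ext):
                assignments[ri].append(
                    GeneAssociation(
                        domain.gene.gene, _signed_distance(regions[ri], domain.gene)
                    )
                )
    for lst in assignments:
        lst.sort(key=lambda a: (abs(a.distance), a.gene))
    return RegionGeneAssignment(regions, assignments)


def regulated_fraction(
    assignment: RegionGeneAssignment, regulated_genes: set[str]
) -> tuple[int, int, float]:
    """``(k, n, k/n)`` where k counts regions associated with >= 1 regulated gene."""
    n = len(assignment.regions)
    if n == 0:
        raise ValidationError("regulated fraction of an empty region list")
    if not regulated_genes:
        warnings.warn("empty regulated gene set: fraction is 0", stacklevel=2)
        return 0, n, 0.0
    k = sum(
        1 for i in range(n) if assignment.genes_for(i) & regulated_genes
    )
    return k, n, k / n


@dataclass
class DistanceHistogram:
    edges: np.ndarray  # increasing; an infinite last edge is appended if absent
    counts: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        labels = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
            labels.append(f"[{lo:g}, {hi_s})")
        return pd.DataFrame({"distance_nt": labels, "count": self.counts})


def distance_to_gene_distribution(
    assignment: RegionGeneAssignment, edges: Sequence[float]
) -> DistanceHistogram:
    """Histogram of each region's minimum |distance| to an associated TSS.

    Regions with no associated gene count in the farthest (infinite) bin.
    """
    arr = np.asarray(edges, dtype=float)
    if not np.all(np.diff(arr) > 0):
        raise ValidationError("edges must be strictly increasing")
    if not math.isinf(arr[-1]):
        arr = np.append(arr, math.inf)
    counts = np.zeros(len(arr) - 1, dtype=int)
    for i in range(len(assignment.regions)):
        d = assignment.min_abs_distance(i)
        idx = np.searchsorted(arr, d, side="right") - 1
        counts[min(max(idx, 0), len(counts) - 1)] += 1
    return DistanceHistogram(arr, counts)
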