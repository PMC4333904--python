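"""Summit-region construction and the interval algebra under every analysis.

The unit of comparison throughout is the fixed-width *summit region*: a
window (200 nt by default) centered on a peak's summit. Two peaks co-occur
when their summit regions overlap by at least ``min_overlap`` nucleotides
(1 nt by default). Distances are summit-to-summit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import GenomicInterval, Peak, PeakSet, ValidationError

__all__ = [
    "summit_region",
    "summit_regions",
    "RegionIndex",
    "OverlapPartition",
    "overlap_partition",
    "nearest_distance",
    "nearest_distances",
    "top_fraction",
    "replicate_containment",
]


def summit_region(
    peak: Peak, width: int = 200, chrom_sizes: dict[str, int] | None = None
) -> GenomicInterval:
    """The ``width``-nt window centered on the peak summit.

    Clipped (truncated, not shifted) at position 0 and, when the chromosome
    length is known, at the chromosome end.
    """
    if width <= 0 or width % 2:
        raise ValidationError(f"summit-region width must be even and positive, got {width}")
    half = width // 2
    start = max(0, peak.summit - half)
    end = peak.summit + half
    if chrom_sizes and peak.chrom in chrom_sizes:
        end = min(end, chrom_sizes[peak.chrom])
    return GenomicInterval(peak.chrom, start, end)


def summit_regions(
    peaks: PeakSet, width: int = 200, chrom_sizes: dict[str, int] | None = None
) -> list[GenomicInterval]:
    return [summit_region(p, width, chrom_sizes) for p in peaks]


class RegionIndex:
    """Sorted per-chromosome interval index answering >= k nt overlap queries."""

    def __init__(self, regions: list[GenomicInterval]) -> None:
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for i, r in enumerate(regions):
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        for chrom, triples in by_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            idx = np.array([t[2] for t in triples], dtype=np.int64)
            max_width = int((ends - starts).max())
            self._index[chrom] = (starts, ends, idx, max_width)

    def query(self, interval: GenomicInterval, min_overlap: int = 1) -> list[int]:
        """Indices of stored regions overlapping ``interval`` by >= min_overlap nt."""
        entry = self._index.get(interval.chrom)
        if entry is None:
            return []
        starts, ends, idx, max_width = entry
        # overlap >= k  <=>  start <= q.end - k  and  end >= q.start + k
        lo = np.searchsorted(starts, interval.start + min_overlap - max_width, "left")
        hi = np.searchsorted(starts, interval.end - min_overlap, "right")
        hits = [
            int(idx[j])
            for j in range(lo, hi)
            if min(ends[j], interval.end) - max(starts[j], interval.start)
            >= min_overlap
        ]
        hits.sort()
        return hits


@dataclass
class OverlapPartition:
    """Partition of two peak sets by summit-region overlap.

    ``pair_map`` maps each A-peak index (into the sorted set ``a``) to the
    sorted indices of B-peaks whose summit regions overlap its own; a peak is
    *shared* when that list is non-empty, counted once however many partners
    it has.
    """

    a: PeakSet
    b: PeakSet
    shared_a: PeakSet
    unique_a: PeakSet
    shared_b: PeakSet
    unique_b: PeakSet
    pair_map: dict[int, list[int]]

    @property
    def n_shared_a(self) -> int:
        return len(self.shared_a)

    @property
    def n_shared_b(self) -> int:
        return len(self.shared_b)


def overlap_partition(
    a: PeakSet,
    b: PeakSet,
    width: int = 200,
    min_overlap: int = 1,
    chrom_sizes: dict[str, int] | None = None,
) -> OverlapPartition:
    """Partition ``a`` and ``b`` into shared/unique peaks by summit-region overlap."""
    if a.genome_id is not None and b.genome_id is not None and a.genome_id != b.genome_id:
        raise ValidationError(
            f"peak sets are on different genomes: {a.genome_id!r} vs {b.genome_id!r}"
        )
    regions_a = summit_regions(a, width, chrom_sizes)
    regions_b = summit_regions(b, width, chrom_sizes)
    pair_map: dict[int, list[int]] = {}
    hit_b: set[int] = set()
    if len(b):
        index_b = RegionIndex(regions_b)
        for i, ra in enumerate(regions_a):
            hits = index_b.query(ra, min_overlap)
            pair_map[i] = hits
            hit_b.update(hits)
    else:
        pair_map = {i: [] for i in range(len(a))}
    shared_a_idx = [i for i in range(len(a)) if pair_map[i]]
    unique_a_idx = [i for i in range(len(a)) if not pair_map[i]]
    shared_b_idx = sorted(hit_b)
    unique_b_idx = [j for j in range(len(b)) if j not in hit_b]
    return OverlapPartition(
        a=a,
        b=b,
        shared_a=a.subset(shared_a_idx),
        unique_a=a.subset(unique_a_idx),
        shared_b=b.subset(shared_b_idx),
        unique_b=b.subset(unique_b_idx),
        pair_map=pair_map,
    )


def nearest_distance(peak: Peak, reference: PeakSet) -> float:
    """Minimum absolute summit-to-summit distance to ``reference``.

    ``inf`` when the reference has no peak on the peak's chromosome, so
    inter-chromosomal "nearest" lands in the farthest distance bin.
    """
    index = reference.summit_index()
    entry = index.get(peak.chrom)
    if entry is None:
        return math.inf
    summits, _ = entry
    j = np.searchsorted(summits, peak.summit)
    best = math.inf
    if j < len(summits):
        best = min(best, abs(int(summits[j]) - peak.summit))
    if j > 0:
        best = min(best, abs(int(summits[j - 1]) - peak.summit))
    return float(best)


def nearest_distances(peaks: PeakSet, reference: PeakSet) -> np.ndarray:
    """Vectorised :func:`nearest_distance` over a whole set (peak order)."""
    out = np.full(len(peaks), math.inf)
    index = reference.summit_index()
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        entry = index.get(chrom)
        if entry is None:
            continue
        summits, _ = entry
        q = np.array([peaks[i].summit for i in idxs], dtype=np.int64)
        j = np.searchsorted(summits, q)
        left = np.where(j > 0, np.abs(q - summits[np.maximum(j - 1, 0)]), np.iinfo(np.int64).max)
        right = np.where(
            j < len(summits), np.abs(summits[np.minimum(j, len(summits) - 1)] - q),
            np.iinfo(np.int64).max,
        )
        d = np.minimum(left, right).astype(float)
        out[idxs] = d
    return out


def top_fraction(peaks: PeakSet, fraction: float = 0.01) -> PeakSet:
    """The ``ceil(fraction * N)`` peaks of highest fold enrichment.

    FE ties at the cutoff are broken by ``(chrom, start, end, name)`` order,
    so the selection is deterministic. An empty input yields an empty set.
    """
    if not (0 < fraction <= 1):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n = len(peaks)
    if n == 0:
        return peaks.subset([])
    k = math.ceil(fraction * n)
    order = sorted(
        range(n), key=lambda i: (-peaks[i].fold_enrichment, peaks[i].sort_key())
    )
    return peaks.subset(order[:k])


def replicate_containment(
    a: PeakSet,
    b: PeakSet,
    width: int = 200,
    chrom_sizes: dict[str, int] | None = None,
) -> float:
    """Fraction of A summit regions contained in B (overlap >= 1 nt).

    Used to check agreement between replicates; warns when the two sets do
    not carry the same factor/tissue labels.
    """
    if len(a) == 0:
        raise ValidationError("containment of an empty peak set is undefined")
    if (a.factor, a.tissue) != (b.factor, b.tissue):
        warnings.warn(
            f"comparing sets with different labels: "
            f"{(a.factor, a.tissue)} vs {(b.factor, b.tissue)}",
            stacklevel=2,
        )
    part = overlap_partition(a, b, width=width, min_overlap=1, chrom_sizes=chrom_sizes)
    return len(part.shared_a) / len(a)
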