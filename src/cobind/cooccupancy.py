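"""Distance-to-nearest-peak histograms stratified by fold enrichment.

These summaries capture the co-occupancy signal: if binding of one factor
promotes binding of another, the *high-FE* peaks of the first factor pile up
close to the second factor's summits while low-FE peaks do not. Distances
are summit-to-summit; peaks on chromosomes absent from the reference get an
infinite distance and land in the farthest bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .intervals import RegionIndex, nearest_distances, summit_regions
from .model import PeakSet, ValidationError

__all__ = [
    "DEFAULT_DISTANCE_EDGES",
    "DEFAULT_FE_EDGES",
    "DistanceFeTable",
    "distance_fe_histogram",
    "high_peak_proximity_fraction",
    "ProximityTestResult",
    "proximity_enrichment_test",
    "StratifiedProximityResult",
    "fe_stratified_proximity_test",
    "multiway_overlap",
]

# distance breakpoints (nt): "close" 200 nt, 1 kb, 10 kb, then unrelated
DEFAULT_DISTANCE_EDGES: tuple[float, ...] = (0.0, 200.0, 1000.0, 10000.0, math.inf)
# FE strata: low, intermediate, high (> 40), top (> 60)
DEFAULT_FE_EDGES: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, math.inf)


def _check_edges(edges: Sequence[float], kind: str) -> np.ndarray:
    arr = np.asarray(edges, dtype=float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ValidationError(f"{kind} edges need at least two values")
    if not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{kind} edges must be strictly increasing")
    return arr


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [e_i, e_{i+1}); values at/above the last edge fall in
    the last bin (i.e. the last bin is closed above)."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


@dataclass
class DistanceFeTable:
    """Counts of peaks per (distance-to-nearest-reference, FE) cell."""

    distance_edges: np.ndarray
    fe_edges: np.ndarray
    counts: np.ndarray  # shape (n_distance_bins, n_fe_bins)

    @property
    def n_peaks(self) -> int:
        return int(self.counts.sum())

    @property
    def distance_totals(self) -> np.ndarray:
        """Unstratified distance histogram (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def fe_totals(self) -> np.ndarray:
        """Unstratified FE histogram (column sums)."""
        return self.counts.sum(axis=0)

    @staticmethod
    def _labels(edges: np.ndarray) -> list[str]:
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
            out.append(f"[{lo:g}, {hi_s})")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self._labels(self.distance_edges), name="distance_nt"),
            columns=pd.Index(self._labels(self.fe_edges), name="fold_enrichment"),
        )


def distance_fe_histogram(
    peaks: PeakSet,
    reference: PeakSet,
    distance_edges: Sequence[float] = DEFAULT_DISTANCE_EDGES,
    fe_edges: Sequence[float] = DEFAULT_FE_EDGES,
) -> DistanceFeTable:
    """Bin each peak by nearest-reference distance and by its own FE."""
    d_edges = _check_edges(distance_edges, "distance")
    f_edges = _check_edges(fe_edges, "FE")
    if d_edges[0] != 0:
        raise ValidationError("first distance edge must be 0")
    nd = len(d_edges) - 1
    nf = len(f_edges) - 1
    counts = np.zeros((nd, nf), dtype=int)
    if len(peaks):
        dist = nearest_distances(peaks, reference)
        fe = peaks.fold_enrichments
        di = _bin_indices(dist, d_edges)
        fi = _bin_indices(fe, f_edges)
        np.add.at(counts, (di, fi), 1)
    return DistanceFeTable(d_edges, f_edges, counts)


def high_peak_proximity_fraction(
    peaks: PeakSet,
    reference: PeakSet,
    fe_threshold: float,
    distance_threshold: float,
) -> float:
    """Among peaks with FE > threshold, the fraction whose nearest reference
    summit lies within ``distance_threshold`` nt."""
    if fe_threshold <= 0 or distance_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    fe = peaks.fold_enrichments
    sel = fe > fe_threshold
    if not sel.any():
        raise ValidationError(f"no peak with FE > {fe_threshold}")
    dist = nearest_distances(peaks, reference)
    return float((dist[sel] <= distance_threshold).mean())


class ProximityTestResult(NamedTuple):
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    fraction_a: float
    fraction_b: float


def _fisher_near_far(near_a, far_a, near_b, far_b) -> tuple[float, float]:
    table = [[near_a, far_a], [near_b, far_b]]
    rows = (near_a + far_a, near_b + far_b)
    cols = (near_a + near_b, far_a + far_b)
    if 0 in rows or 0 in cols:
        warnings.warn(f"degenerate 2x2 table {table}: p set to 1", stacklevel=3)
        return float("nan"), 1.0
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def proximity_enrichment_test(
    peaks_a: PeakSet,
    peaks_b: PeakSet,
    reference: PeakSet,
    fe_threshold: float,
    distance_threshold: float,
) -> ProximityTestResult:
    """Do high peaks of factor A sit closer to the reference than factor B's?

    Two-sided Fisher's exact test on the 2x2 (factor x near/far) table built
    from peaks above the FE threshold in each set.
    """
    results = []
    for ps in (peaks_a, peaks_b):
        fe = ps.fold_enrichments
        sel = fe > fe_threshold
        if not sel.any():
            raise ValidationError(f"no {ps.factor or 'peak'} with FE > {fe_threshold}")
        near = int((nearest_distances(ps, reference)[sel] <= distance_threshold).sum())
        results.append((near, int(sel.sum()) - near))
    (na, fa), (nb, fb) = results
    odds, p = _fisher_near_far(na, fa, nb, fb)
    return ProximityTestResult(
        odds, p, ((na, fa), (nb, fb)), na / (na + fa), nb / (nb + fb)
    )


class StratifiedProximityResult(NamedTuple):
    high_fraction: float
    low_fraction: float
    n_high: int
    n_low: int
    odds_ratio: float
    p_value: float


def fe_stratified_proximity_test(
    peaks: PeakSet,
    reference: PeakSet,
    high_quantile: float = 0.99,
    low_quantile: float = 0.5,
    distance_threshold: float = 200.0,
) -> StratifiedProximityResult:
    """Compare reference proximity of the top-FE stratum against the low one.

    Peaks with FE above the ``high_quantile`` of the set's FE distribution
    form the high group; peaks at or below the ``low_quantile`` the low
    group. Fisher's exact test on near/far counts at ``distance_threshold``.
    """
    if len(peaks) == 0:
        raise ValidationError("empty peak set")
    fe = peaks.fold_enrichments
    hi_cut = float(np.quantile(fe, high_quantile))
    lo_cut = float(np.quantile(fe, low_quantile))
    hi = fe > hi_cut
    lo = fe <= lo_cut
    if not hi.any() or not lo.any():
        raise ValidationError("degenerate FE strata (all FE values equal?)")
    near = nearest_distances(peaks, reference) <= distance_threshold
    na, fa = int((near & hi).sum()), int((~near & hi).sum())
    nb, fb = int((near & lo).sum()), int((~near & lo).sum())
    odds, p = _fisher_near_far(na, fa, nb, fb)
    return StratifiedProximityResult(
        na / max(na + fa, 1), nb / max(nb + fb, 1), na + fa, nb + fb, odds, p
    )


def multiway_overlap(
    sets: list[PeakSet],
    width: int = 200,
    min_overlap: int = 1,
    chrom_sizes: dict[str, int] | None = None,
    names: list[str] | None = None,
) -> dict[frozenset[str], int]:
    """Combinatorial overlap: label each anchor region (first set) with the
    subset of the other factors whose summit regions overlap it, and count
    anchors per label combination (the empty frozenset = anchor alone)."""
    if len(sets) < 2:
        raise ValidationError("multiway overlap needs at least two peak sets")
    if names is None:
        names = []
        for i, s in enumerate(sets):
            label = s.factor or f"set{i}"
            if s.tissue:
                label = f"{label}_{s.tissue}"
            names.append(label)
    anchor = sets[0]
    anchor_regions = summit_regions(anchor, width, chrom_sizes)
    indexes = [
        (names[j], RegionIndex(summit_regions(sets[j], width, chrom_sizes)))
        for j in range(1, len(sets))
        if len(sets[j])
    ]
    counts: dict[frozenset[str], int] = {}
    for region in anchor_regions:
        label = frozenset(
            name for name, idx in indexes if idx.query(region, min_overlap)
        )
        counts[label] = counts.get(label, 0) + 1
    return counts
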