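"""Summit-centered conservation profiles and per-region mean conservation.

Scores are per-base, phastCons-like, in [0, 1]. Uncovered bases (no score in
the track) are excluded from every mean rather than imputed as zero — score
tracks legitimately omit unalignable bases; pass ``impute_zero=True`` to
treat them as 0 instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .model import ConservationTrack, GenomicInterval, PeakSet, ValidationError

__all__ = ["ConservationProfile", "profile", "MeanConservation", "mean_conservation"]


@dataclass
class ConservationProfile:
    """Average conservation by offset relative to the peak summit."""

    offsets: np.ndarray  # nt relative to summit, [-flank, flank)
    mean_score: np.ndarray  # NaN where no peak has coverage
    n_covered: np.ndarray  # peaks contributing at each offset

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_score": self.mean_score,
                "n_covered": self.n_covered,
            }
        )


def profile(
    peaks: PeakSet,
    track: ConservationTrack,
    flank: int = 500,
    impute_zero: bool = False,
) -> ConservationProfile:
    """Mean conservation at each offset in ``[-flank, flank)`` across summits."""
    if flank <= 0:
        raise ValidationError(f"flank must be positive, got {flank}")
    width = 2 * flank
    sums = np.zeros(width)
    counts = np.zeros(width, dtype=int)
    for p in peaks:
        vals = track.values(p.chrom, p.summit - flank, p.summit + flank)
        if impute_zero:
            vals = np.nan_to_num(vals, nan=0.0)
        covered = np.isfinite(vals)
        sums[covered] += vals[covered]
        counts += covered
    if counts.sum() == 0:
        raise ValidationError("no peak has any conservation coverage")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ConservationProfile(
        offsets=np.arange(-flank, flank), mean_score=mean, n_covered=counts
    )


class MeanConservation(NamedTuple):
    mean: float  # NaN when no base is covered
    covered_fraction: float


def mean_conservation(
    region: GenomicInterval, track: ConservationTrack, impute_zero: bool = False
) -> MeanConservation:
    """Mean score over the region's covered bases, plus coverage fraction."""
    vals = track.values(region.chrom, region.start, region.end)
    if impute_zero:
        vals = np.nan_to_num(vals, nan=0.0)
    covered = np.isfinite(vals)
    if not covered.any():
        return MeanConservation(float("nan"), 0.0)
    return MeanConservation(float(vals[covered].mean()), float(covered.mean()))
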