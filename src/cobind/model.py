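"""Core genomic data model shared by every analysis stage.

All coordinates are 0-based, half-open ``[start, end)``, matching BED. Any
1-based input dialect is converted at the I/O boundary, never inside the
model. Chromosome names are compared by exact string match; no ``chr``
prefix munging is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "ConservationTrack",
    "GeneAnnotation",
]


class ValidationError(ValueError):
    """An input violated a model invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_length(other) >= min_overlap

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class Peak:
    """A called binding event: an interval, its summit, and a fold enrichment.

    ``summit`` is an absolute 0-based coordinate inside ``interval``;
    ``fold_enrichment`` (FE) is the peak caller's ChIP/input signal ratio and
    serves as the peak's binding-strength score throughout the pipeline.
    """

    interval: GenomicInterval
    summit: int
    fold_enrichment: float
    score: float | None = None
    name: str = ""
    factor: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside interval {self.interval}"
            )
        if not self.fold_enrichment > 0:
            raise ValidationError(
                f"fold enrichment must be positive, got {self.fold_enrichment}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name)


class PeakSet:
    """A named, factor- and tissue-labelled collection of peaks.

    Peaks are kept sorted by ``(chrom, start, end, name)`` so parsing and all
    downstream selections are deterministic. A per-chromosome summit index is
    built lazily for nearest-distance queries.
    """

    def __init__(
        self,
        peaks: Iterable[Peak],
        factor: str = "",
        tissue: str = "",
        genome_id: str | None = None,
    ) -> None:
        self.peaks: list[Peak] = sorted(peaks, key=Peak.sort_key)
        self.factor = factor or (self.peaks[0].factor if self.peaks else "")
        self.tissue = tissue or (self.peaks[0].tissue if self.peaks else "")
        self.genome_id = genome_id
        self._summit_index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    @property
    def fold_enrichments(self) -> np.ndarray:
        return np.array([p.fold_enrichment for p in self.peaks], dtype=float)

    def chromosomes(self) -> list[str]:
        return sorted({p.chrom for p in self.peaks})

    def summit_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome ``(sorted_summits, peak_indices)`` arrays."""
        if self._summit_index is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for i, p in enumerate(self.peaks):
                by_chrom.setdefault(p.chrom, []).append((p.summit, i))
            index = {}
            for chrom, pairs in by_chrom.items():
                pairs.sort()
                summits = np.array([s for s, _ in pairs], dtype=np.int64)
                idx = np.array([i for _, i in pairs], dtype=np.int64)
                index[chrom] = (summits, idx)
            self._summit_index = index
        return self._summit_index

    def subset(self, indices: Sequence[int]) -> "PeakSet":
        return PeakSet(
            [self.peaks[i] for i in indices],
            factor=self.factor,
            tissue=self.tissue,
            genome_id=self.genome_id,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "name": [p.name for p in self.peaks],
                "summit": [p.summit for p in self.peaks],
                "fold_enrichment": [p.fold_enrichment for p in self.peaks],
                "factor": [p.factor for p in self.peaks],
                "tissue": [p.tissue for p in self.peaks],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PeakSet({len(self)} peaks, factor={self.factor!r}, "
            f"tissue={self.tissue!r})"
        )


class ConservationTrack:
    """Per-base conservation scores in [0, 1] with an explicit coverage mask.

    Internally one dense float array per chromosome, ``NaN`` marking bases
    with no score (phastCons-like tracks legitimately omit unalignable
    bases). Arrays grow on demand; queries outside the stored range return
    uncovered bases.
    """

    def __init__(self) -> None:
        self._scores: dict[str, np.ndarray] = {}

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray]) -> "ConservationTrack":
        track = cls()
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValidationError(f"conservation scores outside [0, 1] on {chrom}")
            track._scores[chrom] = arr.copy()
        return track

    def chromosomes(self) -> list[str]:
        return sorted(self._scores)

    def _ensure(self, chrom: str, length: int) -> np.ndarray:
        arr = self._scores.get(chrom)
        if arr is None:
            arr = np.full(length, np.nan)
            self._scores[chrom] = arr
        elif len(arr) < length:
            grown = np.full(length, np.nan)
            grown[: len(arr)] = arr
            arr = grown
            self._scores[chrom] = arr
        return arr

    def add_values(self, chrom: str, start: int, values) -> None:
        """Assign per-base scores at ``[start, start + len(values))``.

        Re-assigning a base with a conflicting value is an error (overlapping
        bedGraph records must agree); re-assigning the same value is allowed.
        """
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if start < 0:
            raise ValidationError(f"negative start {start} on {chrom}")
        if values.size == 0:
            return
        if np.nanmin(values) < 0 or np.nanmax(values) > 1:
            raise ValidationError(
                f"conservation score outside [0, 1] at {chrom}:{start}"
            )
        arr = self._ensure(chrom, start + values.size)
        window = arr[start : start + values.size]
        clash = np.isfinite(window) & (window != values)
        if clash.any():
            pos = start + int(np.flatnonzero(clash)[0])
            raise ValidationError(
                f"conflicting conservation values at {chrom}:{pos}"
            )
        arr[start : start + values.size] = values

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over ``[start, end)``; NaN where uncovered (incl. out of range)."""
        if end <= start:
            raise ValidationError(f"empty query [{start}, {end})")
        out = np.full(end - start, np.nan)
        arr = self._scores.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def region_mean(self, interval: GenomicInterval) -> tuple[float, float]:
        """``(mean score over covered bases, fraction of bases covered)``.

        The mean is ``NaN`` when no base in the region carries a score.
        """
        vals = self.values(interval.chrom, interval.start, interval.end)
        covered = np.isfinite(vals)
        frac = covered.mean()
        if not covered.any():
            return float("nan"), 0.0
        return float(vals[covered].mean()), float(frac)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its canonical TSS and strand."""

    gene: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError(f"negative TSS {self.tss} for {self.gene}")
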