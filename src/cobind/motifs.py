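"""Degenerate IUPAC consensus scanning and motif occurrence/enrichment stats.

Patterns are consensus strings over the IUPAC alphabet (``N`` = any base,
``D`` = A/G/T, ...). Scanning reports every — possibly overlapping — match
on the forward strand plus, when both strands are scanned, forward-strand
coordinates of matches to the reverse-complemented pattern. An ``N`` in the
scanned genome sequence matches only an ``N`` in the pattern (conservative:
an unsequenced base is never claimed as a motif hit).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy.stats import fisher_exact

from .io import Genome
from .model import GenomicInterval, ValidationError

__all__ = [
    "IUPAC",
    "MotifPattern",
    "MotifHit",
    "reverse_complement",
    "scan",
    "region_counts",
    "occurrence_fraction",
    "enrichment_test",
    "mean_hits_per_region",
    "PATTERNS",
]

# base sets matched by each IUPAC code when scanning genome sequence;
# genome 'N' is matched only by pattern 'N'.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(iupac: str) -> str:
    """Reverse complement of a nucleotide or IUPAC consensus string."""
    return iupac.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate consensus, e.g. ``MotifPattern("Meis", "TGACAG")``."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValidationError("empty motif pattern")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValidationError(
                f"invalid IUPAC character(s) {sorted(bad)} in pattern {self.iupac!r}"
            )
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.iupac) == self.iupac


class MotifHit(NamedTuple):
    pattern: str
    position: int  # 0-based offset of the match start, forward coordinates
    strand: str


# the recognition motifs used throughout: the canonical Meis hexamer, its
# 5-mer core (optionally with a degenerate 6th base), the Hox-Pbx composite
# site and its 7-mer core, and the minimal Hox homeodomain site.
PATTERNS: dict[str, MotifPattern] = {
    "TGACAG": MotifPattern("TGACAG", "TGACAG"),
    "TGACA": MotifPattern("TGACA", "TGACA"),
    "TGACAD": MotifPattern("TGACAD", "TGACAD"),
    "TGATNNAT": MotifPattern("TGATNNAT", "TGATNNAT"),
    "GATNNAT": MotifPattern("GATNNAT", "GATNNAT"),
    "TAAT": MotifPattern("TAAT", "TAAT"),
}


def _overlapping_finditer(regex: re.Pattern, seq: str) -> Iterable[int]:
    pos = 0
    while True:
        m = regex.search(seq, pos)
        if m is None:
            return
        yield m.start()
        pos = m.start() + 1


def _compile(iupac: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in iupac))


def scan(
    seq: str,
    pattern: MotifPattern,
    both_strands: bool = True,
    dedup_palindromic: bool = False,
) -> list[MotifHit]:
    """All matches of ``pattern`` in ``seq``, overlapping matches included.

    Reverse-strand hits are reported at the forward-strand coordinate of the
    match. For a palindromic pattern each site yields one hit per strand
    (two distinct binding events) unless ``dedup_palindromic`` collapses
    them. Hits are ordered by ``(position, strand)``.
    """
    seq = seq.upper()
    hits = [
        MotifHit(pattern.name, p, "+")
        for p in _overlapping_finditer(_compile(pattern.iupac), seq)
    ]
    if both_strands and not (dedup_palindromic and pattern.is_palindromic):
        rc = reverse_complement(pattern.iupac)
        hits += [
            MotifHit(pattern.name, p, "-")
            for p in _overlapping_finditer(_compile(rc), seq)
        ]
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def region_counts(
    regions: Iterable[GenomicInterval],
    genome: Genome,
    pattern: MotifPattern,
    both_strands: bool = True,
) -> np.ndarray:
    """Per-region hit count (both strands by default), in region order."""
    return np.array(
        [
            len(scan(genome.fetch_interval(r), pattern, both_strands=both_strands))
            for r in regions
        ],
        dtype=int,
    )


class OccurrenceResult(NamedTuple):
    k: int  # regions containing >= 1 hit
    n: int
    fraction: float


def occurrence_fraction(
    regions, genome: Genome, pattern: MotifPattern
) -> OccurrenceResult:
    """Fraction of regions containing at least one hit of the pattern."""
    regions = list(regions)
    if not regions:
        raise ValidationError("occurrence fraction of an empty region list")
    counts = region_counts(regions, genome, pattern)
    k = int((counts >= 1).sum())
    return OccurrenceResult(k, len(regions), k / len(regions))


class EnrichmentResult(NamedTuple):
    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def enrichment_test(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the contain / not-contain 2x2 table.

    A degenerate table (any zero margin) is uninformative: p = 1 with a
    warning, odds ratio NaN.
    """
    if not (0 <= k_fg <= n_fg and 0 <= k_bg <= n_bg):
        raise ValidationError("need 0 <= k <= n in both groups")
    table = ((k_fg, n_fg - k_fg), (k_bg, n_bg - k_bg))
    flat = [x for row in table for x in row]
    rows = (table[0][0] + table[0][1], table[1][0] + table[1][1])
    cols = (table[0][0] + table[1][0], table[0][1] + table[1][1])
    if 0 in rows or 0 in cols:
        warnings.warn(f"degenerate 2x2 table {table}: p set to 1", stacklevel=2)
        return EnrichmentResult(float("nan"), 1.0, table)
    odds, p = fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(float(odds), float(p), table)


def mean_hits_per_region(regions, genome: Genome, pattern: MotifPattern) -> float:
    """Arithmetic mean of per-region hit counts over all regions."""
    regions = list(regions)
    if not regions:
        raise ValidationError("mean hits of an empty region list")
    return float(region_counts(regions, genome, pattern).mean())
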