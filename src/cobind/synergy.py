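"""Cross-tissue peak matching, differential-binding classes and the
high-confidence synergistic-binding selection.

The biological question: does a tissue-specific factor (Hoxa2, present only
in the second branchial arch) *enhance* the binding of a broadly bound
factor (Meis) at the sites it co-occupies? The selection intersects two
independent lines of evidence, each computed on 200-nt summit regions:

* ``set_top`` — top-FE Meis peaks in the Hox-positive tissue whose summit
  region overlaps a top-FE Hoxa2 summit region;
* ``set_diff`` — Meis peaks whose FE is materially higher in the
  Hox-positive tissue than at the matched peak in the Hox-negative tissue
  and that overlap any Hoxa2 summit region.

Their region-overlap intersection is the synergistic set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

from .conservation import mean_conservation
from .intervals import overlap_partition, summit_regions, top_fraction
from .io import Genome
from .model import ConservationTrack, GenomicInterval, Peak, PeakSet, ValidationError
from .motifs import PATTERNS, region_counts

__all__ = [
    "PeakPair",
    "match_across_tissues",
    "DifferentialClasses",
    "classify_differential",
    "SynergySelection",
    "select_synergistic",
    "MotifFilterRules",
    "composite_motif_filter",
]


@dataclass
class PeakPair:
    """A peak in tissue A matched (or not) to a peak in tissue B.

    ``fe_ratio`` = FE_A / FE_B; ``inf`` when no B partner overlaps.
    """

    a: Peak
    b: Peak | None
    fe_ratio: float

    @property
    def matched(self) -> bool:
        return self.b is not None


def match_across_tissues(
    a: PeakSet,
    b: PeakSet,
    width: int = 200,
    chrom_sizes: dict[str, int] | None = None,
) -> list[PeakPair]:
    """Greedy one-to-one pairing of A peaks with overlapping B peaks.

    Candidate pairs (summit regions overlapping >= 1 nt) are assigned in
    order of increasing summit distance, ties broken by peak order, so the
    pairing is deterministic and a single broad B peak cannot absorb several
    A peaks. Unmatched A peaks get an absent partner and infinite ratio.
    """
    part = overlap_partition(a, b, width=width, min_overlap=1, chrom_sizes=chrom_sizes)
    candidates = []
    for ai, b_hits in part.pair_map.items():
        for bi in b_hits:
            dist = abs(a[ai].summit - b[bi].summit)
            candidates.append((dist, ai, bi))
    candidates.sort()
    paired_a: dict[int, int] = {}
    used_b: set[int] = set()
    for dist, ai, bi in candidates:
        if ai in paired_a or bi in used_b:
            continue
        paired_a[ai] = bi
        used_b.add(bi)
    pairs = []
    for ai in range(len(a)):
        if ai in paired_a:
            bp = b[paired_a[ai]]
            pairs.append(PeakPair(a[ai], bp, a[ai].fold_enrichment / bp.fold_enrichment))
        else:
            pairs.append(PeakPair(a[ai], None, math.inf))
    return pairs


@dataclass
class DifferentialClasses:
    """Differential-binding classes of the A-tissue peaks.

    ``higher_in_a``: FE ratio >= ratio_min; ``higher_in_b``: ratio <=
    1/ratio_min; ``a_only``: no overlapping B peak; ``unchanged``: matched
    pairs between the two thresholds (excluded from the three classes).
    """

    higher_in_a: PeakSet
    higher_in_b: PeakSet
    a_only: PeakSet
    unchanged: PeakSet


def classify_differential(
    pairs: list[PeakPair], ratio_min: float = 1.5
) -> DifferentialClasses:
    if ratio_min < 1:
        raise ValidationError(f"ratio_min must be >= 1, got {ratio_min}")
    buckets: dict[str, list[Peak]] = {
        "higher_in_a": [], "higher_in_b": [], "a_only": [], "unchanged": []
    }
    for pair in pairs:
        if not pair.matched:
            buckets["a_only"].append(pair.a)
        elif pair.fe_ratio >= ratio_min:
            buckets["higher_in_a"].append(pair.a)
        elif pair.fe_ratio <= 1 / ratio_min:
            buckets["higher_in_b"].append(pair.a)
        else:
            buckets["unchanged"].append(pair.a)
    first = pairs[0].a if pairs else None
    labels = dict(
        factor=first.factor if first else "", tissue=first.tissue if first else ""
    )
    return DifferentialClasses(
        **{k: PeakSet(v, **labels) for k, v in buckets.items()}
    )


@dataclass
class SynergySelection:
    """Outcome of the high-confidence synergistic-binding selection."""

    set_top: PeakSet  # top Meis (tissue A) overlapping top Hoxa2
    set_diff: PeakSet  # differential-up Meis overlapping any Hoxa2
    synergistic: PeakSet  # set_top regions overlapping a set_diff region
    width: int = 200

    @property
    def n_top(self) -> int:
        return len(self.set_top)

    @property
    def n_diff(self) -> int:
        return len(self.set_diff)

    @property
    def n_synergistic(self) -> int:
        return len(self.synergistic)

    def regions(self, which: str = "synergistic") -> list[GenomicInterval]:
        return summit_regions(getattr(self, which), self.width)


def select_synergistic(
    meis_iiba: PeakSet,
    meis_iba: PeakSet,
    hoxa2: PeakSet,
    top_frac: float = 0.01,
    ratio_min: float = 1.5,
    width: int = 200,
    hoxa2_top_frac: float | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> SynergySelection:
    """Select high-confidence synergistic binding events.

    ``top_frac`` is applied to the tissue-A (Hox-positive) Meis set;
    ``hoxa2_top_frac`` (defaulting to ``top_frac``) to the Hoxa2 set.
    Unmatched A-only Meis peaks are excluded from ``set_diff``: the
    differential class requires an FE comparison in both tissues.
    """
    if hoxa2_top_frac is None:
        hoxa2_top_frac = top_frac
    if len(hoxa2) == 0:
        warnings.warn("empty Hoxa2 set: synergy selection is empty", stacklevel=2)
        empty = meis_iiba.subset([])
        return SynergySelection(empty, empty, empty, width)

    top_meis = top_fraction(meis_iiba, top_frac)
    top_hox = top_fraction(hoxa2, hoxa2_top_frac)
    set_top = overlap_partition(
        top_meis, top_hox, width=width, min_overlap=1, chrom_sizes=chrom_sizes
    ).shared_a

    pairs = match_across_tissues(meis_iiba, meis_iba, width=width, chrom_sizes=chrom_sizes)
    up = classify_differential(pairs, ratio_min=ratio_min).higher_in_a
    set_diff = overlap_partition(
        up, hoxa2, width=width, min_overlap=1, chrom_sizes=chrom_sizes
    ).shared_a

    synergistic = overlap_partition(
        set_top, set_diff, width=width, min_overlap=1, chrom_sizes=chrom_sizes
    ).shared_a
    return SynergySelection(set_top, set_diff, synergistic, width)


@dataclass(frozen=True)
class MotifFilterRules:
    """Thresholds of the composite motif/conservation filter."""

    min_gatnnat: int = 1
    min_tgacad: int = 1
    min_taat: int = 3
    min_mean_conservation: float = 0.40


def composite_motif_filter(
    regions: Iterable[GenomicInterval],
    genome: Genome,
    track: ConservationTrack,
    rules: MotifFilterRules = MotifFilterRules(),
) -> list[GenomicInterval]:
    """Keep regions enriched in Hox and Meis recognition motifs and conserved.

    A region passes when it carries >= ``min_gatnnat`` GATNNAT, >=
    ``min_tgacad`` TGACAD and >= ``min_taat`` TAAT hits (both strands) and
    its mean per-base conservation over covered bases is >=
    ``min_mean_conservation``. Regions with zero covered bases are excluded
    with a warning.
    """
    regions = list(regions)
    if not regions:
        return []
    gat = region_counts(regions, genome, PATTERNS["GATNNAT"])
    tga = region_counts(regions, genome, PATTERNS["TGACAD"])
    taat = region_counts(regions, genome, PATTERNS["TAAT"])
    kept = []
    for i, region in enumerate(regions):
        cons = mean_conservation(region, track)
        if cons.covered_fraction == 0:
            warnings.warn(
                f"region {region} has no conservation coverage: excluded",
                stacklevel=2,
            )
            continue
        if (
            gat[i] >= rules.min_gatnnat
            and tga[i] >= rules.min_tgacad
            and taat[i] >= rules.min_taat
            and cons.mean >= rules.min_mean_conservation
        ):
            kept.append(region)
    return kept
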