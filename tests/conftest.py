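"""Shared fixtures and independent brute-force oracles.

The oracles deliberately reimplement each operation in the most naive way
possible (all-pairs scans, sliding windows, exact hypergeometric sums) so
the fast implementations can be checked against them.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from cobind.model import GenomicInterval, Peak, PeakSet


# ---------------------------------------------------------------------------
# construction helpers


def make_peak(summit, fe, chrom="chr1", half=300, name="", factor="", tissue=""):
    return Peak(
        interval=GenomicInterval(chrom, max(0, summit - half), summit + half),
        summit=summit,
        fold_enrichment=fe,
        name=name,
        factor=factor,
        tissue=tissue,
    )


def make_set(summit_fe_pairs, chrom="chr1", factor="", tissue=""):
    return PeakSet(
        [
            make_peak(s, fe, chrom=chrom, name=f"p{i}", factor=factor, tissue=tissue)
            for i, (s, fe) in enumerate(summit_fe_pairs)
        ],
        factor=factor,
        tissue=tissue,
    )


def random_peakset(rng, n, chroms=("chr1", "chr2"), span=100_000, factor="", tissue=""):
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        summit = int(rng.integers(400, span))
        fe = float(np.exp(rng.normal(2.5, 0.8)))
        peaks.append(make_peak(summit, fe, chrom=chrom, name=f"r{i}"))
    return PeakSet(peaks, factor=factor, tissue=tissue)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_summit_region(peak, width=200):
    half = width // 2
    return (peak.chrom, max(0, peak.summit - half), peak.summit + half)


def brute_overlap_pairs(a, b, width=200, min_overlap=1):
    """All-pairs summit-region overlap scan: {a_index: sorted b_indices}."""
    out = {}
    for i, pa in enumerate(a):
        ca, sa, ea = brute_summit_region(pa, width)
        hits = []
        for j, pb in enumerate(b):
            cb, sb, eb = brute_summit_region(pb, width)
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap:
                hits.append(j)
        out[i] = hits
    return out


def brute_nearest(peak, reference):
    best = math.inf
    for q in reference:
        if q.chrom == peak.chrom:
            best = min(best, abs(q.summit - peak.summit))
    return best


def brute_bin(value, edges):
    """Half-open bins; last bin closed above."""
    for k in range(len(edges) - 1):
        if edges[k] <= value < edges[k + 1]:
            return k
    return len(edges) - 2


def brute_distance_fe_counts(peaks, reference, distance_edges, fe_edges):
    counts = np.zeros((len(distance_edges) - 1, len(fe_edges) - 1), dtype=int)
    for p in peaks:
        d = brute_nearest(p, reference)
        counts[brute_bin(d, distance_edges), brute_bin(p.fold_enrichment, fe_edges)] += 1
    return counts


def brute_fisher_two_sided(table):
    """Exact two-sided Fisher p: sum of hypergeometric probabilities of all
    tables with the same margins that are no more probable than the observed
    one. Exact rational arithmetic, no scipy."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return float(min(total, Fraction(1)))


IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
       "W": "W", "K": "M", "M": "K", "B": "V", "D": "H", "H": "D", "V": "B",
       "N": "N"}


def brute_revcomp(s):
    return "".join(_RC[c] for c in reversed(s))


def brute_scan_count(seq, iupac, both_strands=True):
    """Sliding-window character-set matcher (overlaps counted)."""
    seq = seq.upper()

    def count(pat):
        total = 0
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + k] in IUPAC_SETS[p] for k, p in enumerate(pat)):
                total += 1
        return total

    n = count(iupac)
    if both_strands:
        n += count(brute_revcomp(iupac))
    return n


# ---------------------------------------------------------------------------
# session-scoped simulated landscapes (shared by recovery-style tests)


@pytest.fixture(scope="session")
def default_landscapes():
    """20 default-parameter landscapes with their synergy selections."""
    from cobind.simulate import (
        SimulationConfig,
        recovery_report,
        selection_protocol,
        simulate,
    )
    from cobind.synergy import select_synergistic

    runs = []
    for seed in range(20):
        cfg = SimulationConfig(seed=seed)
        land = simulate(cfg)
        proto = selection_protocol(cfg)
        sel = select_synergistic(
            land.meis_iiba, land.meis_iba, land.hoxa2,
            top_frac=proto["top_frac"], hoxa2_top_frac=proto["hoxa2_top_frac"],
            ratio_min=proto["ratio_min"], chrom_sizes=land.chrom_sizes(),
        )
        runs.append((cfg, land, sel, recovery_report(sel, land.truth)))
    return runs
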