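"""Synthetic two-tissue peak-landscape generator with planted ground truth.

The generator emulates the statistical structure of a comparative ChIP-seq
experiment in a Hox-negative ("IBA") and a Hox-positive ("IIBA") tissue:

* a random genome with a chosen GC content;
* shared background Meis binding in both tissues, log-normal fold
  enrichments with small multiplicative between-tissue noise;
* a set of *synergy loci* where the tissue-B (Hox-positive) Meis FE is
  multiplied by ``enhancement_factor``, a Hoxa2 peak sits within 100 nt of
  the Meis summit, and Hox/Meis recognition motifs are written into the
  genome sequence;
* Hoxa2 decoy peaks at a fraction of background loci (bound, not enhanced);
* a conservation track elevated at planted windows;
* a gene grid with a configurable fraction of synergy loci falling in
  regulated genes' domains.

Every artifact draws from its own random stream derived from the master
seed, so adding an output never perturbs earlier ones, and identical
configs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .model import (
    ConservationTrack,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
)
from .motifs import IUPAC
from .synergy import SynergySelection

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedLandscape",
    "simulate",
    "generate",
    "selection_protocol",
    "RecoveryReport",
    "recovery_report",
]

_LOCUS_HALF = 100  # synergy locus = 200-nt window, matching the summit region
_CONS_HALF = 700  # conservation coverage half-width around each locus
_MIN_SEP = 1200  # minimum locus separation (nt)
_MARGIN = 5000  # keep loci away from chromosome ends


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape.

    FE is log-normal (called-peak fold enrichments are strictly positive and
    right-skewed): ``exp(Normal(fe_log_mean, fe_log_sd))``. At synergy loci
    the tissue-B FE is the tissue-A FE times ``enhancement_factor`` times
    log-normal noise of sd ``enhancement_noise_sd``; at background loci the
    same without the enhancement.
    """

    seed: int = 0
    genome_length: int = 2_000_000
    chrom: str = "chr1"
    gc_content: float = 0.42
    n_background_peaks: int = 500
    n_synergy_loci: int = 30
    fe_log_mean: float = math.log(12.0)
    fe_log_sd: float = 0.4
    enhancement_factor: float = 3.0
    enhancement_noise_sd: float = 0.1
    summit_jitter: int = 30
    hoxa2_offset_max: int = 100
    hoxa2_decoy_fraction: float = 0.1
    motif_plant_counts: dict = field(
        default_factory=lambda: {"GATNNAT": 1, "TGACA": 1, "TAAT": 3}
    )
    cons_high: tuple = (8.0, 2.0)  # Beta(a, b) inside planted windows
    cons_low: tuple = (2.0, 8.0)  # Beta(a, b) at background bases
    n_genes: int = 40
    regulated_gene_fraction_at_synergy: float = 0.5

    def validate(self) -> None:
        if self.enhancement_factor <= 1:
            raise ValidationError("enhancement_factor must be > 1")
        for name in ("gc_content", "hoxa2_decoy_fraction", "regulated_gene_fraction_at_synergy"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        n_peaks = self.n_background_peaks + self.n_synergy_loci
        if self.genome_length < 10 * n_peaks * 200:
            raise ValidationError(
                f"genome too small: need >= {10 * n_peaks * 200} nt for "
                f"{n_peaks} peaks, got {self.genome_length}"
            )
        n_slots = len(range(_MARGIN, self.genome_length - _MARGIN, _MIN_SEP))
        if n_peaks > n_slots:
            raise ValidationError(
                f"cannot place {n_peaks} loci at >= {_MIN_SEP} nt separation"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cons_high"] = list(self.cons_high)
        d["cons_low"] = list(self.cons_low)
        return d


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery scoring."""

    synergy_loci: list[GenomicInterval]
    motif_positions: list[list[tuple[str, int]]]  # per locus: (pattern, abs pos)
    regulated_genes: set[str]
    fe: dict  # arrays: synergy/background FE per tissue

    def to_dict(self) -> dict:
        return {
            "synergy_loci": [
                [iv.chrom, iv.start, iv.end] for iv in self.synergy_loci
            ],
            "motif_positions": [
                [[name, int(pos)] for name, pos in locus]
                for locus in self.motif_positions
            ],
            "regulated_genes": sorted(self.regulated_genes),
            "fe": {k: [float(x) for x in v] for k, v in self.fe.items()},
        }


@dataclass
class SimulatedLandscape:
    config: SimulationConfig
    sequences: dict[str, str]
    meis_iba: PeakSet
    meis_iiba: PeakSet
    hoxa2: PeakSet
    conservation: ConservationTrack
    genes: list[GeneAnnotation]
    regulated_genes: set[str]
    truth: GroundTruth

    @property
    def genome(self) -> cio.Genome:
        return cio.Genome.from_dict(self.sequences)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "meis_iba": outdir / "meis_IBA.narrowPeak",
            "meis_iiba": outdir / "meis_IIBA.narrowPeak",
            "hoxa2": outdir / "hoxa2_IIBA.narrowPeak",
            "conservation": outdir / "conservation.bedGraph",
            "genes": outdir / "genes.tsv",
            "regulated_genes": outdir / "regulated_genes.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        cio.write_fasta(self.sequences, paths["genome"])
        cio.write_narrowpeak(self.meis_iba, paths["meis_iba"])
        cio.write_narrowpeak(self.meis_iiba, paths["meis_iiba"])
        cio.write_narrowpeak(self.hoxa2, paths["hoxa2"])
        cio.write_bedgraph(self.conservation, paths["conservation"])
        cio.write_gene_table(self.genes, paths["genes"])
        cio.write_gene_list(self.regulated_genes, paths["regulated_genes"])
        with open(paths["ground_truth"], "w") as fh:
            json.dump(self.truth.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].copy()


def _instantiate_iupac(rng: np.random.Generator, iupac: str) -> str:
    out = []
    for c in iupac:
        choices = IUPAC[c].replace("N", "") or "ACGT"
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _make_peak(chrom, summit, fe, name, factor, tissue, genome_length) -> Peak:
    start = max(0, summit - 200)
    end = min(genome_length, summit + 200)
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        summit=int(summit),
        fold_enrichment=float(fe),
        name=name,
        factor=factor,
        tissue=tissue,
    )


def simulate(config: SimulationConfig) -> SimulatedLandscape:
    """Generate the full landscape deterministically from ``config.seed``."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_genome, rng_loci, rng_fe, rng_hox, rng_cons, rng_genes = (
        np.random.default_rng(s) for s in streams
    )
    L = config.genome_length
    chrom = config.chrom
    n_syn = config.n_synergy_loci
    n_bg = config.n_background_peaks

    # --- locus placement on a jittered lattice (guaranteed separation) ---
    slots = np.arange(_MARGIN, L - _MARGIN, _MIN_SEP)
    chosen = rng_loci.choice(len(slots), size=n_syn + n_bg, replace=False)
    jitter = rng_loci.integers(-_MIN_SEP // 4, _MIN_SEP // 4 + 1, size=n_syn + n_bg)
    centers = slots[chosen] + jitter
    syn_centers = np.sort(centers[:n_syn])
    bg_centers = np.sort(centers[n_syn:])

    # --- genome with planted motifs at synergy loci ---
    seq = _random_sequence(rng_genome, L, config.gc_content)
    plant_list: list[str] = []
    for motif, count in config.motif_plant_counts.items():
        plant_list += [motif] * int(count)
    motif_positions: list[list[tuple[str, int]]] = []
    slot_offsets = np.arange(0, 2 * _LOCUS_HALF - 9, 10)  # 10-nt slots
    if len(plant_list) > len(slot_offsets):
        raise ValidationError("too many motifs to plant in a 200-nt window")
    for c in syn_centers:
        offs = rng_loci.choice(len(slot_offsets), size=len(plant_list), replace=False)
        placed = []
        for motif, oi in zip(plant_list, offs):
            concrete = _instantiate_iupac(rng_loci, motif)
            pos = int(c - _LOCUS_HALF + slot_offsets[oi])
            seq[pos : pos + len(concrete)] = np.frombuffer(
                concrete.encode(), dtype=np.uint8
            )
            placed.append((motif, pos))
        placed.sort(key=lambda t: t[1])
        motif_positions.append(placed)
    sequences = {chrom: seq.tobytes().decode("ascii")}

    # --- fold enrichments ---
    def lognorm(rng, n):
        return np.exp(rng.normal(config.fe_log_mean, config.fe_log_sd, n))

    def noise(rng, n):
        return np.exp(rng.normal(0.0, config.enhancement_noise_sd, n))

    bg_fe_a = lognorm(rng_fe, n_bg)
    bg_fe_b = bg_fe_a * noise(rng_fe, n_bg)
    syn_fe_a = lognorm(rng_fe, n_syn)
    syn_fe_b = syn_fe_a * config.enhancement_factor * noise(rng_fe, n_syn)

    # --- summits (independent jitter per tissue) ---
    j = config.summit_jitter
    bg_sum_a = bg_centers + rng_loci.integers(-j, j + 1, n_bg)
    bg_sum_b = bg_centers + rng_loci.integers(-j, j + 1, n_bg)
    syn_sum_a = syn_centers + rng_loci.integers(-j, j + 1, n_syn)
    syn_sum_b = syn_centers + rng_loci.integers(-j, j + 1, n_syn)

    def build_set(summits, fes, factor, tissue, prefix):
        peaks = [
            _make_peak(chrom, s, fe, f"{prefix}_{i:04d}", factor, tissue, L)
            for i, (s, fe) in enumerate(zip(summits, fes))
        ]
        return PeakSet(peaks, factor=factor, tissue=tissue, genome_id="synthetic")

    meis_iba = build_set(
        np.concatenate([bg_sum_a, syn_sum_a]),
        np.concatenate([bg_fe_a, syn_fe_a]),
        "Meis", "IBA", "meis_IBA",
    )
    meis_iiba = build_set(
        np.concatenate([bg_sum_b, syn_sum_b]),
        np.concatenate([bg_fe_b, syn_fe_b]),
        "Meis", "IIBA", "meis_IIBA",
    )

    # --- Hoxa2: all synergy loci plus decoy background loci ---
    n_decoy = int(round(config.hoxa2_decoy_fraction * n_bg))
    decoy_idx = np.sort(rng_hox.choice(n_bg, size=n_decoy, replace=False))
    hox_syn_sum = syn_centers + rng_hox.integers(
        -config.hoxa2_offset_max, config.hoxa2_offset_max + 1, n_syn
    )
    hox_decoy_sum = bg_centers[decoy_idx] + rng_hox.integers(
        -config.hoxa2_offset_max, config.hoxa2_offset_max + 1, n_decoy
    )
    # synergistic sites carry the strongest Hoxa2 signal (reciprocal
    # enhancement); decoys draw from the baseline FE distribution
    hox_syn_fe = lognorm(rng_hox, n_syn) * config.enhancement_factor
    hox_decoy_fe = lognorm(rng_hox, n_decoy)
    hoxa2 = build_set(
        np.concatenate([hox_syn_sum, hox_decoy_sum]),
        np.concatenate([hox_syn_fe, hox_decoy_fe]),
        "Hoxa2", "IIBA", "hoxa2_IIBA",
    )

    # --- conservation: covered around every locus, elevated at planted sites ---
    arr = np.full(L, np.nan)
    for c in np.sort(np.concatenate([syn_centers, bg_centers])):
        lo, hi = max(0, c - _CONS_HALF), min(L, c + _CONS_HALF)
        arr[lo:hi] = rng_cons.beta(*config.cons_low, size=hi - lo)
    for c in syn_centers:
        lo, hi = max(0, c - _LOCUS_HALF), min(L, c + _LOCUS_HALF)
        arr[lo:hi] = rng_cons.beta(*config.cons_high, size=hi - lo)
    conservation = ConservationTrack.from_arrays({chrom: arr})

    # --- genes on a grid; regulated genes cover a fraction of synergy loci ---
    tss_grid = np.linspace(_MARGIN, L - _MARGIN, config.n_genes).astype(int)
    genes = [
        GeneAnnotation(f"gene{i:03d}", chrom, int(t), "+" if i % 2 == 0 else "-")
        for i, t in enumerate(tss_grid)
    ]
    n_reg_loci = int(round(config.regulated_gene_fraction_at_synergy * n_syn))
    regulated: set[str] = set()
    if n_reg_loci and n_syn:
        reg_loci = rng_genes.choice(n_syn, size=n_reg_loci, replace=False)
        for li in reg_loci:
            nearest = int(np.argmin(np.abs(tss_grid - syn_centers[li])))
            regulated.add(genes[nearest].gene)

    truth = GroundTruth(
        synergy_loci=[
            GenomicInterval(chrom, int(c - _LOCUS_HALF), int(c + _LOCUS_HALF))
            for c in syn_centers
        ],
        motif_positions=motif_positions,
        regulated_genes=regulated,
        fe={
            "synergy_fe_iba": syn_fe_a,
            "synergy_fe_iiba": syn_fe_b,
            "background_fe_iba": bg_fe_a,
            "background_fe_iiba": bg_fe_b,
        },
    )
    return SimulatedLandscape(
        config=config,
        sequences=sequences,
        meis_iba=meis_iba,
        meis_iiba=meis_iiba,
        hoxa2=hoxa2,
        conservation=conservation,
        genes=genes,
        regulated_genes=regulated,
        truth=truth,
    )


def generate(config: SimulationConfig, outdir=None):
    """Simulate and, when ``outdir`` is given, write all artifact files."""
    landscape = simulate(config)
    if outdir is not None:
        landscape.write(outdir)
    return landscape


def selection_protocol(config: SimulationConfig) -> dict:
    """Synergy-selection parameters sized to a simulated landscape.

    With log-normal FE the planted peaks are shifted by
    ``log(enhancement) / fe_log_sd`` standard deviations, so a top-FE window
    a few times larger than the planted fraction still contains the lower
    tail of the enhanced peaks. The Meis window is 3.5x the planted
    fraction; the Hoxa2 window 4/3 of the planted count over the (much
    smaller) Hoxa2 set.
    """
    n_total = config.n_synergy_loci + config.n_background_peaks
    n_hox = config.n_synergy_loci + int(
        round(config.hoxa2_decoy_fraction * config.n_background_peaks)
    )
    if config.n_synergy_loci == 0 or n_hox == 0:
        return {"top_frac": 0.01, "hoxa2_top_frac": 0.01, "ratio_min": 1.5}
    return {
        "top_frac": min(1.0, 3.5 * config.n_synergy_loci / n_total),
        "hoxa2_top_frac": min(1.0, (4 / 3) * config.n_synergy_loci / n_hox),
        "ratio_min": 1.5,
    }


@dataclass
class RecoveryReport:
    precision: float
    recall: float
    n_selected: int
    n_loci: int
    empty_selection: bool = False


def recovery_report(
    selection: SynergySelection, truth: GroundTruth, min_overlap: int = 1
) -> RecoveryReport:
    """Precision/recall of the synergistic set against planted loci.

    A selected summit region is a true positive when it overlaps a planted
    locus by >= ``min_overlap`` nt; recall counts planted loci hit by at
    least one selected region. An empty selection reports precision 0 with
    a flag rather than NaN.
    """
    regions = selection.regions("synergistic")
    n_loci = len(truth.synergy_loci)
    if not regions:
        return RecoveryReport(0.0, 0.0, 0, n_loci, empty_selection=True)
    from .intervals import RegionIndex

    index = RegionIndex(truth.synergy_loci)
    tp = 0
    hit_loci: set[int] = set()
    for r in regions:
        hits = index.query(r, min_overlap)
        if hits:
            tp += 1
            hit_loci.update(hits)
    recall = len(hit_loci) / n_loci if n_loci else 0.0
    return RecoveryReport(tp / len(regions), recall, len(regions), n_loci)
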