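"""End-to-end orchestration: simulate or ingest, then run every analysis
stage in dependency order and emit a machine-readable run report.

The report records every parameter and headline statistic (overlap counts,
synergy set sizes, motif fractions and p-values, conservation contrast,
regulated-gene fractions, recovery metrics when ground truth is present).
Rerunning with identical inputs and seed reproduces the report bit-for-bit
except for the ``timestamp`` field.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .conservation import mean_conservation, profile
from .cooccupancy import (
    DEFAULT_DISTANCE_EDGES,
    DEFAULT_FE_EDGES,
    distance_fe_histogram,
    fe_stratified_proximity_test,
    multiway_overlap,
)
from .genes import associate, build_domains, distance_to_gene_distribution, regulated_fraction
from .intervals import overlap_partition, summit_regions
from .model import ValidationError
from .motifs import PATTERNS, enrichment_test, mean_hits_per_region, occurrence_fraction
from .simulate import (
    SimulationConfig,
    recovery_report,
    selection_protocol,
    simulate,
)
from .synergy import MotifFilterRules, composite_motif_filter, select_synergistic

__all__ = ["RunConfig", "PipelineError", "run"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    Defaults follow the analysis conventions: 200-nt summit regions, 1-nt
    minimum overlap, top 1% FE selection, distance breakpoints 200 nt / 1 kb
    / 10 kb, FE strata at 20/40/60, motif thresholds 1/1/3 and mean
    conservation 0.40. In simulation mode the top fractions default to the
    landscape-sized selection protocol instead of the top 1%.
    """

    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    inputs: dict = field(default_factory=dict)  # file paths when simulate=False
    width: int = 200
    min_overlap: int = 1
    top_frac: float | None = None
    hoxa2_top_frac: float | None = None
    ratio_min: float = 1.5
    distance_edges: tuple = DEFAULT_DISTANCE_EDGES
    fe_edges: tuple = DEFAULT_FE_EDGES
    min_gatnnat: int = 1
    min_tgacad: int = 1
    min_taat: int = 3
    min_mean_conservation: float = 0.40
    basal_up: int = 5000
    basal_down: int = 1000
    max_ext: int = 1_000_000
    flank: int = 500
    high_quantile: float = 0.99
    low_quantile: float = 0.5
    proximity_nt: float = 200.0
    far_gene_nt: float = 50_000.0
    stages: tuple = (
        "overlap", "cooccupancy", "synergy", "motifs", "conservation",
        "filter", "genes",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distance_edges"] = [
            "inf" if math.isinf(e) else float(e) for e in self.distance_edges
        ]
        d["fe_edges"] = ["inf" if math.isinf(e) else float(e) for e in self.fe_edges]
        return d

    def filter_rules(self) -> MotifFilterRules:
        return MotifFilterRules(
            min_gatnnat=self.min_gatnnat,
            min_tgacad=self.min_tgacad,
            min_taat=self.min_taat,
            min_mean_conservation=self.min_mean_conservation,
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    """Return (meis_iiba, meis_iba, hoxa2, genome, track, genes, regulated,
    truth, chrom_sizes, input_record)."""
    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed, **config.sim)
        land = simulate(sim_cfg)
        return (
            land.meis_iiba,
            land.meis_iba,
            land.hoxa2,
            land.genome,
            land.conservation,
            land.genes,
            land.regulated_genes,
            land.truth,
            land.chrom_sizes(),
            {"mode": "simulated", "sim_config": sim_cfg.to_dict()},
        )
    paths = config.inputs
    required = ("meis_iiba", "meis_iba", "hoxa2")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ValidationError(f"missing input paths: {missing}")
    meis_iiba = cio.read_narrowpeak(paths["meis_iiba"], factor="Meis", tissue="IIBA")
    meis_iba = cio.read_narrowpeak(paths["meis_iba"], factor="Meis", tissue="IBA")
    hoxa2 = cio.read_narrowpeak(paths["hoxa2"], factor="Hoxa2", tissue="IIBA")
    genome = cio.Genome.from_fasta(paths["genome"]) if "genome" in paths else None
    track = (
        cio.read_conservation(paths["conservation"])
        if "conservation" in paths
        else None
    )
    genes = cio.read_gene_table(paths["genes"]) if "genes" in paths else None
    regulated = (
        cio.read_gene_list(paths["regulated_genes"])
        if "regulated_genes" in paths
        else set()
    )
    record = {
        "mode": "files",
        "paths": {k: str(v) for k, v in paths.items()},
        "sha256": {k: _sha256(v) for k, v in paths.items()},
    }
    sizes = genome.chrom_sizes() if genome else None
    return meis_iiba, meis_iba, hoxa2, genome, track, genes, regulated, None, sizes, record


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapper.__name__ = fn.__name__
        return wrapper

    return deco


def _combo_key(label: frozenset[str]) -> str:
    return "+".join(sorted(label)) if label else "none"


@_stage("overlap")
def _run_overlap(config, meis_iiba, meis_iba, hoxa2, chrom_sizes):
    part = overlap_partition(
        meis_iiba, meis_iba, width=config.width, min_overlap=config.min_overlap,
        chrom_sizes=chrom_sizes,
    )
    combos = multiway_overlap(
        [hoxa2, meis_iiba, meis_iba], width=config.width,
        min_overlap=config.min_overlap, chrom_sizes=chrom_sizes,
    )
    return {
        "meis_iiba_total": len(meis_iiba),
        "meis_iba_total": len(meis_iba),
        "meis_shared_iiba": len(part.shared_a),
        "meis_unique_iiba": len(part.unique_a),
        "meis_shared_fraction_iiba": len(part.shared_a) / max(len(meis_iiba), 1),
        "hoxa2_combinations": {
            _combo_key(k): v for k, v in sorted(combos.items(), key=lambda kv: _combo_key(kv[0]))
        },
    }


@_stage("cooccupancy")
def _run_cooccupancy(config, meis_iiba, hoxa2, outdir):
    table = distance_fe_histogram(
        meis_iiba, hoxa2, distance_edges=config.distance_edges, fe_edges=config.fe_edges
    )
    if outdir:
        table.to_dataframe().to_csv(outdir / "distance_fe_table.tsv", sep="\t")
    strat = fe_stratified_proximity_test(
        meis_iiba, hoxa2,
        high_quantile=config.high_quantile,
        low_quantile=config.low_quantile,
        distance_threshold=config.proximity_nt,
    )
    return {
        "distance_fe_counts": table.counts.tolist(),
        "distance_edges": ["inf" if math.isinf(e) else e for e in table.distance_edges],
        "fe_edges": ["inf" if math.isinf(e) else e for e in table.fe_edges],
        "high_fe_near_fraction": strat.high_fraction,
        "low_fe_near_fraction": strat.low_fraction,
        "n_high": strat.n_high,
        "n_low": strat.n_low,
        "proximity_p_value": strat.p_value,
    }


@_stage("synergy")
def _run_synergy(config, meis_iiba, meis_iba, hoxa2, truth, chrom_sizes, outdir):
    if config.top_frac is not None:
        top_frac, hox_frac = config.top_frac, config.hoxa2_top_frac
    elif config.simulate:
        proto = selection_protocol(SimulationConfig(seed=config.seed, **config.sim))
        top_frac, hox_frac = proto["top_frac"], proto["hoxa2_top_frac"]
    else:
        top_frac, hox_frac = 0.01, config.hoxa2_top_frac
    sel = select_synergistic(
        meis_iiba, meis_iba, hoxa2,
        top_frac=top_frac, ratio_min=config.ratio_min, width=config.width,
        hoxa2_top_frac=hox_frac, chrom_sizes=chrom_sizes,
    )
    stats = {
        "top_frac": top_frac,
        "hoxa2_top_frac": hox_frac if hox_frac is not None else top_frac,
        "ratio_min": config.ratio_min,
        "n_set_top": sel.n_top,
        "n_set_diff": sel.n_diff,
        "n_synergistic": sel.n_synergistic,
    }
    if truth is not None:
        rec = recovery_report(sel, truth)
        stats["recovery"] = {
            "precision": rec.precision,
            "recall": rec.recall,
            "n_selected": rec.n_selected,
            "n_loci": rec.n_loci,
        }
    if outdir:
        for which in ("set_top", "set_diff", "synergistic"):
            cio.write_bed(sel.regions(which), outdir / f"{which}.bed")
    return sel, stats


@_stage("motifs")
def _run_motifs(config, sel, meis_iiba, genome, chrom_sizes, outdir):
    if genome is None:
        raise ValidationError("motif stage requires a genome FASTA")
    fg = sel.regions("synergistic")
    bg = summit_regions(meis_iiba, config.width, chrom_sizes)
    if not fg:
        return {"skipped": "empty synergistic set"}
    stats = {}
    for name in ("GATNNAT", "TGACA", "TGACAG", "TAAT"):
        occ_fg = occurrence_fraction(fg, genome, PATTERNS[name])
        occ_bg = occurrence_fraction(bg, genome, PATTERNS[name])
        enr = enrichment_test(occ_fg.k, occ_fg.n, occ_bg.k, occ_bg.n)
        stats[name] = {
            "synergistic": {"k": occ_fg.k, "n": occ_fg.n, "fraction": occ_fg.fraction},
            "background": {"k": occ_bg.k, "n": occ_bg.n, "fraction": occ_bg.fraction},
            "p_value": enr.p_value,
            "odds_ratio": None if math.isnan(enr.odds_ratio) else enr.odds_ratio,
        }
    stats["TAAT"]["mean_hits_per_synergistic_region"] = mean_hits_per_region(
        fg, genome, PATTERNS["TAAT"]
    )
    return stats


@_stage("conservation")
def _run_conservation(config, sel, track, outdir):
    if track is None:
        raise ValidationError("conservation stage requires a score track")
    peaks = sel.synergistic if len(sel.synergistic) else sel.set_top
    if not len(peaks):
        return {"skipped": "no regions to profile"}
    prof = profile(peaks, track, flank=config.flank)
    if outdir:
        prof.to_dataframe().to_csv(outdir / "conservation_profile.tsv", sep="\t", index=False)
    center = np.abs(prof.offsets) < 100
    outer = np.abs(prof.offsets) >= config.flank - 100
    means = [
        mean_conservation(r, track).mean for r in sel.regions("synergistic")
    ]
    means = [m for m in means if not math.isnan(m)]
    return {
        "profile_center_mean": float(np.nanmean(prof.mean_score[center])),
        "profile_outer_mean": float(np.nanmean(prof.mean_score[outer])),
        "synergistic_region_mean": float(np.mean(means)) if means else None,
    }


@_stage("filter")
def _run_filter(config, sel, genome, track):
    if genome is None or track is None:
        raise ValidationError("composite filter requires genome and conservation")
    fg = sel.regions("synergistic")
    kept = composite_motif_filter(fg, genome, track, config.filter_rules())
    return {"n_input": len(fg), "n_kept": len(kept)}


@_stage("genes")
def _run_genes(config, sel, hoxa2, genes, regulated, chrom_sizes, outdir):
    if genes is None:
        raise ValidationError("gene association requires a gene table")
    domains = build_domains(
        genes, basal_up=config.basal_up, basal_down=config.basal_down,
        max_ext=config.max_ext, chrom_sizes=chrom_sizes,
    )
    syn_regions = sel.regions("synergistic")
    all_regions = summit_regions(hoxa2, config.width, chrom_sizes)
    out = {}
    assign_all = associate(all_regions, domains)
    k, n, frac = regulated_fraction(assign_all, regulated)
    out["all_hoxa2"] = {"k": k, "n": n, "fraction": frac}
    if syn_regions:
        assign_syn = associate(syn_regions, domains)
        k, n, frac = regulated_fraction(assign_syn, regulated)
        out["synergistic"] = {"k": k, "n": n, "fraction": frac}
        hist = distance_to_gene_distribution(assign_syn, (0.0, config.far_gene_nt))
        out["synergistic_far_fraction"] = float(hist.counts[-1] / max(hist.counts.sum(), 1))
    return out


def run(config: RunConfig, outdir=None) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    (
        meis_iiba, meis_iba, hoxa2, genome, track, genes, regulated, truth,
        chrom_sizes, input_record,
    ) = _load_inputs(config)

    report: dict = {
        "parameters": config.to_dict(),
        "inputs": input_record,
        "stages": {},
    }
    stages = report["stages"]
    enabled = set(config.stages)
    if "overlap" in enabled:
        stages["overlap"] = _run_overlap(config, meis_iiba, meis_iba, hoxa2, chrom_sizes)
    if "cooccupancy" in enabled:
        stages["cooccupancy"] = _run_cooccupancy(config, meis_iiba, hoxa2, outdir)
    sel, synergy_stats = _run_synergy(
        config, meis_iiba, meis_iba, hoxa2, truth, chrom_sizes, outdir
    )
    if "synergy" in enabled:
        stages["synergy"] = synergy_stats
    if "motifs" in enabled:
        stages["motifs"] = _run_motifs(config, sel, meis_iiba, genome, chrom_sizes, outdir)
    if "conservation" in enabled:
        stages["conservation"] = _run_conservation(config, sel, track, outdir)
    if "filter" in enabled:
        stages["filter"] = _run_filter(config, sel, genome, track)
    if "genes" in enabled:
        stages["genes"] = _run_genes(
            config, sel, hoxa2, genes, regulated, chrom_sizes, outdir
        )
    report["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
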