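# cobind

A toolkit for comparative ChIP-seq co-occupancy analysis: does a
tissue-specific transcription factor selectively *enhance* the binding of a
broadly bound factor at the sites it co-occupies?

The motivating setting is the developing vertebrate head. TALE homeodomain
factors (Meis, Pbx) bind a largely shared set of regions in both the
Hox-negative first branchial arch (IBA) and the Hox-positive second arch
(IIBA). Hoxa2, expressed only in the IIBA, binds a subset of Meis-prelabeled
sites that carry Hox recognition motifs, and at those sites the Meis binding
signal is markedly higher in the IIBA. `cobind` implements the genomic
analyses needed to detect and characterise that synergistic binding from
called peaks, and ships a synthetic two-tissue landscape generator so every
stage is testable with planted ground truth and no downloads.

## What it computes

All comparisons operate on fixed-width **summit regions** (200 nt windows
centered on peak summits; two peaks co-occur when their regions overlap by
>= 1 nt), with fold enrichment (FE) as the binding-strength score:

* **Interval algebra** — overlap partitions of peak sets, summit-to-summit
  nearest distances, top-FE fraction selection, replicate containment
  (`cobind.intervals`).
* **Co-occupancy summaries** — distance-to-nearest-peak histograms
  stratified by FE (default distance breakpoints 200 nt / 1 kb / 10 kb; FE
  strata 20/40/60), FE-stratified proximity contrasts with Fisher's exact
  test, multiway combinatorial overlap (`cobind.cooccupancy`).
* **Differential binding and synergy selection** — greedy one-to-one
  cross-tissue peak matching, FE-ratio classes (higher-in-A / higher-in-B /
  A-only / unchanged), and the high-confidence selection
  `synergistic = (top Meis ∩ top Hoxa2) ∩-overlap (differential-up Meis ∩ Hoxa2)`
  plus a composite motif/conservation filter (>= 1 GATNNAT, >= 1 TGACAD,
  >= 3 TAAT, mean conservation >= 0.40) (`cobind.synergy`).
* **Motif statistics** — degenerate IUPAC consensus scanning on both
  strands (overlapping hits counted), per-region counts, occurrence
  fractions and Fisher enrichment against a background set
  (`cobind.motifs`).
* **Conservation** — summit-centered average conservation profiles and
  per-region means from phastCons-like per-base tracks
  (`cobind.conservation`).
* **Gene association** — GREAT-style basal-plus-extension regulatory
  domains (5 kb up / 1 kb down / 1 Mb cap) and regulated-gene fractions
  (`cobind.genes`).
* **Simulation** — a seeded generator of genomes, two-tissue peak sets with
  a controllable multiplicative enhancement at planted synergy loci,
  planted motifs, conservation tracks and gene grids, with ground truth for
  precision/recall scoring (`cobind.simulate`).

Standard formats throughout: narrowPeak, BED, FASTA, bedGraph/wiggle, TSV.

## Worked example

```python
from cobind import (SimulationConfig, simulate, selection_protocol,
                    select_synergistic, recovery_report, occurrence_fraction,
                    enrichment_test, summit_regions, PATTERNS)

cfg = SimulationConfig(seed=1)           # 30 planted loci, 500 background peaks
land = simulate(cfg)
proto = selection_protocol(cfg)
sel = select_synergistic(
    land.meis_iiba, land.meis_iba, land.hoxa2,
    top_frac=proto["top_frac"], hoxa2_top_frac=proto["hoxa2_top_frac"],
    ratio_min=proto["ratio_min"], chrom_sizes=land.chrom_sizes(),
)
print(f"set_top n={sel.n_top}, set_diff n={sel.n_diff}, synergistic n={sel.n_synergistic}")

rec = recovery_report(sel, land.truth)
print(f"precision={rec.precision:.2f}, recall={rec.recall:.2f}")

genome = land.genome
fg = occurrence_fraction(sel.regions("synergistic"), genome, PATTERNS["GATNNAT"])
bg = occurrence_fraction(summit_regions(land.meis_iiba), genome, PATTERNS["GATNNAT"])
enr = enrichment_test(fg.k, fg.n, bg.k, bg.n)
print(f"GATNNAT: {fg.k}/{fg.n} ({100*fg.fraction:.0f}%) vs background "
      f"{bg.k}/{bg.n} ({100*bg.fraction:.0f}%), p = {enr.p_value:.2e}")
```

Output:

```
set_top n=29, set_diff n=30, synergistic n=28
precision=1.00, recall=0.93
GATNNAT: 27/28 (96%) vs background 231/530 (44%), p = 6.78e-09
```

Reading: of the 30 planted synergy loci, 29 tissue-B Meis peaks survive the
top-FE x top-Hoxa2 overlap, 30 peaks are enhanced (FE ratio >= 1.5) and
Hoxa2-bound, and their intersection recovers 28 regions — all true planted
loci (precision 1.0) covering 28/30 of them (recall 0.93). The recovered
regions are strongly enriched for the Hox-Pbx core motif GATNNAT relative
to the full Meis peak background.

The same analyses are available from the shell:

```bash
cobind simulate --seed 1 --outdir sim/
cobind synergy --meis-iiba sim/meis_IIBA.narrowPeak --meis-iba sim/meis_IBA.narrowPeak \
    --hoxa2 sim/hoxa2_IIBA.narrowPeak --top-fraction 0.2 --hoxa2-top-fraction 0.5 \
    --out-prefix syn
cobind run --seed 1 --outdir run/          # full pipeline + JSON report
```

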