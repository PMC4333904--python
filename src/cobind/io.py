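"""Readers and writers for the standard genomic text formats the pipeline touches.

Supported formats: narrowPeak (ENCODE BED6+4), BED3, FASTA (via pyfaidx),
bedGraph, fixed-step wiggle, and TSV gene tables (columns
``gene  chrom  tss  strand``). Everything is converted to the 0-based
half-open convention of :mod:`cobind.model` at this boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import (
    ConservationTrack,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed",
    "write_bed",
    "read_conservation",
    "write_bedgraph",
    "Genome",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_gene_list",
    "write_gene_list",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_narrowpeak(
    path,
    factor: str = "",
    tissue: str = "",
    genome_id: str | None = None,
    fe_field: int = 7,
) -> PeakSet:
    """Read an ENCODE narrowPeak file into a :class:`PeakSet`.

    ``fe_field`` is the 1-based column holding fold enrichment; the default
    (7, signalValue) matches MACS output. A summit offset of -1 (column 10)
    falls back to the interval midpoint, rounded down.
    """
    peaks = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 10:
            raise ParseError(
                f"{path}: line {lineno}: expected >= 10 narrowPeak fields, "
                f"got {len(fields)}"
            )
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = fields[3]
            score = float(fields[4]) if fields[4] not in (".", "") else None
            fe = float(fields[fe_field - 1])
            offset = int(fields[9])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        try:
            interval = GenomicInterval(chrom, start, end)
            summit = (start + end) // 2 if offset == -1 else start + offset
            peaks.append(
                Peak(
                    interval=interval,
                    summit=summit,
                    fold_enrichment=fe,
                    score=score,
                    name=name,
                    factor=factor,
                    tissue=tissue,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(peaks, factor=factor, tissue=tissue, genome_id=genome_id)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name or ".",
                        str(int(p.score) if p.score is not None else 0),
                        ".",
                        f"{p.fold_enrichment:.5g}",
                        "-1",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file; extra columns are ignored."""
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 BED fields")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        try:
            intervals.append(GenomicInterval(chrom, start, end))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_conservation(path) -> ConservationTrack:
    """Read per-base conservation from bedGraph or fixed-step wiggle.

    Scores must lie in [0, 1]; overlapping bedGraph records with conflicting
    values are rejected. Bases never mentioned stay uncovered.
    """
    track = ConservationTrack()
    mode = "bedgraph"
    chrom, pos, step, span = None, 0, 1, 1
    for lineno, line in _data_lines(path):
        if line.startswith("fixedStep"):
            mode = "wiggle"
            params = dict(
                kv.split("=") for kv in line.split()[1:] if "=" in kv
            )
            try:
                chrom = params["chrom"]
                pos = int(params["start"]) - 1  # wiggle is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: bad fixedStep header") from exc
            continue
        try:
            if mode == "wiggle":
                value = float(line.strip())
                track.add_values(chrom, pos, np.full(span, value))
                pos += step
            else:
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 4 bedGraph fields"
                    )
                c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if e <= s:
                    raise ValidationError(
                        f"{path}: line {lineno}: empty interval [{s}, {e})"
                    )
                track.add_values(c, s, np.full(e - s, v))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return track


def write_bedgraph(track: ConservationTrack, path, decimals: int = 4) -> None:
    """Write covered bases as bedGraph, merging runs of equal value."""
    with open(path, "w") as fh:
        for chrom in track.chromosomes():
            arr = np.round(track._scores[chrom], decimals)
            covered = np.isfinite(arr)
            if not covered.any():
                continue
            # run boundaries: coverage changes or value changes
            change = np.ones(len(arr), dtype=bool)
            change[1:] = (covered[1:] != covered[:-1]) | (
                covered[1:] & covered[:-1] & (arr[1:] != arr[:-1])
            )
            starts = np.flatnonzero(change)
            ends = np.append(starts[1:], len(arr))
            for s, e in zip(starts, ends):
                if covered[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.{decimals}g}\n")


class Genome:
    """Random-access nucleotide sequence store (FASTA-backed or in-memory)."""

    def __init__(self, sequences: Mapping[str, str]) -> None:
        self._seqs = {c: str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "Genome":
        return cls(sequences)

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of ``chrom:[start, end)``, clipped to the
        chromosome with a warning when the request runs off either end."""
        if chrom not in self._seqs:
            raise ValidationError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq):
            warnings.warn(
                f"request {chrom}:{start}-{end} clipped to [0, {len(seq)})",
                stacklevel=2,
            )
        return seq[max(start, 0) : min(end, len(seq))]

    def fetch_interval(self, interval: GenomicInterval) -> str:
        return self.fetch(interval.chrom, interval.start, interval.end)


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_table(path) -> list[GeneAnnotation]:
    """TSV with columns ``gene, chrom, tss, strand`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if cols[:4] != ["gene", "chrom", "tss", "strand"]:
        # headerless: re-read without header
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene", "chrom", "tss", "strand"],
            dtype=str,
        )
    return [
        GeneAnnotation(row.gene, row.chrom, int(row.tss), row.strand)
        for row in df.itertuples()
    ]


def write_gene_table(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


def read_gene_list(path) -> set[str]:
    """One gene symbol per line (first tab-separated column)."""
    out = set()
    for _, line in _data_lines(path):
        sym = line.split("\t")[0].strip()
        if sym and sym.lower() != "gene":
            out.add(sym)
    return out


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
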