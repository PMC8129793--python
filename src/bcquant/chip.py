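"""Strand-aware promoter windows and ChIP peak-to-gene assignment.

A gene's promoter window spans −1000 to +200 bases around its
transcription start site (TSS), measured in the direction of
transcription: for a − strand gene, upstream lies at higher genomic
coordinates.  All interval arithmetic is 0-based half-open; BED input
is used as-is and the gene table's TSS column is read as 1-based and
converted.  A peak is assigned to every gene whose window it
intersects (no nearest-gene tie-break), and per-gene binding is
summarised as the number of replicates with at least one overlapping
peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

UPSTREAM = 1000
DOWNSTREAM = 200


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class GeneModel:
    """Gene with a 1-based TSS coordinate and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"TSS must be >= 1 (1-based), got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval
    strand: str


def promoter_window(gene: GeneModel, strand_aware: bool = True) -> PromoterWindow:
    """The −1000..+200 TSS window of a gene, 0-based half-open.

    For a + strand gene with 0-based TSS t0 the window is
    [t0 − 1000, t0 + 200); for a − strand gene (strand-aware mode) the
    mirror [t0 − 199, t0 + 1001), so −1000 lies upstream in the
    direction of transcription.  Width is 1200 bases unless clamped at
    the chromosome start.  With ``strand_aware=False`` every gene uses
    the + strand arithmetic.
    """
    t0 = gene.tss - 1  # 1-based -> 0-based
    if gene.strand == "+" or not strand_aware:
        start, end = t0 - UPSTREAM, t0 + DOWNSTREAM
    else:
        start, end = t0 - (DOWNSTREAM - 1), t0 + UPSTREAM + 1
    return PromoterWindow(gene.gene_id, GenomicInterval(gene.chrom, max(0, start), end),
                          gene.strand)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end), validating each line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if not 0 <= start < end:
                raise ValueError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            rows.append((fields[0], start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_gene_table(path) -> list[GeneModel]:
    """Read a gene table TSV (gene_id, chrom, tss [1-based], strand)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns {sorted(missing)}")
    return [GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples()]


def read_gtf_genes(path) -> list[GeneModel]:
    """Derive gene models from a minimal GTF: feature 'gene', TSS from
    start/end by strand (start for +, end for −)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GTF fields")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "gene":
                continue
            gene_id = None
            for item in attrs.strip().strip(";").split(";"):
                parts = item.strip().split(" ", 1)
                if len(parts) == 2 and parts[0] == "gene_id":
                    gene_id = parts[1].strip('"')
            if gene_id is None:
                raise ValueError(f"{path}: line {lineno}: gene feature without gene_id")
            tss = int(start) if strand == "+" else int(end)
            genes.append(GeneModel(gene_id, chrom, tss, strand))
    return genes


def assign_peaks(peaks_by_replicate: dict[str, pd.DataFrame],
                 genes: list[GeneModel], strand_aware: bool = True) -> pd.DataFrame:
    """Per-gene, per-replicate promoter overlap table.

    ``peaks_by_replicate`` maps replicate id to a (chrom, start, end)
    frame.  A peak counts for every gene whose promoter window it
    intersects (any-base, half-open).  Returns a frame with columns
    gene_id, replicate_id, n_peaks_overlapping, overlap — one row per
    gene × replicate, independent of peak input order.
    """
    windows = [promoter_window(g, strand_aware=strand_aware) for g in genes]
    trees: dict[str, IntervalTree] = {}
    for i, w in enumerate(windows):
        trees.setdefault(w.interval.chrom, IntervalTree()).addi(
            w.interval.start, w.interval.end, i)
    rows = []
    for rep_id in sorted(peaks_by_replicate):
        counts = [0] * len(windows)
        df = peaks_by_replicate[rep_id]
        for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
            tree = trees.get(str(chrom))
            if tree is None:
                continue
            for hit in tree.overlap(int(start), int(end)):
                counts[hit.data] += 1
        for g, c in zip(genes, counts):
            rows.append({"gene_id": g.gene_id, "replicate_id": rep_id,
                         "n_peaks_overlapping": c, "overlap": c > 0})
    return (pd.DataFrame(rows)
            .sort_values(["gene_id", "replicate_id"])
            .reset_index(drop=True))


def replicate_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (n_bound, N_replicates): replicates with >= 1 overlapping peak."""
    n_reps = assignments["replicate_id"].nunique()
    out = (assignments.groupby("gene_id", as_index=False)["overlap"]
           .sum()
           .rename(columns={"overlap": "n_bound"}))
    out["n_bound"] = out["n_bound"].astype(int)
    out["N"] = n_reps
    return out
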