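"""Genome annotation, truncated-genome construction and peak-set algebra.

Candidate enhancer regions are searched for in the "truncated genome": the
genome minus every gene body, the 2 kb upstream of each transcriptional
start site (TSS) and the 500 bp downstream of each termination site (TTS),
both strand-aware.  Open-chromatin peaks from many samples are pooled into a
union peak set by merging peaks whose centres lie within a fixed distance
(default 250 bp) or that overlap, and peaks touching any excluded base are
dropped whole.

All internal coordinates are 0-based half-open.  GTF input is 1-based
inclusive (converted on read); BED input/output is 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "RegionSet",
    "Gene",
    "GenomeAnnotation",
    "TruncationParams",
    "read_chrom_sizes",
    "read_annotation",
    "read_bed",
    "build_exclusion_zones",
    "filter_intergenic_peaks",
    "merge_peak_sets",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval: {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """An ordered collection of intervals (peaks, exclusion zones, regions).

    ``merged=True`` asserts the intervals are sorted by (chrom, start) and
    pairwise non-overlapping; operations that require unambiguous assignment
    (fragment counting, intergenic filtering) insist on it.
    """

    intervals: list[Interval] = field(default_factory=list)
    sorted: bool = False
    merged: bool = False

    def __post_init__(self) -> None:
        if self.merged:
            self._check_merged()

    def _check_merged(self) -> None:
        prev: Interval | None = None
        for iv in self.intervals:
            if prev is not None and prev.chrom == iv.chrom:
                if iv.start < prev.start:
                    raise ValueError("merged RegionSet must be sorted")
                if iv.start < prev.end:
                    raise ValueError(
                        f"merged RegionSet has overlap: {prev} / {iv}"
                    )
            elif prev is not None and prev.chrom > iv.chrom:
                raise ValueError("merged RegionSet must be sorted by chrom")
            prev = iv

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def sort(self) -> "RegionSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return RegionSet(ivs, sorted=True, merged=self.merged)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name or "." for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
            }
        )

    def write_bed(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        df["score"] = 0
        df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )


def read_bed(path: str | os.PathLike, merged: bool = False) -> RegionSet:
    """Read BED3/BED6 into a RegionSet (coordinates kept 0-based half-open)."""
    ivs: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {ln}: expected >=3 BED fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: non-integer coordinate") from e
            name = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            ivs.append(Interval(f[0], start, end, name=name, strand=strand))
    rs = RegionSet(ivs).sort()
    if merged:
        rs = RegionSet(rs.intervals, sorted=True, merged=True)  # validates
    return rs


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        """Strand-aware TSS coordinate (5' end of the gene)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GenomeAnnotation:
    """Gene extents with strand-aware TSS/TTS on named chromosomes."""

    genes: list[Gene]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in self.chrom_sizes:
                raise ValueError(
                    f"gene {g.gene_id!r} on unknown chromosome {g.chrom!r}"
                )
            if not (0 <= g.start < g.end <= self.chrom_sizes[g.chrom]):
                raise ValueError(f"gene {g.gene_id!r} outside chromosome bounds")
            if g.strand not in ("+", "-"):
                raise ValueError(f"gene {g.gene_id!r}: strand must be +/-")

    def __len__(self) -> int:
        return len(self.genes)

    def genes_by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def tss_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )


@dataclass(frozen=True)
class TruncationParams:
    """Exclusion-zone extents and union-merge distance (bp)."""

    upstream_exclude: int = 2000
    downstream_exclude: int = 500
    merge_distance: int = 250

    def __post_init__(self) -> None:
        if min(self.upstream_exclude, self.downstream_exclude, self.merge_distance) < 0:
            raise ValueError("truncation parameters must be >= 0")


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ValueError(f"{path}: line {ln}: expected 2 columns")
            sizes[f[0]] = int(f[1])
    return sizes


def _prescan_gtf(path: str | os.PathLike) -> None:
    # pyranges' reader does not report line numbers; check structure first
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}: line {ln}: expected 9 GTF fields, got {len(f)}")
            try:
                s, e = int(f[3]), int(f[4])
            except ValueError as err:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from err
            if s < 1 or e < s:
                raise ValueError(f"{path}: line {ln}: invalid 1-based coordinates {s}..{e}")


def read_annotation(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int] | str | os.PathLike | None = None,
) -> GenomeAnnotation:
    """Read a GTF into a GenomeAnnotation (one extent per gene_id).

    ``gene`` feature rows are used when present; otherwise transcript/exon
    rows are collapsed to the per-gene union extent.  GTF 1-based inclusive
    coordinates become 0-based half-open.  When ``chrom_sizes`` is omitted,
    chromosome lengths are inferred as the maximum annotated end.
    """
    import pyranges as pr

    if isinstance(chrom_sizes, (str, os.PathLike)):
        chrom_sizes = read_chrom_sizes(chrom_sizes)

    _prescan_gtf(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return GenomeAnnotation([], dict(chrom_sizes or {}))

    df = pr.read_gtf(os.fspath(path)).df
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: no gene_id attribute found")
    genes_df = df[df["Feature"] == "gene"]
    if genes_df.empty:
        genes_df = df
    agg = genes_df.groupby("gene_id", sort=True).agg(
        chrom=("Chromosome", "first"),
        start=("Start", "min"),
        end=("End", "max"),
        strand=("Strand", "first"),
        nchrom=("Chromosome", "nunique"),
    )
    multi = agg.index[agg["nchrom"] > 1]
    if len(multi):
        raise ValueError(f"gene(s) span multiple chromosomes: {list(multi)}")
    if chrom_sizes is None:
        chrom_sizes = agg.groupby("chrom")["end"].max().to_dict()
    genes = [
        Gene(gid, r.chrom, int(r.start), int(r.end), str(r.strand))
        for gid, r in agg.iterrows()
    ]
    return GenomeAnnotation(genes, dict(chrom_sizes))


def _merge_overlapping(ivs: Sequence[Interval]) -> list[Interval]:
    """Merge touching-or-overlapping intervals; input need not be sorted."""
    out: list[Interval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            out.append(Interval(iv.chrom, iv.start, iv.end))
    return out


def build_exclusion_zones(
    ann: GenomeAnnotation, p: TruncationParams | None = None
) -> RegionSet:
    """Strand-aware exclusion zones: gene body + upstream/downstream margins.

    For a plus-strand gene the zone runs from ``start - upstream_exclude`` to
    ``end + downstream_exclude``; minus-strand genes mirror this (the TSS is
    the 3'-most coordinate).  Zones are clipped to chromosome bounds and
    overlap-merged.
    """
    p = p or TruncationParams()
    raw: list[Interval] = []
    for g in ann.genes:
        if g.strand == "+":
            s = g.start - p.upstream_exclude
            e = g.end + p.downstream_exclude
        else:
            s = g.start - p.downstream_exclude
            e = g.end + p.upstream_exclude
        s = max(0, s)
        e = min(ann.chrom_sizes[g.chrom], e)
        raw.append(Interval(g.chrom, s, e))
    merged = _merge_overlapping(raw)
    return RegionSet(merged, sorted=True, merged=True)


def _overlap_mask(
    peaks: Sequence[Interval], exclusion_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]
) -> np.ndarray:
    """True where a peak shares >=1 base with an exclusion interval."""
    mask = np.zeros(len(peaks), dtype=bool)
    for i, pk in enumerate(peaks):
        arr = exclusion_by_chrom.get(pk.chrom)
        if arr is None:
            continue
        starts, ends = arr
        # candidate: the rightmost exclusion starting before peak end
        j = int(np.searchsorted(starts, pk.end, side="left")) - 1
        if j >= 0 and ends[j] > pk.start:
            mask[i] = True
    return mask


def filter_intergenic_peaks(peaks: RegionSet, exclusion: RegionSet) -> RegionSet:
    """Retain only peaks with zero overlap with the exclusion set.

    Whole-peak classification: a single shared base drops the peak (no
    trimming), mirroring "retain only intergenic regions".
    """
    if not exclusion.merged:
        raise ValueError("exclusion RegionSet must be merged (non-overlapping)")
    excl: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in exclusion.by_chrom().items():
        excl[chrom] = (
            np.array([iv.start for iv in ivs]),
            np.array([iv.end for iv in ivs]),
        )
    mask = _overlap_mask(list(peaks), excl)
    kept = [iv for iv, drop in zip(peaks, mask) if not drop]
    return RegionSet(kept, sorted=peaks.sorted, merged=peaks.merged)


def _merge_pass(ivs: list[Interval], d: int) -> tuple[list[Interval], bool]:
    """One left-to-right sweep merging adjacent intervals that overlap or
    whose centres are within d bp.  Returns (result, changed)."""
    if not ivs:
        return ivs, False
    ivs = sorted(ivs, key=lambda v: (v.start, v.end))
    out = [ivs[0]]
    changed = False
    for iv in ivs[1:]:
        cur = out[-1]
        if iv.start < cur.end or abs(iv.centre - cur.centre) <= d:
            out[-1] = Interval(cur.chrom, min(cur.start, iv.start), max(cur.end, iv.end))
            changed = True
        else:
            out.append(iv)
    return out, changed


def merge_peak_sets(
    peak_sets: Iterable[RegionSet], merge_distance: int = 250
) -> RegionSet:
    """Pool peak sets and merge to fixpoint (union peak set).

    Two peaks on the same chromosome merge when they overlap or their
    centres (floor((start+end)/2)) lie within ``merge_distance`` bp; merging
    replaces them by the spanning interval, repeated until no pair merges.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    pooled: dict[str, list[Interval]] = {}
    for rs in peak_sets:
        for iv in rs:
            pooled.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(pooled):
        ivs = pooled[chrom]
        changed = True
        while changed:
            ivs, changed = _merge_pass(ivs, merge_distance)
        out.extend(ivs)
    return RegionSet(out, sorted=True, merged=True)
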