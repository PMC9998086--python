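"""Strand-aware fragment counting, FPM, candidate filtering, directionality.

Enhancer RNAs are transcribed bidirectionally, so each candidate region is
quantified on both strands.  A fragment is assigned to the unique merged
region containing its midpoint, which counts every fragment at most once
and avoids double counting at region boundaries.  Candidate regions must
clear both a mean raw count and a mean fragments-per-million (FPM)
threshold across all samples (defaults 3 and 1.5).

The directionality score of a region is

    D = log10((plus + 1) / (minus + 1)) + 1

where plus/minus are per-strand expression scores; balanced bidirectional
transcription gives D near 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Interval, RegionSet

__all__ = [
    "FragmentSet",
    "CountMatrix",
    "QuantParams",
    "read_fragments",
    "count_fragments",
    "build_count_matrix",
    "compute_fpm",
    "filter_candidates",
    "directionality_score",
    "region_directionality",
]


@dataclass
class FragmentSet:
    """Stranded RNA fragments for one sample; library size = n fragments."""

    sample_id: str
    fragments: list[Interval]
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = len(self.fragments)
        for f in self.fragments:
            if f.strand not in ("+", "-"):
                raise ValueError(f"fragment without strand: {f}")


def read_fragments(path: str | os.PathLike, sample_id: str | None = None) -> FragmentSet:
    """Read a BED6 fragment file (strand required in column 6)."""
    from .intervals import read_bed

    rs = read_bed(path)
    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    return FragmentSet(sid, list(rs))


@dataclass
class CountMatrix:
    """Region x sample fragment counts with per-strand sub-matrices."""

    region_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    plus_counts: np.ndarray
    minus_counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.plus_counts = np.asarray(self.plus_counts)
        self.minus_counts = np.asarray(self.minus_counts)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        shape = (len(self.region_ids), len(self.sample_ids))
        for m in (self.counts, self.plus_counts, self.minus_counts):
            if m.shape != shape:
                raise ValueError(f"count matrix shape {m.shape} != {shape}")
            if (m < 0).any():
                raise ValueError("negative counts")
        if not np.array_equal(self.counts, self.plus_counts + self.minus_counts):
            raise ValueError("counts != plus_counts + minus_counts")
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise ValueError("library_sizes length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self, which: str = "total") -> pd.DataFrame:
        m = {"total": self.counts, "plus": self.plus_counts, "minus": self.minus_counts}[which]
        return pd.DataFrame(m, index=self.region_ids, columns=self.sample_ids)

    def subset_regions(self, mask: np.ndarray) -> "CountMatrix":
        ids = [r for r, keep in zip(self.region_ids, mask) if keep]
        return CountMatrix(
            ids,
            list(self.sample_ids),
            self.counts[mask],
            self.plus_counts[mask],
            self.minus_counts[mask],
            self.library_sizes,
        )


@dataclass(frozen=True)
class QuantParams:
    min_mean_count: float = 3.0
    min_mean_fpm: float = 1.5

    def __post_init__(self) -> None:
        if self.min_mean_count < 0 or self.min_mean_fpm < 0:
            raise ValueError("thresholds must be >= 0")


def _region_arrays(regions: RegionSet) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    by = regions.by_chrom()
    out = {}
    offset = 0
    # preserve the region order of the (sorted) RegionSet for indexing
    idx_of = {id(iv): i for i, iv in enumerate(regions)}
    for chrom, ivs in by.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        idx = np.array([idx_of[id(iv)] for iv in ivs])
        order = np.argsort(starts, kind="stable")
        out[chrom] = (starts[order], ends[order], idx[order])
    return out


def count_fragments(
    regions: RegionSet, frags: FragmentSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Midpoint-assign fragments of one sample to merged regions.

    Returns (total, plus, minus) arrays aligned with ``regions`` order.
    Fragments whose midpoint (floor((start+end)/2)) lies in no region are
    uncounted.  Overlapping regions are an error: assignment would be
    ambiguous.
    """
    if not regions.merged:
        raise ValueError("regions must be merged (non-overlapping) for counting")
    n = len(regions)
    plus = np.zeros(n, dtype=np.int64)
    minus = np.zeros(n, dtype=np.int64)
    arrays = _region_arrays(regions)

    by_chrom: dict[str, list[Interval]] = {}
    for f in frags.fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, fl in by_chrom.items():
        arr = arrays.get(chrom)
        if arr is None:
            continue
        starts, ends, idx = arr
        mids = np.array([(f.start + f.end) // 2 for f in fl])
        is_plus = np.array([f.strand == "+" for f in fl])
        j = np.searchsorted(starts, mids, side="right") - 1
        ok = (j >= 0) & (mids < ends[np.clip(j, 0, len(ends) - 1)])
        tgt = idx[np.clip(j, 0, len(idx) - 1)]
        np.add.at(plus, tgt[ok & is_plus], 1)
        np.add.at(minus, tgt[ok & ~is_plus], 1)
    return plus + minus, plus, minus


def build_count_matrix(regions: RegionSet, fragment_sets: list[FragmentSet]) -> CountMatrix:
    """Count every sample's fragments over one region set."""
    region_ids = [
        iv.name or f"{iv.chrom}:{iv.start}-{iv.end}" for iv in regions
    ]
    plus = np.zeros((len(regions), len(fragment_sets)), dtype=np.int64)
    minus = np.zeros_like(plus)
    lib = np.zeros(len(fragment_sets))
    for j, fs in enumerate(fragment_sets):
        _, p, m = count_fragments(regions, fs)
        plus[:, j] = p
        minus[:, j] = m
        lib[j] = fs.library_size
    return CountMatrix(
        region_ids,
        [fs.sample_id for fs in fragment_sets],
        plus + minus,
        plus,
        minus,
        lib,
    )


def compute_fpm(cm: CountMatrix) -> np.ndarray:
    """fragments-per-million: counts * 1e6 / library size, per sample."""
    if (cm.library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return cm.counts * 1e6 / cm.library_sizes[None, :]


def filter_candidates(
    cm: CountMatrix, p: QuantParams | None = None
) -> tuple[np.ndarray, CountMatrix]:
    """Candidate filter: mean raw count and mean FPM across ALL samples.

    A region passes iff mean(counts) >= min_mean_count and
    mean(FPM) >= min_mean_fpm (both cohorts pooled).
    """
    p = p or QuantParams()
    fpm = compute_fpm(cm)
    mask = (cm.counts.mean(axis=1) >= p.min_mean_count) & (
        fpm.mean(axis=1) >= p.min_mean_fpm
    )
    return mask, cm.subset_regions(mask)


def directionality_score(plus_score, minus_score):
    """log10((plus + 1)/(minus + 1)) + 1; accepts scalars or arrays."""
    plus_score = np.asarray(plus_score, dtype=float)
    minus_score = np.asarray(minus_score, dtype=float)
    if (plus_score < 0).any() or (minus_score < 0).any():
        raise ValueError("strand expression scores must be >= 0")
    out = np.log10((plus_score + 1.0) / (minus_score + 1.0)) + 1.0
    return float(out) if out.ndim == 0 else out


def region_directionality(cm: CountMatrix, normalized: bool = True) -> pd.Series:
    """Per-region directionality from strand counts summed over samples.

    With ``normalized=True`` (default) each sample's strand counts are first
    scaled to per-million of its library; with ``normalized=False`` raw
    counts are summed.
    """
    if normalized:
        if (cm.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        scale = 1e6 / cm.library_sizes[None, :]
        plus = (cm.plus_counts * scale).sum(axis=1)
        minus = (cm.minus_counts * scale).sum(axis=1)
    else:
        plus = cm.plus_counts.sum(axis=1).astype(float)
        minus = cm.minus_counts.sum(axis=1).astype(float)
    return pd.Series(directionality_score(plus, minus), index=cm.region_ids, name="directionality")
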