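"""Genomic interval data model and arithmetic.

All coordinates are 0-based half-open (BED convention). Strand is ignored
throughout: DSB sites are unstranded. The occupancy-fraction encoding
(`overlap_fraction`) is the feature encoding used by the classifiers — a
site covered over 60% of its length by a mark's peaks gets x = 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genome import Genome

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "ProfileMatrix",
    "read_bed",
    "write_bed",
    "intersect_replicates",
    "overlap_fraction",
    "bin_genome",
    "label_intervals",
    "average_profile",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered, canonically sorted collection of :class:`GenomicInterval`.

    Canonicalization sorts by ``(chrom, start, end)`` and collapses intervals
    with identical coordinates (the first occurrence's name/score is kept).
    Per-chromosome start/end arrays and their merged union are cached for the
    coverage arithmetic.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), genome_id: str | None = None):
        seen: dict[tuple[str, int, int], GenomicInterval] = {}
        for iv in intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen[key] = iv
        self.intervals: list[GenomicInterval] = [
            seen[k] for k in sorted(seen.keys())
        ]
        self.genome_id = genome_id
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- container protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(i.chrom, i.start, i.end) for i in self] == [
            (i.chrom, i.start, i.end) for i in other
        ]

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals)"

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    # -- cached arrays -----------------------------------------------------

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays for one chromosome."""
        if self._by_chrom is None:
            by: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                by.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._by_chrom = {
                c: (
                    np.asarray([s for s, _ in v], dtype=np.int64),
                    np.asarray([e for _, e in v], dtype=np.int64),
                )
                for c, v in by.items()
            }
        empty = np.empty(0, dtype=np.int64)
        return self._by_chrom.get(chrom, (empty, empty))

    def merged_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Union of intervals on ``chrom`` as disjoint sorted (starts, ends)."""
        if self._merged is None:
            self._merged = {}
        if chrom not in self._merged:
            starts, ends = self.arrays(chrom)
            self._merged[chrom] = _merge(starts, ends)
        return self._merged[chrom]

    def covered_bases(self, chrom: str, start: int, end: int) -> int:
        """Number of bases of ``[start, end)`` covered by the union of this set."""
        ms, me = self.merged_arrays(chrom)
        if ms.size == 0:
            return 0
        i = int(np.searchsorted(me, start, side="right"))
        j = int(np.searchsorted(ms, end, side="left"))
        if i >= j:
            return 0
        lo = np.clip(ms[i:j], start, end)
        hi = np.clip(me[i:j], start, end)
        return int(np.maximum(hi - lo, 0).sum())

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        """True iff ``[start, end)`` overlaps some interval by >= 1 base."""
        ms, me = self.merged_arrays(chrom)
        if ms.size == 0:
            return False
        # first merged interval with end > start must begin before `end`
        i = int(np.searchsorted(me, start, side="right"))
        return i < ms.size and ms[i] < end

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self],
                "start": [iv.start for iv in self],
                "end": [iv.end for iv in self],
                "name": [iv.name for iv in self],
                "score": [iv.score for iv in self],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, genome_id: str | None = None) -> "IntervalSet":
        has_name = "name" in df.columns
        has_score = "score" in df.columns
        ivs = [
            GenomicInterval(
                str(r.chrom),
                int(r.start),
                int(r.end),
                (str(r.name) if has_name and pd.notna(r.name) else None),
                (float(r.score) if has_score and pd.notna(r.score) else None),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(ivs, genome_id=genome_id)


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted possibly-overlapping intervals into a disjoint union."""
    if starts.size == 0:
        return starts, ends
    out_s: list[int] = [int(starts[0])]
    out_e: list[int] = [int(ends[0])]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(e))
        else:
            out_s.append(int(s))
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


# ---------------------------------------------------------------------------
# BED I/O


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path, genome: Genome | None = None) -> IntervalSet:
    """Read a BED3+ / narrowPeak file into a canonical :class:`IntervalSet`.

    Column 4 is kept as ``name`` and column 5 as ``score`` when parseable.
    ``track``/``browser`` and ``#`` comment lines are skipped. When a genome
    is given, every chromosome must be declared in it.
    """
    intervals: list[GenomicInterval] = []
    bad_chroms: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinate in {fields[1:3]}"
                ) from exc
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval {chrom}:{start}-{end} "
                    "(require 0 <= start < end)"
                )
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            if genome is not None and chrom not in genome:
                bad_chroms.add(chrom)
                continue
            intervals.append(GenomicInterval(chrom, start, end, name, score))
    if bad_chroms:
        raise BedParseError(
            f"{path}: chromosomes absent from genome: {sorted(bad_chroms)}"
        )
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    """Write BED6 (strand is always '.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# Interval arithmetic


def intersect_replicates(
    rep1: IntervalSet, rep2: IntervalSet, clip: bool = False
) -> IntervalSet:
    """Replicate intersection: rep1 peaks supported by rep2.

    With ``clip=False`` (default) the full rep1 peak is returned whenever it
    overlaps some rep2 interval by >= 1 base — peak-call medians suggest whole
    peaks are what downstream sizing expects. With ``clip=True`` the maximal
    covered segments (rep1 ∩ union(rep2)) are returned instead.
    """
    out: list[GenomicInterval] = []
    for iv in rep1:
        ms, me = rep2.merged_arrays(iv.chrom)
        if ms.size == 0:
            continue
        lo = np.maximum(ms, iv.start)
        hi = np.minimum(me, iv.end)
        mask = hi > lo
        if not mask.any():
            continue
        if clip:
            for s, e in zip(lo[mask], hi[mask]):
                out.append(GenomicInterval(iv.chrom, int(s), int(e), iv.name, iv.score))
        else:
            out.append(iv)
    return IntervalSet(out, genome_id=rep1.genome_id)


def overlap_fraction(site: GenomicInterval, track: IntervalSet) -> float:
    """Fraction of the site's bases covered by the union of the track's peaks.

    This is the occupancy encoding x ∈ [0, 1]: x = 1 when a peak fully covers
    the site, x = 0.6 when 60% of the site is covered, 0 when none is.
    Overlapping track peaks are merged first (union semantics), so the value
    is invariant to how covering peaks are split into abutting pieces.
    """
    covered = track.covered_bases(site.chrom, site.start, site.end)
    return covered / site.length


def bin_genome(genome: Genome, width: int = 250) -> IntervalSet:
    """Tile every chromosome with consecutive non-overlapping ``width``-base bins.

    The trailing partial bin is emitted truncated (never dropped), so the sum
    of bin lengths equals the genome size. Bins are named ``chrom:start``.
    """
    if width < 1:
        raise ValueError(f"bin width must be >= 1, got {width}")
    bins: list[GenomicInterval] = []
    for chrom, size in genome.chrom_sizes.items():
        starts = range(0, size, width)
        for s in starts:
            e = min(s + width, size)
            bins.append(GenomicInterval(chrom, s, e, name=f"{chrom}:{s}"))
    return IntervalSet(bins)


def label_intervals(regions: IntervalSet, dsb: IntervalSet) -> np.ndarray:
    """Binary labels aligned with ``regions``: 1 iff >= 1-base overlap with ``dsb``."""
    labels = np.zeros(len(regions), dtype=np.int8)
    for i, iv in enumerate(regions):
        if dsb.overlaps_any(iv.chrom, iv.start, iv.end):
            labels[i] = 1
    return labels


# ---------------------------------------------------------------------------
# Average profiles


@dataclass
class ProfileMatrix:
    """Mean signal around site centers, in offset bins symmetric about 0.

    ``bin_offsets`` are the (strictly increasing) bin-center offsets from the
    site center in bases; ``values`` is the mean per-base coverage depth per
    offset bin across the ``n_sites`` aggregated sites. Sites whose window
    would extend past a chromosome end are dropped and counted in
    ``n_dropped``.
    """

    bin_offsets: np.ndarray
    values: np.ndarray
    n_sites: int
    n_dropped: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.bin_offsets, "mean": self.values, "n": self.n_sites}
        )


def average_profile(
    signal: IntervalSet,
    sites: IntervalSet,
    genome: Genome,
    flank: int = 2000,
    bin: int = 50,
) -> ProfileMatrix:
    """Average coverage-depth profile of ``signal`` around the centers of ``sites``.

    For each site, coverage depth (number of signal intervals covering each
    base) is averaged in ``bin``-base windows over ``[center - flank,
    center + flank)``; the profile is the mean across sites.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if bin < 1:
        raise ValueError("bin must be >= 1")
    if len(sites) == 0:
        raise ValueError("no sites to profile")
    n_bins = (2 * flank) // bin
    if n_bins < 1:
        raise ValueError("flank too small for bin width")
    acc = np.zeros(n_bins, dtype=float)
    n_used = 0
    n_dropped = 0
    for iv in sites:
        c = iv.center
        lo, hi = c - flank, c - flank + n_bins * bin
        size = genome.chrom_sizes.get(iv.chrom)
        if size is None or lo < 0 or hi > size:
            n_dropped += 1
            continue
        starts, ends = signal.arrays(iv.chrom)
        depth = np.zeros(hi - lo, dtype=float)
        if starts.size:
            s = np.clip(starts, lo, hi) - lo
            e = np.clip(ends, lo, hi) - lo
            keep = e > s
            for a, b in zip(s[keep], e[keep]):
                depth[a:b] += 1.0
        acc += depth.reshape(n_bins, bin).mean(axis=1)
        n_used += 1
    if n_used == 0:
        raise ValueError("all sites dropped (windows exceed chromosome bounds)")
    offsets = -flank + bin * np.arange(n_bins) + bin / 2.0
    return ProfileMatrix(offsets, acc / n_used, n_sites=n_used, n_dropped=n_dropped)
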