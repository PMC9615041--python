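"""Genomic interval I/O, merging, and fragment-in-peak counting.

All coordinates are 0-based half-open (BED convention). Peak strand is
ignored throughout; merging treats bookended intervals (gap 0) as
overlapping, matching the common merge-tool default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class BedFormatError(ValueError):
    """Raised for a malformed BED record; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals.

    Lines starting with '#', 'track' or 'browser' are skipped. A record
    with start >= end raises :class:`BedFormatError` naming the line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError("fewer than 3 tab-separated columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"non-integer coordinates: {exc}", lineno)
            if start < 0:
                raise BedFormatError("negative start coordinate", lineno)
            if start >= end:
                raise BedFormatError(f"start {start} >= end {end}", lineno)
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def merge_intervals(
    *interval_sets: Sequence[GenomicInterval],
    max_gap: int = 0,
) -> tuple[list[GenomicInterval], dict[str, str]]:
    """Merge one or more interval sets into disjoint sorted intervals.

    Two intervals are merged iff the gap between them is <= ``max_gap``;
    at the default 0 bookended intervals merge. Returns the merged peaks
    (named ``merged_1`` ... in chromosome/coordinate order) and a
    provenance map from every input interval name to its merged peak name.
    """
    pool: list[GenomicInterval] = [iv for s in interval_sets for iv in s]
    if not pool:
        return [], {}
    order = sorted(range(len(pool)), key=lambda i: (pool[i].chrom, pool[i].start, pool[i].end))
    merged: list[GenomicInterval] = []
    provenance: dict[str, str] = {}
    cur_chrom, cur_start, cur_end = None, 0, 0
    members: list[int] = []

    def _flush() -> None:
        if cur_chrom is None:
            return
        name = f"merged_{len(merged) + 1}"
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end, name))
        for idx in members:
            provenance[pool[idx].name] = name

    for i in order:
        iv = pool[i]
        if iv.chrom == cur_chrom and iv.start <= cur_end + max_gap:
            cur_end = max(cur_end, iv.end)
            members.append(i)
        else:
            _flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            members = [i]
    _flush()
    return merged, provenance


@dataclass
class CountMatrix:
    """Peak x sample integer counts with per-sample (day, replicate) metadata.

    ``samples`` has columns sample_id, day, replicate and one row per count
    column, in column order.
    """

    counts: pd.DataFrame  # index = peak ids, columns = sample ids
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns and sample sheet rows disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        pairs = list(zip(self.samples["day"], self.samples["replicate"]))
        if len(pairs) != len(set(pairs)):
            raise ValueError("(day, replicate) pairs must be unique")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def days(self) -> list:
        return sorted(self.samples["day"].unique().tolist())

    def columns_for_days(self, days: Sequence) -> "CountMatrix":
        mask = self.samples["day"].isin(days).to_numpy()
        sub = self.samples.loc[mask].reset_index(drop=True)
        return CountMatrix(self.counts[list(sub["sample_id"])], sub)

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("peak_id").to_csv(counts_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts, samples)


def count_fragments(
    fragments: Mapping[str, Sequence[GenomicInterval]],
    peaks: Sequence[GenomicInterval],
    samples: pd.DataFrame,
    count_multi_overlap: bool = False,
) -> CountMatrix:
    """Count fragments overlapping peaks, one column per sample.

    A fragment increments a peak iff they overlap by >= 1 bp. A fragment
    overlapping more than one peak is discarded unless
    ``count_multi_overlap`` is set. Peaks must be disjoint per chromosome
    (i.e. already merged).
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        idx = np.array([i for i, p in enumerate(peaks) if p.chrom == chrom])
        starts = np.array([peaks[i].start for i in idx])
        ends = np.array([peaks[i].end for i in idx])
        order = np.argsort(starts)
        s, e = starts[order], ends[order]
        if (s[1:] < e[:-1]).any():
            raise ValueError(f"peaks on {chrom} are not disjoint; merge them first")
        by_chrom[chrom] = (s, e, idx[order])

    mat = np.zeros((len(peaks), len(samples)), dtype=np.int64)
    for j, sample_id in enumerate(samples["sample_id"]):
        for frag in fragments.get(sample_id, ()):
            entry = by_chrom.get(frag.chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            # overlapping peaks: start < frag.end and end > frag.start
            lo = np.searchsorted(ends, frag.start, side="right")
            hi = np.searchsorted(starts, frag.end, side="left")
            hits = idx[lo:hi]
            if len(hits) == 0:
                continue
            if len(hits) > 1 and not count_multi_overlap:
                continue
            mat[hits, j] += 1

    counts = pd.DataFrame(mat, index=[p.name for p in peaks], columns=list(samples["sample_id"]))
    return CountMatrix(counts, samples.reset_index(drop=True))
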