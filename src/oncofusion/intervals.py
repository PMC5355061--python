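"""Genomic interval algebra for binding-site comparison.

Peaks (transcription-factor or oncofusion-protein binding sites) are
strandless half-open intervals in BED convention: 0-based start, exclusive
end.  Two intervals *overlap* iff they share at least one base pair;
touching intervals ([a,b) and [b,c)) do not overlap but are fused by
:func:`merge`.  The module provides BED I/O, merging, directed pairwise
sharing fractions and the three-set Venn classification used to compare
binding programs of several factors.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VENN_LABELS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


class BedFormatError(ValueError):
    """Raised when a BED file contains malformed records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (touching does not count)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """Sorted collection of intervals for one factor.

    Intervals are kept sorted by (chrom, start, end).  Duplicate identical
    intervals are collapsed on construction with a logged warning so that
    sharing fractions never double-count a site.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], factor: str = ""):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        deduped: list[GenomicInterval] = []
        n_dup = 0
        for iv in ivs:
            if deduped and (
                deduped[-1].chrom == iv.chrom
                and deduped[-1].start == iv.start
                and deduped[-1].end == iv.end
            ):
                n_dup += 1
                continue
            deduped.append(iv)
        if n_dup:
            log.warning(
                "PeakSet %r: collapsed %d duplicate identical interval(s)",
                factor, n_dup,
            )
        self.factor = factor
        self.intervals: tuple[GenomicInterval, ...] = tuple(deduped)
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in {iv.chrom for iv in deduped}:
            sub = [iv for iv in deduped if iv.chrom == chrom]
            self._index[chrom] = (
                np.array([iv.start for iv in sub], dtype=np.int64),
                np.array([iv.end for iv in sub], dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"PeakSet(factor={self.factor!r}, n={len(self)})"

    def chromosomes(self) -> list[str]:
        return sorted(self._index)

    def overlaps_any(self, iv: GenomicInterval) -> bool:
        """True iff *iv* shares >= 1 bp with some interval in this set."""
        if iv.chrom not in self._index:
            return False
        starts, ends = self._index[iv.chrom]
        # candidates: peaks starting before iv.end
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi == 0:
            return False
        return bool(np.any(ends[:hi] > iv.start))


def read_bed(path: str | Path, factor: str | None = None) -> PeakSet:
    """Read a BED(3+) file into a :class:`PeakSet`.

    Lines starting with ``#``, ``track`` or ``browser`` are skipped.  Every
    malformed record (fewer than 3 columns, non-integer or negative
    coordinates, start >= end) is collected and reported in a single
    :class:`BedFormatError` naming the offending line numbers.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if start < 0:
                errors.append(f"line {lineno}: negative start {start}")
                continue
            if start >= end:
                errors.append(f"line {lineno}: start {start} >= end {end}")
                continue
            name = fields[3] if len(fields) > 3 else None
            score: float | None = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            intervals.append(GenomicInterval(chrom, start, end, name, score))
    if errors:
        head = "; ".join(errors[:10])
        raise BedFormatError(
            f"{path}: {len(errors)} malformed line(s): {head}"
        )
    return PeakSet(intervals, factor=factor or path.stem)


def write_bed(peaks: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
                if iv.score is not None:
                    cols.append(f"{iv.score:g}")
            fh.write("\t".join(cols) + "\n")


def merge(peaks: PeakSet | Sequence[GenomicInterval]) -> PeakSet:
    """Fuse overlapping *and touching* intervals into maximal runs.

    The union of covered bases is preserved; no two output intervals
    overlap or touch.
    """
    ivs = list(peaks)
    ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    factor = peaks.factor if isinstance(peaks, PeakSet) else ""
    return PeakSet(out, factor=factor)


@dataclass
class SharingResult:
    """Directed sharing between two peak sets.

    ``fraction_a_in_b`` = (#peaks of A overlapping >= 1 peak of B) / |A|;
    NaN when the denominator set is empty (never silently 0).
    """

    factor_a: str
    factor_b: str
    n_a: int
    n_b: int
    n_a_shared: int
    n_b_shared: int
    fraction_a_in_b: float
    fraction_b_in_a: float
    shared_a: tuple[GenomicInterval, ...]
    shared_b: tuple[GenomicInterval, ...]


def pairwise_sharing(a: PeakSet, b: PeakSet) -> SharingResult:
    """Directed peak-level sharing fractions between two binding-site sets.

    A peak "shares" iff it overlaps at least one peak of the other set by
    >= 1 bp.  Both directions are returned because the fractions are not
    symmetric when set sizes differ.
    """
    shared_a = tuple(iv for iv in a if b.overlaps_any(iv))
    shared_b = tuple(iv for iv in b if a.overlaps_any(iv))
    if len(a) == 0 or len(b) == 0:
        log.warning(
            "pairwise_sharing(%s, %s): empty set -> fraction undefined (NaN)",
            a.factor, b.factor,
        )
    frac_a = len(shared_a) / len(a) if len(a) else float("nan")
    frac_b = len(shared_b) / len(b) if len(b) else float("nan")
    return SharingResult(
        factor_a=a.factor, factor_b=b.factor,
        n_a=len(a), n_b=len(b),
        n_a_shared=len(shared_a), n_b_shared=len(shared_b),
        fraction_a_in_b=frac_a, fraction_b_in_a=frac_b,
        shared_a=shared_a, shared_b=shared_b,
    )


def sharing_table(sets: Sequence[PeakSet]) -> pd.DataFrame:
    """All directed pairwise sharing fractions as a tidy table."""
    rows = []
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i >= j:
                continue
            res = pairwise_sharing(a, b)
            rows.append({
                "set": res.factor_a, "other": res.factor_b,
                "n_shared": res.n_a_shared, "n_total": res.n_a,
                "fraction": res.fraction_a_in_b,
            })
            rows.append({
                "set": res.factor_b, "other": res.factor_a,
                "n_shared": res.n_b_shared, "n_total": res.n_b,
                "fraction": res.fraction_b_in_a,
            })
    return pd.DataFrame(rows, columns=["set", "other", "n_shared", "n_total", "fraction"])


@dataclass
class VennClassification:
    """Three-set Venn over merged union regions.

    Each merged region of A union B union C is labelled by which input
    sets contribute >= 1 bp; labels partition the merged union.
    """

    factors: tuple[str, str, str]
    regions: tuple[tuple[GenomicInterval, str], ...]
    counts: dict[str, int]
    sharing: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "factors": list(self.factors),
                "counts": self.counts,
                "n_regions": len(self.regions),
            },
            indent=2,
        )

    def labelled_bed(self, path: str | Path) -> None:
        write_bed(
            [replace(iv, name=label) for iv, label in self.regions], path
        )


def venn3(a: PeakSet, b: PeakSet, c: PeakSet) -> VennClassification:
    """Classify merged union regions of three peak sets into Venn categories.

    The union of all three sets is merged (touching intervals fused); each
    merged region is labelled A/B/C/AB/AC/BC/ABC according to which input
    sets overlap it by >= 1 bp.  Directed peak-level sharing fractions are
    attached because region-level and peak-level accounting both occur in
    practice and differ when peaks are fragmented.
    """
    union = merge(list(a) + list(b) + list(c))
    counts = {lab: 0 for lab in VENN_LABELS}
    regions: list[tuple[GenomicInterval, str]] = []
    for region in union:
        label = ""
        if a.overlaps_any(region):
            label += "A"
        if b.overlaps_any(region):
            label += "B"
        if c.overlaps_any(region):
            label += "C"
        # every merged region comes from at least one input interval
        counts[label] += 1
        regions.append((region, label))
    return VennClassification(
        factors=(a.factor, b.factor, c.factor),
        regions=tuple(regions),
        counts=counts,
        sharing=sharing_table([a, b, c]),
    )
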