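"""Tag counting, library-normalized densities and coverage tracks.

A *tag* is a mapped sequencing read reduced to a single genomic position.
The normalization follows the 1 kb-percent convention: the tag count in a
region is rescaled to a 1 kb-equivalent count and expressed as a
percentage of the library total,

    density = (count / region_length_kb) / library_total * 100

so that summing the density over any exhaustive disjoint tiling of the
genome in 1 kb windows yields exactly 100%.  Tags are counted as single
positions regardless of strand; no fragment extension is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

log = logging.getLogger(__name__)


@dataclass
class TagLibrary:
    """Mapped tag positions per chromosome, with the library total.

    ``tags`` maps chromosome -> sorted int64 array of 0-based positions.
    ``strands`` (optional, same shapes) is carried through I/O but ignored
    by all counting operations.
    """

    tags: dict[str, np.ndarray]
    name: str = ""
    strands: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, pos in self.tags.items():
            pos = np.asarray(pos, dtype=np.int64)
            order = np.argsort(pos, kind="stable")
            self.tags[chrom] = pos[order]
            if chrom in self.strands:
                self.strands[chrom] = np.asarray(self.strands[chrom])[order]

    @property
    def total(self) -> int:
        return int(sum(len(p) for p in self.tags.values()))

    @classmethod
    def read_bed(cls, path: str | Path, name: str | None = None) -> "TagLibrary":
        """Read single-bp tag intervals from BED6 (strand in column 6)."""
        path = Path(path)
        pos: dict[str, list[int]] = {}
        strand: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                chrom, start = f[0], int(f[1])
                pos.setdefault(chrom, []).append(start)
                strand.setdefault(chrom, []).append(f[5] if len(f) > 5 else ".")
        return cls(
            tags={c: np.array(p, dtype=np.int64) for c, p in pos.items()},
            strands={c: np.array(s) for c, s in strand.items()},
            name=name or path.stem,
        )

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.tags):
                pos = self.tags[chrom]
                st = self.strands.get(chrom)
                for i, p in enumerate(pos):
                    s = st[i] if st is not None else "."
                    fh.write(f"{chrom}\t{p}\t{p + 1}\ttag\t0\t{s}\n")


def count_tags(region: GenomicInterval, lib: TagLibrary) -> int:
    """Number of tag positions p with region.start <= p < region.end."""
    pos = lib.tags.get(region.chrom)
    if pos is None:
        return 0
    lo = int(np.searchsorted(pos, region.start, side="left"))
    hi = int(np.searchsorted(pos, region.end, side="left"))
    return hi - lo


def normalized_density(region: GenomicInterval, lib: TagLibrary) -> float:
    """Percent-of-library tag density rescaled to a 1 kb-equivalent count."""
    total = lib.total
    if total <= 0:
        raise ValueError("library total must be positive")
    length_kb = region.length / 1000.0
    if length_kb <= 0:
        raise ValueError("zero-length region")
    return (count_tags(region, lib) / length_kb) / total * 100.0


@dataclass
class DensityMatrix:
    """Peaks x bins normalized-density matrix around peak midpoints."""

    values: np.ndarray  # shape (n_peaks, n_bins), percent of library per kb
    peaks: tuple[GenomicInterval, ...]
    w: int
    n_bins: int
    library: str

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values,
            index=[f"{p.chrom}:{p.start}-{p.end}" for p in self.peaks],
            columns=[f"bin_{i}" for i in range(self.n_bins)],
        )
        df.to_csv(path, sep="\t", index_label="peak")
        meta = {
            "w": self.w, "n_bins": self.n_bins, "library": self.library,
            "units": "percent of library total per kb",
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))

    def sorted_by_signal(self) -> "DensityMatrix":
        """Rows in descending total-signal order (heatmap display convention)."""
        order = np.argsort(-self.values.sum(axis=1), kind="stable")
        return DensityMatrix(
            values=self.values[order],
            peaks=tuple(self.peaks[i] for i in order),
            w=self.w, n_bins=self.n_bins, library=self.library,
        )


def density_matrix(
    peaks: PeakSet | Sequence[GenomicInterval],
    lib: TagLibrary,
    w: int = 5000,
    n_bins: int = 100,
) -> DensityMatrix:
    """Normalized tag density in *n_bins* bins across +/- *w* bp of each midpoint.

    Bin b of peak i covers [mid - w + b*binw, mid - w + (b+1)*binw) with
    binw = 2w / n_bins.  Row order matches input peak order.
    """
    peak_list = tuple(peaks)
    if not peak_list:
        raise ValueError("density_matrix requires a non-empty peak set")
    if (2 * w) % n_bins != 0:
        raise ValueError(f"2w = {2 * w} not divisible by n_bins = {n_bins}")
    binw = (2 * w) // n_bins
    total = lib.total
    if total <= 0:
        raise ValueError("library total must be positive")
    binw_kb = binw / 1000.0
    values = np.zeros((len(peak_list), n_bins))
    for i, p in enumerate(peak_list):
        pos = lib.tags.get(p.chrom)
        if pos is None:
            continue
        mid = p.midpoint
        edges = mid - w + binw * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(pos, edges, side="left"))
        values[i] = (counts / binw_kb) / total * 100.0
    name = getattr(peaks, "factor", "")
    return DensityMatrix(values, peak_list, w, n_bins, lib.name or name)


def average_profile(matrix: DensityMatrix) -> pd.DataFrame:
    """Per-bin mean (and median) density across peaks; the line-graph view."""
    if matrix.values.shape[0] < 1:
        raise ValueError("average_profile requires >= 1 row")
    binw = (2 * matrix.w) // matrix.n_bins
    centers = -matrix.w + binw * np.arange(matrix.n_bins) + binw // 2
    return pd.DataFrame({
        "bin": np.arange(matrix.n_bins),
        "offset_bp": centers,
        "mean": matrix.values.mean(axis=0),
        "median": np.median(matrix.values, axis=0),
    })


def coverage_track(
    lib: TagLibrary,
    chrom_lengths: Mapping[str, int],
    window: int = 10,
) -> pd.DataFrame:
    """Per-bp tag counts averaged over consecutive *window*-bp windows.

    Returns a bedGraph-style table (chrom, start, end, value) with
    zero-valued windows omitted (zero-runs compressed).  The last window of
    a chromosome may be shorter; its value is count / actual span, so total
    mass (sum of value * span) equals the library total.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        length = int(chrom_lengths[chrom])
        pos = lib.tags.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        if len(pos) and (pos[0] < 0 or pos[-1] >= length):
            raise ValueError(
                f"{chrom}: tag positions outside [0, {length})"
            )
        edges = np.arange(0, length + window, window)
        edges[-1] = min(edges[-1], length)
        if edges[-1] <= edges[-2]:
            edges = edges[:-1]
        counts = np.diff(np.searchsorted(pos, edges, side="left"))
        spans = np.diff(edges)
        nz = counts > 0
        for s, e, c in zip(edges[:-1][nz], edges[1:][nz], counts[nz]):
            rows.append((chrom, int(s), int(e), c / (e - s)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.itertuples(index=False, name=None):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
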