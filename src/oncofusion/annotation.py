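"""Genomic-feature annotation of binding sites and target-gene assignment.

Every binding site gets exactly one label — promoter, exon, intron or
intergenic — decided by its midpoint against a gene catalog.  The promoter
is the 500 bp immediately upstream of the transcription start site (TSS),
strand-aware; everything not promoter/exon/intron is intergenic.  When
windows of several genes disagree the priority is
promoter > exon > intron.  Target genes are assigned by nearest TSS within
a +/- 25 kb window around the peak midpoint, the distance signed negative
upstream of the TSS relative to gene strand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, PeakSet

log = logging.getLogger(__name__)

PROMOTER_BP = 500
TARGET_WINDOW_BP = 25_000
FEATURE_LABELS = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """One transcript model: span, strand and exon structure.

    Coordinates are 0-based half-open.  TSS = tx_start on the + strand and
    tx_end - 1 on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"bad transcript span [{self.tx_start}, {self.tx_end})")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping and "
                    f"inside [{self.tx_start}, {self.tx_end})"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def promoter_window(self, promoter_bp: int = PROMOTER_BP) -> tuple[int, int]:
        """Half-open upstream window: [TSS-500, TSS) for +, [TSS+1, TSS+501) for -."""
        if self.strand == "+":
            return (max(0, self.tss - promoter_bp), self.tss)
        return (self.tss + 1, self.tss + 1 + promoter_bp)

    def feature_at(self, pos: int, promoter_bp: int = PROMOTER_BP) -> str:
        """Label of a single base position against this gene alone."""
        ps, pe = self.promoter_window(promoter_bp)
        if ps <= pos < pe:
            return "promoter"
        if self.tx_start <= pos < self.tx_end:
            for s, e in self.exons:
                if s <= pos < e:
                    return "exon"
            return "intron"
        return "intergenic"


class GeneCatalog:
    """Collection of gene models indexed by chromosome; one model per gene."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: tuple[GeneModel, ...] = tuple(
            sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id))
        )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in catalog")
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        # TSS arrays (sorted) per chromosome for nearest-gene queries
        self._tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        for chrom, gs in self._by_chrom.items():
            order = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = (
                np.array([g.tss for g in order], dtype=np.int64), order
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def on_chrom(self, chrom: str) -> Sequence[GeneModel]:
        return self._by_chrom.get(chrom, [])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeneCatalog":
        """Read the RefSeq-like catalog table.

        Columns: gene_id, chrom, strand, tx_start, tx_end, exon_starts,
        exon_ends (the last two comma-separated, 0-based half-open).
        """
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        genes = []
        for row in df.itertuples(index=False):
            starts = [int(x) for x in str(row.exon_starts).split(",") if x]
            ends = [int(x) for x in str(row.exon_ends).split(",") if x]
            genes.append(GeneModel(
                gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
                tx_start=int(row.tx_start), tx_end=int(row.tx_end),
                exons=tuple(zip(starts, ends)),
            ))
        return cls(genes)

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for g in self.genes:
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "tx_start": g.tx_start, "tx_end": g.tx_end,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_PRIORITY = {"promoter": 0, "exon": 1, "intron": 2, "intergenic": 3}


def classify_peak(
    peak: GenomicInterval,
    catalog: GeneCatalog,
    promoter_bp: int = PROMOTER_BP,
) -> str:
    """Single feature label for a binding site, decided by its midpoint.

    The best (highest-priority) label over all genes of the chromosome
    wins, so a midpoint inside one gene's intron but another gene's
    promoter is a promoter hit.  Peaks on chromosomes absent from the
    catalog are intergenic (with a warning).
    """
    genes = catalog.on_chrom(peak.chrom)
    if not genes:
        log.warning(
            "peak %s:%d-%d on chromosome absent from catalog -> intergenic",
            peak.chrom, peak.start, peak.end,
        )
        return "intergenic"
    mid = peak.midpoint
    best = "intergenic"
    for g in genes:
        lab = g.feature_at(mid, promoter_bp)
        if _PRIORITY[lab] < _PRIORITY[best]:
            best = lab
            if best == "promoter":
                break
    return best


def distribution(
    peaks: PeakSet,
    catalog: GeneCatalog,
    promoter_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Feature-label counts and fractions over a peak set (fractions sum to 1)."""
    if len(peaks) == 0:
        raise ValueError("cannot compute feature distribution of an empty peak set")
    counts = {lab: 0 for lab in FEATURE_LABELS}
    for iv in peaks:
        counts[classify_peak(iv, catalog, promoter_bp)] += 1
    n = len(peaks)
    return pd.DataFrame({
        "feature": list(FEATURE_LABELS),
        "count": [counts[lab] for lab in FEATURE_LABELS],
        "fraction": [counts[lab] / n for lab in FEATURE_LABELS],
    })


@dataclass(frozen=True)
class TargetAssignment:
    """Peak -> nearest gene within the window, or none."""

    peak: GenomicInterval
    gene_id: str | None
    distance: int | None  # signed; negative = upstream of TSS (gene strand)


def assign_targets(
    peaks: PeakSet,
    catalog: GeneCatalog,
    window: float = TARGET_WINDOW_BP,
) -> tuple[list[TargetAssignment], set[str]]:
    """Assign each peak to the nearest TSS within +/- *window* bp of its midpoint.

    Ties on |distance| are broken by lexicographically smaller gene id.
    Returns the per-peak assignments and the deduplicated target-gene set.
    Pass ``window=math.inf`` to assign every peak on a gene-bearing
    chromosome.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    assignments: list[TargetAssignment] = []
    targets: set[str] = set()
    for iv in peaks:
        entry = catalog._tss.get(iv.chrom)
        if entry is None:
            assignments.append(TargetAssignment(iv, None, None))
            continue
        tss_arr, order = entry
        mid = iv.midpoint
        # all TSS within the window, by searchsorted range; pick the best
        # by (|distance|, gene_id)
        lo = int(np.searchsorted(tss_arr, mid - window, side="left"))
        hi = int(np.searchsorted(tss_arr, mid + window, side="right"))
        candidates = order[lo:hi]
        best: GeneModel | None = None
        best_abs: int | None = None
        for g in candidates:
            d_abs = abs(mid - g.tss)
            if d_abs > window:
                continue
            if (
                best is None
                or d_abs < best_abs  # type: ignore[operator]
                or (d_abs == best_abs and g.gene_id < best.gene_id)
            ):
                best, best_abs = g, d_abs
        if best is None or best_abs is None:
            assignments.append(TargetAssignment(iv, None, None))
            continue
        signed = mid - best.tss
        if best.strand == "-":
            signed = -signed
        assignments.append(TargetAssignment(iv, best.gene_id, int(signed)))
        targets.add(best.gene_id)
    return assignments, targets


def assignments_table(assignments: Sequence[TargetAssignment]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "chrom": a.peak.chrom, "start": a.peak.start, "end": a.peak.end,
            "gene_id": a.gene_id if a.gene_id is not None else ".",
            "distance": a.distance if a.distance is not None else ".",
        }
        for a in assignments
    ])


def target_overlap3(
    set_a: set[str], set_b: set[str], set_c: set[str]
) -> dict[str, int]:
    """Three-way Venn category counts over target-gene sets.

    The seven categories partition the union of the three sets.
    """
    return {
        "A": len(set_a - set_b - set_c),
        "B": len(set_b - set_a - set_c),
        "C": len(set_c - set_a - set_b),
        "AB": len((set_a & set_b) - set_c),
        "AC": len((set_a & set_c) - set_b),
        "BC": len((set_b & set_c) - set_a),
        "ABC": len(set_a & set_b & set_c),
    }


def annotate_peaks_table(
    peaks: PeakSet,
    catalog: GeneCatalog,
    window: float = TARGET_WINDOW_BP,
    promoter_bp: int = PROMOTER_BP,
) -> pd.DataFrame:
    """Combined per-peak annotation: feature label + target assignment."""
    assignments, _ = assign_targets(peaks, catalog, window)
    rows = []
    for a in assignments:
        rows.append({
            "chrom": a.peak.chrom, "start": a.peak.start, "end": a.peak.end,
            "label": classify_peak(a.peak, catalog, promoter_bp),
            "gene_id": a.gene_id if a.gene_id is not None else ".",
            "distance": a.distance if a.distance is not None else ".",
        })
    return pd.DataFrame(rows)


def distribution_json(dist: pd.DataFrame) -> str:
    return json.dumps(
        {feature: {"count": int(count), "fraction": float(frac)}
         for feature, count, frac in dist.itertuples(index=False, name=None)},
        indent=2,
    )
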