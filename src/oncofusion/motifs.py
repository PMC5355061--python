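"""Position-weight-matrix scanning of binding-site sequences.

A PWM holds per-position base probabilities for a transcription-factor
motif.  Windows are scored as log2 odds against a background base
distribution; hits are windows on either strand scoring at least a
fraction (default 0.9) of the matrix's maximum achievable score — a
self-calibrating cutoff that needs no per-matrix tuning.  The headline
statistic is the percentage of binding sites harboring at least one
occurrence, computed per factor.

The bundled default matrices (RUNX1, SPI1, GATA1, TAL1, CEBPA) are
synthetic consensus-style matrices built from the factors' canonical core
sequences; JASPAR-format files can be substituted via :func:`read_jaspar`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import GenomicInterval, PeakSet

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_THRESHOLD_FRAC = 0.9


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Per-position base-probability matrix with background model.

    ``matrix`` has shape (L, 4) over A, C, G, T.  A pseudocount is mixed in
    and rows renormalized at construction, so log-odds are always finite.
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if m.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if np.any(m < 0):
            raise ValueError("PWM entries must be non-negative")
        # accept counts or probabilities; normalize rows after pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        m = (m + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        self.matrix = m
        bg = (
            np.full(4, 0.25)
            if self.background is None
            else np.asarray(self.background, dtype=float)
        )
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be 4 positive frequencies summing to 1")
        self.background = bg
        with np.errstate(divide="ignore"):  # -inf allowed at pseudocount 0
            self._logodds = np.log2(self.matrix / bg)  # (L, 4), bits

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        """Best achievable log-odds score, in bits."""
        return float(self._logodds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


def logodds_score(seq_window: str, pwm: PWM) -> float:
    """Log2-odds score of one window; N bases contribute 0 bits."""
    if len(seq_window) != len(pwm):
        raise ValueError(
            f"window length {len(seq_window)} != PWM length {len(pwm)}"
        )
    score = 0.0
    for i, base in enumerate(seq_window.upper()):
        if base == "N":
            continue
        j = _BASE_INDEX.get(base)
        if j is None:
            raise ValueError(f"unexpected base {base!r} in sequence window")
        score += pwm._logodds[i, j]
    return score


@dataclass(frozen=True)
class MotifOccurrence:
    peak_id: str
    offset: int  # on the forward sequence, 0-based
    strand: str  # '+' or '-'
    score: float  # bits


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; A,C,G,T -> 0..3, anything else -> 4 (N)."""
    codes = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def scan_peak(
    sequence: str,
    pwm: PWM,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    peak_id: str = "",
) -> list[MotifOccurrence]:
    """All motif occurrences in one peak sequence, both strands.

    A hit is any offset scoring >= threshold_frac * max_score; the minus
    strand is scored on the reverse complement, with the occurrence offset
    reported on the forward sequence.  Sequences shorter than the matrix
    yield an empty list with a warning.
    """
    if not (0.0 < threshold_frac <= 1.0):
        raise ValueError("threshold_frac must be in (0, 1]")
    L = len(pwm)
    if len(sequence) < L:
        log.warning(
            "peak %r: sequence length %d < motif length %d; no scan",
            peak_id, len(sequence), L,
        )
        return []
    cutoff = threshold_frac * pwm.max_score - 1e-9
    lo_n = np.hstack([pwm._logodds, np.zeros((L, 1))])  # extra col: N -> 0 bits
    hits: list[MotifOccurrence] = []
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        codes = _encode(seq)
        n_win = len(seq) - L + 1
        # windows x positions score via sliding gather
        idx = np.arange(L)[None, :] + np.arange(n_win)[:, None]
        scores = lo_n[np.arange(L)[None, :], codes[idx]].sum(axis=1)
        for off in np.nonzero(scores >= cutoff)[0]:
            fwd_off = int(off) if strand == "+" else len(sequence) - L - int(off)
            hits.append(
                MotifOccurrence(peak_id, fwd_off, strand, float(scores[off]))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def fraction_with_motif(
    peaks: PeakSet | Sequence[GenomicInterval],
    genome_fasta: str | Path,
    pwm: PWM,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> float:
    """Percent of binding sites harboring >= 1 motif occurrence."""
    peak_list = list(peaks)
    if not peak_list:
        raise ValueError("fraction_with_motif requires >= 1 peak")
    fasta = Fasta(str(genome_fasta))
    n_hit = 0
    for i, p in enumerate(peak_list):
        if p.chrom not in fasta or p.end > len(fasta[p.chrom]):
            raise ValueError(
                f"peak {p.chrom}:{p.start}-{p.end} outside FASTA bounds"
            )
        seq = str(fasta[p.chrom][p.start:p.end])
        if scan_peak(seq, pwm, threshold_frac, peak_id=p.name or str(i)):
            n_hit += 1
    return 100.0 * n_hit / len(peak_list)


def motif_summary(
    peaks_by_factor: dict[str, PeakSet],
    genome_fasta: str | Path,
    pwms: Sequence[PWM],
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> pd.DataFrame:
    """Percent-with-motif for every (peak set, PWM) pair."""
    rows = []
    for factor, peaks in peaks_by_factor.items():
        for pwm in pwms:
            rows.append({
                "peak_set": factor,
                "motif": pwm.name,
                "percent_with_motif": fraction_with_motif(
                    peaks, genome_fasta, pwm, threshold_frac
                ),
            })
    return pd.DataFrame(rows)


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> PWM:
    """Read a JASPAR-style plain-text matrix.

    Format: optional ``>name`` header, then 4 rows (A, C, G, T) of counts
    or probabilities, optionally wrapped in ``A [ ... ]`` brackets.
    """
    path = Path(path)
    name = path.stem
    rows: list[list[float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        cleaned = line.replace("[", " ").replace("]", " ")
        parts = cleaned.split()
        if parts and parts[0].upper() in ("A", "C", "G", "T"):
            parts = parts[1:]
        rows.append([float(x) for x in parts])
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 matrix rows (A/C/G/T), got {len(rows)}")
    matrix = np.array(rows, dtype=float).T  # -> (L, 4)
    return PWM(name=name, matrix=matrix, pseudocount=pseudocount)


def write_jaspar(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate(BASES):
            vals = " ".join(f"{v:.4f}" for v in pwm.matrix[:, i])
            fh.write(f"{base} [ {vals} ]\n")


def consensus_pwm(
    name: str, consensus: str, strength: float = 0.85,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Consensus-style matrix: the consensus base gets *strength*, the rest split."""
    consensus = consensus.upper()
    m = np.full((len(consensus), 4), (1.0 - strength) / 3.0)
    for i, base in enumerate(consensus):
        m[i, _BASE_INDEX[base]] = strength
    return PWM(name=name, matrix=m, pseudocount=pseudocount)


# Canonical core sequences for the five leukemia-associated factors;
# synthetic consensus-style stand-ins, not empirically derived matrices.
_DEFAULT_CONSENSUS = {
    "RUNX1": "TGTGGTTT",
    "SPI1": "AAAGAGGAAGTG",
    "GATA1": "AGATAAGA",
    "TAL1": "AACAGATG",
    "CEBPA": "TTGCGCAA",
}


def default_pwms(pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """The bundled synthetic consensus-style matrices."""
    return [
        consensus_pwm(name, cons, pseudocount=pseudocount)
        for name, cons in _DEFAULT_CONSENSUS.items()
    ]
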