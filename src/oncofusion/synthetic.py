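"""Synthetic data generator with known ground truth.

Every downstream stage of the pipeline — overlap classification, feature
annotation, motif scanning, tag-density profiling, group comparison and
signature discovery — is exercised on data produced here, so each planted
quantity (Venn category of every peak, motif-planted flag, per-gene
signature subtype, true group means) is recorded and the generator's
bookkeeping serves as an exact oracle.

Conventions:

* All randomness flows from one integer seed through named substreams,
  one per stage, so regenerating a single stage is reproducible.
* Shared peaks are placed at *identical* coordinates across factors and
  unique peaks are separated by more than one peak width, which makes the
  planted Venn labels unambiguous.
* Tags are a uniform per-bp Poisson background plus a per-peak triangular
  enrichment kernel (half-width = peak_width / 2) centred on the peak
  midpoint; the emitted library size is exactly the configured total.
* Expression baselines are log-normal on the linear scale with
  multiplicative log-normal noise; matrices are emitted on the linear
  scale (declared in the file header).  Signature genes get a
  subtype-exclusive fold change drawn log-uniformly from
  [signature_fc, signature_fc_max] — emulating a population of marker
  genes upregulated *at least* signature_fc-fold in one subtype — and
  common-target genes get a uniform shift in the three AML subtypes only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, GeneModel
from .expression import ExpressionMatrix, GroupMap
from .intervals import GenomicInterval, PeakSet
from .motifs import PWM, default_pwms, reverse_complement
from .tag_density import TagLibrary

FACTORS = ("AML1-ETO", "CBFB-MYH11", "PML-RARA")
AML_SUBTYPES = ("t(8;21)", "inv(16)", "t(15;17)")
NORMAL_GROUPS = ("CD34+", "CMP", "GMP")
ALL_GROUPS = AML_SUBTYPES + NORMAL_GROUPS

_STAGES = {
    "genome": 0, "genes": 1, "peaks": 2, "tags": 3,
    "motifs": 4, "effects": 5, "cohort1": 6, "cohort2": 7,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: stage-level reproducibility from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],))
    )


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome/peak/tag/expression data.

    Defaults mirror the comparison the pipeline targets: three peak sets
    of 1000 sites with pairwise sharing 0.20 / 0.05 / 0.06, motifs planted
    in 60% of peaks, and expression cohorts with 20 samples per group and
    subtype-exclusive markers at >= 8-fold.  The 2 x 25 Mb genome keeps
    peaks sparse relative to the 25 kb target-assignment window (roughly
    one binding site per 18 kb), so the target-gene sets of the three
    factors overlap partially rather than trivially coinciding.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 25_000_000
    n_genes: int = 500
    n_peaks_per_factor: int = 1000
    # pairwise sharing structure: AML1-ETO(A)/CBFB-MYH11(B)/PML-RARA(C);
    # the A-C pair is the strongly overlapping one
    overlap_ab: float = 0.05
    overlap_ac: float = 0.20
    overlap_bc: float = 0.06
    overlap_abc: float = 0.02
    peak_width: int = 400
    tags_per_library: int = 200_000
    peak_enrichment: float = 40.0   # mean planted tags per peak
    motif_planted_fraction: float = 0.6
    n_samples_per_group: int = 20
    signature_fc: float = 8.0
    signature_fc_max: float | None = None  # default 4 x signature_fc
    common_target_shift: float = 2.0
    baseline_log_mean: float = np.log(100.0)
    baseline_sigma: float = 1.0      # log-scale sd of gene baselines
    noise_sigma: float = 0.3         # log-scale sd of per-sample noise
    n_signature_per_subtype: int = 10
    n_common_targets: int = 50

    def __post_init__(self) -> None:
        for name in ("overlap_ab", "overlap_ac", "overlap_bc", "overlap_abc",
                     "motif_planted_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        for pair in ("overlap_ab", "overlap_ac", "overlap_bc"):
            if self.overlap_abc > getattr(self, pair) + 1e-12:
                raise ConfigError(
                    f"triple overlap {self.overlap_abc} exceeds pairwise {pair}"
                )
        if self.chrom_length < 10 * self.peak_width:
            raise ConfigError("chrom_length must be >= 10 x peak_width")
        if self.tags_per_library <= 0:
            raise ConfigError("tags_per_library must be positive")
        if self.peak_enrichment < 0:
            raise ConfigError("peak_enrichment must be >= 0")
        if self.signature_fc <= 0 or self.common_target_shift <= 0:
            raise ConfigError("effect sizes must be positive")
        if self.n_samples_per_group < 2:
            raise ConfigError("need >= 2 samples per group")

    @property
    def fc_max(self) -> float:
        return self.signature_fc_max or 4.0 * self.signature_fc

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass
class GroundTruth:
    """Everything the generator planted, for use as a test oracle."""

    venn_labels: list[dict] = field(default_factory=list)      # chrom,start,end,label
    venn_counts: dict[str, int] = field(default_factory=dict)
    tss: dict[str, int] = field(default_factory=dict)          # gene_id -> TSS
    motif_planted: list[dict] = field(default_factory=list)    # per union peak
    planted_tag_counts: list[int] = field(default_factory=list)
    gene_signature: dict[str, str] = field(default_factory=dict)   # gene -> subtype
    gene_signature_fc: dict[str, float] = field(default_factory=dict)
    common_targets: list[str] = field(default_factory=list)
    true_group_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def read_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# genome + gene catalog

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

MIN_GENE_LEN = 2_000
MAX_GENE_LEN = 10_000


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, bytearray], GeneCatalog, GroundTruth]:
    """Random-base genome plus a non-overlapping gene catalog.

    Genes are placed one per slot on an even grid so spans can never
    overlap; each gene gets 1-4 exons and a random strand.  Fails
    explicitly when the requested genes cannot fit.
    """
    rng = _rng(config.seed, "genome")
    genome: dict[str, bytearray] = {}
    for chrom in config.chrom_names():
        codes = rng.integers(0, 4, size=config.chrom_length)
        genome[chrom] = bytearray(_BASE_BYTES[codes].tobytes())

    gt = GroundTruth()
    genes: list[GeneModel] = []
    if config.n_genes > 0:
        grng = _rng(config.seed, "genes")
        chroms = config.chrom_names()
        per_chrom = [config.n_genes // len(chroms)] * len(chroms)
        for i in range(config.n_genes % len(chroms)):
            per_chrom[i] += 1
        gi = 0
        for chrom, n_here in zip(chroms, per_chrom):
            if n_here == 0:
                continue
            slot_w = config.chrom_length // n_here
            if slot_w < MIN_GENE_LEN + 1_000:
                raise ConfigError(
                    f"cannot place {n_here} non-overlapping genes of >= "
                    f"{MIN_GENE_LEN} bp on a {config.chrom_length} bp "
                    f"chromosome (slot width {slot_w})"
                )
            max_len = min(MAX_GENE_LEN, slot_w - 1_000)
            for s in range(n_here):
                length = int(grng.integers(MIN_GENE_LEN, max_len + 1))
                start = s * slot_w + int(grng.integers(0, slot_w - length))
                strand = "+" if grng.random() < 0.5 else "-"
                n_ex = int(grng.integers(1, 5))
                block = length // n_ex
                exons = []
                for b in range(n_ex):
                    bs = start + b * block
                    ex_len = int(grng.integers(max(1, block // 4), max(2, block // 2)))
                    exons.append((bs, min(bs + ex_len, start + length)))
                gene = GeneModel(
                    gene_id=f"G{gi:05d}", chrom=chrom, strand=strand,
                    tx_start=start, tx_end=start + length, exons=tuple(exons),
                )
                genes.append(gene)
                gt.tss[gene.gene_id] = gene.tss
                gi += 1
    return genome, GeneCatalog(genes), gt


def write_fasta(genome: Mapping[str, bytearray], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = bytes(genome[chrom]).decode("ascii")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# peak sets with planted Venn structure

def _venn_counts(config: SimulationConfig) -> dict[str, int]:
    n = config.n_peaks_per_factor
    abc = round(config.overlap_abc * n)
    ab = round(config.overlap_ab * n) - abc
    ac = round(config.overlap_ac * n) - abc
    bc = round(config.overlap_bc * n) - abc
    if min(ab, ac, bc) < 0:
        raise ConfigError("triple overlap fraction exceeds a pairwise fraction")
    counts = {
        "ABC": abc, "AB": ab, "AC": ac, "BC": bc,
        "A": n - ab - ac - abc,
        "B": n - ab - bc - abc,
        "C": n - ac - bc - abc,
    }
    if min(counts.values()) < 0:
        raise ConfigError("overlap fractions leave a factor with < 0 unique peaks")
    return counts


def simulate_peaksets(
    config: SimulationConfig,
) -> tuple[dict[str, PeakSet], GroundTruth]:
    """Three peak sets realizing the requested Venn structure exactly.

    Category counts are derived from the pairwise/triple fractions of
    n_peaks_per_factor; each planted region occupies its own slot of
    3 x peak_width, so distinct regions never overlap and shared regions
    are coordinate-identical across factors.
    """
    counts = _venn_counts(config)
    n_regions = sum(counts.values())
    rng = _rng(config.seed, "peaks")
    pw = config.peak_width
    slot_w = 3 * pw
    slots: list[tuple[str, int]] = []
    for chrom, length in config.chrom_lengths().items():
        for s in range(length // slot_w):
            slots.append((chrom, s * slot_w))
    if n_regions > len(slots):
        raise ConfigError(
            f"{n_regions} peak regions requested but only {len(slots)} "
            f"separated slots available; enlarge the genome"
        )
    chosen = rng.choice(len(slots), size=n_regions, replace=False)
    labels = [lab for lab, k in counts.items() for _ in range(k)]
    gt = GroundTruth(venn_counts=dict(counts))
    regions: list[tuple[GenomicInterval, str]] = []
    for idx, label in zip(chosen, labels):
        chrom, slot_start = slots[idx]
        start = slot_start + int(rng.integers(0, pw))
        iv = GenomicInterval(chrom, start, start + pw, name=label)
        regions.append((iv, label))
        gt.venn_labels.append(
            {"chrom": chrom, "start": start, "end": start + pw, "label": label}
        )
    peaksets: dict[str, PeakSet] = {}
    for letter, factor in zip("ABC", FACTORS):
        ivs = [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"{factor}_{i}")
            for i, (iv, label) in enumerate(regions)
            if letter in label
        ]
        peaksets[factor] = PeakSet(ivs, factor=factor)
    return peaksets, gt


def union_regions(gt: GroundTruth) -> PeakSet:
    """The planted union regions (one interval per Venn-labelled region)."""
    return PeakSet(
        [
            GenomicInterval(r["chrom"], r["start"], r["end"], name=r["label"])
            for r in gt.venn_labels
        ],
        factor="union",
    )


# ---------------------------------------------------------------------------
# tag libraries

def simulate_tags(
    config: SimulationConfig,
    peaks: PeakSet | Sequence[GenomicInterval],
    name: str = "H3ac",
    enrichment: float | None = None,
) -> tuple[TagLibrary, list[int]]:
    """Poisson background plus triangular per-peak enrichment.

    Per peak, Poisson(enrichment) tags are drawn from a triangular kernel
    centred on the midpoint with half-width peak_width / 2; the remaining
    tags are uniform background, so the emitted total is exactly
    tags_per_library.  Returns the library and the per-peak planted counts.
    """
    rng = _rng(config.seed, "tags")
    peak_list = list(peaks)
    lam = config.peak_enrichment if enrichment is None else enrichment
    planted = rng.poisson(lam, size=len(peak_list)).astype(int) if peak_list else np.array([], dtype=int)
    n_planted = int(planted.sum())
    n_background = config.tags_per_library - n_planted
    if n_background < 0:
        raise ConfigError(
            f"planted tags ({n_planted}) exceed tags_per_library "
            f"({config.tags_per_library}); lower peak_enrichment"
        )
    lengths = config.chrom_lengths()
    chroms = sorted(lengths)
    positions: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    # uniform background, chromosomes weighted by length
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    bg_per_chrom = rng.multinomial(n_background, weights)
    for chrom, k in zip(chroms, bg_per_chrom):
        if k:
            positions[chrom].append(rng.integers(0, lengths[chrom], size=k))
    half = config.peak_width / 2.0
    for iv, k in zip(peak_list, planted):
        if k == 0:
            continue
        mid = iv.midpoint
        draws = rng.triangular(mid - half, mid, mid + half, size=int(k))
        pos = np.clip(np.rint(draws).astype(np.int64), 0, lengths[iv.chrom] - 1)
        positions[iv.chrom].append(pos)
    tags = {}
    strands = {}
    for chrom in chroms:
        if positions[chrom]:
            pos = np.concatenate(positions[chrom])
            tags[chrom] = np.sort(pos)
            strands[chrom] = np.where(
                rng.random(len(pos)) < 0.5, "+", "-"
            )
    lib = TagLibrary(tags=tags, strands=strands, name=name)
    assert lib.total == config.tags_per_library
    return lib, [int(k) for k in planted]


# ---------------------------------------------------------------------------
# motif planting

def _scrub_consensus(genome: dict[str, bytearray], peaks: Sequence[GenomicInterval],
                     pwm: PWM, rng: np.random.Generator) -> int:
    """Mutate away chance consensus occurrences inside peak spans.

    Guarantees that at threshold_frac = 1.0 an unplanted peak can never
    score a hit (max-score windows of a consensus-style PWM are exactly
    the consensus string).  Returns the number of mutations applied.
    """
    targets = {pwm.consensus, reverse_complement(pwm.consensus)}
    L = len(pwm.consensus)
    n_mut = 0
    for iv in peaks:
        for _ in range(20):  # occurrences can re-form after a mutation
            seq = bytes(genome[iv.chrom][iv.start:iv.end]).decode("ascii")
            hit = -1
            for t in targets:
                j = seq.find(t)
                if j >= 0:
                    hit = j
                    break
            if hit < 0:
                break
            # flip the centre base of the occurrence to a different base
            pos = iv.start + hit + L // 2
            old = chr(genome[iv.chrom][pos])
            new = rng.permutation([b for b in "ACGT" if b != old])[0]
            genome[iv.chrom][pos] = ord(new)
            n_mut += 1
        else:
            raise RuntimeError("could not scrub consensus occurrences")
    return n_mut


def plant_motifs(
    config: SimulationConfig,
    genome: dict[str, bytearray],
    peaks: PeakSet | Sequence[GenomicInterval],
    pwm: PWM | None = None,
) -> tuple[list[bool], PWM]:
    """Write the PWM consensus into a controlled fraction of peaks.

    Exactly round(motif_planted_fraction x n_peaks) peaks receive the
    consensus at a random internal offset, half of them on the minus
    strand (rounding down).  Chance occurrences in the remaining peaks
    are scrubbed first so the planted flags are exact at a strict scan
    threshold.  With fraction 0 the genome is left untouched.  The genome
    is modified in place.
    """
    if pwm is None:
        pwm = default_pwms()[0]  # RUNX1
    peak_list = list(peaks)
    flags = [False] * len(peak_list)
    if config.motif_planted_fraction == 0.0 or not peak_list:
        return flags, pwm
    L = len(pwm)
    if L >= config.peak_width:
        raise ConfigError(
            f"motif length {L} must be < peak_width {config.peak_width}"
        )
    rng = _rng(config.seed, "motifs")
    _scrub_consensus(genome, peak_list, pwm, rng)
    n_planted = round(config.motif_planted_fraction * len(peak_list))
    chosen = rng.choice(len(peak_list), size=n_planted, replace=False)
    n_minus = n_planted // 2
    consensus = pwm.consensus
    rc = reverse_complement(consensus)
    for rank, idx in enumerate(chosen):
        iv = peak_list[int(idx)]
        motif = rc if rank < n_minus else consensus
        offset = int(rng.integers(0, iv.length - L + 1))
        genome[iv.chrom][iv.start + offset:iv.start + offset + L] = motif.encode()
        flags[int(idx)] = True
    return flags, pwm


# ---------------------------------------------------------------------------
# expression cohorts

@dataclass
class ExpressionSim:
    cohort1: ExpressionMatrix
    cohort2: ExpressionMatrix
    groups1: GroupMap
    groups2: GroupMap
    truth: GroundTruth


def simulate_expression(
    config: SimulationConfig, gene_ids: Sequence[str]
) -> ExpressionSim:
    """Two expression cohorts with shared planted effects.

    Signature genes carry a subtype-exclusive fold change (log-uniform in
    [signature_fc, fc_max], identical in both cohorts); common-target
    genes carry common_target_shift in the three AML subtypes only, so
    CMP/GMP stay at baseline like CD34+.  Noise is independent between
    samples and cohorts.
    """
    gene_ids = list(gene_ids)
    n_needed = 3 * config.n_signature_per_subtype + config.n_common_targets
    if len(gene_ids) < n_needed:
        raise ConfigError(
            f"{len(gene_ids)} genes cannot host {n_needed} planted effects"
        )
    erng = _rng(config.seed, "effects")
    order = erng.permutation(len(gene_ids))
    truth = GroundTruth()
    cursor = 0
    for subtype in AML_SUBTYPES:
        for _ in range(config.n_signature_per_subtype):
            g = gene_ids[order[cursor]]
            truth.gene_signature[g] = subtype
            lo, hi = np.log(config.signature_fc), np.log(config.fc_max)
            truth.gene_signature_fc[g] = float(np.exp(erng.uniform(lo, hi)))
            cursor += 1
    for _ in range(config.n_common_targets):
        truth.common_targets.append(gene_ids[order[cursor]])
        cursor += 1
    baseline = np.exp(
        erng.normal(config.baseline_log_mean, config.baseline_sigma,
                    size=len(gene_ids))
    )
    common = set(truth.common_targets)
    # noiseless expectation per gene and group (lognormal mean factor folded in)
    noise_mean = float(np.exp(config.noise_sigma ** 2 / 2.0))
    effects = np.ones((len(gene_ids), len(ALL_GROUPS)))
    for i, g in enumerate(gene_ids):
        for j, group in enumerate(ALL_GROUPS):
            e = 1.0
            if truth.gene_signature.get(g) == group:
                e = truth.gene_signature_fc[g]
            elif g in common and group in AML_SUBTYPES:
                e = config.common_target_shift
            effects[i, j] = e
        truth.true_group_means[g] = {
            group: float(baseline[i] * effects[i, j] * noise_mean)
            for j, group in enumerate(ALL_GROUPS)
        }

    def one_cohort(stage: str, tag: str) -> tuple[ExpressionMatrix, GroupMap]:
        rng = _rng(config.seed, stage)
        cols = {}
        mapping = {}
        for j, group in enumerate(ALL_GROUPS):
            for s in range(config.n_samples_per_group):
                sample = f"{tag}_{group}_{s}"
                noise = np.exp(rng.normal(0.0, config.noise_sigma,
                                          size=len(gene_ids)))
                cols[sample] = baseline * effects[:, j] * noise
                mapping[sample] = group
        values = pd.DataFrame(cols, index=gene_ids)
        return ExpressionMatrix(values), GroupMap(mapping)

    m1, g1 = one_cohort("cohort1", "c1")
    m2, g2 = one_cohort("cohort2", "c2")
    return ExpressionSim(m1, m2, g1, g2, truth)


# ---------------------------------------------------------------------------
# one-call generation of every input file

def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input plus the ground-truth sidecar.

    Returns a name -> path map of the written files.  Fixed seed implies
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, catalog, gt_genome = simulate_genome(config)
    peaksets, gt_peaks = simulate_peaksets(config)
    union = union_regions(gt_peaks)
    lib, planted_counts = simulate_tags(config, union)
    flags, pwm = plant_motifs(config, genome, union)

    gt = GroundTruth(
        venn_labels=gt_peaks.venn_labels,
        venn_counts=gt_peaks.venn_counts,
        tss=gt_genome.tss,
        motif_planted=[
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "planted": bool(f)}
            for iv, f in zip(union, flags)
        ],
        planted_tag_counts=planted_counts,
    )

    expr = simulate_expression(config, [g.gene_id for g in catalog])
    gt.gene_signature = expr.truth.gene_signature
    gt.gene_signature_fc = expr.truth.gene_signature_fc
    gt.common_targets = expr.truth.common_targets
    gt.true_group_means = expr.truth.true_group_means

    paths: dict[str, Path] = {}

    def _p(name: str, fname: str) -> Path:
        paths[name] = outdir / fname
        return paths[name]

    write_fasta(genome, _p("genome", "genome.fa"))
    catalog.write_tsv(_p("gene_catalog", "genes.tsv"))
    from .intervals import write_bed
    for factor, ps in peaksets.items():
        safe = factor.replace("/", "_")
        write_bed(ps, _p(f"peaks_{factor}", f"peaks_{safe}.bed"))
    write_bed(union, _p("peaks_union", "peaks_union.bed"))
    lib.write_bed(_p("tags", "tags_H3ac.bed"))
    expr.cohort1.write_tsv(_p("expr_cohort1", "expr_cohort1.tsv"))
    expr.cohort2.write_tsv(_p("expr_cohort2", "expr_cohort2.tsv"))
    expr.groups1.write_tsv(_p("groups_cohort1", "groups_cohort1.tsv"))
    expr.groups2.write_tsv(_p("groups_cohort2", "groups_cohort2.tsv"))
    gt.write_json(_p("ground_truth", "ground_truth.json"))
    from .motifs import write_jaspar
    write_jaspar(pwm, _p("pwm", f"pwm_{pwm.name}.jaspar"))
    return paths
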