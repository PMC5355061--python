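"""Group-wise expression summaries, decile sets and fold-change DE calls.

Expression matrices are genes x samples on the linear scale; the scale is
declared in a ``#scale=`` header line of the TSV and log2 input is
exponentiated on load so fold changes are always ratios of linear means.
Group comparisons pair each gene's group mean with its reference-group
mean (two-sided Wilcoxon signed-rank by default; unpaired Mann-Whitney
available), matching the convention of flagging a gene *set* as
differentially expressed between populations at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DE_PSEUDOCOUNT = 1.0
DEFAULT_ALPHA = 0.05


@dataclass
class ExpressionMatrix:
    """Genes x samples linear-scale expression values."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("linear-scale expression values must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV with a ``#scale=linear|log2`` header line.

        A missing scale declaration is treated as linear with a warning;
        log2 matrices are converted to linear on load.
        """
        path = Path(path)
        scale = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#scale="):
            scale = first.strip().split("=", 1)[1]
        if scale is None:
            log.warning("%s: no #scale= header; assuming linear", path)
            scale = "linear"
        if scale not in ("linear", "log2"):
            raise ValueError(f"{path}: unknown scale {scale!r}")
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        if scale == "log2":
            df = np.exp2(df)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#scale=linear\n")
            self.values.to_csv(fh, sep="\t", index_label="gene_id")


class GroupMap:
    """Sample -> group labels; every referenced group needs >= 2 samples."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = dict(mapping)
        counts = pd.Series(list(self.mapping.values())).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                "groups with < 2 samples (comparison needs replicates): "
                + ", ".join(small.index)
            )

    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def samples_of(self, group: str) -> list[str]:
        out = [s for s, g in self.mapping.items() if g == group]
        if not out:
            raise KeyError(f"group {group!r} absent from group map")
        return out

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GroupMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if list(df.columns[:2]) != ["sample_id", "group"]:
            raise ValueError(f"{path}: expected columns sample_id, group")
        return cls(dict(zip(df.sample_id, df.group)))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.mapping), "group": list(self.mapping.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GroupComparison:
    gene_set_label: str
    group: str
    reference: str
    n_genes: int
    mean_of_gene_means: float
    reference_mean: float
    p_value: float
    significant: bool


def _gene_means(matrix: ExpressionMatrix, groups: GroupMap, group: str,
                genes: pd.Index) -> pd.Series:
    cols = groups.samples_of(group)
    return matrix.values.loc[genes, cols].mean(axis=1)


def geneset_group_summary(
    matrix: ExpressionMatrix,
    groups: GroupMap,
    gene_set: Iterable[str],
    reference: str = "CD34+",
    alpha: float = DEFAULT_ALPHA,
    test: Literal["wilcoxon", "mannwhitney"] = "wilcoxon",
) -> list[GroupComparison]:
    """Gene-set expression per group versus a reference population.

    For each group, every gene of the set is summarized by its mean over
    the group's samples; the vector of per-gene means is tested against
    the reference-group vector (paired Wilcoxon signed-rank by default).
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = matrix.genes.intersection(gene_set)
    missing = set(gene_set) - set(present)
    if missing:
        log.warning("gene set: %d gene(s) absent from matrix", len(missing))
    if len(present) == 0:
        raise ValueError("no genes of the set are present in the matrix")
    ref_means = _gene_means(matrix, groups, reference, present)
    out = []
    for group in groups.groups():
        if group == reference:
            continue
        grp_means = _gene_means(matrix, groups, group, present)
        diffs = grp_means.to_numpy() - ref_means.to_numpy()
        if np.allclose(diffs, 0.0):
            p = 1.0
        elif test == "wilcoxon":
            p = float(stats.wilcoxon(
                grp_means, ref_means, zero_method="wilcox",
                alternative="two-sided",
            ).pvalue)
        elif test == "mannwhitney":
            p = float(stats.mannwhitneyu(
                grp_means, ref_means, alternative="two-sided"
            ).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        out.append(GroupComparison(
            gene_set_label="", group=group, reference=reference,
            n_genes=len(present),
            mean_of_gene_means=float(grp_means.mean()),
            reference_mean=float(ref_means.mean()),
            p_value=p, significant=bool(p < alpha),
        ))
    return out


def decile_sets(
    matrix: ExpressionMatrix, groups: GroupMap, group: str
) -> tuple[list[str], list[str]]:
    """Top-10% and bottom-10% expressed genes within a group.

    Genes are ranked by their mean over the group's samples; each set has
    floor(n/10) genes; ties are broken by gene id (ascending) so the sets
    are deterministic.
    """
    if len(matrix.genes) < 10:
        raise ValueError("decile sets need >= 10 genes")
    means = _gene_means(matrix, groups, group, matrix.genes)
    k = len(matrix.genes) // 10
    ranked = means.reset_index()
    ranked.columns = ["gene_id", "mean"]
    top = ranked.sort_values(["mean", "gene_id"], ascending=[False, True])
    bottom = ranked.sort_values(["mean", "gene_id"], ascending=[True, True])
    return list(top.gene_id.head(k)), list(bottom.gene_id.head(k))


def de_call(
    matrix_case: ExpressionMatrix,
    matrix_control: ExpressionMatrix,
    fc_threshold: float = 1.5,
    pseudocount: float = DE_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Fold-change DE call between two conditions on a matched gene universe.

    A gene is DE iff (mean_case + eps) / (mean_control + eps) >= fc or
    <= 1/fc.  Returns a table (gene_id, fc, direction) for DE genes only.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must be > 1")
    if not matrix_case.genes.equals(matrix_control.genes):
        common = matrix_case.genes.intersection(matrix_control.genes)
        if len(common) == 0:
            raise ValueError("case and control share no genes")
        log.warning("de_call: restricting to %d shared genes", len(common))
    else:
        common = matrix_case.genes
    mc = matrix_case.values.loc[common].mean(axis=1) + pseudocount
    mk = matrix_control.values.loc[common].mean(axis=1) + pseudocount
    fc = mc / mk
    up = fc >= fc_threshold
    down = fc <= 1.0 / fc_threshold
    table = pd.DataFrame({
        "gene_id": common, "fc": fc.to_numpy(),
        "direction": np.where(up, "up", np.where(down, "down", "")),
    })
    return table[up.to_numpy() | down.to_numpy()].reset_index(drop=True)


def de_overlap_fraction(
    de_a: pd.DataFrame, de_b: pd.DataFrame, match_direction: bool = False
) -> float:
    """Fraction of DE set A that is also DE in set B.

    Direction-agnostic by default; with ``match_direction`` a gene only
    counts when its up/down label agrees in both sets.
    """
    if len(de_a) == 0:
        raise ValueError("de_overlap_fraction: empty reference DE set")
    if match_direction:
        keys_a = set(zip(de_a.gene_id, de_a.direction))
        keys_b = set(zip(de_b.gene_id, de_b.direction))
    else:
        keys_a = set(de_a.gene_id)
        keys_b = set(de_b.gene_id)
    return len(keys_a & keys_b) / len(keys_a)
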