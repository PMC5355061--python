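"""Two-cohort AML-subtype signature-gene identification.

Discovery: in cohort 1, a gene is a candidate for subtype s when its fold
change — (mean over s samples + 1) / (mean over all other subtype samples
+ 1), linear scale — is >= 8 in *exactly one* subtype.  Validation: the
candidate is screened against an independent cohort; it passes when its
maximal-FC subtype there matches the discovery subtype and the fold
change is at least 2.  Genes passing both filters are the subtype
signature; the FC reference is the other AML subtypes (configurable),
because the aim is subtype-discriminating markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GroupMap

log = logging.getLogger(__name__)

DISCOVERY_FC = 8.0
VALIDATION_FC = 2.0
FC_PSEUDOCOUNT = 1.0


@dataclass
class SignatureCandidate:
    gene_id: str
    subtype: str
    discovery_fc: dict[str, float]   # per-subtype FC in cohort 1
    validated: bool = False
    validation_fc: float | None = None
    reason: str = ""


def _subtype_fc(
    matrix: ExpressionMatrix,
    groups: GroupMap,
    subtypes: Sequence[str],
    pseudocount: float = FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genes x subtypes fold-change table vs the other subtypes' samples."""
    for s in subtypes:
        groups.samples_of(s)  # raises if absent
    cols = {s: groups.samples_of(s) for s in subtypes}
    means = {s: matrix.values[c].mean(axis=1) for s, c in cols.items()}
    fcs = {}
    for s in subtypes:
        other_cols = [c for t in subtypes if t != s for c in cols[t]]
        other_mean = matrix.values[other_cols].mean(axis=1)
        fcs[s] = (means[s] + pseudocount) / (other_mean + pseudocount)
    return pd.DataFrame(fcs)


def discovery_filter(
    matrix: ExpressionMatrix,
    groups: GroupMap,
    subtypes: Sequence[str],
    fc_threshold: float = DISCOVERY_FC,
) -> list[SignatureCandidate]:
    """Genes upregulated at FC >= threshold in exactly one subtype."""
    if len(subtypes) < 2:
        raise ValueError("discovery needs >= 2 subtypes")
    fc = _subtype_fc(matrix, groups, subtypes)
    passing = fc >= fc_threshold
    exactly_one = passing.sum(axis=1) == 1
    candidates = []
    for gene in fc.index[exactly_one]:
        row = fc.loc[gene]
        subtype = row.index[passing.loc[gene]][0]
        candidates.append(SignatureCandidate(
            gene_id=str(gene), subtype=str(subtype),
            discovery_fc={s: float(row[s]) for s in subtypes},
        ))
    return candidates


def validation_screen(
    candidates: Sequence[SignatureCandidate],
    matrix_cohort2: ExpressionMatrix,
    groups2: GroupMap,
    fc_threshold2: float = VALIDATION_FC,
) -> list[SignatureCandidate]:
    """Screen discovery candidates against a second cohort.

    Validated iff the candidate's maximal-FC subtype in cohort 2 equals
    its discovery subtype and that FC is >= the validation threshold.
    Candidates absent from cohort 2 fail with reason "absent".
    """
    if not candidates:
        return []
    subtypes = sorted({c.subtype for c in candidates} |
                      {s for c in candidates for s in c.discovery_fc})
    fc2 = _subtype_fc(matrix_cohort2, groups2, subtypes)
    out = []
    for c in candidates:
        cand = SignatureCandidate(
            gene_id=c.gene_id, subtype=c.subtype,
            discovery_fc=dict(c.discovery_fc),
        )
        if c.gene_id not in fc2.index:
            cand.validated, cand.reason = False, "absent"
        else:
            row = fc2.loc[c.gene_id]
            best = str(row.idxmax())
            best_fc = float(row.max())
            cand.validation_fc = float(row[c.subtype])
            if best != c.subtype:
                cand.validated = False
                cand.reason = f"max FC in {best}, not {c.subtype}"
            elif best_fc < fc_threshold2:
                cand.validated = False
                cand.reason = f"FC {best_fc:.2f} < {fc_threshold2:g}"
            else:
                cand.validated, cand.reason = True, "ok"
        out.append(cand)
    return out


def candidates_table(candidates: Sequence[SignatureCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "gene_id": c.gene_id, "subtype": c.subtype,
            "validated": c.validated, "reason": c.reason,
            "validation_fc": c.validation_fc,
        }
        row.update({f"fc_{s}": v for s, v in c.discovery_fc.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def signature_heatmap_table(
    validated: Sequence[SignatureCandidate],
    matrix: ExpressionMatrix,
    groups: GroupMap,
    subtypes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genes x groups mean-expression matrix, z-scored per gene.

    Constant genes (sigma = 0) map to all-zero rows.  Rows are ordered by
    subtype then gene id so each subtype's block is contiguous.
    """
    genes = [c for c in validated if c.validated]
    if not genes:
        raise ValueError("no validated signature genes")
    groups_list = list(subtypes) if subtypes is not None else groups.groups()
    genes.sort(key=lambda c: (c.subtype, c.gene_id))
    data = {}
    for g in groups_list:
        cols = groups.samples_of(g)
        data[g] = matrix.values.loc[[c.gene_id for c in genes], cols].mean(axis=1)
    table = pd.DataFrame(data)
    mean = table.mean(axis=1)
    std = table.std(axis=1, ddof=0)
    z = table.sub(mean, axis=0).div(std.replace(0.0, np.nan), axis=0).fillna(0.0)
    z.index.name = "gene_id"
    return z
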