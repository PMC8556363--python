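"""Per-class and per-gene driver mutation prevalence.

Prevalence of a driver mutation type is the proportion of assayed
samples carrying it, with a normal-approximation (Wald) 95% confidence
interval clipped to [0, 1].  Per-gene prevalence combines a gene's
mutation classes either by exact union counting (default) or by a
literal inclusion-exclusion style formula over class and joint-class
proportions, with an error-propagation term combining the class CI
bounds.  The literal formula subtracts the triple-joint term together
with the pairwise joints (rather than adding it back as standard
inclusion-exclusion would); both readings are retained because the exact
union is computable directly from the matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from driverdelta.catalog import MutationMatrix, SampleRecord

logger = logging.getLogger(__name__)

Z95 = 1.96

#: Gene-level class groups used when combining a gene's mutation types.
_CLASS_GROUPS = {
    "CNA": ("CNA_gain", "CNA_loss"),
    "SNV": ("SNV", "ncSNV"),
    "SV": ("SV",),
}


@dataclass
class PrevalenceEstimate:
    numerator: int
    denominator: int
    p_hat: float
    ci_low: float
    ci_high: float


@dataclass
class CombinedGenePrevalence:
    gene_id: str
    p_gene: float
    ci_low: float
    ci_high: float
    n: int
    method: str
    pe_by_class: dict = field(default_factory=dict)
    variance_pe: float = float("nan")


def wald_ci(p_hat: float, n: int) -> tuple:
    """95% Wald interval p +/- 1.96 sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n < 1:
        raise ValueError("wald_ci requires n >= 1")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat {p_hat} outside [0, 1]")
    half = Z95 * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


def _restrict(matrix: MutationMatrix, samples, state):
    data = matrix.data
    if state is not None:
        if samples is None:
            raise ValueError("state restriction requires sample records")
        keep = [s.sample_id for s in samples if s.state == state]
        data = data.loc[data.index.intersection(keep)]
    return data


def class_prevalence(
    matrix: MutationMatrix,
    mutation_type: str,
    samples: Optional[Sequence[SampleRecord]] = None,
    state: Optional[str] = None,
) -> PrevalenceEstimate:
    """Prevalence of one mutation type over its assayed denominator."""
    if mutation_type not in matrix.data.columns:
        raise KeyError(f"unknown mutation type {mutation_type!r}")
    col = _restrict(matrix, samples, state)[mutation_type]
    denominator = int(col.notna().sum())
    if denominator == 0:
        raise ValueError(f"{mutation_type}: no assayed samples")
    numerator = int((col == 1.0).sum())
    p_hat = numerator / denominator
    low, high = wald_ci(p_hat, denominator)
    return PrevalenceEstimate(numerator, denominator, p_hat, low, high)


def _group_presence(data: pd.DataFrame, cols: Sequence[str]) -> pd.Series:
    """Per-sample group status: 1 any present, 0 all-assayed absent, NaN
    when no column of the group was assayed."""
    sub = data[list(cols)]
    present = (sub == 1.0).any(axis=1)
    assayed = sub.notna().any(axis=1)
    out = pd.Series(np.nan, index=data.index)
    out[assayed] = 0.0
    out[present] = 1.0
    return out


def error_propagation(ci_bounds: Mapping[str, tuple]) -> tuple:
    """Combine class/joint CI bounds into per-class PE and its variance.

    ``ci_bounds`` maps class names (singles, e.g. ``CNA``) and joint
    combinations (``CNA&SNV``) to (ci_low, ci_high).  Per class,
    PE = sqrt(upper^2 + lower^2).  The gene-level variance term is
    sqrt(sum of single PEs - sum of joint PEs), evaluated literally; a
    negative radicand yields NaN with a logged flag.
    """
    pe = {
        key: float(np.sqrt(high ** 2 + low ** 2))
        for key, (low, high) in ci_bounds.items()
    }
    singles = sum(v for k, v in pe.items() if "&" not in k)
    joints = sum(v for k, v in pe.items() if "&" in k)
    radicand = singles - joints
    if radicand < 0:
        logger.warning(
            "error propagation radicand negative (%.4g); variance set to NaN",
            radicand,
        )
        return pe, float("nan")
    return pe, float(np.sqrt(radicand))


def combined_gene_prevalence(
    matrix: MutationMatrix,
    gene_id: str,
    method: str = "empirical_union",
    samples: Optional[Sequence[SampleRecord]] = None,
    state: Optional[str] = None,
) -> CombinedGenePrevalence:
    """Proportion of samples harboring a mutation of any class in a gene.

    ``empirical_union`` (default) counts samples with at least one
    present cell among the gene's columns over the union of assayed
    samples — the exact quantity.  ``additive_literal`` evaluates the additive
    formula: sum of single class proportions minus the sum of pairwise
    and triple joint proportions, each on its own assayed denominator
    (joints read as "at least both").
    """
    cols = matrix.gene_columns(gene_id)
    if not cols:
        raise KeyError(f"gene {gene_id!r} has no columns in matrix")
    data = _restrict(matrix, samples, state)

    groups = {
        name: [c for c in cols if matrix.column_class(c) in members]
        for name, members in _CLASS_GROUPS.items()
    }
    groups = {k: v for k, v in groups.items() if v}
    status = {k: _group_presence(data, v) for k, v in groups.items()}

    # warn when class assay sets do not intersect
    masks = [s.notna() for s in status.values()]
    if len(masks) > 1:
        joint_assayed = np.logical_and.reduce([m.values for m in masks])
        if not joint_assayed.any():
            logger.warning(
                "%s: class assay sets are disjoint; per-class denominators used",
                gene_id,
            )

    union_assayed = np.logical_or.reduce([m.values for m in masks])
    n_union = int(union_assayed.sum())
    if n_union == 0:
        raise ValueError(f"{gene_id}: no assayed samples")

    ci_bounds = {}
    for name, s in status.items():
        n = int(s.notna().sum())
        if n:
            ci_bounds[name] = wald_ci(float((s == 1.0).sum()) / n, n)
    for r in (2, 3):
        for combo in itertools.combinations(sorted(status), r):
            sub = pd.concat([status[c] for c in combo], axis=1)
            assayed = sub.notna().all(axis=1)
            n = int(assayed.sum())
            if n == 0:
                continue
            joint = float((sub[assayed] == 1.0).all(axis=1).sum()) / n
            ci_bounds["&".join(combo)] = wald_ci(joint, n)

    pe_by_class, variance_pe = error_propagation(ci_bounds)

    if method == "empirical_union":
        any_present = np.logical_or.reduce(
            [(s == 1.0).values for s in status.values()]
        )
        p_gene = float(any_present.sum()) / n_union
    elif method == "additive_literal":
        p_gene = 0.0
        for name, s in status.items():
            n = int(s.notna().sum())
            p_gene += float((s == 1.0).sum()) / n
        for r in (2, 3):
            for combo in itertools.combinations(sorted(status), r):
                sub = pd.concat([status[c] for c in combo], axis=1)
                assayed = sub.notna().all(axis=1)
                n = int(assayed.sum())
                if n == 0:
                    continue
                p_gene -= float((sub[assayed] == 1.0).all(axis=1).sum()) / n
    else:
        raise ValueError(f"unknown method {method!r}")

    low, high = wald_ci(min(max(p_gene, 0.0), 1.0), n_union)
    return CombinedGenePrevalence(
        gene_id=gene_id,
        p_gene=p_gene,
        ci_low=low,
        ci_high=high,
        n=n_union,
        method=method,
        pe_by_class=pe_by_class,
        variance_pe=variance_pe,
    )


def prevalence_table(
    matrix: MutationMatrix,
    samples: Sequence[SampleRecord],
    states: Iterable[str] = ("localized", "mCRPC"),
) -> pd.DataFrame:
    """Per mutation type and disease state prevalence TSV content."""
    rows = []
    for col in matrix.columns:
        gene, mclass = matrix.split_column(col)
        for state in states:
            try:
                est = class_prevalence(matrix, col, samples=samples, state=state)
            except ValueError:
                continue
            rows.append(
                {
                    "mutation_type": col,
                    "gene": gene,
                    "class": mclass,
                    "state": state,
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "p_hat": est.p_hat,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    return pd.DataFrame(rows)
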