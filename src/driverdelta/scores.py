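"""Per-sample burden and prognostic scores.

Covers percent genome altered (PGA) and its chromosome-excluded
adjusted form, a six-feature clinico-genomic relapse signature, the
cell-cycle-progression (CCP) expression score, Youden-J dichotomization
of continuous markers, and median/quartile stratification of RNA
abundance.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

CutpointResult = namedtuple("CutpointResult", ["threshold", "j_statistic"])

#: The six signature features, in scoring order.
SIGNATURE_FEATURES = (
    "myc_gain",
    "atm_snv",
    "tcergl1_beta",
    "actl6b_beta",
    "chr7_translocation",
    "ct_category",
)


def _merge_intervals(intervals: Sequence[tuple]) -> list:
    """Union of half-open intervals; returns merged sorted list."""
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def pga(
    segments: Sequence[tuple],
    genome_size_bp: int,
    exclude_chromosome: Optional[str] = None,
    chromosome_sizes: Optional[Mapping[str, int]] = None,
) -> float:
    """Fraction of the genome altered by copy-number segments.

    ``segments`` are (chrom, start, end) half-open intervals of altered
    bases; overlapping segments are merged so each base counts once.
    With ``exclude_chromosome``, both the altered bases on that
    chromosome and its length (from ``chromosome_sizes``) are dropped,
    keeping the adjusted value a true proportion.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome_size_bp must be positive")
    per_chrom: dict = {}
    for chrom, start, end in segments:
        if end < start:
            raise ValueError(f"negative-length segment {chrom}:{start}-{end}")
        if end == start:
            continue
        per_chrom.setdefault(str(chrom), []).append((int(start), int(end)))

    denominator = genome_size_bp
    if exclude_chromosome is not None:
        per_chrom.pop(str(exclude_chromosome), None)
        if chromosome_sizes is None or exclude_chromosome not in chromosome_sizes:
            raise ValueError(
                f"size of excluded chromosome {exclude_chromosome!r} unknown"
            )
        denominator -= chromosome_sizes[exclude_chromosome]
        if denominator <= 0:
            raise ValueError("excluded chromosome covers the whole genome")

    altered = sum(
        end - start
        for intervals in per_chrom.values()
        for start, end in _merge_intervals(intervals)
    )
    return altered / denominator


@dataclass
class SignatureScore:
    sample_id: str
    feature_flags: dict
    score: Optional[int]
    informative: bool
    bin: Optional[str] = None


def six_feature_signature(features: pd.DataFrame) -> list:
    """Six-feature clinico-genomic signature scores for a cohort.

    ``features`` is indexed by sample with columns ``myc_gain``,
    ``atm_snv``, ``chr7_translocation`` (0/1/NaN), ``tcergl1_beta``,
    ``actl6b_beta`` (methylation beta values), and ``ct_category``.
    Mutation features score 1 when present; TCERGL1 scores 1 when below
    the cohort median (hypomethylation is adverse) and ACTL6B when above
    it (hypermethylation is adverse); clinical T category scores 1 for
    cT2c and 0 for cT1 or cT2a/b.  Samples missing any feature are
    flagged non-informative and excluded from scoring; informative
    samples are median-dichotomized into high/low bins for display.
    """
    missing_cols = set(SIGNATURE_FEATURES) - set(features.columns)
    if missing_cols:
        raise ValueError(f"missing signature features: {sorted(missing_cols)}")

    tcergl1_median = features["tcergl1_beta"].median()
    actl6b_median = features["actl6b_beta"].median()

    out = []
    for sample_id, row in features.iterrows():
        if row[list(SIGNATURE_FEATURES)].isna().any():
            out.append(SignatureScore(str(sample_id), {}, None, False))
            continue
        ct = str(row["ct_category"])
        if ct not in {"cT1", "cT2a/b", "cT2c"}:
            out.append(SignatureScore(str(sample_id), {}, None, False))
            continue
        flags = {
            "myc_gain": bool(row["myc_gain"]),
            "atm_snv": bool(row["atm_snv"]),
            "tcergl1_hypomethylation": bool(row["tcergl1_beta"] < tcergl1_median),
            "actl6b_hypermethylation": bool(row["actl6b_beta"] > actl6b_median),
            "chr7_translocation": bool(row["chr7_translocation"]),
            "ct2c": ct == "cT2c",
        }
        out.append(
            SignatureScore(str(sample_id), flags, int(sum(flags.values())), True)
        )

    scores = [s.score for s in out if s.informative]
    if scores:
        median = float(np.median(scores))
        for s in out:
            if s.informative:
                s.bin = "high" if s.score > median else "low"
    return out


def ccp_score(
    log2_abundance: Mapping[str, float],
    ccp_genes: Sequence[str],
    housekeeping_genes: Sequence[str],
) -> float:
    """Cell-cycle-progression score for one sample.

    Mean log2 abundance over the CCP gene panel minus the mean over the
    housekeeping panel; invariant under a constant shift of all genes.
    """
    missing = [g for g in [*ccp_genes, *housekeeping_genes] if g not in log2_abundance]
    if missing:
        raise KeyError(f"missing genes for CCP score: {missing}")
    ccp_mean = float(np.mean([log2_abundance[g] for g in ccp_genes]))
    hk_mean = float(np.mean([log2_abundance[g] for g in housekeeping_genes]))
    return ccp_mean - hk_mean


def youden_cutpoint(
    values: Sequence[float],
    outcome: Sequence[int],
    direction: str = ">=",
) -> CutpointResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidates are the observed values; with direction ``>=`` a sample
    is called positive when its value >= threshold (``<=`` flips the
    call).  Ties in J break toward the lower threshold.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if values.shape != outcome.shape:
        raise ValueError("values and outcome must align")
    if len(np.unique(outcome)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.ptp(values) == 0:
        raise ValueError("values are constant; no cutpoint exists")
    if direction not in (">=", "<="):
        raise ValueError("direction must be '>=' or '<='")

    pos = outcome == 1
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    best = None
    for threshold in np.unique(values):
        called = values >= threshold if direction == ">=" else values <= threshold
        sens = (called & pos).sum() / n_pos
        spec = (~called & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if best is None or j > best.j_statistic + 1e-12:
            best = CutpointResult(float(threshold), float(j))
    return best


def stratify_abundance(values: Sequence[float], scheme: str = "median") -> pd.Series:
    """Bin samples by abundance: median halves or quartiles.

    Median scheme labels values <= median as ``low``, else ``high``.
    Quartile scheme labels Q1..Q4 with boundary values assigned to the
    lower bin.  All-tied input collapses to a single bin with a warning.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if scheme == "median":
        if s.nunique() == 1:
            warnings.warn("all values tied; single bin returned")
            return pd.Series(["low"] * len(s), index=s.index)
        return pd.Series(np.where(s <= s.median(), "low", "high"), index=s.index)
    if scheme == "quartile":
        if len(s) < 4:
            raise ValueError("quartile scheme requires n >= 4")
        if s.nunique() == 1:
            warnings.warn("all values tied; single bin returned")
            return pd.Series(["Q1"] * len(s), index=s.index)
        q1, q2, q3 = np.quantile(s, [0.25, 0.5, 0.75])
        labels = np.select(
            [s <= q1, s <= q2, s <= q3], ["Q1", "Q2", "Q3"], default="Q4"
        )
        return pd.Series(labels, index=s.index)
    raise ValueError(f"unknown scheme {scheme!r}")
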