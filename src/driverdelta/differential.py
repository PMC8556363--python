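"""Burden-adjusted differential prevalence via a Monte-Carlo binomial null.

Metastatic castration-resistant tumors carry far more mutations overall
than localized tumors, so a raw prevalence difference for any single
driver conflates selection for the driver with the global burden
difference.  The null model here asks: if mutations landed at random,
proportional to each sample's own burden and the gene's genomic
footprint, how big a prevalence difference would we see between the two
disease states?

Per sample and mutation type, the probability of at least one hit is

* SNV / ncSNV: with per-sample burden b (SNVs/Mbp), reference size G
  (Mbp) and coding footprint g (Mbp), the expected mutation count is
  N = round(b * G) and P(hit) = 1 - (1 - g/G)^N.
* CNA / SV: per-sample copy-number burden is expressed as M segments of
  mean length lambda (Mbp) covering PGA * G of the genome, so
  M = max(1, round(PGA * G / lambda)); a segment hits a gene of span s
  (bp) with probability (s/1e6 + lambda)/G, and
  P(hit) = 1 - (1 - p_seg)^M.  A per-base model would saturate at 1 for
  realistic PGA values; the segment process keeps burden weighting
  informative.

Each Monte-Carlo iteration draws one Bernoulli(P(hit)) per sample and
records the simulated prevalence difference between states.  The
empirical p-value is the two-sided exceedance about the null mean;
copy-number classes apply a halving (a CNA can be either a gain or a
loss, each tested as its own mutation type); p-values are floored at
1/n_iter and corrected across mutation types with Benjamini-Hochberg.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from driverdelta.catalog import (
    ASSAY_OF_CLASS,
    DriverCatalogEntry,
    MutationMatrix,
    SampleRecord,
)
from driverdelta.prevalence import Z95

_SIM_CHUNK = 4096


@dataclass
class NullModelConfig:
    """Parameters of the burden-weighted binomial null.

    ``genome_mbp`` is the reference genome size used for whole-genome
    burdens and for the copy-number segment process; ``exome_mbp`` is
    used for exome-derived SNV burdens.  ``cna_segment_mbp`` is the mean
    segment length lambda of the copy-number segment process.
    """

    n_iter: int = 100_000
    seed: int = 0
    genome_mbp: float = 3000.0
    exome_mbp: float = 38.0
    cna_segment_mbp: float = 10.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_iter < 100:
            raise ValueError("n_iter must be >= 100")
        if self.cna_segment_mbp <= 0:
            raise ValueError("cna_segment_mbp must be > 0")
        if self.genome_mbp <= 0 or self.exome_mbp <= 0:
            raise ValueError("reference sizes must be > 0")

    @property
    def p_floor(self) -> float:
        return 1.0 / self.n_iter


@dataclass
class DifferentialResult:
    mutation_type: str
    gene_id: str
    mclass: str
    n_mcrpc: int
    n_localized: int
    p_mcrpc: float
    p_localized: float
    observed_delta: float
    expected_delta: float
    adjusted_delta: float
    delta_ci_low: float
    delta_ci_high: float
    p_value: float
    q_value: float = float("nan")
    direction: str = "null"
    flag: Optional[str] = None


def per_sample_hit_probability(
    sample: SampleRecord,
    entry: DriverCatalogEntry,
    mclass: str,
    config: NullModelConfig,
) -> float:
    """Probability of >= 1 burden-driven hit of ``entry`` in ``sample``."""
    if mclass not in ASSAY_OF_CLASS:
        raise ValueError(f"unknown mutation class {mclass!r}")
    if mclass in ("SNV", "ncSNV"):
        burden = sample.snv_burden_per_mbp
        if math.isnan(burden):
            raise ValueError(f"{sample.sample_id}: SNV burden missing")
        if burden == 0.0:
            return 0.0
        ref_mbp = (
            config.exome_mbp
            if sample.burden_reference == "exome"
            else config.genome_mbp
        )
        g = entry.snv_footprint_mbp
        if g is None or g > ref_mbp:
            raise ValueError(
                f"{entry.gene_id}: footprint {g} exceeds reference {ref_mbp} Mbp"
            )
        n_events = round(burden * ref_mbp)
        if n_events == 0:
            return 0.0
        return float(-np.expm1(n_events * np.log1p(-g / ref_mbp)))

    # CNA gain/loss and SV: segment process weighted by PGA
    pga = sample.pga
    if math.isnan(pga):
        raise ValueError(f"{sample.sample_id}: PGA missing")
    if pga == 0.0:
        return 0.0
    lam = config.cna_segment_mbp
    footprint_mbp = entry.cna_footprint_bp / 1e6
    if footprint_mbp > config.genome_mbp:
        raise ValueError(
            f"{entry.gene_id}: footprint {footprint_mbp} Mbp exceeds genome"
        )
    n_segments = max(1, round(pga * config.genome_mbp / lam))
    p_seg = (footprint_mbp + lam) / config.genome_mbp
    p_seg = min(p_seg, 1.0)
    if p_seg == 1.0:
        return 1.0
    return float(-np.expm1(n_segments * np.log1p(-p_seg)))


def simulate_null(
    p_mut: np.ndarray,
    states: Sequence[str],
    config: NullModelConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """Simulate null prevalence differences (mCRPC minus localized).

    Each iteration draws an independent Bernoulli(p_mut[i]) per sample
    and records the difference of simulated prevalences between the two
    state groups.  Returns (expected_delta, sim_deltas).
    """
    p_mut = np.asarray(p_mut, dtype=float)
    if np.any((p_mut < 0) | (p_mut > 1)) or np.any(np.isnan(p_mut)):
        raise ValueError("p_mut values must lie in [0, 1]")
    states = np.asarray(states)
    if p_mut.shape[0] != states.shape[0]:
        raise ValueError("p_mut and states must align")
    m_mask = states == "mCRPC"
    l_mask = states == "localized"
    if not m_mask.any() or not l_mask.any():
        raise ValueError("both disease states must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = p_mut.shape[0]
    sims = np.empty(config.n_iter, dtype=float)
    done = 0
    while done < config.n_iter:
        chunk = min(_SIM_CHUNK, config.n_iter - done)
        draws = rng.random((chunk, n)) < p_mut
        sims[done : done + chunk] = (
            draws[:, m_mask].mean(axis=1) - draws[:, l_mask].mean(axis=1)
        )
        done += chunk
    return float(sims.mean()), sims


def empirical_pvalue(
    observed_delta: float,
    sim_deltas: np.ndarray,
    mclass: str,
    p_floor: Optional[float] = None,
) -> float:
    """Two-sided exceedance p-value about the null mean.

    Extremeness is |sim - mean| >= |observed - mean|.  Copy-number
    classes halve the exceedance (each CNA direction is its own test);
    the floor (default 1/n_sim) is applied after halving, and the result
    is capped at 1.
    """
    sims = np.asarray(sim_deltas, dtype=float)
    if sims.size == 0:
        raise ValueError("sim_deltas must be non-empty")
    center = sims.mean()
    exceed = float(np.mean(np.abs(sims - center) >= abs(observed_delta - center)))
    if mclass in ("CNA_gain", "CNA_loss"):
        exceed /= 2.0
    if p_floor is None:
        p_floor = 1.0 / sims.size
    return float(min(1.0, max(exceed, p_floor)))


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def delta_ci_yates(p1: float, m: int, p2: float, n: int) -> tuple:
    """95% CI for a difference of proportions with continuity correction.

    (p1 - p2) +/- [1.96 sqrt(p1(1-p1)/m + p2(1-p2)/n) + (1/m + 1/n)/2],
    clipped to [-1, 1].
    """
    if m < 1 or n < 1:
        raise ValueError("group sizes must be >= 1")
    half = Z95 * math.sqrt(p1 * (1 - p1) / m + p2 * (1 - p2) / n)
    half += 0.5 * (1.0 / m + 1.0 / n)
    d = p1 - p2
    return (max(-1.0, d - half), min(1.0, d + half))


def _column_rng(config: NullModelConfig, mutation_type: str) -> np.random.Generator:
    # independent substream per mutation type, keyed by a stable digest of
    # its name -> results do not depend on column order or catalog subsets
    digest = hashlib.sha256(mutation_type.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def differential_table(
    matrix: MutationMatrix,
    samples: Sequence[SampleRecord],
    catalog: Sequence[DriverCatalogEntry],
    config: Optional[NullModelConfig] = None,
) -> list:
    """One burden-adjusted differential result per mutation type.

    Rows lacking assayed samples in one state are flagged rather than
    dropped; flagged rows carry NaN statistics and are excluded from the
    joint FDR correction.  Deterministic under a fixed config seed.
    """
    if config is None:
        config = NullModelConfig()
    by_id = {s.sample_id: s for s in samples}
    entries = {e.gene_id: e for e in catalog}

    results = []
    for col in matrix.columns:
        gene, mclass = matrix.split_column(col)
        entry = entries.get(gene)
        if entry is None:
            continue
        cells = matrix.data[col]
        assayed_ids = [sid for sid in cells.index[cells.notna()] if sid in by_id]
        state = np.array([by_id[sid].state for sid in assayed_ids])
        vals = cells.loc[assayed_ids].values
        m = int((state == "mCRPC").sum())
        n = int((state == "localized").sum())
        if m == 0 or n == 0:
            results.append(
                DifferentialResult(
                    mutation_type=col,
                    gene_id=gene,
                    mclass=mclass,
                    n_mcrpc=m,
                    n_localized=n,
                    p_mcrpc=float("nan"),
                    p_localized=float("nan"),
                    observed_delta=float("nan"),
                    expected_delta=float("nan"),
                    adjusted_delta=float("nan"),
                    delta_ci_low=float("nan"),
                    delta_ci_high=float("nan"),
                    p_value=float("nan"),
                    flag="missing_state",
                )
            )
            continue
        p1 = float(vals[state == "mCRPC"].sum()) / m
        p2 = float(vals[state == "localized"].sum()) / n
        observed = p1 - p2

        p_mut = np.array(
            [
                per_sample_hit_probability(by_id[sid], entry, mclass, config)
                for sid in assayed_ids
            ]
        )
        rng = _column_rng(config, col)
        expected, sims = simulate_null(p_mut, state, config, rng=rng)
        p_value = empirical_pvalue(observed, sims, mclass, config.p_floor)
        ci_low, ci_high = delta_ci_yates(p1, m, p2, n)
        results.append(
            DifferentialResult(
                mutation_type=col,
                gene_id=gene,
                mclass=mclass,
                n_mcrpc=m,
                n_localized=n,
                p_mcrpc=p1,
                p_localized=p2,
                observed_delta=observed,
                expected_delta=expected,
                adjusted_delta=observed - expected,
                delta_ci_low=ci_low,
                delta_ci_high=ci_high,
                p_value=p_value,
            )
        )

    valid = [r for r in results if r.flag is None]
    if valid:
        q = adjust_fdr([r.p_value for r in valid])
        for r, qv in zip(valid, q):
            r.q_value = float(qv)
            if qv < config.alpha:
                r.direction = (
                    "enriched_mCRPC" if r.adjusted_delta > 0 else "depleted_mCRPC"
                )
            else:
                r.direction = "null"
    return results


def differential_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Tabular view of differential results (for the TSV output)."""
    return pd.DataFrame(
        [
            {
                "mutation_type": r.mutation_type,
                "gene": r.gene_id,
                "class": r.mclass,
                "n_mcrpc": r.n_mcrpc,
                "n_localized": r.n_localized,
                "p_mcrpc": r.p_mcrpc,
                "p_localized": r.p_localized,
                "observed_delta": r.observed_delta,
                "expected_delta": r.expected_delta,
                "adjusted_delta": r.adjusted_delta,
                "delta_ci_low": r.delta_ci_low,
                "delta_ci_high": r.delta_ci_high,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "direction": r.direction,
                "flag": r.flag if r.flag else "",
            }
            for r in results
        ]
    )
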