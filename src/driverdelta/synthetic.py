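"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the differential-prevalence analysis
assumes: two disease states whose per-sample SNV burden and percent
genome altered (PGA) come from state-specific distributions (metastatic
castration-resistant tumors are shifted up on both), a driver catalog
with genomic footprints, mutation presence generated from the same
burden-weighted null the analysis tests against plus optional planted
per-gene excess probabilities in the metastatic state, and
proportional-hazards outcome times whose log-hazard is a sum of planted
per-gene effects.

Default cohort sizes and distribution parameters are chosen to resemble
published prostate-cancer cohorts: localized tumors around 1 SNV/Mbp
and ~5% PGA, metastatic tumors around 4.5 SNVs/Mbp and ~25% PGA.

The planted truth is stored alongside the generated data and is never
consumed by the pipeline under test.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from driverdelta.catalog import (
    ASSAY_CLASSES,
    ASSAY_OF_CLASS,
    DriverCatalogEntry,
    GenomicInterval,
    MutationMatrix,
    SampleRecord,
    write_driver_catalog,
)
from driverdelta.differential import NullModelConfig, per_sample_hit_probability
from driverdelta.survival import SurvivalRecord

#: Class mix for generated catalogs, proportioned like a real driver
#: catalog (CNAs and SVs dominate, few non-coding SNV loci).
_CLASS_CYCLE = (
    "CNA_loss", "SNV", "SV", "CNA_gain", "SNV", "SV",
    "CNA_loss", "SNV", "CNA_gain", "SV", "SNV", "ncSNV",
)


@dataclass
class SyntheticConfig:
    """Study conditions for synthetic cohorts.

    Burdens are log-normal per state (location parameters on the log
    scale, shared sigma); PGA is Beta per state.  ``planted_delta`` maps
    gene_id to the excess per-sample hit probability added in the
    metastatic state on top of the burden null; genes absent from the
    map form the calibration (pure-null) set.  ``planted_log_hr`` maps
    gene_id to the log hazard ratio its carriers incur for the outcome
    endpoint.
    """

    n_localized: int = 200
    n_mcrpc: int = 100
    seed: int = 0
    n_genes: int = 24
    # burden model: SNVs/Mbp ~ LogNormal, median 1.0 localized / 4.5 mCRPC
    snv_burden_log_mean_localized: float = 0.0
    snv_burden_log_mean_mcrpc: float = math.log(4.5)
    snv_burden_log_sd: float = 0.5
    # PGA ~ Beta, mean 0.05 localized / 0.25 mCRPC
    pga_beta_localized: tuple = (2.0, 38.0)
    pga_beta_mcrpc: tuple = (2.5, 7.5)
    # assay availability per class (fraction of samples profiled)
    assay_fractions: dict = field(
        default_factory=lambda: {c: 1.0 for c in ASSAY_CLASSES}
    )
    planted_delta: dict = field(default_factory=dict)
    planted_log_hr: dict = field(default_factory=dict)
    endpoint: str = "metastasis"
    baseline_hazard_per_month: float = 0.007
    censoring_rate: float = 0.6
    null_model: NullModelConfig = field(
        default_factory=lambda: NullModelConfig(n_iter=10_000)
    )
    # expression/methylation generator
    target_gene: Optional[str] = None
    rna_baseline: float = 6.6
    rna_loss_shift: float = 0.3
    rna_noise_sd: float = 0.3
    methylation_shift_loss: float = 0.5
    target_spearman: float = -0.4

    def __post_init__(self) -> None:
        if self.n_localized <= 0 or self.n_mcrpc <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must lie in [0, 1]")
        for g, d in self.planted_delta.items():
            if d < 0 or d > 1:
                raise ValueError(f"planted delta for {g} outside [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


@dataclass
class SyntheticTruth:
    """Planted effects and their implied prevalences, per gene."""

    delta: dict
    log_hr: dict
    expected_prevalence: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def make_catalog(
    config: SyntheticConfig,
    classes: Optional[Sequence[str]] = None,
) -> list:
    """Generate a driver catalog with realistic genomic footprints.

    One class per entry, cycling through a CNA/SNV/SV-dominated mix (or
    an explicit ``classes`` cycle); coding footprints a few kb, gene
    spans ~50-300 kb, placed on autosomes with non-overlapping
    intervals.
    """
    rng = config.rng(0)
    cycle = tuple(classes) if classes else _CLASS_CYCLE
    entries = []
    pos = 1_000_000
    for i in range(config.n_genes):
        mclass = cycle[i % len(cycle)]
        gene_id = f"G{i + 1:03d}"
        chrom = str(1 + i % 22)
        span = int(rng.integers(50_000, 300_000))
        snv_fp = float(rng.uniform(0.001, 0.004))  # Mbp of coding sequence
        entries.append(
            DriverCatalogEntry(
                gene_id=gene_id,
                label=gene_id,
                chromosome=chrom,
                classes=frozenset({mclass}),
                snv_footprint_mbp=snv_fp,
                cna_footprint_bp=span,
                interval=GenomicInterval(chrom, pos, pos + span),
            )
        )
        pos += 2_000_000
    return entries


def generate_samples(config: SyntheticConfig) -> list:
    """Draw per-sample burdens, PGA, assay masks, and clinical covariates."""
    rng = config.rng(1)
    records = []
    specs = [("localized", config.n_localized), ("mCRPC", config.n_mcrpc)]
    counter = 0
    for state, n in specs:
        if state == "localized":
            log_mu = config.snv_burden_log_mean_localized
            beta_a, beta_b = config.pga_beta_localized
        else:
            log_mu = config.snv_burden_log_mean_mcrpc
            beta_a, beta_b = config.pga_beta_mcrpc
        burdens = rng.lognormal(log_mu, config.snv_burden_log_sd, size=n)
        pgas = rng.beta(beta_a, beta_b, size=n)
        psas = rng.lognormal(math.log(8.0), 0.5, size=n)
        isup = rng.integers(1, 6, size=n)
        ct = rng.choice(["cT1", "cT2a/b", "cT2c"], size=n, p=[0.45, 0.45, 0.1])
        assay_draw = {
            c: rng.random(n) < config.assay_fractions.get(c, 1.0)
            for c in ASSAY_CLASSES
        }
        for i in range(n):
            counter += 1
            assayed = frozenset(c for c in ASSAY_CLASSES if assay_draw[c][i])
            records.append(
                SampleRecord(
                    sample_id=f"S{counter:05d}",
                    cohort="synthetic",
                    state=state,
                    snv_burden_per_mbp=float(burdens[i]),
                    pga=float(min(pgas[i], 1.0)),
                    assayed_classes=assayed,
                    psa=float(psas[i]),
                    isup_grade=int(isup[i]),
                    ct_category=str(ct[i]),
                )
            )
    return records


def make_truth(
    samples: Sequence[SampleRecord],
    catalog: Sequence[DriverCatalogEntry],
    config: SyntheticConfig,
) -> SyntheticTruth:
    """Record planted effects and the prevalence they imply per state."""
    expected: dict = {}
    for entry in catalog:
        mclass = next(iter(entry.classes))
        delta = config.planted_delta.get(entry.gene_id, 0.0)
        per_state: dict = {}
        for state in ("localized", "mCRPC"):
            probs = []
            for s in samples:
                if s.state != state:
                    continue
                if ASSAY_OF_CLASS[mclass] not in s.assayed_classes:
                    continue
                p = per_sample_hit_probability(s, entry, mclass, config.null_model)
                if state == "mCRPC":
                    p = min(1.0, p + delta)
                probs.append(p)
            per_state[state] = float(np.mean(probs)) if probs else float("nan")
        expected[entry.gene_id] = per_state
    return SyntheticTruth(
        delta={e.gene_id: config.planted_delta.get(e.gene_id, 0.0) for e in catalog},
        log_hr={e.gene_id: config.planted_log_hr.get(e.gene_id, 0.0) for e in catalog},
        expected_prevalence=expected,
    )


def plant_mutations(
    samples: Sequence[SampleRecord],
    catalog: Sequence[DriverCatalogEntry],
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> MutationMatrix:
    """Draw the presence matrix from the null plus planted excess.

    Cell probability is min(1, p_null(sample, gene) + delta_g for
    metastatic samples); cells of unassayed classes stay NaN.
    """
    rng = config.rng(2)
    sample_ids = [s.sample_id for s in samples]
    columns = [m for e in catalog for m in e.mutation_types()]
    data = pd.DataFrame(np.nan, index=sample_ids, columns=columns)
    for entry in catalog:
        delta = truth.delta.get(entry.gene_id, 0.0)
        for mclass in sorted(entry.classes):
            col = f"{entry.gene_id}:{mclass}"
            for s in samples:
                if ASSAY_OF_CLASS[mclass] not in s.assayed_classes:
                    continue
                p = per_sample_hit_probability(s, entry, mclass, config.null_model)
                if s.state == "mCRPC":
                    p = min(1.0, p + delta)
                data.at[s.sample_id, col] = float(rng.random() < p)
    return MutationMatrix(data)


def _calibrate_censor_horizon(event_times: np.ndarray, censoring_rate: float) -> float:
    """Uniform-censoring horizon giving the target expected censor rate.

    With censoring C ~ U(0, horizon), sample i is censored when C falls
    before its event time, with probability min(T_i / horizon, 1); the
    horizon is solved by bisection so the mean censoring probability
    matches the target (the censor fraction decreases as the horizon
    grows).
    """
    def censor_frac(h: float) -> float:
        return float(np.mean(np.minimum(event_times / h, 1.0)))

    lo, hi = 1e-9, float(event_times.max()) * 2
    while censor_frac(hi) > censoring_rate and hi < 1e12:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censor_frac(mid) > censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_outcomes(
    samples: Sequence[SampleRecord],
    matrix: MutationMatrix,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> list:
    """Exponential proportional-hazards outcome times for localized samples.

    The hazard is baseline * exp(sum of planted log-HRs over carried
    mutations); censoring is independent uniform, calibrated to the
    configured censoring rate.  Outcomes are also written back onto the
    sample records.
    """
    rng = config.rng(3)
    localized = [s for s in samples if s.state == "localized"]
    if not localized:
        return []
    gene_cols = {
        gene: [c for c in matrix.columns if matrix.column_gene(c) == gene]
        for gene in truth.log_hr
    }
    rates = []
    for s in localized:
        log_hr = 0.0
        for gene, lhr in truth.log_hr.items():
            if lhr == 0.0:
                continue
            carried = any(
                matrix.data.at[s.sample_id, c] == 1.0 for c in gene_cols[gene]
            )
            if carried:
                log_hr += lhr
        rates.append(config.baseline_hazard_per_month * math.exp(log_hr))
    rates = np.asarray(rates)
    event_times = rng.exponential(1.0 / rates)

    records = []
    if config.censoring_rate >= 1.0:
        times = np.full(len(localized), 0.001)
        observed = np.zeros(len(localized), dtype=bool)
    elif config.censoring_rate <= 0.0:
        times = event_times
        observed = np.ones(len(localized), dtype=bool)
    else:
        horizon = _calibrate_censor_horizon(event_times, config.censoring_rate)
        censor_times = rng.uniform(0.0, horizon, size=len(localized))
        observed = event_times <= censor_times
        times = np.where(observed, event_times, censor_times)
    times = np.maximum(times, 1e-6)
    for s, t, ev in zip(localized, times, observed):
        rec = SurvivalRecord(s.sample_id, config.endpoint, float(t), bool(ev))
        s.outcomes[config.endpoint] = (rec.time, rec.event)
        records.append(rec)
    return records



def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import spearmanr

    return float(spearmanr(x, y)[0])


def generate_expression_methylation(
    samples: Sequence[SampleRecord],
    matrix: MutationMatrix,
    config: SyntheticConfig,
) -> tuple:
    """RNA abundance and promoter methylation for a target gene.

    Carriers of a copy-number loss in the target gene get lower RNA and
    higher promoter methylation; the RNA-methylation coupling
    coefficient is chosen so the realized Spearman correlation is close
    to the configured target (default -0.4).  Returns (rna, methylation)
    DataFrames indexed by sample.
    """
    rng = config.rng(4)
    target = config.target_gene
    if target is None:
        loss_cols = [
            c for c in matrix.columns if matrix.column_class(c) == "CNA_loss"
        ]
        if not loss_cols:
            raise ValueError("no CNA_loss column to target; set target_gene")
        target = matrix.column_gene(loss_cols[0])
    col = f"{target}:CNA_loss"
    if col not in matrix.columns:
        raise ValueError(f"target gene {target!r} has no CNA_loss column")

    ids = matrix.samples
    loss = (matrix.data[col] == 1.0).values.astype(float)

    sigma_m, sigma_e = 1.0, config.rna_noise_sd
    s_m = config.methylation_shift_loss
    s_r = config.rna_loss_shift

    meth = rng.normal(0.0, sigma_m, size=len(ids)) + s_m * loss
    noise = rng.normal(0.0, sigma_e, size=len(ids))

    def _rna(beta: float) -> np.ndarray:
        return config.rna_baseline - s_r * loss - beta * meth + noise

    # the loss pathway alone already couples RNA and methylation; add
    # direct coupling only as needed to reach the configured Spearman
    # correlation, calibrated on the realized draws (the realized
    # correlation is monotone decreasing in the coupling coefficient)
    beta = 0.0
    rho_target = config.target_spearman
    if rho_target < 0.0 and _spearman(_rna(0.0), meth) > rho_target:
        lo, hi = 0.0, 1.0
        while _spearman(_rna(hi), meth) > rho_target and hi < 1e3:
            hi *= 2
        for _ in range(60):
            beta = 0.5 * (lo + hi)
            if _spearman(_rna(beta), meth) > rho_target:
                lo = beta
            else:
                hi = beta
    rna = _rna(beta)
    rna_frame = pd.DataFrame({target: rna}, index=ids)
    meth_frame = pd.DataFrame({f"{target}_promoter": meth}, index=ids)
    return rna_frame, meth_frame


# ---------------------------------------------------------------------------
# cohort file emission (same formats the readers ingest)


def write_cohort_files(
    samples: Sequence[SampleRecord],
    matrix: MutationMatrix,
    catalog: Sequence[DriverCatalogEntry],
    truth: SyntheticTruth,
    outdir,
) -> dict:
    """Emit SEG / MAF / ncSNV / BEDPE / clinical / catalog / truth files.

    Raw call rows are reconstructed from the presence matrix so that
    reading them back through the harmonization path reproduces the
    matrix exactly.  Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_gene = {e.gene_id: e for e in catalog}

    seg_rows, maf_rows, nc_rows, sv_rows = [], [], [], []
    for sid in matrix.samples:
        for col in matrix.columns:
            if matrix.data.at[sid, col] != 1.0:
                continue
            gene, mclass = matrix.split_column(col)
            entry = by_gene[gene]
            iv = entry.interval
            if mclass in ("CNA_gain", "CNA_loss"):
                seg_rows.append(
                    {
                        "sample": sid,
                        "chrom": iv.chrom,
                        # SEG convention: 1-based inclusive
                        "start": iv.start + 1,
                        "end": iv.end,
                        "call": "gain" if mclass == "CNA_gain" else "loss",
                    }
                )
            elif mclass == "SNV":
                maf_rows.append(
                    {"sample": sid, "gene": gene, "consequence": "Missense_Mutation"}
                )
            elif mclass == "ncSNV":
                nc_rows.append({"sample": sid, "locus_id": gene})
            elif mclass == "SV":
                mid = (iv.start + iv.end) // 2
                subtype = "translocation"
                if entry.sv_subtype_filter:
                    subtype = sorted(entry.sv_subtype_filter)[0]
                sv_rows.append(
                    {
                        "sample": sid,
                        "chrom1": iv.chrom,
                        "start1": mid,
                        "end1": mid + 1,
                        "chrom2": "99",
                        "start2": 1,
                        "end2": 2,
                        "sv_type": subtype,
                    }
                )

    paths = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        paths[name.split(".")[0]] = path

    _write("cna.seg", pd.DataFrame(seg_rows,
           columns=["sample", "chrom", "start", "end", "call"]))
    _write("snv.maf.tsv", pd.DataFrame(maf_rows,
           columns=["sample", "gene", "consequence"]))
    _write("ncsnv.tsv", pd.DataFrame(nc_rows, columns=["sample", "locus_id"]))
    _write("sv.bedpe.tsv", pd.DataFrame(sv_rows,
           columns=["sample", "chrom1", "start1", "end1",
                    "chrom2", "start2", "end2", "sv_type"]))

    clin_rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "cohort": s.cohort,
            "state": s.state,
            "snv_burden_per_mbp": s.snv_burden_per_mbp,
            "pga": s.pga,
            "assayed_classes": ",".join(sorted(s.assayed_classes)),
            "burden_reference": s.burden_reference,
            "psa": s.psa,
            "isup_grade": s.isup_grade,
            "ct_category": s.ct_category,
        }
        for ep, (time, event) in s.outcomes.items():
            row[f"{ep}_time"] = time
            row[f"{ep}_event"] = int(event)
        clin_rows.append(row)
    _write("clinical.tsv", pd.DataFrame(clin_rows))

    catalog_path = outdir / "catalog.yaml"
    write_driver_catalog(catalog, catalog_path)
    paths["catalog"] = catalog_path

    matrix_path = outdir / "matrix.tsv"
    matrix.to_tsv(matrix_path)
    paths["matrix"] = matrix_path

    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
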