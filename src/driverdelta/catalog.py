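"""Driver catalog, sample records, and mutation-matrix construction.

Harmonizes heterogeneous somatic call tables (SEG copy-number segments,
MAF-like SNV tables, BEDPE structural variants) against a curated driver
catalog into a single samples x driver-mutation-types presence matrix.
Each driver mutation type is a (gene or locus, mutation class) pair;
classes are copy-number gain/loss, coding SNV, non-coding SNV, and SV.

Not every cohort assays every class, so the matrix distinguishes
``absent`` (assayed, not mutated) from ``not assayed`` (NaN); class
denominators count only assayed samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Recognized driver mutation classes (matrix column classes).
MUTATION_CLASSES = ("CNA_gain", "CNA_loss", "SNV", "ncSNV", "SV")

#: Assay classes a cohort may or may not have profiled.
ASSAY_CLASSES = ("CNA", "SNV", "ncSNV", "SV")

#: Map from mutation class to the assay that detects it.
ASSAY_OF_CLASS = {
    "CNA_gain": "CNA",
    "CNA_loss": "CNA",
    "SNV": "SNV",
    "ncSNV": "ncSNV",
    "SV": "SV",
}

DISEASE_STATES = ("localized", "mCRPC")

# Copy-number log2 thresholds for sequencing-derived categorical calls.
# Autosomes: gain >= 3, loss <= 1.65; X/Y: gain >= 1.4, loss <= 0.6
# (boundaries inclusive).
_LOG2_THRESHOLDS = {
    "autosome": {"gain": 3.0, "loss": 1.65},
    "allosome": {"gain": 1.4, "loss": 0.6},
}

_CATEGORICAL_CNA = {
    "deep deletion": "loss",
    "shallow deletion": "loss",
    "loss": "loss",
    "neutral": "neutral",
    "gain": "gain",
    "amplification": "gain",
}

# Consequence terms retained for coding driver SNVs: missense, stop
# gained/lost, and canonical splice-site variants.  Frameshift indels are
# deliberately excluded.  Keys are lower-case with MAF and Sequence
# Ontology spellings.
_SNV_INCLUDE = {
    "missense": "missense",
    "missense_variant": "missense",
    "missense_mutation": "missense",
    "nonsense_mutation": "stop_gained",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "nonstop_mutation": "stop_lost",
    "splice_donor_variant": "splice_donor",
    "splice_donor": "splice_donor",
    "splice_acceptor_variant": "splice_acceptor",
    "splice_acceptor": "splice_acceptor",
    "splice_site": "splice_donor",
}

_SNV_EXCLUDE = {
    "silent",
    "synonymous",
    "synonymous_variant",
    "frame_shift_del",
    "frame_shift_ins",
    "frameshift_variant",
    "frameshift",
    "in_frame_del",
    "in_frame_ins",
    "intron_variant",
    "intron",
    "3'utr",
    "5'utr",
    "igr",
    "rna",
}


class CatalogError(ValueError):
    """Raised for malformed or inconsistent driver-catalog input."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise CatalogError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and start < self.end and self.start < end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DriverCatalogEntry:
    """One driver gene or recurrently mutated locus.

    Parameters
    ----------
    gene_id
        Unique identifier; subtype-split entries (e.g. PTEN inversions
        vs. translocations/deletions) use distinct ids.
    snv_footprint_mbp
        Coding footprint in Mbp used to size the SNV hit probability.
    cna_footprint_bp
        Gene span in bp used to size the CNA/SV hit probability.
    interval
        Genomic span of the gene body (for segment overlap).
    pooled_loci
        Auxiliary intervals whose hits count toward this entry, e.g. the
        AR enhancer ~624 kb upstream of the AR gene body.
    sv_subtype_filter
        If set, only SVs of these subtypes are routed to this entry.
    """

    gene_id: str
    label: str
    chromosome: str
    classes: frozenset
    snv_footprint_mbp: Optional[float] = None
    cna_footprint_bp: Optional[int] = None
    interval: Optional[GenomicInterval] = None
    pooled_loci: list = field(default_factory=list)
    sv_subtype_filter: Optional[frozenset] = None

    def __post_init__(self) -> None:
        self.classes = frozenset(self.classes)
        if not self.classes:
            raise CatalogError(f"{self.gene_id}: classes must be non-empty")
        unknown = self.classes - set(MUTATION_CLASSES)
        if unknown:
            raise CatalogError(f"{self.gene_id}: unknown classes {sorted(unknown)}")
        if self.classes & {"SNV", "ncSNV"}:
            if self.snv_footprint_mbp is None or self.snv_footprint_mbp <= 0:
                raise CatalogError(
                    f"{self.gene_id}: SNV classes require snv_footprint_mbp > 0"
                )
        if self.classes & {"CNA_gain", "CNA_loss", "SV"}:
            if self.cna_footprint_bp is None or self.cna_footprint_bp <= 0:
                raise CatalogError(
                    f"{self.gene_id}: CNA/SV classes require cna_footprint_bp > 0"
                )
        if self.sv_subtype_filter is not None:
            self.sv_subtype_filter = frozenset(
                s.lower() for s in self.sv_subtype_filter
            )

    @property
    def allosomal(self) -> bool:
        return self.chromosome.lstrip("chr") in {"X", "Y"}

    def mutation_types(self) -> list:
        return [f"{self.gene_id}:{c}" for c in MUTATION_CLASSES if c in self.classes]


@dataclass
class SampleRecord:
    """One tumor sample with burden, assay, and clinical annotations."""

    sample_id: str
    cohort: str
    state: str
    snv_burden_per_mbp: float = float("nan")
    pga: float = float("nan")
    assayed_classes: frozenset = frozenset(ASSAY_CLASSES)
    burden_reference: str = "genome"
    psa: Optional[float] = None
    isup_grade: Optional[int] = None
    ct_category: Optional[str] = None
    outcomes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in DISEASE_STATES:
            raise ValueError(f"{self.sample_id}: unknown state {self.state!r}")
        self.assayed_classes = frozenset(self.assayed_classes)
        unknown = self.assayed_classes - set(ASSAY_CLASSES)
        if unknown:
            raise ValueError(f"{self.sample_id}: unknown assays {sorted(unknown)}")
        if not math.isnan(self.pga) and not 0.0 <= self.pga <= 1.0:
            raise ValueError(f"{self.sample_id}: PGA {self.pga} outside [0, 1]")
        if not math.isnan(self.snv_burden_per_mbp) and self.snv_burden_per_mbp < 0:
            raise ValueError(f"{self.sample_id}: negative SNV burden")
        if self.burden_reference not in ("genome", "exome"):
            raise ValueError(
                f"{self.sample_id}: burden_reference must be genome or exome"
            )
        for endpoint, (time, _event) in self.outcomes.items():
            if time <= 0:
                raise ValueError(
                    f"{self.sample_id}: non-positive time for {endpoint}"
                )


class MutationMatrix:
    """Samples x driver-mutation-types presence matrix.

    Cells are 1.0 (present), 0.0 (assayed, absent), or NaN (class not
    assayed for that sample).  Columns are ``gene_id:class`` strings.
    """

    def __init__(self, data: pd.DataFrame):
        for col in data.columns:
            gene, _, mclass = col.rpartition(":")
            if not gene or mclass not in MUTATION_CLASSES:
                raise ValueError(f"malformed matrix column {col!r}")
        bad = data.stack(future_stack=True).dropna()
        if not bad.isin([0.0, 1.0]).all():
            raise ValueError("matrix cells must be 0, 1 or NaN")
        self.data = data.astype(float)
        self.data.index.name = "sample_id"

    # -- column metadata ------------------------------------------------
    @staticmethod
    def split_column(col: str) -> tuple:
        gene, _, mclass = col.rpartition(":")
        return gene, mclass

    def column_class(self, col: str) -> str:
        return self.split_column(col)[1]

    def column_gene(self, col: str) -> str:
        return self.split_column(col)[0]

    def gene_columns(self, gene_id: str) -> list:
        return [c for c in self.data.columns if self.column_gene(c) == gene_id]

    @property
    def columns(self) -> list:
        return list(self.data.columns)

    @property
    def samples(self) -> list:
        return list(self.data.index)

    # -- counting -------------------------------------------------------
    def denominator(self, col: str) -> int:
        """Number of samples assayed for the column's class."""
        return int(self.data[col].notna().sum())

    def numerator(self, col: str) -> int:
        return int((self.data[col] == 1.0).sum())

    # -- persistence ----------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.data.replace({1.0: "1", 0.0: "0"}).fillna("NA")
        out.to_csv(path, sep="\t", index=True)

    @classmethod
    def read_tsv(cls, path) -> "MutationMatrix":
        frame = pd.read_csv(
            path, sep="\t", index_col="sample_id", na_values=["NA"], dtype=str
        )
        return cls(frame.apply(pd.to_numeric))


# ---------------------------------------------------------------------------
# catalog loading


def _parse_interval(raw, context: str) -> GenomicInterval:
    try:
        chrom, start, end = raw
        return GenomicInterval(str(chrom), int(start), int(end))
    except (TypeError, ValueError) as exc:
        raise CatalogError(f"{context}: malformed interval {raw!r}") from exc


def load_driver_catalog(path) -> list:
    """Load a structured-text (YAML) driver catalog.

    The file holds a ``drivers`` list; each item carries gene_id, label,
    chromosome, class list, footprints, and optional interval /
    pooled_loci / sv_subtype_filter fields.  Duplicate (gene_id, class)
    pairs are rejected so that matrix columns are unique.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise CatalogError(f"{path}: empty catalog file")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark else ""
        raise CatalogError(f"{path}: parse error{line}: {exc}") from exc
    if not isinstance(doc, dict) or "drivers" not in doc:
        raise CatalogError(f"{path}: catalog must contain a 'drivers' list")

    entries = []
    seen = set()
    for i, item in enumerate(doc["drivers"]):
        context = f"{path}: drivers[{i}]"
        try:
            entry = DriverCatalogEntry(
                gene_id=str(item["gene_id"]),
                label=str(item.get("label", item["gene_id"])),
                chromosome=str(item["chromosome"]),
                classes=frozenset(item["classes"]),
                snv_footprint_mbp=item.get("snv_footprint_mbp"),
                cna_footprint_bp=item.get("cna_footprint_bp"),
                interval=(
                    _parse_interval(item["interval"], context)
                    if "interval" in item
                    else None
                ),
                pooled_loci=[
                    _parse_interval(loc, context)
                    for loc in item.get("pooled_loci", [])
                ],
                sv_subtype_filter=(
                    frozenset(item["sv_subtype_filter"])
                    if item.get("sv_subtype_filter")
                    else None
                ),
            )
        except KeyError as exc:
            raise CatalogError(f"{context}: missing field {exc}") from exc
        except CatalogError as exc:
            raise CatalogError(f"{context}: {exc}") from exc
        for mtype in entry.mutation_types():
            if mtype in seen:
                raise CatalogError(f"{context}: duplicate mutation type {mtype}")
            seen.add(mtype)
        entries.append(entry)
    return entries


def write_driver_catalog(entries: Sequence[DriverCatalogEntry], path) -> None:
    """Serialize a catalog back to the YAML dialect read by the loader."""
    doc = {"drivers": []}
    for e in entries:
        item = {
            "gene_id": e.gene_id,
            "label": e.label,
            "chromosome": e.chromosome,
            "classes": sorted(e.classes),
        }
        if e.snv_footprint_mbp is not None:
            item["snv_footprint_mbp"] = float(e.snv_footprint_mbp)
        if e.cna_footprint_bp is not None:
            item["cna_footprint_bp"] = int(e.cna_footprint_bp)
        if e.interval is not None:
            item["interval"] = [e.interval.chrom, e.interval.start, e.interval.end]
        if e.pooled_loci:
            item["pooled_loci"] = [
                [loc.chrom, loc.start, loc.end] for loc in e.pooled_loci
            ]
        if e.sv_subtype_filter is not None:
            item["sv_subtype_filter"] = sorted(e.sv_subtype_filter)
        doc["drivers"].append(item)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# call harmonization


def normalize_cna_call(raw, chromosome_class: str = "autosome") -> str:
    """Pool a raw copy-number call to ``gain`` / ``neutral`` / ``loss``.

    Categorical calls pool shallow and deep deletions to loss and
    gain/amplification to gain.  Numeric log2 copy-number scores are
    thresholded with inclusive boundaries; thresholds differ between
    autosomes and sex chromosomes.  NaN scores mean the sample was not
    assayed at that locus.
    """
    if chromosome_class not in _LOG2_THRESHOLDS:
        raise ValueError(f"unknown chromosome_class {chromosome_class!r}")
    if isinstance(raw, str):
        key = raw.strip().lower()
        if key not in _CATEGORICAL_CNA:
            raise ValueError(f"unknown CNA category {raw!r}")
        return _CATEGORICAL_CNA[key]
    value = float(raw)
    if math.isnan(value):
        return "not_assayed"
    thr = _LOG2_THRESHOLDS[chromosome_class]
    if value >= thr["gain"]:
        return "gain"
    if value <= thr["loss"]:
        return "loss"
    return "neutral"


def filter_snv_consequence(consequence: str) -> bool:
    """True iff the consequence is a retained coding driver class.

    Retained: missense, stop gained/lost, splice donor/acceptor.
    Frameshift indels and synonymous changes are excluded; unknown terms
    are excluded conservatively with a logged warning.
    """
    key = str(consequence).strip().lower()
    if key in _SNV_INCLUDE:
        return True
    if key not in _SNV_EXCLUDE:
        logger.warning("unrecognized SNV consequence %r excluded", consequence)
    return False


# ---------------------------------------------------------------------------
# file readers (plumbing around standard text formats)


def read_seg(path) -> pd.DataFrame:
    """Read a SEG-like CNA table into 0-based half-open coordinates.

    Expected columns: sample, chrom, start, end, and either ``log2``
    (numeric copy-number score) or ``call`` (categorical).  SEG input is
    1-based inclusive per convention and converted on read.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.columns = [c.lower() for c in frame.columns]
    required = {"sample", "chrom", "start", "end"}
    if not required <= set(frame.columns):
        raise ValueError(f"SEG file {path} missing columns {required - set(frame.columns)}")
    frame["start"] = frame["start"].astype(int) - 1
    frame["end"] = frame["end"].astype(int)
    if "log2" not in frame.columns and "call" not in frame.columns:
        raise ValueError(f"SEG file {path} needs a 'log2' or 'call' column")
    return frame


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like SNV table (sample, gene, consequence)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.columns = [c.lower() for c in frame.columns]
    rename = {"tumor_sample_barcode": "sample", "hugo_symbol": "gene",
              "variant_classification": "consequence"}
    frame = frame.rename(columns=rename)
    required = {"sample", "gene", "consequence"}
    if not required <= set(frame.columns):
        raise ValueError(f"MAF file {path} missing columns {required - set(frame.columns)}")
    return frame


def read_bedpe(path) -> pd.DataFrame:
    """Read a BEDPE-like SV table (0-based half-open breakpoint loci)."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame.columns = [c.lower() for c in frame.columns]
    required = {"sample", "chrom1", "start1", "end1", "chrom2", "start2", "end2",
                "sv_type"}
    if not required <= set(frame.columns):
        raise ValueError(
            f"BEDPE file {path} missing columns {required - set(frame.columns)}"
        )
    return frame


def read_clinical(path) -> pd.DataFrame:
    """Read the per-sample clinical/outcome TSV."""
    frame = pd.read_csv(path, sep="\t")
    frame.columns = [c.lower() for c in frame.columns]
    if "sample_id" not in frame.columns:
        raise ValueError(f"clinical table {path} missing sample_id")
    return frame


def samples_from_clinical(frame: pd.DataFrame) -> list:
    """Build SampleRecords from a clinical table.

    Outcome columns follow the pattern ``<endpoint>_time`` /
    ``<endpoint>_event`` (months, 0/1); assayed classes are a
    comma-separated ``assayed_classes`` column.
    """
    endpoints = sorted(
        c[: -len("_time")] for c in frame.columns if c.endswith("_time")
    )
    records = []
    for _, row in frame.iterrows():
        outcomes = {}
        for ep in endpoints:
            time = row.get(f"{ep}_time")
            event = row.get(f"{ep}_event")
            if pd.notna(time) and pd.notna(event):
                outcomes[ep] = (float(time), bool(int(event)))
        assayed = row.get("assayed_classes", ",".join(ASSAY_CLASSES))
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                cohort=str(row.get("cohort", "synthetic")),
                state=str(row["state"]),
                snv_burden_per_mbp=float(row.get("snv_burden_per_mbp", "nan")),
                pga=float(row.get("pga", "nan")),
                assayed_classes=frozenset(
                    s for s in str(assayed).split(",") if s
                ),
                burden_reference=str(row.get("burden_reference", "genome")),
                psa=float(row["psa"]) if pd.notna(row.get("psa")) else None,
                isup_grade=(
                    int(row["isup_grade"])
                    if pd.notna(row.get("isup_grade"))
                    else None
                ),
                ct_category=(
                    str(row["ct_category"])
                    if pd.notna(row.get("ct_category"))
                    else None
                ),
                outcomes=outcomes,
            )
        )
    return records


# ---------------------------------------------------------------------------
# matrix construction


def _entry_hit_by_interval(entry: DriverCatalogEntry, chrom, start, end) -> bool:
    if entry.interval is not None and entry.interval.overlaps(chrom, start, end):
        return True
    return any(loc.overlaps(chrom, start, end) for loc in entry.pooled_loci)


def build_mutation_matrix(
    calls: Mapping[str, pd.DataFrame],
    catalog: Sequence[DriverCatalogEntry],
    samples: Sequence[SampleRecord],
) -> MutationMatrix:
    """Assemble the samples x mutation-types matrix from harmonized calls.

    ``calls`` maps assay names to tables: ``cna`` (SEG-style with
    chrom/start/end and log2 or call, or gene-level with gene and call),
    ``snv`` (sample, gene, consequence), ``ncsnv`` (sample, locus_id),
    ``sv`` (BEDPE-style).  Any subset of keys may be present.

    Rules applied here: a CNA hits a gene iff the segment overlaps the
    gene span (or a pooled locus such as the AR enhancer) by at least one
    base; multiple hits per gene and class collapse to a single present
    cell; SVs are routed by subtype when the entry restricts subtype;
    cells of unassayed classes stay NaN and never count as absent.
    """
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    by_id = {s.sample_id: s for s in samples}

    columns = [m for entry in catalog for m in entry.mutation_types()]
    data = pd.DataFrame(np.nan, index=sample_ids, columns=columns)
    for s in samples:
        for col in columns:
            mclass = col.rpartition(":")[2]
            if ASSAY_OF_CLASS[mclass] in s.assayed_classes:
                data.loc[s.sample_id, col] = 0.0

    def _check_sample(sample_id: str, assay: str, context: str):
        if sample_id not in by_id:
            raise ValueError(f"{context}: unknown sample {sample_id!r}")
        if assay not in by_id[sample_id].assayed_classes:
            raise ValueError(
                f"{context}: sample {sample_id!r} has no {assay} assay; "
                "call rejected"
            )
        return by_id[sample_id]

    def _set(sample_id: str, entry: DriverCatalogEntry, mclass: str) -> None:
        if mclass in entry.classes:
            data.loc[sample_id, f"{entry.gene_id}:{mclass}"] = 1.0

    cna = calls.get("cna")
    if cna is not None:
        gene_level = "gene" in cna.columns
        for _, row in cna.iterrows():
            sid = str(row["sample"])
            _check_sample(sid, "CNA", "CNA call")
            if gene_level:
                hit_entries = [e for e in catalog if e.gene_id == str(row["gene"])]
                chrom_class = (
                    "allosome" if hit_entries and hit_entries[0].allosomal
                    else "autosome"
                )
            else:
                chrom = str(row["chrom"])
                hit_entries = [
                    e
                    for e in catalog
                    if _entry_hit_by_interval(e, chrom, int(row["start"]), int(row["end"]))
                ]
                chrom_class = (
                    "allosome" if chrom.lstrip("chr") in {"X", "Y"} else "autosome"
                )
            raw = row["call"] if "call" in row.index and pd.notna(row.get("call")) \
                else row["log2"]
            state = normalize_cna_call(raw, chrom_class)
            if state == "neutral" or state == "not_assayed":
                continue
            for entry in hit_entries:
                _set(sid, entry, f"CNA_{state}")

    snv = calls.get("snv")
    if snv is not None:
        by_gene = {e.gene_id: e for e in catalog}
        for _, row in snv.iterrows():
            sid = str(row["sample"])
            _check_sample(sid, "SNV", "SNV call")
            if not filter_snv_consequence(row["consequence"]):
                continue
            entry = by_gene.get(str(row["gene"]))
            if entry is not None:
                _set(sid, entry, "SNV")

    ncsnv = calls.get("ncsnv")
    if ncsnv is not None:
        by_gene = {e.gene_id: e for e in catalog}
        for _, row in ncsnv.iterrows():
            sid = str(row["sample"])
            _check_sample(sid, "ncSNV", "ncSNV call")
            entry = by_gene.get(str(row["locus_id"]))
            if entry is not None:
                _set(sid, entry, "ncSNV")

    sv = calls.get("sv")
    if sv is not None:
        for _, row in sv.iterrows():
            sid = str(row["sample"])
            _check_sample(sid, "SV", "SV call")
            subtype = str(row["sv_type"]).strip().lower()
            for entry in catalog:
                if "SV" not in entry.classes:
                    continue
                if entry.sv_subtype_filter is not None and \
                        subtype not in entry.sv_subtype_filter:
                    continue
                hit = _entry_hit_by_interval(
                    entry, str(row["chrom1"]), int(row["start1"]), int(row["end1"])
                ) or _entry_hit_by_interval(
                    entry, str(row["chrom2"]), int(row["start2"]), int(row["end2"])
                )
                if hit:
                    _set(sid, entry, "SV")

    return MutationMatrix(data)
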