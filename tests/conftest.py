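"""Shared fixtures: tiny hand-built catalogs, cohorts, and matrices."""

import numpy as np
import pandas as pd
import pytest

from driverdelta.catalog import (
    DriverCatalogEntry,
    GenomicInterval,
    MutationMatrix,
    SampleRecord,
)


@pytest.fixture
def toy_catalog():
    """Three-gene catalog: AR-like entry with a pooled enhancer locus,
    PTEN-like SV entries split by subtype, and a plain multi-class gene."""
    ar = DriverCatalogEntry(
        gene_id="AR",
        label="AR",
        chromosome="X",
        classes=frozenset({"CNA_gain", "SNV"}),
        snv_footprint_mbp=0.0028,
        cna_footprint_bp=186_000,
        interval=GenomicInterval("X", 67_544_000, 67_730_000),
        pooled_loci=[GenomicInterval("X", 66_895_000, 66_910_000)],
    )
    pten_inv = DriverCatalogEntry(
        gene_id="PTEN-inv",
        label="PTEN inversions",
        chromosome="10",
        classes=frozenset({"SV"}),
        cna_footprint_bp=1_000_000,
        interval=GenomicInterval("10", 89_000_000, 90_000_000),
        sv_subtype_filter=frozenset({"inversion"}),
    )
    pten_td = DriverCatalogEntry(
        gene_id="PTEN-td",
        label="PTEN translocations and deletions",
        chromosome="10",
        classes=frozenset({"SV"}),
        cna_footprint_bp=1_000_000,
        interval=GenomicInterval("10", 89_000_000, 90_000_000),
        sv_subtype_filter=frozenset({"translocation", "deletion"}),
    )
    tp53 = DriverCatalogEntry(
        gene_id="TP53",
        label="TP53",
        chromosome="17",
        classes=frozenset({"CNA_loss", "SNV", "SV"}),
        snv_footprint_mbp=0.0012,
        cna_footprint_bp=19_000,
        interval=GenomicInterval("17", 7_668_000, 7_687_000),
    )
    return [ar, pten_inv, pten_td, tp53]


@pytest.fixture
def toy_samples():
    records = []
    for i in range(1, 4):
        records.append(
            SampleRecord(
                sample_id=f"L{i}",
                cohort="toy",
                state="localized",
                snv_burden_per_mbp=1.0,
                pga=0.05,
            )
        )
    for i in range(1, 4):
        records.append(
            SampleRecord(
                sample_id=f"M{i}",
                cohort="toy",
                state="mCRPC",
                snv_burden_per_mbp=4.0,
                pga=0.25,
            )
        )
    return records


def make_matrix(cells: dict, samples, columns) -> MutationMatrix:
    """Matrix from a {(sample, column): value} dict; unset cells are 0
    (assayed, absent)."""
    data = pd.DataFrame(0.0, index=list(samples), columns=list(columns))
    for (sample, column), value in cells.items():
        data.at[sample, column] = value
    return MutationMatrix(data)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
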