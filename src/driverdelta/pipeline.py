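"""End-to-end orchestration with deterministic outputs and a manifest.

Stages: cohort acquisition (synthetic generation or reading call
files), prevalence tabulation, burden-adjusted differential prevalence,
and the outcome screen.  All randomness is routed through one seed; a
run manifest records the config hash, seed, stage timings, and sha256
checksums of every output so identical (config, seed) pairs can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

import driverdelta
from driverdelta.catalog import (
    build_mutation_matrix,
    load_driver_catalog,
    read_bedpe,
    read_clinical,
    read_maf,
    read_seg,
    samples_from_clinical,
    MutationMatrix,
)
from driverdelta.differential import (
    NullModelConfig,
    differential_frame,
    differential_table,
)
from driverdelta.prevalence import prevalence_table
from driverdelta.survival import screen_candidates
from driverdelta import synthetic

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(
    config: dict,
    outdir,
    seed: Optional[int] = None,
    n_iter: Optional[int] = None,
) -> dict:
    """Run all stages and return the manifest dictionary.

    ``config`` holds either a ``synthetic`` section (forwarded to
    :class:`~driverdelta.synthetic.SyntheticConfig`) or an ``inputs``
    section with paths (catalog, clinical, cna/snv/ncsnv/sv call
    files).  ``seed`` and ``n_iter`` override the corresponding config
    entries.  Outputs: prevalence.tsv, differential.tsv,
    candidates.tsv, matrix.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = dict(config)
    if seed is not None:
        config["seed"] = seed
    seed = int(config.get("seed", 0))

    null_kwargs = dict(config.get("null_model", {}))
    if n_iter is not None:
        null_kwargs["n_iter"] = n_iter
    null_kwargs.setdefault("n_iter", 10_000)
    null_kwargs["seed"] = seed
    null_config = NullModelConfig(**null_kwargs)

    manifest = {
        "package_version": driverdelta.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": {},
    }

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = round(
                    time.perf_counter() - self_inner.t0, 4
                )
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s done in %.2fs", name, manifest["stages"][name])

        return _Timer()

    with _stage("cohort"):
        if "synthetic" in config:
            syn_kwargs = dict(config["synthetic"])
            syn_kwargs["seed"] = seed
            syn_kwargs["null_model"] = null_config
            syn = synthetic.SyntheticConfig(**syn_kwargs)
            catalog = synthetic.make_catalog(syn)
            samples = synthetic.generate_samples(syn)
            truth = synthetic.make_truth(samples, catalog, syn)
            matrix = synthetic.plant_mutations(samples, catalog, truth, syn)
            synthetic.generate_outcomes(samples, matrix, truth, syn)
            truth.to_json(outdir / "truth.json")
        else:
            inputs = config.get("inputs")
            if not inputs:
                raise ValueError("config needs a 'synthetic' or 'inputs' section")
            catalog = load_driver_catalog(inputs["catalog"])
            samples = samples_from_clinical(read_clinical(inputs["clinical"]))
            if "matrix" in inputs:
                matrix = MutationMatrix.read_tsv(inputs["matrix"])
            else:
                calls = {}
                if "cna" in inputs:
                    calls["cna"] = read_seg(inputs["cna"])
                if "snv" in inputs:
                    calls["snv"] = read_maf(inputs["snv"])
                if "ncsnv" in inputs:
                    calls["ncsnv"] = pd.read_csv(inputs["ncsnv"], sep="\t")
                if "sv" in inputs:
                    calls["sv"] = read_bedpe(inputs["sv"])
                matrix = build_mutation_matrix(calls, catalog, samples)
        matrix.to_tsv(outdir / "matrix.tsv")
        logger.info("cohort: %d samples, %d mutation types",
                    len(samples), len(matrix.columns))

    with _stage("prevalence"):
        prev = prevalence_table(matrix, samples)
        _write_tsv(prev, outdir / "prevalence.tsv")
        logger.info("prevalence: %d rows", len(prev))

    with _stage("differential"):
        results = differential_table(matrix, samples, catalog, null_config)
        diff = differential_frame(results)
        _write_tsv(diff, outdir / "differential.tsv")
        logger.info("differential: %d rows", len(diff))

    with _stage("screen"):
        screen_cfg = config.get("screen", {})
        endpoint = screen_cfg.get("endpoint", "metastasis")
        have_endpoint = any(
            endpoint in s.outcomes for s in samples if s.state == "localized"
        )
        if have_endpoint:
            report = screen_candidates(
                results,
                matrix,
                samples,
                endpoint=endpoint,
                alpha=screen_cfg.get("alpha", 0.05),
                min_localized_prevalence=screen_cfg.get(
                    "min_localized_prevalence", 0.05
                ),
            )
        else:
            if config.get("require_outcomes", False):
                raise KeyError(f"no localized outcomes for endpoint {endpoint!r}")
            report = pd.DataFrame()
        _write_tsv(report, outdir / "candidates.tsv")
        logger.info("screen: %d candidates", len(report))

    for name in ("matrix.tsv", "prevalence.tsv", "differential.tsv",
                 "candidates.tsv"):
        manifest["outputs"][name] = _sha256(outdir / name)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
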