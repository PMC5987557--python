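"""End-to-end orchestration: simulate → call DMRs → annotate → validate.

A single config (dict or YAML file) drives the run; every threshold used
and a hash of every input file is logged into the JSON run report, so a
report is self-describing and a rerun with the same config and seed is
identical apart from its timestamp.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .annotate import annotate_dmrs, summarize_categories, tfbs_in_dmrs, write_annotated_tsv
from .dmr import DMRParams, call_dmrs
from .io import (
    read_chrom_sizes,
    read_clone_matrix,
    read_cohort_table,
    read_cytosine_report,
    read_gene_models,
    read_tfbs_bed,
    write_dmrs_bed,
)
from .simulate import SimulationConfig, write_simulation
from .validate import run_validation

log = logging.getLogger("twindmr")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _require(mapping: dict, key: str, stage: str):
    if key not in mapping or mapping[key] is None:
        raise PipelineError(f"stage '{stage}': config missing required field '{key}'")
    return mapping[key]


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute every configured stage and return the run report.

    The config has optional sections ``simulate`` (generate inputs),
    ``inputs`` (use existing files), ``dmr``, ``annotate`` and
    ``validate``; ``seed`` and ``outdir`` sit at the top level.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(outdir or cfg.get("outdir", "twindmr_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = SimulationConfig(seed=seed, **(cfg["simulate"] or {}))
        sim_opts = cfg.get("simulate_outputs", {})
        try:
            inputs = write_simulation(sim_cfg, outdir / "sim", **sim_opts)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate': {exc}") from exc
        log.info("simulate: wrote inputs under %s", outdir / "sim")
    elif "inputs" in cfg:
        inputs = dict(cfg["inputs"])
        for key in ("sample1", "sample2", "chrom_sizes"):
            _require(inputs, key, "inputs")
    else:
        raise PipelineError("stage 'config': need a 'simulate' or 'inputs' section")

    dmr_cfg = cfg.get("dmr", {}) or {}
    params = DMRParams(**dmr_cfg)

    # --- DMR calling ------------------------------------------------------
    try:
        s1 = read_cytosine_report(inputs["sample1"], min_depth=1, sample_id="sample1")
        s2 = read_cytosine_report(inputs["sample2"], min_depth=1, sample_id="sample2")
        chrom_sizes = read_chrom_sizes(inputs["chrom_sizes"])
        dmrs, scan_report = call_dmrs(s1, s2, params, chrom_sizes)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'call-dmrs': {exc}") from exc
    write_dmrs_bed(dmrs, outdir / "dmrs.bed")
    log.info(
        "call-dmrs: %d windows tested, %d significant, %d DMRs (%d hyper / %d hypo)",
        scan_report.windows_tested, scan_report.dmws_significant,
        scan_report.dmrs, scan_report.n_hyper, scan_report.n_hypo,
    )

    # --- annotation -------------------------------------------------------
    ann_cfg = cfg.get("annotate", {}) or {}
    category_summary = None
    n_distinct_tfs = None
    if inputs.get("genes"):
        try:
            genes = read_gene_models(inputs["genes"], dialect=ann_cfg.get("dialect", "refflat"))
            tfbs = read_tfbs_bed(inputs["tfbs"]) if inputs.get("tfbs") else None
            annotated = annotate_dmrs(
                dmrs, genes, tfbs_records=tfbs,
                upstream_bp=int(ann_cfg.get("upstream_bp", 2000)),
                downstream_bp=int(ann_cfg.get("downstream_bp", 2000)),
            )
            category_summary = summarize_categories(annotated).to_dict()
            if tfbs is not None:
                _, tf_set = tfbs_in_dmrs(dmrs, tfbs)
                n_distinct_tfs = len(tf_set)
            write_annotated_tsv(annotated, outdir / "annotated.tsv")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'annotate': {exc}") from exc
        log.info("annotate: %d promoter DMRs, %s distinct TFs",
                 category_summary["n_promoter_dmrs"], n_distinct_tfs)

    # --- validation -------------------------------------------------------
    val_cfg = cfg.get("validate", {}) or {}
    validation = None
    if inputs.get("clones") and inputs.get("cohort"):
        try:
            cohort_table = read_cohort_table(inputs["cohort"])
            matrices = {
                row: read_clone_matrix(Path(inputs["clones"]) / f"{row}.tsv")
                for row in cohort_table["sample_id"]
            }
            validation = run_validation(
                matrices, cohort_table, threshold=float(val_cfg.get("threshold", 0.5))
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'validate': {exc}") from exc
        with open(outdir / "validation.json", "w") as fh:
            json.dump(validation, fh, indent=2)
        log.info("validate: Fisher p = %g", validation["fisher_p"])

    # --- report -----------------------------------------------------------
    input_hashes = {
        k: _sha256(v) for k, v in inputs.items() if Path(str(v)).is_file()
    }
    report = {
        "schema_version": 1,
        "parameters": {"dmr": asdict(params), "annotate": ann_cfg, "validate": val_cfg},
        "input_hashes": input_hashes,
        "counts": {
            **scan_report.to_dict(),
            "category_summary": category_summary,
            "n_distinct_tfs": n_distinct_tfs,
        },
        "validation": validation,
        "provenance": {
            "seed": seed,
            "tool_version": __version__,
            "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def report_without_timestamps(report: dict) -> dict:
    """Copy of a run report with the volatile timestamp removed."""
    out = json.loads(json.dumps(report))
    out.get("provenance", {}).pop("generated_at", None)
    return out
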