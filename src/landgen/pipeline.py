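"""End-to-end pipeline: simulate (optional) -> QC -> scans -> RDA -> annotate.

Driven by a YAML config; every stage writes its artifacts under the output
directory and a manifest records versions, seeds, thresholds and stage
outputs so a run is fully reproducible from config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import map_windows_to_genes, read_bed, read_gff3, significant_genes, summarize_contrasts
from .io import read_fixture, read_sample_frame, read_vcf, write_fixture
from .ordination import gea_pipeline
from .qc import QcThresholds, filter_variants, ld_prune
from .scan import build_layer, layered_scan
from .sim import SimConfig, simulate_haplotypes, simulate_metadata

log = logging.getLogger("landgen.pipeline")

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages and return the manifest dict.

    Config keys (all optional except one of ``simulate`` / ``inputs``):

    - ``simulate``: kwargs for :class:`~landgen.sim.SimConfig`
    - ``inputs``: paths ``vcf``, ``metadata``, ``env``, ``traits``
    - ``qc``: kwargs for :class:`~landgen.qc.QcThresholds`
    - ``scan``: ``layers`` (list of I/II/III), ``span``, ``step``,
      ``top_frac``, ``gradients``, ``inner_gradient``, ``xpehh`` (bool)
    - ``rda``: ``modes``, ``condition``, ``sd_mult``, ``n_axes``,
      ``n_permutations``, ``ld_prune`` (bool)
    - ``annotation``: path to BED or GFF3 (stage skipped when absent)
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "landgen_version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }
    t_all = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"t_start": time.time() - t_all}
        return manifest["stages"][name]

    def done(rec, **extra):
        rec["seconds"] = round(time.time() - t_all - rec.pop("t_start"), 3)
        rec.update(extra)

    try:
        if "simulate" in config:
            rec = stage("simulate")
            sim_kwargs = dict(config.get("simulate") or {})
            if seed is not None:
                sim_kwargs["seed"] = seed
            sc = SimConfig(**sim_kwargs)
            frame = simulate_metadata(sc)
            panel = simulate_haplotypes(sc, frame)
            paths = write_fixture(panel, frame, None, out / "simulated")
            done(rec, config=asdict(sc) | {"predictor_corr": None}, outputs=paths)
        elif "inputs" in config:
            rec = stage("load")
            inp = config["inputs"]
            panel = read_vcf(inp["vcf"])
            frame = read_sample_frame(
                inp["metadata"], inp.get("env"), inp.get("traits")
            )
            done(rec, inputs={k: str(v) for k, v in inp.items()})
        else:
            raise ValueError("config needs a 'simulate' or 'inputs' section")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate/load", e) from e

    try:
        rec = stage("qc")
        th = QcThresholds(**(config.get("qc") or {}))
        panel, report = filter_variants(panel, th)
        report.to_json(out / "qc_report.json")
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        done(rec, thresholds=asdict(th), report=report.to_dict())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qc", e) from e

    scan_cfg = config.get("scan", {})
    layer_results = {}
    if scan_cfg:
        try:
            rec = stage("scan")
            span = int(scan_cfg.get("span", 50_000))
            step = int(scan_cfg.get("step", 25_000))
            top = float(scan_cfg.get("top_frac", 0.01))
            summaries = []
            for lid in scan_cfg.get("layers", ["I", "II", "III"]):
                layer = build_layer(
                    frame,
                    lid,
                    gradients=tuple(scan_cfg.get("gradients", ("I", "III", "IV"))),
                    inner_gradient=scan_cfg.get("inner_gradient", "II"),
                )
                res = layered_scan(
                    panel,
                    frame,
                    layer,
                    span=span,
                    step=step,
                    top_frac=top,
                    run_xpehh=bool(scan_cfg.get("xpehh", True)),
                )
                layer_results[lid] = res
                for cname, cres in res.items():
                    cres["fst"].to_csv(
                        out / f"scan_layer{lid}_{cname}_fst.tsv", sep="\t", index=False
                    )
                    if "xpehh" in cres:
                        cres["xpehh"].to_csv(
                            out / f"scan_layer{lid}_{cname}_xpehh.tsv",
                            sep="\t",
                            index=False,
                        )
                summ = summarize_contrasts(res)
                summ.insert(0, "layer", lid)
                summaries.append(summ)
            if summaries:
                pd.concat(summaries).to_csv(
                    out / "scan_summary.tsv", sep="\t", index=False
                )
            done(rec, layers=list(layer_results))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("scan", e) from e

    rda_cfg = config.get("rda", {})
    if rda_cfg:
        try:
            rec = stage("rda")
            work = panel
            if rda_cfg.get("ld_prune", True):
                kept = ld_prune(work, QcThresholds(**(config.get("qc") or {})))
                work = work.take_variants(kept)
            rda_summaries = {}
            for mode in rda_cfg.get("modes", ["environment", "phenotype"]):
                res = gea_pipeline(
                    work,
                    frame,
                    mode=mode,
                    condition_on=tuple(rda_cfg.get("condition", ("longitude", "latitude"))),
                    sd_mult=float(rda_cfg.get("sd_mult", 3.5)),
                    n_axes=int(rda_cfg.get("n_axes", 3)),
                    n_permutations=int(rda_cfg.get("n_permutations", 999)),
                    random_state=seed or 0,
                )
                res.outliers.to_csv(out / f"rda_{mode}_outliers.tsv", sep="\t", index=False)
                res.manhattan.to_csv(out / f"rda_{mode}_manhattan.tsv", sep="\t", index=False)
                summary = {
                    "retained_predictors": res.retained_predictors,
                    "eigenvalues": list(np.round(res.rda.eigenvalues_, 10)),
                    "proportion_explained": list(np.round(res.rda.proportion_explained_, 6)),
                    "r2": res.rda.r2_,
                    "adj_r2": res.rda.adj_r2_,
                    "pseudo_f": res.rda.pseudo_f_,
                    "p_value": res.rda.p_value_,
                    "n_outliers": int(len(res.outliers)),
                    "n_samples": res.n_samples,
                }
                rda_summaries[mode] = summary
                with open(out / f"rda_{mode}_result.json", "w") as fh:
                    json.dump(summary, fh, indent=1)
            done(rec, summaries=rda_summaries)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rda", e) from e

    ann_path = config.get("annotation")
    if ann_path and layer_results:
        try:
            rec = stage("annotate")
            genes = (
                read_gff3(ann_path)
                if str(ann_path).endswith((".gff", ".gff3"))
                else read_bed(ann_path)
            )
            gene_hits = {}
            for lid, res in layer_results.items():
                for cname, cres in res.items():
                    mapped = map_windows_to_genes(cres["fst"], genes)
                    gene_hits[f"{lid}:{cname}:fst"] = significant_genes(mapped)
                    if "xpehh" in cres:
                        mapped = map_windows_to_genes(cres["xpehh"], genes)
                        gene_hits[f"{lid}:{cname}:xpehh"] = significant_genes(mapped)
            with open(out / "significant_genes.json", "w") as fh:
                json.dump(gene_hits, fh, indent=1)
            done(rec, n_genes=len(genes))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("annotate", e) from e
    elif not ann_path:
        manifest["stages"]["annotate"] = {"skipped": "no annotation file configured"}

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
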