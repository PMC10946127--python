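"""Readers and writers: VCFv4.2 (phased GT), metadata/env/trait TSVs, ground truth.

The VCF writer emits plain-text VCFv4.2 with phased ``a|b`` genotypes and
``./.`` for missing diploid calls; the reader goes through cyvcf2 so anything
cyvcf2 accepts (including bgzipped files) round-trips into a
:class:`~landgen.panel.HaplotypePanel`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import HaplotypePanel
from .sim import ENV_PREDICTORS, TRAITS

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_fixture",
    "read_fixture",
    "read_sample_frame",
]

_META_COLS = [
    "sample_id",
    "population_id",
    "gradient",
    "agroecology",
    "longitude",
    "latitude",
]


def write_vcf(panel: HaplotypePanel, path) -> Path:
    """Write a panel as uncompressed VCFv4.2 with phased genotypes."""
    path = Path(path)
    h0 = panel.haplotypes[0::2, :]
    h1 = panel.haplotypes[1::2, :]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=landgen\n")
        for c in panel.chromosomes:
            fh.write(f"##contig=<ID={c},length={panel.contig_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        for j in range(panel.n_snps):
            gts = [
                "./."
                if panel.missing[i, j]
                else f"{h0[i, j]}|{h1[i, j]}"
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.chrom[j]}:{panel.pos[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def read_vcf(path, min_qual: float | None = None) -> HaplotypePanel:
    """Read a biallelic SNP VCF into a HaplotypePanel (requires phased GT).

    Unphased heterozygotes are rejected: haplotype-based scans are meaningless
    on unphased data.  Missing genotypes (``./.``) are masked.  When
    ``min_qual`` is given, records carrying a numeric QUAL below it are
    skipped (site-quality filtering is otherwise assumed done upstream).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    contig_lengths = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig="):
            body = line.split("<", 1)[1].rstrip(">")
            parts = dict(kv.split("=", 1) for kv in body.split(","))
            if "ID" in parts and "length" in parts:
                contig_lengths[parts["ID"]] = int(parts["length"])

    chrom, pos, ref, alt, haps, miss = [], [], [], [], [], []
    for var in vcf:
        if min_qual is not None and var.QUAL is not None and var.QUAL < min_qual:
            continue
        if len(var.ALT) != 1:
            raise ValueError(f"non-biallelic record at {var.CHROM}:{var.POS}")
        arr = var.genotype.array()
        a0, a1, phased = arr[:, 0], arr[:, 1], arr[:, 2]
        m = (a0 < 0) | (a1 < 0)
        het_unphased = (~m) & (a0 != a1) & (phased == 0)
        if np.any(het_unphased):
            raise ValueError(
                f"unphased heterozygote at {var.CHROM}:{var.POS}; phased GT required"
            )
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        h = np.empty(2 * len(samples), dtype=np.uint8)
        h[0::2] = np.where(m, 0, a0)
        h[1::2] = np.where(m, 0, a1)
        haps.append(h)
        miss.append(m)

    return HaplotypePanel(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        haplotypes=np.array(haps, dtype=np.uint8).T,
        sample_ids=samples,
        missing=np.array(miss, dtype=bool).T,
        contig_lengths=contig_lengths,
    )


def write_fixture(panel, frame, specs: dict | None, out_dir) -> dict:
    """Serialize a simulated dataset: VCF, metadata/env/trait TSVs, ground truth.

    ``specs`` may carry lists under keys ``sweeps`` / ``clines`` and a dict
    under ``qtl_effects``; they are stored verbatim in ``ground_truth.json``
    so recovery tests never re-derive them.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "metadata": out / "samples.tsv",
        "env": out / "environment.tsv",
        "traits": out / "traits.tsv",
        "truth": out / "ground_truth.json",
    }
    write_vcf(panel, paths["vcf"])
    frame[_META_COLS].to_csv(paths["metadata"], sep="\t", index=False)
    frame[["sample_id"] + ENV_PREDICTORS].to_csv(paths["env"], sep="\t", index=False)
    frame[["sample_id"] + TRAITS].to_csv(paths["traits"], sep="\t", index=False)
    truth = {"sweeps": [], "clines": [], "qtl_effects": {}}
    if specs:
        truth["sweeps"] = [
            s.to_dict() if hasattr(s, "to_dict") else s for s in specs.get("sweeps", [])
        ]
        truth["clines"] = [
            s.to_dict() if hasattr(s, "to_dict") else s for s in specs.get("clines", [])
        ]
        truth["qtl_effects"] = specs.get("qtl_effects", {})
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_sample_frame(metadata_path, env_path=None, traits_path=None) -> pd.DataFrame:
    """Load and join the metadata, environment and trait tables on sample_id."""
    frame = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    for p in (env_path, traits_path):
        if p is not None:
            t = pd.read_csv(p, sep="\t", dtype={"sample_id": str})
            frame = frame.merge(t, on="sample_id", how="left", validate="1:1")
    return frame


def read_fixture(dir_path):
    """Load a fixture directory written by :func:`write_fixture`.

    Returns (panel, frame, ground_truth dict).
    """
    d = Path(dir_path)
    panel = read_vcf(d / "genotypes.vcf")
    frame = read_sample_frame(d / "samples.tsv", d / "environment.tsv", d / "traits.tsv")
    with open(d / "ground_truth.json") as fh:
        truth = json.load(fh)
    return panel, frame, truth
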