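"""Window-to-gene mapping, gene-set enrichment, and cross-contrast summaries.

Gene annotation is accepted as BED (0-based half-open, converted on read) or
GFF3 (1-based inclusive); the internal convention is 1-based inclusive.  A
gene maps to a window iff the two intervals share at least one base pair.
Enrichment of a query gene list against user-supplied gene sets is the
upper-tail hypergeometric test with Benjamini–Hochberg correction across
sets (significance reported at q < 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneInterval",
    "read_bed",
    "read_gff3",
    "map_windows_to_genes",
    "hypergeometric_enrichment",
    "summarize_contrasts",
]


@dataclass(frozen=True)
class GeneInterval:
    """A gene interval, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")


def read_bed(path) -> list:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            strand = f[5] if len(f) > 5 else "."
            genes.append(
                GeneInterval(name, f[0], int(f[1]) + 1, int(f[2]), strand)
            )
    return genes


def read_gff3(path, feature_types=("gene",)) -> list:
    """Read gene intervals from GFF3 (already 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}-{f[4]}"
            genes.append(GeneInterval(name, f[0], int(f[3]), int(f[4]), f[6]))
    return genes


def map_windows_to_genes(windows: pd.DataFrame, genes: list) -> pd.DataFrame:
    """Map each window to the genes its interval intersects by >= 1 bp.

    Returns the window table with a ``genes`` column (list of gene names).
    Genes on chromosomes absent from the window tiling are skipped and
    counted in a warning.
    """
    known = set(windows["chrom"].astype(str))
    by_chrom: dict = {}
    skipped = 0
    for g in genes:
        if str(g.chrom) not in known:
            skipped += 1
            continue
        by_chrom.setdefault(str(g.chrom), []).append(g)
    if skipped:
        warnings.warn(f"{skipped} genes on chromosomes absent from the window tiling")

    for c in by_chrom:
        by_chrom[c].sort(key=lambda g: g.start)

    out = windows.copy()
    mapped = []
    for _, w in out.iterrows():
        gl = [
            g.gene
            for g in by_chrom.get(str(w["chrom"]), [])
            if g.start <= w["end"] and g.end >= w["start"]
        ]
        mapped.append(gl)
    out["genes"] = mapped
    return out


def significant_genes(mapped_windows: pd.DataFrame) -> list:
    """Deduplicated union of genes over significant windows, first-hit order."""
    seen: dict = {}
    sig = mapped_windows[mapped_windows.get("significant", False) == True]  # noqa: E712
    for gl in sig["genes"]:
        for g in gl:
            seen.setdefault(g, None)
    return list(seen)


def hypergeometric_enrichment(
    query: list, gene_sets: dict, universe: list, q_threshold: float = 0.1
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query against gene sets.

    For a universe of N genes, a set of K, and a query of n with k overlap,
    p = P(X >= k), X ~ Hypergeometric(N, K, n).  Benjamini–Hochberg q across
    the supplied sets; ``significant`` flags q < ``q_threshold``.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty gene universe")
    q = set(query) & uni
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & uni
        k = len(q & mem)
        p = float(hypergeom.sf(k - 1, len(uni), len(mem), len(q)))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(mem),
                "query_size": len(q),
                "universe_size": len(uni),
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < q_threshold
    return out


def summarize_contrasts(layer_results: dict) -> pd.DataFrame:
    """Per-contrast mean FST, significant-window counts, and overlap summary.

    ``layer_results`` is the output of :func:`landgen.scan.layered_scan`;
    contrast order is preserved.
    """
    rows = []
    for name, res in layer_results.items():
        fst = res["fst"]
        row = {
            "contrast": name,
            "mean_fst": res["mean_fst"],
            "n_windows": int(fst["stat"].notna().sum()),
            "n_sig_fst": int(fst["significant"].sum()),
        }
        if "xpehh" in res:
            row["n_sig_xpehh"] = int(res["xpehh"]["significant"].sum())
            ov = res["overlap"]
            row["n_overlap"] = ov["n_overlap"]
            row["pct_overlap_union"] = ov["pct_of_union"]
            row["pct_overlap_fst"] = ov["pct_of_a"]
            row["pct_overlap_xpehh"] = ov["pct_of_b"]
        rows.append(row)
    return pd.DataFrame(rows)
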