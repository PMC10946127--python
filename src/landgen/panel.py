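"""Phased haplotype panel: the in-memory substrate of every scan.

A :class:`HaplotypePanel` holds biallelic, phased diploid genotypes as a
``(2 * n_samples, n_snps)`` 0/1 haplotype matrix plus per-variant chromosome,
1-based position and ref/alt alleles.  Missingness is recorded at the diploid
genotype level (a whole genotype is either observed or missing, matching the
``./.`` VCF convention); haplotype entries under a missing genotype are
placeholders and must never be read directly — use :meth:`dosage`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HaplotypePanel"]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with variant coordinates.

    Parameters
    ----------
    chrom : array of str, shape (n_snps,)
        Chromosome identifier per variant.
    pos : array of int, shape (n_snps,)
        1-based physical position, strictly increasing within chromosome.
    ref, alt : arrays of str, shape (n_snps,)
        Reference / alternate allele.
    haplotypes : array of uint8, shape (2 * n_samples, n_snps)
        Rows ``2*i`` and ``2*i + 1`` are the two phased haplotypes of sample
        ``i``; entries are 0 (ref) or 1 (alt).
    sample_ids : list of str
    missing : bool array, shape (n_samples, n_snps), optional
        True where the diploid genotype is unobserved.
    contig_lengths : dict, optional
        Chromosome id -> length in bp.  Defaults to the last position seen.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    sample_ids: list
    missing: np.ndarray | None = None
    contig_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.sample_ids = list(self.sample_ids)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                "haplotype matrix must have two rows per sample "
                f"(got {self.haplotypes.shape[0]} rows, {len(self.sample_ids)} samples)"
            )
        if self.haplotypes.shape[1] != self.pos.shape[0]:
            raise ValueError("haplotype columns must match number of variants")
        if self.missing is None:
            self.missing = np.zeros((self.n_samples, self.n_snps), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (self.n_samples, self.n_snps):
                raise ValueError("missing mask must be (n_samples, n_snps)")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        if not self.contig_lengths:
            self.contig_lengths = {
                c: int(self.pos[self.chrom == c].max()) for c in self.chromosomes
            }

    # ------------------------------------------------------------------ basic
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return int(self.pos.shape[0])

    @property
    def chromosomes(self) -> list:
        """Chromosome ids in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def variant_ids(self) -> np.ndarray:
        return np.array(
            [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
        )

    # ------------------------------------------------------------- genotypes
    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage per sample, NaN where the genotype is missing.

        Returns
        -------
        ndarray of float, shape (n_samples, n_snps)
        """
        d = (
            self.haplotypes[0::2, :].astype(np.float64)
            + self.haplotypes[1::2, :].astype(np.float64)
        )
        d[self.missing] = np.nan
        return d

    def genotype_counts(self, sample_idx=None) -> np.ndarray:
        """Counts of (hom-ref, het, hom-alt) per variant over observed genotypes.

        Returns
        -------
        ndarray of int, shape (n_snps, 3)
        """
        d = self.dosage()
        if sample_idx is not None:
            d = d[np.asarray(sample_idx), :]
        out = np.zeros((self.n_snps, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(d == g, axis=0)
        return out

    def alt_frequency(self, sample_idx=None) -> np.ndarray:
        """Observed alternate-allele frequency per variant (NaN if fully missing)."""
        d = self.dosage()
        if sample_idx is not None:
            d = d[np.asarray(sample_idx), :]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing.mean(axis=0)

    # -------------------------------------------------------------- subsets
    def take_variants(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            haplotypes=self.haplotypes[:, idx],
            sample_ids=self.sample_ids,
            missing=self.missing[:, idx],
            contig_lengths=dict(self.contig_lengths),
        )

    def take_samples(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        hap_rows = np.empty(2 * idx.size, dtype=np.int64)
        hap_rows[0::2] = 2 * idx
        hap_rows[1::2] = 2 * idx + 1
        return HaplotypePanel(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            haplotypes=self.haplotypes[hap_rows, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            missing=self.missing[idx, :],
            contig_lengths=dict(self.contig_lengths),
        )

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=np.int64)

    def haplotype_rows(self, sample_idx) -> np.ndarray:
        """Row indices into ``haplotypes`` for the given sample indices."""
        sample_idx = np.asarray(sample_idx)
        rows = np.empty(2 * sample_idx.size, dtype=np.int64)
        rows[0::2] = 2 * sample_idx
        rows[1::2] = 2 * sample_idx + 1
        return rows

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            haplotypes=self.haplotypes.copy(),
            sample_ids=list(self.sample_ids),
            missing=self.missing.copy(),
            contig_lengths=dict(self.contig_lengths),
        )

    def variant_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref,
                "alt": self.alt,
            }
        )
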