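"""Genotype-level quality control: call rate, MAF, Hardy–Weinberg, LD pruning.

Filters are applied in a fixed order — call rate, then minor allele
frequency, then the Hardy–Weinberg exact test — and the removals of each
step are recorded.  LD pruning scans sliding windows of variants and greedily
removes the lower-MAF member of any pair whose genotype-dosage r-squared
exceeds the threshold, iterating until the retained set is stable (the
classic ``--indep-pairwise`` style of pruning, with an explicit deterministic
tie-break).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from math import lgamma

import numpy as np
import pandas as pd

__all__ = ["QcThresholds", "QcReport", "hwe_exact_test", "filter_variants", "ld_r2", "ld_prune"]


@dataclass
class QcThresholds:
    """Filter thresholds; defaults follow common WGS practice.

    Variants are removed when call rate < ``call_rate_min``, MAF <
    ``maf_min`` (strict: MAF exactly at the threshold is retained), or HWE
    exact p < ``hwe_p_min``.  LD pruning uses windows of ``ld_window``
    variants advanced by ``ld_step``, removing within-window pairs with
    r-squared > ``ld_r2_max``.
    """

    maf_min: float = 0.05
    call_rate_min: float = 0.7
    hwe_p_min: float = 5e-6
    ld_window: int = 100
    ld_step: int = 10
    ld_r2_max: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")
        if not (0.0 <= self.call_rate_min <= 1.0):
            raise ValueError("call_rate_min must lie in [0, 1]")
        if not (0.0 <= self.hwe_p_min <= 1.0):
            raise ValueError("hwe_p_min must lie in [0, 1]")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must be <= ld_window")
        if not (0.0 <= self.ld_r2_max <= 1.0):
            raise ValueError("ld_r2_max must lie in [0, 1]")


@dataclass
class QcReport:
    """Per-filter removal accounting; removals plus retained equal the input."""

    n_input: int
    removed: dict = field(default_factory=dict)
    n_retained: int = 0
    n_samples: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "retained", "n_removed": self.n_retained})
        return pd.DataFrame(rows)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional test for Hardy–Weinberg equilibrium at one site.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more probable
    than the observed one (standard exact test, not mid-p).  A monomorphic
    site has a single compatible configuration and returns p = 1.
    """
    for v in (n_hom_ref, n_het, n_hom_alt):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotyped sample required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # log P(het = h | allele counts) up to the shared normalizing constant:
    # P ∝ n! / (hom_common! * het! * hom_rare!) * 2^het
    def log_weight(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return h * np.log(2.0) - lgamma(h + 1) - lgamma(rare_hom + 1) - lgamma(common_hom + 1)

    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logw = np.array([log_weight(int(h)) for h in hets])
    probs = np.exp(logw - logw.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_variants(panel, thresholds: QcThresholds | None = None):
    """Apply call-rate, MAF and HWE filters to a panel.

    Returns (filtered panel, :class:`QcReport`).  The filters run in the
    fixed order call rate -> MAF -> HWE so each removal count is conditional
    on the previous filters.  MAF and HWE use observed (non-missing)
    genotypes only.
    """
    th = thresholds or QcThresholds()
    m = panel.n_snps
    keep = np.ones(m, dtype=bool)
    removed = {}

    cr = panel.call_rate()
    bad = keep & (cr < th.call_rate_min)
    removed["call_rate"] = int(bad.sum())
    keep &= ~bad

    freq = panel.alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    bad = keep & (np.isnan(maf) | (maf < th.maf_min))
    removed["maf"] = int(bad.sum())
    keep &= ~bad

    counts = panel.genotype_counts()
    hwe_bad = np.zeros(m, dtype=bool)
    for j in np.flatnonzero(keep):
        p = hwe_exact_test(int(counts[j, 0]), int(counts[j, 1]), int(counts[j, 2]))
        hwe_bad[j] = p < th.hwe_p_min
    removed["hwe"] = int(hwe_bad.sum())
    keep &= ~hwe_bad

    report = QcReport(
        n_input=m,
        removed=removed,
        n_retained=int(keep.sum()),
        n_samples=panel.n_samples,
    )
    if report.n_retained == 0:
        warnings.warn("no variants survive QC filtering")
    return panel.take_variants(np.flatnonzero(keep)), report


def ld_r2(dosage_i, dosage_j) -> float:
    """Squared Pearson correlation of two genotype-dosage vectors.

    Missing entries (NaN) are excluded pairwise.  If either vector has zero
    variance over the complete pairs the correlation is undefined for
    pruning purposes and 0 is returned.
    """
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        return 0.0
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r * r


def _window_r2(D):
    """r^2 matrix for a complete (no-NaN) dosage block of shape (n, k)."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(D, rowvar=False)
    c = np.nan_to_num(c, nan=0.0)
    return c * c


def ld_prune(panel, thresholds: QcThresholds | None = None) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept variant indices.

    Within each window of ``ld_window`` consecutive variants (per
    chromosome), every retained pair with r-squared strictly above
    ``ld_r2_max`` loses its lower-MAF member (tie broken against the later
    position).  Windows advance by ``ld_step`` and the scan repeats until no
    further removal occurs, so the result is deterministic and no surviving
    within-window pair exceeds the threshold.
    """
    th = thresholds or QcThresholds()
    D = panel.dosage()
    freq = panel.alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.nan_to_num(np.minimum(freq, 1.0 - freq))
    keep = np.ones(panel.n_snps, dtype=bool)
    has_nan = np.isnan(D).any(axis=0)

    chrom_groups = [np.flatnonzero(panel.chrom == c) for c in panel.chromosomes]
    changed = True
    while changed:
        changed = False
        for sites in chrom_groups:
            survivors = sites[keep[sites]]  # windows slide over surviving variants
            nloc = survivors.size
            start = 0
            while start < nloc:
                win = survivors[start : start + th.ld_window]
                live = win[keep[win]]
                if live.size > 1:
                    if not has_nan[live].any():
                        r2 = _window_r2(D[:, live])
                    else:
                        r2 = None
                    for ii in range(live.size):
                        vi = live[ii]
                        if not keep[vi]:
                            continue
                        for jj in range(ii + 1, live.size):
                            vj = live[jj]
                            if not keep[vi]:
                                break
                            if not keep[vj]:
                                continue
                            val = r2[ii, jj] if r2 is not None else ld_r2(D[:, vi], D[:, vj])
                            if val > th.ld_r2_max:
                                if maf[vi] < maf[vj]:
                                    drop = vi
                                elif maf[vj] < maf[vi]:
                                    drop = vj
                                else:  # tie: drop the later position
                                    drop = vj
                                keep[drop] = False
                                changed = True
                start += th.ld_step
    return np.flatnonzero(keep)
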