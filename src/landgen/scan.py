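"""Selection-signature scans: Weir–Cockerham FST, EHH/iHH/XP-EHH, windows.

Two complementary statistics are computed over sliding genomic windows
(default 50 kb span, 25 kb step):

* the Weir & Cockerham (1984) moment estimator of FST per biallelic site,
  averaged per window — sensitive to older differentiation;
* XP-EHH, the standardized log-ratio of integrated extended haplotype
  homozygosity (iHH) between two populations at each site, averaged per
  window — sensitive to recent, near-fixed sweeps.

Window significance is empirical: windows are ranked on the statistic and the
rank divided by the number of windows; the top fraction (default 1%) is
flagged.  A layered driver expands a grouping rule (by gradient, by
agroecology pooled across gradients, or by agroecology within one gradient)
into pairwise contrasts and runs both scans plus their overlap on each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FstComponents",
    "EhhCurve",
    "LayerSpec",
    "wc_fst_per_site",
    "wc_fst_sites",
    "make_windows",
    "windowed_fst",
    "ehh",
    "ihh",
    "xpehh",
    "empirical_p",
    "overlap_windows",
    "build_layer",
    "layered_scan",
]

EHH_CUTOFF = 0.05  # stop extending once homozygosity decays below this
MIN_CORE_MAF = 0.05  # cores rarer than this (pooled) are skipped in XP-EHH


# --------------------------------------------------------------------------
# Weir-Cockerham FST
# --------------------------------------------------------------------------


@dataclass
class FstComponents:
    """Per-site Weir–Cockerham variance components.

    ``a`` is the among-population component, ``b`` among individuals within
    populations, ``c`` within individuals; ``theta = a / (a + b + c)``.
    ``theta`` is NaN where the site is monomorphic across both populations.
    """

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0.0:
            return float("nan")
        return self.a / denom


def wc_fst_sites(counts1: np.ndarray, counts2: np.ndarray):
    """Vectorized two-population Weir–Cockerham components.

    Parameters
    ----------
    counts1, counts2 : int arrays, shape (m, 3)
        Per-site (hom-ref, het, hom-alt) genotype counts in each population.

    Returns
    -------
    a, b, c, theta : float arrays, shape (m,)
        theta is NaN where undefined (a+b+c = 0 or a population unobserved).
    """
    counts1 = np.atleast_2d(np.asarray(counts1, dtype=float))
    counts2 = np.atleast_2d(np.asarray(counts2, dtype=float))
    r = 2.0
    n1 = counts1.sum(axis=1)
    n2 = counts2.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (2 * counts1[:, 2] + counts1[:, 1]) / (2 * n1)
        p2 = (2 * counts2[:, 2] + counts2[:, 1]) / (2 * n2)
        h1 = counts1[:, 1] / n1
        h2 = counts2[:, 1] / n2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)
    bad = (n1 == 0) | (n2 == 0) | (nbar <= 1.0)
    for arr in (a, b, c, theta):
        arr[bad] = np.nan
    return a, b, c, theta


def wc_fst_per_site(counts_pop1, counts_pop2) -> FstComponents:
    """Weir–Cockerham components at a single site from genotype-count triples."""
    a, b, c, _ = wc_fst_sites(
        np.asarray(counts_pop1)[None, :], np.asarray(counts_pop2)[None, :]
    )
    return FstComponents(a=float(a[0]), b=float(b[0]), c=float(c[0]))


# --------------------------------------------------------------------------
# windows
# --------------------------------------------------------------------------


def make_windows(contig_lengths: dict, span: int = 50_000, step: int = 25_000) -> pd.DataFrame:
    """Tile each chromosome with 1-based overlapping windows.

    Window k covers ``[1 + k*step, k*step + span]`` for
    ``k = 0 .. floor((length - span)/step) + 1`` (never below 0), so the last
    window is truncated at the chromosome end by at most ``span - step`` and
    a chromosome shorter than the span yields a single truncated window.
    """
    if span < step:
        raise ValueError("window span must be >= step")
    rows = []
    for chrom, length in contig_lengths.items():
        length = int(length)
        k_last = max(0, (length - span) // step + 1)
        for k in range(k_last + 1):
            rows.append(
                {
                    "chrom": str(chrom),
                    "start": 1 + k * step,
                    "end": min(k * step + span, length),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_aggregate(windows: pd.DataFrame, chrom, pos, values, span, step, extra=None):
    """Mean of per-site values over each window (NaN sites ignored).

    ``extra`` maps column name -> per-site array summed (not averaged) per
    window over sites where the main value is defined.
    """
    values = np.asarray(values, dtype=float)
    n_win = len(windows)
    sums = np.zeros(n_win)
    counts = np.zeros(n_win, dtype=np.int64)
    extra = extra or {}
    extra_sums = {k: np.zeros(n_win) for k in extra}

    win_chrom = windows["chrom"].to_numpy()
    chrom_first = {}
    chrom_nwin = {}
    for i, c in enumerate(win_chrom):
        chrom_first.setdefault(c, i)
        chrom_nwin[c] = chrom_nwin.get(c, 0) + 1

    max_off = int(np.ceil(span / step))
    for c in chrom_first:
        sel = np.flatnonzero(np.asarray(chrom) == c)
        if sel.size == 0:
            continue
        p = np.asarray(pos)[sel]
        v = values[sel]
        ok = ~np.isnan(v)
        sel, p, v = sel[ok], p[ok], v[ok]
        if sel.size == 0:
            continue
        k_max = (p - 1) // step
        for off in range(max_off):
            k = k_max - off
            valid = (k >= 0) & (k < chrom_nwin[c]) & (p <= k * step + span)
            gi = chrom_first[c] + k[valid]
            np.add.at(sums, gi, v[valid])
            np.add.at(counts, gi, 1)
            for name, arr in extra.items():
                np.add.at(extra_sums[name], gi, np.asarray(arr)[sel[valid]])

    out = windows.copy()
    with np.errstate(invalid="ignore"):
        out["stat"] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out["n_snps"] = counts
    for name, s in extra_sums.items():
        out[name] = s
    return out


def windowed_fst(panel, contrast, windows: pd.DataFrame, span=50_000, step=25_000) -> pd.DataFrame:
    """Mean per-window Weir–Cockerham theta for a two-population contrast.

    ``contrast`` is a pair of sample-index arrays.  The primary window
    statistic (column ``stat``) is the arithmetic mean of per-site theta over
    sites where it is defined; a ratio-of-sums column ``stat_ratio``
    (sum a / sum(a+b+c)) is also emitted.  Windows without informative SNPs
    carry NaN and are excluded from downstream ranking.
    """
    idx_a, idx_b = contrast
    c1 = panel.genotype_counts(idx_a)
    c2 = panel.genotype_counts(idx_b)
    a, b, c, theta = wc_fst_sites(c1, c2)
    denom = a + b + c
    ok = ~np.isnan(theta)
    a_ = np.where(ok, a, np.nan)
    d_ = np.where(ok, denom, np.nan)
    out = _window_aggregate(
        windows,
        panel.chrom,
        panel.pos,
        theta,
        span,
        step,
        extra={"_sum_a": np.nan_to_num(a_), "_sum_d": np.nan_to_num(d_)},
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["stat_ratio"] = np.where(out["_sum_d"] != 0, out["_sum_a"] / out["_sum_d"], np.nan)
    return out.drop(columns=["_sum_a", "_sum_d"])


# --------------------------------------------------------------------------
# EHH / iHH / XP-EHH
# --------------------------------------------------------------------------


@dataclass
class EhhCurve:
    """EHH decay curve around a core locus for one core allele.

    Positions are absolute bp; each direction starts at the core with EHH 1
    and may end with one value below the stopping cutoff (recorded but not
    integrated by :func:`ihh`).
    """

    core_index: int
    core_pos: int
    core_allele: int
    left_pos: np.ndarray = field(default_factory=lambda: np.array([]))
    left_ehh: np.ndarray = field(default_factory=lambda: np.array([]))
    right_pos: np.ndarray = field(default_factory=lambda: np.array([]))
    right_ehh: np.ndarray = field(default_factory=lambda: np.array([]))


def _ehh_direction(H, rows, js, cutoff):
    """EHH values walking over site columns ``js`` for haplotype ``rows``.

    Haplotype groups are refined incrementally: each step splits every group
    by the next site's allele via an O(n) bincount relabeling (group labels
    stay < n, so keys ``2*label + allele`` stay < 2n).
    """
    n = rows.size
    pair_tot = n * (n - 1)
    labels = np.zeros(n, dtype=np.int64)
    vals = []
    sub = H[rows, :]
    for j in js:
        key = labels * 2 + sub[:, j]
        cnt = np.bincount(key, minlength=2 * n)
        e = float((cnt * (cnt - 1)).sum()) / pair_tot
        relabel = np.cumsum(cnt > 0) - 1
        labels = relabel[key]
        vals.append(e)
        if e < cutoff:
            break
    return np.array(vals)


def ehh(panel, sample_idx, core_index: int, core_allele: int, cutoff: float = EHH_CUTOFF) -> EhhCurve:
    """Extended haplotype homozygosity around a core site in one population.

    EHH at offset d is the probability that two randomly drawn core-allele
    carrier haplotypes are identical over every site from the core out to d;
    it equals 1 at the core and is non-increasing outward.  Computation in a
    direction stops once EHH drops below ``cutoff``.
    """
    rows = panel.haplotype_rows(np.asarray(sample_idx))
    obs = ~np.repeat(panel.missing[np.asarray(sample_idx), core_index], 2)
    rows = rows[obs]
    carriers = rows[panel.haplotypes[rows, core_index] == core_allele]
    if carriers.size < 2:
        raise ValueError("EHH undefined: fewer than 2 carriers of the core allele")

    chrom = panel.chrom[core_index]
    on_chrom = np.flatnonzero(panel.chrom == chrom)
    right_js = on_chrom[on_chrom > core_index]
    left_js = on_chrom[on_chrom < core_index][::-1]

    right = _ehh_direction(panel.haplotypes, carriers, right_js, cutoff)
    left = _ehh_direction(panel.haplotypes, carriers, left_js, cutoff)
    core_pos = int(panel.pos[core_index])
    return EhhCurve(
        core_index=core_index,
        core_pos=core_pos,
        core_allele=core_allele,
        left_pos=np.concatenate([[core_pos], panel.pos[left_js[: left.size]]]),
        left_ehh=np.concatenate([[1.0], left]),
        right_pos=np.concatenate([[core_pos], panel.pos[right_js[: right.size]]]),
        right_ehh=np.concatenate([[1.0], right]),
    )


def ihh(curve: EhhCurve, cutoff: float = EHH_CUTOFF) -> float:
    """Integrated EHH: trapezoidal area of the decay curve over bp, both sides.

    Only points with EHH >= ``cutoff`` are integrated; the final sub-cutoff
    point of a direction (if any) is excluded.  A degenerate single-point
    curve has iHH 0.
    """
    total = 0.0
    for p, v in ((curve.left_pos, curve.left_ehh), (curve.right_pos, curve.right_ehh)):
        keep = v >= cutoff
        if keep.sum() < 2:
            continue
        d = np.abs(p[keep] - curve.core_pos).astype(float)
        total += float(np.trapezoid(v[keep], d))
    return total


def _pop_site_ihh(Hpop, core_j, pos, chrom_sites, cutoff):
    """Allele-count-weighted iHH at one core site for one population.

    ``Hpop`` is the population's haplotype submatrix.  Computes per-allele
    iHH among carriers (alleles with >= 2 carriers) and combines them with
    weights proportional to carrier count, so the measure stays defined when
    one allele is rare or absent.  Returns NaN when no allele has two
    carriers.
    """
    core_allele = Hpop[:, core_j]
    pos_core = float(pos[core_j])
    ci = int(np.searchsorted(chrom_sites, core_j))
    parts = []
    for al in (0, 1):
        carriers = np.flatnonzero(core_allele == al)
        n = carriers.size
        if n < 2:
            continue
        pair_tot = n * (n - 1)
        area = 0.0
        for js in (chrom_sites[ci + 1 :], chrom_sites[:ci][::-1]):
            labels = np.zeros(n, dtype=np.int64)
            prev_e, prev_d = 1.0, 0.0
            for j in js:
                key = labels * 2 + Hpop[carriers, j]
                cnt = np.bincount(key, minlength=2 * n)
                e = float((cnt * (cnt - 1)).sum()) / pair_tot
                if e < cutoff:
                    break
                relabel = np.cumsum(cnt > 0) - 1
                labels = relabel[key]
                d = abs(float(pos[j]) - pos_core)
                area += 0.5 * (prev_e + e) * (d - prev_d)
                prev_e, prev_d = e, d
        parts.append((n, area))
    if not parts:
        return float("nan")
    w = np.array([p[0] for p in parts], dtype=float)
    v = np.array([p[1] for p in parts], dtype=float)
    return float(np.sum(w / w.sum() * v))


try:  # compiled fast path for genome-wide scans
    from numba import njit

    @njit(cache=True)
    def _ihh_chrom_kernel(H, sites, pos, use, cutoff, out):  # pragma: no cover
        n = H.shape[0]
        ns = sites.size
        labels = np.empty(n, np.int64)
        key = np.empty(n, np.int64)
        cnt = np.empty(2 * n, np.int64)
        carriers = np.empty(n, np.int64)
        for si in range(ns):
            j0 = sites[si]
            if not use[j0]:
                out[j0] = np.nan
                continue
            total = 0.0
            wsum = 0.0
            for al in range(2):
                ncar = 0
                for h in range(n):
                    if H[h, j0] == al:
                        carriers[ncar] = h
                        ncar += 1
                if ncar < 2:
                    continue
                pair_tot = ncar * (ncar - 1)
                area = 0.0
                for direction in range(2):
                    for c in range(ncar):
                        labels[c] = 0
                    prev_e = 1.0
                    prev_d = 0.0
                    ii = si
                    while True:
                        ii = ii + 1 if direction == 0 else ii - 1
                        if ii < 0 or ii >= ns:
                            break
                        j = sites[ii]
                        for t in range(2 * ncar):
                            cnt[t] = 0
                        for c in range(ncar):
                            kk = labels[c] * 2 + H[carriers[c], j]
                            key[c] = kk
                            cnt[kk] += 1
                        s = 0
                        for t in range(2 * ncar):
                            s += cnt[t] * (cnt[t] - 1)
                        e = s / pair_tot
                        if e < cutoff:
                            break
                        lab = 0
                        for t in range(2 * ncar):
                            if cnt[t] > 0:
                                cnt[t] = lab
                                lab += 1
                        for c in range(ncar):
                            labels[c] = cnt[key[c]]
                        d = abs(pos[j] - pos[j0])
                        area += 0.5 * (prev_e + e) * (d - prev_d)
                        prev_e = e
                        prev_d = d
                total += ncar * area
                wsum += ncar
            out[j0] = total / wsum if wsum > 0 else np.nan

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _pop_ihh_all_sites(Hpop, chrom_sites, pos, use, cutoff):
    """Allele-count-weighted iHH at every usable core site of one chromosome."""
    out = np.full(pos.shape[0], np.nan)
    if _HAVE_NUMBA:
        _ihh_chrom_kernel(
            Hpop,
            chrom_sites.astype(np.int64),
            pos.astype(np.float64),
            use,
            float(cutoff),
            out,
        )
    else:
        for j in chrom_sites:
            if use[j]:
                out[j] = _pop_site_ihh(Hpop, j, pos, chrom_sites, cutoff)
    return out


def xpehh(
    panel,
    pop_a_idx,
    pop_b_idx,
    windows: pd.DataFrame | None = None,
    span: int = 50_000,
    step: int = 25_000,
    cutoff: float = EHH_CUTOFF,
    min_maf: float = MIN_CORE_MAF,
):
    """Cross-population EHH scan between two populations.

    Per site the unstandardized score is ``ln(iHH_A / iHH_B)`` with iHH the
    allele-count-weighted integrated EHH in each population; scores are then
    standardized genome-wide (mean 0, SD 1 over defined sites).  Positive
    values indicate reduced haplotype diversity (selection) in population A,
    negative in population B.  Sites where either iHH is 0 or undefined, or
    whose pooled minor-allele frequency is below ``min_maf``, are excluded.

    Returns
    -------
    sites : DataFrame with chrom, pos, raw and standardized scores
    windows : DataFrame of per-window mean standardized score, or None when
        no window frame is given.
    """
    pop_a_idx = np.asarray(pop_a_idx)
    pop_b_idx = np.asarray(pop_b_idx)
    Ha = np.ascontiguousarray(panel.haplotypes[panel.haplotype_rows(pop_a_idx), :])
    Hb = np.ascontiguousarray(panel.haplotypes[panel.haplotype_rows(pop_b_idx), :])
    pos = panel.pos

    freq = (Ha.sum(axis=0) + Hb.sum(axis=0)) / (Ha.shape[0] + Hb.shape[0])
    maf = np.minimum(freq, 1 - freq)

    use = maf >= min_maf
    raw = np.full(panel.n_snps, np.nan)
    for chrom in panel.chromosomes:
        chrom_sites = np.flatnonzero(panel.chrom == chrom)
        ia = _pop_ihh_all_sites(Ha, chrom_sites, pos, use, cutoff)
        ib = _pop_ihh_all_sites(Hb, chrom_sites, pos, use, cutoff)
        ok = (ia > 0.0) & (ib > 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw[ok] = np.log(ia[ok] / ib[ok])

    ok = ~np.isnan(raw)
    if ok.sum() >= 2 and np.nanstd(raw) > 0:
        z = (raw - np.nanmean(raw)) / np.nanstd(raw)
    else:
        z = raw.copy()
    sites = pd.DataFrame(
        {"chrom": panel.chrom, "pos": panel.pos, "xpehh_raw": raw, "xpehh": z}
    )
    win = None
    if windows is not None:
        win = _window_aggregate(windows, panel.chrom, panel.pos, z, span, step)
    return sites, win


# --------------------------------------------------------------------------
# empirical significance and overlap
# --------------------------------------------------------------------------


def empirical_p(
    window_stats: pd.DataFrame,
    two_sided: bool = False,
    stat_col: str = "stat",
    top_frac: float = 0.01,
) -> pd.DataFrame:
    """Rank-based empirical window p-values.

    One-sided (FST): p = rank/N with rank 1 the largest statistic.  Two-sided
    (XP-EHH): each window gets its tail's rank-based p over all N windows and
    a signed -log10 p carrying the statistic's sign.  Ties share the maximum
    (worst) rank of their block.  Windows whose statistic is undefined are
    excluded from N and carry NaN.  The significance flag marks the top
    ``top_frac`` of windows: with all values distinct exactly
    floor(top_frac * N) windows are flagged.
    """
    v = window_stats[stat_col].to_numpy(dtype=float)
    defined = ~np.isnan(v)
    n = int(defined.sum())
    if n == 0:
        raise ValueError("all window statistics are undefined")
    out = window_stats.copy()
    vals = v[defined]
    order = np.sort(vals)
    # rank with max-tie convention via counts of >= / <=
    ge = n - np.searchsorted(order, vals, side="left")  # count of values >= v
    le = np.searchsorted(order, vals, side="right")  # count of values <= v

    p = np.full(v.shape, np.nan)
    slp = np.full(v.shape, np.nan)
    max_rank = int(np.floor(top_frac * n + 1e-9))
    sig = np.zeros(v.shape, dtype=bool)
    if two_sided:
        sign = np.where(vals >= 0, 1.0, -1.0)
        rank = np.where(vals >= 0, ge, le)
        p[defined] = rank / n
        slp[defined] = sign * (-np.log10(rank / n))
        sig[defined] = rank <= max_rank
    else:
        p[defined] = ge / n
        slp[defined] = -np.log10(ge / n)
        sig[defined] = ge <= max_rank
    out["p"] = p
    out["signed_log10p"] = slp
    out["significant"] = sig
    return out


def overlap_windows(stats_a: pd.DataFrame, stats_b: pd.DataFrame) -> dict:
    """Overlap report between the significant window sets of two scans.

    The denominator of an overlap percentage is ambiguous, so all three
    candidates are reported: percent of the union, of set A, and of set B.
    """
    key_cols = ["chrom", "start", "end"]
    ka = stats_a[key_cols].apply(tuple, axis=1)
    kb = stats_b[key_cols].apply(tuple, axis=1)
    if not ka.equals(kb):
        raise ValueError("window tilings differ between the two scans")
    set_a = set(ka[stats_a["significant"].fillna(False)])
    set_b = set(kb[stats_b["significant"].fillna(False)])
    inter = set_a & set_b
    union = set_a | set_b

    def pct(num, den):
        return 100.0 * num / den if den else 0.0

    return {
        "n_significant_a": len(set_a),
        "n_significant_b": len(set_b),
        "n_overlap": len(inter),
        "pct_of_union": pct(len(inter), len(union)),
        "pct_of_a": pct(len(inter), len(set_a)),
        "pct_of_b": pct(len(inter), len(set_b)),
    }


# --------------------------------------------------------------------------
# analytical layers
# --------------------------------------------------------------------------


@dataclass
class LayerSpec:
    """One analytical layer: a grouping rule expanded into pairwise contrasts.

    ``contrasts`` maps a contrast name to a pair of sample-id lists.
    """

    layer_id: str
    grouping: str
    contrasts: dict


def build_layer(frame: pd.DataFrame, layer_id: str, gradients=("I", "III", "IV"), inner_gradient="II") -> LayerSpec:
    """Expand a layer rule into pairwise contrasts over the sample frame.

    Layer I contrasts gradients (default the three with shared ancestry);
    layer II contrasts agroecologies pooled over those gradients; layer III
    contrasts agroecologies within the genetically distinct gradient.
    """
    contrasts = {}
    if layer_id == "I":
        groups = {
            g: frame.loc[frame["gradient"] == g, "sample_id"].tolist()
            for g in gradients
        }
        grouping = "by gradient"
    elif layer_id == "II":
        sub = frame[frame["gradient"].isin(gradients)]
        agros = list(dict.fromkeys(sub["agroecology"]))
        groups = {
            a: sub.loc[sub["agroecology"] == a, "sample_id"].tolist() for a in agros
        }
        grouping = f"by agroecology pooled over gradients {','.join(gradients)}"
    elif layer_id == "III":
        sub = frame[frame["gradient"] == inner_gradient]
        agros = list(dict.fromkeys(sub["agroecology"]))
        groups = {
            a: sub.loc[sub["agroecology"] == a, "sample_id"].tolist() for a in agros
        }
        grouping = f"by agroecology within gradient {inner_gradient}"
    else:
        raise ValueError(f"unknown layer {layer_id!r}")

    names = list(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            contrasts[f"{names[i]}_vs_{names[j]}"] = (groups[names[i]], groups[names[j]])
    return LayerSpec(layer_id=layer_id, grouping=grouping, contrasts=contrasts)


def layered_scan(
    panel,
    frame: pd.DataFrame,
    layer: LayerSpec,
    span: int = 50_000,
    step: int = 25_000,
    top_frac: float = 0.01,
    run_xpehh: bool = True,
) -> dict:
    """Run FST (and optionally XP-EHH) scans for every contrast of a layer.

    Returns contrast name -> dict with ``fst`` (window table with empirical
    p), ``mean_fst`` (genome-wide mean of the window statistic), and when
    requested ``xpehh_sites``, ``xpehh`` and the FST-vs-XP-EHH ``overlap``
    report.
    """
    windows = make_windows(panel.contig_lengths, span, step)
    results = {}
    for name, (ids_a, ids_b) in layer.contrasts.items():
        if not ids_a or not ids_b:
            warnings.warn(f"contrast {name}: empty side, skipped")
            continue
        idx_a = panel.sample_indices(ids_a)
        idx_b = panel.sample_indices(ids_b)
        fst = empirical_p(
            windowed_fst(panel, (idx_a, idx_b), windows, span, step),
            two_sided=False,
            top_frac=top_frac,
        )
        res = {
            "fst": fst,
            "mean_fst": float(np.nanmean(fst["stat"].to_numpy())),
        }
        if run_xpehh:
            sites, win = xpehh(panel, idx_a, idx_b, windows, span, step)
            win = empirical_p(win, two_sided=True, top_frac=top_frac)
            res["xpehh_sites"] = sites
            res["xpehh"] = win
            res["overlap"] = overlap_windows(fst, win)
        results[name] = res
    return results
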