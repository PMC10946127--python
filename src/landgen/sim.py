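"""Synthetic structured populations with known ground truth.

Emulates a gradient-by-agroecology sampling design: populations (villages) are
nested in elevation-defined agroecologies (lowland / midaltitude / highland)
within geographic gradients.  Genotypes follow the Balding–Nichols model —
per-population allele frequencies are Beta-distributed around an ancestral
frequency with variance parameter ``fst_level`` — and phased haplotypes are
built as recombinant mosaics of a per-population founder pool, so that both
site-level differentiation and haplotype-sharing LD exist.  Hard selective
sweeps, environmental allele-frequency clines and polygenic traits can be
injected on top, with the injected ground truth recorded for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "SimConfig",
    "SweepSpec",
    "ClineSpec",
    "AGRO_BANDS",
    "ENV_PREDICTORS",
    "TRAITS",
    "simulate_metadata",
    "simulate_haplotypes",
    "balding_nichols_frequencies",
    "inject_sweep",
    "inject_env_cline",
    "simulate_traits",
    "parametric_fst",
]

#: Elevation bands (m.a.s.l.) of the conventional agroecological classes.
AGRO_BANDS = {
    "lowland": (400.0, 1800.0),
    "midaltitude": (1800.0, 2400.0),
    "highland": (2400.0, 3500.0),
}

#: Environmental predictors carried per sample (elevation first).
ENV_PREDICTORS = [
    "elevation",
    "temperature_seasonality",
    "precip_warmest_quarter",
    "precip_coldest_quarter",
    "solar_radiation_may",
    "soil_clay_content",
]

#: Quantitative traits carried per sample.
TRAITS = ["body_weight", "beak_length", "comb_width", "wattle_width", "earlobe_width"]

# natural-unit (mean, sd) used to de-standardize generated predictors
_PREDICTOR_SCALE = {
    "temperature_seasonality": (120.0, 30.0),
    "precip_warmest_quarter": (450.0, 150.0),
    "precip_coldest_quarter": (60.0, 30.0),
    "solar_radiation_may": (20000.0, 2500.0),
    "soil_clay_content": (30.0, 8.0),
}

# baseline mean, residual sd, and elevation effect (per 1 SD of elevation)
# for the default, zero-heritability trait surface written by simulate_metadata
_TRAIT_BASE = {
    "body_weight": (1500.0, 180.0, -60.0),
    "beak_length": (32.0, 2.5, -0.8),
    "comb_width": (45.0, 8.0, -4.0),
    "wattle_width": (30.0, 6.0, -3.0),
    "earlobe_width": (20.0, 4.0, -1.2),
}

# default target correlation matrix among ENV_PREDICTORS (elevation first);
# moderately realistic signs: highlands are cooler-season-stable, wetter in the
# warm season, less irradiated in May
_DEFAULT_PRED_CORR = np.array(
    [
        [1.00, -0.35, 0.45, -0.25, -0.40, 0.15],
        [-0.35, 1.00, -0.30, 0.20, 0.30, -0.10],
        [0.45, -0.30, 1.00, 0.30, -0.35, 0.20],
        [-0.25, 0.20, 0.30, 1.00, 0.10, 0.05],
        [-0.40, 0.30, -0.35, 0.10, 1.00, -0.05],
        [0.15, -0.10, 0.20, 0.05, -0.05, 1.00],
    ]
)

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class SimConfig:
    """Parameters of the synthetic sampling design and genome.

    Defaults mirror the emulated study design: 4 gradients x 3 agroecologies,
    26 populations (two per cell plus two extra villages), 16 birds per
    village, and a Balding–Nichols differentiation level of 0.02 typical of
    weakly structured village populations.
    """

    n_gradients: int = 4
    agroecologies: tuple = ("lowland", "midaltitude", "highland")
    pops_per_cell: int = 2
    n_extra_pops: int = 2
    samples_per_pop: int = 16
    n_chromosomes: int = 4
    chrom_length: int = 10_000_000
    n_snps: int = 20_000
    founder_haplotypes: int = 100
    recombination_rate: float = 1e-8
    fst_level: float = 0.02
    missing_rate: float = 0.0
    predictor_corr: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fst_level < 1.0):
            raise ValueError("fst_level must lie in [0, 1)")
        for name in (
            "n_gradients",
            "pops_per_cell",
            "samples_per_pop",
            "n_chromosomes",
            "chrom_length",
            "n_snps",
            "founder_haplotypes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_extra_pops < 0:
            raise ValueError("n_extra_pops must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        for a in self.agroecologies:
            if a not in AGRO_BANDS:
                raise ValueError(f"unknown agroecology {a!r}")

    @property
    def corr(self) -> np.ndarray:
        c = self.predictor_corr
        if c is None:
            return _DEFAULT_PRED_CORR.copy()
        c = np.asarray(c, dtype=float)
        k = len(ENV_PREDICTORS)
        if c.shape != (k, k):
            raise ValueError(f"predictor_corr must be {k}x{k}")
        return c


@dataclass
class SweepSpec:
    """Ground truth of one injected hard sweep."""

    populations: list
    chrom: str
    core_pos: int
    carrier_fraction: float
    span: int

    def __post_init__(self):
        if not (0.0 < self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must lie in (0, 1]")
        if self.span < 1:
            raise ValueError("span must be positive")

    def to_dict(self):
        return asdict(self)


@dataclass
class ClineSpec:
    """Ground truth of one injected environmental allele-frequency cline."""

    locus: int
    predictor: str
    slope: float
    baseline: float

    def __post_init__(self):
        if not (0.0 < self.baseline < 1.0):
            raise ValueError("baseline frequency must lie in (0, 1)")
        if self.predictor not in ENV_PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")

    def to_dict(self):
        return asdict(self)


# --------------------------------------------------------------------------
# metadata
# --------------------------------------------------------------------------


def simulate_metadata(config: SimConfig) -> pd.DataFrame:
    """Generate the per-sample metadata table (the SampleFrame).

    One row per sampled bird: population, gradient, agroecology, geographic
    coordinates, elevation drawn inside the population's agroecology band,
    six environmental predictors, and five baseline quantitative traits.
    Environmental predictors are population-level constants copied to each
    sample (one coordinate is recorded per village); conditional on elevation
    they follow the configured predictor-predictor correlation matrix.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([int(config.seed), 11])
    corr = config.corr
    k = len(ENV_PREDICTORS)

    # conditional construction: predictors | elevation ~ N(c_oe * z_elev, Schur)
    c_oe = corr[1:, 0]
    schur = corr[1:, 1:] - np.outer(c_oe, c_oe)
    try:
        chol = np.linalg.cholesky(schur + 1e-12 * np.eye(k - 1))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "predictor correlation matrix is not positive semi-definite "
            "given elevation"
        ) from exc

    cells = [
        (g, a) for g in range(config.n_gradients) for a in config.agroecologies
    ]
    pops = []
    for ci, (g, a) in enumerate(cells):
        n_here = config.pops_per_cell + (1 if ci < config.n_extra_pops else 0)
        for j in range(n_here):
            pops.append((g, a, j))

    # gradient centers scattered over an Ethiopia-like bounding box
    glon = 34.0 + 9.0 * rng.random(config.n_gradients)
    glat = 4.0 + 10.0 * rng.random(config.n_gradients)

    rows = []
    for g, a, j in pops:
        lo, hi = AGRO_BANDS[a]
        elev = float(rng.uniform(lo, hi))
        rows.append(
            {
                "population_id": f"G{_ROMAN[g]}_{a}_{j + 1}",
                "gradient": _ROMAN[g],
                "agroecology": a,
                "longitude": float(glon[g] + rng.normal(0.0, 0.4)),
                "latitude": float(glat[g] + rng.normal(0.0, 0.4)),
                "elevation": elev,
            }
        )
    pop_df = pd.DataFrame(rows)

    z_elev = (pop_df["elevation"] - pop_df["elevation"].mean()) / pop_df[
        "elevation"
    ].std(ddof=0)
    eps = rng.standard_normal((len(pop_df), k - 1))
    z_other = np.outer(z_elev.to_numpy(), c_oe) + eps @ chol.T
    for i, name in enumerate(ENV_PREDICTORS[1:]):
        mu, sd = _PREDICTOR_SCALE[name]
        pop_df[name] = mu + sd * z_other[:, i]

    # expand populations to samples
    sample_rows = []
    for _, p in pop_df.iterrows():
        for s in range(config.samples_per_pop):
            r = dict(p)
            r["sample_id"] = f"{p['population_id']}_s{s + 1:02d}"
            sample_rows.append(r)
    frame = pd.DataFrame(sample_rows)

    # baseline (zero-heritability) traits: elevation effect + individual noise;
    # comb and wattle width share a latent thermoregulation factor
    n = len(frame)
    ze = (
        (frame["elevation"] - frame["elevation"].mean())
        / frame["elevation"].std(ddof=0)
    ).to_numpy()
    shared = rng.standard_normal(n)
    for t in TRAITS:
        mu, sd, b = _TRAIT_BASE[t]
        noise = rng.standard_normal(n)
        if t in ("comb_width", "wattle_width"):
            noise = 0.75 * shared + np.sqrt(1 - 0.75**2) * noise
        frame[t] = mu + b * ze + sd * noise

    cols = (
        ["sample_id", "population_id", "gradient", "agroecology", "longitude",
         "latitude"]
        + ENV_PREDICTORS
        + TRAITS
    )
    return frame[cols].reset_index(drop=True)


# --------------------------------------------------------------------------
# haplotypes
# --------------------------------------------------------------------------


def balding_nichols_frequencies(p0: np.ndarray, fst: float, n_pops: int, rng) -> np.ndarray:
    """Per-population allele frequencies under the Balding–Nichols model.

    Each population's frequency is Beta(p0*(1-F)/F, (1-p0)*(1-F)/F); at F = 0
    the draw degenerates to the ancestral frequency exactly.

    Returns array of shape (n_pops, n_snps).
    """
    p0 = np.asarray(p0, dtype=float)
    if fst == 0.0:
        return np.tile(p0, (n_pops, 1))
    scale = (1.0 - fst) / fst
    return rng.beta(p0 * scale, (1.0 - p0) * scale, size=(n_pops, p0.size))


def _draw_positions(rng, length: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 10))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_haplotypes(config: SimConfig, frame: pd.DataFrame):
    """Generate the phased haplotype panel for a simulated SampleFrame.

    Ancestral frequencies are Uniform(0.05, 0.95); per-population frequencies
    are Balding–Nichols with parameter ``fst_level``.  Each population gets an
    independent founder pool drawn at its frequencies, and sample haplotypes
    are recombinant founder mosaics (per-bp switch probability
    ``recombination_rate``; founders are redrawn at each chromosome start).
    With ``recombination_rate = 0`` every haplotype is an exact founder copy.

    Deterministic given ``config.seed``.
    """
    from .panel import HaplotypePanel

    rng = np.random.default_rng([int(config.seed), 23])
    m = config.n_snps
    per_chrom = [m // config.n_chromosomes] * config.n_chromosomes
    for i in range(m % config.n_chromosomes):
        per_chrom[i] += 1

    chrom = np.concatenate(
        [np.repeat(str(c + 1), n) for c, n in enumerate(per_chrom)]
    ).astype(object)
    pos = np.concatenate(
        [_draw_positions(rng, config.chrom_length, n) for n in per_chrom]
    )
    bases = np.array(list("ACGT"), dtype=object)
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    p0 = rng.uniform(0.05, 0.95, size=m)

    pop_ids = frame["population_id"].drop_duplicates().tolist()
    pop_freq = balding_nichols_frequencies(p0, config.fst_level, len(pop_ids), rng)

    # per-site switch probability for the founder mosaic
    switch = np.empty(m)
    start = 0
    for n in per_chrom:
        gaps = np.diff(pos[start : start + n], prepend=pos[start])
        s = 1.0 - np.exp(-config.recombination_rate * gaps)
        s[0] = 1.0  # new chromosome: fresh founder
        switch[start : start + n] = s
        start += n

    K = config.founder_haplotypes
    sample_order = frame["sample_id"].tolist()
    hap_blocks = []
    col_idx = np.arange(m)
    for pi, pop in enumerate(pop_ids):
        n_here = int((frame["population_id"] == pop).sum())
        founders = (rng.random((K, m)) < pop_freq[pi]).astype(np.uint8)
        nh = 2 * n_here
        cand = rng.integers(0, K, size=(nh, m))
        sw = rng.random((nh, m)) < switch
        sw[:, 0] = True
        last = np.maximum.accumulate(np.where(sw, col_idx, 0), axis=1)
        founder_id = np.take_along_axis(cand, last, axis=1)
        hap_blocks.append(founders[founder_id, col_idx])

    haplotypes = np.concatenate(hap_blocks, axis=0)
    n_samples = len(sample_order)
    missing = np.zeros((n_samples, m), dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random((n_samples, m)) < config.missing_rate

    return HaplotypePanel(
        chrom=chrom,
        pos=pos,
        ref=bases[ref_idx],
        alt=bases[alt_idx],
        haplotypes=haplotypes,
        sample_ids=sample_order,
        missing=missing,
        contig_lengths={
            str(c + 1): int(config.chrom_length) for c in range(config.n_chromosomes)
        },
    )


# --------------------------------------------------------------------------
# signal injection
# --------------------------------------------------------------------------


def inject_sweep(panel, frame: pd.DataFrame, spec: SweepSpec, seed: int = 0):
    """Inject a hard selective sweep into the target populations.

    Over ``[core_pos - span/2, core_pos + span/2]`` a ``carrier_fraction`` of
    the target populations' haplotypes is replaced by identical copies of one
    donor haplotype, forcing extended haplotype homozygosity around the core.
    Other populations and loci outside the span are untouched.  Returns a new
    panel; the input is not modified.
    """
    out = panel.copy()
    lo = spec.core_pos - spec.span // 2
    hi = spec.core_pos + spec.span // 2
    clen = out.contig_lengths.get(spec.chrom)
    if clen is None:
        raise ValueError(f"chromosome {spec.chrom!r} not in panel")
    if not (1 <= spec.core_pos <= clen):
        raise ValueError("sweep core position outside chromosome")
    if lo < 1 or hi > clen:
        warnings.warn("sweep span truncated at chromosome end")
        lo, hi = max(lo, 1), min(hi, clen)
    sites = np.flatnonzero((out.chrom == spec.chrom) & (out.pos >= lo) & (out.pos <= hi))
    if sites.size == 0:
        warnings.warn("sweep span contains no variants; panel unchanged")
        return out

    rng = np.random.default_rng([int(seed), 31, int(spec.core_pos)])
    target = frame["population_id"].isin(spec.populations)
    sample_idx = panel.sample_indices(frame.loc[target, "sample_id"].tolist())
    rows = out.haplotype_rows(sample_idx)
    if rows.size == 0:
        raise ValueError("sweep target populations contain no samples")
    n_carriers = max(1, int(round(spec.carrier_fraction * rows.size)))
    donor = rows[0]
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    out.haplotypes[np.ix_(carriers, sites)] = out.haplotypes[donor, sites]
    return out


def inject_env_cline(panel, frame: pd.DataFrame, spec: ClineSpec, seed: int = 0):
    """Resample one locus so its population frequencies track a predictor.

    The per-population alternate-allele frequency becomes
    ``logistic(logit(baseline) + slope * z)`` where ``z`` is the predictor
    standardized across populations.  Only the cline locus is touched.
    """
    if not (0 <= spec.locus < panel.n_snps):
        raise ValueError(f"cline locus {spec.locus} out of range")
    out = panel.copy()
    rng = np.random.default_rng([int(seed), 37, int(spec.locus)])

    pop_vals = frame.groupby("population_id", sort=False)[spec.predictor].first()
    z = (pop_vals - pop_vals.mean()) / pop_vals.std(ddof=0)
    freqs = expit(logit(spec.baseline) + spec.slope * z)

    for pop, f in freqs.items():
        sample_idx = panel.sample_indices(
            frame.loc[frame["population_id"] == pop, "sample_id"].tolist()
        )
        rows = out.haplotype_rows(sample_idx)
        out.haplotypes[rows, spec.locus] = (rng.random(rows.size) < f).astype(np.uint8)
    return out


def simulate_traits(
    panel,
    frame: pd.DataFrame,
    qtl_effects: dict | None = None,
    env_effects: dict | None = None,
    residual_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Overwrite trait columns with a genetic + environmental architecture.

    ``trait = baseline + sum(effect * dosage) + sum(coef * predictor) + N(0, sd)``.

    Parameters
    ----------
    qtl_effects : dict, optional
        trait name -> list of (locus index, additive effect per alt allele).
    env_effects : dict, optional
        trait name -> {predictor name: coefficient on the standardized predictor}.
    residual_sd : float
        SD of the iid residual added to every trait.
    """
    qtl_effects = qtl_effects or {}
    env_effects = env_effects or {}
    for t in list(qtl_effects) + list(env_effects):
        if t not in TRAITS:
            raise ValueError(f"unknown trait {t!r}")
    dosage = panel.dosage()
    # mean-impute missing dosages for trait construction only
    col_mean = np.nanmean(dosage, axis=0)
    nan_r, nan_c = np.where(np.isnan(dosage))
    dosage[nan_r, nan_c] = col_mean[nan_c]

    rng = np.random.default_rng([int(seed), 41])
    out = frame.copy()
    order = panel.sample_indices(out["sample_id"].tolist())
    for t in TRAITS:
        mu = _TRAIT_BASE[t][0]
        val = np.full(len(out), mu)
        for locus, eff in qtl_effects.get(t, []):
            if not (0 <= locus < panel.n_snps):
                raise ValueError(f"QTL locus {locus} out of range")
            val = val + eff * dosage[order, locus]
        for pred, coef in env_effects.get(t, {}).items():
            x = out[pred].to_numpy(dtype=float)
            z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
            val = val + coef * z
        if residual_sd > 0:
            val = val + rng.normal(0.0, residual_sd, size=len(out))
        out[t] = val
    return out


# --------------------------------------------------------------------------
# parametric FST
# --------------------------------------------------------------------------


def parametric_fst(subpop_frequencies, weights=None) -> float:
    """FST from true subpopulation allele frequencies: (HT - HS) / HT.

    HS is the weighted mean of within-population expected heterozygosity
    2p(1-p); HT the expected heterozygosity at the weighted mean frequency.
    0 means no differentiation, 1 complete differentiation.  Returns NaN for
    a site monomorphic over all populations (HT = 0).  Used to validate the
    simulator's ground truth, not as an estimator.
    """
    p = np.asarray(subpop_frequencies, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if weights is None:
        w = np.full(p.shape, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    hs = float(np.sum(w * 2.0 * p * (1.0 - p)))
    pbar = float(np.sum(w * p))
    ht = 2.0 * pbar * (1.0 - pbar)
    if ht == 0.0:
        return float("nan")
    return (ht - hs) / ht
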