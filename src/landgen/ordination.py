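"""Constrained and unconstrained ordination of genotype dosage matrices.

:class:`GenotypePCA` implements genotype PCA with Patterson normalization
(each SNP centered and scaled by sqrt(p(1-p))), the standard way population
structure is summarized before association analysis.

:class:`PartialRDA` implements (partial) redundancy analysis: the dosage
matrix is regressed on a predictor table — after both are residualized on
conditioning covariates such as geography — and the fitted values are
eigen-decomposed.  Canonical eigenvalues, axis variance fractions, SNP
loadings, adjusted R-squared (Ezekiel) and a permutation pseudo-F test come
out.  SNPs whose loadings sit far in the tails of the loading distribution
on the leading constrained axes are candidate loci associated with the
predictors; each candidate is assigned to the predictor it correlates with
most strongly.

Both classes follow the scikit-learn estimator protocol (``fit``,
``get_params``/``set_params``, trailing-underscore fitted attributes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "GenotypePCA",
    "PartialRDA",
    "reduce_predictors",
    "rda_outliers",
    "assign_outliers",
    "gea_pipeline",
    "GeaResult",
]

#: |r| bins used when tabulating candidate-SNP/predictor correlations
R_BINS = [0.0, 0.3, 0.4, 0.5, 0.6, 1.0]


def _mean_impute(Y: np.ndarray) -> np.ndarray:
    """Column-mean impute NaNs (ordination only; QC and FST never impute)."""
    Y = np.array(Y, dtype=float)
    col_mean = np.nanmean(Y, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    r, c = np.where(np.isnan(Y))
    Y[r, c] = col_mean[c]
    return Y


def _fix_signs(U, V=None):
    """Deterministic sign convention: largest-|u| entry of each axis positive."""
    for k in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, k]))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
            if V is not None:
                V[:, k] = -V[:, k]
    return U, V


class GenotypePCA(BaseEstimator):
    """Genotype PCA with Patterson normalization.

    Each SNP column is mean-imputed, centered, and scaled by
    ``sqrt(p(1-p))`` with ``p`` the sample allele frequency; monomorphic
    SNPs are dropped.  The eigendecomposition is of the sample-by-sample
    covariance ``M M^T / m`` over the ``m`` retained SNPs.

    Attributes
    ----------
    eigenvalues_ : (k,) leading eigenvalues of the sample covariance
    scores_ : (n, k) sample principal-component scores (U * S)
    n_dropped_ : number of monomorphic SNPs excluded
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        """Fit on an (n_samples, n_snps) dosage matrix (NaN = missing)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("need a 2-D dosage matrix with >= 2 samples, >= 1 SNP")
        Y = _mean_impute(X)
        p = Y.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        self.n_dropped_ = int((~poly).sum())
        Y = Y[:, poly]
        if Y.shape[1] == 0:
            raise ValueError("no polymorphic SNPs left for PCA")
        M = (Y - Y.mean(axis=0)) / np.sqrt(p[poly] * (1 - p[poly]))
        m = M.shape[1]
        k = min(self.n_components, min(M.shape) - 1) if min(M.shape) > 1 else 1
        U, S, _ = np.linalg.svd(M, full_matrices=False)
        U, _ = _fix_signs(U[:, :k])
        S = S[:k]
        self.eigenvalues_ = S**2 / m
        self.scores_ = U * S
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).scores_


def reduce_predictors(table: pd.DataFrame, threshold: float = 0.7, forced_keep=()) -> list:
    """Greedy collinearity reduction of a predictor/trait table.

    While any pair of retained columns has |Pearson r| strictly above
    ``threshold``, the worst pair's member with the larger mean |r| against
    all other retained columns is dropped.  Columns in ``forced_keep`` are
    never dropped; a forced pair above the threshold is kept with a warning
    (e.g. two traits both retained on biological grounds).

    Returns the retained column names in original order.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    corr = table.corr().abs()
    keep = set(cols)
    while True:
        worst, worst_r = None, threshold
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if a in keep and b in keep and corr.loc[a, b] > worst_r:
                    if a in forced_keep and b in forced_keep:
                        continue
                    worst, worst_r = (a, b), corr.loc[a, b]
        if worst is None:
            break
        a, b = worst
        droppable = [c for c in worst if c not in forced_keep]
        if len(droppable) == 1:
            drop = droppable[0]
        else:
            others = [c for c in keep]
            mean_r = {
                c: corr.loc[c, [o for o in others if o != c]].mean() for c in worst
            }
            drop = max(worst, key=lambda c: (mean_r[c], cols.index(c)))
        keep.discard(drop)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if a in keep and b in keep and corr.loc[a, b] > threshold:
                warnings.warn(
                    f"forced_keep retains {a!r} and {b!r} with |r| = "
                    f"{corr.loc[a, b]:.2f} above {threshold}"
                )
    return [c for c in cols if c in keep]


def _residualize(A: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of the columns of A on [intercept, Z] by least squares."""
    n = A.shape[0]
    if Z is None or Z.size == 0:
        return A - A.mean(axis=0)
    design = np.column_stack([np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(design, A, rcond=None)
    return A - design @ coef


class PartialRDA(BaseEstimator):
    """Partial redundancy analysis of a dosage matrix on predictors.

    Fits ``Y ~ X | Z``: response and predictors are residualized on the
    conditioning covariates, the multivariate least-squares fit of the
    residualized response on the residualized predictors is computed, and
    the fitted-value matrix is decomposed by SVD into canonical axes.

    Parameters
    ----------
    n_permutations : permutations for the pseudo-F test (add-one p-value).
    random_state : seed for the permutation test.
    scale : if True, variance-scale response columns (default False:
        centered allele counts, the ordination convention for dosages).

    Attributes (after fit)
    ----------------------
    eigenvalues_ : canonical eigenvalue per constrained axis (sv^2 / (n-1))
    proportion_explained_ : fraction of constrained variance per axis
    site_scores_ : (n, rank) sample scores (U * S)
    snp_loadings_ : (m, rank) Pearson r between each residualized SNP and
        each axis's site scores; NaN for zero-variance SNPs
    biplot_scores_ : (p, rank) correlations of predictors with the axes
    r2_, adj_r2_ : constrained variance fraction and Ezekiel adjustment
    pseudo_f_, p_value_ : permutation F-test of the constraint
    rank_ : number of constrained axes (rank of residualized X)
    """

    def __init__(self, n_permutations: int = 999, random_state: int = 0, scale: bool = False):
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.scale = scale

    def fit(self, Y, X, Z=None):
        """Fit the partial RDA.

        Parameters
        ----------
        Y : (n, m) response dosage matrix (NaN allowed; mean-imputed)
        X : (n, p) predictor table (DataFrame or array), complete
        Z : (n, q) conditioning table (geography), complete, optional
        """
        self.predictor_names_ = (
            list(X.columns) if isinstance(X, pd.DataFrame) else None
        )
        Y = _mean_impute(np.asarray(Y, dtype=float))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        Zarr = None if Z is None else np.asarray(Z, dtype=float)
        if Zarr is not None and Zarr.ndim == 1:
            Zarr = Zarr[:, None]
        n, m = Y.shape
        if X.shape[0] != n or (Zarr is not None and Zarr.shape[0] != n):
            raise ValueError("Y, X and Z must have aligned samples")
        if np.isnan(X).any() or (Zarr is not None and np.isnan(Zarr).any()):
            raise ValueError("predictor and conditioning tables must be complete")

        Yc = Y - Y.mean(axis=0)
        if self.scale:
            sd = Yc.std(axis=0)
            Yc = Yc / np.where(sd > 0, sd, 1.0)
        Yres = _residualize(Yc, Zarr)
        Xres = _residualize(X, Zarr)

        # drop collinear predictor columns after residualization
        qx, rx, piv = _qr_rank(Xres)
        self.rank_ = qx.shape[1]
        self.dropped_predictors_ = [
            (self.predictor_names_[j] if self.predictor_names_ else j)
            for j in piv[self.rank_ :]
        ]
        if self.dropped_predictors_:
            warnings.warn(
                f"collinear predictors dropped after conditioning: {self.dropped_predictors_}"
            )

        fitted = qx @ (qx.T @ Yres)
        U, S, Vt = np.linalg.svd(fitted, full_matrices=False)
        k = self.rank_
        U, Vt_t = _fix_signs(U[:, :k].copy(), Vt[:k].T.copy())
        S = S[:k]
        self.eigenvalues_ = S**2 / (n - 1)
        tot = self.eigenvalues_.sum()
        self.proportion_explained_ = (
            self.eigenvalues_ / tot if tot > 0 else np.zeros(k)
        )
        self.site_scores_ = U * S

        sst = float((Yres**2).sum())
        ssf = float((S**2).sum())
        self.r2_ = ssf / sst if sst > 0 else 0.0

        p = self.rank_
        q = 0 if Zarr is None else np.linalg.matrix_rank(_residualize(Zarr, None))
        self.n_conditioning_ = q
        if n - 1 - q - p > 0:
            self.adj_r2_ = 1.0 - (1.0 - self.r2_) * (n - 1 - q) / (n - 1 - q - p)
        else:
            self.adj_r2_ = float("nan")

        # loadings: correlation of each residualized SNP with each axis
        self.snp_loadings_ = _corr_columns(Yres, self.site_scores_)
        self.biplot_scores_ = _corr_columns(Xres[:, piv[:k]], self.site_scores_)

        self._permutation_test(Yres, Xres[:, piv[:k]], n, p, q, sst)
        return self

    def _permutation_test(self, Yres, Xres, n, p, q, sst):
        df_resid = n - 1 - p - q
        if df_resid <= 0 or sst == 0:
            self.pseudo_f_ = float("nan")
            self.p_value_ = float("nan")
            return
        r2 = self.r2_
        self.pseudo_f_ = (r2 / p) / ((1.0 - r2) / df_resid)
        rng = np.random.default_rng(self.random_state)
        count = 0
        for _ in range(self.n_permutations):
            perm = rng.permutation(n)
            Xp = Xres[perm]
            qp, _, _ = _qr_rank(Xp)
            r2p = float(((qp.T @ Yres) ** 2).sum()) / sst
            fp = (r2p / p) / ((1.0 - r2p) / df_resid)
            if fp >= self.pseudo_f_:
                count += 1
        self.p_value_ = (1.0 + count) / (1.0 + self.n_permutations)


def _qr_rank(X, tol=1e-10):
    """Rank-revealing QR via pivoting; returns (Q_rank, R, pivot order)."""
    from scipy.linalg import qr

    if X.size == 0:
        return np.zeros((X.shape[0], 0)), np.zeros((0, 0)), np.array([], dtype=int)
    Q, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(1.0, diag[0] if diag.size else 1.0)).sum())
    return Q[:, :rank], R, piv


def _corr_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between every column of A and every column of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    sa = np.sqrt((Ac**2).sum(axis=0))
    sb = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Ac.T @ Bc) / np.outer(sa, sb)
    out[sa == 0, :] = np.nan
    return out


# --------------------------------------------------------------------------
# loading outliers and candidate assignment
# --------------------------------------------------------------------------


def rda_outliers(loadings: np.ndarray, sd_mult: float = 3.5, n_axes: int = 3) -> pd.DataFrame:
    """Flag SNPs whose loadings sit beyond ``sd_mult`` SDs on leading axes.

    Per axis among the first ``n_axes``, a SNP is flagged when
    ``|loading - mean| > sd_mult * SD`` of that axis's loading distribution
    (at 3.5 SD this is the two-tailed normal p = 0.0005 convention).  The
    outlier set is the union over axes; each SNP is reported once with its
    most extreme axis.  Axes with zero loading SD contribute no outliers.
    """
    L = np.asarray(loadings, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    if L.shape[1] < n_axes:
        raise ValueError(f"need >= {n_axes} axes, got {L.shape[1]}")
    L = L[:, :n_axes]
    z = np.full(L.shape, 0.0)
    for k in range(n_axes):
        col = L[:, k]
        ok = ~np.isnan(col)
        mu, sd = col[ok].mean(), col[ok].std()
        if sd > 0:
            z[ok, k] = (col[ok] - mu) / sd
    best_axis = np.argmax(np.abs(z), axis=1)
    best_z = z[np.arange(L.shape[0]), best_axis]
    flagged = np.abs(best_z) > sd_mult
    return pd.DataFrame(
        {
            "snp": np.flatnonzero(flagged),
            "axis": best_axis[flagged] + 1,
            "loading": L[flagged, best_axis[flagged]],
            "zscore": best_z[flagged],
        }
    ).reset_index(drop=True)


def assign_outliers(
    outliers: pd.DataFrame,
    Y_res: np.ndarray,
    X_res: np.ndarray,
    predictor_names: list,
) -> pd.DataFrame:
    """Assign each outlier SNP to its most-correlated predictor.

    Pearson r is computed between the SNP's residualized dosage and each
    residualized predictor; the predictor with maximal |r| wins (ties break
    by predictor order).  |r| is binned into (0,0.3], (0.3,0.4], (0.4,0.5],
    (0.5,0.6], (0.6,1] — left-open, right-closed.  SNPs with zero-variance
    residualized dosage are reported unassigned.
    """
    out = outliers.copy()
    preds, rs, bins = [], [], []
    for snp in out["snp"]:
        y = Y_res[:, int(snp)]
        if y.std() == 0:
            preds.append(None)
            rs.append(np.nan)
            bins.append(None)
            continue
        r = _corr_columns(y[:, None], X_res)[0]
        j = int(np.nanargmax(np.abs(r)))
        preds.append(predictor_names[j])
        rs.append(float(r[j]))
        absr = abs(float(r[j]))
        k = np.searchsorted(R_BINS, absr, side="left")
        k = max(1, min(k, len(R_BINS) - 1))
        bins.append(f"({R_BINS[k - 1]},{R_BINS[k]}]")
    out["assigned"] = preds
    out["r"] = rs
    out["r_bin"] = bins
    return out


# --------------------------------------------------------------------------
# end-to-end genotype-environment / genotype-phenotype association
# --------------------------------------------------------------------------


@dataclass
class GeaResult:
    """Bundle returned by :func:`gea_pipeline`."""

    rda: PartialRDA
    retained_predictors: list
    outliers: pd.DataFrame
    manhattan: pd.DataFrame
    n_samples: int
    mode: str


def gea_pipeline(
    panel,
    frame: pd.DataFrame,
    mode: str,
    predictors: list | None = None,
    condition_on: tuple = ("longitude", "latitude"),
    reduce_threshold: float = 0.7,
    forced_keep=(),
    sd_mult: float = 3.5,
    n_axes: int = 3,
    n_permutations: int = 999,
    random_state: int = 0,
) -> GeaResult:
    """Genotype-environment or genotype-phenotype association via partial RDA.

    Composes predictor reduction (|r| > ``reduce_threshold`` collinearity
    elimination), partial RDA conditioned on geography, loading-outlier
    detection on the first ``n_axes`` axes, and candidate-SNP assignment.
    Per-SNP significance in the Manhattan table is the two-tailed normal
    tail probability of the SNP's most extreme standardized loading, with
    the ``sd_mult``-SD line corresponding to p = 0.0005 at 3.5 SD.

    ``mode`` selects the environmental predictor set or the trait set from
    the sample frame; samples with missing predictor/trait values are
    dropped with a report.
    """
    from .sim import ENV_PREDICTORS, TRAITS

    if mode not in ("environment", "phenotype"):
        raise ValueError("mode must be 'environment' or 'phenotype'")
    cand = predictors or (ENV_PREDICTORS if mode == "environment" else TRAITS)

    cols = list(cand) + list(condition_on)
    complete = frame[cols].notna().all(axis=1)
    if not complete.all():
        warnings.warn(f"{int((~complete).sum())} samples dropped for missing values")
    sub = frame.loc[complete].reset_index(drop=True)
    idx = panel.sample_indices(sub["sample_id"].tolist())
    Y = panel.dosage()[idx, :]

    retained = reduce_predictors(sub[list(cand)], reduce_threshold, forced_keep)
    X = sub[retained]
    Z = sub[list(condition_on)].to_numpy(dtype=float) if condition_on else None

    rda = PartialRDA(n_permutations=n_permutations, random_state=random_state)
    rda.fit(Y, X, Z)

    L = rda.snp_loadings_[:, : min(n_axes, rda.rank_)]
    out = rda_outliers(L, sd_mult=sd_mult, n_axes=L.shape[1])
    Yres = _residualize(_mean_impute(Y), Z)
    Xres = _residualize(X.to_numpy(dtype=float), Z)
    out = assign_outliers(out, Yres, Xres, retained)

    # Manhattan: per-SNP max |z| over retained axes -> two-tailed normal p
    z = np.zeros(L.shape)
    for k in range(L.shape[1]):
        col = L[:, k]
        ok = ~np.isnan(col)
        sd = col[ok].std()
        if sd > 0:
            z[ok, k] = (col[ok] - col[ok].mean()) / sd
    zmax = np.max(np.abs(z), axis=1)
    pvals = 2.0 * stats.norm.sf(zmax)
    manhattan = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "zmax": zmax,
            "p": pvals,
            "log10p": -np.log10(np.maximum(pvals, 1e-300)),
            "significant": zmax > sd_mult,
        }
    )
    return GeaResult(
        rda=rda,
        retained_predictors=retained,
        outliers=out,
        manhattan=manhattan,
        n_samples=len(sub),
        mode=mode,
    )
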