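"""Per-drug association testing of somatic and germline variants.

Somatic markers are tested with an ordinary linear model

    y = 1*mu + W*alpha + x_s*beta_s + psi,        psi ~ N(0, sigma_e^2 I)

and germline dosages with a linear mixed model that adds a polygenic random
effect whose covariance is the realized-relatedness (kinship) matrix K,

    y = 1*mu + W*alpha + x_g*beta_g + g + psi,    g ~ N(0, sigma_g^2 K),

absorbing population-structure confounding.  Both models are fitted by
maximum likelihood (not REML) so the likelihood-ratio test of beta = 0 is
internally consistent; P values come from chi^2 with 1 degree of freedom.

The LMM is solved in the eigenbasis of K: with K = U diag(lam) U^T the
rotated model has independent errors with variances sigma_g^2 (lam_i + delta)
where delta = sigma_e^2 / sigma_g^2.  beta and sigma_g^2 are profiled out in
closed form and delta is optimized on a log-spaced grid with golden-section
refinement.  ``lmm_scan`` vectorizes the per-variant fit across a whole
genotype block, which is what makes permutation-based error control
affordable.

Phenotypes are quantile-normalized to a standard Gaussian before testing;
effect sizes are re-estimated on the original 1-AUC scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypePanel, validate_kinship

__all__ = [
    "AssociationRecord",
    "KinshipEigen",
    "quantile_normalize",
    "tissue_covariates",
    "realized_relatedness",
    "kinship_eigh",
    "lm_association",
    "lm_scan",
    "lmm_association",
    "lmm_scan",
    "effect_size_original_scale",
    "compare_qtl_effect_sizes",
]

_LOG2PI = np.log(2.0 * np.pi)
_DELTA_GRID = np.logspace(-5, 5, 50)


# ---------------------------------------------------------------------------
# phenotype and covariate preparation
# ---------------------------------------------------------------------------

def quantile_normalize(y) -> np.ndarray:
    """Rank-based inverse-normal transform: value i -> Phi^-1((r_i - 0.5)/n)
    with average ranks for ties.  Constant input maps to all zeros."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 observations to quantile normalize")
    if np.ptp(y) == 0:
        warnings.warn("constant phenotype: quantile normalization returns zeros")
        return np.zeros_like(y)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.size)


def tissue_covariates(tissues) -> tuple[np.ndarray, list[str]]:
    """One-hot tissue design minus a reference level (first alphabetically);
    the intercept is added separately by the fitting routines."""
    t = pd.Series(tissues)
    levels = sorted(t.unique())
    W = np.column_stack([(t == lv).to_numpy(dtype=float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(t), 0))
    return W, levels


def realized_relatedness(panel_or_dosages, return_unscaled: bool = False) -> np.ndarray:
    """Realized-relatedness matrix K = Z Z^T / M from standardized dosages
    Z_ij = (d_ij - 2 af_j) / sqrt(2 af_j (1 - af_j)); monomorphic variants are
    excluded and K is scaled so its mean diagonal equals 1 (unless
    ``return_unscaled``)."""
    d = panel_or_dosages.dosages if isinstance(panel_or_dosages, GenotypePanel) \
        else np.asarray(panel_or_dosages, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        af = np.nanmean(d, axis=0) / 2.0
    poly = (af > 0) & (af < 1)
    if poly.sum() < 1:
        raise ValueError("no polymorphic variants for relatedness")
    d = d[:, poly]
    af = af[poly]
    Z = (d - 2.0 * af) / np.sqrt(2.0 * af * (1.0 - af))
    Z = np.nan_to_num(Z)  # missing -> population mean
    K = Z @ Z.T / Z.shape[1]
    K = 0.5 * (K + K.T)
    if return_unscaled:
        return K
    return K / np.mean(np.diag(K))


@dataclass
class KinshipEigen:
    """Cached eigendecomposition K = U diag(lam) U^T (lam clipped at 0)."""

    lam: np.ndarray
    U: np.ndarray


def kinship_eigh(K: np.ndarray) -> KinshipEigen:
    K = validate_kinship(K)
    lam, U = np.linalg.eigh(K)
    return KinshipEigen(lam=np.clip(lam, 0.0, None), U=U)


# ---------------------------------------------------------------------------
# association records
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    """One variant-drug association test."""

    drug: str
    variant: str
    beta: float
    se: float
    p_value: float
    test_type: str  # "somatic" | "germline"
    ll_null: float
    ll_alt: float
    flags: tuple[str, ...] = ()

    @property
    def lr_stat(self) -> float:
        return max(0.0, 2.0 * (self.ll_alt - self.ll_null))


def _design(W: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if W is None or np.size(W) == 0:
        return ones
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != n:
        W = W.T
    return np.hstack([ones, W])


# ---------------------------------------------------------------------------
# linear model (somatic tests)
# ---------------------------------------------------------------------------

def _ols_ll(rss: float, n: int) -> float:
    return -0.5 * n * (_LOG2PI + 1.0 + np.log(rss / n))


def lm_association(y, W, x, drug: str = "drug", variant: str = "variant"
                   ) -> AssociationRecord:
    """Likelihood-ratio test of beta = 0 in y = mu + W a + x b + noise."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    M = _design(W, n)
    Q, _ = np.linalg.qr(M)
    y_r = y - Q @ (Q.T @ y)
    x_r = x - Q @ (Q.T @ x)
    den = float(x_r @ x_r)
    rss0 = float(y_r @ y_r)
    flags: tuple[str, ...] = ()
    if den <= 1e-12 * max(1.0, float(x @ x)):
        warnings.warn("variant collinear with covariates: test undefined")
        return AssociationRecord(drug, variant, np.nan, np.nan, np.nan,
                                 "somatic", _ols_ll(rss0, n), _ols_ll(rss0, n),
                                 ("collinear",))
    num = float(x_r @ y_r)
    beta = num / den
    rss1 = max(rss0 - num * num / den, 1e-300)
    ll0, ll1 = _ols_ll(rss0, n), _ols_ll(rss1, n)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    se = float(np.sqrt((rss1 / n) / den))
    return AssociationRecord(drug, variant, float(beta), se, p, "somatic",
                             ll0, ll1, flags)


def lm_scan(y, W, X) -> pd.DataFrame:
    """Vectorized ``lm_association`` across the columns of X."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    M = _design(W, n)
    Q, _ = np.linalg.qr(M)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)
    den = (X_r ** 2).sum(axis=0)
    rss0 = float(y_r @ y_r)
    num = X_r.T @ y_r
    ok = den > 1e-12 * np.maximum(1.0, (X ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, num / den, np.nan)
        rss1 = np.where(ok, np.maximum(rss0 - num * num / den, 1e-300), rss0)
        lr = np.where(ok, np.maximum(0.0, n * np.log(rss0 / rss1)), np.nan)
        se = np.where(ok, np.sqrt((rss1 / n) / den), np.nan)
    p = stats.chi2.sf(lr, df=1)
    return pd.DataFrame({"beta": beta, "se": se, "p_value": p,
                         "ll_null": _ols_ll(rss0, n),
                         "ll_alt": _ols_ll(rss0, n) + 0.5 * lr})


# ---------------------------------------------------------------------------
# linear mixed model (germline tests)
# ---------------------------------------------------------------------------

def _profile_ll(delta: float, lam: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """Profile log-likelihood at fixed delta; beta and sigma_g^2 profiled."""
    n = yr.size
    v = lam + delta
    sw = 1.0 / np.sqrt(v)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma_g2 = max(rss / n, 1e-300)
    ll = -0.5 * (n * _LOG2PI + n + n * np.log(sigma_g2) + np.log(v).sum())
    return ll, beta, sigma_g2, Xw


def _fit_delta(lam, yr, Xr, extra_deltas=(), refine: bool = True):
    """Maximize the profile likelihood over delta (grid + local refinement)."""
    grid = np.sort(np.unique(np.concatenate([_DELTA_GRID, np.asarray(extra_deltas)]))) \
        if len(extra_deltas) else _DELTA_GRID
    lls = np.array([_profile_ll(d, lam, yr, Xr)[0] for d in grid])
    k = int(np.argmax(lls))
    delta = float(grid[k])
    if refine and 0 < k < grid.size - 1:
        res = optimize.minimize_scalar(
            lambda ld: -_profile_ll(10.0 ** ld, lam, yr, Xr)[0],
            bounds=(np.log10(grid[k - 1]), np.log10(grid[k + 1])),
            method="bounded", options={"xatol": 1e-3},
        )
        if -res.fun >= lls[k]:
            delta = float(10.0 ** res.x)
    ll, beta, sigma_g2, Xw = _profile_ll(delta, lam, yr, Xr)
    boundary = delta <= _DELTA_GRID[0] * 1.001 or delta >= _DELTA_GRID[-1] * 0.999
    return delta, ll, beta, sigma_g2, Xw, boundary


def lmm_association(y, W, x, K=None, eig: KinshipEigen | None = None,
                    drug: str = "drug", variant: str = "variant"
                    ) -> AssociationRecord:
    """LR test of beta = 0 in the kinship LMM (chi^2, 1 df).

    Either ``K`` or a precomputed :class:`KinshipEigen` must be supplied.
    With K = I the model collapses to the plain linear model and P values
    agree with :func:`lm_association` exactly.
    """
    if eig is None:
        if K is None:
            raise ValueError("provide K or its eigendecomposition")
        eig = kinship_eigh(K)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    M = _design(W, n)
    yr = eig.U.T @ y
    Mr = eig.U.T @ M
    xr = eig.U.T @ x

    delta0, ll0, *_ = _fit_delta(eig.lam, yr, Mr)
    Xr = np.hstack([Mr, xr[:, None]])
    # include the null's optimum in the alternative's grid so LR >= 0 always
    delta1, ll1, beta_full, sigma_g2, Xw, boundary = _fit_delta(
        eig.lam, yr, Xr, extra_deltas=(delta0,))

    # collinearity check in the rotated weighted basis
    q, _ = np.linalg.qr(Xw[:, :-1])
    x_res = Xw[:, -1] - q @ (q.T @ Xw[:, -1])
    den = float(x_res @ x_res)
    flags: list[str] = []
    if den <= 1e-12 * max(1.0, float(Xw[:, -1] @ Xw[:, -1])):
        warnings.warn("variant collinear with covariates: test undefined")
        return AssociationRecord(drug, variant, np.nan, np.nan, np.nan,
                                 "germline", ll0, ll0, ("collinear",))
    if boundary:
        flags.append("delta_boundary")
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    beta = float(beta_full[-1])
    se = float(np.sqrt(sigma_g2 / den))
    return AssociationRecord(drug, variant, beta, se, p, "germline",
                             ll0, ll1, tuple(flags))


def lmm_scan(y, W, X, eig: KinshipEigen, refine_null: bool = True
             ) -> pd.DataFrame:
    """Vectorized LMM association of every column of X against y.

    The null model (no variant) is fitted once; each variant's delta is then
    optimized over the same log-spaced grid augmented with the null optimum,
    profiling beta and sigma_g^2 in closed form per grid point.  Returns a
    DataFrame with beta, se, p_value and log-likelihoods, row-aligned to X's
    columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    M = _design(W, n)
    yr = eig.U.T @ y
    Mr = eig.U.T @ M
    Xr = eig.U.T @ X

    delta0, ll0, *_ = _fit_delta(eig.lam, yr, Mr, refine=refine_null)
    grid = np.sort(np.unique(np.append(_DELTA_GRID, delta0)))
    G = grid.size

    lls = np.empty((G, m))
    nums = np.empty((G, m))
    dens = np.empty((G, m))
    rsss = np.empty((G, m))
    x_sq = (X ** 2).sum(axis=0)
    for g, delta in enumerate(grid):
        v = eig.lam + delta
        sw = 1.0 / np.sqrt(v)
        logdet = float(np.log(v).sum())
        Mw = Mr * sw[:, None]
        Q, _ = np.linalg.qr(Mw)
        yw = yr * sw
        y_res = yw - Q @ (Q.T @ yw)
        Xw = Xr * sw[:, None]
        X_res = Xw - Q @ (Q.T @ Xw)
        den = (X_res ** 2).sum(axis=0)
        num = X_res.T @ y_res
        rss_y = float(y_res @ y_res)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = np.maximum(rss_y - num * num / np.where(den > 0, den, np.inf),
                             1e-300)
        lls[g] = -0.5 * (n * _LOG2PI + n + n * np.log(rss / n) + logdet)
        nums[g], dens[g], rsss[g] = num, den, rss

    best = np.argmax(lls, axis=0)
    cols = np.arange(m)
    den_b = dens[best, cols]
    ok = den_b > 1e-12 * np.maximum(1.0, x_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, nums[best, cols] / den_b, np.nan)
        sigma_g2 = rsss[best, cols] / n
        se = np.where(ok, np.sqrt(sigma_g2 / den_b), np.nan)
    ll_alt = lls[best, cols]
    lr = np.where(ok, np.maximum(0.0, 2.0 * (ll_alt - ll0)), np.nan)
    p = stats.chi2.sf(lr, df=1)
    return pd.DataFrame({"beta": beta, "se": se, "p_value": p,
                         "ll_null": ll0, "ll_alt": ll_alt,
                         "delta": grid[best]})


# ---------------------------------------------------------------------------
# effect sizes and their comparison
# ---------------------------------------------------------------------------

def effect_size_original_scale(y_raw, W, x, K=None, eig: KinshipEigen | None = None,
                               test_type: str = "germline") -> float:
    """Effect size from refitting the chosen model on the raw 1-AUC scale
    (the P value companion comes from the quantile-normalized fit)."""
    if test_type == "somatic" or (K is None and eig is None):
        return lm_association(y_raw, W, x).beta
    return lmm_association(y_raw, W, x, K=K, eig=eig).beta


@dataclass
class EffectSizeComparison:
    mean_somatic: float
    sem_somatic: float
    mean_germline: float
    sem_germline: float
    t_stat: float
    p_value: float


def compare_qtl_effect_sizes(somatic_lead_betas, germline_lead_betas
                             ) -> EffectSizeComparison:
    """Welch two-sample t-test on |effect size| of somatic vs germline lead
    QTLs, with means +/- standard errors."""
    a = np.abs(np.asarray(somatic_lead_betas, dtype=float))
    b = np.abs(np.asarray(germline_lead_betas, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 effect sizes per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return EffectSizeComparison(
        mean_somatic=float(a.mean()), sem_somatic=float(stats.sem(a)),
        mean_germline=float(b.mean()), sem_germline=float(stats.sem(b)),
        t_stat=float(t), p_value=float(p),
    )
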