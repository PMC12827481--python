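"""Per-gene linear modelling with empirical-Bayes variance moderation.

Each gene is fitted by ordinary least squares to a design of an intercept,
optional donor/batch fixed effects, and a treatment indicator whose
coefficient is the treatment-vs-control contrast.  The design is QR
transformed so that the contrast occupies a single coordinate of the data
and the residuals occupy the remaining ``d`` orthonormal coordinates --
exactly the representation the rotation gene-set test resamples in.

Residual variances are shrunk toward a prior via the standard scaled-F
empirical-Bayes model: s_g^2 ~ s0^2 * F(d, d0) marginally under the null.
(d0, s0^2) are estimated by the method of moments on log s^2 using
digamma/trigamma identities; with ``trend=True`` the prior variance s0^2
becomes a smooth (lowess) function of average log-expression.  Moderated
t-statistics are mapped to normal-equivalent z-scores through the t CDF,
with log-space tails so large statistics do not saturate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

D0_CAP = 1e6  # prior df above this are reported as infinity


@dataclass
class ContrastFit:
    """Per-gene OLS fit of the treatment-minus-control contrast.

    ``effect_coord`` is the contrast-direction coordinate of the QR-rotated
    data (effect / unscaled SE); ``resid_coords`` (genes x d) are the
    residual-space coordinates, with ||resid_coords||^2 = d * s2.
    """

    gene_ids: list[str]
    effect: np.ndarray
    effect_se_unscaled: float
    s2: np.ndarray
    df_resid: int
    amean: np.ndarray
    effect_coord: np.ndarray
    resid_coords: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"effect": self.effect, "s2": self.s2, "amean": self.amean},
            index=self.gene_ids,
        )


@dataclass
class ModerationResult:
    """Empirical-Bayes moderated variances and statistics.

    ``s02`` is a scalar, or a per-gene array when a mean-variance trend is
    fitted.  ``df_total = d0 + d`` (np.inf when no shrinkage limit applies).
    """

    d0: float
    s02: float | np.ndarray
    s2_post: np.ndarray
    t: np.ndarray
    z: np.ndarray
    df_total: float
    trend: bool = False

    def s02_per_gene(self, n: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.s02, dtype=float), (n,)).copy()


def _design_matrix(groups: np.ndarray, donors: np.ndarray | None) -> np.ndarray:
    """Intercept + donor dummies + treatment indicator (last column)."""
    n = len(groups)
    cols = [np.ones(n)]
    if donors is not None:
        levels = pd.unique(donors)
        for lev in levels[1:]:
            cols.append((donors == lev).astype(float))
    cols.append((groups == "treatment").astype(float))
    return np.column_stack(cols)


def fit_contrast(matrix, design) -> ContrastFit:
    """Fit the treatment-vs-control contrast for every gene.

    ``matrix`` is a log-scale :class:`~aegis.expression.ExpressionMatrix`;
    ``design`` a :class:`~aegis.expression.SampleDesign` whose sample ids
    all appear in the matrix.  Donors enter as additive fixed effects when
    more than one level is present.
    """
    if matrix.scale != "log":
        raise ValueError("fit_contrast expects a log-scale matrix")
    design.check_matrix(matrix)
    tab = design.table
    m = matrix.subset_samples(list(tab["sample_id"]))
    groups = tab["group"].to_numpy()
    if "treatment" not in groups or "control" not in groups:
        raise ValueError("design needs both treatment and control samples")
    donors = tab["donor"].to_numpy() if tab["donor"].nunique() > 1 else None
    X = _design_matrix(groups, donors)
    n, p = X.shape
    d = n - p
    if d < 1:
        raise ValueError(f"fewer than 1 residual degree of freedom (n={n}, p={p})")
    Q, R = np.linalg.qr(X, mode="complete")
    diag = np.abs(np.diag(R[:p, :p]))
    if diag.min() < 1e-10 * diag.max():
        raise ValueError("rank-deficient design matrix")
    Y = m.values  # genes x n
    coords = Y @ Q  # genes x n
    sign = np.sign(R[p - 1, p - 1])
    effect_coord = coords[:, p - 1] * sign
    u = 1.0 / np.abs(R[p - 1, p - 1])  # unscaled SE of the contrast
    resid_coords = coords[:, p:]
    s2 = (resid_coords**2).sum(axis=1) / d
    return ContrastFit(
        gene_ids=list(m.gene_ids),
        effect=effect_coord * u,
        effect_se_unscaled=u,
        s2=s2,
        df_resid=d,
        amean=Y.mean(axis=1),
        effect_coord=effect_coord,
        resid_coords=resid_coords,
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_f_dist(s2: np.ndarray, df: int, covariate: np.ndarray | None = None,
                span: float = 0.5):
    """Moments-of-log-variance fit of s^2 ~ s0^2 F(df, d0).

    Returns (d0, s0^2) with s0^2 a scalar, or a per-gene array when a
    ``covariate`` (average log-expression) is given, in which case the
    location is a robustified lowess trend in the covariate.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 1e-18  # numerically-zero variances (exact data) carry no information
    if ok.sum() < 2:
        raise ValueError(
            "fewer than 2 positive residual variances; data are exact/degenerate"
        )
    e_all = np.full_like(s2, np.nan)
    e_all[ok] = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is None:
        loc = np.nanmean(e_all)
        resid = e_all[ok] - loc
        evar = resid.var(ddof=1)
    else:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        cov = np.asarray(covariate, dtype=float)
        fitted = lowess(e_all[ok], cov[ok], frac=span, it=1, return_sorted=False)
        # genes with s2 == 0 take the nearest fitted trend value
        loc = np.interp(cov, np.sort(cov[ok]), fitted[np.argsort(cov[ok])])
        resid = e_all[ok] - loc[ok]
        evar = resid.var(ddof=1)
    evar -= special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if d0 > D0_CAP:
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isinf(d0):
        # no dispersion beyond chi^2 sampling noise: the prior IS the variance
        if covariate is None:
            s02 = float(s2[ok].mean())
        else:
            s02 = np.exp(loc + special.digamma(df / 2.0) - np.log(df / 2.0))
    else:
        s02 = np.exp(loc + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return d0, s02


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Normal-equivalent scores: z = Phi^-1(F_t(t; df)), computed through
    log-space tails so |t| up to hundreds maps without saturating."""
    t = np.asarray(t, dtype=float)
    if np.isinf(df):
        return t.copy()
    z = np.empty_like(t)
    pos = t >= 0
    with np.errstate(divide="ignore"):
        z[pos] = -special.ndtri_exp(stats.t.logsf(t[pos], df))
        z[~pos] = special.ndtri_exp(stats.t.logcdf(t[~pos], df))
    return z


def moderate(
    fit: ContrastFit,
    trend: bool = False,
    prior_df: float | None = None,
    prior_var: float | np.ndarray | None = None,
) -> ModerationResult:
    """Shrink per-gene variances and form moderated t and z statistics.

    s2_post = (d0 * s0^2 + d * s2) / (d0 + d);  t = effect_coord / s~;
    z = Phi^-1(F_t(t; d0 + d)).  ``prior_df``/``prior_var`` override the
    estimated hyperparameters (``prior_df=0`` recovers the ordinary t).
    """
    d = fit.df_resid
    if prior_df is not None and prior_var is not None:
        d0, s02 = float(prior_df), prior_var
    elif prior_df is not None or prior_var is not None:
        raise ValueError("override both prior_df and prior_var, or neither")
    else:
        d0, s02 = _fit_f_dist(fit.s2, d, covariate=fit.amean if trend else None)
    s02_arr = np.broadcast_to(np.asarray(s02, dtype=float), fit.s2.shape)
    if np.isinf(d0):
        s2_post = s02_arr.copy()
        df_total = np.inf
    elif d0 == 0:
        s2_post = fit.s2.copy()
        df_total = float(d)
    else:
        s2_post = (d0 * s02_arr + d * fit.s2) / (d0 + d)
        df_total = float(d0 + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.effect_coord / np.sqrt(s2_post)
    t = np.where(np.isnan(t), 0.0, t)
    z = t_to_z(t, df_total)
    return ModerationResult(
        d0=d0, s02=s02 if np.ndim(s02) else float(np.asarray(s02)),
        s2_post=s2_post, t=t, z=z, df_total=df_total, trend=trend,
    )
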