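"""Linear mixed models with Gaussian spatial residual correlation.

The driver analyses need random intercepts (study nested in taxonomic
group) *and* spatially correlated residuals, a combination none of the
installed Python model libraries offers, so the REML machinery lives
here. The marginal covariance is

    V = sigma2 * ( sum_k gamma_k Z_k Z_k' + C(rho, nu) )

where ``Z_k`` are random-intercept indicator matrices with variance
ratios ``gamma_k``, and ``C`` is the residual correlation:
``C_ij = (1 - nu) exp(-(d_ij / rho)^2) + nu 1[i = j]`` for the Gaussian
spatial structure (identity when the spatial component is off). Variance
ratios (and the optional nugget ``nu``) are estimated by maximising the
restricted likelihood with the range ``rho`` profiled over a log-spaced
grid of pairwise distances — robust, and it makes the "reported rho
maximises the profile" property directly checkable. Fixed-effect
inference is Wald t with ``n - p`` residual degrees of freedom.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize, stats

from .types import ModelFit

EARTH_RADIUS_KM = 6371.0
_JITTER = 1e-8  # diagonal stabiliser for coincident-site correlations


def great_circle_km(lat, lon) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) from degree coordinates."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def planar_degree_distance(lat, lon) -> np.ndarray:
    """Euclidean distance in raw degrees (precedent-mirroring alternative)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return np.hypot(lat[:, None] - lat[None, :], lon[:, None] - lon[None, :])


def _group_indicators(data: pd.DataFrame, groups: Sequence[str],
                      nested: bool) -> dict[str, np.ndarray]:
    """Indicator matrix per random-intercept level; nesting by key composition."""
    out = {}
    for k, col in enumerate(groups):
        if nested and k > 0:
            labels = data[list(groups[: k + 1])].astype(str).agg(":".join, axis=1)
        else:
            labels = data[col].astype(str)
        codes, _ = pd.factorize(labels)
        Z = np.zeros((len(data), codes.max() + 1))
        Z[np.arange(len(data)), codes] = 1.0
        out[col] = Z
    return out


def _design(data: pd.DataFrame, formula: str):
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    Xm = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        _, R, piv = linalg.qr(Xm, mode="economic", pivoting=True)
        tol = np.abs(R[0, 0]) * max(Xm.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(Xm.shape[1])
                   if abs(R[i, i]) <= tol]
        raise ValueError(f"singular design; aliased terms: {aliased}")
    return y.to_numpy(dtype=float).ravel(), Xm, list(X.columns)


def _reml_pieces(y, X, W):
    """(beta, sigma2, cov_unscaled, reml_loglik, chol) for one W."""
    n, p = X.shape
    c, low = linalg.cho_factor(W, lower=True)
    WiX = linalg.cho_solve((c, low), X)
    Wiy = linalg.cho_solve((c, low), y)
    XtWiX = X.T @ WiX
    beta = linalg.solve(XtWiX, X.T @ Wiy, assume_a="pos")
    r = y - X @ beta
    Wir = linalg.cho_solve((c, low), r)
    quad = float(r @ Wir)
    sigma2 = quad / (n - p)
    logdet_W = 2.0 * float(np.sum(np.log(np.diag(c))))
    sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0)
                 + logdet_W + logdet_XtWiX)
    cov_unscaled = linalg.inv(XtWiX)
    return beta, sigma2, cov_unscaled, ll, (c, low)


def _spatial_corr(dist: np.ndarray, rho: float, nugget: float) -> np.ndarray:
    corr = np.exp(-((dist / rho) ** 2))
    C = (1.0 - nugget) * corr
    np.fill_diagonal(C, 1.0)
    return C


def default_rho_grid(dist: np.ndarray, n_rho: int = 10) -> np.ndarray:
    """Log-spaced candidate ranges between the 1st and 99th distance percentiles."""
    d = dist[np.triu_indices_from(dist, k=1)]
    d = d[d > 0]
    if d.size == 0:
        return np.array([1.0])
    lo, hi = np.percentile(d, [1, 99])
    lo = max(lo, 1e-6)
    hi = max(hi, lo * (1 + 1e-6))
    return np.geomspace(lo, hi, n_rho)


def fit_lmm(data: pd.DataFrame, formula: str,
            groups: Sequence[str] = (), nested: bool = True,
            spatial: str = "none",
            coords: tuple[str, str] = ("latitude", "longitude"),
            distance: str = "greatcircle",
            rho_grid: Optional[np.ndarray] = None, n_rho: int = 10,
            nugget: bool = False) -> ModelFit:
    """Fit a linear mixed model by REML.

    Parameters
    ----------
    data : one row per site; must contain every formula term, the
        grouping columns, and the coordinate columns when spatial != "none".
    formula : patsy formula, e.g. ``"rate ~ temp_change * realm"``.
    groups : random-intercept grouping columns, outermost first; with
        ``nested`` each level's labels are composed with the outer ones
        (study nested in taxonomic group).
    spatial : "gaussian" for the distance-decaying residual correlation,
        "none" for independent residuals.
    rho_grid : candidate spatial ranges; defaults to a log-spaced grid
        between the 1st and 99th percentiles of pairwise distances.
    nugget : also estimate a nugget proportion in (0, 1).

    Returns a :class:`~thermoshift.types.ModelFit`.
    """
    data = data.reset_index(drop=True)
    y, X, terms = _design(data, formula)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    Zs = _group_indicators(data, groups, nested)
    for col, Z in Zs.items():
        if Z.shape[1] < 2:
            raise ValueError(f"random level {col!r} needs >= 2 groups")
    Ks = {col: Z @ Z.T for col, Z in Zs.items()}
    group_names = list(Ks)

    if spatial == "gaussian":
        if distance == "greatcircle":
            dist = great_circle_km(data[coords[0]], data[coords[1]])
        elif distance == "planar":
            dist = planar_degree_distance(data[coords[0]], data[coords[1]])
        else:
            raise ValueError(f"unknown distance: {distance}")
        rhos = (np.asarray(rho_grid, dtype=float) if rho_grid is not None
                else default_rho_grid(dist, n_rho))
    elif spatial == "none":
        dist, rhos = None, np.array([np.nan])
    else:
        raise ValueError(f"unknown spatial spec: {spatial}")

    I = np.eye(n)

    def build_W(theta: np.ndarray, rho: float) -> np.ndarray:
        gammas = np.exp(theta[: len(group_names)])
        if spatial == "gaussian":
            nu = (1.0 / (1.0 + np.exp(-theta[-1]))) if nugget else 0.0
            # jitter keeps W factorable when sites share coordinates
            C = _spatial_corr(dist, rho, nu) + _JITTER * I
        else:
            C = I
        W = C.copy()
        for g, name in zip(gammas, group_names):
            W = W + g * Ks[name]
        return W

    n_theta = len(group_names) + (1 if nugget and spatial == "gaussian" else 0)
    converged = True
    best = None  # (ll, rho, theta)
    for rho in rhos:
        if n_theta == 0:
            theta_hat = np.empty(0)
            ll = _reml_pieces(y, X, build_W(theta_hat, rho))[3]
        else:
            def neg_ll(theta, rho=rho):
                try:
                    return -_reml_pieces(y, X, build_W(theta, rho))[3]
                except linalg.LinAlgError:
                    return np.inf
            x0 = np.zeros(n_theta)
            res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-6, "fatol": 1e-8,
                                             "maxiter": 2000})
            if not res.success:
                converged = False
            theta_hat, ll = res.x, -res.fun
        if best is None or ll > best[0]:
            best = (ll, rho, theta_hat)

    ll, rho_hat, theta_hat = best
    W = build_W(theta_hat, rho_hat)
    beta, sigma2, cov_unscaled, ll, _ = _reml_pieces(y, X, W)
    cov = sigma2 * cov_unscaled
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    df = n - p
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    gammas = np.exp(theta_hat[: len(group_names)]) if n_theta else np.array([])
    vc = {name: float(g * sigma2) for name, g in zip(group_names, gammas)}
    nu = 0.0
    if nugget and spatial == "gaussian":
        nu = float(1.0 / (1.0 + np.exp(-theta_hat[-1])))
    fitted = X @ beta
    fit = ModelFit(terms=terms, params=beta, se=se, tvalues=tvals,
                   pvalues=pvals, vc=vc, sigma2=float(sigma2),
                   rho=None if spatial == "none" else float(rho_hat),
                   nugget=nu, loglik=float(ll), n_used=n, df_resid=df,
                   residuals=y - fitted, fitted=fitted, converged=converged)
    fit.cov_params = cov
    fit.spec = {"formula": formula, "groups": tuple(groups), "nested": nested,
                "spatial": spatial, "coords": coords, "distance": distance,
                "rho_grid": None if rho_grid is None else np.asarray(rho_grid),
                "n_rho": n_rho, "nugget": nugget}
    return fit


def reml_profile(data: pd.DataFrame, formula: str, rhos: Sequence[float],
                 **kwargs) -> pd.DataFrame:
    """Restricted log-likelihood at each candidate spatial range."""
    rows = []
    for rho in rhos:
        fit = fit_lmm(data, formula, spatial="gaussian",
                      rho_grid=np.array([rho]), **kwargs)
        rows.append({"rho": rho, "loglik": fit.loglik})
    return pd.DataFrame(rows)


def refit_without_outliers(fit: ModelFit, data: pd.DataFrame,
                           k_sd: float = 2.0) -> ModelFit:
    """Refit once after dropping residual outliers.

    Points whose marginal residual lies more than ``k_sd`` sample
    standard deviations from the residual mean are excluded; the model is
    refit a single time (no iteration) with the specification stored on
    the original fit. With ``k_sd = inf`` or no outliers the refit is an
    identical re-estimation.
    """
    if fit.residuals is None or not hasattr(fit, "spec"):
        raise ValueError("fit carries no residuals/spec to refit from")
    resid = np.asarray(fit.residuals)
    centred = np.abs(resid - resid.mean())
    sd = resid.std(ddof=1)
    if np.allclose(resid, resid.mean()):  # effectively constant residuals
        keep = np.ones(len(resid), bool)
    else:
        keep = ~(centred > k_sd * sd)
    if keep.all():
        new = fit
        excluded = []
    else:
        data = data.reset_index(drop=True)
        excluded = list(data.index[~keep])
        spec = dict(fit.spec)
        new = fit_lmm(data.loc[keep], spec.pop("formula"), **spec)
    new.excluded = excluded
    return new
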