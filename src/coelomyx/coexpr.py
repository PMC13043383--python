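"""Depth-aware gene-gene co-expression from UMI counts.

UMI counts are modelled as Poisson thinnings of latent expression:
X_ij | z_ij ~ Poisson(s_i z_ij) with E z_ij = mu_j and
Cov(z_ij, z_ik) = sigma_jk, where s_i is the cell's sequencing depth. Naive
Pearson correlation of raw counts is attenuated by Poisson noise and inflated
by shared depth; this estimator removes both by solving the moment conditions

    E[X_ij - s_i mu_j]                                     = 0
    E[(X_ij - s_i mu_j)^2 - s_i mu_j - s_i^2 sigma_jj]     = 0
    E[(X_ij - s_i mu_j)(X_ik - s_i mu_k) - s_i^2 sigma_jk] = 0

by iteratively reweighted least squares, weighting each condition by the
inverse of its estimated variance (g_ij = s_i mu_j + s_i^2 sigma_jj for the
mean equation, g^2 for the variance equation, g_ij g_ik for the covariance
equation). The co-expression estimate is the implied latent correlation
rho_jk = sigma_jk / sqrt(sigma_jj sigma_kk), and the test of sigma_jk = 0
refers the weighted-least-squares slope over its standard error to the
standard normal.

Differential co-expression between two cell groups is assessed with a
label-permutation test on the treated-minus-control difference in rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stats_enrich import benjamini_hochberg

WEIGHT_FLOOR = 1e-10


@dataclass
class MarginalFit:
    """Converged per-gene marginal estimates on a count block."""

    mu: np.ndarray
    sigma: np.ndarray  # latent variance, may be negative pre-clip
    converged: np.ndarray
    n_iter: int


def _as_dense(X) -> np.ndarray:
    if hasattr(X, "todense"):
        return np.asarray(X.todense(), float)
    return np.asarray(X, float)


def fit_marginals(
    X: np.ndarray, depths: np.ndarray, max_iter: int = 10, tol: float = 1e-5
) -> MarginalFit:
    """IRLS estimates of mu_j and sigma_jj for every column of ``X``.

    Initialized with unit weights; iterates until the maximum relative change
    of (mu, sigma) drops below ``tol`` or ``max_iter`` is reached (the last
    iterate is returned either way, with per-gene convergence flags).
    """
    X = _as_dense(X)
    s = np.asarray(depths, float)
    if np.any(s <= 0):
        raise ValueError("depths must be > 0")
    s2 = s**2
    s_col = s[:, None]

    # unit-weight initialization
    mu = (s @ X) / s2.sum()
    e = X - s_col * mu
    y = e**2 - s_col * mu
    sigma = (s2 @ y) / (s2**2).sum()

    converged = np.zeros(X.shape[1], bool)
    it = 0
    for it in range(1, max_iter + 1):
        g = s_col * mu + s2[:, None] * np.clip(sigma, 0.0, None)
        g = np.maximum(g, WEIGHT_FLOOR)
        mu_new = ((s_col * X) / g).sum(0) / ((s2[:, None]) / g).sum(0)
        e = X - s_col * mu_new
        y = e**2 - s_col * mu_new
        g2 = g**2
        sigma_new = ((s2[:, None] * y) / g2).sum(0) / ((s2[:, None] ** 2) / g2).sum(0)
        scale = np.maximum(np.abs(mu), 1e-12), np.maximum(np.abs(sigma), 1e-12)
        delta = np.maximum(
            np.abs(mu_new - mu) / scale[0], np.abs(sigma_new - sigma) / scale[1]
        )
        mu, sigma = mu_new, sigma_new
        converged = delta < tol
        if converged.all():
            break
    return MarginalFit(mu=mu, sigma=sigma, converged=converged, n_iter=it)


def _pair_covariance(
    X: np.ndarray, s: np.ndarray, fit: MarginalFit, jidx: np.ndarray, kidx: np.ndarray
):
    """WLS covariance estimates and z statistics for index pairs (j, k)."""
    s_col = s[:, None]
    s2 = s**2
    e = X - s_col * fit.mu
    g = s_col * fit.mu + s2[:, None] * np.clip(fit.sigma, 0.0, None)
    g = np.maximum(g, WEIGHT_FLOOR)
    P = e / g
    R = s2[:, None] / g
    num = (s2[:, None] * P[:, jidx] * P[:, kidx]).sum(0)
    den = (R[:, jidx] * R[:, kidx]).sum(0)
    sigma_jk = num / den
    z = sigma_jk * np.sqrt(den)
    return sigma_jk, z


def _records_for_pairs(X, s, fit, jidx, kidx):
    """Assemble rho/p/flags for pairs given a marginal fit."""
    sigma = fit.sigma
    sigma_clip = np.clip(sigma, 0.0, None)
    self_pair = jidx == kidx
    sigma_jk = np.empty(len(jidx))
    z = np.empty(len(jidx))
    if np.any(~self_pair):
        sjk, zz = _pair_covariance(X, s, fit, jidx[~self_pair], kidx[~self_pair])
        sigma_jk[~self_pair] = sjk
        z[~self_pair] = zz
    if np.any(self_pair):
        j = jidx[self_pair]
        # self pair: sigma_jk is the marginal variance; z from the variance equation
        s2 = s**2
        g = s[:, None] * fit.mu[j] + s2[:, None] * sigma_clip[j]
        g = np.maximum(g, WEIGHT_FLOOR)
        den = ((s2[:, None] ** 2) / g**2).sum(0)
        sigma_jk[self_pair] = sigma[j]
        z[self_pair] = sigma[j] * np.sqrt(den / 2.0)

    denom = np.sqrt(sigma_clip[jidx] * sigma_clip[kidx])
    valid = (sigma_clip[jidx] > 0) & (sigma_clip[kidx] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(valid, sigma_jk / np.where(denom > 0, denom, np.nan), np.nan)
    clipped = valid & (np.abs(rho) > 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    neg_var = (sigma[jidx] < 0) | (sigma[kidx] < 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return sigma_jk, rho, z, p, valid, clipped | neg_var


def estimate_coexpression(
    counts,
    depths,
    pairs,
    gene_names=None,
    max_iter: int = 10,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Estimate latent co-expression for a list of gene pairs.

    ``counts`` is cells x genes (AnnData, sparse or dense); ``depths`` the
    per-cell sequencing depths (by convention the per-cell total UMI count
    over all genes of the matrix; pass ``None`` to compute that). ``pairs``
    is a sequence of (gene_j, gene_k) names (or integer column pairs when
    ``gene_names`` is None and counts is an array).

    Returns one record per pair with mu/sigma estimates, the clipped latent
    correlation ``rho``, the normal-theory p for sigma_jk = 0, BH ``q``
    across the supplied pairs, and a validity flag (False when either latent
    variance is non-positive, so rho is undefined) plus a ``flagged`` column
    marking clipping or negative-variance repairs.
    """
    if hasattr(counts, "X"):  # AnnData
        gene_names = list(counts.var_names)
        X_full = counts.X
    else:
        X_full = counts
    if depths is None:
        depths = np.asarray(
            X_full.sum(axis=1), float
        ).ravel() if hasattr(X_full, "tocsr") else np.asarray(X_full, float).sum(axis=1)
    depths = np.asarray(depths, float)

    if gene_names is not None:
        name_to_idx = {g: i for i, g in enumerate(gene_names)}
        missing = [g for jk in pairs for g in jk if g not in name_to_idx]
        if missing:
            raise KeyError(f"pair genes absent from the matrix: {sorted(set(missing))}")
        full_j = np.array([name_to_idx[j] for j, _ in pairs])
        full_k = np.array([name_to_idx[k] for _, k in pairs])
    else:
        full_j = np.array([j for j, _ in pairs], int)
        full_k = np.array([k for _, k in pairs], int)

    used = np.unique(np.concatenate([full_j, full_k]))
    remap = {int(g): i for i, g in enumerate(used)}
    jidx = np.array([remap[int(j)] for j in full_j])
    kidx = np.array([remap[int(k)] for k in full_k])
    X = _as_dense(X_full[:, used])

    fit = fit_marginals(X, depths, max_iter=max_iter, tol=tol)
    if not fit.converged.all():
        warnings.warn("IRLS did not converge for some genes; last iterate used")
    sigma_jk, rho, z, p, valid, flagged = _records_for_pairs(X, depths, fit, jidx, kidx)

    table = pd.DataFrame(
        {
            "gene_j": [j for j, _ in pairs],
            "gene_k": [k for _, k in pairs],
            "mu_j": fit.mu[jidx],
            "mu_k": fit.mu[kidx],
            "sigma_jj": fit.sigma[jidx],
            "sigma_kk": fit.sigma[kidx],
            "sigma_jk": sigma_jk,
            "rho": rho,
            "z": z,
            "p": np.where(valid, p, np.nan),
            "valid": valid,
            "flagged": flagged | ~fit.converged[jidx] | ~fit.converged[kidx],
        }
    )
    table["q"] = benjamini_hochberg(table["p"])
    return table


def filter_significant_pairs(
    records: pd.DataFrame, q_threshold: float = 0.05, rho_threshold: float = 0.5
) -> pd.DataFrame:
    """Retain valid pairs with q < ``q_threshold`` (strict) and signed
    rho > ``rho_threshold`` (strict)."""
    keep = (
        records["valid"]
        & (records["q"] < q_threshold)
        & (records["rho"] > rho_threshold)
    )
    return records.loc[keep.fillna(False)]


# ---------------------------------------------------------------------------
# permutation differential co-expression
# ---------------------------------------------------------------------------


def _rho_by_groups(X, s, group_mask, jidx, kidx, max_iter, tol):
    """rho per pair in each of the two groups defined by a boolean mask."""
    out = []
    for mask in (group_mask, ~group_mask):
        fit = fit_marginals(X[mask], s[mask], max_iter=max_iter, tol=tol)
        _, rho, _, _, valid, _ = _records_for_pairs(X[mask], s[mask], fit, jidx, kidx)
        out.append((rho, valid))
    (rho_a, valid_a), (rho_b, valid_b) = out
    return rho_a, rho_b, valid_a & valid_b


def differential_coexpression(
    counts_ctrl,
    counts_trt,
    pairs,
    gene_names=None,
    depths_ctrl=None,
    depths_trt=None,
    n_per_group: int = 10000,
    n_permutations: int = 1000,
    seed: int | None = None,
    max_iter: int = 10,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """Permutation test for treated-minus-control co-expression differences.

    ``min(n_per_group, available)`` cells per group are subsampled once
    without replacement (seeded); the observed difference
    delta = rho_treated - rho_control is computed on the subsample; the two
    subsamples are then pooled and group labels permuted ``n_permutations``
    times, re-estimating delta each round. The two-sided p-value uses the
    add-one convention p = (1 + #{|delta_b| >= |delta|}) / (B + 1);
    permutation rounds where either group's estimate is invalid for a pair
    are dropped for that pair (reducing its B, recorded in ``B_used``). BH
    adjustment is across pairs.
    """
    rng = np.random.default_rng(seed)

    def prep(counts, depths):
        if hasattr(counts, "X"):
            names = list(counts.var_names)
            X = counts.X
        else:
            names, X = gene_names, counts
        if depths is None:
            depths = (
                np.asarray(X.sum(axis=1), float).ravel()
                if hasattr(X, "tocsr")
                else np.asarray(X, float).sum(axis=1)
            )
        return names, X, np.asarray(depths, float)

    names_c, Xc, sc_ = prep(counts_ctrl, depths_ctrl)
    names_t, Xt, st_ = prep(counts_trt, depths_trt)
    names = names_c if names_c is not None else names_t

    if Xc.shape[0] < 50 or Xt.shape[0] < 50:
        raise ValueError("each group needs at least 50 cells")

    if names is not None:
        name_to_idx = {g: i for i, g in enumerate(names)}
        full_j = np.array([name_to_idx[j] for j, _ in pairs])
        full_k = np.array([name_to_idx[k] for _, k in pairs])
    else:
        full_j = np.array([j for j, _ in pairs], int)
        full_k = np.array([k for _, k in pairs], int)
    used = np.unique(np.concatenate([full_j, full_k]))
    remap = {int(g): i for i, g in enumerate(used)}
    jidx = np.array([remap[int(j)] for j in full_j])
    kidx = np.array([remap[int(k)] for k in full_k])

    n_c = min(n_per_group, Xc.shape[0])
    n_t = min(n_per_group, Xt.shape[0])
    pick_c = rng.choice(Xc.shape[0], size=n_c, replace=False)
    pick_t = rng.choice(Xt.shape[0], size=n_t, replace=False)
    Xp = np.vstack([_as_dense(Xc[pick_c][:, used]), _as_dense(Xt[pick_t][:, used])])
    sp_ = np.concatenate([sc_[pick_c], st_[pick_t]])
    is_trt = np.zeros(n_c + n_t, bool)
    is_trt[n_c:] = True

    rho_t, rho_c, valid_obs = _rho_by_groups(Xp, sp_, is_trt, jidx, kidx, max_iter, tol)
    delta_obs = rho_t - rho_c

    B = n_permutations
    exceed = np.zeros(len(pairs))
    b_used = np.zeros(len(pairs), int)
    for _ in range(B):
        perm = rng.permutation(n_c + n_t)
        mask_b = np.zeros(n_c + n_t, bool)
        mask_b[perm[:n_t]] = True
        rt, rc, vb = _rho_by_groups(Xp, sp_, mask_b, jidx, kidx, max_iter, tol)
        db = rt - rc
        ok = vb & np.isfinite(db)
        exceed[ok] += np.abs(db[ok]) >= np.abs(delta_obs[ok])
        b_used += ok

    with np.errstate(invalid="ignore"):
        p = (1.0 + exceed) / (b_used + 1.0)
    p = np.where(valid_obs & (b_used > 0), p, np.nan)
    table = pd.DataFrame(
        {
            "gene_j": [j for j, _ in pairs],
            "gene_k": [k for _, k in pairs],
            "rho_treated": rho_t,
            "rho_control": rho_c,
            "delta": delta_obs,
            "p": p,
            "valid": valid_obs,
            "n_control": n_c,
            "n_treated": n_t,
            "B_used": b_used,
            "B": B,
            "seed": seed if seed is not None else -1,
        }
    )
    table["q"] = benjamini_hochberg(table["p"])
    table["significant"] = table["q"] < 0.05
    return table
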