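"""Negative-exponential distance decay of community similarity.

Community similarity (1 - Sørensen dissimilarity) is modelled as a
negative-exponential function of environmental distance, here the absolute
difference in base flow index (BFI) between sample pairs:

    E[S] = exp(b0 + b1 * d)

The model is a Gaussian GLM with a log link, fitted by iteratively
reweighted least squares (IRLS).  Goodness of fit is a deviance-based
pseudo-R², the proportional reduction in deviance relative to the
intercept-only model.  Because sample pairs sharing a site are not
independent, significance comes from permuting BFI labels across whole
sites, and slopes between two datasets (e.g. AAV vs OTU tables of the same
gene) are compared by a cluster bootstrap over sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DecayFit",
    "ConvergenceError",
    "delta_bfi",
    "attach_delta_bfi",
    "fit_negative_exponential",
    "permutation_significance",
    "bootstrap_compare_slopes",
]


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last iterate for diagnosis."""


@dataclass
class DecayFit:
    """A fitted negative-exponential decay model.

    ``intercept`` is on the log scale (ln of similarity at zero distance)
    and ``rate`` is the decay slope per unit distance (negative when
    similarity declines).  ``pseudo_r2`` is 1 - residual/null deviance.
    """

    intercept: float
    rate: float
    pseudo_r2: float
    null_deviance: float
    residual_deviance: float
    n_pairs: int
    p_value: float | None = None
    family: str = "gaussian"
    link: str = "log"
    n_iter: int = 0

    def predict(self, distance) -> np.ndarray:
        d = np.asarray(distance, dtype=float)
        return np.exp(self.intercept + self.rate * d)


def delta_bfi(meta: pd.DataFrame) -> pd.DataFrame:
    """Pairwise absolute BFI differences between samples.

    ``meta`` must have columns ``sample_id`` and ``bfi``.  Returns a long
    table (sample_i, sample_j, delta_bfi) over all n*(n-1)/2 unordered
    pairs, matching the pair ordering used by
    :func:`bficomm.community_structure.pairwise_dissimilarity`.
    """
    if len(meta) < 2:
        raise ValueError("need at least two samples")
    ids = meta["sample_id"].to_numpy()
    bfi = meta["bfi"].to_numpy(dtype=float)
    rows = [
        (ids[i], ids[j], abs(bfi[i] - bfi[j]))
        for i, j in itertools.combinations(range(len(ids)), 2)
    ]
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "delta_bfi"])


def attach_delta_bfi(pairs: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Add a ``delta_bfi`` column to a pairwise table.

    Unlike a join against :func:`delta_bfi`, this maps each sample to its
    BFI directly, so pair orientation (i, j) vs (j, i) cannot drop rows.
    """
    bfi = meta.set_index("sample_id")["bfi"]
    bfi_i = pairs["sample_i"].map(bfi)
    bfi_j = pairs["sample_j"].map(bfi)
    if bfi_i.isna().any() or bfi_j.isna().any():
        missing = set(pairs.loc[bfi_i.isna(), "sample_i"]) | set(
            pairs.loc[bfi_j.isna(), "sample_j"]
        )
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    return pairs.assign(delta_bfi=(bfi_i - bfi_j).abs())


def _irls_log_gaussian(y, d, max_iter=200, tol=1e-12):
    """Gaussian GLM with log link via IRLS; returns (beta, mu, n_iter)."""
    X = np.column_stack([np.ones_like(d), d])
    # start from a log-linear regression on similarity floored away from 0
    eps = max(1e-6, 1e-3 * float(np.max(y))) if np.max(y) > 0 else 1e-6
    z0 = np.log(np.clip(y, eps, None))
    beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    dev = np.sum((y - mu) ** 2)
    for it in range(1, max_iter + 1):
        w = mu**2  # (dmu/deta)^2 / V(mu) with V = 1
        z = eta + (y - mu) / mu
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ConvergenceError(f"singular IRLS system at iter {it}") from exc
        eta = np.clip(X @ beta_new, -30.0, 30.0)
        mu = np.exp(eta)
        dev_new = np.sum((y - mu) ** 2)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < 1e-10 or abs(dev - dev_new) < tol * (dev + tol):
            return beta, mu, it
        dev = dev_new
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(last beta={beta}, deviance={dev:.6g})"
    )


def fit_negative_exponential(similarity, distance) -> DecayFit:
    """Fit E[S] = exp(b0 + b1*d) to pairwise similarities.

    Parameters
    ----------
    similarity : array-like of float in [0, 1]
        Pairwise community similarity, 1 - Sørensen dissimilarity.
    distance : array-like of float
        Pairwise environmental distance (|ΔBFI|), same length.

    Zero-similarity pairs are retained: the log link constrains the mean,
    not the observations.
    """
    y = np.asarray(similarity, dtype=float)
    d = np.asarray(distance, dtype=float)
    if y.shape != d.shape:
        raise ValueError("similarity and distance must have equal length")
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("need at least three pairs to fit a decay model")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(d)):
        raise ValueError("non-finite values in similarity or distance")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("similarities must lie in [0, 1]")
    if np.all(y == 0):
        raise ValueError("all similarities are zero; decay model undefined")
    beta, mu, n_iter = _irls_log_gaussian(y, d)
    residual_deviance = float(np.sum((y - mu) ** 2))
    null_deviance = float(np.sum((y - y.mean()) ** 2))
    if null_deviance <= 0:
        pseudo_r2 = 0.0
    else:
        pseudo_r2 = 1.0 - residual_deviance / null_deviance
    pseudo_r2 = float(min(1.0, max(0.0, pseudo_r2)))
    return DecayFit(
        intercept=float(beta[0]),
        rate=float(beta[1]),
        pseudo_r2=pseudo_r2,
        null_deviance=null_deviance,
        residual_deviance=residual_deviance,
        n_pairs=len(y),
    )


def _pair_table(pairs: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Join site/BFI metadata onto a pairwise similarity table."""
    required = {"sample_i", "sample_j", "similarity"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pair table needs columns {sorted(required)}")
    site = meta.set_index("sample_id")["site_id"]
    out = pairs.copy()
    out["site_i"] = out["sample_i"].map(site)
    out["site_j"] = out["sample_j"].map(site)
    if out[["site_i", "site_j"]].isna().any().any():
        missing = set(out.loc[out["site_i"].isna(), "sample_i"]) | set(
            out.loc[out["site_j"].isna(), "sample_j"]
        )
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    return out


def permutation_significance(
    pairs: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> DecayFit:
    """Site-level permutation test for a distance-decay relationship.

    ``pairs`` holds one row per sample pair with columns ``sample_i``,
    ``sample_j`` and ``similarity``; ``meta`` maps ``sample_id`` to
    ``site_id`` and ``bfi`` (one BFI per site).  BFI values are shuffled
    across whole sites — not across individual pairs — so the pairwise
    dependence structure is preserved under the null.  The p-value is
    (1 + #{permuted pseudo-R² >= observed}) / (n_perm + 1).

    Returns the observed :class:`DecayFit` with ``p_value`` filled in.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    tab = _pair_table(pairs, meta)
    site_bfi = (
        meta.drop_duplicates("site_id").set_index("site_id")["bfi"].sort_index()
    )
    sites = site_bfi.index.to_numpy()
    if len(sites) < 4:
        raise ValueError(
            f"only {len(sites)} distinct sites; permutation space too small"
        )
    y = tab["similarity"].to_numpy(dtype=float)
    i_idx = pd.Categorical(tab["site_i"], categories=sites).codes
    j_idx = pd.Categorical(tab["site_j"], categories=sites).codes
    bfi = site_bfi.to_numpy(dtype=float)
    observed = fit_negative_exponential(y, np.abs(bfi[i_idx] - bfi[j_idx]))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(bfi)
        d_perm = np.abs(perm[i_idx] - perm[j_idx])
        try:
            fit_p = fit_negative_exponential(y, d_perm)
        except (ConvergenceError, ValueError):
            # a pathological permutation counts as non-exceeding evidence
            continue
        if fit_p.pseudo_r2 >= observed.pseudo_r2:
            exceed += 1
    observed.p_value = (1 + exceed) / (n_perm + 1)
    return observed


@dataclass
class SlopeComparison:
    """Cluster-bootstrap comparison of two decay slopes."""

    rate_a: float
    rate_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    p_value: float
    n_boot: int
    boot_rates_a: np.ndarray = field(repr=False, default=None)
    boot_rates_b: np.ndarray = field(repr=False, default=None)


def _resample_fit(tab, sites, rng):
    """One cluster-bootstrap refit; redraws until >= 3 distinct sites."""
    for _ in range(100):
        draw = rng.choice(len(sites), size=len(sites), replace=True)
        if len(np.unique(draw)) >= 3:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw a resample with 3 distinct sites")
    chosen = [sites[k] for k in draw]
    parts = []
    for i, j in itertools.combinations(range(len(chosen)), 2):
        si, sj = chosen[i], chosen[j]
        if si == sj:
            sub = tab[(tab["site_i"] == si) & (tab["site_j"] == si)]
        else:
            sub = tab[
                ((tab["site_i"] == si) & (tab["site_j"] == sj))
                | ((tab["site_i"] == sj) & (tab["site_j"] == si))
            ]
        if len(sub):
            parts.append(sub)
    boot = pd.concat(parts, ignore_index=True)
    return fit_negative_exponential(
        boot["similarity"].to_numpy(), boot["delta_bfi"].to_numpy()
    )


def bootstrap_compare_slopes(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    meta: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> SlopeComparison:
    """Compare decay rates of two datasets sharing a site set.

    Sites are resampled with replacement; every sample pair among the
    resampled sites (including within-site replicate pairs when a site is
    drawn more than once) enters each refit.  Reports percentile 95% CIs
    for each rate and a two-sided bootstrap p-value for rate_a - rate_b.
    """
    site_bfi = (
        meta.drop_duplicates("site_id").set_index("site_id")["bfi"].sort_index()
    )
    sites = list(site_bfi.index)
    tabs = []
    for pairs in (pairs_a, pairs_b):
        tab = _pair_table(pairs, meta)
        bfi_i = tab["site_i"].map(site_bfi)
        bfi_j = tab["site_j"].map(site_bfi)
        tab["delta_bfi"] = (bfi_i - bfi_j).abs()
        tabs.append(tab)
    tab_a, tab_b = tabs
    fit_a = fit_negative_exponential(
        tab_a["similarity"].to_numpy(), tab_a["delta_bfi"].to_numpy()
    )
    fit_b = fit_negative_exponential(
        tab_b["similarity"].to_numpy(), tab_b["delta_bfi"].to_numpy()
    )
    rng = np.random.default_rng(seed)
    rates_a = np.empty(n_boot)
    rates_b = np.empty(n_boot)
    for k in range(n_boot):
        # one shared site resample per replicate keeps A and B paired
        state = rng.bit_generator.state
        rates_a[k] = _resample_fit(tab_a, sites, rng).rate
        rng.bit_generator.state = state
        rates_b[k] = _resample_fit(tab_b, sites, rng).rate
    diff = rates_a - rates_b
    p_lo = np.mean(diff <= 0)
    p_hi = np.mean(diff >= 0)
    p = min(1.0, 2 * min(p_lo, p_hi) + 1 / (n_boot + 1))
    return SlopeComparison(
        rate_a=fit_a.rate,
        rate_b=fit_b.rate,
        ci_a=tuple(np.percentile(rates_a, [2.5, 97.5])),
        ci_b=tuple(np.percentile(rates_b, [2.5, 97.5])),
        p_value=float(p),
        n_boot=n_boot,
        boot_rates_a=rates_a,
        boot_rates_b=rates_b,
    )
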