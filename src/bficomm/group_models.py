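"""Group-level models: richness vs BFI and qPCR proportions vs BFI.

Feature richness is modelled as a function of BFI (plus geology and
optionally season) with a negative binomial GLM (log link, dispersion
estimated by maximum likelihood); explained deviance is summarised as D²
(proportional reduction in deviance over the intercept-only model) and as
adjusted D² with the (n-1)/(n-p) correction.

qPCR-derived group proportions — e.g. ammonia-oxidising archaea as a share
of all ammonia oxidisers (AOA + AOB + anammox), or functional-gene copies
relative to bacterial 16S rRNA copies — are modelled with beta regression
(logit mean link, constant precision φ, maximum likelihood) and the mean
coefficients are reported on the odds scale (exponentiated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import betaln
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "GroupModelFit",
    "compute_group_proportions",
    "squeeze_proportions",
    "fit_negbin",
    "fit_beta",
    "compare_with_season",
]

AO_GENES = ("aoa_amoA", "aob_amoA", "hzo")
REFERENCE_GENE = "bac_16S"


@dataclass
class GroupModelFit:
    """A fitted negative-binomial or beta regression.

    ``coefficients`` are on the link (log or logit) scale; for beta fits
    ``odds_scale`` holds their exponentials.  ``dispersion`` is the NB
    theta (1/alpha) or the beta precision phi.  ``d2`` is explained
    deviance, ``adj_d2`` its small-sample adjustment (can be negative).
    """

    family: str
    coefficients: dict[str, float]
    odds_scale: dict[str, float]
    dispersion: float
    d2: float
    adj_d2: float
    z_values: dict[str, float]
    p_values: dict[str, float]
    n: int
    deviance: float = float("nan")
    null_deviance: float = float("nan")
    aic: float = float("nan")
    terms: tuple[str, ...] = ()
    llf: float = float("nan")


def compute_group_proportions(q: pd.DataFrame) -> pd.DataFrame:
    """Per-sample group proportions from a long qPCR copy table.

    ``q`` has columns ``sample_id``, ``gene``, ``copies``.  Returns one row
    per sample with:

    * ``p_aoa``, ``p_aob``, ``p_anammox`` — each gene's share of the total
      ammonia-oxidising community (aoa_amoA + aob_amoA + hzo); they sum
      to 1.
    * ``ratio_<gene>_16S`` — every functional gene's copies divided by
      bacterial 16S rRNA copies.

    Samples whose ammonia-oxidiser total (or 16S count, for the ratios) is
    zero are flagged NaN rather than dropped.
    """
    wide = q.pivot_table(
        index="sample_id", columns="gene", values="copies", aggfunc="mean"
    )
    missing = [g for g in AO_GENES if g not in wide.columns]
    if missing:
        raise ValueError(f"qPCR table lacks gene(s): {missing}")
    out = pd.DataFrame(index=wide.index)
    ao_total = wide[list(AO_GENES)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["p_aoa"] = wide["aoa_amoA"] / ao_total
        out["p_aob"] = wide["aob_amoA"] / ao_total
        out["p_anammox"] = wide["hzo"] / ao_total
        if REFERENCE_GENE in wide.columns:
            for gene in wide.columns:
                if gene == REFERENCE_GENE:
                    continue
                out[f"ratio_{gene}_16S"] = wide[gene] / wide[REFERENCE_GENE]
    out.loc[ao_total <= 0, ["p_aoa", "p_aob", "p_anammox"]] = np.nan
    return out


def squeeze_proportions(p: pd.Series | np.ndarray) -> np.ndarray:
    """Move exact 0/1 proportions into the open interval.

    Applies the standard (p*(n-1) + 0.5)/n transform, and only when the
    data actually contain boundary values — beta support is open but
    interior data need no shrinkage.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any((arr == 0) | (arr == 1)):
        n = arr.size
        arr = (arr * (n - 1) + 0.5) / n
    return arr


def _design(data: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Intercept + numeric/dummy-coded design matrix for the given terms."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in terms:
        col = data[term]
        if col.dtype.kind in "biufc":
            X[term] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True)
            X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def fit_negbin(
    counts: pd.Series | np.ndarray,
    data: pd.DataFrame,
    terms: tuple[str, ...] = ("bfi", "geology"),
) -> GroupModelFit:
    """Negative binomial GLM of counts (e.g. richness) on BFI and geology.

    The overdispersion alpha (theta = 1/alpha) is estimated by full
    maximum likelihood; D² and adjusted D² come from the deviances of a
    NB GLM refit at the estimated alpha.
    """
    y = np.asarray(counts, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    X = _design(data, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} not greater than number of terms p = {p}")
    nb = sm.NegativeBinomial(y, X.to_numpy(), loglike_method="nb2")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # convergence is checked explicitly below; boundary alpha also
        # breaks the optimizer's Hessian inversion, which we do not use
        warnings.simplefilter("ignore")
        res = nb.fit(disp=False, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            # alpha -> 0 (Poisson limit) stalls BFGS at the boundary; a
            # tiny gradient there is still a maximum
            grad = np.max(np.abs(res.mle_retvals.get("gopt", [np.inf])))
            if grad > 1e-3:
                res = nb.fit(disp=False, maxiter=2000, method="nm",
                             start_params=res.params)
                if not res.mle_retvals.get("converged", True):
                    raise RuntimeError(
                        "negative binomial fit did not converge: "
                        f"{res.mle_retvals}"
                    )
    alpha = max(float(res.params[-1]), 1e-8)
    fam = sm.families.NegativeBinomial(alpha=alpha)
    glm = sm.GLM(y, X.to_numpy(), family=fam).fit(
        start_params=res.params[:-1], maxiter=100
    )
    d2 = 1.0 - glm.deviance / glm.null_deviance
    d2 = float(min(1.0, max(0.0, d2)))
    adj_d2 = 1.0 - ((n - 1) / (n - p)) * (1.0 - d2)
    names = list(X.columns)
    coefs = dict(zip(names, map(float, res.params[:-1])))
    zvals = dict(zip(names, map(float, res.tvalues[:-1])))
    pvals = dict(zip(names, map(float, res.pvalues[:-1])))
    # confidence intervals on the mean-model coefficients (NaN when the
    # information matrix is singular at a boundary alpha)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ci = res.conf_int()
        except Exception:
            ci = np.full((len(names), 2), np.nan)
    conf = {nm: (float(ci[k][0]), float(ci[k][1])) for k, nm in enumerate(names)}
    fit = GroupModelFit(
        family="negative_binomial",
        coefficients=coefs,
        odds_scale={k: float(np.exp(v)) for k, v in coefs.items()},
        dispersion=1.0 / alpha,
        d2=d2,
        adj_d2=float(adj_d2),
        z_values=zvals,
        p_values=pvals,
        n=n,
        deviance=float(glm.deviance),
        null_deviance=float(glm.null_deviance),
        aic=float(res.aic),
        terms=terms,
        llf=float(res.llf),
    )
    fit.conf_int = conf
    return fit


def _beta_loglik_saturated(y: np.ndarray, phi: float) -> float:
    """Beta log-likelihood with mu_i = y_i (clipped), the saturated model."""
    mu = np.clip(y, 1e-6, 1 - 1e-6)
    a = mu * phi
    b = (1 - mu) * phi
    return float(np.sum((a - 1) * np.log(y) + (b - 1) * np.log1p(-y) - betaln(a, b)))


def fit_beta(
    proportions: pd.Series | np.ndarray,
    data: pd.DataFrame,
    terms: tuple[str, ...] = ("bfi",),
) -> GroupModelFit:
    """Beta regression of proportions on BFI (and optional season/geology).

    Logit mean link with a constant precision φ, fitted by maximum
    likelihood.  Mean-model coefficients are also reported exponentiated
    ("odds scale": the multiplicative change in the odds of the proportion
    per unit predictor).  D² is the reduction in deviance relative to the
    intercept-only beta fit, with deviance measured against the saturated
    model at the fitted φ.
    """
    y = squeeze_proportions(proportions)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("proportions must lie in (0, 1) after squeezing")
    X = _design(data, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} not greater than number of terms p = {p}")
    res = BetaModel(y, X.to_numpy()).fit(disp=False, maxiter=500)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {res.mle_retvals}")
    null = BetaModel(y, np.ones((n, 1))).fit(disp=False, maxiter=500)
    phi = float(np.exp(res.params[-1]))  # precision uses a log link
    ll_sat = _beta_loglik_saturated(y, phi)
    dev = 2.0 * (ll_sat - float(res.llf))
    null_dev = 2.0 * (ll_sat - float(null.llf))
    d2 = 1.0 - dev / null_dev if null_dev > 0 else 0.0
    d2 = float(min(1.0, max(0.0, d2)))
    adj_d2 = 1.0 - ((n - 1) / (n - p)) * (1.0 - d2)
    names = list(X.columns)
    coefs = dict(zip(names, map(float, res.params[:-1])))
    zvals = dict(zip(names, map(float, res.tvalues[:-1])))
    pvals = dict(zip(names, map(float, res.pvalues[:-1])))
    fit = GroupModelFit(
        family="beta",
        coefficients=coefs,
        odds_scale={k: float(np.exp(v)) for k, v in coefs.items()},
        dispersion=phi,
        d2=d2,
        adj_d2=float(adj_d2),
        z_values=zvals,
        p_values=pvals,
        n=n,
        deviance=float(dev),
        null_deviance=float(null_dev),
        aic=float(res.aic),
        terms=terms,
        llf=float(res.llf),
    )
    ci = res.conf_int()
    fit.conf_int = {
        nm: (float(ci[k][0]), float(ci[k][1])) for k, nm in enumerate(names)
    }
    return fit


@dataclass
class ModelComparison:
    delta_deviance: float
    delta_aic: float
    d2_ratio: float
    terms_without: tuple[str, ...]
    terms_with: tuple[str, ...]


def compare_with_season(
    fit_without: GroupModelFit, fit_with: GroupModelFit
) -> ModelComparison:
    """Compare nested fits with and without a season (or other) term.

    Reports the deviance drop, the AIC change, and the ratio of explained
    deviances D²_with / D²_without — the "fold improvement" in explained
    deviance from adding the term.
    """
    if fit_without.family != fit_with.family:
        raise ValueError("fits must share a family")
    if fit_without.n != fit_with.n:
        raise ValueError("fits must be on identical data (unequal n)")
    if not set(fit_without.terms) <= set(fit_with.terms):
        raise ValueError(
            f"designs are not nested: {fit_without.terms} vs {fit_with.terms}"
        )
    if fit_without.d2 > 0:
        ratio = fit_with.d2 / fit_without.d2
    else:
        ratio = float("inf") if fit_with.d2 > 0 else 1.0
    return ModelComparison(
        delta_deviance=float(fit_without.deviance - fit_with.deviance),
        delta_aic=float(fit_with.aic - fit_without.aic),
        d2_ratio=float(ratio),
        terms_without=fit_without.terms,
        terms_with=fit_with.terms,
    )
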