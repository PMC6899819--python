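"""Estimands computed from posterior draws.

The model parameters ``mu_c[k]`` are *conditional* (study-specific) log
odds ratios: the effect of switching treatment within a single study.
Models with random study intercepts (3 and 4) additionally support
*marginal* (population-averaged) estimands: the marginal treatment mean
``pi_k = E[expit(theta_ik)]`` over the between-study heterogeneity
distribution, and marginal contrasts ``g(pi_k) - g(pi_k')`` on a chosen
link scale.  Conditional odds ratios are generally further from 1 than
marginal ones (non-collapsibility); the two coincide as heterogeneity
vanishes.

For models with fixed intercepts (1 and 2), absolute effects are obtained
by applying the conditional odds ratio to an externally supplied underlying
risk (:func:`external_target`), which is usually the better-sourced
quantity anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .mcmc import ParamSummary, PosteriorDraws, summarize

__all__ = [
    "EstimandRequest",
    "conditional_contrast",
    "marginal_mean",
    "marginal_mean_draws",
    "marginal_contrast",
    "external_target",
]

_LINKS = {
    "logit": logit,
    "identity": lambda p: p,
    "log": np.log,
}


@dataclass(frozen=True)
class EstimandRequest:
    """A single estimand specification (used by the CLI)."""

    kind: str  # conditional_logOR | conditional_OR | marginal_mean |
    #            marginal_contrast | external_target
    treatments: tuple[int, ...]
    link: str = "logit"
    external_risk: float | None = None

    def __post_init__(self) -> None:
        kinds = (
            "conditional_logOR",
            "conditional_OR",
            "marginal_mean",
            "marginal_contrast",
            "external_target",
        )
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.link not in _LINKS:
            raise ValueError(f"link must be one of {tuple(_LINKS)}")
        if self.external_risk is not None and not (
            0.0 < self.external_risk < 1.0
        ):
            raise ValueError("external_risk must be in (0, 1)")


def conditional_contrast(
    draws: PosteriorDraws, k: int, k2: int, scale: str = "log"
) -> ParamSummary:
    """Summary of the conditional k vs k2 contrast.

    ``scale='log'`` gives the log odds ratio mu_c[k] - mu_c[k2];
    ``scale='or'`` exponentiates each draw first.
    """
    if scale not in ("log", "or"):
        raise ValueError("scale must be 'log' or 'or'")
    if k == k2:
        warnings.warn(
            "contrast of a treatment with itself is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
        v = 0.0 if scale == "log" else 1.0
        return ParamSummary(v, v, v)
    x = draws.contrast(k, k2)
    if scale == "or":
        x = np.exp(x)
    return summarize(x)


def _gh_expit_mean(mean: np.ndarray, sd: np.ndarray, n_nodes: int) -> np.ndarray:
    """E[expit(N(mean, sd^2))] by Gauss-Hermite quadrature, vectorized."""
    t, w = np.polynomial.hermite.hermgauss(n_nodes)
    w = w / np.sqrt(np.pi)
    grid = mean[:, None] + np.sqrt(2.0) * sd[:, None] * t[None, :]
    return expit(grid) @ w


def _arm_mean_var(draws: PosteriorDraws, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw between-study mean and variance of theta_ik for arm k."""
    spec = draws.spec
    if spec.model not in (3, 4):
        raise ValueError(
            "marginal estimands need random study intercepts (models 3 or "
            "4); models 1-2 treat intercepts as fixed effects, so the "
            "between-study distribution of arm log odds is not modeled — "
            "use external_target with an externally sourced underlying risk"
        )
    if spec.model == 3:
        mean = draws.array("mu_a[1]") + (
            draws.contrast(k, 1) if k != 1 else 0.0
        )
        var = draws.array("sigma_a") ** 2
        if k != 1:
            if spec.heterogeneity == "CH":
                var = var + draws.array("sigma_c") ** 2
            else:
                var = var + draws.array(f"Sigma_c[{k},{k}]")
        return mean, var
    mean = draws.array(f"mu_a[{k}]")
    if spec.heterogeneity == "CH":
        var = draws.array("sigma_a") ** 2
    else:
        var = draws.array(f"Sigma_a[{k},{k}]")
    return mean, var


def marginal_mean_draws(
    draws: PosteriorDraws, k: int, n_nodes: int = 32
) -> np.ndarray:
    """Per-draw marginal mean pi_k = E[expit(theta_ik)] for arm k.

    The expectation over the fitted between-study normal is evaluated by
    fixed-node Gauss-Hermite quadrature (deterministic given a draw).  For
    model 3 the non-reference arm integrates over intercept and contrast
    heterogeneity jointly (independent by construction); for model 4 over
    the arm's row of the heterogeneity covariance.
    """
    mean, var = _arm_mean_var(draws, k)
    return _gh_expit_mean(np.asarray(mean), np.sqrt(var), n_nodes)


def marginal_mean(
    draws: PosteriorDraws, k: int, n_nodes: int = 32
) -> ParamSummary:
    """Posterior summary of the marginal treatment mean pi_k."""
    return summarize(marginal_mean_draws(draws, k, n_nodes=n_nodes))


def marginal_contrast(
    draws: PosteriorDraws,
    k: int,
    k2: int,
    link: str = "logit",
    n_nodes: int = 32,
) -> ParamSummary:
    """Summary of the marginal contrast g(pi_k) - g(pi_k2).

    ``link='identity'`` yields the marginal risk difference; ``'logit'``
    the marginal log odds ratio; ``'log'`` the marginal log risk ratio.
    """
    if link not in _LINKS:
        raise ValueError(f"link must be one of {tuple(_LINKS)}")
    g = _LINKS[link]
    pk = marginal_mean_draws(draws, k, n_nodes=n_nodes)
    pk2 = marginal_mean_draws(draws, k2, n_nodes=n_nodes)
    ok = np.ones(pk.shape, dtype=bool)
    if link == "log":
        ok = (pk > 0) & (pk2 > 0)
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} draws with zero marginal "
                "mean under the log link",
                RuntimeWarning,
                stacklevel=2,
            )
    return summarize(g(pk[ok]) - g(pk2[ok]))


def external_target(
    draws: PosteriorDraws,
    external_risk: float,
    k: int,
    k2: int = 1,
    integrate_heterogeneity: bool = False,
    n_nodes: int = 32,
) -> ParamSummary:
    """Risk difference of k vs k2 at an externally supplied underlying risk.

    Per draw: ``expit(logit(r) + contrast) - r``.  By default the posterior
    draw of the *mean* contrast is plugged in; with
    ``integrate_heterogeneity=True`` the contrast heterogeneity is
    integrated over (Gauss-Hermite), which matters when the external risk
    is far from 1/2 because expit is curved.  The default plug-in summary
    understates heterogeneity-induced spread in the absolute effect; treat
    it as the effect at the underlying risk ``r`` for an average study.
    """
    if not (0.0 < external_risk < 1.0):
        raise ValueError("external_risk must be in (0, 1)")
    c = draws.contrast(k, k2)
    base = logit(external_risk)
    if integrate_heterogeneity:
        spec = draws.spec
        if spec.heterogeneity == "CH":
            sd = draws.array("sigma_c")
        else:
            # contrast variance of the k-k2 pair from the monitored covariance
            sd = np.sqrt(_pair_contrast_var(draws, k, k2))
        risk = _gh_expit_mean(base + c, sd, n_nodes)
    else:
        risk = expit(base + c)
    return summarize(risk - external_risk)


def _pair_contrast_var(draws: PosteriorDraws, k: int, k2: int) -> np.ndarray:
    spec = draws.spec
    name = "Sigma_a" if spec.model == 4 else "Sigma_c"

    def entry(i, j):
        i, j = min(i, j), max(i, j)
        if name == "Sigma_c" and (i == 1 or j == 1):
            return 0.0  # contrasts are relative to treatment 1
        return draws.array(f"{name}[{i},{j}]")

    return np.asarray(
        entry(k, k) - 2.0 * entry(k, k2) + entry(k2, k2)
    ) + np.zeros(len(draws.draws))
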