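"""Structural models for arm-based and contrast-based NMA of binary outcomes.

Four Bayesian hierarchical models are supported, all with the exact binomial
arm-level likelihood ``y_ik ~ Binomial(n_ik, expit(theta_ik))``:

* **Model 1** — contrast-based, fixed study intercepts, describing observed
  arms only (the Lu-Ades model): ``theta_ik = alpha_i + delta_ik`` with
  ``delta_ik ~ N(mu_k - mu_b, sigma_c^2)`` relative to a study reference arm.
* **Model 2** — contrast-based, fixed study intercepts, describing all
  possible arms: contrast vectors ``delta_i ~ MVN(mu_c, Sigma_c)``.  An
  equivalent arm-based (AB) form writes ``theta_ik = alpha_i + mu_k + eta_ik``
  with ``eta_i ~ MVN(0, Sigma_a)``.
* **Model 3** — model 2 plus *random* study intercepts
  ``alpha_i ~ N(mu_a1, sigma_a^2)``.
* **Model 4** — random study intercepts correlated with treatment effects
  (the Hong model).  AB form: ``theta_i ~ MVN(mu_a, Sigma_a)``; an
  equivalent CB form models ``(alpha_i, delta_i)`` jointly.

Heterogeneity is either *common* (CH: one contrast heterogeneity variance for
every pairwise contrast, via compound-symmetry structures) or *non-common*
(NCH: an unstructured covariance with an inverse-Wishart prior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.special import expit, psi

from .network import Network

__all__ = [
    "ModelSpec",
    "PriorConfig",
    "ParameterState",
    "p_matrix",
    "ch_contrast_cov",
    "model2_ab_arm_cov",
    "model4_ch_cov",
    "diagonal_arm_cov",
    "contrast_variance",
    "sigma_c_from_arm",
    "rho_lower_bound",
    "linear_predictor",
    "log_posterior",
    "derived_contrasts",
    "sample_prior",
]


# ---------------------------------------------------------------------------
# covariance structures
# ---------------------------------------------------------------------------


def p_matrix(n: int, rho: float) -> np.ndarray:
    """The n x n matrix with unit diagonal and all off-diagonals ``rho``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.eye(n) * (1.0 - rho) + np.full((n, n), rho)


def rho_lower_bound(n: int) -> float:
    """Lower end of the open interval on which P_n(rho) is positive definite."""
    return -1.0 / (n - 1) if n > 1 else -1.0


def ch_contrast_cov(sigma_c2: float, K: int) -> np.ndarray:
    """Common-heterogeneity contrast covariance: sigma_c^2 * P_{K-1}(0.5).

    Every pairwise contrast (with or without the reference) then has
    heterogeneity variance exactly ``sigma_c2``.
    """
    if sigma_c2 < 0:
        raise ValueError("sigma_c2 must be non-negative")
    if K < 2:
        raise ValueError("K must be >= 2")
    return sigma_c2 * p_matrix(K - 1, 0.5)


def model2_ab_arm_cov(sigma_c2: float, K: int) -> np.ndarray:
    """Arm-effect covariance of the symmetric AB form of model 2: 0.5*sigma_c^2*I."""
    if sigma_c2 < 0:
        raise ValueError("sigma_c2 must be non-negative")
    return 0.5 * sigma_c2 * np.eye(K)


def model4_ch_cov(sigma_a2: float, rho_a: float, K: int) -> np.ndarray:
    """Compound-symmetry arm covariance sigma_a^2 * P_K(rho_a) of model 4 CH."""
    if sigma_a2 < 0:
        raise ValueError("sigma_a2 must be non-negative")
    if not (rho_lower_bound(K) < rho_a <= 1.0):
        raise ValueError(
            f"rho_a={rho_a} outside ({rho_lower_bound(K)}, 1] for K={K}"
        )
    return sigma_a2 * p_matrix(K, rho_a)


def diagonal_arm_cov(sigma_a2: np.ndarray | float, K: int) -> np.ndarray:
    """Diagonal arm covariance diag(sigma_1^2..sigma_K^2).

    Provided for comparison only: it forces every contrast heterogeneity to
    exceed the arm heterogeneities, which is usually backwards, and is not
    used by any fitted model here.
    """
    s = np.broadcast_to(np.asarray(sigma_a2, dtype=float), (K,))
    if np.any(s < 0):
        raise ValueError("variances must be non-negative")
    return np.diag(s.copy())


def contrast_variance(Sigma: np.ndarray, k: int, k2: int) -> float:
    """Heterogeneity variance of the k vs k2 contrast implied by an arm
    covariance: Sigma_kk - 2*Sigma_kk2 + Sigma_k2k2 (1-based indices)."""
    if k == k2:
        raise ValueError("k and k2 must differ")
    i, j = k - 1, k2 - 1
    return float(Sigma[i, i] - 2.0 * Sigma[i, j] + Sigma[j, j])


def sigma_c_from_arm(sigma_a2: float, rho_a: float) -> float:
    """Contrast heterogeneity variance implied by model 4 CH: 2*sigma_a^2*(1-rho_a)."""
    return 2.0 * sigma_a2 * (1.0 - rho_a)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorConfig:
    """Prior configuration shared across the four models.

    Parameters
    ----------
    fixed_effect_sd:
        Standard deviation of the vague normal prior on every unconstrained
        location parameter (study intercepts, overall means).  Default
        ``sqrt(1000)``: a N(0, 1000) prior where 1000 is the *variance*.
    het_location, het_scale:
        Mean and SD of the normal prior on ``log sigma_c^2`` (equivalently a
        lognormal prior on the contrast heterogeneity variance).  The default
        is an evidence-based prior of the kind derived from large empirical
        collections of binary-outcome meta-analyses for log-odds-ratio
        heterogeneity in pharmacological-versus-placebo comparisons; it is a
        configurable stand-in and posterior sensitivity to it should be
        checked in applications.
    arm_het_location, arm_het_scale:
        Normal prior on ``log sigma_a^2`` (model 3's intercept heterogeneity;
        also anchors the arm-variance scale of the model-4 NCH prior).
        Weakly informative by default: arm heterogeneity is typically larger
        than contrast heterogeneity.
    nch_df_extra:
        Inverse-Wishart degrees of freedom = dimension + ``nch_df_extra``.
        The scale matrix is moment-matched so that the prior mean of the log
        contrast heterogeneity variance equals ``het_location`` (the IW
        family cannot simultaneously match the spread; the prior is
        acknowledged to be informative).
    """

    fixed_effect_sd: float = math.sqrt(1000.0)
    het_location: float = -2.13
    het_scale: float = 1.58
    arm_het_location: float = -1.0
    arm_het_scale: float = 2.0
    nch_df_extra: int = 2

    def __post_init__(self) -> None:
        for name in ("fixed_effect_sd", "het_scale", "arm_het_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nch_df_extra < 1:
            raise ValueError("nch_df_extra must be >= 1 for a proper IW prior")

    # -- inverse-Wishart hyperparameters ----------------------------------

    def nch_df(self, dim: int) -> float:
        return dim + self.nch_df_extra

    def _matched_quadform(self, dim: int, location: float) -> float:
        # v'Sigma v ~ InvGamma(a, v'S v / 2) under IW(nu, S) with
        # a = (nu - dim + 1)/2, so E[log v'Sigma v] = log(v'S v / 2) - psi(a).
        a = (self.nch_df(dim) - dim + 1.0) / 2.0
        return 2.0 * math.exp(location + psi(a))

    def nch_scale_contrast(self, K: int) -> np.ndarray:
        """IW scale for Sigma_c (dim K-1): s0 * P(0.5), so every pairwise
        contrast variance has prior mean of its log equal to het_location."""
        s0 = self._matched_quadform(K - 1, self.het_location)
        return s0 * p_matrix(K - 1, 0.5)

    def nch_scale_arm(self, K: int) -> np.ndarray:
        """IW scale for Sigma_a (dim K): compound symmetry with the arm
        variance matched to the arm-heterogeneity prior and the implied
        contrast variance matched to the contrast-heterogeneity prior."""
        s_aa = self._matched_quadform(K, self.arm_het_location)
        s_cc = self._matched_quadform(K, self.het_location)
        rho0 = 1.0 - s_cc / (2.0 * s_aa)
        if not (rho_lower_bound(K) < rho0 < 1.0):
            raise ValueError(
                "moment-matched IW scale is not positive definite; "
                "arm and contrast heterogeneity prior locations are "
                "incompatible"
            )
        return s_aa * p_matrix(K, rho0)

    # -- scalar prior log-densities ---------------------------------------

    def logp_location(self, x: np.ndarray | float) -> float:
        v = self.fixed_effect_sd**2
        x = np.asarray(x, dtype=float)
        return float(
            -0.5 * np.sum(x**2) / v
            - 0.5 * x.size * math.log(2.0 * math.pi * v)
        )

    def logp_log_sigma_c2(self, log_s2: float) -> float:
        z = (log_s2 - self.het_location) / self.het_scale
        return -0.5 * z * z - math.log(self.het_scale) - 0.5 * math.log(
            2.0 * math.pi
        )

    def logp_log_sigma_a2(self, log_s2: float) -> float:
        z = (log_s2 - self.arm_het_location) / self.arm_het_scale
        return -0.5 * z * z - math.log(self.arm_het_scale) - 0.5 * math.log(
            2.0 * math.pi
        )

    def to_dict(self) -> dict:
        return {
            "fixed_effect_sd": self.fixed_effect_sd,
            "het_location": self.het_location,
            "het_scale": self.het_scale,
            "arm_het_location": self.arm_het_location,
            "arm_het_scale": self.arm_het_scale,
            "nch_df_extra": self.nch_df_extra,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorConfig":
        return cls(**dict(d))


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

_DEFAULT_FORM = {1: "CB", 2: "CB", 3: "CB", 4: "AB"}


@dataclass(frozen=True)
class ModelSpec:
    """Which structural model to fit, in which form, with which priors.

    ``form`` is meaningful for models 2 and 4 only (each has equivalent CB
    and AB parameterizations); models 1 and 3 are CB by construction.
    """

    model: int
    form: str | None = None
    heterogeneity: str = "CH"
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3, 4):
            raise ValueError("model must be 1, 2, 3 or 4")
        if self.heterogeneity not in ("CH", "NCH"):
            raise ValueError("heterogeneity must be 'CH' or 'NCH'")
        form = self.form or _DEFAULT_FORM[self.model]
        if form not in ("CB", "AB"):
            raise ValueError("form must be 'CB' or 'AB'")
        if self.model in (1, 3) and form != "CB":
            raise ValueError(f"model {self.model} has no AB form here")
        if self.model == 1 and self.heterogeneity == "NCH":
            raise ValueError(
                "model 1 supports CH only; use model 2 for NCH "
                "(it describes all arms and imposes positive-semidefinite "
                "second-order consistency automatically)"
            )
        if self.model == 2 and form == "AB" and self.heterogeneity == "NCH":
            raise ValueError(
                "the symmetric AB form of model 2 is defined for CH only"
            )
        object.__setattr__(self, "form", form)

    @property
    def label(self) -> str:
        form = f" ({self.form})" if self.model in (2, 4) else ""
        return f"model {self.model}{form} {self.heterogeneity}"

    @property
    def random_intercepts(self) -> bool:
        return self.model in (3, 4)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "form": self.form,
            "heterogeneity": self.heterogeneity,
            "priors": self.priors.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        if "priors" in d and not isinstance(d["priors"], PriorConfig):
            d["priors"] = PriorConfig.from_dict(d["priors"])
        return cls(**d)


# ---------------------------------------------------------------------------
# parameter state and structural equations
# ---------------------------------------------------------------------------


@dataclass
class ParameterState:
    """One point in a model's parameter space.

    Study-level latents are keyed by study id.  ``delta[sid]`` maps a
    non-reference treatment to its contrast; ``eta``/``theta`` map any
    treatment to the model-2-AB arm effect / model-4-AB arm log-odds.
    ``mu_c`` has length K with ``mu_c[0] = 0`` (treatment 1 is reference).
    Components irrelevant to a given model may be left ``None``.
    """

    alpha: dict | None = None
    delta: dict | None = None
    eta: dict | None = None
    theta: dict | None = None
    mu_c: np.ndarray | None = None
    mu_a: np.ndarray | None = None  # length K (model 4)
    mu_a1: float | None = None  # model 3 intercept mean
    sigma_c2: float | None = None
    sigma_a2: float | None = None
    rho_a: float | None = None
    Sigma_c: np.ndarray | None = None
    Sigma_a: np.ndarray | None = None

    def validate(self, K: int) -> None:
        for name in ("sigma_c2", "sigma_a2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rho_a is not None and not (
            rho_lower_bound(K) < self.rho_a <= 1.0
        ):
            raise ValueError("rho_a outside positive-definite range")
        for name in ("Sigma_c", "Sigma_a"):
            m = getattr(self, name)
            if m is not None:
                w = np.linalg.eigvalsh(np.asarray(m))
                if w.min() < -1e-10 * max(1.0, w.max()):
                    raise ValueError(f"{name} is not positive semidefinite")


def _study_reference(net: Network, study_id, model: int) -> int:
    """Model 1 uses the lowest-numbered treatment in the study as b_i;
    models 2-4 always anchor on treatment 1 (observed or not)."""
    if model == 1:
        return min(net.design_of(study_id))
    return 1


def linear_predictor(
    spec: ModelSpec, state: ParameterState, net: Network, study_id, treatment: int
) -> float:
    """The arm log-odds theta_ik implied by the model's structural equation."""
    K = net.n_treatments
    if not 1 <= treatment <= K:
        raise ValueError(f"treatment {treatment} not in 1..{K}")
    b = _study_reference(net, study_id, spec.model)
    if spec.model == 1 or (spec.model in (2, 3, 4) and spec.form == "CB"):
        alpha = state.alpha[study_id]
        if treatment == b:
            return float(alpha)
        return float(alpha + state.delta[study_id][treatment])
    if spec.model == 2:  # AB form
        mu_k = 0.0 if treatment == 1 else float(state.mu_c[treatment - 1])
        return float(state.alpha[study_id] + mu_k + state.eta[study_id][treatment])
    # model 4 AB form: theta is the latent itself
    return float(state.theta[study_id][treatment])


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    z = np.linalg.solve(L, x - mean)
    return float(
        -0.5 * z @ z
        - np.log(np.diag(L)).sum()
        - 0.5 * x.size * math.log(2.0 * math.pi)
    )


def _model4_star_cov(Sigma_a: np.ndarray) -> np.ndarray:
    """Covariance of (alpha_i1, delta_i2..delta_iK) implied by Sigma_a."""
    K = Sigma_a.shape[0]
    T = np.zeros((K, K))
    T[0, 0] = 1.0
    for k in range(1, K):
        T[k, 0] = -1.0
        T[k, k] = 1.0
    return T @ Sigma_a @ T.T


def log_posterior(spec: ModelSpec, state: ParameterState, net: Network) -> float:
    """Joint log posterior density at ``state`` (up to no additive constant:
    the exact binomial coefficients are included).

    Latent vectors are evaluated marginally over any components the state
    does not provide (a valid MVN marginalization, so providing only the
    observed arms gives the same fit as providing all arms).  Returns -inf
    for states outside the support.
    """
    K = net.n_treatments
    pr = spec.priors
    try:
        state.validate(K)
    except ValueError:
        return -np.inf

    lp = 0.0
    # exact binomial likelihood
    for arm in net.arms:
        theta = linear_predictor(spec, state, net, arm.study_id, arm.treatment_id)
        lp += float(stats.binom.logpmf(arm.events, arm.size, expit(theta)))
        if not np.isfinite(lp):
            return -np.inf

    # structural densities and location priors
    if spec.model == 1:
        s2 = state.sigma_c2
        for sid in net.study_ids:
            b = min(net.design_of(sid))
            for k in net.design_of(sid):
                if k == b:
                    continue
                mdiff = _mu_c_at(state, k) - _mu_c_at(state, b)
                lp += float(
                    stats.norm.logpdf(state.delta[sid][k], mdiff, math.sqrt(s2))
                )
        lp += pr.logp_location([state.alpha[s] for s in net.study_ids])
        lp += pr.logp_location(state.mu_c[1:])
        lp += pr.logp_log_sigma_c2(math.log(s2))
        return float(lp)

    if spec.model in (2, 3) and spec.form == "CB":
        Sig = (
            ch_contrast_cov(state.sigma_c2, K)
            if spec.heterogeneity == "CH"
            else np.asarray(state.Sigma_c, dtype=float)
        )
        for sid in net.study_ids:
            ks = sorted(state.delta[sid])
            idx = [k - 2 for k in ks]
            x = np.array([state.delta[sid][k] for k in ks])
            mean = np.array([_mu_c_at(state, k) for k in ks])
            lp += _mvn_logpdf(x, mean, Sig[np.ix_(idx, idx)])
        alphas = np.array([state.alpha[s] for s in net.study_ids], dtype=float)
        if spec.model == 2:
            lp += pr.logp_location(alphas)
        else:
            lp += float(
                stats.norm.logpdf(
                    alphas, state.mu_a1, math.sqrt(state.sigma_a2)
                ).sum()
            )
            lp += pr.logp_location(state.mu_a1)
            lp += pr.logp_log_sigma_a2(math.log(state.sigma_a2))
        lp += pr.logp_location(state.mu_c[1:])
        if spec.heterogeneity == "CH":
            lp += pr.logp_log_sigma_c2(math.log(state.sigma_c2))
        else:
            lp += float(
                stats.invwishart.logpdf(
                    state.Sigma_c, pr.nch_df(K - 1), pr.nch_scale_contrast(K)
                )
            )
        return float(lp)

    if spec.model == 2 and spec.form == "AB":
        Sig = model2_ab_arm_cov(state.sigma_c2, K)
        for sid in net.study_ids:
            ks = sorted(state.eta[sid])
            x = np.array([state.eta[sid][k] for k in ks])
            idx = [k - 1 for k in ks]
            lp += _mvn_logpdf(x, np.zeros(len(ks)), Sig[np.ix_(idx, idx)])
        lp += pr.logp_location([state.alpha[s] for s in net.study_ids])
        lp += pr.logp_location(state.mu_c[1:])
        lp += pr.logp_log_sigma_c2(math.log(state.sigma_c2))
        return float(lp)

    # model 4
    if spec.heterogeneity == "CH":
        sigma_a2 = state.sigma_c2 / (2.0 * (1.0 - state.rho_a))
        Sigma_a = model4_ch_cov(sigma_a2, state.rho_a, K)
    else:
        Sigma_a = np.asarray(state.Sigma_a, dtype=float)
    if spec.form == "AB":
        for sid in net.study_ids:
            ks = sorted(state.theta[sid])
            x = np.array([state.theta[sid][k] for k in ks])
            idx = [k - 1 for k in ks]
            mean = np.array([state.mu_a[k - 1] for k in ks])
            lp += _mvn_logpdf(x, mean, Sigma_a[np.ix_(idx, idx)])
        lp += pr.logp_location(state.mu_a)
    else:  # CB form of model 4
        Star = _model4_star_cov(Sigma_a)
        for sid in net.study_ids:
            ks = sorted(state.delta[sid])
            idx = [0] + [k - 1 for k in ks]
            x = np.array(
                [state.alpha[sid]] + [state.delta[sid][k] for k in ks]
            )
            mean = np.array(
                [state.mu_a1] + [_mu_c_at(state, k) for k in ks]
            )
            lp += _mvn_logpdf(x, mean, Star[np.ix_(idx, idx)])
        lp += pr.logp_location(state.mu_a1)
        lp += pr.logp_location(state.mu_c[1:])
    if spec.heterogeneity == "CH":
        # independent lognormal priors on the two heterogeneity variances
        # (density on the (log sigma_c^2, log sigma_a^2) scale), truncated
        # to the positive-definite region of the compound-symmetry matrix
        lo = rho_lower_bound(K)
        if not (lo < state.rho_a < 1.0):
            return -np.inf
        lp += pr.logp_log_sigma_c2(math.log(state.sigma_c2))
        lp += pr.logp_log_sigma_a2(math.log(sigma_a2))
    else:
        lp += float(
            stats.invwishart.logpdf(
                Sigma_a, pr.nch_df(K), pr.nch_scale_arm(K)
            )
        )
    return float(lp)


def _mu_c_at(state: ParameterState, k: int) -> float:
    if k == 1:
        return 0.0
    if state.mu_c is not None:
        return float(state.mu_c[k - 1])
    return float(state.mu_a[k - 1] - state.mu_a[0])


def derived_contrasts(spec: ModelSpec, state: ParameterState) -> np.ndarray:
    """Overall mean contrasts mu_c (length K, first entry 0).

    For model 4's AB parameterization these are mu_a[k] - mu_a[1]; for the
    other models the contrast means are passed through unchanged.
    """
    if spec.model == 4 and spec.form == "AB":
        mu_a = np.asarray(state.mu_a, dtype=float)
        return mu_a - mu_a[0]
    out = np.asarray(state.mu_c, dtype=float).copy()
    out[0] = 0.0
    return out


# ---------------------------------------------------------------------------
# prior-predictive sampling
# ---------------------------------------------------------------------------


def sample_prior(spec: ModelSpec, n_draws: int, seed: int, K: int = 3):
    """Independent draws from the prior of a model's key parameters.

    Returns a DataFrame with overall mean contrasts ``mu_c[k]``, the implied
    pairwise contrast heterogeneity variances ``cvar[k,j]`` (identical
    columns under CH), arm variances ``avar[k]`` where the model has them,
    and ``rho_a`` for model 4 CH.  Used to verify that the variance-component
    priors are comparable across models after moment matching.
    """
    import pandas as pd

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    pr = spec.priors
    out: dict[str, np.ndarray] = {}
    for k in range(2, K + 1):
        out[f"mu_c[{k}]"] = rng.normal(0.0, pr.fixed_effect_sd, n_draws)
    pairs = [(k, j) for k in range(1, K + 1) for j in range(k + 1, K + 1)]

    if spec.heterogeneity == "CH":
        s_c2 = np.exp(rng.normal(pr.het_location, pr.het_scale, n_draws))
        for k, j in pairs:
            out[f"cvar[{k},{j}]"] = s_c2
        if spec.model == 3:
            out["avar[1]"] = np.exp(
                rng.normal(pr.arm_het_location, pr.arm_het_scale, n_draws)
            )
        if spec.model == 4:
            # independent arm-variance prior, truncated to the region where
            # the implied compound-symmetry correlation is positive definite
            lo = rho_lower_bound(K)
            avar = np.exp(
                rng.normal(pr.arm_het_location, pr.arm_het_scale, n_draws)
            )
            rho = 1.0 - s_c2 / (2.0 * avar)
            bad = rho <= lo
            while bad.any():
                s_c2[bad] = np.exp(
                    rng.normal(pr.het_location, pr.het_scale, int(bad.sum()))
                )
                avar[bad] = np.exp(
                    rng.normal(
                        pr.arm_het_location, pr.arm_het_scale, int(bad.sum())
                    )
                )
                rho = 1.0 - s_c2 / (2.0 * avar)
                bad = rho <= lo
            for k, j in pairs:
                out[f"cvar[{k},{j}]"] = s_c2
            out["rho_a"] = rho
            for k in range(1, K + 1):
                out[f"avar[{k}]"] = avar
    else:
        if spec.model in (2, 3):
            df, S = pr.nch_df(K - 1), pr.nch_scale_contrast(K)
            draws = stats.invwishart.rvs(df, S, size=n_draws, random_state=rng)
            draws = draws.reshape(n_draws, K - 1, K - 1)
            full = np.zeros((n_draws, K, K))
            full[:, 1:, 1:] = draws  # treatment 1 row/col zero (delta_1 = 0)
            for k, j in pairs:
                out[f"cvar[{k},{j}]"] = np.array(
                    [contrast_variance(m, k, j) for m in full]
                )
            if spec.model == 3:
                out["avar[1]"] = np.exp(
                    rng.normal(pr.arm_het_location, pr.arm_het_scale, n_draws)
                )
        else:
            df, S = pr.nch_df(K), pr.nch_scale_arm(K)
            draws = stats.invwishart.rvs(df, S, size=n_draws, random_state=rng)
            draws = draws.reshape(n_draws, K, K)
            for k, j in pairs:
                out[f"cvar[{k},{j}]"] = np.array(
                    [contrast_variance(m, k, j) for m in draws]
                )
            for k in range(1, K + 1):
                out[f"avar[{k}]"] = draws[:, k - 1, k - 1]
    return pd.DataFrame(out)
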