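"""Internal MCMC samplers.

One adaptive random-walk Metropolis-within-Gibbs sampler per model family,
vectorized across studies.  Design notes:

* Location hyperparameters (overall means) are updated by *exact* conjugate
  Gibbs draws wherever they enter the model linearly with normal priors;
  study-level latents use componentwise adaptive random-walk Metropolis
  steps (target acceptance 0.44, adaptation during burn-in only, kernel
  frozen afterwards so the post-burn-in chain is a fixed Markov kernel).
* Common-heterogeneity (CH) models use the *marginal* representation of the
  latent multivariate-normal vectors (observed components only) — an exact
  MVN marginalization, so the fit is identical to modeling all possible
  arms, but with fewer latent dimensions.
* Non-common-heterogeneity (NCH) models keep the full latent vectors and
  Gibbs-impute the unobserved components each sweep, which makes the
  inverse-Wishart update of the unstructured covariance conjugate.  The
  model-4 arm-based sampler uses the same full-vector representation.
* Variance components move on unconstrained scales (log variance; a scaled
  logit for the compound-symmetry correlation rho_a).

The paper-facing contract is the posterior, not the engine: any correct
sampler may be substituted, and the CB/AB equivalence tests act as the
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats
from .models import ModelSpec, p_matrix, rho_lower_bound
from .network import Network

_JITTER = 1e-10


def _softplus(x):
    return np.logaddexp(0.0, x)


def _chol_logdet(L):
    return 2.0 * np.sum(np.log(np.diag(L)))


class _Adapt:
    """Per-component adaptive step sizes (Robbins-Monro on the log scale)."""

    def __init__(self, shape, initial=0.5, target=0.44):
        self.ls = np.full(shape, math.log(initial))
        self.t = 0
        self.target = target
        self.frozen = False
        self.n_prop = 0
        self.n_acc = 0.0

    @property
    def step(self):
        return np.exp(self.ls)

    def update(self, accepted):
        acc = np.asarray(accepted, dtype=float)
        self.n_prop += acc.size
        self.n_acc += acc.sum()
        if self.frozen:
            return
        self.t += 1
        g = min(0.25, 2.0 / math.sqrt(self.t + 20.0))
        self.ls += g * (acc - self.target)
        np.clip(self.ls, -12.0, 6.0, out=self.ls)


@dataclass
class _Group:
    """Studies sharing a design (same observed treatment set)."""

    design: tuple[int, ...]  # 0-based treatment indices, sorted
    rows: np.ndarray  # study row indices


class _NetArrays:
    """Arm counts as dense (n_studies x K) matrices (zeros where unobserved)."""

    def __init__(self, net: Network):
        self.net = net
        self.sids = list(net.study_ids)
        self.n = len(self.sids)
        self.K = net.n_treatments
        self.Y = np.zeros((self.n, self.K))
        self.M = np.zeros((self.n, self.K))
        self.obs = np.zeros((self.n, self.K), dtype=bool)
        row = {s: i for i, s in enumerate(self.sids)}
        for arm in net.arms:
            i, k = row[arm.study_id], arm.treatment_id - 1
            self.Y[i, k] = arm.events
            self.M[i, k] = arm.size
            self.obs[i, k] = True
        designs: dict[tuple[int, ...], list[int]] = {}
        for i, sid in enumerate(self.sids):
            d = tuple(k - 1 for k in net.design_of(sid))
            designs.setdefault(d, []).append(i)
        self.groups = [
            _Group(design=d, rows=np.asarray(r, dtype=int))
            for d, r in sorted(designs.items())
        ]
        self.d_arms = self.obs.sum(axis=1)  # arms per study
        # empirical logits with 0.5 continuity (initialization only)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.logit0 = np.log(
                (self.Y + 0.5) / (self.M - self.Y + 0.5)
            )
        self.logit0[~self.obs] = 0.0

    def binom_col(self, k, theta_col, rows=None):
        """Unnormalized binomial log-lik of arm column k at log-odds theta."""
        if rows is None:
            return self.Y[:, k] * theta_col - self.M[:, k] * _softplus(theta_col)
        return self.Y[rows, k] * theta_col - self.M[rows, k] * _softplus(
            theta_col
        )

    def binom_rows(self, Theta):
        """Per-study sum of binomial log-lik over all observed arms."""
        return (self.Y * Theta - self.M * _softplus(Theta)).sum(axis=1)


class _SamplerBase:
    def __init__(self, spec: ModelSpec, net: Network, rng: np.random.Generator):
        self.spec = spec
        self.pr = spec.priors
        self.rng = rng
        self.dat = _NetArrays(net)
        self.v0 = self.pr.fixed_effect_sd**2
        self.acceptors: dict[str, _Adapt] = {}

    # -- common pieces -----------------------------------------------------

    def _adapt(self, key, shape, initial=0.5):
        if key not in self.acceptors:
            self.acceptors[key] = _Adapt(shape, initial=initial)
        return self.acceptors[key]

    def freeze(self):
        for a in self.acceptors.values():
            a.frozen = True

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (a.n_acc / a.n_prop if a.n_prop else float("nan"))
            for k, a in self.acceptors.items()
        }

    def _mh(self, logratio):
        """Vectorized accept decision for log MH ratios."""
        logratio = np.asarray(logratio, dtype=float)
        u = self.rng.random(logratio.shape)
        with np.errstate(over="ignore"):
            return np.log(u) < logratio

    def check_init(self):
        vals = np.concatenate([v.ravel() for v in self.state_arrays()])
        if not np.all(np.isfinite(vals)):
            raise RuntimeError(
                f"non-finite initial state for {self.spec.label}: "
                f"{self.state_arrays()}"
            )

    # subclasses: param_names, state_arrays, sweep, monitor


# ---------------------------------------------------------------------------
# model 1: Lu-Ades CB model, observed arms only, CH, two-arm studies
# ---------------------------------------------------------------------------


class Model1Sampler(_SamplerBase):
    def __init__(self, spec, net, rng):
        super().__init__(spec, net, rng)
        dat = self.dat
        if np.any(dat.d_arms != 2):
            raise ValueError(
                "model 1 is restricted to two-arm studies here; use models "
                "2-4 for multi-arm networks"
            )
        self.bb = np.empty(dat.n, dtype=int)  # study reference b_i (0-based)
        self.kk = np.empty(dat.n, dtype=int)  # the other treatment
        for i in range(dat.n):
            ks = np.flatnonzero(dat.obs[i])
            self.bb[i], self.kk[i] = ks[0], ks[1]
        # initial values
        rows = np.arange(dat.n)
        self.A = dat.logit0[rows, self.bb].copy()
        self.D = dat.logit0[rows, self.kk] - self.A
        self.mu = np.zeros(dat.K)
        for k in range(1, dat.K):
            sel = (self.kk == k) & (self.bb == 0)
            if sel.any():
                self.mu[k] = self.D[sel].mean()
        self.x_c = self.pr.het_location  # log sigma_c^2 at prior median
        self._rows = rows

    def param_names(self):
        return [f"mu_c[{k + 1}]" for k in range(1, self.dat.K)] + ["sigma_c"]

    def state_arrays(self):
        return [self.A, self.D, self.mu, np.array([self.x_c])]

    def monitor(self):
        return np.concatenate([self.mu[1:], [math.exp(0.5 * self.x_c)]])

    def sweep(self):
        dat, rng, rows = self.dat, self.rng, self._rows
        s2 = math.exp(self.x_c)
        md = self.mu[self.kk] - self.mu[self.bb]

        ad = self._adapt("alpha", dat.n)
        prop = self.A + ad.step * rng.standard_normal(dat.n)
        # both arms shift with alpha
        cur_ref = dat.Y[rows, self.bb] * self.A - dat.M[
            rows, self.bb
        ] * _softplus(self.A)
        cur_alt = dat.Y[rows, self.kk] * (self.A + self.D) - dat.M[
            rows, self.kk
        ] * _softplus(self.A + self.D)
        new_ref = dat.Y[rows, self.bb] * prop - dat.M[rows, self.bb] * _softplus(
            prop
        )
        new_alt = dat.Y[rows, self.kk] * (prop + self.D) - dat.M[
            rows, self.kk
        ] * _softplus(prop + self.D)
        dll = (
            new_ref
            + new_alt
            - cur_ref
            - cur_alt
            - (prop**2 - self.A**2) / (2.0 * self.v0)
        )
        acc = self._mh(dll)
        self.A = np.where(acc, prop, self.A)
        ad.update(acc)

        ad = self._adapt("delta", dat.n)
        prop = self.D + ad.step * rng.standard_normal(dat.n)
        cur_alt = dat.Y[rows, self.kk] * (self.A + self.D) - dat.M[
            rows, self.kk
        ] * _softplus(self.A + self.D)
        new_alt = dat.Y[rows, self.kk] * (self.A + prop) - dat.M[
            rows, self.kk
        ] * _softplus(self.A + prop)
        dll = (
            new_alt
            - cur_alt
            - ((prop - md) ** 2 - (self.D - md) ** 2) / (2.0 * s2)
        )
        acc = self._mh(dll)
        self.D = np.where(acc, prop, self.D)
        ad.update(acc)

        # conjugate update of each overall mean contrast
        for k in range(1, dat.K):
            sel_k = self.kk == k
            sel_b = self.bb == k
            obs = np.concatenate(
                [
                    self.D[sel_k] + self.mu[self.bb[sel_k]],
                    self.mu[self.kk[sel_b]] - self.D[sel_b],
                ]
            )
            prec = obs.size / s2 + 1.0 / self.v0
            mean = obs.sum() / s2 / prec
            self.mu[k] = mean + rng.standard_normal() / math.sqrt(prec)

        # log sigma_c^2 random walk
        md = self.mu[self.kk] - self.mu[self.bb]
        ss = float(((self.D - md) ** 2).sum())
        ad = self._adapt("x_c", (), initial=0.4)
        xp = self.x_c + float(ad.step) * rng.standard_normal()
        dll = (
            -0.5 * dat.n * (xp - self.x_c)
            - 0.5 * ss * (math.exp(-xp) - math.exp(-self.x_c))
            + self.pr.logp_log_sigma_c2(xp)
            - self.pr.logp_log_sigma_c2(self.x_c)
        )
        acc = bool(self._mh(dll))
        if acc:
            self.x_c = xp
        ad.update(acc)


# ---------------------------------------------------------------------------
# CB marginal sampler: models 2 CH, 3 CH, and the CB form of model 4 CH
# ---------------------------------------------------------------------------


class CBMarginalSampler(_SamplerBase):
    """Latents per study: (alpha_i, observed contrasts), jointly MVN.

    model 2: alpha block = vague prior N(0, v0), contrasts ~ sigma_c^2 P(0.5)
    model 3: alpha block = N(mu_a1, sigma_a^2), independent of contrasts
    model 4 CB: joint covariance Sigma* derived from (sigma_c^2, rho_a)
    """

    def __init__(self, spec, net, rng):
        super().__init__(spec, net, rng)
        if spec.heterogeneity != "CH":
            raise ValueError("CBMarginalSampler handles CH only")
        dat = self.dat
        self.model = spec.model
        # contrast slots per group: observed non-reference treatments
        for g in dat.groups:
            g.cidx = tuple(k for k in g.design if k != 0)  # type: ignore
        # initial values
        self.A = np.where(
            dat.obs[:, 0], dat.logit0[:, 0], dat.logit0.mean(axis=1)
        )
        self.D = np.zeros((dat.n, dat.K))
        for g in dat.groups:
            for k in g.cidx:
                self.D[g.rows, k] = dat.logit0[g.rows, k] - self.A[g.rows]
        self.mu = np.zeros(dat.K)
        for k in range(1, dat.K):
            sel = dat.obs[:, k]
            if sel.any():
                self.D[~sel, k] = 0.0
                self.mu[k] = self.D[sel, k].mean()
        self.mu_a1 = float(self.A.mean())
        self.x_c = self.pr.het_location
        self.x_a = self.pr.arm_het_location
        lo = rho_lower_bound(dat.K)
        self._lo = lo
        if self.model == 4:
            # keep the implied correlation inside its PD interval at start
            while 1.0 - math.exp(self.x_c - self.x_a) / 2.0 <= lo:
                self.x_a += 0.5
        self._free = (
            [("a1", None)] if self.model in (3, 4) else []
        ) + [("mu", k) for k in range(1, dat.K)]
        self._refresh_cov()

    # -- covariance bookkeeping -------------------------------------------

    @property
    def rho(self):
        # model 4 CH: correlation implied by the two heterogeneity variances
        return 1.0 - math.exp(self.x_c - self.x_a) / 2.0

    def _cov_for(self, g, x_c=None, x_a=None):
        """Joint covariance of (alpha_i, contrasts) for a design group."""
        x_c = self.x_c if x_c is None else x_c
        x_a = self.x_a if x_a is None else x_a
        s_c2 = math.exp(x_c)
        d = len(g.cidx)
        if self.model in (2, 3):
            V = np.zeros((1 + d, 1 + d))
            V[0, 0] = self.v0 if self.model == 2 else math.exp(x_a)
            V[1:, 1:] = s_c2 * p_matrix(d, 0.5) if d else np.zeros((0, 0))
            return V
        if 1.0 - math.exp(x_c - x_a) / 2.0 <= self._lo:
            return None  # outside the positive-definite region
        V = np.empty((1 + d, 1 + d))
        V[0, 0] = math.exp(x_a)
        V[0, 1:] = V[1:, 0] = -0.5 * s_c2
        V[1:, 1:] = s_c2 * p_matrix(d, 0.5) if d else np.zeros((0, 0))
        return V

    def _refresh_cov(self):
        self._L = []
        self._Lam = []
        self._ld = []
        for g in self.dat.groups:
            V = self._cov_for(g)
            if V is None:
                raise RuntimeError("covariance state left the PD region")
            L = np.linalg.cholesky(V)
            self._L.append(L)
            self._Lam.append(sla.cho_solve((L, True), np.eye(V.shape[0])))
            self._ld.append(_chol_logdet(L))

    def _local_vec(self, g):
        """(n_g, 1+d) latent matrix and its mean for a group."""
        cols = list(g.cidx)
        v = np.column_stack([self.A[g.rows]] + [self.D[g.rows, k] for k in cols])
        m0 = 0.0 if self.model == 2 else self.mu_a1
        m = np.concatenate([[m0], self.mu[cols]]) if cols else np.array([m0])
        return v, m

    def _struct_logpdf_total(self, x_c=None, x_a=None):
        total = 0.0
        for g in self.dat.groups:
            V = self._cov_for(g, x_c=x_c, x_a=x_a)
            if V is None:
                return -np.inf
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -np.inf
            v, m = self._local_vec(g)
            zres = sla.solve_triangular(L, (v - m).T, lower=True)
            total += -0.5 * float(
                (zres**2).sum()
            ) - 0.5 * len(g.rows) * _chol_logdet(L)
        return total

    # -- parameter names / monitoring -------------------------------------

    def param_names(self):
        K = self.dat.K
        names = [f"mu_c[{k + 1}]" for k in range(1, K)] + ["sigma_c"]
        if self.model == 3:
            names += ["mu_a[1]", "sigma_a"]
        if self.model == 4:
            names += [f"mu_a[{k + 1}]" for k in range(K)] + [
                "sigma_a",
                "rho_a",
            ]
        return names

    def state_arrays(self):
        return [self.A, self.D, self.mu, np.array([self.x_c, self.x_a])]

    def monitor(self):
        out = list(self.mu[1:]) + [math.exp(0.5 * self.x_c)]
        if self.model == 3:
            out += [self.mu_a1, math.exp(0.5 * self.x_a)]
        if self.model == 4:
            out += [self.mu_a1] + [self.mu_a1 + m for m in self.mu[1:]]
            out += [math.exp(0.5 * self.x_a), self.rho]
        return np.asarray(out)

    # -- sweep -------------------------------------------------------------

    def _slot_update(self, gi, g, j):
        """MH update of local component j for all studies in group g."""
        dat, rng = self.dat, self.rng
        Lam = self._Lam[gi]
        v, m = self._local_vec(g)
        r = v - m
        Gcol = r @ Lam[:, j]
        key = f"slot[{gi},{j}]"
        ad = self._adapt(key, len(g.rows))
        eps = ad.step * rng.standard_normal(len(g.rows))
        rj_new = r[:, j] + eps
        dstruct = -0.5 * (
            Lam[j, j] * (rj_new**2 - r[:, j] ** 2)
            + 2.0 * eps * (Gcol - Lam[j, j] * r[:, j])
        )
        if j == 0:
            # alpha shifts every observed arm of the study
            Theta = self.A[g.rows, None] + self.D[g.rows]
            Theta[:, 0] = self.A[g.rows]
            cur = (
                dat.Y[g.rows] * Theta - dat.M[g.rows] * _softplus(Theta)
            ).sum(axis=1)
            Theta_new = Theta + eps[:, None]
            new = (
                dat.Y[g.rows] * Theta_new
                - dat.M[g.rows] * _softplus(Theta_new)
            ).sum(axis=1)
            dll = new - cur + dstruct
        else:
            k = g.cidx[j - 1]
            th = self.A[g.rows] + self.D[g.rows, k]
            dll = (
                dat.binom_col(k, th + eps, g.rows)
                - dat.binom_col(k, th, g.rows)
                + dstruct
            )
        acc = self._mh(dll)
        if j == 0:
            self.A[g.rows] = np.where(acc, self.A[g.rows] + eps, self.A[g.rows])
        else:
            k = g.cidx[j - 1]
            self.D[g.rows, k] = np.where(
                acc, self.D[g.rows, k] + eps, self.D[g.rows, k]
            )
        ad.update(acc)

    def _gibbs_mu(self):
        """Exact conjugate draw of the free location parameters."""
        free = self._free
        p = len(free)
        Lpost = np.zeros((p, p))
        b = np.zeros(p)
        np.fill_diagonal(Lpost, 1.0 / self.v0)
        for gi, g in enumerate(self.dat.groups):
            Lam = self._Lam[gi]
            v, _ = self._local_vec(g)
            dloc = 1 + len(g.cidx)
            # F maps free params to local mean components
            F = np.zeros((dloc, p))
            for col, (kind, k) in enumerate(free):
                if kind == "a1":
                    F[0, col] = 1.0
                elif k in g.cidx:
                    F[1 + g.cidx.index(k), col] = 1.0
            FtL = F.T @ Lam
            Lpost += len(g.rows) * FtL @ F
            b += FtL @ v.sum(axis=0)
        L = np.linalg.cholesky(Lpost)
        mean = sla.cho_solve((L, True), b)
        draw = mean + sla.solve_triangular(
            L.T, self.rng.standard_normal(p), lower=False
        )
        for val, (kind, k) in zip(draw, free):
            if kind == "a1":
                self.mu_a1 = float(val)
            else:
                self.mu[k] = float(val)

    def _var_update(self, name):
        ad = self._adapt(name, (), initial=0.3)
        step = float(ad.step)
        cur = getattr(self, name)
        prop = cur + step * self.rng.standard_normal()
        kwargs = {name: prop}
        new = self._struct_logpdf_total(**kwargs)
        old = self._struct_logpdf_total()
        if name == "x_c":
            dprior = self.pr.logp_log_sigma_c2(prop) - self.pr.logp_log_sigma_c2(
                cur
            )
        else:
            dprior = self.pr.logp_log_sigma_a2(prop) - self.pr.logp_log_sigma_a2(
                cur
            )
        acc = bool(self._mh(new - old + dprior))
        if acc:
            setattr(self, name, prop)
            self._refresh_cov()
        ad.update(acc)

    def sweep(self):
        for gi, g in enumerate(self.dat.groups):
            for j in range(1 + len(g.cidx)):
                self._slot_update(gi, g, j)
        self._gibbs_mu()
        self._var_update("x_c")
        if self.model in (3, 4):
            self._var_update("x_a")


class CBTwoArmSampler(CBMarginalSampler):
    """Fast path of :class:`CBMarginalSampler` for networks in which every
    study is two-arm and contains the reference treatment.

    The joint latent (alpha_i, delta_i) then has the *same* 2x2 covariance
    in every study, so all Metropolis updates vectorize across studies with
    no per-design bookkeeping.  Covers all in-scope datasets.
    """

    @staticmethod
    def applicable(spec, net) -> bool:
        if spec.heterogeneity != "CH":
            return False
        return all(
            len(d) == 2 and 1 in d for d in net.designs.values()
        )

    def __init__(self, spec, net, rng):
        super().__init__(spec, net, rng)
        dat = self.dat
        self.kk = np.array(
            [next(k for k in g.cidx) for g in dat.groups for _ in g.rows]
        )
        order = np.concatenate([g.rows for g in dat.groups])
        self.kk = self.kk[np.argsort(order)]
        rows = np.arange(dat.n)
        self.Dv = self.D[rows, self.kk].copy()
        self._y0, self._m0arm = dat.Y[:, 0], dat.M[:, 0]
        self._yk = dat.Y[rows, self.kk]
        self._mk = dat.M[rows, self.kk]
        self._cnt = np.bincount(self.kk, minlength=dat.K).astype(float)

    def _v2(self, x_c=None, x_a=None):
        x_c = self.x_c if x_c is None else x_c
        x_a = self.x_a if x_a is None else x_a
        s_c2 = math.exp(x_c)
        if self.model == 2:
            V = np.array([[self.v0, 0.0], [0.0, s_c2]])
        elif self.model == 3:
            V = np.array([[math.exp(x_a), 0.0], [0.0, s_c2]])
        else:
            if 1.0 - math.exp(x_c - x_a) / 2.0 <= self._lo:
                return None  # implied correlation outside PD interval
            V = np.array(
                [[math.exp(x_a), -0.5 * s_c2], [-0.5 * s_c2, s_c2]]
            )
        return V

    @staticmethod
    def _inv2(V):
        det = V[0, 0] * V[1, 1] - V[0, 1] ** 2
        if det <= 0 or V[0, 0] <= 0:
            return None, np.inf
        Lam = (
            np.array([[V[1, 1], -V[0, 1]], [-V[0, 1], V[0, 0]]]) / det
        )
        return Lam, math.log(det)

    def _resid(self):
        m0 = 0.0 if self.model == 2 else self.mu_a1
        return self.A - m0, self.Dv - self.mu[self.kk]

    def state_arrays(self):
        return [self.A, self.Dv, self.mu, np.array([self.x_c, self.x_a])]

    def sweep(self):
        dat, rng = self.dat, self.rng
        n = dat.n
        Lam, ld = self._inv2(self._v2())

        # study intercepts
        ad = self._adapt("alpha", n)
        eps = ad.step * rng.standard_normal(n)
        r0, r1 = self._resid()
        dstruct = -0.5 * (
            Lam[0, 0] * ((r0 + eps) ** 2 - r0**2)
            + 2.0 * eps * Lam[0, 1] * r1
        )
        th0, thk = self.A, self.A + self.Dv
        dll = (
            self._y0 * eps
            - self._m0arm * (_softplus(th0 + eps) - _softplus(th0))
            + self._yk * eps
            - self._mk * (_softplus(thk + eps) - _softplus(thk))
            + dstruct
        )
        acc = self._mh(dll)
        self.A = np.where(acc, self.A + eps, self.A)
        ad.update(acc)

        # study contrasts
        ad = self._adapt("delta", n)
        eps = ad.step * rng.standard_normal(n)
        r0, r1 = self._resid()
        dstruct = -0.5 * (
            Lam[1, 1] * ((r1 + eps) ** 2 - r1**2)
            + 2.0 * eps * Lam[0, 1] * r0
        )
        thk = self.A + self.Dv
        dll = (
            self._yk * eps
            - self._mk * (_softplus(thk + eps) - _softplus(thk))
            + dstruct
        )
        acc = self._mh(dll)
        self.Dv = np.where(acc, self.Dv + eps, self.Dv)
        ad.update(acc)

        self._gibbs_mu_fast(Lam)
        self._var_update_fast("x_c")
        if self.model in (3, 4):
            self._var_update_fast("x_a")

    def _gibbs_mu_fast(self, Lam):
        K = self.dat.K
        has_a1 = self.model in (3, 4)
        ks = [k for k in range(1, K)]
        p = len(ks) + (1 if has_a1 else 0)
        Lpost = np.zeros((p, p))
        b = np.zeros(p)
        np.fill_diagonal(Lpost, 1.0 / self.v0)
        sumA_k = np.bincount(self.kk, weights=self.A, minlength=K)
        sumD_k = np.bincount(self.kk, weights=self.Dv, minlength=K)
        off = 1 if has_a1 else 0
        for j, k in enumerate(ks):
            Lpost[off + j, off + j] += self._cnt[k] * Lam[1, 1]
            b[off + j] += Lam[0, 1] * sumA_k[k] + Lam[1, 1] * sumD_k[k]
        if has_a1:
            Lpost[0, 0] += self.dat.n * Lam[0, 0]
            for j, k in enumerate(ks):
                Lpost[0, off + j] = Lpost[off + j, 0] = self._cnt[k] * Lam[0, 1]
            b[0] = Lam[0, 0] * self.A.sum() + Lam[0, 1] * self.Dv.sum()
        L = np.linalg.cholesky(Lpost)
        mean = np.linalg.solve(Lpost, b)
        draw = mean + sla.solve_triangular(
            L.T, self.rng.standard_normal(p), lower=False
        )
        if has_a1:
            self.mu_a1 = float(draw[0])
        for j, k in enumerate(ks):
            self.mu[k] = float(draw[off + j])

    def _struct_total_fast(self, **kw):
        V = self._v2(**kw)
        if V is None:
            return -np.inf
        Lam, ld = self._inv2(V)
        if Lam is None:
            return -np.inf
        r0, r1 = self._resid()
        q = (
            Lam[0, 0] * float(r0 @ r0)
            + 2.0 * Lam[0, 1] * float(r0 @ r1)
            + Lam[1, 1] * float(r1 @ r1)
        )
        return -0.5 * q - 0.5 * self.dat.n * ld

    def _var_update_fast(self, name):
        ad = self._adapt(name, (), initial=0.3)
        cur = getattr(self, name)
        prop = cur + float(ad.step) * self.rng.standard_normal()
        new = self._struct_total_fast(**{name: prop})
        old = self._struct_total_fast()
        if name == "x_c":
            dprior = self.pr.logp_log_sigma_c2(prop) - self.pr.logp_log_sigma_c2(cur)
        else:
            dprior = self.pr.logp_log_sigma_a2(prop) - self.pr.logp_log_sigma_a2(cur)
        acc = bool(self._mh(new - old + dprior))
        if acc:
            setattr(self, name, prop)
        ad.update(acc)


# ---------------------------------------------------------------------------
# symmetric AB form of model 2 (CH)
# ---------------------------------------------------------------------------


class ABSymSampler(_SamplerBase):
    """theta_ik = alpha_i + mu_k + eta_ik with eta ~ N(0, 0.5 sigma_c^2)."""

    def __init__(self, spec, net, rng):
        super().__init__(spec, net, rng)
        dat = self.dat
        self.A = np.where(
            dat.obs[:, 0], dat.logit0[:, 0], dat.logit0.mean(axis=1)
        )
        self.mu = np.zeros(dat.K)
        for k in range(1, dat.K):
            sel = dat.obs[:, k]
            if sel.any():
                self.mu[k] = (dat.logit0[sel, k] - self.A[sel]).mean()
        self.E = np.zeros((dat.n, dat.K))
        self.E[dat.obs] = (dat.logit0 - self.A[:, None] - self.mu[None, :])[
            dat.obs
        ]
        self.x_c = self.pr.het_location
        self.n_eta = int(dat.obs.sum())

    def param_names(self):
        return [f"mu_c[{k + 1}]" for k in range(1, self.dat.K)] + ["sigma_c"]

    def state_arrays(self):
        return [self.A, self.E, self.mu, np.array([self.x_c])]

    def monitor(self):
        return np.concatenate([self.mu[1:], [math.exp(0.5 * self.x_c)]])

    def _theta(self):
        T = self.A[:, None] + self.mu[None, :] + self.E
        return T

    def sweep(self):
        dat, rng = self.dat, self.rng
        half_s2 = 0.5 * math.exp(self.x_c)

        ad = self._adapt("alpha", dat.n)
        eps = ad.step * rng.standard_normal(dat.n)
        T = self._theta()
        cur = dat.binom_rows(T)
        new = dat.binom_rows(T + eps[:, None])
        dll = (
            new
            - cur
            - ((self.A + eps) ** 2 - self.A**2) / (2.0 * self.v0)
        )
        acc = self._mh(dll)
        self.A = np.where(acc, self.A + eps, self.A)
        ad.update(acc)

        for k in range(dat.K):
            sel = dat.obs[:, k]
            rows = np.flatnonzero(sel)
            if rows.size == 0:
                continue
            ad = self._adapt(f"eta[{k}]", rows.size)
            eps = ad.step * rng.standard_normal(rows.size)
            th = self.A[rows] + self.mu[k] + self.E[rows, k]
            e_new = self.E[rows, k] + eps
            dll = (
                dat.binom_col(k, th + eps, rows)
                - dat.binom_col(k, th, rows)
                - (e_new**2 - self.E[rows, k] ** 2) / (2.0 * half_s2)
            )
            acc = self._mh(dll)
            self.E[rows, k] = np.where(acc, e_new, self.E[rows, k])
            ad.update(acc)

        for k in range(1, dat.K):
            rows = np.flatnonzero(dat.obs[:, k])
            if rows.size == 0:
                # treatment never observed: posterior equals the prior
                self.mu[k] = rng.normal(0.0, self.pr.fixed_effect_sd)
                continue
            ad = self._adapt(f"mu[{k}]", ())
            eps = float(ad.step) * rng.standard_normal()
            th = self.A[rows] + self.mu[k] + self.E[rows, k]
            dll = float(
                (dat.binom_col(k, th + eps, rows) - dat.binom_col(k, th, rows)).sum()
            ) - ((self.mu[k] + eps) ** 2 - self.mu[k] ** 2) / (2.0 * self.v0)
            acc = bool(self._mh(dll))
            if acc:
                self.mu[k] += eps
            ad.update(acc)

        sse = float((self.E[dat.obs] ** 2).sum())
        ad = self._adapt("x_c", (), initial=0.3)
        xp = self.x_c + float(ad.step) * rng.standard_normal()
        dll = (
            -0.5 * self.n_eta * (xp - self.x_c)
            - sse * (math.exp(-xp) - math.exp(-self.x_c))
            + self.pr.logp_log_sigma_c2(xp)
            - self.pr.logp_log_sigma_c2(self.x_c)
        )
        acc = bool(self._mh(dll))
        if acc:
            self.x_c = xp
        ad.update(acc)


# ---------------------------------------------------------------------------
# full-vector augmented sampler: model 4 AB (CH/NCH), models 2-3 NCH
# ---------------------------------------------------------------------------


class AugmentedSampler(_SamplerBase):
    """Keeps the complete latent vector per study ("all possible arms").

    model 4 AB: X = theta_i (length K), mean mu_a, covariance Sigma_a
    model 2/3 NCH: X = delta_i (length K-1), mean mu_c, covariance Sigma_c,
        plus the study intercept alpha_i (vague or random).
    Unobserved components are Gibbs-imputed from their conditional MVN each
    sweep, making the inverse-Wishart covariance update conjugate.
    """

    def __init__(self, spec, net, rng):
        super().__init__(spec, net, rng)
        dat = self.dat
        self.model = spec.model
        self.nch = spec.heterogeneity == "NCH"
        self.is_m4 = spec.model == 4
        self.p = dat.K if self.is_m4 else dat.K - 1
        lo = rho_lower_bound(dat.K)
        self._lo = lo

        # latent matrix X, intercepts, means
        if self.is_m4:
            self.X = dat.logit0.copy()
            self.mean = np.array(
                [
                    dat.logit0[dat.obs[:, k], k].mean()
                    if dat.obs[:, k].any()
                    else dat.logit0[dat.obs].mean()
                    for k in range(dat.K)
                ]
            )
            for k in range(dat.K):
                self.X[~dat.obs[:, k], k] = self.mean[k]
        else:
            self.A = np.where(
                dat.obs[:, 0], dat.logit0[:, 0], dat.logit0.mean(axis=1)
            )
            self.X = np.zeros((dat.n, dat.K - 1))
            self.mean = np.zeros(dat.K - 1)
            for k in range(1, dat.K):
                sel = dat.obs[:, k]
                if sel.any():
                    self.mean[k - 1] = (dat.logit0[sel, k] - self.A[sel]).mean()
                self.X[sel, k - 1] = dat.logit0[sel, k] - self.A[sel]
                self.X[~sel, k - 1] = self.mean[k - 1]
            self.mu_a1 = float(self.A.mean())
            self.x_a = self.pr.arm_het_location

        # covariance state
        self.x_c = self.pr.het_location
        if self.is_m4:
            self.x_a = self.pr.arm_het_location
            while 1.0 - math.exp(self.x_c - self.x_a) / 2.0 <= lo:
                self.x_a += 0.5
        if self.nch:
            if self.is_m4:
                self.iw_df = self.pr.nch_df(dat.K)
                self.iw_S = self.pr.nch_scale_arm(dat.K)
            else:
                self.iw_df = self.pr.nch_df(dat.K - 1)
                self.iw_S = self.pr.nch_scale_contrast(dat.K)
            self.Sigma = self.iw_S / (self.iw_df - self.p - 1.0)
        else:
            self.Sigma = self._ch_sigma()
        self._refresh_cov()

        # observed/unobserved column sets per design group (in X coords)
        for g in dat.groups:
            if self.is_m4:
                o = list(g.design)
            else:
                o = [k - 1 for k in g.design if k != 0]
            u = [j for j in range(self.p) if j not in o]
            g.xo, g.xu = o, u  # type: ignore
            g.ix_oo = np.ix_(o, o)
            g.ix_uo = np.ix_(u, o)
            g.ix_uu = np.ix_(u, u)
            g.ix_ro = np.ix_(g.rows, o)
            g.ix_ru = np.ix_(g.rows, u)

    # -- covariance helpers ------------------------------------------------

    @property
    def rho(self):
        return 1.0 - math.exp(self.x_c - self.x_a) / 2.0

    def _ch_sigma(self, x_c=None, x_a=None):
        x_c = self.x_c if x_c is None else x_c
        x_a = self.x_a if x_a is None else x_a
        rho = 1.0 - math.exp(x_c - x_a) / 2.0
        return math.exp(x_a) * p_matrix(self.dat.K, rho)

    @staticmethod
    def _cs_prec_logdet(s2: float, rho: float, K: int):
        """Precision and log-determinant of s2 * P_K(rho), closed form."""
        denom = 1.0 + (K - 1) * rho
        if s2 <= 0 or rho >= 1.0 or denom <= 0:
            return None, np.inf
        Lam = (np.eye(K) - (rho / denom) * np.ones((K, K))) / (
            (1.0 - rho) * s2
        )
        ld = K * math.log(s2) + (K - 1) * math.log(1.0 - rho) + math.log(denom)
        return Lam, ld

    def _refresh_cov(self):
        if self.nch or not self.is_m4:
            L = np.linalg.cholesky(self.Sigma)
            self._Lam = sla.cho_solve((L, True), np.eye(self.p))
            self._ld = _chol_logdet(L)
        else:
            self._Lam, self._ld = self._cs_prec_logdet(
                math.exp(self.x_a), self.rho, self.p
            )

    # -- names / monitoring ------------------------------------------------

    def param_names(self):
        K = self.dat.K
        names = [f"mu_c[{k + 1}]" for k in range(1, K)]
        if self.is_m4:
            names += [f"mu_a[{k + 1}]" for k in range(K)]
            if self.nch:
                names += [
                    f"Sigma_a[{j + 1},{k + 1}]"
                    for j in range(K)
                    for k in range(j, K)
                ]
            else:
                names += ["sigma_c", "sigma_a", "rho_a"]
        else:
            names += [
                f"Sigma_c[{j + 2},{k + 2}]"
                for j in range(K - 1)
                for k in range(j, K - 1)
            ]
            if self.model == 3:
                names += ["mu_a[1]", "sigma_a"]
        return names

    def state_arrays(self):
        out = [self.X, self.mean, self.Sigma]
        if not self.is_m4:
            out.append(self.A)
        return out

    def monitor(self):
        K = self.dat.K
        if self.is_m4:
            mu_c = self.mean - self.mean[0]
            out = list(mu_c[1:]) + list(self.mean)
            if self.nch:
                out += [
                    self.Sigma[j, k] for j in range(K) for k in range(j, K)
                ]
            else:
                rho = self.rho
                s_c2 = math.exp(self.x_c)
                out += [
                    math.sqrt(s_c2),
                    math.sqrt(s_c2 / (2.0 * (1.0 - rho))),
                    rho,
                ]
        else:
            out = list(self.mean)
            out += [
                self.Sigma[j, k]
                for j in range(K - 1)
                for k in range(j, K - 1)
            ]
            if self.model == 3:
                out += [self.mu_a1, math.exp(0.5 * self.x_a)]
        return np.asarray(out)

    # -- sweep pieces -------------------------------------------------------

    def _impute(self):
        for g in self.dat.groups:
            if not g.xu:
                continue
            o, u = g.xo, g.xu
            Soo = self.Sigma[g.ix_oo]
            Suo = self.Sigma[g.ix_uo]
            B = np.linalg.solve(Soo, Suo.T).T
            cond = self.Sigma[g.ix_uu] - B @ Suo.T
            cond = 0.5 * (cond + cond.T) + _JITTER * np.eye(len(u))
            L = np.linalg.cholesky(cond)
            resid = self.X[g.ix_ro] - self.mean[o]
            m = self.mean[u] + resid @ B.T
            zdraw = self.rng.standard_normal((len(g.rows), len(u)))
            self.X[g.ix_ru] = m + zdraw @ L.T

    def _theta(self):
        if self.is_m4:
            return self.X
        T = np.empty((self.dat.n, self.dat.K))
        T[:, 0] = self.A
        T[:, 1:] = self.A[:, None] + self.X
        return T

    def _slot_updates(self):
        dat, rng = self.dat, self.rng
        Lam = self._Lam
        R = self.X - self.mean
        G = R @ Lam
        for j in range(self.p):
            k_arm = j if self.is_m4 else j + 1
            rows = np.flatnonzero(dat.obs[:, k_arm])
            if rows.size == 0:
                continue  # never-observed treatment column: imputation only
            ad = self._adapt(f"x[{j}]", rows.size)
            eps = ad.step * rng.standard_normal(rows.size)
            rj = R[rows, j]
            dstruct = -0.5 * (
                Lam[j, j] * ((rj + eps) ** 2 - rj**2)
                + 2.0 * eps * (G[rows, j] - Lam[j, j] * rj)
            )
            th = (
                self.X[rows, j]
                if self.is_m4
                else self.A[rows] + self.X[rows, j]
            )
            dll = (
                dat.binom_col(k_arm, th + eps, rows)
                - dat.binom_col(k_arm, th, rows)
                + dstruct
            )
            acc = self._mh(dll)
            upd = np.where(acc, eps, 0.0)
            self.X[rows, j] += upd
            R[rows, j] += upd
            G[rows] += np.outer(upd, Lam[j])
            ad.update(acc)

    def _alpha_update(self):
        dat, rng = self.dat, self.rng
        ad = self._adapt("alpha", dat.n)
        eps = ad.step * rng.standard_normal(dat.n)
        T = self._theta()
        cur = dat.binom_rows(T)
        new = dat.binom_rows(T + eps[:, None])
        if self.model == 2:
            dprior = -((self.A + eps) ** 2 - self.A**2) / (2.0 * self.v0)
        else:
            s_a2 = math.exp(self.x_a)
            dprior = -(
                (self.A + eps - self.mu_a1) ** 2 - (self.A - self.mu_a1) ** 2
            ) / (2.0 * s_a2)
        acc = self._mh(new - cur + dprior)
        self.A = np.where(acc, self.A + eps, self.A)
        ad.update(acc)

    def _gibbs_mean(self):
        n = self.dat.n
        Lpost = np.eye(self.p) / self.v0 + n * self._Lam
        b = self._Lam @ self.X.sum(axis=0)
        L = np.linalg.cholesky(Lpost)
        mean = np.linalg.solve(Lpost, b)
        self.mean = mean + np.linalg.solve(
            L.T, self.rng.standard_normal(self.p)
        )

    def _gibbs_sigma_nch(self):
        R = self.X - self.mean
        S = self.iw_S + R.T @ R
        S = 0.5 * (S + S.T)
        self.Sigma = stats.invwishart.rvs(
            self.iw_df + self.dat.n, S, random_state=self.rng
        ).reshape(self.p, self.p)
        self._refresh_cov()

    def _cs_quad_logdet(self, x_c, x_a):
        """Total structural log-density terms for model 4 CH, closed form."""
        s_a2 = math.exp(x_a)
        rho = 1.0 - math.exp(x_c - x_a) / 2.0
        K = self.p
        denom = 1.0 + (K - 1) * rho
        if rho <= self._lo or denom <= 0 or rho >= 1.0:
            return -np.inf
        R = self.X - self.mean
        s2tot = float((R**2).sum())
        s1sq = float((R.sum(axis=1) ** 2).sum())
        q = (s2tot - (rho / denom) * s1sq) / ((1.0 - rho) * s_a2)
        ld = (
            K * math.log(s_a2)
            + (K - 1) * math.log(1.0 - rho)
            + math.log(denom)
        )
        return -0.5 * q - 0.5 * self.dat.n * ld

    def _ch_var_update(self, name):
        # model 4 CH: scalar moves of log sigma_c^2 and the rho transform
        ad = self._adapt(name, (), initial=0.25)
        cur = getattr(self, name)
        prop = cur + float(ad.step) * self.rng.standard_normal()
        kw = {"x_c": self.x_c, "x_a": self.x_a}
        kw[name] = prop
        dll = self._cs_quad_logdet(**kw) - self._cs_quad_logdet(
            x_c=self.x_c, x_a=self.x_a
        )
        if name == "x_c":
            dll += self.pr.logp_log_sigma_c2(prop) - self.pr.logp_log_sigma_c2(
                cur
            )
        else:
            dll += self.pr.logp_log_sigma_a2(prop) - self.pr.logp_log_sigma_a2(
                cur
            )
        acc = bool(self._mh(dll))
        if acc:
            setattr(self, name, prop)
            self.Sigma = self._ch_sigma()
            self._refresh_cov()
        ad.update(acc)

    def _model3_hyper_updates(self):
        rng = self.rng
        s_a2 = math.exp(self.x_a)
        prec = self.dat.n / s_a2 + 1.0 / self.v0
        m = (self.A.sum() / s_a2) / prec
        self.mu_a1 = float(m + rng.standard_normal() / math.sqrt(prec))
        ss = float(((self.A - self.mu_a1) ** 2).sum())
        ad = self._adapt("x_a", (), initial=0.3)
        xp = self.x_a + float(ad.step) * rng.standard_normal()
        dll = (
            -0.5 * self.dat.n * (xp - self.x_a)
            - 0.5 * ss * (math.exp(-xp) - math.exp(-self.x_a))
            + self.pr.logp_log_sigma_a2(xp)
            - self.pr.logp_log_sigma_a2(self.x_a)
        )
        acc = bool(self._mh(dll))
        if acc:
            self.x_a = xp
        ad.update(acc)

    def sweep(self):
        self._impute()
        if not self.is_m4:
            self._alpha_update()
        self._slot_updates()
        self._gibbs_mean()
        if self.nch:
            self._gibbs_sigma_nch()
        else:
            self._ch_var_update("x_c")
            self._ch_var_update("x_a")
        if self.model == 3:
            self._model3_hyper_updates()


def build_sampler(spec: ModelSpec, net: Network, rng) -> _SamplerBase:
    if spec.model == 1:
        return Model1Sampler(spec, net, rng)
    if spec.model == 2 and spec.form == "AB":
        return ABSymSampler(spec, net, rng)
    if spec.heterogeneity == "NCH":
        return AugmentedSampler(spec, net, rng)
    if spec.model == 4 and spec.form == "AB":
        return AugmentedSampler(spec, net, rng)
    if CBTwoArmSampler.applicable(spec, net):
        return CBTwoArmSampler(spec, net, rng)
    return CBMarginalSampler(spec, net, rng)
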