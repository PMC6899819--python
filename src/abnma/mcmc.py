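"""Fitting NMA models by MCMC, and summarizing the posterior draws.

The default chain regime is a single chain with 50 000 burn-in updates and
200 000 further updates thinned to every 20th (10 000 retained draws).  On
the small networks this package targets, a full fit takes on the order of a
minute; shorter chains are appropriate for quick exploration and are used by
the package's own test suite.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import build_sampler
from .models import ModelSpec
from .network import Network

__all__ = [
    "ChainConfig",
    "PosteriorDraws",
    "ParamSummary",
    "fit",
    "autocorrelation",
    "summarize",
    "posterior_slope",
    "mcse_median",
]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain regime: burn-in, retained updates, thinning, seed."""

    burn_in: int = 50_000
    post_burn_updates: int = 200_000
    thin: int = 20
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.post_burn_updates < 1:
            raise ValueError("burn_in >= 0 and post_burn_updates >= 1 required")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin >= 1 and n_chains >= 1 required")

    @property
    def n_kept(self) -> int:
        return self.post_burn_updates // self.thin

    def to_dict(self) -> dict:
        return {
            "burn_in": self.burn_in,
            "post_burn_updates": self.post_burn_updates,
            "thin": self.thin,
            "seed": self.seed,
            "n_chains": self.n_chains,
        }

    @classmethod
    def from_dict(cls, d) -> "ChainConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class ParamSummary:
    """Posterior median with central 95% credible interval."""

    median: float
    ci_low: float
    ci_high: float

    def __iter__(self):
        yield from (self.median, self.ci_low, self.ci_high)


@dataclass
class PosteriorDraws:
    """Retained MCMC samples of the monitored parameters.

    ``draws`` has one row per retained sample (chains stacked in order) and
    one column per monitored parameter.
    """

    draws: pd.DataFrame
    spec: ModelSpec
    config: ChainConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws.columns)

    def array(self, parameter: str) -> np.ndarray:
        if parameter not in self.draws.columns:
            raise KeyError(
                f"parameter {parameter!r} not monitored; available: "
                f"{self.parameters}"
            )
        return self.draws[parameter].to_numpy()

    def by_chain(self, parameter: str) -> np.ndarray:
        """(n_chains, n_kept) array of one parameter's draws."""
        x = self.array(parameter)
        return x.reshape(self.config.n_chains, -1)

    def contrast(self, k: int, k2: int) -> np.ndarray:
        """Draws of the k vs k2 overall mean log odds ratio."""
        a = 0.0 if k == 1 else self.array(f"mu_c[{k}]")
        b = 0.0 if k2 == 1 else self.array(f"mu_c[{k2}]")
        return np.asarray(a - b) + np.zeros(len(self.draws))

    # -- persistence -------------------------------------------------------

    def save(self, draws_path, meta_path) -> None:
        self.draws.to_csv(draws_path, index=False)
        with open(meta_path, "w") as fh:
            json.dump(
                {
                    "spec": self.spec.to_dict(),
                    "config": self.config.to_dict(),
                    "acceptance": self.acceptance,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, draws_path, meta_path) -> "PosteriorDraws":
        draws = pd.read_csv(draws_path)
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(
            draws=draws,
            spec=ModelSpec.from_dict(meta["spec"]),
            config=ChainConfig.from_dict(meta["config"]),
            acceptance=meta.get("acceptance", {}),
        )


def fit(spec: ModelSpec, net: Network, config: ChainConfig | None = None) -> PosteriorDraws:
    """Draw from the joint posterior of ``spec`` on ``net``.

    A fixed seed yields bitwise-identical draws on repeat.  Step sizes adapt
    during burn-in only; the post-burn-in kernel is fixed.
    """
    config = config or ChainConfig()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_chains)
    chains = []
    names = None
    acceptance: dict = {}
    for c in range(config.n_chains):
        rng = np.random.default_rng(children[c])
        sampler = build_sampler(spec, net, rng)
        sampler.check_init()
        names = sampler.param_names()
        kept = np.empty((config.n_kept, len(names)))
        for t in range(config.burn_in):
            sampler.sweep()
        sampler.freeze()
        j = 0
        for t in range(config.post_burn_updates):
            sampler.sweep()
            if t % config.thin == config.thin - 1:
                kept[j] = sampler.monitor()
                j += 1
        chains.append(kept[:j])
        acceptance[f"chain{c}"] = sampler.acceptance_rates()
    draws = pd.DataFrame(np.vstack(chains), columns=names)
    return PosteriorDraws(
        draws=draws, spec=spec, config=config, acceptance=acceptance
    )


# ---------------------------------------------------------------------------
# posterior summaries and diagnostics
# ---------------------------------------------------------------------------


def summarize(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> ParamSummary:
    """Posterior median and central 95% interval (linear-interpolation
    quantiles of the retained draws)."""
    x = draws.array(parameter) if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    q = np.quantile(x, [0.5, 0.025, 0.975])
    return ParamSummary(median=float(q[0]), ci_low=float(q[1]), ci_high=float(q[2]))


def autocorrelation(draws: PosteriorDraws | np.ndarray, parameter: str | None = None, lag: int = 1) -> float:
    """Sample autocorrelation of the thinned chain at the given lag.

    Computed per chain and averaged.  A constant chain returns 0 with a
    warning (by convention, to keep diagnostic tables NaN-free).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if isinstance(draws, PosteriorDraws):
        X = draws.by_chain(parameter)
    else:
        X = np.atleast_2d(np.asarray(draws, dtype=float))
    vals = []
    for x in X:
        if lag >= x.size:
            raise ValueError("not enough retained draws for this lag")
        v = x.var()
        if v == 0.0:
            warnings.warn(
                "constant chain: autocorrelation undefined, returning 0",
                RuntimeWarning,
                stacklevel=2,
            )
            vals.append(0.0)
            continue
        xc = x - x.mean()
        vals.append(float((xc[:-lag] * xc[lag:]).mean() / v))
    return float(np.mean(vals))


def posterior_slope(draws: PosteriorDraws, y: str, x: str) -> float:
    """Least-squares slope of y-draws on x-draws across retained samples."""
    xv = draws.array(x)
    yv = draws.array(y)
    vx = xv.var()
    if vx == 0.0:
        raise ValueError(f"zero variance in {x!r}: slope undefined")
    return float(((xv - xv.mean()) * (yv - yv.mean())).mean() / vx)


def mcse_median(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Monte Carlo standard error of the posterior median (arviz quantile
    MCSE, which accounts for chain autocorrelation)."""
    import arviz as az

    if isinstance(draws, PosteriorDraws):
        X = draws.by_chain(parameter)
    else:
        X = np.atleast_2d(np.asarray(draws, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.mcse(X, method="quantile", prob=0.5))


def summary_table(draws: PosteriorDraws) -> pd.DataFrame:
    """Median and 95% CrI for every monitored parameter."""
    rows = []
    for p in draws.parameters:
        s = summarize(draws, p)
        rows.append((p, s.median, s.ci_low, s.ci_high))
    return pd.DataFrame(rows, columns=["parameter", "median", "ci_low", "ci_high"])
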