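"""Deterministic hypothetical NMA datasets with known truth.

Ten constructed datasets probe when NMA models that use between-study
information go wrong.  The network has three treatments X (=1), Y (=2) and
Z (=3); every study has an X arm, studies compare either Y or Z with X, and
Y and Z are truly identical (true Z-Y log odds ratio 0), so any nonzero
estimated Z-Y contrast is model-induced bias.

The log odds of an event on X runs systematically from -2 to 0 across
studies (overall event fraction about 25%).  Scenarios:

1. log OR 0 in all studies, 200 per arm
2. log OR 0.5 in all studies, 200 per arm
3. log OR 0.5 in all studies, 50 per arm (smaller studies => more
   between-study information)
4. log OR averaging 0.5, *decreasing* with underlying risk, 200 per arm
5. log OR averaging 0.5, *increasing* with underlying risk, 200 per arm

Subtype ``a``: Y-X and Z-X studies are similar — six Y-X designs
interleaved with five Z-X designs across the X grid (11 studies).
Subtype ``b``: the five Y-X studies take the low half of the X grid and the
five Z-X studies the high half (10 studies), so between-study information
disagrees with within-study information and design is confounded with
underlying risk.

Arm counts are *expected* counts rounded half-up, not sampled: the datasets
are fixed constructions and regenerate bitwise-identically.  Binomial
sampling is available behind a flag for robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .network import Network, network_from_frame

__all__ = [
    "ScenarioSpec",
    "TruthRecord",
    "generate",
    "effect_rule",
    "design_bias_oracle",
    "simulate_ch_network",
    "ALL_SCENARIOS",
]

X, Y, Z = 1, 2, 3
_GRID_A = np.linspace(-2.0, 0.0, 11)
_GRID_B_LOW = np.linspace(-2.0, -1.2, 5)
_GRID_B_HIGH = np.linspace(-0.8, 0.0, 5)
_ALPHA_BAR = -1.0
# slope of the scenario 4/5 effect rule, calibrated so the between-design
# gap in mean true effects is exactly -/+0.5 under the subtype-b grid
# (the Y-X and Z-X design means of the X log odds are 1.2 apart)
_SLOPE = 0.5 / 1.2

ALL_SCENARIOS = [(s, t) for s in (1, 2, 3, 4, 5) for t in ("a", "b")]


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one hypothetical dataset."""

    scenario: int
    subtype: str
    arm_size: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4, 5):
            raise ValueError("scenario must be 1..5")
        if self.subtype not in ("a", "b"):
            raise ValueError("subtype must be 'a' or 'b'")
        default = 50 if self.scenario == 3 else 200
        size = default if self.arm_size is None else self.arm_size
        if self.scenario == 3 and size != 50:
            raise ValueError("scenario 3 uses 50 per arm")
        if self.scenario != 3 and size != 200:
            raise ValueError("scenarios 1, 2, 4, 5 use 200 per arm")
        object.__setattr__(self, "arm_size", size)

    @property
    def x_grid(self) -> np.ndarray:
        """Study-level X log odds, paired with the study's comparator."""
        if self.subtype == "a":
            return _GRID_A.copy()
        return np.concatenate([_GRID_B_LOW, _GRID_B_HIGH])

    @property
    def comparators(self) -> list[int]:
        if self.subtype == "a":
            # interleave six Y-X designs with five Z-X designs
            return [Y if i % 2 == 0 else Z for i in range(len(_GRID_A))]
        return [Y] * len(_GRID_B_LOW) + [Z] * len(_GRID_B_HIGH)

    @property
    def name(self) -> str:
        return f"{self.scenario}{self.subtype}"


def effect_rule(spec: ScenarioSpec, x_logodds: float | np.ndarray) -> np.ndarray:
    """True Y/Z-vs-X log odds ratio as a function of the study's X log odds.

    Scenario 1: 0.  Scenarios 2-3: 0.5.  Scenarios 4 and 5: linear in the
    X log odds, centered so the grid average is exactly 0.5, decreasing
    (scenario 4) or increasing (scenario 5) with underlying risk.
    """
    x = np.asarray(x_logodds, dtype=float)
    if spec.scenario == 1:
        return np.zeros_like(x)
    if spec.scenario in (2, 3):
        return np.full_like(x, 0.5)
    sign = -1.0 if spec.scenario == 4 else 1.0
    return 0.5 + sign * _SLOPE * (x - _ALPHA_BAR)


@dataclass(frozen=True)
class TruthRecord:
    """The generating truth of a hypothetical dataset."""

    true_logOR_YX: float
    true_logOR_ZX: float
    true_logOR_ZY: float
    study_comparator: tuple[int, ...] = ()
    study_x_logodds: tuple[float, ...] = ()
    study_logOR: tuple[float, ...] = ()


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def generate(
    spec: ScenarioSpec,
    sample: bool = False,
    seed: int | None = None,
) -> tuple[Network, TruthRecord]:
    """Construct the dataset for one scenario/subtype.

    With ``sample=False`` (default) arm events are expected counts rounded
    half-up — fully deterministic.  With ``sample=True`` they are binomial
    draws using ``seed``.
    """
    x = spec.x_grid
    comp = spec.comparators
    delta = effect_rule(spec, x)
    n = spec.arm_size
    rng = np.random.default_rng(seed) if sample else None

    rows = []
    for i, (a, c, d) in enumerate(zip(x, comp, delta), start=1):
        p_x = expit(a)
        p_c = expit(a + d)
        if sample:
            ev_x = int(rng.binomial(n, p_x))
            ev_c = int(rng.binomial(n, p_c))
        else:
            ev_x = int(_round_half_up(np.array(n * p_x)))
            ev_c = int(_round_half_up(np.array(n * p_c)))
        rows.append((i, X, ev_x, n))
        rows.append((i, c, ev_c, n))
    frame = pd.DataFrame(rows, columns=["study", "treatment", "events", "size"])
    net = network_from_frame(frame)
    mean_d = float(delta.mean())
    truth = TruthRecord(
        true_logOR_YX=mean_d,
        true_logOR_ZX=mean_d,
        true_logOR_ZY=0.0,
        study_comparator=tuple(comp),
        study_x_logodds=tuple(float(v) for v in x),
        study_logOR=tuple(float(v) for v in delta),
    )
    return net, truth


def design_bias_oracle(net: Network, truth: TruthRecord) -> float:
    """Expected bias of the direct Z-Y comparison from design confounding.

    The mean true Y/Z-vs-X effect among Z-X studies minus that among Y-X
    studies: what an analysis that simply contrasts the two design strata
    (or that lets between-study information leak across designs) is pulled
    toward, relative to the true Z-Y effect of 0.  Pure bookkeeping on the
    generating truth; for subtype-a layouts (balanced designs) it is 0.
    """
    comp = np.asarray(truth.study_comparator)
    d = np.asarray(truth.study_logOR)
    if not (comp == Z).any() or not (comp == Y).any():
        return 0.0
    return float(d[comp == Z].mean() - d[comp == Y].mean())


def simulate_ch_network(
    n_studies: int,
    arm_size: int,
    mu_c: np.ndarray,
    sigma_c: float,
    seed: int,
    alpha_mean: float = -1.0,
    alpha_sd: float = 0.5,
) -> Network:
    """Sample a two-arm-per-study network from the model-2 CH generative
    process: study intercepts N(alpha_mean, alpha_sd^2), contrast vectors
    MVN(mu_c, sigma_c^2 P(0.5)), binomial arm counts.  Designs {1,k}
    alternate over the non-reference treatments k = 2..K.
    """
    mu_c = np.asarray(mu_c, dtype=float)
    K = mu_c.size + 1
    rng = np.random.default_rng(seed)
    cov = sigma_c**2 * (0.5 * np.eye(K - 1) + 0.5)
    rows = []
    for i in range(1, n_studies + 1):
        k = 2 + (i - 1) % (K - 1)
        alpha = rng.normal(alpha_mean, alpha_sd)
        delta = rng.multivariate_normal(mu_c, cov)[k - 2]
        ev1 = int(rng.binomial(arm_size, expit(alpha)))
        ev2 = int(rng.binomial(arm_size, expit(alpha + delta)))
        rows.append((i, 1, ev1, arm_size))
        rows.append((i, k, ev2, arm_size))
    frame = pd.DataFrame(rows, columns=["study", "treatment", "events", "size"])
    return network_from_frame(frame)
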