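"""Competing demographic scenario templates and their uniform priors.

Four piecewise-constant effective-population-size (Ne) histories are
compared: constant size, a single increase, a single bottleneck, and a
fluctuating history (an ancestral expansion followed by a more recent
decline).  Each template declares named Ne parameters (diploid individuals),
event times (generations before the most recent sample, "gbp"), and ordering
constraints among them; parameter values are drawn from uniform priors by
resampling until the constraints hold, which preserves the uniform marginals
conditioned on the constraint.

Mutation-model hyperparameters (mean rate, per-locus Gamma dispersion, and
the geometric multi-step parameter of the generalized stepwise model) ride
along with each draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SCENARIO_NAMES",
    "PriorSpec",
    "DemographicScenario",
    "ParameterDraw",
    "Trajectory",
    "make_scenario",
    "sample_prior",
    "to_trajectory",
]

SCENARIO_NAMES = ("constant", "increasing", "bottleneck", "fluctuating")

_SCENARIO_PARAMS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "constant": (("N",), ()),
    "increasing": (("N_anc", "N_cur"), ("t",)),
    "bottleneck": (("N_pre", "N_post"), ("t",)),
    "fluctuating": (("N_anc", "N_hist", "N_pres"), ("t1", "t2")),
}

_MAX_REJECTION_ATTEMPTS = 10**5


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds for demographic and mutation parameters.

    Defaults: Ne uniform on [10, 100000] diploids, event times uniform on
    [1, 5000] generations, mean mutation rate uniform on [1e-4, 1e-3] per
    locus per generation with per-locus rates Gamma-distributed around the
    mean (shape 2), and the geometric multi-step parameter of the GSM
    uniform on [0.1, 0.3].
    """

    ne_bounds: tuple[float, float] = (10.0, 100_000.0)
    time_bounds: tuple[float, float] = (1.0, 5000.0)
    param_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    mu_mean_bounds: tuple[float, float] = (1e-4, 1e-3)
    gamma_shape: float = 2.0
    gsm_p_bounds: tuple[float, float] = (0.1, 0.3)
    rate_mode: str = "per_locus"  # or "shared"

    def __post_init__(self):
        for lo, hi in (self.ne_bounds, self.time_bounds, self.mu_mean_bounds,
                       self.gsm_p_bounds, *self.param_bounds.values()):
            if not lo < hi:
                raise ValueError(f"prior bounds ({lo}, {hi}) must satisfy lo < hi")
        if not (0 < self.mu_mean_bounds[0] and self.mu_mean_bounds[1] < 1e-2):
            raise ValueError("mutation-rate bounds must lie within (0, 1e-2)")
        if self.rate_mode not in ("per_locus", "shared"):
            raise ValueError(f"unknown rate_mode {self.rate_mode!r}")

    def bounds_for(self, param: str) -> tuple[float, float]:
        if param in self.param_bounds:
            return self.param_bounds[param]
        return self.time_bounds if param.startswith("t") else self.ne_bounds


@dataclass(frozen=True)
class DemographicScenario:
    """A named piecewise-constant Ne template with priors and constraints."""

    name: str
    ne_params: tuple[str, ...]
    time_params: tuple[str, ...]
    prior: PriorSpec

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.ne_params + self.time_params

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def constraints_ok(self, params: Mapping[str, float]) -> bool:
        p = params
        if self.name == "constant":
            return True
        if self.name == "increasing":
            return p["N_anc"] < p["N_cur"]
        if self.name == "bottleneck":
            return p["N_post"] < p["N_pre"]
        if self.name == "fluctuating":
            return (
                p["N_hist"] > p["N_anc"]
                and p["N_hist"] > p["N_pres"]
                and p["t1"] > p["t2"]
            )
        raise ValueError(f"unknown scenario {self.name!r}")


@dataclass(frozen=True)
class ParameterDraw:
    """One prior draw: scenario parameters plus mutation hyperparameters."""

    scenario: str
    params: dict[str, float]
    mu_mean: float
    gsm_p: float
    locus_rates: np.ndarray | None = None

    def as_record(self) -> dict[str, float]:
        rec = {"scenario": self.scenario, **self.params,
               "mu_mean": self.mu_mean, "gsm_p": self.gsm_p}
        return rec


def make_scenario(name: str, prior: PriorSpec | None = None) -> DemographicScenario:
    """Instantiate one of the four scenario templates."""
    if name not in _SCENARIO_PARAMS:
        raise ValueError(
            f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}"
        )
    ne, times = _SCENARIO_PARAMS[name]
    return DemographicScenario(
        name=name, ne_params=ne, time_params=times, prior=prior or PriorSpec()
    )


def _draw_raw(scenario: DemographicScenario, rng: np.random.Generator) -> dict[str, float]:
    out: dict[str, float] = {}
    for p in scenario.ne_params:
        lo, hi = scenario.prior.bounds_for(p)
        out[p] = float(rng.uniform(lo, hi))
    for p in scenario.time_params:
        lo, hi = scenario.prior.bounds_for(p)
        # event times are integer generations >= 1
        out[p] = float(rng.integers(int(np.ceil(lo)), int(np.floor(hi)) + 1))
    return out


def sample_prior(
    scenario: DemographicScenario,
    rng: np.random.Generator,
    n_loci: int | None = None,
) -> ParameterDraw:
    """Draw scenario parameters from the prior, resampling until the
    scenario's ordering constraints hold.

    When ``n_loci`` is given, per-locus mutation rates are drawn too
    (Gamma around the mean in ``per_locus`` mode, replicated in ``shared``
    mode).
    """
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        params = _draw_raw(scenario, rng)
        if scenario.constraints_ok(params):
            break
    else:
        raise RuntimeError(
            f"scenario {scenario.name!r}: constraint acceptance too low "
            f"({_MAX_REJECTION_ATTEMPTS} attempts failed)"
        )
    prior = scenario.prior
    mu_mean = float(rng.uniform(*prior.mu_mean_bounds))
    gsm_p = float(rng.uniform(*prior.gsm_p_bounds))
    rates = None
    if n_loci is not None:
        from .coalescent import draw_locus_rates

        shape = np.inf if prior.rate_mode == "shared" else prior.gamma_shape
        rates = draw_locus_rates(mu_mean, n_loci, shape, rng)
    return ParameterDraw(
        scenario=scenario.name, params=params, mu_mean=mu_mean,
        gsm_p=gsm_p, locus_rates=rates,
    )


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-constant Ne as a function of generations before present.

    ``sizes[i]`` applies on ``[breaks[i-1], breaks[i])`` (with breaks
    ascending, ``breaks[-1]`` implicit at infinity), so the function is
    right-continuous in gbp: at a change time the older epoch's size applies.
    """

    breaks: np.ndarray  # ascending event times (gbp), length k-1
    sizes: np.ndarray  # epoch sizes recent -> ancient, length k

    def __post_init__(self):
        if len(self.sizes) != len(self.breaks) + 1:
            raise ValueError("need exactly one more size than breaks")
        if np.any(np.asarray(self.sizes) <= 0):
            raise ValueError("Ne must be positive in every epoch")
        if np.any(np.diff(self.breaks) <= 0):
            raise ValueError("breaks must be strictly increasing")

    def __call__(self, g):
        idx = np.searchsorted(self.breaks, g, side="right")
        return np.asarray(self.sizes)[idx]


def to_trajectory(draw: ParameterDraw) -> Trajectory:
    """Turn a parameter draw into its piecewise-constant Ne step function."""
    p = draw.params
    if draw.scenario == "constant":
        breaks, sizes = [], [p["N"]]
    elif draw.scenario == "increasing":
        breaks, sizes = [p["t"]], [p["N_cur"], p["N_anc"]]
    elif draw.scenario == "bottleneck":
        breaks, sizes = [p["t"]], [p["N_post"], p["N_pre"]]
    elif draw.scenario == "fluctuating":
        breaks = [p["t2"], p["t1"]]
        sizes = [p["N_pres"], p["N_hist"], p["N_anc"]]
    else:
        raise ValueError(f"unknown scenario {draw.scenario!r}")
    return Trajectory(
        breaks=np.asarray(breaks, dtype=float),
        sizes=np.asarray(sizes, dtype=float),
    )
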