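"""Demographic scenarios for a bottlenecked island population.

Six piecewise-constant demographies for a single panmictic, haploid,
maternally inherited locus, on a backwards-in-time axis measured in
generations before present (time 0 = the modern sampling layer):

``constant``
    one effective size through time;
``expansion``
    post-glacial expansion: small ancestral size growing (instantaneously,
    backwards: shrinking) at ``t_post_glaciation``;
``expansion_bottleneck``
    post-glacial expansion followed by a single recent bottleneck at a
    free time ``t_bottleneck``;
``bottleneck_eu``
    expansion plus a bottleneck 1-10 generations ago (European settlement);
``bottleneck_pol``
    expansion plus a bottleneck 20-30 generations ago (Polynesian
    settlement);
``bottleneck_pol_eu``
    expansion plus both bottlenecks in sequence.

All sizes are haploid (female) effective sizes: the coalescence rate for k
lineages in an epoch of size N is k(k-1)/(2N) per generation.  Times
convert to years by multiplying with ``generation_time_years`` (default 25).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SCENARIO_IDS",
    "Uniform",
    "PriorSet",
    "DemographicScenario",
    "default_priors",
    "draw_params",
    "build_scenario",
    "scenario_param_names",
]

SCENARIO_IDS = (
    "constant",
    "expansion",
    "expansion_bottleneck",
    "bottleneck_eu",
    "bottleneck_pol",
    "bottleneck_pol_eu",
)

DEFAULT_GENERATION_TIME_YEARS = 25.0

# Published uniform prior bounds for the refined bottleneck models; the
# generic recent-bottleneck time of `expansion_bottleneck` spans both
# candidate settlement windows.
_BOUNDS: dict[str, tuple[float, float]] = {
    "ne_modern": (1.0, 200.0),
    "ne_pre_european": (5e3, 6e5),
    "ne_pre_human": (5e3, 6e5),
    "ne_pre_glaciation": (1e3, 3e5),
    "t_bottleneck": (1.0, 30.0),
    "t_bottleneck_eu": (1.0, 10.0),
    "t_bottleneck_pol": (20.0, 30.0),
    "t_post_glaciation": (300.0, 600.0),
    "mu": (1e-8, 1e-7),
}

# The constant model's single size reuses the pre-glaciation bounds (the
# ancestral-size prior); the expansion model's post-expansion size reuses the
# pre-European prior, nesting it inside the bottleneck models.
_SCENARIO_PARAMS: dict[str, tuple[str, ...]] = {
    "constant": ("ne", "mu"),
    "expansion": ("ne_pre_european", "ne_pre_glaciation", "t_post_glaciation", "mu"),
    "expansion_bottleneck": (
        "ne_modern",
        "ne_pre_european",
        "ne_pre_glaciation",
        "t_bottleneck",
        "t_post_glaciation",
        "mu",
    ),
    "bottleneck_eu": (
        "ne_modern",
        "ne_pre_european",
        "ne_pre_glaciation",
        "t_bottleneck_eu",
        "t_post_glaciation",
        "mu",
    ),
    "bottleneck_pol": (
        "ne_modern",
        "ne_pre_european",
        "ne_pre_glaciation",
        "t_bottleneck_pol",
        "t_post_glaciation",
        "mu",
    ),
    "bottleneck_pol_eu": (
        "ne_modern",
        "ne_pre_european",
        "ne_pre_human",
        "ne_pre_glaciation",
        "t_bottleneck_eu",
        "t_bottleneck_pol",
        "t_post_glaciation",
        "mu",
    ),
}

# Order conditions between effective sizes, per scenario: (greater, lesser).
_SCENARIO_CONSTRAINTS: dict[str, tuple[tuple[str, str], ...]] = {
    "constant": (),
    "expansion": (("ne_pre_european", "ne_pre_glaciation"),),
    "expansion_bottleneck": (("ne_pre_european", "ne_pre_glaciation"),),
    "bottleneck_eu": (("ne_pre_european", "ne_pre_glaciation"),),
    "bottleneck_pol": (("ne_pre_european", "ne_pre_glaciation"),),
    "bottleneck_pol_eu": (
        ("ne_pre_human", "ne_pre_glaciation"),
        ("ne_pre_human", "ne_pre_european"),
    ),
}


@dataclass(frozen=True)
class Uniform:
    """Uniform prior on [low, high)."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"uniform prior requires low < high, got ({self.low}, {self.high})")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass
class PriorSet:
    """Named uniform priors plus pairwise order constraints.

    ``constraints`` is a list of (greater, lesser) parameter-name pairs; a
    draw is accepted only if every greater-parameter exceeds its
    lesser-parameter.
    """

    priors: dict[str, Uniform]
    constraints: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for hi, lo in self.constraints:
            for name in (hi, lo):
                if name not in self.priors:
                    raise ValueError(f"constraint references undeclared parameter {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.priors)

    def bounds(self, name: str) -> tuple[float, float]:
        u = self.priors[name]
        return (u.low, u.high)

    def satisfies(self, params: Mapping[str, float]) -> bool:
        return all(params[hi] > params[lo] for hi, lo in self.constraints)

    def to_dict(self) -> dict:
        return {
            "priors": {k: [u.low, u.high] for k, u in self.priors.items()},
            "constraints": [list(c) for c in self.constraints],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorSet":
        return cls(
            priors={k: Uniform(*v) for k, v in d["priors"].items()},
            constraints=[tuple(c) for c in d["constraints"]],
        )


def scenario_param_names(scenario_id: str) -> tuple[str, ...]:
    """Free parameters of a scenario, in canonical order."""
    _check_scenario(scenario_id)
    return _SCENARIO_PARAMS[scenario_id]


def _check_scenario(scenario_id: str) -> None:
    if scenario_id not in SCENARIO_IDS:
        raise ValueError(
            f"unknown scenario id {scenario_id!r}; expected one of {', '.join(SCENARIO_IDS)}"
        )


def default_priors(scenario_id: str) -> PriorSet:
    """Published uniform priors (and order conditions) for a scenario."""
    _check_scenario(scenario_id)
    names = _SCENARIO_PARAMS[scenario_id]
    priors = {}
    for name in names:
        key = "ne_pre_glaciation" if name == "ne" else name
        priors[name] = Uniform(*_BOUNDS[key])
    return PriorSet(priors=priors, constraints=list(_SCENARIO_CONSTRAINTS[scenario_id]))


def draw_params(
    priors: PriorSet,
    rng: np.random.Generator,
    max_rejects: int = 10**6,
) -> dict[str, float]:
    """Draw one parameter vector from ``priors``, rejecting until all order
    constraints hold.

    Raises ``RuntimeError`` after ``max_rejects`` consecutive rejected draws
    (unsatisfiable constraints given the bounds).
    """
    for _ in range(max_rejects):
        params = {name: float(u.sample(rng)) for name, u in priors.priors.items()}
        if priors.satisfies(params):
            return params
    raise RuntimeError(
        f"could not satisfy order constraints {priors.constraints} in {max_rejects} draws"
    )


@dataclass
class DemographicScenario:
    """Piecewise-constant haploid size history.

    ``epochs`` is an ordered list of (start time in generations before
    present, haploid effective size); the first epoch starts at 0 and the
    last extends to infinity.  ``size_at`` is right-continuous in backwards
    time: at an epoch boundary the older epoch's size applies.
    """

    scenario_id: str
    epochs: list[tuple[float, float]]
    generation_time_years: float = DEFAULT_GENERATION_TIME_YEARS

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("scenario needs at least one epoch")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(n <= 0 for _, n in self.epochs):
            raise ValueError("effective sizes must be positive")

    @property
    def epoch_starts(self) -> np.ndarray:
        return np.array([t for t, _ in self.epochs])

    def size_at(self, t: float) -> float:
        """Haploid effective size at time ``t`` generations before present."""
        if t < 0:
            raise ValueError("time before present must be >= 0")
        idx = int(np.searchsorted(self.epoch_starts, t, side="right")) - 1
        return self.epochs[idx][1]

    def to_years(self, t_generations: float) -> float:
        return t_generations * self.generation_time_years

    def to_dict(self) -> dict:
        return {
            "scenario_id": self.scenario_id,
            "epochs": [list(e) for e in self.epochs],
            "generation_time_years": self.generation_time_years,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicScenario":
        return cls(
            scenario_id=d["scenario_id"],
            epochs=[tuple(e) for e in d["epochs"]],
            generation_time_years=d.get("generation_time_years", DEFAULT_GENERATION_TIME_YEARS),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _require(params: Mapping[str, float], scenario_id: str, *names: str) -> list[float]:
    vals = []
    for name in names:
        if name not in params:
            raise ValueError(f"scenario {scenario_id!r} requires parameter {name!r}")
        vals.append(float(params[name]))
    return vals


def build_scenario(
    scenario_id: str,
    params: Mapping[str, float],
    generation_time_years: float = DEFAULT_GENERATION_TIME_YEARS,
) -> DemographicScenario:
    """Convert named parameters into an epoch list for ``scenario_id``.

    Epochs run backwards in time: the size in force between two event times
    is the size the population had *forward-in-time after* the younger
    event.  E.g. for ``bottleneck_pol_eu``::

        [0, ne_modern], [t_bottleneck_eu, ne_pre_european],
        [t_bottleneck_pol, ne_pre_human], [t_post_glaciation, ne_pre_glaciation]
    """
    _check_scenario(scenario_id)
    if scenario_id == "constant":
        (ne, _mu) = _require(params, scenario_id, "ne", "mu")
        epochs = [(0.0, ne)]
    elif scenario_id == "expansion":
        ne_eu, ne_gl, t_pg, _mu = _require(
            params, scenario_id, "ne_pre_european", "ne_pre_glaciation", "t_post_glaciation", "mu"
        )
        epochs = [(0.0, ne_eu), (t_pg, ne_gl)]
    elif scenario_id == "expansion_bottleneck":
        ne_m, ne_eu, ne_gl, t_b, t_pg, _mu = _require(
            params,
            scenario_id,
            "ne_modern",
            "ne_pre_european",
            "ne_pre_glaciation",
            "t_bottleneck",
            "t_post_glaciation",
            "mu",
        )
        epochs = [(0.0, ne_m), (t_b, ne_eu), (t_pg, ne_gl)]
    elif scenario_id == "bottleneck_eu":
        ne_m, ne_eu, ne_gl, t_eu, t_pg, _mu = _require(
            params,
            scenario_id,
            "ne_modern",
            "ne_pre_european",
            "ne_pre_glaciation",
            "t_bottleneck_eu",
            "t_post_glaciation",
            "mu",
        )
        epochs = [(0.0, ne_m), (t_eu, ne_eu), (t_pg, ne_gl)]
    elif scenario_id == "bottleneck_pol":
        ne_m, ne_eu, ne_gl, t_pol, t_pg, _mu = _require(
            params,
            scenario_id,
            "ne_modern",
            "ne_pre_european",
            "ne_pre_glaciation",
            "t_bottleneck_pol",
            "t_post_glaciation",
            "mu",
        )
        epochs = [(0.0, ne_m), (t_pol, ne_eu), (t_pg, ne_gl)]
    else:  # bottleneck_pol_eu
        ne_m, ne_eu, ne_h, ne_gl, t_eu, t_pol, t_pg, _mu = _require(
            params,
            scenario_id,
            "ne_modern",
            "ne_pre_european",
            "ne_pre_human",
            "ne_pre_glaciation",
            "t_bottleneck_eu",
            "t_bottleneck_pol",
            "t_post_glaciation",
            "mu",
        )
        epochs = [(0.0, ne_m), (t_eu, ne_eu), (t_pol, ne_h), (t_pg, ne_gl)]
    return DemographicScenario(
        scenario_id=scenario_id, epochs=epochs, generation_time_years=generation_time_years
    )
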