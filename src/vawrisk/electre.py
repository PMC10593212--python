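"""ELECTRE TRI-B ordinal sorting engine.

Alternatives are compared with n ordered limit profiles b_1 <= ... <= b_n
that bound n + 1 ordered categories.  For a pair (a, b) the engine computes,
per criterion j with indifference / preference / veto thresholds
q_j <= p_j <= v_j:

* partial concordance c_j(a, b) — the degree to which criterion j supports
  "a is at least as good as b": 1 while b exceeds a by less than q_j,
  0 once the gap reaches p_j, linear in between;
* partial discordance D_j(a, b) — the degree to which criterion j opposes
  that assertion: 0 while the gap is below p_j, 1 at the veto v_j, linear
  in between;
* the global concordance C(a, b), the weight-normalised mean of the c_j;
* the credibility sigma(a, b) = C * prod_{j: D_j > C} (1 - D_j)/(1 - C),
  i.e. concordance discounted by every strong discordance; a single
  criterion at its veto annihilates credibility.

"a outranks b" (a S b) holds when sigma(a, b) >= lambda with the cut level
lambda in [0.5, 1].  The pessimistic rule scans profiles downwards and
assigns the first class whose lower bound the alternative outranks; the
optimistic rule scans upwards and stops at the first profile strictly
preferred to the alternative.

Criteria may be declared ``minimize``; their evaluations (alternative and
profile alike) are sign-flipped on entry so all formulas read as maximise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from .exceptions import ConfigError
from .io import PerformanceTable
from .reporting import label_classes

Direction = Literal["maximize", "minimize"]


@dataclass(frozen=True)
class CriterionSpec:
    """One criterion: weight w, thresholds q <= p <= v, and direction."""

    code: str
    weight: float
    q: float
    p: float
    v: float
    direction: Direction = "maximize"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ConfigError(f"{self.code}: weight must be positive")
        if not 0 <= self.q <= self.p <= self.v:
            raise ConfigError(
                f"{self.code}: thresholds must satisfy 0 <= q <= p <= v, "
                f"got q={self.q}, p={self.p}, v={self.v}")
        if self.direction not in ("maximize", "minimize"):
            raise ConfigError(f"{self.code}: unknown direction {self.direction!r}")


@dataclass(frozen=True)
class LimitProfiles:
    """Per-criterion ordered boundary evaluations g_j(b_1) ... g_j(b_n).

    ``boundaries`` maps criterion code -> tuple of n values, nondecreasing
    on the direction-adjusted (maximise) scale; every criterion carries the
    same n.  n profiles induce n + 1 ordered categories.
    """

    boundaries: dict[str, tuple[float, ...]]
    directions: dict[str, Direction] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.boundaries.values()}
        if len(lengths) != 1:
            raise ConfigError("all criteria must have the same number of profiles")
        (n,) = lengths
        if n < 1:
            raise ConfigError("at least one limit profile is required")
        for code, values in self.boundaries.items():
            sign = -1.0 if self.directions.get(code) == "minimize" else 1.0
            adjusted = [sign * v for v in values]
            if any(a > b for a, b in zip(adjusted, adjusted[1:])):
                raise ConfigError(
                    f"{code}: profiles must be ordered b_1 <= ... <= b_n "
                    "on the direction-adjusted scale")

    @property
    def n_profiles(self) -> int:
        return len(next(iter(self.boundaries.values())))

    def vector(self, h: int, criteria: Sequence[str]) -> np.ndarray:
        """Profile b_h (1-based) as an array in the given criterion order."""
        return np.array([self.boundaries[c][h - 1] for c in criteria])


@dataclass(frozen=True)
class ModelConfig:
    """Full sorter configuration: criteria, profiles, lambda cut, rule."""

    criteria: tuple[CriterionSpec, ...]
    profiles: LimitProfiles
    lambda_cut: float = 0.60
    assignment_rule: Literal["pessimistic", "optimistic", "both"] = "both"

    def __post_init__(self) -> None:
        if not 0.5 <= self.lambda_cut <= 1.0:
            raise ConfigError(
                f"lambda cut {self.lambda_cut} outside [0.5, 1]")
        codes = [c.code for c in self.criteria]
        if len(set(codes)) != len(codes):
            raise ConfigError("criterion codes must be unique")
        if set(codes) != set(self.profiles.boundaries):
            raise ConfigError("profiles must cover exactly the criterion codes")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.criteria)

    @property
    def n_profiles(self) -> int:
        return self.profiles.n_profiles

    @property
    def n_classes(self) -> int:
        return self.n_profiles + 1

    def with_lambda(self, lambda_cut: float) -> "ModelConfig":
        return replace(self, lambda_cut=lambda_cut)

    def with_weights(self, weights: Sequence[float]) -> "ModelConfig":
        if len(weights) != len(self.criteria):
            raise ConfigError("one weight per criterion required")
        new = tuple(replace(c, weight=w) for c, w in zip(self.criteria, weights))
        return replace(self, criteria=new)


@dataclass(frozen=True)
class AssignmentResult:
    """Sorted classes for one alternative (class index 1 = worst category)."""

    id: str
    class_pessimistic: int
    class_optimistic: int
    label: str
    name: str = ""


# ---------------------------------------------------------------------------
# elementary indices
# ---------------------------------------------------------------------------

def partial_concordance(ga: float, gb: float, spec: CriterionSpec) -> float:
    """c_j(a, b): support for "a at least as good as b" on criterion j.

    Degenerate q == p collapses to a step function at p.
    """
    diff = gb - ga
    if diff < spec.q:
        return 1.0
    if diff >= spec.p:
        return 0.0
    return (spec.p - diff) / (spec.p - spec.q)


def partial_discordance(ga: float, gb: float, spec: CriterionSpec) -> float:
    """D_j(a, b): opposition to "a at least as good as b" on criterion j.

    Degenerate p == v collapses to a step function at v.
    """
    diff = gb - ga
    if diff < spec.p:
        return 0.0
    if diff >= spec.v:
        return 1.0
    return (diff - spec.p) / (spec.v - spec.p)


def global_concordance(partials: Sequence[float],
                       weights: Sequence[float]) -> float:
    """Weighted mean sum(w_j c_j) / sum(w_j) of the partial concordances."""
    if len(partials) == 0:
        raise ValueError("at least one criterion is required")
    if len(partials) != len(weights):
        raise ValueError("partials and weights must have equal length")
    total = float(sum(weights))
    return float(sum(w * c for w, c in zip(weights, partials)) / total)


def credibility(concordance: float, discordances: Sequence[float]) -> float:
    """sigma: global concordance discounted by strong discordances.

    Only criteria whose discordance exceeds the global concordance
    contribute a factor (1 - D_j)/(1 - C); with no such criterion sigma
    equals C.  Any D_j = 1 (veto reached) with C < 1 gives sigma = 0.
    """
    sigma = concordance
    for d in discordances:
        if d > concordance:
            # d > C implies C < 1 here, so the denominator is nonzero
            sigma *= (1.0 - d) / (1.0 - concordance)
    return sigma


def outranks(sigma: float, lambda_cut: float) -> bool:
    """True iff sigma >= lambda (inclusive cut)."""
    if not 0.5 <= lambda_cut <= 1.0:
        raise ConfigError(f"lambda cut {lambda_cut} outside [0.5, 1]")
    return sigma >= lambda_cut


# ---------------------------------------------------------------------------
# pairwise credibility and assignment
# ---------------------------------------------------------------------------

def _adjusted(values: np.ndarray, criteria: Sequence[CriterionSpec]) -> np.ndarray:
    """Sign-flip minimize criteria so every formula reads as maximise."""
    signs = np.array([-1.0 if c.direction == "minimize" else 1.0
                      for c in criteria])
    return np.asarray(values, dtype=float) * signs


def credibility_pair(ga: Sequence[float], gb: Sequence[float],
                     criteria: Sequence[CriterionSpec]) -> float:
    """sigma(a, b) for already direction-adjusted evaluation vectors."""
    partials = [partial_concordance(x, b, s) for x, b, s in zip(ga, gb, criteria)]
    C = global_concordance(partials, [s.weight for s in criteria])
    D = [partial_discordance(x, b, s) for x, b, s in zip(ga, gb, criteria)]
    return credibility(C, D)


def assign_pessimistic(x: Sequence[float], config: ModelConfig) -> int:
    """Descending scan: first profile the alternative outranks fixes the class.

    Returns h + 1 for the highest h with x S b_h, or 1 when x outranks no
    profile.  ``x`` is a raw performance row in config criterion order.
    """
    xa = _adjusted(x, config.criteria)
    for h in range(config.n_profiles, 0, -1):
        bh = _adjusted(config.profiles.vector(h, config.codes), config.criteria)
        if outranks(credibility_pair(xa, bh, config.criteria), config.lambda_cut):
            return h + 1
    return 1


def assign_optimistic(x: Sequence[float], config: ModelConfig) -> int:
    """Ascending scan: stop at the first profile strictly preferred to x.

    b_h is strictly preferred when sigma(b_h, x) >= lambda while
    sigma(x, b_h) < lambda; with no such profile the top class is assigned.
    """
    xa = _adjusted(x, config.criteria)
    for h in range(1, config.n_profiles + 1):
        bh = _adjusted(config.profiles.vector(h, config.codes), config.criteria)
        b_over_x = outranks(credibility_pair(bh, xa, config.criteria),
                            config.lambda_cut)
        x_over_b = outranks(credibility_pair(xa, bh, config.criteria),
                            config.lambda_cut)
        if b_over_x and not x_over_b:
            return h
    return config.n_profiles + 1


def classify_all(table: PerformanceTable,
                 config: ModelConfig) -> list[AssignmentResult]:
    """Sort every non-excluded alternative into one of the n + 1 classes.

    The headline ``label`` is derived from the pessimistic class, the
    conservative choice for risk screening.
    """
    if tuple(table.criteria) != config.codes:
        raise ConfigError(
            f"criteria mismatch: table has {table.criteria}, "
            f"config has {config.codes}")
    if len(table.alternatives) == 0:
        raise ConfigError("performance table has no alternatives")
    results = []
    for alt_id, row in zip(table.alternatives, table.values):
        pes = assign_pessimistic(row, config)
        opt = assign_optimistic(row, config)
        results.append(AssignmentResult(
            id=alt_id,
            class_pessimistic=pes,
            class_optimistic=opt,
            label=label_classes(pes, config.n_profiles),
            name=table.names.get(alt_id, ""),
        ))
    return results


# ---------------------------------------------------------------------------
# study configuration and YAML round-trip
# ---------------------------------------------------------------------------

#: per-criterion limit profiles b_1..b_5 of the study configuration,
#: on the normalised [0, 1] scale (C1 SPI, C2 HDI, C3 GDP per capita, C4 Gini)
DEFAULT_PROFILES = {
    "C1": (0.1, 0.2, 0.3, 0.4, 0.5),
    "C2": (0.48, 0.57, 0.62, 0.68, 0.69),
    "C3": (0.01, 0.03, 0.04, 0.08, 0.50),
    "C4": (0.37, 0.68, 0.70, 0.72, 0.85),
}

#: study thresholds and weights: q, p, v identical across criteria;
#: HDI and Gini carry the largest weights
DEFAULT_PARAMETERS = {
    "C1": dict(weight=0.5, q=0.1, p=0.2, v=1.0),
    "C2": dict(weight=1.0, q=0.1, p=0.2, v=1.0),
    "C3": dict(weight=0.3, q=0.1, p=0.2, v=1.0),
    "C4": dict(weight=1.0, q=0.1, p=0.2, v=1.0),
}

DEFAULT_LAMBDA = 0.60


def default_config(invert_gini: bool = False,
                   lambda_cut: float = DEFAULT_LAMBDA) -> ModelConfig:
    """The study configuration: four criteria, five profiles, lambda = 0.60.

    All criteria are maximised as published; ``invert_gini`` flips C4 to
    minimise for users who read higher inequality as higher risk.
    """
    criteria = []
    for code, params in DEFAULT_PARAMETERS.items():
        direction = ("minimize" if invert_gini and code == "C4"
                     else "maximize")
        criteria.append(CriterionSpec(code=code, direction=direction, **params))
    directions = {c.code: c.direction for c in criteria}
    profiles = LimitProfiles(
        boundaries={k: tuple(v) for k, v in DEFAULT_PROFILES.items()},
        directions=directions)
    return ModelConfig(criteria=tuple(criteria), profiles=profiles,
                       lambda_cut=lambda_cut)


def load_config(path: str | Path) -> ModelConfig:
    """Load a sorter configuration from the documented YAML schema.

    Schema::

        lambda: 0.60
        assignment_rule: both        # pessimistic | optimistic | both
        criteria:
          - {code: C1, weight: 0.5, q: 0.1, p: 0.2, v: 1.0, direction: maximize}
          ...
        profiles:
          C1: [0.1, 0.2, 0.3, 0.4, 0.5]
          ...
    """
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        criteria = tuple(
            CriterionSpec(code=c["code"], weight=float(c["weight"]),
                          q=float(c["q"]), p=float(c["p"]), v=float(c["v"]),
                          direction=c.get("direction", "maximize"))
            for c in raw["criteria"])
        profiles = LimitProfiles(
            boundaries={k: tuple(float(x) for x in v)
                        for k, v in raw["profiles"].items()},
            directions={c.code: c.direction for c in criteria})
        return ModelConfig(
            criteria=criteria, profiles=profiles,
            lambda_cut=float(raw.get("lambda", DEFAULT_LAMBDA)),
            assignment_rule=raw.get("assignment_rule", "both"))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed configuration file: {exc}") from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration in the YAML schema read by :func:`load_config`."""
    payload = {
        "lambda": config.lambda_cut,
        "assignment_rule": config.assignment_rule,
        "criteria": [
            dict(code=c.code, weight=c.weight, q=c.q, p=c.p, v=c.v,
                 direction=c.direction)
            for c in config.criteria],
        "profiles": {k: list(v)
                     for k, v in config.profiles.boundaries.items()},
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
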