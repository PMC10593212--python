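"""Synthetic municipality datasets with a known latent protection structure.

The generator emulates the shape of a Brazilian municipal survey extract
(one row per municipality: five binary protection-equipment flags, HDI,
GDP per capita, Gini, complaint counts) without any real data.  A single
latent "protection capacity" factor couples all indicators:

* each equipment flag is a Bernoulli draw whose log-odds increase with
  capacity (police stations are rarest, campaigns most common);
* HDI increases stochastically with capacity inside ``hdi_range``;
* GDP per capita is log-normal with location increasing in capacity;
* Gini *decreases* stochastically with capacity inside ``gini_range``
  (better-run municipalities are less unequal);
* complaint counts are Poisson with a rate increasing in capacity —
  deliberately reproducing the reporting-access paradox: well-equipped
  municipalities record *more* complaints because victims can reach the
  services, not because violence is more prevalent.

Optionally one record is emitted with every indicator missing, mirroring
a municipality that did not answer the survey and must be excluded from
classification.  The latent capacity is stored on each record (never
serialised to CSV) so recovery tests can compare it with the assigned
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .exceptions import ConfigError
from .io import INDICATOR_FIELDS, MunicipalRecord

#: per-equipment intercepts on the log-odds scale: specialised police
#: stations are the rarest equipment, campaigns the most widespread
EQUIPMENT_INTERCEPTS = (-1.5, -0.5, 0.0, -0.8, -1.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic municipality generator.

    Defaults emulate a state-wide survey of 144 municipalities with one
    non-respondent, HDI spanning the low-to-mid development range, Gini
    spanning the published profile grid, and GDP per capita log-normal
    around 15 thousand currency units.
    """

    n: int = 144
    seed: int = 0
    capacity_sd: float = 1.0
    equipment_slope: float = 1.2
    hdi_range: tuple[float, float] = (0.40, 0.85)
    hdi_capacity_slope: float = 1.0
    gini_range: tuple[float, float] = (0.35, 0.85)
    gini_capacity_slope: float = 1.0
    gdp_log_mean: float = 9.6  # exp(9.6) ~ 14.8k per capita
    gdp_log_sd: float = 0.5
    gdp_capacity_slope: float = 0.4
    complaints_base_rate: float = 20.0
    complaints_capacity_slope: float = 1.0
    include_fully_missing: bool = True
    indicator_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("n must be at least 2")
        for name in ("hdi_range", "gini_range"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo < hi <= 1.0:
                raise ConfigError(f"{name} must be an interval within [0, 1]")
        if self.capacity_sd < 0 or self.gdp_log_sd < 0:
            raise ConfigError("spread parameters must be non-negative")
        if self.complaints_base_rate < 0:
            raise ConfigError("complaints_base_rate must be non-negative")


def generate_municipalities(params: GeneratorParams) -> list[MunicipalRecord]:
    """Draw a deterministic synthetic dataset of ``params.n`` municipalities.

    When ``include_fully_missing`` is set the last record has every
    indicator absent (the survey non-respondent); it still counts toward
    ``n``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    capacity = rng.normal(0.0, params.capacity_sd, size=n)

    # equipment: independent Bernoulli flags, log-odds linear in capacity
    logits = (np.array(EQUIPMENT_INTERCEPTS)[None, :]
              + params.equipment_slope * capacity[:, None])
    equipment = (rng.random((n, 5)) < expit(logits)).astype(int)

    # bounded indicators via a probit-style link: the latent score
    # (capacity plus noise) is squashed to (0, 1) and mapped to the range
    def bounded(lo: float, hi: float, slope: float, sign: float) -> np.ndarray:
        score = sign * slope * capacity + rng.normal(
            0.0, params.indicator_noise_sd, size=n)
        return lo + (hi - lo) * norm.cdf(score)

    hdi = bounded(*params.hdi_range, params.hdi_capacity_slope, +1.0)
    gini = bounded(*params.gini_range, params.gini_capacity_slope, -1.0)

    gdp = np.exp(params.gdp_log_mean
                 + params.gdp_capacity_slope * capacity
                 + rng.normal(0.0, params.gdp_log_sd, size=n))

    rate = params.complaints_base_rate * np.exp(
        params.complaints_capacity_slope * capacity)
    complaints = rng.poisson(rate)

    records = []
    width = len(str(n))
    for i in range(n):
        rec_id = f"M{i + 1:0{width}d}"
        name = f"Municipality {i + 1}"
        if params.include_fully_missing and i == n - 1:
            records.append(MunicipalRecord(
                id=rec_id, name=name, equipment=(0, 0, 0, 0, 0),
                hdi=None, gdp_per_capita=None, gini=None, complaints=None,
                missing=frozenset(INDICATOR_FIELDS + ("complaints",)),
                latent_capacity=float(capacity[i])))
            continue
        records.append(MunicipalRecord(
            id=rec_id, name=name, equipment=tuple(int(f) for f in equipment[i]),
            hdi=float(hdi[i]), gdp_per_capita=float(gdp[i]),
            gini=float(gini[i]), complaints=int(complaints[i]),
            latent_capacity=float(capacity[i])))
    return records
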