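"""Synthetic field-experiment, activity and disposal-share generators.

The published observation tables and the city statistics behind the
inventory are not distributed in machine-readable form, so this module
generates tables with the same statistical structure: an exponential
straw-grain relationship with multiplicative log-normal noise and
region-specific parameters for the field observations; per city-year
acreage and grain yield records, including "NA" (no statistics) and
zero-acreage (wheat-free municipal district) rows; and Dirichlet-sampled
recycle/burn/remove shares.

Every generator is a pure function of the seed: identical configuration
gives byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .inventory import CityRecord, DisposalShares
from .regions import REGION_PROVINCES, Region, coerce_region
from .yield_model import FieldObservation

#: Per-region observation counts matching the assembled literature corpus.
DEFAULT_N_OBS: dict[Region, int] = {Region.NC: 1728, Region.CC: 2209, Region.SC: 1184}

#: Illustrative true (a, b) per region: straw/grain ratio ~1.0-1.4 over the
#: grain range, highest in central China.
DEFAULT_TRUE_PARAMS: dict[Region, tuple[float, float]] = {
    Region.NC: (2800.0, 1.3e-4),
    Region.CC: (3200.0, 1.2e-4),
    Region.SC: (3000.0, 1.15e-4),
}

_REGION_STREAM = {Region.NC: 0, Region.CC: 1, Region.SC: 2}


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study.

    ``n_obs_per_region`` may be a single count or a per-region mapping;
    ``true_params`` maps region -> (a in kg ha^-1, b in ha kg^-1);
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal straw-yield noise; ``grain_sampling`` is ``uniform`` or
    ``truncnorm`` over ``grain_range``.
    """

    seed: int = 0
    n_obs_per_region: int | Mapping[Region, int] = field(
        default_factory=lambda: dict(DEFAULT_N_OBS))
    grain_range: tuple[float, float] = (1000.0, 9000.0)
    true_params: Mapping[Region, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PARAMS))
    noise_cv: float = 0.1
    grain_sampling: str = "uniform"
    n_cities_per_region: int = 12
    years: Sequence[int] = (2011, 2012, 2013, 2014, 2015)
    area_range: tuple[float, float] = (5.0, 600.0)  # 1000 ha
    na_fraction: float = 0.05
    zero_fraction: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.grain_range
        if not 0 < lo < hi:
            raise ValueError(f"grain_range must satisfy 0 < min < max, got {self.grain_range}")
        alo, ahi = self.area_range
        if not 0 < alo < ahi:
            raise ValueError(f"area_range must satisfy 0 < min < max, got {self.area_range}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.na_fraction < 0 or self.zero_fraction < 0:
            raise ValueError("na_fraction and zero_fraction must be >= 0")
        if self.na_fraction + self.zero_fraction >= 1:
            raise ValueError("na_fraction + zero_fraction must be < 1")
        if self.grain_sampling not in ("uniform", "truncnorm"):
            raise ValueError(f"unknown grain_sampling {self.grain_sampling!r}")
        if self.n_cities_per_region <= 0 or not self.years:
            raise ValueError("need n_cities_per_region > 0 and a non-empty year list")

    def n_obs(self, region: Region) -> int:
        if isinstance(self.n_obs_per_region, Mapping):
            return int(self.n_obs_per_region[region])
        return int(self.n_obs_per_region)

    def params(self, region: Region) -> tuple[float, float]:
        return self.true_params[region]


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    # independent, order-insensitive streams per generator/region
    return np.random.default_rng([cfg_seed, stream])


def _sample_grain(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> np.ndarray:
    lo, hi = cfg.grain_range
    if cfg.grain_sampling == "uniform":
        return rng.uniform(lo, hi, size=n)
    # truncated normal centred mid-range, sd a quarter of the span
    mid, sd = 0.5 * (lo + hi), 0.25 * (hi - lo)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mid, sd, size=n - filled)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def generate_observations(cfg: SyntheticConfig,
                          region: Region | str) -> list[FieldObservation]:
    """Field observations for one region under straw = a*exp(b*grain)*eps.

    ``eps`` is log-normal with mean 1 and coefficient of variation
    ``noise_cv`` (positive by construction, no truncation needed); with
    ``noise_cv=0`` the generating curve is returned exactly.  The harvest
    index of every record is grain / (grain + straw), hence in (0, 1).
    """
    region = coerce_region(region)
    a, b = cfg.params(region)
    n = cfg.n_obs(region)
    rng = _rng(cfg.seed, 10 + _REGION_STREAM[region])
    grain = _sample_grain(rng, cfg, n)
    straw = a * np.exp(b * grain)
    if cfg.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
        straw = straw * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    return [
        FieldObservation(region=region, grain_yield=float(g), straw_yield=float(s),
                         harvest_index=float(g / (g + s)))
        for g, s in zip(grain, straw)
    ]


def generate_city_table(cfg: SyntheticConfig) -> list[CityRecord]:
    """City-year activity records across the three wheat zones.

    Provinces cycle through each zone's province list; every city carries
    one record per year.  ``na_fraction`` of city-years are emitted as
    missing and ``zero_fraction`` as zero-acreage municipal districts, so
    the pipeline's "NA"/"0" propagation rules are exercised.
    """
    rng = _rng(cfg.seed, 20)
    records: list[CityRecord] = []
    for region in Region:
        provinces = REGION_PROVINCES[region]
        for c in range(cfg.n_cities_per_region):
            province = provinces[c % len(provinces)]
            city_id = f"{region}-{province}-{c:02d}"
            for year in cfg.years:
                u = rng.random()
                area = float(rng.uniform(*cfg.area_range))
                grain = float(rng.uniform(*cfg.grain_range))
                if u < cfg.na_fraction:
                    records.append(CityRecord(city_id, province, region, int(year),
                                              None, None, status="missing"))
                elif u < cfg.na_fraction + cfg.zero_fraction:
                    records.append(CityRecord(city_id, province, region, int(year),
                                              0.0, None, status="zero"))
                else:
                    records.append(CityRecord(city_id, province, region, int(year),
                                              area, grain, status="ok"))
    return records


def generate_disposal_shares(seed: int, n: int,
                             concentration: Sequence[float] = (1.0, 1.0, 1.0),
                             ) -> list[DisposalShares]:
    """Dirichlet-sampled (recycle, burn, remove) share triples.

    ``concentration`` holds the three positive Dirichlet parameters; with
    (1, 1, 1) the shares are uniform on the simplex.  The remove share is
    written as 1 - recycle - burn so each triple sums to 1 exactly.
    """
    conc = np.asarray(concentration, dtype=float)
    if conc.shape != (3,) or np.any(conc <= 0):
        raise ValueError("concentration must be 3 positive numbers")
    if n <= 0:
        raise ValueError("n must be positive")
    draws = _rng(seed, 30).dirichlet(conc, size=n)
    return [DisposalShares(float(r), float(b), 1.0 - float(r) - float(b))
            for r, b, _ in draws]
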