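"""The city-level straw accounting chain.

Four steps per city-year:

1. total straw  = straw yield per hectare x planting area,
2. disposal     = total straw x (recycle, burn, remove) shares,
3. nutrients    = (recycled + burned) x regional N/P/K mass fractions,
4. emissions    = burned x per-pollutant emission factor.

Unit conventions follow the published data sheets: planting area in
1000 ha, per-hectare yields in kg ha^-1, straw amounts in 10^4 tons,
nutrient supplies and pollutant emissions in tons.  All conversions live
in this module and nowhere else.

Missing-data semantics: a city-year with no statistics stays *missing*
through every step and is excluded from aggregates; a wheat-free municipal
district is a numeric zero and stays zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .coefficients import (
    EmissionFactors,
    NutrientCoefficients,
    NUTRIENTS,
    POLLUTANTS,
)
from .regions import Region, coerce_region
from .yield_model import StrawYieldModel, predict_straw_yield

#: kg ha^-1 x 1000 ha = 1 t; divide by 1e4 for the sheet unit of 10^4 t.
_KGHA_X_1000HA_TO_1E4T = 1e-4
#: 10^4 t -> t.
_1E4T_TO_T = 1e4
#: g kg^-1 = kg t^-1; divide by 1000 for t per t burned.
_G_PER_KG_TO_T_PER_T = 1e-3

SHARE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DisposalShares:
    """Fractions of total straw recycled, burned and removed; they sum to 1."""

    p_recycle: float
    p_burn: float
    p_remove: float

    def __post_init__(self) -> None:
        for name, p in self.as_dict().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        total = self.p_recycle + self.p_burn + self.p_remove
        if abs(total - 1.0) > SHARE_SUM_TOL:
            raise ValueError(f"disposal shares must sum to 1, got {total!r}")

    def as_dict(self) -> dict[str, float]:
        return {"p_recycle": self.p_recycle, "p_burn": self.p_burn,
                "p_remove": self.p_remove}


@dataclass(frozen=True)
class CityRecord:
    """One city-year activity record.

    ``status`` is one of ``ok`` (positive area and yield), ``zero``
    (wheat-free municipal district, area 0) and ``missing`` (no statistics;
    numeric fields absent).  ``straw_yield_per_ha`` is filled by the yield
    model during :func:`run_inventory` unless supplied directly.
    """

    city_id: str
    province: str
    region: Region
    year: int
    area: float | None  # 1000 ha
    grain_yield_per_ha: float | None  # kg ha^-1
    straw_yield_per_ha: float | None = None  # kg ha^-1
    status: str = "ok"

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", coerce_region(self.region))
        if self.status not in ("ok", "zero", "missing"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "ok":
            if self.area is None or self.area <= 0:
                raise ValueError(f"{self.city_id}/{self.year}: ok record needs area > 0")
            if self.grain_yield_per_ha is None or self.grain_yield_per_ha <= 0:
                raise ValueError(f"{self.city_id}/{self.year}: ok record needs grain yield > 0")
        elif self.status == "zero":
            if self.area not in (0, 0.0):
                raise ValueError(f"{self.city_id}/{self.year}: zero record must have area 0")
        else:  # missing
            if any(v is not None for v in (self.area, self.grain_yield_per_ha,
                                           self.straw_yield_per_ha)):
                raise ValueError(
                    f"{self.city_id}/{self.year}: missing record must carry no numbers"
                )


@dataclass(frozen=True)
class InventoryResult:
    """Per city-year outputs of the full chain.

    Straw amounts in 10^4 t; nutrient supplies and emissions in t.  For a
    ``missing`` record every numeric field is None; for a ``zero`` record
    every numeric field is 0.
    """

    city_id: str
    province: str
    region: Region
    year: int
    status: str
    area: float | None  # 1000 ha
    grain_yield_per_ha: float | None  # kg ha^-1
    straw_yield_per_ha: float | None  # kg ha^-1
    total_straw: float | None  # 10^4 t
    recycled: float | None  # 10^4 t
    burned: float | None  # 10^4 t
    removed: float | None  # 10^4 t
    nutrient_supply: dict[str, float | None] = field(default_factory=dict)  # t
    emissions: dict[str, float | None] = field(default_factory=dict)  # t


def total_straw_yield(rec: CityRecord) -> float | None:
    """Eq.-1 step: total straw (10^4 t) from per-ha yield and area.

    Missing records propagate None; zero records give 0.0.
    """
    if rec.status == "missing":
        return None
    if rec.status == "zero":
        return 0.0
    if rec.straw_yield_per_ha is None:
        raise ValueError(f"{rec.city_id}/{rec.year}: straw_yield_per_ha not filled")
    return rec.straw_yield_per_ha * rec.area * _KGHA_X_1000HA_TO_1E4T


def partition_disposal(total: float, shares: DisposalShares) -> tuple[float, float, float]:
    """Eq.-2 step: split a straw total into (recycled, burned, removed)."""
    if total < 0:
        raise ValueError(f"total straw must be >= 0, got {total}")
    return (total * shares.p_recycle, total * shares.p_burn, total * shares.p_remove)


def nutrient_supply(recycled: float, burned: float, region: Region | str,
                    coeffs: NutrientCoefficients) -> dict[str, float]:
    """Eq.-3 step: N/P/K returned to the field, in tons.

    ``recycled`` and ``burned`` are in 10^4 t (the sheet unit); removed
    straw contributes nothing.
    """
    region = coerce_region(region)
    if recycled < 0 or burned < 0:
        raise ValueError("straw masses must be >= 0")
    mass_t = (recycled + burned) * _1E4T_TO_T
    return {n: mass_t * coeffs.fraction(region, n) for n in NUTRIENTS}


def burning_emissions(burned_t: float, efs: EmissionFactors) -> dict[str, float]:
    """Eq.-4 step: pollutant emissions (t) from a burned straw mass (t)."""
    if burned_t < 0:
        raise ValueError(f"burned mass must be >= 0, got {burned_t}")
    return {k: burned_t * efs.ef[k] * _G_PER_KG_TO_T_PER_T for k in POLLUTANTS}


def _resolve_shares(rec: CityRecord,
                    shares: DisposalShares | Mapping,
                    ) -> DisposalShares:
    """Precedence: per-city > per-region > global."""
    if isinstance(shares, DisposalShares):
        return shares
    for key in (rec.city_id, rec.region, "global"):
        if key in shares:
            return shares[key]
    raise KeyError(
        f"no disposal shares for city {rec.city_id!r} (region {rec.region}); "
        "supply a per-city, per-region or 'global' entry"
    )


def run_inventory(cities: Iterable[CityRecord],
                  shares: DisposalShares | Mapping,
                  coeffs: NutrientCoefficients,
                  efs: EmissionFactors,
                  models: Mapping[Region, StrawYieldModel] | None = None,
                  ) -> list[InventoryResult]:
    """Run the four-step chain over a city table.

    ``shares`` is either one :class:`DisposalShares` applied everywhere or a
    mapping keyed by city_id, :class:`Region` or ``"global"`` (precedence in
    that order).  ``models`` supplies the fitted regional yield models used
    to fill ``straw_yield_per_ha`` where absent; records that already carry
    a straw yield do not need one.

    Raises on duplicate (city_id, year) keys and on ok-records whose region
    has no fitted model.
    """
    cities = list(cities)
    keys = [(c.city_id, c.year) for c in cities]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (city, year) rows: {dupes}")

    models = models or {}
    lacking = sorted({c.city_id for c in cities
                      if c.status == "ok" and c.straw_yield_per_ha is None
                      and c.region not in models})
    if lacking:
        raise ValueError(f"no fitted straw model for cities: {lacking}")

    results: list[InventoryResult] = []
    for rec in cities:
        if rec.status == "missing":
            results.append(InventoryResult(
                rec.city_id, rec.province, rec.region, rec.year, "missing",
                None, None, None, None, None, None, None,
                {n: None for n in NUTRIENTS}, {p: None for p in POLLUTANTS}))
            continue
        if rec.status == "ok" and rec.straw_yield_per_ha is None:
            rec = replace(rec, straw_yield_per_ha=float(
                predict_straw_yield(models[rec.region], rec.grain_yield_per_ha)))
        total = total_straw_yield(rec)
        recycled, burned, removed = partition_disposal(total, _resolve_shares(rec, shares))
        nutrients = nutrient_supply(recycled, burned, rec.region, coeffs)
        emissions = burning_emissions(burned * _1E4T_TO_T, efs)
        results.append(InventoryResult(
            rec.city_id, rec.province, rec.region, rec.year, rec.status,
            rec.area, rec.grain_yield_per_ha, rec.straw_yield_per_ha,
            total, recycled, burned, removed, nutrients, emissions))
    return results


def aggregate(results: Iterable[InventoryResult],
              by: str = "national") -> pd.DataFrame:
    """Sum inventory outputs over non-missing records.

    ``by`` is ``"national"``, ``"region"`` or ``"province"``.  Missing
    records are excluded; if every record in a group is missing the group
    does not appear.  Straw columns stay in 10^4 t, nutrients and emissions
    in t.
    """
    rows = []
    for r in results:
        if r.status == "missing":
            continue
        row = {"region": str(r.region), "province": r.province,
               "total_straw_1e4t": r.total_straw, "recycled_1e4t": r.recycled,
               "burned_1e4t": r.burned, "removed_1e4t": r.removed}
        row.update({f"{n}_t": r.nutrient_supply[n] for n in NUTRIENTS})
        row.update({f"{p}_t": r.emissions[p] for p in POLLUTANTS})
        rows.append(row)
    value_cols = (["total_straw_1e4t", "recycled_1e4t", "burned_1e4t", "removed_1e4t"]
                  + [f"{n}_t" for n in NUTRIENTS] + [f"{p}_t" for p in POLLUTANTS])
    if not rows:
        return pd.DataFrame(columns=value_cols)
    df = pd.DataFrame(rows)
    if by == "national":
        return df[value_cols].sum().to_frame().T
    if by in ("region", "province"):
        return df.groupby(by, sort=True)[value_cols].sum().reset_index()
    raise ValueError(f"unknown aggregation level {by!r}")


def mass_balance_ok(result: InventoryResult, rel_tol: float = 1e-9) -> bool:
    """Check recycled + burned + removed == total for one record."""
    if result.status == "missing":
        return True
    parts = result.recycled + result.burned + result.removed
    return math.isclose(parts, result.total_straw, rel_tol=rel_tol, abs_tol=1e-12)
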