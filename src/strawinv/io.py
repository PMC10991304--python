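"""Table I/O for every pipeline stage.

Dialect: comma-separated UTF-8 CSV with a header row, "." decimal, and the
literal token "NA" for missing values.  Column names embed the unit (e.g.
``area_1000ha``, ``total_straw_1e4t``) because the unit conventions differ
per sheet.  A city-year with area "NA" is a *missing* record; one with
area 0 is a wheat-free municipal district and stays a numeric zero.

``write_sheets`` mirrors the published five-sheet layout: models building,
wheat planting situation, straw field management, nutrient supplies and
gaseous pollutants, one CSV per sheet, rows ordered by (province, city,
year).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .coefficients import NUTRIENTS, POLLUTANTS
from .inventory import CityRecord, DisposalShares, InventoryResult
from .regions import Region, coerce_region, region_of_province
from .yield_model import FieldObservation, StrawYieldModel

NA = "NA"

CITY_COLUMNS = ["province", "city_id", "year", "area_1000ha", "grain_yield_kg_ha"]
OBS_COLUMNS = ["region", "grain_yield_kg_ha", "straw_yield_kg_ha", "harvest_index"]
MODEL_COLUMNS = ["region", "a_kg_ha", "b_ha_kg", "n_obs", "r_squared", "residual_sd_kg_ha"]
SHARES_COLUMNS = ["scope", "p_recycle", "p_burn", "p_remove"]

SHEET_FILES = {
    "models_building": "models_building.csv",
    "wheat_planting_situation": "wheat_planting_situation.csv",
    "straw_field_management": "straw_field_management.csv",
    "nutrient_supplies": "nutrient_supplies.csv",
    "gaseous_pollutants": "gaseous_pollutants.csv",
}


class TableFormatError(ValueError):
    """A table violated the expected schema; names the row and column."""


def _parse_float(token: str, row: int, column: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise TableFormatError(
            f"row {row}, column {column!r}: cannot parse {token!r} as a number"
        ) from None


def _fmt(value, decimals: int | None = None) -> str:
    if value is None:
        return NA
    if decimals is None:
        return repr(float(value)) if isinstance(value, float) else str(value)
    return f"{value:.{decimals}f}"


# ---------------------------------------------------------------- city table

def read_city_table(path: str | Path) -> list[CityRecord]:
    """Parse a city activity CSV into records with ok/zero/missing status.

    Strict parsing: malformed numbers and negative areas or yields raise
    :class:`TableFormatError` naming the offending row and column; an
    unrecognized province raises :class:`~strawinv.regions.UnknownProvinceError`.
    """
    records: list[CityRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing_cols = set(CITY_COLUMNS) - set(reader.fieldnames or ())
        if missing_cols:
            raise TableFormatError(f"{path}: missing required columns {sorted(missing_cols)}")
        for i, row in enumerate(reader, start=2):  # header is row 1
            province = row["province"].strip()
            region = region_of_province(province)
            city_id = row["city_id"].strip()
            year = int(_parse_float(row["year"], i, "year"))
            area_tok = row["area_1000ha"].strip()
            grain_tok = row["grain_yield_kg_ha"].strip()
            if area_tok == NA:
                records.append(CityRecord(city_id, province, region, year,
                                          None, None, status="missing"))
                continue
            area = _parse_float(area_tok, i, "area_1000ha")
            if area < 0:
                raise TableFormatError(f"row {i}, column 'area_1000ha': negative area {area}")
            if area == 0:
                records.append(CityRecord(city_id, province, region, year,
                                          0.0, None, status="zero"))
                continue
            grain = _parse_float(grain_tok, i, "grain_yield_kg_ha")
            if grain <= 0:
                raise TableFormatError(
                    f"row {i}, column 'grain_yield_kg_ha': non-positive yield {grain}")
            records.append(CityRecord(city_id, province, region, year, area, grain))
    return records


def write_city_table(records: Iterable[CityRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CITY_COLUMNS)
        for r in sorted(records, key=lambda r: (r.province, r.city_id, r.year)):
            writer.writerow([
                r.province, r.city_id, r.year,
                NA if r.status == "missing" else _fmt(r.area),
                _fmt(r.grain_yield_per_ha),
            ])


# ------------------------------------------------------------- observations

def write_observations(obs: Iterable[FieldObservation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBS_COLUMNS)
        for o in obs:
            writer.writerow([str(o.region), _fmt(o.grain_yield),
                             _fmt(o.straw_yield), _fmt(o.harvest_index)])


def read_observations(path: str | Path) -> list[FieldObservation]:
    out: list[FieldObservation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            straw = row.get("straw_yield_kg_ha", "").strip()
            hi = row.get("harvest_index", "").strip()
            out.append(FieldObservation(
                region=coerce_region(row["region"].strip()),
                grain_yield=_parse_float(row["grain_yield_kg_ha"], i, "grain_yield_kg_ha"),
                straw_yield=None if straw in ("", NA) else _parse_float(
                    straw, i, "straw_yield_kg_ha"),
                harvest_index=None if hi in ("", NA) else _parse_float(
                    hi, i, "harvest_index"),
            ))
    return out


# ------------------------------------------------------------ fitted models

def write_models(models: Iterable[StrawYieldModel], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MODEL_COLUMNS)
        for m in sorted(models, key=lambda m: str(m.region)):
            writer.writerow([str(m.region), _fmt(m.a), _fmt(m.b), m.n_obs,
                             _fmt(m.r_squared), _fmt(m.residual_sd)])


def read_models(path: str | Path) -> dict[Region, StrawYieldModel]:
    out: dict[Region, StrawYieldModel] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            region = coerce_region(row["region"].strip())
            out[region] = StrawYieldModel(
                region=region,
                a=_parse_float(row["a_kg_ha"], i, "a_kg_ha"),
                b=_parse_float(row["b_ha_kg"], i, "b_ha_kg"),
                n_obs=int(_parse_float(row["n_obs"], i, "n_obs")),
                r_squared=_parse_float(row["r_squared"], i, "r_squared"),
                residual_sd=_parse_float(row["residual_sd_kg_ha"], i, "residual_sd_kg_ha"),
            )
    return out


# ----------------------------------------------------------- disposal shares

def write_shares(shares: Mapping, path: str | Path) -> None:
    """Write a shares mapping (keys: "global", region codes or city ids)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SHARES_COLUMNS)
        for scope, s in shares.items():
            writer.writerow([str(scope), _fmt(s.p_recycle), _fmt(s.p_burn),
                             _fmt(s.p_remove)])


def read_shares(path: str | Path) -> dict[str | Region, DisposalShares]:
    out: dict[str | Region, DisposalShares] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            scope_tok = row["scope"].strip()
            scope: str | Region = scope_tok
            if scope_tok in Region.__members__:
                scope = Region(scope_tok)
            out[scope] = DisposalShares(
                _parse_float(row["p_recycle"], i, "p_recycle"),
                _parse_float(row["p_burn"], i, "p_burn"),
                _parse_float(row["p_remove"], i, "p_remove"),
            )
    return out


# ------------------------------------------------------------- five sheets

def _sorted_results(results: Iterable[InventoryResult]) -> list[InventoryResult]:
    return sorted(results, key=lambda r: (r.province, r.city_id, r.year))


def write_sheets(results: Iterable[InventoryResult], out_dir: str | Path,
                 models: Iterable[StrawYieldModel] = (),
                 ) -> dict[str, Path]:
    """Write the five-sheet output structure as CSV files under ``out_dir``.

    Returns the mapping sheet name -> written path.  Missing city-years
    carry "NA" in every numeric cell; zero districts carry 0.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = _sorted_results(results)
    paths = {name: out_dir / fname for name, fname in SHEET_FILES.items()}

    write_models(models, paths["models_building"])

    with open(paths["wheat_planting_situation"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CITY_COLUMNS + ["straw_yield_kg_ha", "total_straw_1e4t"])
        for r in results:
            missing = r.status == "missing"
            writer.writerow([
                r.province, r.city_id, r.year,
                NA if missing else _fmt(r.area),
                _fmt(r.grain_yield_per_ha) if r.grain_yield_per_ha is not None
                else (NA if missing else 0),
                _fmt(r.straw_yield_per_ha) if r.straw_yield_per_ha is not None
                else (NA if missing else 0),
                _fmt(r.total_straw),
            ])

    with open(paths["straw_field_management"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["province", "city_id", "year", "recycled_1e4t",
                         "burned_1e4t", "removed_1e4t"])
        for r in results:
            writer.writerow([r.province, r.city_id, r.year, _fmt(r.recycled),
                             _fmt(r.burned), _fmt(r.removed)])

    with open(paths["nutrient_supplies"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["province", "city_id", "year"] + [f"{n}_t" for n in NUTRIENTS])
        for r in results:
            writer.writerow([r.province, r.city_id, r.year]
                            + [_fmt(r.nutrient_supply[n]) for n in NUTRIENTS])

    with open(paths["gaseous_pollutants"], "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["province", "city_id", "year"]
                        + [f"{p.replace('.', '')}_t" for p in POLLUTANTS])
        for r in results:
            writer.writerow([r.province, r.city_id, r.year]
                            + [_fmt(r.emissions[p]) for p in POLLUTANTS])
    return paths


def write_uncertainty(summaries: Mapping[str, "object"], path: str | Path) -> None:
    rows = [{"quantity": s.quantity, "mean": s.mean, "sd": s.sd,
             "p5": s.p5, "p95": s.p95} for s in summaries.values()]
    pd.DataFrame(rows, columns=["quantity", "mean", "sd", "p5", "p95"]).to_csv(
        path, index=False, na_rep=NA)


# ---------------------------------------------------------------- config

def load_config(path: str | Path) -> dict:
    """Load a YAML key-value config file; an empty file gives an empty dict."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise TableFormatError(f"{path}: config must be a key-value mapping")
    return data
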