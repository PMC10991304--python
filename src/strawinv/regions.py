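"""Wheat-zone regions of mainland China and the province-to-region mapping.

Three ecological wheat planting zones are used throughout: northern China
(NC), central China (CC) and southern China (SC).  Each zone is defined by
an explicit province list; provinces outside the lists (e.g. Tianjin,
Inner Mongolia) have no zone and are refused rather than guessed.
"""

from __future__ import annotations

from enum import Enum


class UnknownProvinceError(KeyError):
    """Raised for a province that belongs to none of the three wheat zones."""


class Region(str, Enum):
    NC = "NC"
    CC = "CC"
    SC = "SC"

    def __str__(self) -> str:  # plain code in tables and messages
        return self.value


REGION_PROVINCES: dict[Region, tuple[str, ...]] = {
    Region.NC: ("Shanxi", "Shaanxi", "Ningxia", "Gansu", "Qinghai", "Xinjiang"),
    Region.CC: ("Beijing", "Hebei", "Henan", "Shandong"),
    Region.SC: ("Anhui", "Jiangsu", "Zhejiang", "Hubei", "Chongqing", "Sichuan",
                "Guizhou", "Yunnan"),
}

PROVINCE_TO_REGION: dict[str, Region] = {
    prov: region for region, provs in REGION_PROVINCES.items() for prov in provs
}


def region_of_province(province: str) -> Region:
    """Map a province name to its wheat zone.

    Raises
    ------
    UnknownProvinceError
        If the province is in none of the three zone lists.  There is no
        silent default: the zone assignment is a closed-world rule.
    """
    try:
        return PROVINCE_TO_REGION[province]
    except KeyError:
        raise UnknownProvinceError(
            f"province {province!r} belongs to no wheat zone (NC/CC/SC)"
        ) from None


def coerce_region(region: "Region | str") -> Region:
    """Accept either a Region or its string code; reject anything else."""
    if isinstance(region, Region):
        return region
    try:
        return Region(region)
    except ValueError:
        raise ValueError(f"unknown region code {region!r}; expected NC, CC or SC") from None
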