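"""Straw nutrient concentrations and open-burning emission factors.

Two nutrient coefficient sets ship with the package:

``table1``
    Region-specific straw N/P/K mass fractions measured in the three wheat
    zones (N 0.49-0.52 %, P 0.032-0.037 %, K 1.801-1.809 %).  This is the
    default: a straw potassium content near 1.8 % dry matter is the
    physically plausible magnitude.

``eq3text``
    A variant in which P and K are ten-fold higher (P 0.32-0.37 %,
    K 18.01-18.09 %).  Both sets circulate in the source literature for
    these coefficients; the variant is selectable so either accounting can
    be reproduced, never silently mixed.

Emission factors are grams of pollutant per kilogram of straw burned, for
PM2.5, SO2, NOx, NH3, CH4 and CO2.

Coefficients of variation (CV) drive the Monte-Carlo uncertainty module.
The source compilations do not print them, so the shipped default of 0.1
is an illustrative placeholder meant to be overridden from a CV file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .regions import Region, coerce_region

NUTRIENTS: tuple[str, ...] = ("N", "P", "K")
POLLUTANTS: tuple[str, ...] = ("PM2.5", "SO2", "NOx", "NH3", "CH4", "CO2")

#: Illustrative default CV used when no measured CV is supplied.
DEFAULT_CV = 0.1


@dataclass(frozen=True)
class NutrientCoefficients:
    """Regional straw nutrient mass fractions with per-nutrient CVs.

    ``fractions`` maps region -> {nutrient -> dimensionless mass fraction};
    ``cv`` maps nutrient -> coefficient of variation.
    """

    fractions: dict[Region, dict[str, float]]
    cv: dict[str, float] = field(default_factory=lambda: {n: DEFAULT_CV for n in NUTRIENTS})
    name: str = "custom"

    def __post_init__(self) -> None:
        for region, fracs in self.fractions.items():
            for nutrient in NUTRIENTS:
                f = fracs[nutrient]
                if not 0.0 < f < 1.0:
                    raise ValueError(
                        f"{self.name}: {nutrient} fraction for {region} is {f}; "
                        "mass fractions must lie in (0, 1)"
                    )
        for nutrient, c in self.cv.items():
            if c < 0:
                raise ValueError(f"CV for {nutrient} must be >= 0, got {c}")

    def fraction(self, region: Region | str, nutrient: str) -> float:
        return self.fractions[coerce_region(region)][nutrient]

    def with_cv(self, cv: dict[str, float]) -> "NutrientCoefficients":
        return replace(self, cv={**self.cv, **cv})


@dataclass(frozen=True)
class EmissionFactors:
    """Per-pollutant emission factors in g per kg straw burned, with CVs."""

    ef: dict[str, float]
    cv: dict[str, float] = field(default_factory=lambda: {p: DEFAULT_CV for p in POLLUTANTS})

    def __post_init__(self) -> None:
        for pollutant in POLLUTANTS:
            if self.ef[pollutant] <= 0:
                raise ValueError(f"emission factor for {pollutant} must be positive")
        for pollutant, c in self.cv.items():
            if c < 0:
                raise ValueError(f"CV for {pollutant} must be >= 0, got {c}")

    def with_cv(self, cv: dict[str, float]) -> "EmissionFactors":
        return replace(self, cv={**self.cv, **cv})


TABLE1_NUTRIENTS = NutrientCoefficients(
    fractions={
        Region.NC: {"N": 0.0049, "P": 0.00032, "K": 0.01801},
        Region.CC: {"N": 0.0052, "P": 0.00037, "K": 0.01809},
        Region.SC: {"N": 0.0051, "P": 0.00032, "K": 0.01801},
    },
    name="table1",
)

EQ3TEXT_NUTRIENTS = NutrientCoefficients(
    fractions={
        Region.NC: {"N": 0.0049, "P": 0.0032, "K": 0.1801},
        Region.CC: {"N": 0.0052, "P": 0.0037, "K": 0.1809},
        Region.SC: {"N": 0.0051, "P": 0.0032, "K": 0.1801},
    },
    name="eq3text",
)

DEFAULT_EMISSION_FACTORS = EmissionFactors(
    ef={"PM2.5": 7.6, "SO2": 0.85, "NOx": 3.3, "NH3": 0.37, "CH4": 3.4, "CO2": 1460.0},
)

_NUTRIENT_SETS = {"table1": TABLE1_NUTRIENTS, "eq3text": EQ3TEXT_NUTRIENTS}


def nutrient_set(name: str) -> NutrientCoefficients:
    """Return a shipped nutrient coefficient set by name (table1 | eq3text)."""
    try:
        return _NUTRIENT_SETS[name]
    except KeyError:
        raise ValueError(
            f"unknown nutrient coefficient set {name!r}; choose from {sorted(_NUTRIENT_SETS)}"
        ) from None
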