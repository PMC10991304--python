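"""Monte-Carlo propagation of coefficient uncertainty.

Only the coefficients are randomized: straw nutrient mass fractions and
per-pollutant emission factors are drawn from normal distributions with
mean equal to the point estimate and standard deviation mean*CV, while the
activity data (areas, yields, disposal shares) stay fixed.  The nutrient
and emission equations are re-evaluated per draw and each output quantity
is summarized by its mean, standard deviation and 5th-95th percentile
interval (linear interpolation between order statistics; conventions
differ across toolchains, so the choice is fixed here).

Negative normal draws are physically meaningless for mass fractions and
emission factors; by default they are resampled, optionally clamped to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .coefficients import EmissionFactors, NutrientCoefficients, NUTRIENTS, POLLUTANTS
from .inventory import InventoryResult, run_inventory
from .regions import Region
from .yield_model import StrawYieldModel

_1E4T_TO_T = 1e4


@dataclass(frozen=True)
class MCConfig:
    """Monte-Carlo settings: 1000 draws by default, seeded, with a
    truncation rule for negative coefficient draws (resample | clamp)."""

    n_draws: int = 1000
    seed: int = 0
    cv_overrides: Mapping[str, float] | None = None
    truncation: str = "resample"

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError(f"n_draws must be >= 2, got {self.n_draws}")
        if self.truncation not in ("resample", "clamp"):
            raise ValueError(f"unknown truncation rule {self.truncation!r}")
        if self.cv_overrides:
            bad = {k: v for k, v in self.cv_overrides.items() if v < 0}
            if bad:
                raise ValueError(f"CV overrides must be >= 0: {bad}")


@dataclass(frozen=True)
class UncertaintySummary:
    """Distribution summary for one output quantity (same units as it)."""

    quantity: str
    mean: float
    sd: float
    p5: float
    p95: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.p5 > self.p95 + 1e-12:
            raise ValueError(f"p5 {self.p5} exceeds p95 {self.p95}")


def _draw(rng: np.random.Generator, mean: float, cv: float, n: int,
          truncation: str) -> np.ndarray:
    """n draws from Normal(mean, mean*cv) with the negative-draw rule applied."""
    if cv == 0:
        return np.full(n, mean)
    out = rng.normal(mean, abs(mean) * cv, size=n)
    if truncation == "clamp":
        return np.maximum(out, 0.0)
    neg = out < 0
    while np.any(neg):
        out[neg] = rng.normal(mean, abs(mean) * cv, size=int(neg.sum()))
        neg = out < 0
    return out


def _effective_cv(base: Mapping[str, float], cfg: MCConfig, key: str) -> float:
    if cfg.cv_overrides and key in cfg.cv_overrides:
        return cfg.cv_overrides[key]
    return base.get(key, 0.0)


def draw_coefficients(coeffs: NutrientCoefficients, efs: EmissionFactors,
                      cfg: MCConfig) -> list[tuple[NutrientCoefficients, EmissionFactors]]:
    """n_draws independent coefficient sets, reproducible under the seed.

    Nutrient CVs may be overridden per nutrient (keys "N", "P", "K") and
    emission-factor CVs per pollutant via ``cfg.cv_overrides``.
    """
    rng = np.random.default_rng([cfg.seed, 40])
    n = cfg.n_draws
    frac_draws = {
        region: {nut: _draw(rng, coeffs.fractions[region][nut],
                            _effective_cv(coeffs.cv, cfg, nut), n, cfg.truncation)
                 for nut in NUTRIENTS}
        for region in coeffs.fractions
    }
    ef_draws = {p: _draw(rng, efs.ef[p], _effective_cv(efs.cv, cfg, p), n, cfg.truncation)
                for p in POLLUTANTS}
    sets = []
    for i in range(n):
        fr = {region: {nut: float(frac_draws[region][nut][i]) for nut in NUTRIENTS}
              for region in frac_draws}
        ef = {p: float(ef_draws[p][i]) for p in POLLUTANTS}
        sets.append((replace(coeffs, fractions=fr, name=f"{coeffs.name}#draw{i}"),
                     replace(efs, ef=ef)))
    return sets


def _summary(name: str, samples: np.ndarray) -> UncertaintySummary:
    if np.ptp(samples) == 0:  # degenerate (all CVs zero): collapse exactly
        v = float(samples[0])
        return UncertaintySummary(name, v, 0.0, v, v)
    p5, p95 = np.percentile(samples, [5, 95])  # linear interpolation
    return UncertaintySummary(name, float(samples.mean()),
                              float(samples.std(ddof=1)), float(p5), float(p95))


def propagate(cities, shares, coeffs: NutrientCoefficients, efs: EmissionFactors,
              cfg: MCConfig,
              models: Mapping[Region, StrawYieldModel] | None = None,
              ) -> dict[str, UncertaintySummary]:
    """Propagate coefficient uncertainty through the inventory.

    Runs the deterministic inventory once to fix the activity side (the
    recycled-plus-burned mass per region and the total burned mass), then
    re-evaluates the nutrient and emission steps per coefficient draw.
    National totals are summarized per nutrient (keys "N_t", "P_t", "K_t")
    and per pollutant (e.g. "CO2_t"), all in tons.

    Inventory errors (duplicate keys, missing models, bad shares) surface
    unchanged from the deterministic run.
    """
    base = run_inventory(cities, shares, coeffs, efs, models=models)
    return propagate_from_results(base, coeffs, efs, cfg)


def propagate_from_results(results: Iterable[InventoryResult],
                           coeffs: NutrientCoefficients, efs: EmissionFactors,
                           cfg: MCConfig) -> dict[str, UncertaintySummary]:
    """Monte-Carlo summaries from an existing deterministic inventory run."""
    results = [r for r in results if r.status != "missing"]
    mass_by_region = {region: 0.0 for region in Region}  # recycled+burned, t
    burned_t = 0.0
    for r in results:
        mass_by_region[r.region] += (r.recycled + r.burned) * _1E4T_TO_T
        burned_t += r.burned * _1E4T_TO_T

    rng = np.random.default_rng([cfg.seed, 41])
    n = cfg.n_draws
    out: dict[str, UncertaintySummary] = {}
    for nut in NUTRIENTS:
        total = np.zeros(n)
        for region, mass in mass_by_region.items():
            draws = _draw(rng, coeffs.fractions[region][nut],
                          _effective_cv(coeffs.cv, cfg, nut), n, cfg.truncation)
            total += mass * draws
        out[f"{nut}_t"] = _summary(f"{nut}_t", total)
    for p in POLLUTANTS:
        draws = _draw(rng, efs.ef[p], _effective_cv(efs.cv, cfg, p), n, cfg.truncation)
        out[f"{p}_t"] = _summary(f"{p}_t", burned_t * draws * 1e-3)
    return out


@dataclass(frozen=True)
class NormalityDiagnostic:
    """QQ diagnostic: correlation of sample vs theoretical normal quantiles."""

    correlation: float
    n: int
    threshold: float
    passed: bool


def normality_check(samples, threshold: float = 0.99) -> NormalityDiagnostic:
    """Correlation-based QQ normality check.

    Pairs the ordered samples with standard-normal quantiles and reports
    the correlation coefficient; ``passed`` is True when it exceeds the
    threshold (default 0.99).  Needs at least 10 samples with non-zero
    variance.
    """
    x = np.asarray(list(samples), dtype=float)
    if x.size < 10:
        raise ValueError(f"normality check needs >= 10 samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normality check rejected: samples have zero variance")
    (_, _), (_, _, r) = stats.probplot(x, dist="norm")
    return NormalityDiagnostic(correlation=float(r), n=int(x.size),
                               threshold=threshold, passed=bool(r > threshold))
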