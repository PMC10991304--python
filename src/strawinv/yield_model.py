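"""Regional empirical exponential grain-to-straw yield model.

Straw yield per hectare is modelled as an exponential function of grain
yield, ``straw = a * exp(b * grain)``, fitted independently per wheat zone.
The derived harvest index ``HI(g) = g / (g + straw(g))`` rises at low
yields and flattens or declines as grain yield increases, which a constant
straw-to-grain ratio cannot capture.  ``compare_ratio_schemes`` quantifies
how constant-ratio schemes deviate from the fitted curve.

Residuals are minimized in straw space (raw kg ha^-1), not log space, so
high-yield observations are not down-weighted; an ordinary linear
regression of log(straw) on grain supplies the starting values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .regions import Region, coerce_region

#: Consistency tolerance between a stated harvest index and one recomputed
#: from grain and straw yields.
HI_TOLERANCE = 1e-6

#: Convergence tolerance on the parameter step and the iteration cap of the
#: nonlinear least-squares fit.
FIT_XTOL = 1e-10
FIT_MAXFEV = 10000


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the initialization estimates."""

    def __init__(self, message: str, a0: float, b0: float):
        super().__init__(message)
        self.a0 = a0
        self.b0 = b0


@dataclass(frozen=True)
class FieldObservation:
    """One field-experiment record.

    At least one of ``straw_yield`` (kg ha^-1) and ``harvest_index``
    (grain / (grain + straw), dimensionless) must be present; when both are
    given they must agree to within ``HI_TOLERANCE``.
    """

    region: Region
    grain_yield: float
    straw_yield: float | None = None
    harvest_index: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", coerce_region(self.region))
        if not (self.grain_yield > 0 and math.isfinite(self.grain_yield)):
            raise ValueError(f"grain_yield must be finite and positive, got {self.grain_yield}")
        if self.straw_yield is None and self.harvest_index is None:
            raise ValueError("need at least one of straw_yield or harvest_index")
        if self.straw_yield is not None and self.straw_yield <= 0:
            raise ValueError(f"straw_yield must be positive, got {self.straw_yield}")
        if self.harvest_index is not None and not 0.0 < self.harvest_index < 1.0:
            raise ValueError(f"harvest_index must lie in (0, 1), got {self.harvest_index}")
        if self.straw_yield is not None and self.harvest_index is not None:
            implied = self.grain_yield / (self.grain_yield + self.straw_yield)
            if abs(self.harvest_index - implied) > HI_TOLERANCE:
                raise ValueError(
                    f"inconsistent record: stated HI {self.harvest_index:.6f} vs "
                    f"{implied:.6f} implied by grain and straw yields"
                )


@dataclass(frozen=True)
class StrawYieldModel:
    """Fitted exponential model straw = a * exp(b * grain) for one region.

    ``a`` is the straw yield at zero grain yield (kg ha^-1); ``b`` (ha kg^-1)
    controls how fast straw grows with grain yield.  ``r_squared`` and
    ``residual_sd`` are computed in straw space.
    """

    region: Region
    a: float
    b: float
    n_obs: int
    r_squared: float
    residual_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", coerce_region(self.region))
        if self.a <= 0:
            raise ValueError(f"scale parameter a must be positive, got {self.a}")
        if self.n_obs < 3:
            raise ValueError(f"a fitted model needs n_obs >= 3, got {self.n_obs}")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def normalize_observation(obs: FieldObservation) -> FieldObservation:
    """Fill whichever of straw yield / harvest index is absent.

    Uses straw = grain * (1 - HI) / HI and HI = grain / (grain + straw).
    Idempotent: a complete record is returned unchanged.
    """
    if obs.straw_yield is not None and obs.harvest_index is not None:
        return obs
    if obs.straw_yield is None:
        hi = obs.harvest_index
        straw = obs.grain_yield * (1.0 - hi) / hi
        return replace(obs, straw_yield=straw)
    hi = obs.grain_yield / (obs.grain_yield + obs.straw_yield)
    return replace(obs, harvest_index=hi)


def _exp_model(grain: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(b * grain)


def fit_straw_model(observations: Iterable[FieldObservation],
                    region: Region | str) -> StrawYieldModel:
    """Least-squares fit of straw = a * exp(b * grain) on one region's data.

    Observations from other regions are ignored so a mixed table can be
    passed directly.  Requires at least 3 usable records.

    Raises
    ------
    ValueError
        Fewer than 3 usable observations.
    FitError
        The optimizer failed to converge; the exception carries the
        log-linear initialization estimates ``a0`` and ``b0``.
    """
    region = coerce_region(region)
    complete = [normalize_observation(o) for o in observations if o.region == region]
    grain = np.array([o.grain_yield for o in complete], dtype=float)
    straw = np.array([o.straw_yield for o in complete], dtype=float)
    usable = np.isfinite(grain) & np.isfinite(straw) & (grain > 0) & (straw > 0)
    grain, straw = grain[usable], straw[usable]
    if grain.size < 3:
        raise ValueError(
            f"need >= 3 usable observations to fit region {region}, got {grain.size}"
        )

    # log-linear OLS initialization: log(straw) = log(a) + b * grain
    coef = np.polynomial.polynomial.polyfit(grain, np.log(straw), 1)
    a0, b0 = float(np.exp(coef[0])), float(coef[1])

    try:
        popt, _ = curve_fit(_exp_model, grain, straw, p0=(a0, b0),
                            xtol=FIT_XTOL, maxfev=FIT_MAXFEV)
    except RuntimeError as exc:
        raise FitError(f"exponential fit for region {region} did not converge: {exc}",
                       a0=a0, b0=b0) from exc
    a_hat, b_hat = float(popt[0]), float(popt[1])

    residuals = straw - _exp_model(grain, a_hat, b_hat)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((straw - straw.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    dof = max(grain.size - 2, 1)
    return StrawYieldModel(
        region=region,
        a=a_hat,
        b=b_hat,
        n_obs=int(grain.size),
        r_squared=min(max(r2, 0.0), 1.0),
        residual_sd=math.sqrt(ss_res / dof),
    )


def predict_straw_yield(model: StrawYieldModel, grain_yield: float) -> float:
    """Straw yield (kg ha^-1) predicted at a grain yield (kg ha^-1)."""
    if np.any(np.asarray(grain_yield) < 0):
        raise ValueError("grain_yield must be >= 0")
    return model.a * np.exp(model.b * grain_yield)


def harvest_index_curve(model: StrawYieldModel, grain_yield: float) -> float:
    """Model-implied harvest index grain / (grain + straw(grain)); in (0, 1)."""
    g = np.asarray(grain_yield, dtype=float)
    if np.any(g <= 0):
        raise ValueError("grain_yield must be positive for a harvest index")
    return g / (g + predict_straw_yield(model, g))


def compare_ratio_schemes(model: StrawYieldModel,
                          constant_ratios: Mapping[str, float],
                          grain_grid: Sequence[float]) -> pd.DataFrame:
    """Contrast the exponential model with constant straw-to-grain ratios.

    For each grid point and each scheme the table holds the model straw
    yield, the scheme straw yield (ratio * grain), their signed difference
    (scheme - model) and the scheme/model ratio.  Per-scheme summary rows
    (grain = NaN) carry the mean relative deviation
    mean((scheme - model) / model) and its sign, which flags systematic
    under- or over-estimation relative to the fitted curve.
    """
    if len(grain_grid) == 0:
        raise ValueError("grain_grid must be non-empty")
    for scheme, ratio in constant_ratios.items():
        if ratio <= 0:
            raise ValueError(f"scheme {scheme!r} has non-positive ratio {ratio}")

    grid = np.asarray(grain_grid, dtype=float)
    model_straw = predict_straw_yield(model, grid)
    rows = []
    for scheme, ratio in constant_ratios.items():
        scheme_straw = ratio * grid
        diff = scheme_straw - model_straw
        for g, ms, ss, d in zip(grid, model_straw, scheme_straw, diff):
            rows.append({"scheme": scheme, "grain_yield_kg_ha": g,
                         "model_straw_kg_ha": ms, "scheme_straw_kg_ha": ss,
                         "difference_kg_ha": d, "scheme_over_model": ss / ms})
        rel = diff / model_straw
        mean_rel = float(rel.mean())
        rows.append({"scheme": scheme, "grain_yield_kg_ha": np.nan,
                     "model_straw_kg_ha": np.nan, "scheme_straw_kg_ha": np.nan,
                     "difference_kg_ha": np.nan, "scheme_over_model": np.nan,
                     "mean_relative_deviation": mean_rel,
                     "deviation_sign": int(np.sign(mean_rel))})
    columns = ["scheme", "grain_yield_kg_ha", "model_straw_kg_ha",
               "scheme_straw_kg_ha", "difference_kg_ha", "scheme_over_model",
               "mean_relative_deviation", "deviation_sign"]
    return pd.DataFrame(rows, columns=columns)
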