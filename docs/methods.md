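# Methods

## Straw-yield model

Per wheat zone (NC, CC, SC — defined by explicit province lists; any other
province is refused, never defaulted) we model straw yield per hectare as
an exponential function of grain yield, S(G) = a·exp(b·G), with a in
kg ha⁻¹ (straw at zero grain yield) and b in ha kg⁻¹. The exponential form
encodes the agronomic observation that the harvest index
HI(G) = G/(G + S(G)) stabilises or declines at high yields: with b > 0 the
implied HI curve rises, peaks near G = where dHI/dG = 0, and decreases
thereafter, whereas a constant straw-to-grain ratio forces HI constant.
The functional form sits behind a small interface (`fit_straw_model` /
`predict_straw_yield`), so an alternative (e.g. power-law) could be
slotted in for sensitivity analysis without touching the accounting chain.

**Fitting.** Nonlinear least squares in straw space (scipy `curve_fit`,
parameter tolerance 1e-10, 10 000 evaluation cap), initialised by ordinary
linear regression of log S on G. Residuals are minimized on raw straw
yields, not logs, so high-yield observations are not down-weighted; the
choice matters because the policy-relevant totals are dominated by
high-yield cities. R² and the residual SD are reported in straw space.
Non-convergence raises an error carrying the log-linear starting values.
Records may state straw yield, harvest index, or both; both-present
records inconsistent beyond |ΔHI| = 1e-6 are rejected rather than
averaged. Fits are strictly per-region; there is no pooled national fit,
since the regional yield-partitioning differences are the point of the
zonal model.

## Accounting chain and units

The chain is linear throughout: TY = S(G)·Area, AS_d = TY·PS_d,
TNS_j = (AS_recycle + AS_burn)·NC_j, GP_k = AS_burn·EC_k. Unit
conventions follow the published sheet layout and are centralized in
`inventory.py`: area in 1000 ha, per-ha yields in kg ha⁻¹ (so
kg ha⁻¹ × 1000 ha = 1 t), straw amounts in 10⁴ t, nutrients and emissions
in t (g kg⁻¹ ≡ kg t⁻¹). Values are written at full precision; rounding is
the presentation layer's concern.

**Coefficients.** Two nutrient sets ship: `table1` (default; N 0.49/0.52/
0.51 %, P 0.032/0.037/0.032 %, K 1.801/1.809/1.801 % for NC/CC/SC) and
`eq3text`, identical except P and K are ten-fold higher. Both appear in
the source literature for these coefficients; 1.8 % is the physically
plausible straw-K magnitude, hence the default, but the variant is
selectable because some published headline numbers are only reproducible
with it. They are never mixed. Emission factors: PM2.5 7.6, SO2 0.85,
NOx 3.3, NH3 0.37, CH4 3.4, CO2 1460 g kg⁻¹.

**Missing data.** "NA" means no statistics: the record propagates as
missing through every step and is excluded from regional/national sums.
Acreage 0 means a wheat-free municipal district: all outputs are numeric
zeros and are included (harmlessly) in sums. Duplicate (city, year) keys
are rejected. Disposal shares resolve with precedence city > region >
global.

## Monte-Carlo uncertainty

Only coefficients are randomized; activity data (areas, yields, disposal
shares) stay fixed. Each nutrient fraction and emission factor is drawn
from Normal(mean, mean·CV), 1000 draws by default, and the (linear)
nutrient and emission steps are re-evaluated per draw; outputs are
summarized by mean, SD and the 5th–95th percentile interval, computed by
linear interpolation between order statistics (conventions differ between
toolchains, so the convention is fixed and documented). Negative draws are
physically meaningless for mass fractions and emission factors and are
resampled by default (clamping to zero is selectable); at the default
CV = 0.1 truncation is a ~1e-23 tail event, so it does not bias the
moments. Because the chain is linear in the coefficients, analytic means
and SDs exist in closed form, and the test suite holds the MC moments to
them within three standard errors; CV = 0 collapses every percentile to
the deterministic value exactly (constant draw vectors short-circuit the
summary to avoid accumulating float-summation error). A QQ-correlation
normality diagnostic (threshold 0.99) is provided for checking draw and
output distributions. The source compilations for the coefficients do not
publish their CVs, so the shipped default CV of 0.1 is an illustrative
placeholder meant to be overridden from a CV file; uncertainty in the
fitted (a, b) is deliberately not propagated — the accounting treats the
fitted curve as fixed, matching the scope of coefficient-only uncertainty.

## Synthetic-data generator

The generator emulates the study's inputs so the pipeline is testable
without the non-redistributable source tables. Field observations: grain
yields uniform on 1000–9000 kg ha⁻¹ (a truncated normal is selectable),
straw = a·exp(b·G)·ε with ε log-normal, mean 1 and CV `noise_cv`
(positive by construction, matching the positivity and heteroscedasticity
of real straw yields); per-zone sample sizes default to the assembled
corpus sizes 1728/2209/1184. The true (a, b) per zone — (2800, 1.3e-4),
(3200, 1.2e-4), (3000, 1.15e-4) — and the noise CV of 0.1 are this
package's choices: no fitted coefficients or variance structure are
published, so these were picked once to give realistic straw-to-grain
ratios (~1.0–1.4 over the grain range, highest in CC) and are not tuned.
Activity tables: 12 cities per zone × 2011–2015, acreage uniform on
5–600 × 1000 ha, with 5 % of city-years emitted as "NA" and 5 % as
zero-acreage districts so both propagation rules are exercised. Disposal
shares are Dirichlet-sampled (shares are a configurable input, never
hard-coded; the analysis scripts use a global 0.6/0.2/0.2
recycle/burn/remove split). All generators are pure functions of the seed
with independent per-purpose streams, so identical configurations give
byte-identical tables regardless of call order.

What the generator does *not* emulate: spatial correlation between
neighbouring cities, year-over-year trends in acreage or yield, reporting
artifacts in official statistics, and between-study heterogeneity in the
field observations. Passing tests therefore demonstrate correctness of
the estimators and accounting on data satisfying the model's assumptions,
not fidelity of any specific published total.

## Problem sizes

The default test and analysis runs use corpus-sized observation tables
(5121 rows), 180 synthetic city-years and 1000 Monte-Carlo draws; the
percentile-convergence check uses 100 000 draws of a single-coefficient
quantity, where (p95−p5)/σ must approach 2·z₀.₉₅ = 3.2898. Parameter
recovery is verified noiselessly to a relative 1e-6 and, under CV-10 %
noise with n = 500, to better than 10 % relative error on b across 50
seeds.

## Known limitations

- Three broad zones only; finer ecological planting zones would need their
  own fits (the interface supports any region keying, the shipped lists do
  not).
- The exponential model is fitted to yields within 1000–9000 kg ha⁻¹;
  extrapolation beyond the observed range inherits exponential growth.
- Nutrient supply counts recycled *and* burned straw identically; nutrient
  losses during combustion (especially N volatilisation) are not modelled,
  matching the accounting being reproduced.
- Disposal shares are treated as known inputs; their sampling uncertainty
  is off by default (a hook exists in the MC layer's design but only
  coefficients are randomized).
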