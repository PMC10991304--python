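# strawinv — bottom-up wheat-straw inventory for China's wheat zones

`strawinv` estimates city-level wheat straw resources, the N/P/K nutrients
returned to cropland by straw recycling and burning, and the gaseous
pollutants (PM2.5, SO2, NOx, NH3, CH4, CO2) emitted by open straw burning,
across mainland China's three ecological wheat zones — northern (NC),
central (CC) and southern China (SC). It is written for agro-environmental
researchers and policy analysts who need a reproducible, testable version
of this accounting rather than a spreadsheet.

## The model

Most straw inventories scale grain statistics by a constant straw-to-grain
ratio. Field data show the ratio is not constant: the harvest index
HI = G / (G + S) (grain G over total above-ground biomass) stabilises or
declines as grain yield rises, so straw grows faster than grain at high
yields. `strawinv` therefore fits, per wheat zone, the exponential model

    S(G) = a · exp(b · G)        [kg ha⁻¹]

by nonlinear least squares in straw space (log-linear regression only
initialises the fit). The accounting chain per city *i* and year is

    TYᵢ   = S(Gᵢ) · Areaᵢ                    total straw        [10⁴ t]
    ASᵢ,d = TYᵢ · PSd      d ∈ {recycle, burn, remove}          [10⁴ t]
    TNSᵢ,j = (ASᵢ,recycle + ASᵢ,burn) · NCᵢ,j   j ∈ {N, P, K}   [t]
    GPᵢ,k = ASᵢ,burn · ECk    k ∈ {PM2.5, SO2, NOx, NH3, CH4, CO2}  [t]

with zone-specific straw nutrient mass fractions NC (N ≈ 0.5 %, P ≈
0.032–0.037 %, K ≈ 1.8 %; a ten-fold-higher P/K variant is selectable as
`eq3text`) and emission factors EC in g per kg burned (7.6, 0.85, 3.3,
0.37, 3.4, 1460). Coefficient uncertainty is propagated by Monte-Carlo
(normal draws, mean·CV standard deviation, 1000 repetitions) and reported
as 5th–95th percentiles. "NA" city-years propagate as missing and are
excluded from aggregates; zero-acreage districts stay numeric zeros.

Because the underlying observation tables and the national statistics
extracts are not redistributable, the package ships a synthetic-data
module that generates study-shaped inputs (exponential straw-grain
structure with multiplicative log-normal noise, per-zone sample sizes
1728/2209/1184, activity tables with "NA"/zero rows, Dirichlet disposal
shares), so every stage is testable offline.

## Worked example

The numbered scripts under `analysis/` run the whole study end to end:

```sh
python analysis/01_simulate.py --seed 1     # synthetic inputs -> results/data/
python analysis/02_fit_yield_models.py      # fit per-zone exponential models
python analysis/03_run_inventory.py         # Eq. chain -> five sheets + totals
python analysis/04_uncertainty.py --seed 1  # 1000-draw Monte-Carlo
python analysis/05_compare_ratio_schemes.py # vs constant-ratio schemes
```

With seed 1 the fitting step prints

```
NC: a =   2815.7 kg/ha  b = 1.292e-04 ha/kg  R2 = 0.8806  n = 1728  (b recovery error 0.61%)
CC: a =   3182.6 kg/ha  b = 1.210e-04 ha/kg  R2 = 0.8698  n = 2209  (b recovery error 0.81%)
SC: a =   3012.0 kg/ha  b = 1.138e-04 ha/kg  R2 = 0.8592  n = 1184  (b recovery error 1.02%)
```

— the fitted (a, b) recover the generating parameters to ~1 % under 10 %
multiplicative noise. The inventory step then reports the synthetic
national totals, e.g.

```
total straw      26979.1 x 1e4 t (burned 5395.8)
nutrient returns N 1094947 t, P 73020 t, K 3893475 t
burning CO2 7.878e+07 t, CH4 1.835e+05 t, PM2.5 4.101e+05 t
```

and the Monte-Carlo step brackets each total, e.g.
`CO2_t: mean 7.883e+07 t  5th-95th [6.549e+07, 9.193e+07]` — a ±17 % band
driven by the 10 % coefficient CVs. The comparison step shows every
constant-ratio scheme (0.95–1.15) *underestimating* straw relative to the
exponential curve by 3–27 % on average over the 1000–9000 kg ha⁻¹ grid.

The same pipeline is scriptable via the `strawinv` CLI
(`simulate | fit | inventory | uncertainty | compare`, every subcommand
seeded and byte-deterministic).

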