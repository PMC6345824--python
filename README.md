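# bloomphen

Phytoplankton bloom **phenology metrics** — the timings of growth-period
initiation, peak, termination, and the duration in between — estimated from
surface and depth-resolved chlorophyll-a (Chl-a) time series, together with
the water-column diagnostics used to judge whether a satellite's surface view
is representative of the full water column.

It is written for biological oceanographers who want to compare phenology
seen by an ocean-colour satellite (which senses only the first optical depth)
against phenology from a biogeochemical profiling float (which sees the whole
upper water column, including the Subsurface Chlorophyll Maximum that
satellites miss). Because year-long co-located float/satellite records are
rare, the package ships a synthetic-data generator that emulates a coupled
annual cycle with known (planted) timings, so every stage of the pipeline is
testable offline.

## The method

Given a complete, regularly spaced series of 5-day composite Chl-a values
*C₁ … Cₙ*:

1. **Threshold** — `T = median(C) × 1.05` (the series median plus 5 %).
2. **Anomalies and cumulative sums** — `aₖ = Cₖ − T`,  `Sₖ = Σ_{j≤k} aⱼ`.
   The cumulative sum *S* rises while Chl-a sits above the threshold and
   falls while below, so the gradient of *S* (identically the anomaly
   series) changes sign exactly at the threshold crossings.
3. **Initiation** — the first composite of the above-threshold excursion
   containing the series maximum (the growth peak).
4. **Termination** — the first composite after the peak where the gradient
   turns negative.
5. **Duration** — number of 5-day periods between initiation and termination.

Three input series are built and detected independently, each with its own
threshold:

| series      | definition                                                    |
|-------------|---------------------------------------------------------------|
| `sat_surf`  | satellite pixel matchups (nearest pixel, 3-pixel longitudinal window mean), 5-day composites |
| `argo_surf` | per-profile Chl-a averaged over the first optical depth `Zeu/4.6` |
| `argo_int`  | per-profile Chl-a integrated from the surface to the euphotic depth `Zeu` (mg m⁻²) |

Float profiles are first corrected (deep dark-offset removal, the
community factor-of-2 fluorometer calibration, a mixed-layer
non-photochemical-quenching fill, the ×1.06 oxygen-optode gain), then the
water-column diagnostics are derived: euphotic depth (1 % PAR level on
log-interpolated PAR), mixed-layer depth (density threshold +0.03 kg m⁻³
relative to 10 m), Brunt–Väisälä frequency `N² = (g/ρ̄)(∂ρ/∂z)`, and
depth-band Chl-a integrals.

## Worked example

Run the end-to-end pipeline on the built-in synthetic year (a northern Red
Sea-like annual cycle: winter deep-mixing bloom, stratified-season SCM,
multiplicative observation noise, 10 % missing satellite composites):

```bash
bloomphen run --seed 11 --out out/
```

prints

```
argo_surf: initiation=2015-11-04 peak=2016-01-18 termination=2016-04-17 duration=33 periods
argo_int: initiation=2015-11-04 peak=2016-02-07 termination=2016-04-07 duration=31 periods
sat_surf: initiation=2015-11-04 peak=2016-02-07 termination=2016-04-07 duration=31 periods
```

All three platforms detect initiation in the same 5-day period (early
November, when the mixed layer starts to deepen and erode the SCM) and
terminate in early-to-mid April when stratification resumes — a ~5-month
main growth period. The float surface series here terminates two composites
after the satellite; that bias comes from the quenching fill, which
extrapolates the mixed-layer maximum upward and overshoots on noisy deep
mixed layers (see `docs/methods.md`). `out/report.json` carries the full
comparison, e.g. the signed timing differences in 5-day periods and the
Spearman rank correlation between the two surface series
(`rho = 0.695, n = 73` for this seed — the flat oligotrophic background
makes within-season ranks noise-dominated on synthetic data).

Other entry points: `bloomphen simulate` (write fixture CSV/NetCDF profiles
and matchups), `bloomphen derive` (per-profile scalars), `bloomphen
phenology` (detect on one series CSV), `bloomphen report` (re-render a saved
report). Everything is also available as a library:

```python
from bloomphen import SyntheticScenario, RunConfig, run
report = run(RunConfig(scenario=SyntheticScenario(seed=11)))
report.metrics["sat_surf"].initiation_date
```

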