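# Methods

This note documents the models, conventions and numerical choices behind
`bloomphen`, and what the synthetic tests do and do not demonstrate about
real observations.

## The phenology detector

The detector operates on a complete (gap-free) series of 5-day composite
Chl-a values. The threshold criterion is the series median **times** 1.05;
the alternative reading "median plus an absolute 0.05" is available as
`threshold_rule="median_plus_0.05"` but is not the default, because the
relative form is the convention of the threshold-criterion literature and is
what makes the detector scale-invariant (multiplying the series by any
λ > 0 rescales the threshold identically and leaves all detected indices
unchanged — asserted as a property test).

Anomalies are the series minus the threshold; their cumulative sum rises
while the series sits above the threshold, so the gradient of the cumulative
sum — identically the anomaly series, by telescoping — changes sign exactly
at threshold crossings. The detector is therefore equivalent to a direct
threshold-crossing scan, and the test suite keeps an independent brute-force
scan and asserts index-and-flag equality on 500 random series.

Conventions the detector needs but that a method description rarely states:

* **Zero anomalies** are neither a rise nor a fall; strict inequalities are
  used on both sides, so a composite exactly at threshold defers to the next
  non-zero one.
* **Ties at the maximum** resolve to the first occurrence, which gives the
  earliest admissible termination search window and is deterministic.
* **Series already above threshold at the first composite** report
  initiation = 0 with an `initiation_at_start` flag. An annual window should
  be anchored in the low-Chl season so this case does not arise.
* **Multiple above-threshold excursions** set `multiple_growth_periods`; the
  reported metrics describe the excursion containing the global peak (the
  *main* growth period). This also resolves the corner case where an early
  brief excursion precedes the main one: initiation belongs to the peak's
  excursion, keeping `initiation ≤ peak < termination`.
* The year is treated as **linear, not circular**: no wrap-around search.
* Dates are reported as the start date of the detected composite.

## Profile processing

Corrections are applied in a fixed order — dark offset, fluorescence
calibration, quenching fill — with every step and its parameters recorded in
a provenance log, and are applied exactly once per derivation.

* **Dark offset**: median Chl-a in the 900–1000 m window (near the float's
  parking depth, where phytoplankton are absent) is subtracted everywhere
  and the result clipped at zero; the clip count is logged. Fewer than three
  deep samples skips the correction with a warning rather than guessing.
* **Calibration**: fluorometric Chl-a divided by a sensor bias factor
  (default 2 for WET Labs ECO-type sensors when enabled; the synthetic
  generator emits already-calibrated concentrations, so the pipeline default
  is off).
* **Quenching (NPQ) fill**: daytime fluorescence is depressed near the
  surface. For well-mixed layers the profile should be homogeneous within
  the mixed layer, so values above the depth of the mixed-layer Chl-a
  maximum are replaced by that maximum. The correction never decreases a
  value and is switchable off. Two known artifacts, both visible in the
  synthetic experiments: (1) on noisy profiles the fill inherits the
  *maximum* of N mixed-layer samples, an upward bias that grows with
  mixed-layer depth — in the default noisy scenario this delays the detected
  float-surface termination by one to two composites relative to the
  satellite; (2) if an SCM sits inside a deep mixed layer the fill
  extrapolates the SCM peak to the surface. Neither artifact is "fixed"
  here because the rule is the method; they are reported through the
  pipeline's timing-difference table.
* **Oxygen**: optode gain factor (default 1.06) applied multiplicatively.

Derived scalars:

* **Euphotic depth** is where PAR first falls to 1 % of its surface
  reference, taken as the *shallowest valid PAR sample* since floats rarely
  sample at 0 m. The crossing is located on log(PAR) (light decays
  exponentially between samples); linear interpolation on raw PAR would bias
  the depth shallow. A profile that never reaches 1 % raises
  `zeu_below_profile`.
* **First optical depth** = Zeu/4.6 exactly, the layer an ocean-colour
  sensor effectively sees.
* **Surface Chl-a** is the depth-weighted (trapezoidal) mean over
  [shallowest sample, first optical depth], with the boundary value linearly
  interpolated. A plain sample mean is the other defensible reading; the
  trapezoidal form was chosen so the statistic is invariant under grid
  refinement, and is recorded here as a package decision.
* **Integrals** use the trapezoidal rule with interpolated boundary values;
  above the shallowest sample the profile is extended as a constant. The
  integral is additive over adjacent intervals to machine precision on a
  shared grid.
* **Mixed-layer depth**: density threshold +0.03 kg m⁻³ relative to the
  density interpolated at 10 m, crossing linearly interpolated. When the
  threshold is never crossed the profile bottom is returned with
  `mld_at_profile_bottom` instead of an absent value, so deep winter mixing
  does not punch holes in the time series.
* **Buoyancy frequency**: N² = (g/ρ̄)·(Δρ/Δz) on adjacent sample pairs at
  mid-depths, g = 9.81 m s⁻²; negative values are kept and flagged.
* **Density** is taken from the profile when present (a sigma-convention
  vector is detected by magnitude and offset by 1000 kg m⁻³); otherwise it
  is computed from T/S with the one-atmosphere EOS-80 polynomial (validated
  against the published check value ρ(S=35, T=5, p=0) = 1027.675 kg m⁻³).
  Tests feed density directly, so this choice is not load-bearing.
* Operations are defined on depth in metres; pressure is converted at ingest
  with a monotone ~1 dbar ≈ 1 m map.

## Time-series construction

Composites are 5-day bins anchored at the first observation date, half-open
(`[origin + 5k, origin + 5k+5)`: a sample exactly on a boundary belongs to
the later bin), indexed contiguously with empty bins as masked gaps. Gap
filling is piecewise-linear interpolation between the nearest observed
neighbours — the 1-D reduction of least-squares in-painting with the linear
operator — with constant extension at the ends rather than extrapolation, to
avoid manufacturing trends; it is idempotent and filled values are clipped
at zero and flagged in the gap mask.

Satellite matchups take the nearest grid pixel by coordinate (ties break
toward the west/south pixel, deterministically) and average a 3-pixel window
in longitude at fixed latitude; a window with no valid pixels becomes a gap.
The Spearman rank correlation between series is computed only over bins
observed (not gap-filled) in both, with average ranks on ties and a
two-sided p-value.

## The synthetic generator

The generator's defaults are the study conditions: a 365-day year starting
30 September sampled daily on a 1-m grid to 1000 m, a winter deep-mixing
bloom window on days 35–190 (early November to early April, aligned to
composite boundaries — the method's native 5-day resolution), surface Chl-a
0.1 mg m⁻³ stepping to 0.5 mg m⁻³ in the bloom, an SCM at 75 m (deepening to
~100 m by late summer, σ = 15 m) with amplitude up to 0.35 mg m⁻³ in spring
and zero during the bloom (erosion by mixing), a mixed layer cycling between
25 m and 150 m with a 0.5 kg m⁻³ pycnocline smoothed over 10 m, PAR decaying
exponentially with Kd = 0.05 m⁻¹ from a fixed surface value, a fluorometer
dark offset of 0.02 mg m⁻³, lognormal multiplicative noise with CV = 0.1,
10 % missing satellite windows, and a daytime quenching depression of 0.3
above 15 m. Noise/gap levels are field-plausible conventions (the kind of
scatter a merged ocean-colour product and a single fluorometer show), not
fitted values. Lognormal noise keeps concentrations positive; the plateau
tapers linearly to zero over 10 m below the mixed layer so the trapezoidal
integrals do not amplify a step discontinuity.

One physical-consistency constraint is built into the default schedules: the
SCM amplitude stays zero until the post-bloom mixed layer has shoaled back
above the SCM depth, because an SCM cannot persist inside an actively mixing
layer — and, operationally, letting the two overlap makes the quenching fill
extrapolate the SCM to the surface and systematically delay the detected
surface termination.

The planted truth record carries the bloom-edge days, the MLD/Zeu/SCM-depth
schedules and the noise-free first-optical-depth surface mean used as the
satellite truth (the satellite sees no fluorometer dark offset or quenching,
which are instrument artifacts of the float channel).

What the generator does **not** emulate: advection and eddies (the float is
quasi-Lagrangian here), cloud-correlated gap structure (gaps are
independent), photoacclimation (Chl-to-biomass variability), any bio-optics
beyond exponential PAR, and Chl-dependent light attenuation. Passing the
synthetic tests therefore demonstrates the correctness of the *computations*
under known conditions, not the field accuracy of the corrections on real
sensors.

## Scales and problem sizes

The recovery and agreement experiments use one synthetic year of 365 daily
profiles × 1000 depths (73 composites); the agreement ensemble uses 100
seeded realisations and the detector-oracle comparison 500 random series.
These sizes make the full suite and the acceptance script each run in well
under a minute apiece on one CPU while leaving the statistics stable to the
seed.

## Known limitations

* The quenching fill is a stand-in for empirical shallow-mixing formulations
  whose full parameterisation is sensor-specific; it is deliberately simple,
  documented, and switchable.
* The noisy-ensemble Spearman correlation between the two surface series
  (~0.70–0.74) is lower than on typical real records because the synthetic
  background season is flat: within-season ranks are then pure noise. The
  statistic is reported, not asserted against a target.
* The detector reports a single main growth period; secondary excursions are
  flagged, not characterised.
* No operational Argo quality-control flag handling; inputs are assumed
  already screened to the level of the fixture formats.
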