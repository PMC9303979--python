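# Methods

This note records the scientific and numerical choices behind `biopump`: the
diagnostics, the first-order steady-state model, and the synthetic ensemble
the tests run against.

## Diagnostics

**AOU and sign convention.** Apparent oxygen utilization is computed as
`AOU = O2_sat(thetao, so) − o2`, positive where oxygen has been consumed, so
that the derived carbon storage is positive in a respiring interior. The
saturation concentration uses the Garcia–Gordon (1992) polynomial in scaled
temperature, by default the coefficient set fitted to the Benson–Krause data
(the set in common oceanographic use; the "combined fit" set is selectable).
The fit is gravimetric (µmol kg⁻¹); conversion to the volumetric `o2` unit
uses a fixed reference density ρ₀ = 1025 kg m⁻³. A constant ρ₀ keeps AOU
exactly linear in `o2`, which all downstream diagnostics rely on; the ~2%
spatial variation of true in-situ density is far below the inter-model spread
these diagnostics are meant to resolve. CMIP6 `thetao` is already potential
temperature and is passed to the fit directly.

**C_soft.** The sequestered-carbon inventory is the volume integral
`C_soft = Σ AOU · (117/170) · 12.01 g mol⁻¹ · dV`, reported in Pg C. It is
an *inventory*, not a mean concentration: dividing by the total ocean volume
would produce g C m⁻³, not petagrams, and the quantity of interest (hundreds
to ~1700 Pg C) is the inventory. The mean-concentration variant is available
via `compute_csoft(..., per_volume=True)`. Masked (land) cells contribute
zero volume.

**Flux extraction.** `expc` is annually averaged first, then linearly
interpolated in depth (z, not log z) to 100 m and 1000 m; a model level that
coincides with the target depth is passed through exactly. Columns whose
deepest valid level lies above the target are masked and excluded. Global
integrals multiply by `areacello`, by the molar mass of carbon, and by the
seconds per year *of the run's calendar* (360-day vs 365-day accounting
differs by 1.4%, larger than some of the trends of interest).

**Transfer efficiency.** Globally, `TE = 100 · F1000 / EP100`. Per-column
maps use the same ratio where the 100 m flux exceeds a floor
(default 10⁻¹² mol m⁻² s⁻¹, configurable); the floor only prevents ratio
blow-ups where export is effectively zero, and with it disabled the global TE
equals the flux-weighted aggregation of the map exactly.

**Stratification index.** Area-weighted global mean of σ₀(200 m) − σ₀(top
level). "Surface" is the top model level (no extrapolation to 0 m); 200 m
uses the same linear interpolation as the fluxes. σ₀ is the surface-referenced
potential density anomaly evaluated with the classic one-atmosphere (EOS-80)
international equation of state at (θ, S). The package deliberately uses this
closed-form polynomial rather than a TEOS-10 implementation: at the surface
reference pressure, for a *difference* of densities 200 m apart, the two
formulations agree to well below the inter-model signal, and the EOS-80
surface equation is compact, verifiable against the published UNESCO check
values, and free of Absolute-Salinity conversion ambiguity for model output
in practical salinity.

**Order of averaging.** AOU and σ₀ are computed at the native (monthly)
resolution and then annually averaged, because both are nonlinear in (θ, S);
averaging first would alias the seasonal cycle into the metric. The POC flux
is averaged first (it enters linearly everywhere), matching the convention of
annually averaging `expc` before computing export.

**Annual means, drift removal, smoothing.** Annual means weight months by
their length in the run's calendar; partially covered first/last years are
dropped with a warning. Drift removal subtracts the control's *actual* values
over the equivalent segment starting at the branch year (integer-year
alignment; sub-annual branch times are rounded) — not a fitted trend — so any
drift shape shared by the runs cancels exactly; if the control ends early the
anomaly is truncated to the overlap with a warning. Smoothing is a centered
moving average (default window 10 y) with shorter windows at the edges
(`min_periods = ceil(window/2)`), preserving series length; the pipeline
clamps the window to the series length for very short (truncated) series.
Anomalies are computed on raw series and smoothed afterwards.

## First-order steady-state model

At steady state, carbon respired at depth z resides in the interior for the
residence time τ(z) before re-ventilation, so the standing stock is

    C_soft = ∫_{z0}^{zmax} R(z) τ(z) dz + F(zmax) τ(zmax)

with the Martin curve F(z) = EP (z/z₀)⁻ᵇ, z₀ = 100 m, and R = −dF/dz.
Choices:

- **τ(z):** log-linear from 10 y at 100 m to 1000 y at 4000 m, spanning the
  canonical 10–1000-year range of interior residence times; tabulated on 200
  log-spaced nodes and interpolated linearly in log depth. A user-supplied
  table can replace it.
- **Bottom boundary:** flux reaching z_max = 4000 m is treated as sequestered
  at τ(z_max) rather than lost. This preserves exact carbon conservation and
  the closed form C_soft = τ·EP for constant τ, which doubles as the model's
  analytic self-test.
- **Quadrature:** composite trapezoid on a log-spaced grid of 800 nodes;
  a 50× refinement changes C_soft by < 0.1% (asserted in tests).
- **Scan ranges:** the general scan defaults to EP ∈ [2, 20] Pg C yr⁻¹ and
  b ∈ [0.4, 1.6], spanning published sediment-trap attenuation estimates and
  the spread of modelled export.

**Headline spread.** The question "how much can storage differ between
simulations that agree on export?" is answered at a fixed, representative
export production of 6 Pg C yr⁻¹ (a canonical observation-based global
estimate, mid-range of CMIP-class models), sweeping b over the interval
implied by the preindustrial ensemble transfer-efficiency spread of 3–25% at
1000 m via b = −log₁₀(TE/100): b ∈ [0.602, 1.523]. Under these choices the
max-minus-min steady-state C_soft is ≈968 Pg C (computed, not asserted —
`scripts/acceptance.py` recomputes it). Because C_soft is linear in EP, the
spread scales proportionally with the chosen reference export; fixing EP is
what makes the number a statement about flux-curve uncertainty alone. Over
random (EP, b) draws the coefficient of determination of C_soft against
F(1000 m) exceeds that against EP — deep flux, not export, predicts storage.

## Synthetic ensemble

The generator emulates the *statistical and structural* features the pipeline
must handle, not any model's physics:

- **Construction.** Each column carries F(z) = EP_cell (z/100)⁻ᵇ with
  spatially varying EP and b; oxygen is saturation (from θ, S) minus a
  respiration deficit AOU = (170/117) R(z) τ_gen(z), so C_soft is exactly the
  carbon implied by the flux field. The generator's residence profile
  τ_gen(z) = 1000 y · ((z−100)/4900)^1.5 rises from zero at the export depth
  (the ventilated surface has no accumulated respiration signal) to 1000 y at
  the bottom — this keeps oxygen positive everywhere while preserving the
  causal flux→storage link.
- **Trends.** Scenario runs prescribe, per century: export −0.5 Pg C yr⁻¹,
  transfer efficiency −1 percentage point (applied as a uniform shift of the
  attenuation exponent), stratification +0.2 kg m⁻³ (realized as
  surface-intensified warming with 200 m e-folding), and residence times
  +20% (ventilation slowdown). The τ trend is what makes sequestered carbon
  *rise* while export *falls* — the joint pattern of warming projections;
  with a fixed τ a declining export would necessarily drain the inventory.
- **Drift and branching.** All runs carry weak linear drifts as functions of
  parent (control) time; scenarios branch at `branch_year` with CMIP6-style
  `branch_time_in_parent` metadata, so branch-aligned subtraction cancels the
  drift exactly.
- **Calendar and seasonality.** Monthly means on a 360-day calendar; all
  seasonal cycles have exactly zero annual mean, and noise is injected per
  year, so the closed-form annual ground truths are exact.
- **Grid.** Log-spaced levels from 5 m to 5000 m with the nearest levels
  snapped exactly onto 100/200/1000 m. This makes the generator's power-law
  bookkeeping commensurate with the pipeline's linear depth interpolation;
  on a 20-level grid without snapping, interpolating a convex power law
  would bias the 1000 m flux by ~3% — a discretisation artifact, not a
  pipeline error — swamping the noise-scaled tolerances.
- **Noise.** Independent lognormal multipliers on per-cell export
  (σ = 0.003 per cell-year) and an annual surface-intensified temperature
  scalar (σ = 0.02 °C). These represent the residual internal variability of
  *global annual* metrics, deliberately weak so prescribed 50-year trends
  dominate with wide margin for any seed; real ensembles have substantially
  larger internal variability, so passing recovery tests here demonstrates
  correct bookkeeping, not skill against realistic noise. `ground_truth`
  propagates both noise sources analytically (delta method) to a 1-σ effect
  per global metric, which the tests use as 3-σ tolerances.
- **What is not emulated:** eddy/mesoscale structure, realistic bathymetry,
  ballasting, plankton functional types, oxygen disequilibrium, and
  inter-variable covariances beyond the flux→AOU closure. Conclusions from
  the synthetic tests are about the correctness of the processing chain, not
  about real CMIP6 behaviour.

## Numerical conventions

Depth is metres, positive down, increasing with index everywhere inside the
package; orientation is normalised at the I/O boundary. Arrays are ordered
(time, lev, lat, lon). Missing data are NaN and contribute zero to integrals
and zero weight to means. netCDF output is netCDF3 classic via the scipy
backend with no timestamp attributes, so identical inputs produce
byte-identical files. All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawn keys per (experiment, variable).

## Known limitations

- The AOU proxy attributes all oxygen deficit to soft-tissue respiration;
  preformed disequilibrium and carbonate-pump contributions are out of scope.
- The first-order model assumes a single global-mean residence-time profile
  and steady state; transient storage and spatially resolved transport are
  out of scope, so its numbers quantify flux-curve uncertainty, not a
  prediction for any particular model.
- The EOS-80 density choice and the fixed ρ₀ unit conversion introduce
  sub-percent biases that are irrelevant for anomalies and inter-model
  spread but would matter for absolute comparison with observational
  climatologies.
- Transfer-efficiency maps are reported wherever the export floor is
  exceeded; no additional regional masking is applied.
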