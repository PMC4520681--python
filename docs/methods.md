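# Methods

## The macroecological model

The model predicts the abundance (N), biomass (B) and production (P) of
marine consumers per m² of sea surface from two environmental drivers:
depth-integrated primary production P_P (g C m⁻² d⁻¹) and sea surface
temperature T_C (°C). All production is assumed to occur, and be
consumed, in the layer from the surface to the analysis depth — the
deeper of the euphotic depth (a quartic polynomial in log₁₀ column
chlorophyll, capped at 180 m where the relationship loses validity) and
the mixed-layer depth, additionally capped at the bottom depth in shelf
cells (a physical necessity the depth-integration convention otherwise
ignores).

### Phytoplankton size structure

Four regression-based metrics describe the phytoplankton community:
spectrum slope b_P and intercept a_P (functions of log₁₀ P_P), the
median-production cell mass M_P50 (pg C) and the central-80%-of-
production mass range M_P1090 (functions of log₁₀ P_P and T_C). Two
interpretation choices deserve note:

* **The range metric is a mass-ratio factor.** We treat the regressed
  M_P1090 as the factor M_P90/M_P10 whose log₁₀ is the range in
  log-mass units. Treating the regressed value itself as the log-range
  makes the upper-tail extension below insoluble over most of the warm
  ocean (the radicand (5/4)M_P90^(b+1) − (1/4)M_P50^(b+1) goes negative
  for b_P < −1 whenever the range exceeds ≈1.8 decades), so the factor
  reading is the only one under which the model runs globally.
* **Symmetric quantile placement.** M_P10 and M_P90 are placed
  symmetrically about log₁₀ M_P50; the metrics do not pin down the
  placement and this is the simplest reading.

The distribution bounds M_P0 and M_P100 extend each tail to capture a
further 10% of integrated production under the power-law density m^b_P,
so production over [M_P0, M_P100] is exactly 1.25× that over
[M_P10, M_P90] (a property the tests verify by quadrature).

### Export and the energy entering the food web

The fraction of production by small cells (φ_S, cells ≤ 12.9 pg C, the
5 µm equivalent spherical diameter) integrates the linear-in-log
production density (½b_P x² + a_P x antiderivative) between the bounds,
clamped to [0, 1] — under the regressions' mass scales the whole
distribution in fact sits below the 5 µm reference everywhere in the
forcing envelope, so φ_S = 1 via the clamp and the export ratio varies
through temperature and depth; the general formula is retained (and
tested) for overridden coefficient sets. The Dunne-type export ratio
φ_E = (e^(T·k_D)(φ_SD φ_S + φ_LD φ_L) + R r_B φ_L)/(1+R), with
R = Z·D/S the vertically integrated remineralisation coefficient, is
evaluated at the analysis depth and at the 200 m reference; the
relative-export multiplier τ_R = 1 + φ_Eref − φ_EZ then scales the
first-step transfer efficiency: energy entering the consumer food web
is 10^ε_P · P_P · τ_R (g C m⁻² d⁻¹), annualised (×365) and converted
carbon→wet by 1/(0.32 × 0.11) ≈ 28.4.

### Spectrum construction

That production is anchored at primary consumers of wet mass equivalent
to M_P50 · 10^μ_P (μ_P the realised log₁₀ PPMR of primary consumers)
and converted to biomass by dividing by the metabolic specific
production rate P/M = e^(c₁ − E/(k T_K)) M^(r−1) (T_K = T_C + 273;
division, since biomass is production over a specific rate — the
dimensional reading). From the anchor, production declines by the
secondary-consumer transfer efficiency 10^ε_S per μ_S decades of mass,
giving the biomass-spectrum slope b_C = ε_S/μ_S + (1 − r). The (1 − r)
term is the lossless-transfer baseline: with ε_S = 0 production is flat
in mass and biomass rises as M^(1−r) through the specific rate. The two
constructions (slope/intercept line vs explicit production decay) agree
bin-for-bin to 10⁻¹⁰ relative error; this equivalence is the module's
internal oracle. The spectrum is discretised in 0.1 log₁₀ bins (default
1 g – 10⁶ g, extensible to 10⁻⁵ g); per-bin P = B × P/M and N = B/M.

### Uncertainty propagation

Sampled parameters: the four regression coefficient rows (independent
normals; within-row correlation defaults to 0) and ε_P, ε_S, μ_P, μ_S,
r. Each (PPMR, TE) pair is drawn from a bivariate normal with
correlation ρ = −0.2 — a weak negative covariance; the value is a
configurable default, as no published estimate pins it down. Draws that
produce unusable phytoplankton spectra (slope at the integrable limit,
non-positive tail radicands) are excluded, not resampled, and counted;
percentiles use linear interpolation between order statistics.

Regional and global totals apply **one shared draw to all cells per
iteration** (independent-draw mode available): parameter uncertainty is
systematic, and per-cell independent draws would largely cancel in
area-weighted sums, understating the global interval. A cell's 1 g m⁻²
over 1 km² is exactly 1 tonne, which is the unit bridge for totals.

## The dynamic size- and trait-based model

Thirteen species, distinguished only by asymptotic mass M∞ = 10^{0,
0.5, …, 6} g, live on a joint 150-class log grid from 10⁻¹⁰ g (resource
floor) to 10⁶ g; consumers occupy classes from 0.001 g, the resource up
to 0.1 g. Per species the number density follows
∂N/∂t + ∂(gN)/∂m = −(μ_pred + μ_0 + F)N with an egg-flux boundary at
0.005 g. Encounter is γ m^q times kernel-weighted prey biomass
(lognormal kernel in log prey:predator ratio, centre β, width σ in ln
units); feeding level f = E/(E + h m^n τ_T); growth
g = α f h m^n τ_T (1 − ψ) − k_s m^p τ_T floored at zero, with ψ the
smooth maturation allocation at η_mat M∞; predation mortality is the
satiation-limited intake of all predators; the resource regenerates
semichemostatically toward κ m^(−λ) at rate r₀ m^(n−1). Reproduction
(efficiency ε_repro, halved for the female share) feeds a Beverton-Holt
recruitment cap. The temperature multiplier
τ_T = e^((−E/k)(1/T_K − 1/283)) scales maximum intake, standard
metabolism and background mortality only, so the intake:metabolism
ratio is temperature-invariant while absolute rates, and hence prey
mortality, increase with warming; r₀ is not temperature-scaled by
default (a config flag enables it).

Numerics: fully implicit upwind transport in mass (positivity-
preserving for any time step), implicit resource update, dt = 0.1 yr.
Equilibrium protocol: ≥120 yr spin-up, then 60-yr means, extending
window by window until the community slope changes by <1% between
consecutive windows (cold, unproductive forcing can need far longer;
exceeding the 600-yr ceiling marks the run non-converged rather than
failing silently). The community slope b_C is the least-squares slope
of log₁₀(biomass per bin) vs log₁₀(mass) over 100 g – 10 kg.

### Parameter choices

The scaling exponents follow the standard trait-based conventions
(n = p = 0.75, q = 0.8, λ = 2 + q − n = 2.05, η_mat = 0.25, α = 0.6,
h = 30 g^0.25 yr⁻¹). The remaining coefficients were set by exploring
the model's coexistence and stability space, with three explicit
criteria: all 13 species persist unfished across the forcing envelope,
the realised (diet-weighted) log₁₀ PPMR at the reference cell (15 °C,
0.5 g C m⁻² d⁻¹) equals the macro model's realised PPMR of 3 within
0.05, and the unfished slope band reachable by calibration covers the
macro model's interquartile slope range. This yields k_s = 2 g^0.25
yr⁻¹ (a higher metabolic coefficient pushes the largest species' feeding
level below break-even and they starve), σ = 1.8, β = 450 (the
preference exceeding the realised ratio of 1000^… is expected: with
small prey relatively more abundant, the realised ratio sits above the
preference by (λ−2)σ²/ln 10 ≈ 0.07 decades for power-law prey — a
closed form the tests verify), μ_0 = 0.6 yr⁻¹, ε_repro = 0.1. The
search coefficient γ is derived from a design feeding level f₀ = 0.6
against the current resource level κ, which makes the equilibrium
exactly linear in κ — the property the calibration exploits.

The Beverton-Holt cap is a multiple (default 1×) of the egg flux each
species would need to fill the community power law at its asymptotic
mass, with the cap's M∞ scaling taken at a survival exponent a = 0.2.
This cap is the model's stand-in for unresolved early-life density
dependence; it is what guarantees coexistence of all 13 species, and
its M∞ scaling controls how standing biomass — and therefore yield —
partitions between small and large species. The default makes small
species the dominant yield contributors and produces dome-shaped total
yield curves with an interior MMSY on the multiplier grid; larger
exponents over-weight large species until total yield no longer peaks
within the swept range.

### Calibration to the macro baseline

The two resource parameters are calibrated per cell against a chosen
percentile of the macro model's Monte-Carlo distribution (25th/50th/
75th by convention):

* **r₀ sets the shape.** Resource turnover relative to consumer demand
  changes feeding levels along the spectrum and with them the
  equilibrium slope. The slope response is continuous but not monotone
  (species-level structure moves through the two-decade fit window), so
  the search scans r₀ coarsely on a log grid, brackets every sign
  change of (slope − target) and refines the best bracket by Brent's
  method.
* **κ sets the scale.** With γ tied to κ the equilibrium densities are
  exactly proportional to κ, so κ is solved in closed form from the
  biomass ratio after the slope search.

A final verification run reports both residuals; calibrations that
cannot reach the target slope within ±2% are flagged non-converged, the
behaviour reserved for forcing under which the dynamic model has no
stable spectrum. At the reference cell all three percentile
calibrations close with slope residuals below 0.1%.

### Fishing

Selectivity is knife-edge by species and size: F(m) = F_species ×
multiplier × τ_T for m ≥ 0.01 L_c³ (the length-mass cube law
M = 0.01 L³ also fixes the quoted asymptotic lengths, 5–464 cm). The
four scenario tables are shipped as code constants, including the
rows that apply only inside large marine ecosystems and scenario C's
shared-F band for individuals above 48 cm. The multiplier sweep
(0–3 in 0.05 steps by default) re-equilibrates the community at each
point, warm-starting from the previous point's state; yield is the
time-mean of Σ_species ∫ F N m dm, depth-integrated. MMSY is read off
the grid without interpolation. Regional curves aggregate by
area-weighted summation per multiplier; the global MMSY is the maximum
of the summed curve, never the sum of per-region maxima.

## The synthetic forcing generator

Cells are sampled uniformly in temperature (−2 to 30 °C) and uniformly
in log₁₀ primary production (0.01 to 3 g C m⁻² d⁻¹) — the envelope of
realistic open-ocean combinations — with chlorophyll derived from
production through a configurable monotone stand-in
(Chl = c · P_P^0.8, normalised to 1 mg m⁻² at 0.25 g C m⁻² d⁻¹; the
relationship real forcing fields obey is product-specific and not
published), mixed layers of 10–150 m, log-uniform bottom depths and
round-robin LME/FAO region labels. What it deliberately does not
emulate: spatial autocorrelation, the joint (T, P_P) density of the
real ocean (uniform sampling over-weights rare corners), seasonality
(the models consume annual means), and coastal optics. Tests passing on
synthetic cells therefore demonstrate the model mechanics and their
internal consistency across the envelope — not agreement with any
observed ocean field.

## Numerical and degenerate-input conventions

Euphotic depth is clamped at 180 m; analysis depth at the bottom.
Non-positive production, chlorophyll, area or bottom depth are hard
errors; sea surface temperatures outside [−3, 35] °C are flagged but
accepted. Monte-Carlo draws with b_P within 10⁻⁹ of −1, non-positive
tail radicands or a zero production integral raise a degenerate-draw
error that the uncertainty layer converts into an exclusion count; a
cell whose draws are more than half degenerate is an error naming the
cell. φ_S is clamped to [0, 1] when the reference mass falls outside
the distribution bounds. In the trait model, non-finite abundances
abort with diagnostics rather than propagate; the implicit scheme
cannot produce negative densities.

## Known limitations

Surface temperature stands for the whole water column, biasing rates
high and biomass low where consumers live deeper. The macro model's
uncertainty envelope covers parameters only — not forcing, not model
structure. The trait model's parameterisation is one defensible point
in a space the data do not constrain; its yield predictions inherit the
calibration baseline's uncertainty but none of its own structural
uncertainty. Consumers are not partitioned into fish and others.
Movement between cells, benthic production and non-phytoplankton
primary production are absent, so coastal and reef systems are
under-predicted by construction.
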