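# Methods

`ridgehab` budgets the habitable space and biomass standing stocks of an
Arctic sea-ice pack made of pressure ridges and level first-/second-year
ice (FYI/SYI). This note records the model, its assumptions, the
defaults, and the numerical choices.

## Brine physics

The liquid (brine) volume fraction of sea ice is computed from bulk
salinity S (PSS-78) and temperature T (°C) with either

* the Frankenstein–Garner closed form,
  `V_b/V = S (0.532 + 49.185/|T|) / 1000`, valid on [−22.9, −0.5] °C, or
* the Cox–Weeks phase relations with the Leppäranta–Manninen warm-ice
  coefficients for −2 < T < 0 °C, assuming air-free ice:
  `V_b/V = ρ S / F1(T)` with `ρ = ρ_i F1 / (F1 − ρ_i S F2)` and
  `ρ_i = 0.917 − 1.403·10⁻⁴ T` g cm⁻³.

The coefficient tables are pinned in `constants.py` with citation
strings. The two parameterizations agree within ~5 % over S ∈ [2, 8],
T ∈ [−10, −2]. Because the two publications fitted F1/F2 independently,
the −2 °C piece boundary carries a residual jump of ≈2·10⁻⁴ per salinity
unit; it is below 10⁻³ for the bulk salinities that matter here (≤ 5)
and is asserted at that level in the tests rather than hidden.

Ice is classed permeable when the brine fraction strictly exceeds a
configurable threshold, default 0.05 (the conventional percolation
threshold for columnar ice). The boundary value 0.05 itself is
impermeable by design.

**Temperature convention.** Field narratives quote a single brine value
per ice class, not a profile. The package's convention: submerged keel
rubble is evaluated at the seawater freezing point (default −1.9 °C, a
configurable constant — no salinity-dependent freezing-point formula is
applied); level ice at the mean of the surface temperature and the
freezing point, approximating the mid-depth of a linear winter gradient.
With surface −10 °C this yields brine fractions of 0.106 (rubble, S=4)
and 0.044 (level ice, S=5) — the "10 % vs 5 %" winter contrast. The
convention is a named, overridable parameter of
`scenario_brine_fractions` / `level_ice_temperature`; evaluating level
ice at, e.g., the surface temperature instead gives 0.036.

## Keel geometry

A keel of depth `h_k` (m below the waterline) has a consolidated layer
`h_c` and rubble of thickness `h_rbl = h_k − h_c` with macroporosity `μ`
(water-filled void fraction). Rubble is modeled as a stack of blocks of
thickness `h_b` and length `l_b` (default `l_b = 3.5 h_b`), giving
`h_rbl (1−μ)/h_b` blocks per m² of footprint.

Surface-area ratio (block faces per footprint, relative to level ice):

    S_rbl/S_li = h_rbl (1−μ) / (h_b l_b) · (l_b + 2 h_b)

counting the top, bottom and two end faces of each block; block side
faces are ignored. Brine-volume ratio of a ridge to level ice of
thickness `h_li`:

    V_b,rdg/V_b,li = h_cl/h_li + h_rbl (1−μ)/h_li · v_b,rbl/v_b,li

Unit volumes (m³ per m² of the ice type's footprint, i.e. meters), with
an exterior skin `δ_ext` (default 0.1 m) on each horizontal block face
and a bottom layer `δ_bot` (default 0.1 m) for every ice type:

    voids    = h_rbl μ
    exterior = h_rbl (1−μ)/h_b · 2 δ_ext
    interior = h_c + h_rbl (1−μ)/h_b · (h_b − 2 δ_ext)
    bottom   = δ_bot
    level-ice interior = draft − δ_bot

Totals are always sums of components (`voids + exterior + interior +
bottom = h_k + δ_bot` holds to 1e-9 for every valid morphology and is
property-tested); no separate closed form for "total ridge ice" is
used, since a closed form rounded independently of its parts cannot stay
consistent with them. Only the submerged column counts: sail and
freeboard are excluded as non-habitat, and level-ice *draft* (thickness
× 0.9 ice/seawater density ratio when only thickness is known) is the
integration depth. The packaged configuration stores drafts of 1.3 m
(FYI) and 1.4 m (SYI), the 0.9-scaled buoy thicknesses (1.4/1.5 m)
rounded to the 0.1 m core-section resolution at which the compartment
table is defined.

Default morphology (the packaged July configuration): `h_k = 3.9` m,
`h_c = 2.2` m, `μ = 0.17`, `h_b = 0.3` m, coverages ridge 22 %, FYI
50 %, SYI 28 %. These give ridge unit volumes 0.29 / 0.94 / 2.67 / 0.1 m
and habitable ice volumes of 0.82 m (ridge), 0.65 m (FYI), 0.39 m (SYI)
per m² of total sea ice.

## Standing stocks and uncertainty

Each (variable, ice type, compartment) cell carries a mean ± SE
concentration (mg m⁻³) with its sample count. Stocks:

* per compartment: mean × unit volume × areal coverage (mg m⁻²);
* per area of the ice type's own footprint: Σᵢ meanᵢ × vᵢ;
* per coverage (per m² of total sea ice): per-area × areal fraction;
* per volume: per-area / total unit volume (voids included in the
  divisor, matching the reference accounting);
* relative share: 100 × per-coverage / Σ per-coverage, summing to 100 %.

SEs propagate to first order assuming independent compartment errors
and *exact* volumes and coverages: exact constants scale SE linearly,
sums add in quadrature, and percentage shares use the delta method.
Volumes and coverages of course carry sampling error of their own (μ
from 8 drill lines, coverages from one laser-scanner survey); treating
them as exact understates the SEs, and bootstrap alternatives are out
of scope. Under this model the propagated ridge Chl-a per-area SE is
±8.8 mg m⁻², larger than the ±5 printed in the reference table (whose
propagation details are unstated); SEs are therefore reported but only
their internal consistency is asserted.

Tables are computed unrounded and displayed at 2 significant figures by
default. The table-reproduction tests and the acceptance script budget
from unit volumes rounded to the 0.01 m display resolution of the
reference table, since that table's stock columns were derived from its
own displayed volumes; the full-precision result differs by ~0.3 %.

C:Chl-a ratios are reported with their computation basis (per-area or
per-volume) attached, because the ratio of rounded stocks is not
basis-invariant.

## Sample preparation

* Chl-a from oven-dried filters is multiplied by 1.8 (dried filters
  retain 1.8× less pigment than standard treatment); applied wherever
  the `dried_flag` is set, before averaging.
* Leucine incorporation (nmol L⁻¹ d⁻¹) converts to bacterial carbon
  production with 1.5 kg C mol⁻¹ (from 1797 g protein mol⁻¹ leucine ×
  0.86 g C g⁻¹ protein, recorded as provenance, never re-multiplied),
  which collapses to ×1.5 in mg C m⁻³ d⁻¹; no isotope dilution.
* BSi/LSi time-course digestion: OLS through the trailing
  `linear_window` points (default 3 — the linear mineral phase; the
  window is a package choice and configurable) extrapolated to t = 0;
  the intercept is BSi (clipped at 0 with a warning if negative), LSi =
  (final alkaline Si − BSi) + HF-phase Si.
* Aggregation: mean, SE = sd(ddof=1)/√n. Single-sample compartments
  (they occur — single cores during difficult weather) report SE 0 with
  an explicit `degenerate` flag rather than failing; downstream
  quadrature then underestimates that cell's SE, visibly flagged.

## Synthetic data

The generator emulates the July sampling campaign so the full pipeline
is testable without the deposited field data: for each table cell it
draws `n` values from a zero-truncated normal whose *parent* parameters
are (mean, SE·√n). Concentrations are non-negative and several cells
have sd of the order of the mean, so truncation genuinely bites; the
analytic post-truncation moments are exposed
(`CompartmentSpec.population_mean/sd`) and recovery experiments compare
against them, not the parent values. A moment-matched lognormal is
available for strongly skewed cells; note a zero-truncated normal
cannot realize CV ≥ 1 (e.g. the ridge exterior Chl-a cell at CV 1.9),
so its parent mean is not its realized mean there by a wide margin.

Drill logs discretize the rubble layer at a stated vertical resolution
with i.i.d. void cells at probability μ; real voids are spatially
correlated, but only the porosity *estimator* (pooled void fraction,
SE from between-line spread) is under test, not void geometry. Ice
profiles interpolate temperature linearly with optional seeded jitter.

What passing tests show: the estimators are unbiased and calibrated
under the assumed sampling laws at the campaign's n. What they do not
show: robustness to spatial correlation, non-independent compartment
errors, or seasonal non-stationarity — none of which the budget model
itself claims to handle.

All generators are bit-reproducible given (spec, seed). The recovery
acceptance check uses 200 pipeline replicates (≈3 s) and the drill
check 500 surveys (<1 s); per-cell 2-SE coverage is required to reach
90 % (measured 93–96 %).

## Known limitations

* The geometric keel model is 1-D in the vertical: no 3-D keel shape,
  consolidation evolution, or melt modeling.
* SEs treat geometry as exact (above); relative-share SEs assume
  independent numerator terms.
* The brine scenario's single-temperature convention is a stated
  simplification of a profile; use `profile_brine_fractions` on real
  core profiles where available.
* The permeability threshold is a step function of brine fraction;
  connectivity hysteresis is not represented.
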