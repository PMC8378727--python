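# Methods

## Model structure and stepping

The simulator advances five carbon pools (DPM, RPM, BIO, HUM, IOM; all in
Mg C ha⁻¹ over a fixed topsoil depth) on a monthly time step. Within one
month the order of operations is fixed and documented so mass accounting is
unambiguous:

1. the water budget is updated (SMD ← clamp(SMD + 0.75·pan evaporation −
   rain) between the saturation bound and the applicable maximum deficit);
2. the rate modifiers a (temperature), b (moisture) and c (cover) are
   computed from the updated state;
3. the month's plant and exogenous inputs are assembled per the active
   modification flags, and poaching (if enabled and triggered) scales the
   plant components;
4. the pre-existing stock of each active pool decays by the exact
   exponential P·exp(−k·a·b·c/12) — not an Euler step — the decomposed
   carbon is split into CO₂/BIO/HUM by clay content, and the fresh inputs
   are then credited to their entry pools.

Crediting inputs after decay of the pre-existing stock (rather than before)
is a declared convention; with monthly exponential decay the difference is a
sub-percent timing effect, and the chosen order makes the mass-balance
identity ΔSOC = Σinputs − ΣCO₂ hold to floating-point accumulation error,
which every run audits (`SimulationResult.mass_balance_error`).

Reference constants: k = 10 / 0.3 / 0.66 / 0.02 yr⁻¹; temperature factor
a = 47.91/(1 + exp(106.06/(T + 18.27))), zero at or below −18.27 °C; cover
factor 0.6 under vegetation; x(clay) = 1.67·(1.85 + 1.60·e^(−0.0786·clay));
BIO:HUM = 46:54; lumped plant input DPM:RPM = 1.44 (59 % DPM).

## Soil water and the extended moisture factor

The soil moisture deficit is **signed**: positive below field capacity,
negative between field capacity and saturation. The sign convention was
chosen so the poaching trigger "SMD ≤ −10 mm" reads literally. In default
mode the deficit is floored at 0 (field capacity); in saturation-extended
mode it may fall to smd_saturation = −(θ_sat − θ_fc)·depth·10 mm. Excess
water beyond saturation is shed instantly by the clamp (no lateral flow, no
snow, no water table).

θ_fc (33 kPa) and θ_sat come from the Saxton & Rawls (2006) texture
regressions (sand, clay, organic matter % — default OM 2 %), behind an
interface that also accepts measured values (`theta_override`). The dry-side
maximum deficit keeps the reference clay polynomial
(20 + 1.3·clay − 0.01·clay²)·depth/23, with the bare-soil cap at 1/1.8 of
it.

The moisture factor b is 1.0 from field capacity down to 44.4 % of the
maximum deficit, declines linearly to 0.2 at the maximum deficit, and — in
extended mode — declines linearly from 1.0 at field capacity to 0.2 at
saturation: b = 1 − 0.8·SMD/SMD_saturation for SMD < 0. The dry-side plateau
threshold is kept unchanged in extended mode. b is continuous over the whole
admissible domain and clamped to [0.2, 1.0] against float rounding at the
endpoints. If the weather series carries Penman PET instead of open-pan
evaporation, a config switch (`evap_is_pet`) sets the 0.75 factor to 1.0.

Note that the two moisture modes follow different SMD trajectories: the
extended deficit is never larger than the default one, so on the *dry* side
the extended factor can exceed the default factor for the same forcing.
The "extended ≤ default" ordering that makes RothC_3 accumulate more carbon
than RothC_2 is a wet-climate property, which is why the version-ladder
ordering tests run on wet fixtures.

## Exogenous organic matter

Applied carbon is partitioned from Van Soest fractions (% of volatile
solids) via anaerobic biodegradability B = 0.905·e^(−0.055·lignin):
HUM = lignin·(1−B), RPM = lignin·B + (holocellulose+solubles)·(1−B),
DPM = (holocellulose+solubles)·B, normalized by total VS so the fractions
sum to one exactly (DPM closed by residual). Only the *sum* of
holocellulose and solubles enters the arithmetic, so the shipped default
ruminant quality — lignin 18.5 % VS (midpoint of the 9–28 % literature
interval), remainder split evenly — is data, not code, and overridable per
application; it yields the 0.1/0.6/0.3 HUM/RPM/DPM split at one-decimal
rounding. With the modification off, every application uses the fixed
farmyard-manure split (DPM 49 %, RPM 49 %, HUM 2 %), so the version ladder
is well defined. Nitrogen dynamics of manure are out of scope.

## Plant inputs

Standing above-ground biomass (Mg DM ha⁻¹ yr⁻¹) × 45 % C gives above-ground
carbon. Residue fractions: 20 % when grazed; 30 % unharvested × 50 % turned
over = 15 % when cut. Below-ground carbon is above-ground C × R:S with
R:S = 4.7375·e^(−0.0043·N_input); half of it turns over annually as root
residue. Net rhizodeposition is 0.5 × below-ground C biomass (root C
stock) — the ratio is applied to root *biomass*, not root residue, matching
its definition as a net rhizodeposition-to-root ratio; all of it enters DPM.

Quality: the RPM share of a residue equals its NDF fraction (carbon assumed
equally concentrated in fibre and solubles — a stated simplification), the
below-ground NDF is the above-ground value plus 8 percentage points of
lignin, and DPM is the complement. NDF may be given per month to express
seasonal lignification.

Annual component totals are spread over months by a weight vector summing
to 1. The shipped `EUROPEAN_GRASSLAND_PATTERN`
(.03 .03 .08 .11 .14 .14 .12 .11 .10 .08 .03 .03, Jan–Dec) is a declared
growing-season-weighted preset — flat November–February minimum, May–June
peak — and is user-overridable; totals are conserved under any valid
pattern.

With the plant-residue modification off, the pipeline degrades to the
classic single lumped input at DPM:RPM = 1.44. The lumped quantity is
defined as above-ground + below-ground residue C *without* rhizodeposits:
the default treatment under-counts root-derived inputs, and the step from
RothC_1 to RothC_2 then reflects exactly the carbon the modification adds.

## Poaching

Trigger: grazing in the month AND SMD ≤ −10 mm (configurable threshold).
Severity: reduction = min(max_reduction, damage_per_lsu · stocking rate),
defaults 0.10 per LSU ha⁻¹ capped at 0.5. The reduction multiplies **all
three plant components** of that month (configurable in principle; EOM
inputs are never touched), with no carry-over between months — treading
damage in these systems is short-lived. The functional form is deliberately
parametric: mechanistic hoof-print/deformation equations would demand data
(soil strength, hoof loading) outside this package's inputs, so the model
preserves the qualitative contract — saturation + grazing as trigger,
severity growing with stocking density, month-local effect — with all three
constants exposed in configuration.

## Initialization

IOM = 0.049·TOC^1.139 (Falloon). The active carbon (TOC − IOM) is split by
the model's own steady-state proportions under constant forcing: with input
fraction f_d = 0.59 to DPM and f_r = 0.41 to RPM, flux balance of the
first-order system gives pool sizes proportional to

f_d/k_d : f_r/k_r : 0.46·α/((1−α)·k_b) : 0.54·α/((1−α)·k_h),

where α = 1/(1+x(clay)) is the retained fraction of decomposed carbon. The
shares depend only on clay and the rate constants (input rate and rate
modifiers cancel), HUM is closed by residual so pools sum to the measured
stock exactly, and HUM is always the largest active pool in the realistic
clay range. This closed form is the quantity that published SOC/clay
pedotransfer initializations for this model family are fitted to emulate;
it is exposed behind a swappable interface (`active_fractions`), and a
spin-up alternative (`init_method="spinup"`: cycle the forcing to
quasi-equilibrium, then rescale to the measured stock) is provided.

## Evaluation and sensitivity

BIAS = mean(simulated − observed) (negative = underestimation);
RMSE is reported both absolute (Mg C ha⁻¹) and as % of the observed mean,
since both conventions circulate and they differ materially;
EF = 1 − Σ(sim−obs)²/Σ(obs−mean)², requiring ≥ 2 observations with spread
(NaN otherwise). RMSE ≥ |BIAS| always holds for same-unit definitions.

Sensitivity uses one-at-a-time sweeps of a modification input over its
plausible interval — NDF 30–70 %, EOM lignin 9–28 % VS, moisture factor
pinned to a constant in 0.2–1 — running the full simulation at each grid
point and reporting (max − min)/max over the final SOC stocks. The index is
scale-invariant, and for monotone responses the endpoints determine it.

## Synthetic sites

The fixture generator emulates intensive temperate moist grassland: wet
profiles draw annual precipitation > 1000 mm against ~670 mm open-pan
evaporation (so soils sit near saturation most of the winter and often into
the grazing season), mean air temperature 7–10.6 °C with a July-peaked
sinusoid, N input 183–229 kg N ha⁻¹ yr⁻¹, initial SOC 64.7–137 Mg C ha⁻¹,
clay 20–35 %, depth 20 or 30 cm. `wet_grazed` grazes May–October at 1–2
LSU ha⁻¹ with excreta C (2–3 Mg C yr⁻¹) spread over the grazing months;
`wet_cut` takes four cuts with slurry after each; `dry_grazed` uses the same
management under a rain-limited climate (~390 mm against ~860 mm
evaporation) whose deficit never approaches saturation, so poaching can
never trigger. Observations are a reference RothC_3 run plus Gaussian noise
(σ = 1.5 Mg C ha⁻¹). All draws come from one seeded generator in fixed
order, so fixtures are pure functions of the seed.

What the fixtures do *not* emulate: real weather autocorrelation and
extremes, grazing feedback on biomass, measured SOC time series. Passing
the ladder-ordering and evaluation tests therefore demonstrates internal
consistency of the mechanisms under realistic forcing magnitudes, not
predictive skill on real sites — evaluating that requires user-supplied
site data through the same interfaces. Default simulations are 8 years of
monthly steps, which keeps every test and the acceptance script on the
order of seconds.

## Numerical choices and degenerate inputs

- Decay uses the exact per-month exponential; a fine-step Euler integration
  of the underlying ODE is used in tests as an independent oracle (at hourly
  sub-steps its truncation error is negligible against the 0.5 % check).
- Mass conservation is enforced by construction: partitions close their last
  component by residual (CO₂ in the clay split, DPM in the EOM partition,
  HUM in initialization).
- Texture fractions must sum to 100 ± 1 %; monthly patterns to 1 ± 1e−9;
  Van Soest fractions to 100 ± 1 % VS. Weather series must be contiguous
  months; gaps are reported with the missing month.
- The temperature factor returns exactly 0 at or below −18.27 °C and guards
  the overflow region just above the cutoff.
- The moisture factor clamps to [0.2, 1] against last-ulp rounding at the
  segment endpoints.
- Configs with poaching enabled but no grazing months are legal but inert
  (logged warning).

## Known limitations

Single soil layer and fixed depth; no radiocarbon; no sub-monthly dynamics;
no nitrogen cycling or plant growth feedback; runoff above saturation is
discarded instantly; the poaching severity model is parametric rather than
mechanistic; pedotransfer-based initialization inherits the usual
uncertainty of such functions relative to measured soil fractionation.
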