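# Methods

`chillpea` couples three model components — a thermal-time phenology engine
with a soil-water modifier, a post-flowering frost yield penalty, and a
grid-search procedure that detects a cold-temperature yield threshold — and
exercises them end-to-end on synthetic data in which the cold effect is
implanted and therefore known.  This note records the model equations, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices that were genuinely open.

## Phenology

Stages progress in the fixed order sowing (1) → germination (2) →
emergence (3) → end of juvenile phase (4) → flowering (5) → end of
flowering (6) → end of pod fill (7).  Each phase accumulates daily thermal
time from the day after the phase starts and advances on the day its target
(°Cd) is met; the excess above the target is discarded.  Germination is
entered the day after sowing (no thermal target of its own), and end of
flowering / end of pod fill share one accumulator counted from the start of
flowering, so their targets are both expressed "from flowering".  Maturity
(8) carries no target; traces end at end of pod fill.

**Daily thermal time.**  The diurnal temperature course is sampled at eight
three-hourly points interpolated between Tmin and Tmax with the cubic
fractions `0.92105 + 0.1140k − 0.0703k² + 0.0053k³` (k = 1..8), each point
is passed through a piecewise-linear response — zero at the base
temperature, rising linearly to a plateau of `opt − base` at the optimum,
falling linearly to zero at the maximum — and the eight responses are
averaged.  Cardinal temperatures default to 0 / 30 / 40 °C and are
configurable per cultivar.

**Soil-water modifier.**  Above an activation boundary and once the crop
has emerged, the day's thermal time is multiplied by a linear factor:

    TTm = TT × (1.65 − FASW)   when FASW ≥ 0.65 and stage ≥ 3,

with FASW the fractional available soil water over the top 600 mm,

    FASW = Σ(sw − LL15) / Σ(DUL − LL15),

summed over layers (the layer straddling 600 mm is pro-rated by depth;
should the profile be shallower than the limit the whole profile is used
with a one-time warning) and clipped to [0, 1].  The boundary is applied
with `≥`; at exactly 0.65 the multiplier is 1, so the choice between `≥`
and `>` is observationally irrelevant — but the identity `TTm == TT` at the
boundary is asserted exactly, which a naive `1.65 − FASW` in binary floating
point misses by 1 ulp.  The multiplier is therefore rounded to 12 decimal
places, stripping the representation error of the decimal constants while
changing no value by more than 1e-12.  FASW is evaluated at the start of
the day.  The consequence of the modifier is that wetter soil (FASW > 0.65)
slows perceived thermal time by up to 35 %, delaying flowering — the
"wetter never flowers earlier" property that the suite checks over
randomised FASW trajectories.

**Photoperiod.**  A linear ramp multiplies the day's (water-modified)
thermal time: factor 1 at or above a saturating day length, `1 −
sensitivity` at or below a critical day length, linear between.  Day length
uses the textbook sunrise equation with declination `−23.44° · cos(2π(doy +
10)/365.25)`.  The ramp applies at every stage; the fixture cultivar ships
with sensitivity 0 so that the soil-water modifier can be tested in
isolation, and the ordering question (photoperiod before or after the water
modifier) does not arise because both enter multiplicatively.

**Sowing rule.**  Within a sowing window (defaults: early 10–30 April, mid
1–21 May, late 22 May – 11 June), the crop is sown on the first day whose
trailing 7-day rainfall (inclusive) is ≥ 25 mm **and** whose whole-profile
plant-available water exceeds 80 mm; if no day qualifies, the last day of
the window is used and flagged as forced.

**Peak flowering** is the mid-point of flowering start and end, floored to
a whole day.  The reproductive period (RP) spans flowering start to end of
pod fill, and is the window for frost counting, cold-day percentages and
reproductive rainfall.

## Frost

A frost event is a day with screen (1.5 m) minimum temperature ≤ 0 °C.
Each post-flowering event removes about 5 % of yield.  Whether the 5 %
applies to the potential or the already-reduced yield is genuinely open;
the default compounds multiplicatively, `YF = Y·0.95^events` (bounded,
never negative), with an additive mode `YF = Y·max(0, 1 − 0.05·events)`
for sensitivity analysis.  The two agree exactly at one event.

Frost risk at flowering is summarised by the overlap coefficient of
Gaussian kernel density estimates (Silverman bandwidth) of frost
day-of-year and peak-flowering day-of-year, evaluated on the day 1–366
grid: `Σ min(f̂_frost, f̂_peak) · 1 day ∈ [0, 1]`.  Degenerate samples
(fewer than two points or zero spread) fall back to a unit-bandwidth
Gaussian.  Wrap-around at the year boundary is ignored; all relevant events
fall mid-year in the southern hemisphere.  No frost days yields coefficient
0 with an explicit no-frost flag.

## Threshold detection

For candidate threshold `tc`, season `t` has cold-day percentage
`P_t(tc) = 100 · #{RP days with Tmin ≤ tc} / #RP days` (the `≤` follows the
displayed definition of P).  The frost-affected yield is regressed by OLS:

    YF_t = β0 + β1·P_t(tc) + β2·R_t + e_t,

with `R_t` the RP rainfall and the error variance estimated from residuals
(fixing σ² = 1 would make the kg/ha effect sizes dimensionally
inconsistent).  The grid spans 0.0–19.0 °C in 0.1 °C steps, endpoints
included (191 candidates).  Candidates where the design is rank deficient —
P constant across seasons, most commonly identically 0 or 100 — are
excluded rather than treated as p = 1, since the regression is undefined
there.  The candidate with the smallest two-sided p-value for β1 wins;
ties within 1e-12 go to the warmest candidate.  A detection additionally
requires p < 0.05 and that the selected T_C lie between the first and third
quartiles (linear-interpolation rule) of the RP minima pooled across all
seasons at the site.  β1 at the selected threshold is the yield change in
kg/ha per one percentage-point increase in cold days, rainfall held fixed.

Numerical choices: candidate ordering uses log p-values (`t.logsf`), since
with strong effects p underflows to 0.0 for many candidates and the
max-T_C tie rule would then drift warm; a numerically exact fit (residual
variance below (1e-9 × RMS yield)²) is classified directly — p = 0 when
the P term contributes to the fitted values, p = 1 when it does not (the
constant-yield case).  No multiple-testing correction is applied across the
191 candidates.

Detected thresholds across sites are regressed on latitude and longitude
(OLS via statsmodels, which also supplies the coefficient p-values).

## Model evaluation statistics

RMSD uses the N−1 divisor, `sqrt(Σ(Sᵢ−Mᵢ)²/(N−1))`, as conventionally
reported alongside the Willmott index in this literature; the 1/N form is
available via an option.  Willmott's `d = 1 − Σ(S−M)² / Σ(|S−M̄|+|M−M̄|)²`
uses the measured-side mean and is deliberately not symmetric.  R² is the
squared Pearson correlation (not regression-through-origin R²).  Undefined
cases (zero denominator, zero variance) return None rather than a number.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the analysis consumes,
not any particular station record:

- daily centre temperature = annual sinusoid (amplitude A, southern-
  hemisphere phase: peak mid-January when latitude < 0) + AR(1) anomalies
  (lag-1 correlation ρ, marginal sd σ_d) + an independent year-level
  anomaly (sd σ_y); Tmin/Tmax sit symmetrically at a fixed diurnal range;
- rain = Bernoulli(occurrence) × Gamma(shape, scale) amounts;
- radiation = a seasonal sinusoid with small noise (carried for format
  completeness; nothing downstream consumes it);
- soil water = an explicit bucket cascade (rain in at the top, saturation
  overflow immediate, a fixed fraction of water above DUL percolating per
  day, temperature-proportional evapotranspiration extracted top-down,
  bounded by LL15), reset to FASW 0.5 on every 1 November to mimic a
  winter fallow.  Its only contract is a plausible FASW trajectory;
- potential yield = γ0 + γ2·R − γ1·P(T_C) + ε, ε ~ N(0, σ_yield²), floored
  at zero, then degraded by the frost penalty where frost occurs.  The
  threshold is sharp by construction, which is what makes recovery
  well-posed.

Every output is a pure function of (spec, seed); substreams are keyed by
(seed, year, component), so extending the year range reproduces the
original years bit-for-bit.

**Default site.**  70 seasons (1950–2019) at latitude −35: annual-mean
centre temperature 15.5 °C, seasonal amplitude 2.0 °C, diurnal range
11 °C, day-anomaly sd 1.5 °C with lag-1 correlation 0.9, year-anomaly sd
0.5 °C, rain on 30 % of days with Gamma(0.8, 6) amounts (~530 mm/yr),
γ0 = 1500 kg/ha, γ2 = 2 kg/ha/mm, γ1 = 5 kg/ha per %, T_C = 10.0 °C,
σ_yield = 100 kg/ha.  These were chosen, once, by a design-stage power
analysis: the implanted threshold is only statistically identifiable from
70 seasons when the September–November minima straddle it with strong
persistence and year-to-year variation (those two features, not the
day-level jitter, carry the between-year variance of P that the regression
needs), and when the minima cluster near the threshold so that every
0.1 °C grid step flips some days (keeping neighbouring candidates
distinguishable and the quartile band centred on the truth).  The price is
a muted seasonal cycle relative to a real inland site; the generator should
be read as a stylised temperate location constructed so the estimand is
recoverable, not as a climate reconstruction.  Lowering the annual mean to
~8 °C gives a frosty site (used for the overlap diagnostics); the default
site is effectively frost-free, which also keeps the recovery studies free
of the ~150 kg/ha of extra variance the frost penalty would inject.

**Recovery study conditions.**  The replicate studies build season records
from a fixed 1 September – 30 November window (91 days) over the generated
weather rather than running the phenology engine per replicate; this keeps
50-replicate studies in seconds while exercising the weather generator and
the full detection procedure.  The full pipeline (sowing rule → phenology →
RP-derived records) is exercised separately in the scenario runs and the
end-to-end determinism checks.

What the generator does **not** emulate: spatially correlated multi-site
weather, climate trends, realistic seasonal ET cycles, smooth (logistic)
cold-response alternatives, or any biomass/transpiration physiology.
Passing tests therefore demonstrate that the procedure recovers a sharp
implanted threshold under these stylised conditions — not that any real
site's threshold is identified, and not that the linear yield model
describes a crop simulator's yield formation.

## Problem sizes

Replicate studies use 50 replicates × 70 seasons × 91 RP days; the
regression oracle check uses 100 random designs of 5–40 seasons; phenology
property checks use 200 randomised 260-day trajectories; scenario runs use
three sites × three windows × 20 seasons.  The whole suite completes in
well under a minute on one CPU.

## Known limitations

- Stage targets other than the 690 °Cd juvenile phase are synthetic
  fixture values; cardinal temperatures are defaults, not calibrated.
- The bucket water balance has temperature-proportional ET only (base
  0 °C, default 0.10 mm/day/°C chosen for a near-neutral annual balance);
  no radiation or crop-cover term.
- The overlap coefficient ignores year-boundary wrap-around.
- The quartile detection band is computed from pooled (not per-year) RP
  minima; the pooled rule is stable and matches the wide-P rationale.
- With very strong implanted effects and warm-tie resolution, the selected
  T_C sits at the warm edge of the exactly-tied candidate set; this is at
  most one data-spacing above the implanted value.
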