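# Methods

## Model and procedure

The package treats dryland GPP as a function of climatic water balance:
per-area GPP (kg C m⁻² yr⁻¹) in each of eight regions is a smooth
polynomial of the aridity index AI = P/PET on the dryland domain
AI ∈ (0, 0.65). Fitting that curve on a baseline window and driving it
with a projected AI series converts a climate (drying/wetting) scenario
into a GPP scenario. The assumptions this rests on:

- AI is a sufficient statistic for per-area GPP within a region; ecosystem
  state (species composition, CO₂ fertilisation, land use) is frozen at
  its baseline relationship. Lagged and carryover responses to climate
  anomalies are deliberately out of scope.
- The response curve is stationary in time: a cell that dries to AI = 0.3
  in 2080 behaves like a cell that sat at AI = 0.3 in the baseline.
- Classification thresholds are exact inequalities — hyperarid AI ≤ 0.05,
  arid ≤ 0.2, semiarid ≤ 0.5, subhumid < 0.65, humid otherwise — applied
  to a window-mean AI climatology (`climatology window` = the analysis
  window; per-year classification is also supported, since period-mean vs
  annual classification is a genuinely open choice).

## Fitting and uncertainty

Per region, ordinary least squares on a Vandermonde design. The degree is
chosen by small-sample-corrected AIC over degrees 2–4 (recorded on the
fit); the curves are smooth and saturating, so low degrees suffice, and an
explicit criterion keeps the choice reproducible. Default samples are one
point per dryland cell (baseline-mean GPP vs baseline-mean AI,
`sample_mode="cell_mean"`); pooled cell-years are available
(`"cell_year"`). Samples are unweighted by area (an `area_weight` hook is
deliberately not a default, as there is no physical reason a large cell
should pull the response curve harder).

Uncertainty uses the out-of-sample *prediction* interval
ŷ ± t₀.₉₇₅,ₙ₋ₚ·s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀) — the projection use case asks where
a future cell-level GPP value will fall, not where the mean curve lies —
with the confidence interval available as an option. When aggregating
cells to regional totals the per-cell bounds are summed without an
independence assumption; that band is conservative and is documented as
such rather than as a formal 95% interval of the total. Central, lower
and upper predictions are floored at zero (flooring is monotone, so the
band ordering survives). Cells with AI outside (0, 0.65) in a given year
are excluded from that year's dryland accounting, exactly as the curves
are only valid on the domain they were fitted on.

Model series can be calibrated to a reference with `bias_correct`:
affine mean/variance matching on an overlap of ≥ 5 years. Affine matching
is minimal and invertible; quantile mapping is left as an extension hook.

## Variability decomposition

Trend shares use the linearity of the OLS slope: the slope of a sum is
the sum of slopes, so region (or subtype) shares slope_i/Σslope_j sum to
one exactly. IAV is the mean absolute anomaly; anomalies are OLS-detrended
by default (trend and IAV are reported as separate quantities, so the IAV
should not re-count the trend; mean-removal is switchable for
sensitivity). IAV shares use f_i = Σ_t x_it·sign(X_t)/Σ_t|X_t|, defined on
any complete partition; years with X_t = 0 are excluded with a warning
(the index divides by X_t, and exact zeros occur only in constructed
data). Regional and subtype tables both derive from the single
region × subtype partition, so the two margins are consistent by
construction. Driver attribution is a sequential incremental-R²
partition, precipitation first, then temperature, remainder reported as
unexplained; the ordering convention matters and is configurable, and an
order-averaged variant would be the natural extension.

## Conversion accounting

The single most consequential bookkeeping choice: a cell crossing the
0.65 boundary into the drylands contributes its **full future GPP** to the
dryland ledger (its humid-era GPP was never dryland GPP), and a cell
leaving contributes **minus its full baseline GPP**; cells staying inside
contribute the ordinary difference. With this convention the 25 pathway
changes sum exactly to the net dryland GPP change, and percent shares
(pathway ÷ net change × 100) sum to 100% — the closure the ledger is
tested on. Shares are normalised by the *net* change, not the gross
positive change. The per-area decomposition defines, per year, the
historical group as baseline-dryland cells still dryland that year and
the expanded group as dryland cells that were humid at baseline; the two
partition each year's drylands, so group totals add exactly.

## Synthetic scenarios

The generator emulates the statistical structure the analysis needs, not
geography:

- 40 × 80 cells at 0.5°, eight rectangular pseudo-regions (2 × 4 blocks).
  Within each region AI rises smoothly ~0.02 → ~1.1 west-to-east, so all
  five classes are present everywhere.
- True GPP(AI) curves are mild per-region quadratics peaking near
  ~1 kg C m⁻² yr⁻¹ at the humid margin — the magnitude gridded GPP
  products show across the dryland gradient. Observation noise is
  Gaussian (sd 0.05 kg C m⁻² yr⁻¹) truncated at zero; truncation (rather
  than resampling) keeps the field physical but biases the mean upward
  where the curve sits within ~2 sd of zero, and the tests model that
  with censored-normal moments. Spatial noise correlation is a knob
  (default off — no value is asserted for it).
- Regional AI trends are weighted in space by a Gaussian bump centred at
  baseline AI 0.80 (width 0.20) plus a 15% uniform floor: drying
  concentrates along the dryland–humid margin, where expansion actually
  happens, while the floor produces in-dryland degradation and subtype
  conversions. A spatially uniform shift over a uniform AI density would
  make expansion gain and degradation loss cancel almost exactly — the
  margin weighting is what lets total dryland GPP rise while per-area GPP
  of historical drylands falls. The bump width is chosen so converted
  area scales roughly linearly with the trend; with the default trends
  the dryland area grows ~12% by 2085–2100 in the moderate scenario and
  ~23% in the high-forcing analog (whose trends are scaled by 23/11, the
  ratio of published end-of-century expansion rates).
- Interannual variability: coherent per-region AR(1) AI anomalies
  (ρ = 0.35) with amplitudes largest in Australia, South America and
  Africa, making those regions the ground-truth leaders of global IAV for
  rank-recovery tests. Temperature is correlated with the PET anomaly.
- Tower sites: 13 dryland cells; Reco ≥ 0 and NEE emitted as GPP + Reco so
  the partitioning identity GPP = NEE − Reco holds literally with
  GPP ≥ 0 (the printed form of the identity, with the respiration sign
  folded into NEE).

What the generator does **not** emulate: real coastlines and region
polygons, seasonality (all fields are annual), spatially varying PET
climatology beyond a constant base, lag effects, disturbance, and land
use. Passing tests therefore demonstrate the correctness and calibration
of the *method* — recovery of known curves, interval coverage, exact
closure of the accounting identities — not the realism of any particular
projected number.

## Numerical choices

- Cell areas: exact spherical integral R²Δλ(sin φ₂ − sin φ₁), so areas
  add exactly and are hemispherically symmetric; unit chain
  kg C m⁻² yr⁻¹ × km² → Pg C yr⁻¹ via 10⁻⁶.
- Classification boundaries implemented with closed-right `searchsorted`
  so AI = 0.05/0.2/0.5 fall in the lower class and AI = 0.65 is humid.
- AICc degree search skips rank-deficient designs; an all-equal-AI sample
  set is an error, as is a sample count below degree + 2.
- A zero-variance series in `bias_correct` gets a mean-only shift with a
  warning; a zero-variance response in `linear_trend` returns slope 0 and
  p = 1.
- Problem sizes in tests and drivers (a 3 200-cell grid, 101 years,
  200-replicate recovery runs, 10⁴-draw coverage and null-calibration
  simulations) are chosen so every statistical check has comfortable
  power while the whole suite stays interactive.

## Known limitations

- The conservative summed uncertainty band overstates the width of the
  regional 95% interval when cell errors are independent.
- Truncated GPP noise biases fits slightly upward in hyperarid cells
  whose true GPP is within ~2 noise sd of zero.
- The driver partition is order-dependent by design; reporting order
  follows the convention of precipitation first.
- Classification of a window by its mean AI (rather than per-year) makes
  subtype areas depend mildly on the window length.
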