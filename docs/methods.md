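# Methods

## Scope and design

`forestbenefit` quantifies the climate impact of alternative forest
management strategies for a single landscape by differencing cumulative
carbon uptake against a business-as-usual (BAU) reference.  The pipeline has
four stages: (i) simulate landscape carbon stocks and harvest flows per
5-year period over 150 years; (ii) propagate harvested carbon through
first-order-decay wood-product pools; (iii) convert harvested carbon into
avoided fossil emissions via a realized substitution level; (iv) assemble
per-scenario cumulative uptake and difference it against BAU.

The landscape simulator is an *emulator*: it reproduces the aggregate
behaviour of empirical stand simulators (age-structured growth, rotation
forestry, set-asides, fertilisation, residue extraction) without their
species-, site- and treatment-specific models, which are not publicly
printed.  Everything downstream of the growth function — mortality, harvest
scheduling, pool transfers, product decay, substitution, differencing — is
exact bookkeeping, and the per-period carbon balance closes to
floating-point precision.

## Landscape simulator

**State.** Stand area on a fixed age grid (class midpoints 2.5, 7.5, …,
147.5 y; the top class absorbs), split into a managed and a set-aside
cohort, each with a standing volume density (m³/ha) per class, plus
landscape-level deadwood and soil carbon pools.  Default landscape:
1,486,000 ha.

**Initial age structure.** Exponential over the grid with mean 51.7 y.
This choice is doubly anchored: it matches the target mean age, and it
independently places ≈10% of the area above 116 y, consistent with the
reported share of old stands withdrawn for conservation in the reference
landscape.

**Growth.** The potential yield curve is Chapman–Richards,
`V(a) = Vmax(1 − e^(−ra))^s` with `Vmax = 800 m³/ha`, `r = 0.01 /yr`,
`s = 2`.  Two scale factors are calibrated once at initialisation:

* `volume_scale` (β): initial standing volumes are `β·V(a)`, with β chosen
  so the area-weighted mean volume equals 149.6 m³/ha.  Standing volumes sit
  below the potential curve because managed stands have been repeatedly
  thinned.
* `increment_scale` (γ): the gross increment of a stand of age `a` is
  `γ·V′(a)`, with γ chosen so the area-weighted initial *net* increment
  (gross minus background mortality on the standing stock) equals
  5.53 m³/ha/yr.

The increment is decoupled from the standing-volume curve deliberately.
For an exponential age distribution with mean Ā, any model in which both
standing volume and increment derive from one curve forces mean increment
= mean volume / Ā ≈ 2.9 m³/ha/yr (integration by parts), which is
incompatible with the observed 5.53 at mean volume 149.6.  Real landscapes
escape the identity because harvesting keeps standing volume below
potential while site productivity stays high; the two-scale calibration
captures exactly that.  Class volume is capped at `Vmax`; with the default
shape old stands keep growing at 4–7 m³/ha/yr, so set-asides continue to
sequester for decades, as empirical models predict for boreal forests.

The calibrated BAU run realises 5.43 m³/ha/yr over 150 years (−1.8% vs the
5.53 target) and 5.55 over the first 50 years.

**Fertilisation.** A fertilised hectare keeps a ×1.15 increment boost for
10 years (two periods), so a scenario fertilising F ha/yr maintains 10·F ha
of boosted area.  The boost magnitude is a configuration default; the
sources print treated area and dose but no growth response.  Fast-growing
species planting is treated analogously: planted area accumulates over a
50-year residence and receives a ×1.10 increment multiplier.

**Mortality.** Uniform 0.5%/yr across ages, compounded within the period;
the flux (whole-tree carbon) moves to the deadwood pool.  This
deliberately understates today's elevated, age-dependent mortality — see
Limitations.

**Harvest scheduling.** The period target is
`harvest_target_fraction × net growth of ALL land` (set-aside growth
included), matching the prescription of harvest as a share of landscape
growth.  A fixed 30% of the target is thinnings, removed proportionally
from managed classes aged 20 y up to the rotation age (at most 30% of that
pool per period); the remainder is final felling of the oldest eligible
classes (age ≥ 80 y + the scenario's rotation delta), with partial felling
of the marginal class for an exact match.  When eligible area runs out the
shortfall is recorded on the harvest flow, not raised: this is what makes
realized harvest drop endogenously in set-aside and long-rotation
scenarios (e.g. −24% under 3× set-aside), reproducing the pattern that
realized intensities deviate from targets.  Felled area re-enters at age 0.

**Biomass partitioning.** Whole-tree carbon is 1.55× stem carbon
(slash 0.30, stump–root 0.25 of stem C); stem volume converts at
0.205 tC/m³ (0.41 t DM/m³ × 0.5 C fraction).  The widely quoted "1.3"
conversion between per-m³ and per-tonne substitution units is
unit-ambiguous in the literature and is therefore an explicit argument of
`substitution.convert_units`, not a hidden constant.  Slash and stumps are
extracted up to the scenario intensities (t DM ha⁻¹ yr⁻¹ over the whole
landscape area, C fraction 0.5); stumps are lifted only at final felling.
Unextracted residues enter the deadwood pool.

**Dead pools.** Deadwood decays first-order at 0.04 /yr; 20% of the decayed
carbon transfers to the soil pool (0.002 /yr).  Both pools use the exact
exponential update with continuous inflow,
`P' = e^(−kΔt)P + ((1−e^(−kΔt))/(kΔt))·I`, so a constant-rate fine-step
integration reproduces the trajectory to <0.1%.

**Order of operations** per period: grow → mortality → harvest (with
ageing) → pool decay.  The invariant `Δ(living+dead+soil) = gross growth −
extracted harvest − decay outflow` holds exactly; total area is constant.

## Wood products

Stemwood carbon is allocated 0.30 / 0.10 / 0.40 / 0.20 to sawn wood,
boards, paper & pulp and bioenergy (a documented default for the national
product mix; the underlying flow studies do not print a single share
vector).  Extracted slash and stumps route wholly to bioenergy.  Half-lives
are the IPCC defaults (35 / 25 / 2 y); the bioenergy class (half-life 0) is
released within the period of harvest.  Note the paper & pulp class decays
exponentially even though its half-life is below the period — only a
half-life of zero means immediate consumption.  Half-lives are per-scenario
configuration, so conventions that set paper to 0 y are reproducible.  The
update is the exact exponential, which makes the 35-y half-life identity
(50.000…% after seven 5-y steps) exact rather than approximate.  Reduced
harvest shrinks inflows proportionally across classes; the product mix is
assumed unchanged between scenarios.

## Substitution

The primary currency is the realized substitution level RS
(ton fossil C avoided / ton C harvested), which folds in the share of
harvest providing substitution.  Shipped presets: 0.42, 0.65, 1.30 (the
literature's sensitivity levels), 0.53 (mean of the three usage-based
estimates 0.42, 0.52, 0.65) and 0.9–1.1 (the band deduced for
high-substitution studies).  A DF + substituting-share pair is accepted as
an alternate entry path (RS = DF × share); specifying both paths at once is
refused.  Literature rows in which DF × share does not reproduce the quoted
RS reflect differing per-study accounting bases; RS is treated as
authoritative and never inferred from the other two columns.

## Climate ledger and benefit

All accounting is in tonnes C; CO₂ (×44/12) only at the reporting layer.
Ledgers are re-baselined to zero at simulation start.  Per period:
forest stock change + HWP pool change + RS × extracted carbon; the
cumulative sum is the scenario's uptake, and benefit = alternative − BAU,
so positive benefit means more atmospheric carbon removed or avoided.

Since RS multiplies the only RS-dependent term, benefit at any horizon is
affine in RS with slope equal to the cumulative harvest difference.
`deduce_substitution_level` solves
`RS = (target − B@RS=0) / (B@RS=1 − B@RS=0)` exactly (no iteration) and
refuses equal-harvest arms, where RS is unidentifiable.
`sign_change_year` reports the first period boundary at which a benefit
series turns negative after having been positive; series that start with a
brief negative dip (as set-aside scenarios do at high RS, when substitution
losses precede the stock build-up) are scanned from their first positive
period.

## What the emulator does and does not show

Passing the directional tests shows that the *accounting structure* —
substitution affecting reduced-harvest and intensified strategies in
opposite directions, and intervention magnitude controlling which strategy
wins — is reproduced under a calibrated but simplified forest model.  The
emulator's benefit magnitudes and crossing times are indicative only
(e.g. the 3× set-aside benefit at RS = 1.30 turns negative at year 70
here); empirical simulators with species- and site-specific growth, NFI
initial states and climate-driven growth trends will place these features
differently.  Realized harvest intensities in m³fub (under bark) are not
reproduced: the emulator works in m³ stem volume and is checked for
direction and calibration, not those exact values.

## Numerical choices

* 5-year time step, 30 periods; horizons must be multiples of 5 y.
* Exact exponential updates everywhere (no Euler error); mass-balance
  assertions at 1e-9 relative.
* Partial felling of the marginal age class makes the harvest match exact
  up to eligibility; ties are broken oldest-first.
* Scenario YAML rejects unknown keys; intervention ratios are rounded
  half-up to one decimal for reporting, with the exact quotient retained.
* The emulator is deterministic: identical configuration gives
  bit-identical output.

## Limitations

* Background mortality is uniform in age and calibrated to historical
  levels; elevated storm/drought/pest mortality in old stands would reduce
  set-aside benefits.
* Static demand: no market response, carbon leakage, or
  decarbonisation-driven decay of displacement factors.
* One landscape, one species aggregate, no climate effect on growth.
* Soil pool initialised empty and re-baselined; only the *change* in soil
  carbon enters the ledger, so absolute soil stocks are not meaningful.
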