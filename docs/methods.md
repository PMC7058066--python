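# Methods

## Model

The budget treats a city as twelve nitrogen reservoirs (subsystems) inside a
fixed boundary, exchanging N with four external pools: world trade, the
ocean, the surrounding atmosphere and a notional fixation source that feeds
biological, industrial (Haber–Bosch) and combustion fixation into the
system. Fluxes are annual, directed, nonnegative magnitudes in Gg N y⁻¹; a
bidirectional exchange is two records. For each subsystem and year the stock
change is defined as accumulation = inputs − outputs, and the system-level
budget counts only boundary-crossing flows. There is no sub-annual dynamics,
no spatially explicit transport, and no carry-over of stocks between years
beyond the reported annual accumulation.

Flux magnitudes come from a declarative sum-of-products grammar:
`value = Σ amount(activity) × parameter × multiplier`, with a small strict
unit table (g/kg/t/kt/Mt/Gg masses; capita, head, ha, km², m³ carriers).
Unknown or incommensurable units abort evaluation naming the term; silent
unit slips are the dominant failure mode in element budgets. The grammar is
linear by construction — saturating processes (e.g. volatilization limits)
cannot be expressed and are a known simplification. An evaluated flux
inherits the *worst* reliability grade among its terms.

## Uncertainty propagation

Inputs are graded high / moderate / low, mapping to coefficients of
variation 0.1 / 0.2 / 0.3. Each Monte Carlo trial multiplies every activity
amount and parameter value by an independent factor 1 + cv·z, with z
standard normal truncated below at −1/cv (so values stay nonnegative; the
truncated mass is ≤ Φ(−1/0.3) ≈ 4×10⁻⁴, leaving the first two moments
essentially unchanged). The truncated normal was chosen over a lognormal
because it matches the CV parameterization directly; the sampling routine is
isolated so a lognormal variant can be swapped in. No correlations between
inputs are modelled — a limitation, since shared statistical sources surely
correlate in reality.

Summaries report the ensemble mean, SD (ddof = 1), CV, and empirical 5th and
95th percentiles with linear interpolation, over 10,000 trials by default.
Seeding: one master seed expands to per-trial substreams via
`SeedSequence(seed, spawn_key=(trial,))`; each trial draws a multiplier for
*every* input, and the activity-only / parameter-only / full runs of the
uncertainty decomposition simply mask which multipliers apply, so the three
ensembles share draws and are directly comparable.

## Fate indicators

Fate fractions classify one year's boundary outflows plus terrestrial
accumulation as percentages of total input: denitrified N₂ (species-tagged
N₂ crossing the boundary), reactive atmospheric transfer, riverine transfer
to the ocean, trade outputs, and accumulation in the seven terrestrial
subsystems (farmland, livestock, forest, aquaculture, human, ground water,
urban green); a residual closes the budget. Percentages are rounded
half-away-from-zero at one decimal (zero decimals where integers are
customary) and the unrounded values are always retained, because several
published percentages differ from recomputation only through upstream
rounding of the fluxes themselves (e.g. the surface-water fraction computes
to 7.6 % where 7.7 % is in print, and the anthropogenic-creation share to
94.9 % where 95.0 % is in print). Anthropogenic creation excludes natural
biological fixation but includes its agricultural component.

Life-cycle traces (industrial and food chains) are label-driven: a chain
configuration maps ordered stages to flux labels and each stage is the sum
of its labelled fluxes. The human absorption ratio published for the food
chain has no stated denominator; it is stored as an annotated fixture
constant only, not recomputed.

## Driver decomposition

The extended STIRPAT regression `ln I = a + b ln P + c ln A + d₁ ln T₁ +
d₂ ln T₂ + e` is fitted by OLS on natural logs (the base is fixed and
documented because it must be applied consistently). Reported diagnostics:
t-values, p-values with the conventional star mapping (< 0.001 ***,
< 0.01 **, < 0.05 *), VIFs, R², plus adjusted R² and Durbin–Watson as
honest small-sample extras (21 annual observations against 4 predictors is
a short series). Rank-deficient designs raise a singularity error naming the
collinear pair. Annual growth rates are geometric (CAGR) over the full
window — the compounding form (1 + r)^β the effect coefficient uses implies
it. Contribution rates follow the normalization
100·|EC−1| / Σ|EC−1| · R² and therefore sum to 100·R² exactly; with the
published growth rates, elasticities and R² = 0.940 they come to
33.2 / 17.7 / 12.8 / 30.4 (sum 94.0), whereas the published table prints
34.10 / 18.06 / 13.25 / 30.51 (sum 95.92) — inconsistent with its own
footnote formula. The formula is implemented as stated; the printed rates
are kept as annotated constants and not reverse-engineered. The published
"other factors −0.274" row has no stated definition and is excluded.

## Synthetic city generator

The generator emulates the statistical structure the analysis assumes, not
any real city's magnitudes: 21 annual snapshots (1995–2015) in which every
activity follows an exponential trend times lognormal noise (default
σ = 0.03). Defaults encode the qualitative trajectory of a fast-growing
southern-Chinese megalopolis: population +2.35 % y⁻¹ (8.48 M → 13.5 M),
animal-source food share +0.46 % y⁻¹, energy intensity ≈ −3.5 % y⁻¹
(energy growing ~5 % y⁻¹ against GDP ~9 % y⁻¹), imports growing 5–7 % y⁻¹,
and farmland area, fertilizer, straw burning and livestock slowly
declining. Parameter values (N contents, emission factors, per-capita
rates) are set to round literature-scale magnitudes so headline fluxes land
in the tens of Gg N y⁻¹. Trend components depend only on the configuration;
noise depends only on the seed. Mass balance closes exactly every year by
construction because accumulation is *defined* as inputs − outputs.

What the generator does **not** emulate: cross-input correlations, policy
breakpoints (e.g. emission-control regimes bending the NOx series), realistic
closure of the industry and human stocks (both accumulate more than a real
city would), or any attempt to match real activity magnitudes beyond scale.
Tests passing on synthetic data therefore demonstrate correctness of the
accounting, propagation and regression machinery — not empirical fidelity to
any particular city.

## Worked-example fixture

The built-in Guangzhou fixture encodes only published aggregates: boundary
fluxes, subsystem accumulations, the driver table, and the handful of
internal fluxes reported in text (1995 fertilizer 52.3, 2015 wastewater
36.6, NOx 34.2 → 92.3, food-to-human 76.6, garbage 3.3 → 18.8,
surface-water inputs 17.2 → 47.2 Gg). The internal routing that per-subsystem
closure forces beyond those numbers consists of synthetic balancing flows,
marked `"balancing"` in the fixture's provenance map; they make no claim
about real routing. Published Monte Carlo percentile bounds enter only as
annotated constants (their underlying activity data are not public). Two
published inconsistencies are kept, not patched: the 1995 totals close at
142.5 − 99.2 = 43.3 Gg against a printed 44.7 Gg, and the import split
(food 61.5 / goods 50.4 in 2015) preserves the printed 111.9 total and the
printed 76.6 food flux rather than the separately printed industrial
throughput, which cannot be reconciled with them.

## Numerical choices and problem sizes

* Quantiles: empirical, linear interpolation (distribution-free).
* Percent rounding: decimal half-away-from-zero on the shortest decimal
  representation of the float.
* Degenerate inputs fail loudly: nonpositive denominators are domain
  errors; a compartment with no incident fluxes balances to zero with a
  logged warning; all effect coefficients equal to 1 make contribution
  rates undefined.
* Default study sizes: 10,000 Monte Carlo trials for calibration summaries,
  1,000–4,000 trials for decomposition and amplification studies, 1,000
  random networks in the conservation suite, and regression recovery at
  n = 21 (noiseless) and n = 100 (noisy, 2-SE check) — sizes chosen so the
  statistical tolerances quoted in the tests are comfortably resolved.
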