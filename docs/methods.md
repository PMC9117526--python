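# Methods

## The conversion model

A published food LCA value is a footprint per kg *as produced* at some
system boundary, usually cradle-to-farm-gate. The quantity a diet study
needs is the footprint per kg *as consumed*. The package converts between
the two with

```
FP_consumed = FP_farm_gate · e · 1/(1 − L) + S
```

* `e ≥ 1` — edible-fraction correction. Plant foods: `1/edible_portion`
  (the footprint of a whole banana is charged to its flesh). Animal foods:
  `1/boneless_ratio` on the study's mass basis — live weight or dressed
  carcass weight (ratios: sheep 0.33/0.67, chicken 0.65/0.75, beef
  0.46/0.83, pork 0.43/0.62, fish 0.54 live only). A food uses one of the
  two corrections, never both: they encode the same adjustment on
  different bases. The literature rarely states which basis a record used,
  so the basis is per-record metadata defaulting to `live`.
* `L` — total supply-chain loss proportion (production, post-harvest
  handling, storage, processing, transportation). Dividing by the
  *surviving* fraction `1 − L` is the physically meaningful reading of a
  loss correction: producing 1 kg eaten requires `1/(1 − L)` kg grown.
  Dividing by `L` itself (a ×6.6 inflation for rice) is dimensionally
  absurd; it exists only as an audit mode.
* `S` — post-farm-gate GHGE stage additions (processing, storage,
  transportation, packaging, preparation at home), kg CO₂-eq per kg as
  produced. Applied for GHGE only: post-farm-gate increases in water and
  land use are negligible, so those indicators keep `S = 0` (a nonzero
  value passed for WU/LU is coerced to zero and recorded in the audit
  trail). Stage additions are *not* inflated by `e` or the loss factor —
  the formula is applied literally.

### Loss cascades

Stage losses combine **additively** by default; this reproduces every
printed total of the loss table (e.g. rice 3.47+2.66+6.17+2.18+0.74 =
15.22%). A multiplicative mode (`1 − Π(1 − lᵢ)`), which treats each stage
as acting on the survivors of the previous one, is available for
sensitivity analysis and is always slightly smaller. Commodity-level rows
(Rice/Wheat/Corn, Pork/Beef/Mutton) take precedence over group-level rows
when a food carries a commodity tag; the Cereals and Meat groups have *no*
group-level row, so untagged foods in those groups fall back to the
unweighted mean of the group's commodity totals. Rows carrying only a
printed total (Eggs 10.5%, Beverages 5%, Liquor 5%) are used as given.

### Printed vs recomputed totals

Several printed stage-total cells are internally inconsistent with their
row sums (Meat 0.603 vs 0.300, Poultry 0.521 vs 0.218, Aquatic 0.350 vs
0.141, Beverages/Liquor 0.049 vs 0.088, Sugars 0.081 vs 0.206). Default
behaviour recomputes totals from the stage values — the six consistent
rows (Cereals 0.184, Legumes 0.230, Dairy 0.186, Eggs 0.180, Fats and oils
0.728, Tubers 0.032) validate exactly — and `totals="printed"` uses the
printed column verbatim, since both are defensible readings of the source.
Validation compares each row at an absolute tolerance of 0.01 on the
printed scale (kg CO₂-eq/kg for stages, percentage points for losses),
which classifies the 0.008-level vegetable/fruit and the 0.01-level
loss-rounding differences as `rounding` and everything larger as
`inconsistent`. Whether the anomalous meat total embeds an undocumented
correction cannot be resolved from the source; both numbers are
reportable.

### Cooking-energy model

Preparation-at-home GHGE = energy intensity × fuel emission factor.
Intensity is `(minutes/60) × rate / batch_kg`, with rate either a gas
burner draw (default 0.4 m³/h) or appliance power (rice: 0.9 kW cooker).
Cooking times: vegetables and legumes 2 min/500 g, meat 40 min/500 g,
aquatic products and poultry 20 min/kg, eggs 10 min/200 g, rice
35 min/500 g. Fuel emission factors are **required configuration** (the
source's numeric factors are not in its main text); a calibration helper
back-solves the factor implied by each published preparation cell — e.g.
cereals 0.109/(1.05 kWh/kg) ≈ 0.104 kg CO₂-eq/kWh, meat
0.175/(0.533 m³/kg) ≈ 0.328 kg CO₂-eq/m³. The implied gas factors are not
mutually consistent across groups (0.17–1.02), so the helper reports them
per group instead of fitting one global value. Groups without a cooking
spec (fruits, beverages, raw-eaten foods) contribute zero preparation
energy. The other stage parameters (processing, storage, transport,
packaging) are fixed per-group inputs; machine capacities and transport
distances behind them are documentation, not model inputs.

## Corpus statistics

Screening keeps records published 2005–2020 with a stated boundary and a
finite non-negative value; every rejection carries a machine-readable
reason and screening is idempotent. Summaries count distinct items,
distinct sources and record totals per group × indicator. Standard
deviations use the n−1 sample denominator (the source does not state its
convention) and are undefined for a single value; means are unweighted
across values by default, with an `across="items"` switch to average
item-level means instead, since the source is ambiguous on this point.

## Gap filling and provenance

Resolution order per food × indicator: own literature mean → direct
mapping (same food irrespective of form or grade; mapping chains resolve
transitively, cycles are errors) → processing variant (base value plus the
group's processing-stage addition) → recipe disaggregation → proxy
imputation. Proxy rules default to the land-use donors of the source
(tubers and fungi ← vegetables mean, nuts ← fruits mean) and are
extensible. Anything unresolvable is reported `unmapped`, never written as
a silent zero. Every result carries an ordered provenance trail of applied
transforms.

Recipes express raw ingredient kg per kg of composite *as consumed*
(the source does not fix the normalization; per-kg-composite composes
cleanly), with cooked→raw conversion `raw = cooked / yield` at ingredient
entry. Ingredient footprints are as-consumed totals, since the recipe's
output unit is per kg consumed. Nested recipes flatten exactly; cyclic
recipe graphs are rejected.

## Diet linkage

Person-day footprint = Σ grams/1000 × per-kg footprint, per indicator.
Unmapped intake is excluded with an itemized warning (optional group-mean
fallback); the report partitions 100% of intake mass into mapped +
unmapped so exclusions cannot pass unnoticed.

## Synthetic data

The generator emulates the four input kinds so the whole pipeline is
testable offline: a registry with composition-table-style codes covering
the 17 groups; a literature corpus whose per-group values are lognormal
(non-negative, right-skewed, the natural choice when only a mean and SD
are known) with moments matched to the published per-group summary table;
nested recipes; and an intake survey generated together with its
closed-form expected per-person footprints. Five percent of corpus records
deliberately violate a screening rule (year outside 2005–2020 or missing
boundary) to exercise the screen. All randomness derives from a single
root seed via per-stage child streams; a fixed seed gives byte-identical
outputs.

What the synthetic data does *not* emulate: real between-study
heterogeneity and method bias (process vs input-output LCA), correlated
values within studies, bibliographic duplication, or realistic food-code
structure. Passing tests therefore demonstrate that the *pipeline
arithmetic and bookkeeping* are correct under known ground truth, not that
any particular real-world footprint estimate is accurate.

## Problem sizes and numerical choices

The default test corpus uses the published per-group counts (~2,000
records over 51 group × indicator cells); parameter-recovery checks use
n = 500 values for one cell, asserting recovery within 3 standard errors;
formula-oracle equivalence uses 1,000 random draws at 1e-12 relative;
end-to-end diet linkage is checked at 1e-9 relative for a 50-person
survey. Degenerate inputs are handled explicitly: zero-SD targets produce
constant values, zero cooking minutes zero energy, empty corpora empty
tables (with a warning, not an error), all-absent stage rows are errors
where a total is demanded and `no_stage_detail` where only validated.

## Known limitations

* Waste-management / end-of-life stages are outside the system boundary.
* Import shares, regional recipe variation and study weighting are not
  modelled; values are unweighted averages of a national literature.
* The sugars-and-preserves loss row duplicates the vegetables row in the
  source and is transcribed as printed.
* Food codes are opaque strings; no numeric semantics are assumed.
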