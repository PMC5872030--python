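# Methods

## Scope and data flow

The package models the computational chain of a bloom-harvesting campaign:
jar-test dose selection → microbubble flotation → resource mass balance →
biomass characterisation (FAME profile, community diversity) → full-scale
techno-economic assessment. Measured inputs are small delimiter-separated
tables (dose–response grids, flotation time series, a two-column
physicochemistry table, FAME yield tables, OTU count tables) plus a YAML
parameter file for the scale-up/cost scenario. All percentages are carried
on the 0–100 scale; contents are mass fractions (g/g), converted from
µg·mg⁻¹ quotes at ingest (×10⁻³).

## Separation

**Removal efficiency.** `E = 100·(1 − C_t/C_0)` on any concentration proxy
(Chlorophyll *a* throughout). Measurement noise can push `C_t` marginally
above `C_0`; apparent negative removals within 0.5 percentage points are
clamped to zero, larger overshoots are treated as data errors. The 0.5 pp
default reflects replicate scatter typical of Chl *a* assays.

**Dose–response and dose selection.** Jar-test grids are coarse (here
1–9 mg/L chitosan) and not guaranteed monotone, so the curve is
piecewise-linear through the measured points with no smoothing and no
extrapolation. Two operating points are selected from the *measured* points
only: SE_max is the smallest dose whose efficiency is within 1 pp of the
grid maximum (replicate SDs are of that order, so near-ties go to the
cheaper dose); SE_sub-max is the dose nearest a user-supplied target
efficiency (default 70%), ties toward the lower dose. Selection is
invariant to input ordering and matches an exhaustive scan by construction.

**Flotation kinetics.** The data are sampled points; the fitted form
`E(t) = E_∞(1 − e^{−kt})` is the standard first-order flotation-rate model,
chosen as the minimal saturating curve with an interpretable plateau `E_∞`
(asymptotic harvesting efficiency, %) and rate `k` (min⁻¹). With exactly two
points the interpolating pair is found exactly by a bracketed 1-D root
search on `k` (the efficiency ratio `(1−e^{−kt₁})/(1−e^{−kt₂})` is monotone
in `k`); with more points, bounded least squares (`scipy.optimize.curve_fit`,
`E_∞ ∈ [0,100]`, `k ≥ 0`). An all-zero series short-circuits to
`E_∞ = 0`. Decreasing efficiencies beyond a 2 pp noise tolerance draw a
warning but still fit — skimming artefacts can re-suspend flocs.

**Paired comparison.** The classical paired *t* statistic with a two-sided
p from the *t* distribution. All-zero differences are a degenerate design
with no evidence of change; p = 1.0 by convention rather than scipy's NaN.

## Resource recovery

Standing stock is `kg = (g/L) × (m³)` over a photic-zone volume range.
Recoverable mass is `stock × content × efficiency/100` at full precision;
rounding (integer kg for lipids, 2 dp for phosphate and protein, mirroring
how such figures are conventionally reported) happens only in the report
table. The flotation efficiency measured on the Chl *a* proxy is applied to
bulk biomass — i.e. the model assumes pigmented and non-pigmented biomass
are removed alike, which overstates recovery if flocs are algae-enriched.
Protein may be derived from total nitrogen with the algal N-to-protein
factor 4.78; a derived fraction above 1 is rejected as an impossible
composition. No downstream extraction/purification losses are modelled.

## FAME profiling

Names follow the lipid shorthand `Cx:y[n-z][ cis|trans]`; the omega token is
accepted with or without a dash since supplier mix sheets vary. Zero double
bonds → SFA, one → MUFA, two or more → PUFA. Group yields are plain sums
(mg·g⁻¹ biomass) with a relative profile over total FAME mass; duplicate
species names are ambiguous and rejected. A replicate-count "true hit"
filter (default: detected in ≥3 replicates) screens long-format tables
before aggregation, averaging the yield over the replicates where a species
was detected.

## Community diversity

OTU counts aggregate to a chosen taxonomic rank parsed from
`k__;p__;...;g__` strings. A taxon keeps its own row if it reaches the
display threshold (default 1%, inclusive) in *any* sample — the rule that
keeps a taxon visible in every column of a stacked-bar figure once it clears
the threshold anywhere; the rest pool into "other". OTUs without an
assignment at the rank go to "unmatched", which is bookkeeping and never
pooled. Shannon diversity uses natural log (the ecological default; no base
was imposed by the data), with `0 ≤ H' ≤ ln S`, equality at a single taxon
and at uniformity. No rarefaction is applied before `H'`; sampling depths in
the intended use are similar across samples, and `H'` is scale-invariant for
proportional count changes.

## Scale-up and techno-economics

The design point is one pontoon module treating a 24,000 L batch. Air demand
scales linearly from the laboratory basis of 1 mL·min⁻¹ of air per litre
treated (24 L/min per batch). A compressor's free-air delivery derates to
~25% of nameplate at 3 bar(g); feasibility is derated flow ≥ demand, and the
flag flips exactly at equality. The batch cycle is fill + treat + drain
(48 + 30 + 48 = 126 min by default). Energy items cost
`kW × (min/60) × tariff` (default £0.15/kWh); flocculant costs
`dose × volume × price/kg` over the whole treated volume.

Whole-lake costing keeps `n_batches = total/batch` fractional — the ledger
is a costing view, not a schedule (a scheduling view should take the
ceiling). Per-batch OPEX figures supplied in the scenario file are taken as
given even where a power×duty×tariff derivation disagrees (the bundled
compressor line is such a case: £0.83/batch given vs £0.0825 derivable from
1.1 kW × 30 min; the given figure plausibly includes maintenance or duty
beyond the treat window, and both paths are implemented). The skimmer is
costed at 16 kW, the figure consistent with its quoted £1.20/batch. Currency
is rounded only at presentation. Solar sizing is
`n = ceil(load / (panel rating × derate))` for an explicit continuous load —
deliberately an argument, not the full equipment list, since which loads a
PV array should carry is a design trade-off.

Composite CAPEX items expand component lists (e.g. tank = 2 diffusers ×
£210 + £1000 vessel = £1420).

## Synthetic data

Generators mirror the statistical structure each stage assumes, with seeded
`numpy.random.default_rng` determinism:

* **Dose–response:** Hill curve `E(d) = e_max d^h/(ec50^h + d^h)` plus
  additive Gaussian noise on the percentage scale, clipped to [0, 100]. The
  Hill form is the minimal saturating family with a tunable steepness; the
  measured curves are saturating but come with no stated functional form.
* **Flotation:** the first-order model above, same noise treatment.
* **Community:** Dirichlet-multinomial counts; the expected share of the top
  taxon is the `dominance` parameter (a bloom ≈ 0.97, a recovered community
  ≈ 0.3), remainder spread evenly, Dirichlet precision 200 by default.
* **Composition:** truncated-normal (resampled into [0, 1]) around
  configured means; defaults are the case-study contents (lipid 0.1037,
  phosphate 0.00902, protein 0.32545 g/g).

What synthetic data does *not* emulate: dose–response non-monotonicity from
overdosing and floc restabilisation, autocorrelated flotation noise,
phylogenetically structured communities, or compositional correlation
between lipid/protein/P contents. Passing tests therefore demonstrate
correctness of the computations and estimator behaviour under the assumed
forms, not robustness to real-data pathologies.

## Numerical choices and problem sizes

* Exact unit factors (cfm→L/min = 28.3168); conversions round-trip to 1e-9
  relative.
* Kinetics/Hill recovery on noiseless data is exact to <1e-6; noisy-recovery
  checks use 6 time points, sd = 2 pp, 20 seeded replicates (median absolute
  `E_∞` error < 2 pp).
* Diversity contrasts use 10 taxa at 50,000 reads over 20 seeded replicates
  per dominance level — small enough to run in seconds, deep enough that
  multinomial noise is negligible against the dominance effect.
* Table delimiters are auto-detected from the header line (tab else comma);
  decimal separator is ".".

## Known limitations

Dose selection only ever returns measured doses (no interpolated optimum);
the TEA has no NPV/inflation, hydraulic or bubble-physics component; the
diversity module starts from an OTU table (clustering pipelines are out of
scope); the recovery model inherits the Chl-a-equals-biomass assumption
discussed above.
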