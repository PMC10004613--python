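# Methods

## Scope and model

`tracerisk` implements the deterministic, ingestion-route human-health
risk assessment used for heavy metals and trace elements in edible animal
tissue, applied here to six elements (Pb, Cd, Cr, Fe, Cu, Zn) in six
edible chicken body parts sampled from six urban markets (three chickens
per market, 108 part-samples per element).

The chain is: flame-AAS instrument readings → blank-corrected
concentrations → concentration summaries under an explicit
censoring policy → exposure and risk indices → regulatory screening.

### Quantification

A digested 1 g sample brought to 50 ml gives a dilution factor D = 50.
With instrument reading R (ppm) and batch reagent blank B,

    c [mg/kg] = max(0, R − B) × D / W.

Negative blank-corrected readings have no physical meaning; they are
clamped to zero and flagged per sample rather than propagated. The
calibration line (response vs. standard concentration, standards 0.0–2.0
mg/l, 0.0–0.5 mg/l for Cd) is an ordinary least-squares fit; a fit with
non-positive slope or r² < 0.995 is reported but flagged unusable. The
r² threshold is a conventional AAS acceptance level, configurable; no
value is prescribed by the study design itself.

Spike recovery is 100 × (spiked − unspiked) / added. Recoveries are
**reported, not applied**: the packaged concentration table combined with
the published intake tables shows no recovery correction in the original
arithmetic, so correcting would break reproduction. Dry/fresh basis
conversion is the mass balance c_fresh = c_dry × (1 − m) with tissue
moisture fraction m (muscle 0.7278, liver 0.6974 from gravimetric
estimates; other parts default 0.70, a placeholder since their moisture
was not measured).

### Censoring policy

Below-detection-limit (BDL) cells are handled under two explicit
policies: `zero` (censored values contribute 0 and count in the
denominator) and `omit` (excluded from mean, SD and denominator).
`zero` is the default for risk propagation — it is the only policy under
which the published across-market mean intakes (e.g. Cd) reproduce —
while `omit` is the default for concentration reporting. Min/max are
always over detected values. The policy is recorded in every summary. A
cell entirely censored under `omit` yields NaN with `n_detected = 0`,
never a silent zero. No distributional BDL imputation (e.g. LOD/√2 or
maximum-likelihood) is attempted: the reproduction target uses
substitution, and with ≤6 values per cell an imputation model would be
noise.

### Risk indices

For mean concentration MC (mg/kg fresh weight), daily food consumption
DFC = FIR (g/person/day) and body weight BW (kg):

- EDI = DFC × MC / BW, in µg/kg BW/day (g × mg/kg = µg).
- THQ = (EFr × ED × FIR × MC) / (RfD × BW × AT) × 10⁻³. The denominator
  grouping (RfD × BW × AT) is the only reading consistent with the
  published hazard table. With the default AT = EFr × ED this collapses
  to THQ = EDI × 10⁻³ / RfD, an identity the property suite checks to
  1e-12 relative.
- TTHQ = Σ_elements THQ per food item; HI = Σ_items TTHQ. THQ ≥ 1 and
  HI > 1 raise hazard flags.
- TCR = (EFr × ED × FIR × MC × CSFo) / (BW × AT) × 10⁻³ = EDI × 10⁻³ ×
  CSFo under the default AT. Elements without a slope factor (Fe, Zn)
  return a not-applicable result, not zero.

Defaults: adult DFC 17.4 g/day, BW 60 kg, ED 70 y; child 8.3 g/day,
27 kg, 14 y; EFr 365 d/y. RfDs (mg/kg/day): Pb 0.0035, Cd 0.001,
Cr 0.003, Fe 0.7, Cu 0.04, Zn 0.3. CSFo ((mg/kg/day)⁻¹): Pb 0.0085,
Cd 0.38, Cr 0.5, Cu 1.5.

Across-market aggregation of TCR defaults to **sum**: although such
values are often labelled "means", the published per-element totals are
arithmetically the sums of the six per-market risks (all eight values
verified), so `sum` reproduces them; `mean` is available behind a
warning. Lifetime-risk bands: [0, 1e-6) negligible, [1e-6, 1e-4]
acceptable (closed on both ends — the source defines only the strict
"less than"/"more than" outer bands, leaving the boundary points to the
middle band), (1e-4, ∞) unacceptable.

Risk tables are computed from muscle (meat) by default; any body part
can be selected. BDL market cells contribute 0 with the full market
count in the denominator of across-market means, which is the convention
the published intake table follows.

### Regulatory screening

Ten agencies' maximum-allowable-concentration limits are packaged, keyed
by tissue class. Body parts map to classes as muscle→meat,
liver/kidney→their own class when the agency prints one else offal,
gizzard/heart/brain→offal. An "offal" limit covers liver and kidney
unless a dedicated class exists. A blank agency×element cell is treated
as "no limit defined" and reported as such (a visible finding with no
limit), not as compliance by omission. Exceedance is strict: a
measurement exactly at the limit is compliant. The FAO/WHO Cu limit of
0.4 mg/kg is applied to every tissue class.

## Synthetic data generator

The generator emulates the full study: 6 markets × 3 chickens × 6 parts
× 6 elements, triplicate 1 g digests at dilution 50, a reagent blank of
0.005 ppm, and 2% multiplicative reading noise (a typical flame-AAS
repeatability level). Chicken-level concentrations are lognormal —
positive, right-skewed, SD comparable to the mean, as residue data are —
with per-cell (part, element) median and geometric SD obtained by
moment-matching the packaged market-mean table: for arithmetic mean m
and SD s, σ² = ln(1 + (s/m)²), median = m/√(1 + (s/m)²). Cells with
fewer than two detected markets fall back to geometric SD 1.5.

Noise is multiplicative on the whole instrument reading (signal plus
blank), not on the concentration, so blank subtraction and the zero
clamp are genuinely exercised downstream. Recovery samples are paired
spiked/unspiked triplicates whose noise-free recovery percent equals
exactly 100 × the configured true recovery (defaults are the six QC
recoveries the package targets). Detection limits are synthetic —
the instrument's true limits are unpublished — chosen once so that Cd
and Cr are censored most often, matching the qualitative censoring
pattern of the real table.

All randomness flows through one `numpy.random.Generator` seeded from
the config (derived streams offset the seed by small constants), so a
fixed seed reproduces the study byte-for-byte.

What the generator does **not** model: between-market covariance or
farm-level hierarchy (markets are independent), inter-element
correlation within a chicken, drift or carry-over in the instrument, and
matrix effects on recovery. Passing end-to-end tests therefore shows the
pipeline is self-consistent under the stated statistical model, not that
the model captures every feature of real market-basket data.

## Numerical choices

- Internal unit is mg/kg fresh weight; µg appears only in EDI and the
  10⁻³ factors convert µg-scale intake to mg where RfD/CSFo apply.
- Rounding happens only at serialization: EDI/THQ/TTHQ/HI to 3 decimals,
  TCR to two significant figures in scientific notation. All
  comparisons in tests use unrounded values with explicit tolerances.
- Summary SD uses ddof=1; a single included value gives SD 0.
- On a market-mean table, summary min/max are the min/max of market
  means (labelled as such); chicken-level ranges require chicken-level
  records.
- `assess` requires one record per market × element and rejects
  duplicates, directing chicken-level data through `summarize` first.

## Problem sizes in the test suite

The suite runs the full packaged 216-cell table everywhere it is cheap
(sub-second). Simulation-based checks use 200 chickens per cell for
lognormal parameter recovery (3 geometric-SE tolerance), 1000 draws for
the median-censoring check (±0.065 around 0.5, a ±4σ binomial band) and
for noisy reading recovery (0.5% relative), and 30 chickens per market
for the end-to-end generate→quantify→summarize→intake comparison (15%
relative, dominated by lognormal sampling error). These sizes keep every
check's sampling error well inside its tolerance.

## Known limitations

- Point estimates only: no Monte Carlo uncertainty propagation, no
  dermal/inhalation routes, no multi-food hazard index beyond treating
  markets as items.
- The packaged table carries market-level means; chicken-level spread
  enters only through the synthetic generator.
- Two published across-market summary cells (and the Badda muscle Fe
  intake) are internally inconsistent with the packaged concentration
  table and are documented rather than reproduced.
- Regulatory limits are a snapshot of the ten agencies packaged; the
  screen is not a live regulatory database.
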