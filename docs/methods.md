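# Methods

This note documents the models, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Sample model and screening

A survey is a tidy table with one row per well-season. Concentrations are
mg/L; EC is µS/cm; hardness is mg/L CaCO₃. Conversions to milliequivalents
use IUPAC atomic weights (Ca 40.078, Mg 24.305, Na 22.990, K 39.098,
HCO₃ 61.016, CO₃ 60.008, Cl 35.453, SO₄ 96.06, NO₃ 62.004 g/mol) and
absolute valences. Total hardness uses the standard identity
TH = 2.497·Ca + 4.115·Mg; a measured TH column, when present, is preferred
and never overwritten. Charge-balance error
CBE = 100·(Σcat − Σan)/(Σcat + Σan) (meq) is a QC statistic only; |CBE| > 10
is flagged, not rejected, because survey reports frequently publish
unbalanced analyses.

Guideline screening uses strict `>` against each limit, so a value exactly
at its limit passes — this matches the "higher than the permissible limit"
reading of survey reports. The pH band 6.5–8.5 is inclusive on both ends.
Default limits are the common drinking-water values (NO₃ 50, TH 500, BOD 5,
COD 20, Ca 200, TDS 1000 mg/L, EC 1500 µS/cm, plus Mg 150, Na 200, K 12,
HCO₃ 500, Cl 250, SO₄ 250 for completeness); all are configurable through a
YAML standards file. Missing values are reported as "not screened", never
silently passed. Percentages round half-up to two decimals.

## Chadha facies diagram

x is the meq-% difference (Ca+Mg) − (Na+K) over total cations; y is
(CO₃+HCO₃) − (Cl+SO₄) over the sum of those four axis anions (nitrate does
not enter the diagram). Quadrants give the primary water type: (+,+) field 5
Ca-Mg-HCO₃ (temporary hardness), (+,−) field 6 Ca-Mg-Cl (reverse ion
exchange), (−,−) field 7 Na-Cl, (−,+) field 8 Na-HCO₃. The overlapping
half-plane fields 1–4 (alkaline earths / alkalis / weak acids / strong
acids dominant) are exposed as boolean flags rather than competing classes,
since they are implied by the signs of x and y. Points exactly on an axis go
to the positive side. Samples whose |y| falls within a small band (5 meq-%
by convention) sit near the anion equiline and are the ones survey reports
sometimes group with the "alkaline earths exceed alkalis" field rather than
a quadrant.

The TDS–TH water-class quadrant splits soft/hard at TH 180 mg/L and
fresh/brackish at TDS 1000 mg/L, boundaries going to the upper class. A
`paper_mode` flag drops the TDS split and labels everything brackish,
because regional reports sometimes class low-TDS hard waters as "hard
brackish" on the hardness axis alone; the conventional split remains the
library default.

## Ratio diagnostics

Ratios are molar (computed from mg/L via molar masses) except
(Ca+Mg)/(HCO₃+SO₄), which is on the equivalent scale as used on
carbonate/gypsum equiline plots. Zero denominators produce null-with-reason
entries, never infinities, and nulled axes contribute no source label.
Label rules: Na/Cl > 1 → silicate weathering / cation exchange; < 1 →
anthropogenic input / reverse exchange; (Ca+Mg)/(HCO₃+SO₄) above 1 →
carbonate dissolution dominant, below 1 → silicate influence, within ±5 % of
1 → mixed carbonate+evaporite dissolution (the band operationalises
"falling close to the equiline" and is configurable); Ca/HCO₃ within
[0.25, 0.5] → carbonic-acid-driven calcite dissolution (between the 1:4 and
1:2 lines). End-member attribution on Na-normalised mixing plots uses
nearest-neighbour distance in log-ratio space to the classic global
riverine end-members (carbonate Ca/Na ≈ 50, Mg/Na ≈ 10, HCO₃/Na ≈ 120;
silicate Ca/Na ≈ 0.35, Mg/Na ≈ 0.24, HCO₃/Na ≈ 2); this is a reconstruction
of diagram group membership, clearly not a measured quantity, and the
registry is replaceable.

## EWQI

Weights are computed **per run** — per season and per well subset — so each
evaluation matrix speaks for itself; weights are never shared across
seasons. Conventions chosen for degenerate cases: 0·ln 0 := 0 in the
entropy sum; a constant column gets e_j = 1 and weight 0 (a no-information
parameter should not influence the index, and this avoids 0/0 in the
proportion matrix); an all-degenerate matrix is an error. The pH rating
uses S_pH = 8.5 above neutral and 6.5 below, with q_pH = 0 at exactly 7
(the limit of both branches). Rank thresholds are 25/50/100/150 for ranks
I–V; this is the standard five-class scheme and the only one consistent
with scores near 95 classing as moderate (III) and near 120 as poor (IV).
Scores are reported to two decimals.

## Health risk

CDI = C_w·IRW·EF·ED/(BW·AT) collapses to C_w·k with the effective ingestion
rate k = IRW·EF·ED/(BW·AT) in L/(kg·day); HQ = CDI/RfD with RfD =
1.6 mg/kg/day for nitrate; HI = Σ HQ (equal to HQ here, nitrate being the
only contaminant, but implemented as a sum). Categories are left-closed at
0.1, 1 and 4. Because full exposure quintuples for a given survey are often
unavailable while headline HI values are printed, default profiles are
specified by calibrated effective rates anchored at a reference
concentration: adults k = 1.45·1.6/61 ≈ 0.0380, children 1.80·1.6/61 ≈
0.0472, infants 1.91·1.6/61 ≈ 0.0501 L/(kg·day). The calibration is
validated by prediction: HI is linear in concentration for fixed exposure
parameters, so rates calibrated on wet-season anchors must reproduce
dry-season HI statistics at dry-season concentrations — the acceptance
script exercises exactly this. A user-supplied IRW/EF/ED/BW/AT quintuple
overrides k.

## IDW mapping

All sample points are used (no search radius) with weights d^−p, default
p = 2; a query within 1e-9 coordinate units of a sample returns that
sample's value, making the surface an exact interpolator. None of these
settings is canonical — GIS defaults vary — so all are parameters. The
estimate is a convex combination of the data, hence bounded by the data
range, and translation-invariant. Grids are planar (no CRS), written as
ESRI ASCII with nodata −9999; classification uses the same left-closed
boundary convention as the EWQI ranks and HI categories, so classifying a
raster commutes with classifying each value.

## Synthetic survey generator

The generator emulates the *summary structure* of a 27-well, two-season
survey: per-parameter min/max/mean per season, target NO₃–Cl Pearson
correlations (0.16 wet, 0.64 dry), a positive NO₃–TDS association (0.45
both seasons; only the direction of that association is documented in
surveys of this kind, the value is a realistic choice), and named-well
roles — seven nitrate-exceedance wells per season, three wet-season
hardness-exceedance wells, one soft well holding the dry-season hardness
minimum (174.282 mg/L). Mechanics:

- **Marginals**: scaled Beta on [min, max] with the Beta mean matching the
  target mean and concentration a+b = 4 (moderately dispersed, unimodal —
  a generic choice for bounded environmental variables).
- **Dependence**: a Gaussian copula over (NO₃, Cl, TDS); the copula
  correlation is calibrated by a cached, deterministic fixed-point
  simulation of the generator's own n = 27 pipeline (including the
  stratification below), so that the *mean sample Pearson r across surveys*
  hits the target. Other parameters are independent.
- **Role constraints**: a piecewise-linear, rank-preserving squeeze of the
  copula uniforms places exactly the k largest draws above the exceedance
  boundary; whole copula rows are then assigned so the named wells receive
  the exceeding values. Rank preservation is what keeps the imposed
  correlation intact despite the forced counts.
- **Mean matching**: a bounded power transform on the unit interval (exact,
  monotone, bound-preserving) nudges each season's sample mean onto the
  target; for stratified columns only the below-boundary stratum is
  transformed so exceedance counts cannot change. This is a generator
  artifact, not a data claim.
- **Geometry**: wells keep the same coordinates and depth in both seasons;
  the high-nitrate named wells cluster in the north-west corner of the
  bounding box so interpolated quality and risk maps show one concentrated
  at-risk region, qualitatively like urban-contamination surveys.

A fixed seed produces a byte-identical CSV. What the generator does *not*
emulate: real spatial autocorrelation of chemistry (only the NW clustering
of high-NO₃ wells), inter-ion mass-balance coupling (TH is generated from
its own printed marginal rather than from Ca and Mg, so the survey-level
charge balance is as unbalanced as the published means imply), seasonal
within-well persistence beyond shared geometry, and measurement error.
Passing tests therefore demonstrate correctness of the *methods* on data
with the documented summary structure, not validity of any conclusion about
a real aquifer.

Na/K summary statistics in the emulated survey are internally inconsistent
in the source report; the generator uses Na 9–68 mg/L (means 32.41 wet,
33.41 dry) and K 0.30–1.90 (mean 1.09, wet) / 0.30–3.06 (mean 1.27, dry),
the only assignment compatible with the printed cation abundance order.

## Problem sizes and determinism

The test suite runs the full two-season generator across 200 seeds for the
correlation-recovery check (a few seconds; the calibration is computed once
per process and cached), 100 random matrices for EWQI oracle equivalence,
and 20×20-cell rasters for IDW oracle equivalence. All randomness flows
from explicit seeds; hypothesis property tests run derandomised.

## Known limitations

- The Chadha half-plane grouping of near-equiline samples is a band-width
  convention; diagram-based group memberships are not exactly recoverable
  from summary statistics.
- End-member mixing attribution depends entirely on the configured
  end-member registry.
- Exposure profiles expressed only as effective rates cannot be decomposed
  into unique IRW/EF/ED/BW/AT quintuples.
- No speciation or equilibrium chemistry (no saturation indices), no
  kriging, no dermal or carcinogenic risk pathways, no uncertainty
  propagation on exposure parameters.
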