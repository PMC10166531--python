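# Methods

## The accessibility model

Accessibility is modelled as nearest-facility network driving time on a
fixed origin–destination matrix: areas × hospitals → hours. The matrix is
treated as a directed area→facility lookup; no symmetry or time-of-day
structure is assumed, and no distance is ever computed from geometry (the
matrix stands in for a road-network measure, which Euclidean or Manhattan
distance would misrepresent in sparsely populated regions). Coordinates are
WGS84 lon/lat throughout and are used only for drawing and for the synthetic
generator; no projected CRS is needed.

Given an open clinic set `C`, an area's time is `d(a,C) = min_{c∈C} t(a,c)`,
ties broken by lexicographically smallest facility id so results are
reproducible. Every patient inherits the time of their residential area —
the published per-patient statements ("x% of patients within 1 hour") are
derived from area-level times, which forces this convention. Three
statistics summarise a clinic set per scope (All, GreaterSydney, ACT,
RestOfState):

- `% within threshold`: share of *covered* patients with `d(a,C) <
  threshold`, strictly — an area at exactly the threshold is outside,
  matching the "less than one hour" phrasing. Threshold defaults to 1.0 h.
- `mean`: patient-count-weighted mean of area times over covered patients.
- `max`: maximum area time over areas holding ≥ 1 in-scope patient. (Taken
  over patient-bearing areas, not patients; identical whenever every such
  area has a patient, which is the case by construction.)

**Missing travel data.** An area with no matrix entry for any facility is
"uncovered" (the grey areas of the original maps). Its patients are excluded
from all three statistics and reported as a separate count; missing times
are never imputed (treating them as infinite would let data gaps masquerade
as inaccessibility). Missingness in the source dataset is area-level: an
area either has driving-time data or it does not. The monotonicity
guarantee — adding clinics never lowers coverage and never raises any
area's time, the mean, or the max — holds under area-level missingness,
because the covered denominator is then invariant to the clinic set. With
hypothetical per-pair gaps, a newly covered far area could raise the mean;
the per-pair case is supported by the lookup API but is not the modelled
regime.

**Clinic reach tables** count patients (and lost-to-follow-up patients)
within the threshold of one specific facility, ignoring all others. Rows
deliberately overlap across clinics; assignment-based partitioning is what
`nearest_clinic_time` provides.

**Candidate evaluation** recomputes every summary for `C ∪ candidates`
(candidates must be disjoint from `C`) and reports per-scope deltas.
`rank_candidate_hospitals` is a reproducible stand-in for a planner
hand-picking sites off the map: iteratively take the covered, patient-bearing
area in scope with the longest current time and open the closest eligible
hospital that strictly improves it. It is a demonstration heuristic;
p-median/max-cover optimisation is out of scope.

## Cohort selection and derived flags

The selection flow retains patients who (a) are adults at the study window
end, (b) have an address linkable to an in-scope area, and (c) attended at
least once inside the window. Exclusions are counted first-match in the
fixed order age → address → encounter (the source flowchart is sequential
but does not fix the order of the last two; one fixed order keeps counts
well-defined). "Adult" is calendar age ≥ 18 at the window end: a patient
whose 18th birthday falls exactly on the window end is included. Elsewhere
ages and gaps are converted at 365.25 days/year; no day-count convention was
given, and the choice only moves third-decimal values.

Area linkage: an exact (postcode, suburb) concordance match wins; among
multiple rows the highest population weight wins, ties broken by smallest
area id, with every ambiguous linkage logged for audit (standing in for the
manual address-cleaning step of the original workflow). A postcode-only
fallback applies only when the suburb is missing; a present-but-unmatched
suburb leaves the record unresolved rather than guessing.

Follow-up is referenced to the window end for living patients and the date
of death for deceased patients, so a patient who died a year after their
last visit is not "lost" no matter how old the death is. Lost to follow-up
means a gap strictly greater than 3.0 years ("longer than three years");
an exact 3-year gap is retained. The alive/deceased distinction is purely a
filter — deceased patients keep the death-date reference even when a filter
restricts the view to living patients.

Attendance-period notes: "encounter within the study period" is implemented
as clinic attendance dates, the only encounter type carried in the data
model. The demographic summary reports sample SDs (n−1); undefined moments
(n ≤ 1) are reported as missing, never NaN.

## Privacy model

Two output branches: private (identity) and public. Public mode replaces
every displayed patient count in (0, threshold) — area totals, severity and
diagnosis breakdowns, lost-to-follow-up counts, per-clinic table cells,
selection-flow and summary-table Ns — with a sentinel serialized as the
string `"masked"`, never a number. The threshold defaults to five
("below five individuals"); zeros are displayed, since a zero describes no
individual. Where a severity breakdown is published next to its displayed
total, a single masked cell would equal total minus the displayed siblings,
so the smallest remaining non-zero sibling is masked too (complementary
suppression). Diagnosis counts carry no total constraint (patients can have
several diagnoses) so primary suppression suffices there. Masking is
idempotent. Accessibility percentages, means and maxima are *not* masked in
public mode, matching the publicly deployed figures; per-clinic count cells
are masked by default but the policy flag `mask_clinic_tables` makes that
configurable, since the source is silent on that table. Drive-time layers
carry no patient information and always pass through.

## The synthetic world

The generator emulates the *structure* of the real inputs, not their
geography. Areas are square cells on a grid with a designated city corner.
Remoteness classes are distance-rank blocks from that corner matching the
configured mix; the default mix is the published state population shares
(74.45 / 19.02 / 6.03 / 0.42 / 0.08 % across the five ARIA classes). The
capital-territory region is a compact block of cells around an anchor at
~55 % of the grid diagonal with its own clinic at the block centre; the
metro region is the block nearest the corner (35 % of areas by default) and
the rest is rest-of-state. IRSD deciles are uniform 1–10; Indigenous
population percentage is drawn with a higher base in remoter classes
(1.5 / 4 / 8 / 15 / 30 % times lognormal noise); populations are
N(10000, 2000²) clipped at 500.

Travel time is `centroid km × winding factor (1.3) / speed (80 km/h) +
lognormal noise (scale 0.05 h)`; with the noise scale at zero times are
exactly linear in distance, which the tests exploit. A configurable fraction
(default 10 %) of Remote/VeryRemote areas lose all matrix entries to emulate
the grey no-data areas. Facilities sit at area centroids: 4 current clinics
(3 at the city corner, 1 in the capital block) and 36 candidate-eligible
hospitals spread evenly along the distance ranking, 40 sites in all.

The cohort defaults are the published study-population marginals: n = 3056,
mean age 43.70 (SD 16.65), 49.21 % female, severity mix 1230/894/456/476,
per-severity attendance means 2.29/4.27/5.86/1.9, per-severity
lost-to-follow-up 68.13/34.00/21.71/4.62 % (which reproduces the overall
41.33 %). Two source figures conflict on the attendance SD (2.29 in the
text vs 3.35 (2.80) in the summary table); the table values are used.
Specifics of the mechanism:

- **Ages**: normal truncated at 18. Truncation shifts a distribution's
  mean, so the pre-truncation location is calibrated by root-finding
  (`scipy.stats.truncnorm` + `brentq`) so the realised mean equals the
  target; the realised SD is then slightly below the nominal 16.65.
- **Attendance counts**: `1 + Poisson(mean − 1)` — keeps the target mean
  while guaranteeing the ≥ 1 visit the selection flow requires.
- **Care gaps**: a two-component mixture — recent `U[0, 2.99)` vs lost
  `U(3.01, 15]` — with the mixing weight equal to the per-severity
  lost-to-follow-up target; the small gap around 3.0 keeps day-rounding
  from crossing the strict threshold. The gap is anchored at the death date
  for the deceased fraction (12.3 %, the deceased share implied by the
  published selection counts).
- **Placement**: patients land in areas proportional to population ×
  0.8^(remoteness rank) (a mild rural thinning). Severity and remoteness
  are independent by default; an interaction knob can shift severe cases
  ruralward, as no joint distribution was published.
- **Contamination**: minors (2 %), unmappable postcodes (1.5 %) and
  records with only pre-window attendances (1 %) are appended to exercise
  the selection flow; their counts are exact by construction so flow tests
  can predict them.

Everything is driven by `numpy.random.default_rng` seeded from the config,
and file outputs are written with sorted keys, so identical configs give
byte-identical bundles.

**What the grid world does not emulate.** Real metro areas are small and
dense; grid cells are uniform, so the synthetic "major cities" band spans
hours of driving and absolute coverage percentages (e.g. ~13 % of patients
within 1 h of the default 4 clinics) sit far below the real service's
(~83 %). Qualitative structure is preserved — metro > rest-of-state
accessibility, full capital-territory coverage, rural candidates strictly
improving rural coverage/mean/max — and that structure, not the absolute
level, is what the tests assert. Spatial autocorrelation of disease
prevalence and realistic polygon shapes are likewise out of scope.

## Reporting

The report is a pure function of a serializable `ToolState` (filters, scope,
layer, clinic sets, focus areas, privacy policy, threshold) plus the loaded
inputs: every table is recomputed, nothing is cached, and identical inputs
yield byte-identical bodies (the provenance timestamp lives outside the
body). Sections are fixed: Patient Data, Area Data, Current ACHD Clinics,
New ACHD Clinics, Area Focus; the original section list names a singular
"Current ACHD Clinic", implemented as one section covering all current
clinics. Area Focus panels accumulate in selection order and always show
area attributes (IRSD, remoteness, Indigenous %, population) — these
describe the area, not patients — while masking patient counts per policy.
All numbers are injected from typed results into the Markdown template-free
renderer, so the privacy audit can enumerate every displayed count cell
(`Report.count_cells`).

## Numerical and degenerate-input conventions

- Empty cohort: summaries report N = 0 with missing moments, not an error.
- Zero covered patients in scope: statistics reported missing, no NaNs.
- Facility without any matrix column: reach row of zeros plus a warning.
- Attendances after the follow-up reference clamp the gap to 0 with a
  warning.
- Scales chosen for the default world (192 areas, 40 facilities, 3056 + 138
  records) keep a full generate→select→aggregate→evaluate→report cycle
  under two seconds, so the whole pipeline is exercised at full size in
  tests.

## Known limitations

- The border assumption is inherited from the source setting: patients are
  assumed not to cross state borders for care.
- Reach and coverage operate at residential-area granularity; within-area
  heterogeneity is invisible.
- The candidate picker is a greedy demonstration device, not an optimiser.
- Severity is an input field (clinician-assigned anatomic complexity); no
  classification algorithm is implemented.
- Masking guards against exact subtraction recovery within one area's
  severity/total split; it does not provide formal differential privacy, and
  cross-table or longitudinal differencing attacks are out of scope.
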