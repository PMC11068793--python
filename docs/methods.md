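# Methods

## The classification model

`periodx` implements the 2017 AAP/EFP classification of periodontal and
peri-implant conditions as a deterministic rule system over a full-mouth
chart and a patient profile. The primary diagnosis is resolved in a fixed
order; the identifiers of every fired rule are appended to the report so
any diagnosis can be audited step by step.

**Case definition.** A dentition is a periodontitis case when it has
interproximal CAL ≥ 1 mm on at least two non-adjacent natural teeth
(the interdental rule), or buccal/lingual CAL ≥ 3 mm on at least two
teeth (the buccal/lingual rule). CAL is probing depth plus signed
recession; recession is positive when the gingival margin lies apical to
the cemento-enamel junction. Adjacency uses the Universal numbering
system: consecutive numbers within one arch, so teeth 16 and 17 are not
adjacent. The interdental rule takes precedence when both fire.

**Stage.** Severity comes from the worst interproximal CAL (with a
fallback to the worst mid-facial CAL for a purely buccal/lingual case):
1–2 mm → I, 3–4 mm → II, ≥ 5 mm → III. Complexity factors — any probing
depth ≥ 6 mm, furcation involvement class ≥ 2, or a charted vertical
defect — raise the stage to at least III regardless of the CAL band.
A stage that has reached III becomes IV when ≥ 5 teeth have been lost to
periodontitis, fewer than 20 natural teeth remain, or masticatory
dysfunction is recorded. The returned stage is the maximum of the
severity and complexity readings; complexity and the stage-IV
discriminators only raise, never lower.

**Grade.** Indirect evidence is the ratio r of worst percentage
radiographic bone loss to age in years: r < 0.25 → A, 0.25 ≤ r ≤ 1.0 → B
(both endpoints grade B), r > 1.0 → C. Risk modifiers upgrade and never
downgrade: smoking ≥ 10 cigarettes/day → C, 1–9/day → at least B;
diabetes with HbA1c ≥ 7.0% → C, diagnosed diabetes with lower or unknown
HbA1c → at least B. Grading requires at least one recorded bone-loss
value; charts without any raise a "grading evidence missing" error rather
than guessing.

**Extent.** The affected-tooth set is the natural teeth carrying the
case-defining interproximal attachment loss. If that set is confined to
first/second molars and incisors with both groups represented, the extent
is the molar-incisor pattern, taking precedence over the fraction rule;
otherwise the fraction of affected over scorable teeth decides
(< 30% localized, ≥ 30% generalized).

**Non-cases.** A dentition that fails the case definition is graded on
gingival status: bleeding on probing at < 10% of probed sites is clinical
gingival health — on an intact periodontium when no attachment or bone
loss exists anywhere, on a reduced periodontium otherwise — and ≥ 10% is
gingivitis, annotated generalized above 30%. Implants are classified
independently: no inflammation → peri-implant health; bleeding or
suppuration without progressive bone loss → peri-implant mucositis;
progressive radiographic bone loss → peri-implantitis. A chart with no
natural teeth takes its primary status from its worst implant.

All thresholds above live in `src/periodx/data/clinical_constants.json`
and are read at run time by both the engine and the question tree, so a
future revision of the classification is a data edit.

### Design choices where the rules were genuinely open

- *CAL convention.* CAL = PD + signed recession, integer millimetres.
  Probes read in 1 mm increments; integer arithmetic keeps every boundary
  test exact.
- *Missing measurements.* An unmeasured site is simply absent from the
  chart and is excluded from maxima and from the bleeding denominator;
  nothing is imputed. A natural tooth therefore carries 1–6 uniquely
  labelled sites (implants 4–6).
- *Severity site selection.* The stage reads the single worst
  interproximal site. A "worst site" reading is the only one consistent
  with publishing severity as CAL/PD threshold pairs.
- *Attribution of CAL.* The classification restricts the case definition
  to attachment loss of inflammatory periodontal origin. The chart format
  carries no attribution field; all recorded CAL is treated as
  periodontal, and non-periodontal causes are expected to be excluded at
  charting time. This is a known simplification.
- *Flag-based secondary rules.* The six secondary categories are pure
  functions of explicit chart flags plus thresholds (e.g. an
  endodontic-periodontal lesion requires the endodontic flag *and* a
  pocket ≥ 6 mm on the same tooth; occlusal trauma requires fremitus,
  widened PDL or mobility ≥ 2). Clinical judgement is pushed into the
  charting, keeping the rules auditable.

## The question tree

The shipped tree (`data/default_tree.json`, ~130 nodes) encodes the same
logic as a guided questionnaire: case definition → extent → CAL severity
band → complexity factors → stage-IV discriminators → grade, with side
branches for gingival status and implants. Question nodes carry an info
text (the expandable "information icon") and a machine-readable predicate
identifier; `auto_answer` resolves each predicate from the chart summary
and profile, so tree and engine can be cross-checked mechanically. The
tree is a rooted DAG — paths converge on shared downstream questions —
validated for dangling references, unreachable nodes, cycles, questions
with fewer than two answers and leaves without treatment suggestions.
The JSON file is generated from `build_default_tree()` and a test pins
the shipped file to the programmatic build, so the two cannot drift.

## The synthetic cohort generator

`chart_for_diagnosis(label, seed)` inverts the rules: it chooses the
affected teeth, sets their interproximal CAL and PD inside the target
stage band (keeping PD below 6 mm when the stage must stay below III),
sets the worst bone-loss/age ratio inside the target grade band with no
upgrading risk factors, and sizes the affected set for the target extent
(forcing a canine into sets that would otherwise mimic the molar-incisor
pattern). Stage IV charts lose five teeth to periodontitis while keeping
at least 20. Randomness touches only non-determining detail: which teeth,
probing-depth jitter within band, bleeding placement. Rule inversion
rather than rejection sampling guarantees coverage of labels that are
rare in practice (the molar-incisor pattern appeared once per 150
patients in the reference cohort).

Default cohort frequencies reproduce a 150-patient teaching-clinic
population: the 18 tabulated periodontitis labels weighted by their
printed frequency column (renormalized; its rows sum to 151 against a
printed total of 150, which renormalization makes irrelevant), and
secondary-condition rates of 129/150 (tooth/prosthesis factors), 118/150
(occlusal trauma), 52/150 (mucogingival), 49/150 (systemic), 18/150
(endo-periodontal) and 13/150 (abscess). Secondary conditions are
injected through flags chosen never to perturb the primary label; the
endo-periodontal lesion, which needs a ≥ 6 mm pocket, is only injected on
charts whose stage permits one, so its realized rate sits slightly below
nominal on health-dominated cohorts.

What the generator does *not* emulate: spatial correlation of pocketing
across neighbouring sites, measurement error and examiner disagreement,
partially erupted or supernumerary teeth, longitudinal change, and any
correlation between stage and patient age beyond the grade construction.
Passing round-trip tests therefore demonstrates the internal consistency
of rules, tree and generator — not field performance on real charts.

## Accuracy scoring and the signed-rank test

Accuracy tables follow the "correct/total (percent)" convention with rows
per gold-standard label, columns per training-year group, pooled margins,
half-up rounding to a caller-chosen number of decimals, and an undefined
marker "(–)" for empty denominators. Primary correctness is an exact
match of (category, extent, stage, grade). Secondary conditions are
scored per *diagnosis incident* — one gold secondary condition on one
patient — because the reference denominators (379 incidents over 150
patients) count incidents, not patients.

The Wilcoxon matched-pairs statistic is W+, the rank sum of positive
differences after zeros are dropped (all-zero input is degenerate with
p = 1 by convention). For n ≤ 25 without ties in |d| the two-sided
p-value is exact: the null distribution of W+ is built by convolution
over sign assignments and p = min(1, 2·min(P(W ≤ w), P(W ≥ w))). With
ties or larger n, mid-ranks and the normal approximation with tie
correction are used (no continuity correction, matching the common
reference implementations). The exact path is verified in the tests both
against brute-force enumeration of all 2^n sign assignments and against
an independent library implementation.

## Power simulation

The paired design question — how many participants make a 10-point
accuracy improvement detectable — is answered by Monte Carlo: each
replicate draws n paired differences from Normal(true_difference = 10,
sd = 10) percentage points and applies the exact two-sided signed-rank
test at alpha = 0.01; power is the rejection fraction over reps = 10,000
replicates (Monte-Carlo SE ≈ 0.005 near power 0.5). Rejection uses
p < alpha. Continuous draws make ties and zeros almost surely absent, so
the exact null CDF is computed once per n and the whole simulation
vectorizes; the four planning sample sizes run in about a second.

Interpreting "accuracy ~ Normal(20%, 10%) with a +10% true difference"
as *paired differences* ~ Normal(10, 10) is the one reading that
reproduces all four published planning powers (0.47, 0.92, 0.81, 0.95 at
n = 10, 20, 16, 22); modelling two correlated arms explicitly would
require an unpublished correlation. `min_n_for_power` searches the
smoothed curve — pool-adjacent-violators isotonic regression — because
the true power at the threshold (≈ 0.81 at n = 16 for target 0.8) sits
within Monte-Carlo resolution of the target, and raw estimates flip-flop.

## Numerical and degenerate-input choices

- Integer millimetre arithmetic everywhere in charting; no floating-point
  boundaries in the classification.
- Grade interval closed on both ends at B (r = 0.25 and r = 1.0 are B).
- Charts with no present teeth or implants are rejected as undiagnosable;
  implant-only charts are diagnosed from the worst implant.
- Percent rounding is decimal half-up, not banker's rounding, matching
  printed tables.
- The signed-rank exact path switches to the approximation exactly when a
  tie in |d| or n > 25 appears; the boundary is covered by tests.

## Known limitations

- Direct (longitudinal) grading evidence and the full stage III/IV
  complexity factor list (ridge defects, occlusal collapse) are not
  modelled; the input hooks exist but only the documented discriminators
  are computed.
- The question wording in the shipped tree is this package's own; only
  the underlying logic, not any published questionnaire text, is
  reproduced.
- Mucogingival phenotype subtypes, abscess/lesion differentials and
  peri-implant radiographic thresholds are reduced to single flags.
- Per-participant results of the original mock examination were never
  published, so those summary statistics cannot be recomputed; the paired
  comparison is exercised on simulated cohorts instead (a perfect test
  arm versus an error-prone control arm, which the test flags at
  p < 0.01 as expected).
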