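# periodx

Deterministic decision support for periodontal diagnosis, plus the study
statistics needed to evaluate such a tool.

Periodontal diagnosis under the 2017 AAP/EFP classification is a rule
system: a *case definition* (interproximal clinical attachment loss, CAL,
on ≥ 2 non-adjacent teeth, or buccal/lingual CAL ≥ 3 mm on ≥ 2 teeth),
a *stage* I–IV (severity from worst interdental CAL — 1–2 mm → I,
3–4 mm → II, ≥ 5 mm → III/IV — with complexity factors shifting the stage
up and tooth loss discriminating stage IV), a *grade* A–C (the ratio of
percentage radiographic bone loss to age, upgraded by smoking and
diabetes), and an *extent* (localized < 30% of teeth, generalized ≥ 30%,
or molar-incisor pattern). Applying the system consistently chairside is
hard, especially for trainees; `periodx` encodes it as an auditable rule
engine and as a guided question tree, and provides the statistical
machinery used to evaluate diagnostic accuracy in paired
control-versus-tool study designs.

The package is aimed at dental-education researchers and at anyone
building or validating periodontal decision-support tools.

## What is inside

- **`chart_model`** — full-mouth charting types (6 sites/tooth, probing
  depth and signed recession in mm, bleeding on probing, furcation,
  mobility, radiographic bone loss, clinical flags), a JSON and a CSV
  dialect, and chart summaries (CAL = PD + recession, worst-site maxima,
  bleeding fraction).
- **`classification_engine`** — case definition, stage, grade, extent,
  gingival status (health intact/reduced, gingivitis), peri-implant status
  (health, mucositis, peri-implantitis), and a full `diagnose()` report
  with rule-level rationale. All thresholds live in one versioned config
  file.
- **`secondary_findings`** — the six secondary condition categories
  (tooth/prosthesis-related factors, occlusal trauma, mucogingival
  deformity, systemic-disease manifestation, endodontic-periodontal
  lesion, periodontal abscess).
- **`decision_tree`** — a serializable question tree with validation,
  scripted and interactive traversal, and an auto-answer bridge that
  resolves each question from a chart; the tree provably agrees with the
  engine on generated cohorts.
- **`synth_cohort`** — labeled synthetic cohorts built by rule inversion,
  with diagnosis frequencies mirroring a 150-patient teaching-clinic
  cohort.
- **`study_stats`** — "n/n (%)" accuracy tables with pooled margins, an
  exact Wilcoxon matched-pairs signed-rank test (convolution null
  distribution, brute-force-verified), and paired condition comparisons.
- **`power_sim`** — Monte-Carlo power and sample-size search for the
  paired two-sided exact signed-rank test.

## Worked example

```python
from periodx import (CohortConfig, sample_cohort, diagnose,
                     default_tree, auto_answer)

cohort = sample_cohort(CohortConfig(n_patients=3, seed=7))
tree = default_tree()
for case in cohort:
    report = diagnose(case.chart)
    path, leaf = auto_answer(tree, case.chart)
    print(report.primary.label, "| tree:", leaf.diagnosis["stage"],
          leaf.diagnosis["grade"], "| rationale:", report.rationale[:3])
```

prints

```
generalized periodontitis stage IV grade C | tree: IV C | rationale: ('C.interdental_rule', 'E.generalized_ge_30pct', 'S.severity_CAL_ge_5')
generalized periodontitis stage IV grade B | tree: IV B | rationale: ('C.interdental_rule', 'E.generalized_ge_30pct', 'S.severity_CAL_ge_5')
localized periodontitis stage III grade C | tree: III C | rationale: ('C.interdental_rule', 'E.localized_lt_30pct', 'S.severity_CAL_ge_5')
```

Each line is a primary diagnosis (extent, stage, grade), the matching leaf
of the question tree, and the first fired rules: the case definition branch
that fired, the extent cut-off, and the CAL severity band.

The same functionality is available from the shell:

```sh
periodx simulate --n 150 --seed 1 --out cohort/
periodx diagnose --in cohort/ --out reports/
periodx interact            # guided Q&A session
periodx power --n-min 10 --n-max 25 --reps 10000 --seed 1
```

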