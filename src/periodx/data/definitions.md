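# Definitions

**CAL (clinical attachment loss)** — distance from the cemento-enamel
junction to the base of the pocket, in mm; computed here as probing depth
plus signed recession.

**PD (probing depth)** — distance from the gingival margin to the base of
the pocket, in mm, read in 1 mm increments.

**Recession** — position of the gingival margin relative to the
cemento-enamel junction; positive when the margin lies apical to the CEJ,
negative when coronal to it.

**BOP (bleeding on probing)** — site-level bleeding indicator; the fraction
of bleeding sites over probed sites drives the gingivitis rules.

**Periodontitis case definition** — interproximal CAL on two or more
non-adjacent teeth, or buccal/lingual CAL of 3 mm or more on two or more
teeth, attributable to inflammatory periodontal breakdown.

**Staging (I-IV)** — severity and complexity tier of periodontitis:
severity from worst interdental CAL (1-2 mm stage I, 3-4 mm stage II,
5 mm or more stage III/IV), with deep pockets, furcation involvement or
vertical defects shifting the stage up, and tooth loss, a dentition below
20 teeth or masticatory dysfunction discriminating stage IV.

**Grading (A-C)** — progression-rate tier: indirect evidence from the
percentage radiographic bone loss divided by age (below 0.25 grade A, up to
1.0 grade B, above grade C), upgraded but never downgraded by smoking and
diabetes.

**Extent** — localized (under 30% of teeth involved), generalized (30% or
more), or molar-incisor pattern (involvement confined to first/second
molars and incisors, with both involved).

**Intact vs reduced periodontium** — no attachment or bone loss versus
loss present without (or after treatment of) periodontitis.

**Gingivitis** — bleeding on probing at 10% or more of sites without
meeting the periodontitis case definition; generalized above 30% of sites.

**Peri-implant mucositis** — inflammation (bleeding/suppuration on probing)
around an implant without progressive bone loss.

**Peri-implantitis** — peri-implant inflammation with progressive
radiographic bone loss.

**Endodontic-periodontal lesion** — combined pulpal and periodontal
pathology on one tooth; here an endodontically involved tooth with a pocket
of 6 mm or more.

**Furcation involvement** — horizontal attachment loss between the roots of
a multirooted tooth, classes 1-3.

**Fremitus** — palpable or visible movement of a tooth under occlusal
function; a sign of traumatic occlusal force.

**Diagnosis incident** — one gold-standard secondary condition on one
patient; a single patient can contribute several incidents.

**Gold standard** — the calibrated periodontics faculty diagnosis against
which other diagnoses are scored.
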