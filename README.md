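# oxpathway

Oxygen-pathway analysis and V̇O₂ deficit recovery (VDR) for invasive
cardiopulmonary exercise testing (iCPET).

Exercise intolerance in conditions such as long COVID (PASC) and chronic
fatigue syndrome / myalgic encephalitis (CFS/ME) cannot be attributed to a
single organ from a reduced V̇O₂peak alone, and the classical Fick
decomposition (cardiac output × arteriovenous O₂ difference) confounds
interdependent quantities: extraction depends on delivery and capillary
transit time. Oxygen-pathway analysis resolves this by modelling the serial
transport/utilization cascade from mouth to mitochondria with six
physiologically non-coupled parameters, each governed by its own equation:

| parameter | meaning | governing relation |
|---|---|---|
| V̇a | alveolar ventilation (L/min) | PAO₂ = PIO₂ − 863·(V̇O₂/1000)/V̇a |
| D_L | lung O₂ diffusion (mL/min/mmHg) | Bohr integration, venous → arterial vs PAO₂ |
| Q̇ | cardiac output (L/min) | V̇O₂ = 10·Q̇·(CaO₂ − CvO₂) |
| Hb | hemoglobin (g/dL) | CaO₂ = 1.34·Hb·SO₂ + 0.003·PO₂ |
| D_M | muscle O₂ diffusion (mL/min/mmHg) | Bohr integration, arterial → venous vs P_mito |
| Vmax | mitochondrial OXPHOS capacity (mL/min) | V̇O₂ = Vmax·P_mito/(P_mito + P50_mito) |

The package provides, per subject and per cohort:

- **Inverse stage** (`oxpathway.estimation`) — estimate the six parameters
  from a peak iCPET record (gas exchange, direct-Fick cardiac output,
  arterial and mixed-venous blood gases) via Bohr capillary integration over
  the Severinghaus dissociation curve and closed-form relations.
- **Forward stage** (`oxpathway.forward`) — solve the coupled six-equation
  system for the achievable V̇O₂peak of any parameter set, and compute the
  **VDR**: raise each sub-normal parameter, one at a time, to its
  predicted-normal value, re-solve, and express the V̇O₂ gain as a percent
  of the subject's deficit (Wasserman-predicted minus measured V̇O₂peak).
  VDR ranks which defect most limits exercise — i.e. the most promising
  treatment target.
- **Reference norms** (`oxpathway.norms`) — Wasserman/Hansen predicted
  V̇O₂, linear normal-value models for the six parameters, percent-predicted
  (heat-map) and percent-of-control (radar) transforms, the healthy-control
  eligibility classifier (V̇O₂ and CO ≥ 80 % predicted, RER > 1.05, rest
  mPAP < 25 mmHg, mPAP–CO slope < 3 mmHg/(L/min)).
- **Cohort statistics** (`oxpathway.stats`) — Kruskal–Wallis omnibus tests
  (with exact permutation p at small n), Bonferroni-adjusted pairwise
  rank-sum (or Dunn) post hocs, median [p25, p75] summary tables.
- **Synthetic cohorts** (`oxpathway.simulate`) — internally consistent
  three-group iCPET cohorts (control / PASC-like / CFS-like) with retained
  ground-truth parameters, so every stage is testable without patient data.

## Worked example

Simulate a study-sized cohort (11 control / 15 PASC-like / 11 CFS-like) and
run the full analysis:

```bash
$ oxpathway simulate --out demo/cohort --seed 11
wrote 37 subjects (0 failures) to demo/cohort/subjects.csv; median VO2peak 1353 mL/min

$ oxpathway analyze --input demo/cohort/subjects.csv --out demo/results --seed 11
analyzed 37 subjects (0 row-level failures) -> demo/results/
```

`demo/results/` now contains per-subject parameter estimates
(`parameters.csv`), VDR percentages (`vdr.csv`), heat-map and radar exports,
a Table-style group summary with omnibus p values and post hoc letters:

```
variable,control,PASC,CFS,p,significant_pairs
vo2_ml_min,"1.95e+03 [1.72e+03, 2.25e+03]","1.38e+03 [1.18e+03, 1.53e+03]","1.06e+03 [883, 1.09e+03]",2.14e-05,"b,a,c"
co_l_min,"20.9 [18.2, 22.6]","15.6 [14.7, 17.9]","12 [10.1, 13.6]",3.09e-04,"a,c"
```

(letters: a = control vs CFS, b = control vs PASC, c = CFS vs PASC), and the
cohort VDR medians (`vdr_summary.json`, percent of deficit with bootstrap
CIs). For this seed the VDR medians are

```
PASC  va 15.4  dl 13.7  q 12.0  hb 3.7  dm 30.7  vmax 10.0
CFS   va  1.1  dl  0.4  q  3.8  hb 0.0  dm 22.2  vmax -0.6
```

— muscle O₂ diffusion (D_M) is the dominant recoverable defect in both
disease-like groups: restoring it to normal recovers the largest share of
the V̇O₂ deficit, mirroring the physiology the generator encodes.

The same pipeline runs on real data: any CSV following the subject schema in
`oxpathway/io.py` (one row per subject, saturations in percent) can be fed
to `oxpathway analyze`, optionally with a user reference table
(`--ref-table coefficients.json`).

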