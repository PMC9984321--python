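# cacscore

Coronary-artery-calcium (CAC) scoring on CT, for researchers who want to
quantify how well calcium scores derived from **non-gated low-dose CT**
(LDCT, the attenuation-correction scan of a cardiac PET study) agree with the
gold standard — manual Agatston scoring of a dedicated, ECG-gated
calcium-scoring CT (CSCT). The package implements the full computational
chain: Agatston scoring with a tube-voltage-adapted detection threshold, the
6-point cardiovascular risk scale, ordinal method-agreement statistics, and a
synthetic thorax-phantom/cohort simulator so that every stage runs and is
tested without patient data.

## The methods in brief

**Agatston score.** On contiguous 3 mm axial slices, pixels with
HU ≥ 130 are grouped into in-plane connected components; components with
area < 1 mm² are discarded; each remaining lesion contributes
*area (mm²) × w*, where the density weight *w* is 1, 2, 3 or 4 for a peak HU
in [130, 200), [200, 300), [300, 400), [400, ∞). The scan score is the sum
over slices, reported in total and per coronary artery (LM, LAD, LCx, RCA;
LM+LAD also combined).

**Voltage-adapted threshold.** At 130 kVp calcium attenuates less than at
120 kVp, so the fixed 130 HU cut-off under-detects. With a 200 mg/cm³
hydroxyapatite calibration rod measured at both voltages,

```
t_130kVp = 130 HU × HU_CaHA@130kVp / HU_CaHA@120kVp
```

With the measured rod values 249 HU (130 kVp) and 269 HU (120 kVp) this
evaluates to 120.33 HU.

**Risk scale and agreement.** Agatston totals map onto the ordinal 6-point
scale 0, 1–10, 11–100, 101–400, 401–1 000, > 1 000. Two methods compared on
the same patients yield a 6×6 confusion matrix, summarised by the
linear-weighted Cohen kappa (weights `w_ij = 1 − |i−j|/5`, asymptotic SE and
95% CI), the percentages of cases in the same / within one category,
the false-zero rate, and sensitivity/specificity/PPV/NPV of calcium
detection (positive = Agatston ≥ 1).

## Worked example

Recompute the agreement analysis of a published 6×6 risk-classification
matrix (visual LDCT scoring vs gated reference, 213 subjects, shipped as a
fixture):

```bash
$ cacscore compare --table src/cacscore/fixtures/table6C.csv
weighted linear kappa: 0.822 (95% CI 0.776-0.867, excellent)
% same category:   74.2
% within one:      98.1
% false zero:      3.3
sensitivity 96.5  specificity 100.0  PPV 100.0  NPV 63.2
```

Reading: chance-corrected ordinal agreement is 0.82 (excellent band); 74.2%
of subjects land in the identical risk category and 98.1% within one; 3.3%
of subjects with calcium are wrongly given a zero score; every
calcium-positive call is correct (PPV 100%) but a zero score rules calcium
out with only 63.2% certainty.

Score a CT volume, simulate data, or calibrate the threshold:

```bash
cacscore score --in scan.nii.gz --mask vessels.nii.gz --calibration calib.json
cacscore simulate-phantom --kvp 130 --out phantom130.nii.gz
cacscore calibrate --phantom-120 p120.nii.gz --phantom-target p130.nii.gz
cacscore simulate-cohort --n 60 --seed 7 --out cohort/
cacscore run-study --n 60 --seed 7 --out study/
```

`run-study` executes the whole replica — simulate paired scans, calibrate,
score the gated scans at 130 HU and the LDCT scans at the adapted threshold,
categorise, and tabulate agreement per scoring arm.

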