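# overscanqa

Retrospective scan-range quality assurance for lung-cancer-screening
chest low-dose CT (LDCT).

In screening LDCT the scan range is still set by hand, so scans routinely
extend beyond the anatomy that needs to be covered (overscan, wasted
dose) or fall short of it (underscan, lost diagnostic coverage).
Accreditation audits check this by eye against two criterion landmarks —
the upper end of the vocal cords superiorly (in practice the thyroid
cartilage, which is easier to see and covers the cords) and the lower
pole of the kidney inferiorly — which is laborious, subjective, and only
feasible for a sample of scans. `overscanqa` automates that audit for
medical physicists and radiology QA teams: it decides overscan/underscan
per side, measures the overscan length, and estimates the excessive
effective dose, then evaluates the decision algorithm with the full
battery of diagnostic-accuracy statistics an accreditation study uses.

## The algorithm

A three-stage pipeline per CT series:

1. **Landmark segmentation** — binary masks for the thyroid cartilage
   and the kidneys. A deterministic classical backend (HU thresholding +
   3-D connected components) is the reference; an optional trainable
   per-pixel classifier with the usual recipe (augmentation by rotation
   ≤ 5° and translation ≤ 5 px, two-class cross-entropy, early stopping
   on a tuning set) can replace it. Masks are scored with the Dice
   similarity coefficient, DSC = 2|A∩B|/(|A|+|B|).
2. **Rule-based logical operations** — one branch per side produces four
   Boolean identification items (A: superior overscan, B: inferior
   overscan, C: superior underscan, D: inferior underscan), all False by
   default. With the cartilage localized, the slices superior to its top
   decide item A (strictly more than τ_superior = 9 mm ⇒ overscan); with
   the kidney localized, the scan length beyond its most inferior slice
   decides item B (strictly more than τ_inferior = 3 mm, the kidney's
   intrinsic movement range). When a landmark is missing, 64×64-pixel
   ROI patches on the ten extreme slices are examined instead — anchored
   on the airway (HU in [−1000, −900]) superiorly and the spine
   (HU > 150) inferiorly — looking for pyriform-sinus air pockets, a
   closed vocal-cord lumen run longer than τ_superior, or lung
   parenchyma (items C/D).
3. **Final decision** — OR gates over (A, B) and (C, D) give the
   overscan/underscan verdicts; overscan length = number of overscan
   slices × slice thickness; excessive effective dose per side
   = CTDI_vol × length × k with k_superior = 0.0059 and
   k_inferior = 0.015 mSv·mGy⁻¹·cm⁻¹ (neck and abdomen conversion
   factors).

Evaluation statistics: accuracy/sensitivity/specificity with exact
Clopper-Pearson 95% CIs, Cohen's κ, Fisher's exact test, a
linear-approximation ROC (trapezoid AUC) over a threshold sweep,
univariate odds ratios, and the workload-reduction summary.

Because no patient data ships with the package, a seeded synthetic
phantom generator (`overscanqa.phantom`) renders chest volumes
containing every cue the rules inspect, with exactly known scan margins
and ground-truth masks — the whole pipeline is testable hermetically.

## Worked example

```python
from overscanqa import (ContingencyTable, diagnostic_metrics, cohens_kappa,
                        fisher_exact, PhantomSpec, generate_phantom,
                        decide_volume, Thresholds)

# a phantom scanned 20 mm above the thyroid-cartilage top, CTDI_vol 2.42 mGy
vol, truth = generate_phantom(PhantomSpec(superior_margin=20, inferior_margin=0,
                                          ctdi_vol=2.42, seed=7))
report = decide_volume(vol, Thresholds())
print("status:", report.status)
print("superior overscan:", report.superior_count, "slices =",
      report.superior_length_mm, "mm")
print("excess dose:", round(report.dose.total_mSv, 4), "mSv")

table = ContingencyTable(tp=46, fp=6, fn=1, tn=157)
m = diagnostic_metrics(table)
for name, res in m.items():
    est, lo, hi = res.as_percent()
    print(f"{name}: {est}% (95% CI {lo}-{hi})")
print("kappa:", round(cohens_kappa(table), 3), " Fisher p < 0.001:",
      fisher_exact(table) < 0.001)
```

prints

```
status: overscan
superior overscan: 20 slices = 20.0 mm
excess dose: 0.0286 mSv
accuracy: 96.67% (95% CI 93.25-98.65)
sensitivity: 97.87% (95% CI 88.71-99.95)
specificity: 96.32% (95% CI 92.16-98.64)
kappa: 0.908  Fisher p < 0.001: True
```

The phantom's 20 mm superior margin exceeds τ_superior = 9 mm, so the
case is flagged as a superior overscan of 20 slices (1-mm slices); its
excess dose is 2.42 mGy × 2.0 cm × 0.0059 ≈ 0.029 mSv — of the order of
a single chest radiograph, i.e. a QA concern rather than a safety one.
The contingency-table block reproduces the validation statistics of a
210-case audit with 47 radiologist-tagged overscans.

The same workflow is available from the shell:

```sh
overscanqa generate --n 20 --seed 7 --out cohort/
overscanqa decide   --input cohort/ --out predictions.csv
overscanqa evaluate --pred predictions.csv --gold cohort/truth.csv --out metrics.json
overscanqa dose     --ctdi 2.42 --superior-cm 1.59
```

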