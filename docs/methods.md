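# Methods

## Scope and model

`overscanqa` implements a retrospective scan-range audit for chest LDCT
as a three-stage pipeline: landmark segmentation, rule-based logical
operations per side, and a final OR-gate decision with overscan length
and excessive effective dose. The decision logic is the core
contribution of the package; segmentation and statistics are support
stages around it.

Geometric conventions, fixed across the package:

* slice index 0 is the most superior slice; per-slice physical z
  strictly decreases with index (head-first supine read top-down);
* lengths are computed from the physical inter-slice spacing, which
  equals the nominal reconstructed thickness for the data the package
  emulates but takes precedence when the two differ, because reported
  lengths must reflect physical coverage;
* overscan slices are counted on reconstructed images, and a reported
  count includes *all* slices beyond the landmark limit — the decision
  thresholds τ are alert thresholds, not deductions from the length.

## Decision rules and parameters

All tunable parameters live in `decision.Thresholds`:

| parameter | default | meaning |
|---|---|---|
| `tau_superior` | 9 mm | maximal acceptable scan above the thyroid-cartilage top |
| `tau_inferior` | 3 mm | maximal acceptable scan beyond the kidney bottom; matches the kidney's intrinsic (respiratory/peristaltic) movement range |
| `airway_window` | [−1000, −900] HU | air/lumen detector window, inclusive |
| `spine_hu` | 150 HU | bone threshold, strict `>` |
| `parenchyma_window` | [−950, −650] HU | lung-parenchyma pixel window |
| `parenchyma_fraction` | 0.20 | patch area fraction for "contains parenchyma", `>=` |
| `min_component_px` | 10 px | minimal 2-D component area for locators/detectors |
| `min_landmark_voxels` | 5 | per-slice mask voxels for a landmark to count as present |
| `pyriform_lateral_px` | 6 px | minimal lateral offset of sinus air from the patch midline |
| `patch_size`, `n_patch_slices` | 64 px, 10 | ROI patch geometry |
| `k_superior`, `k_inferior` | 0.0059, 0.015 mSv·mGy⁻¹·cm⁻¹ | neck/abdomen dose-conversion factors |

Boundary conventions, stated once and tested explicitly: τ comparisons
are strict (a case exactly at 9 mm is acceptable); area-fraction
detectors use `>=`; the bone threshold is strict (a voxel at exactly
150 HU is not bone).

Design choices where the procedure was genuinely open:

* **τ_superior on both superior routes.** The threshold is applied both
  when the cartilage is directly localized (slices above its top) and in
  the patch fallback (closed-lumen run length). A uniform threshold
  keeps the ROC threshold sweep coherent across routes.
* **Pyriform-sinus criterion.** Operationalized as at least one
  enclosed air component on each side of the patch midline at a minimal
  lateral offset. Components touching the patch border are rejected:
  sinus recesses are enclosed by tissue, whereas air outside the body
  always reaches the border. A single central air component is the
  airway, not the sinuses.
* **Closed-cord criterion.** A slice counts as "closed" when the central
  third of its airway-anchored patch contains no air component of at
  least the minimal area.
* **Patch-route slice counts.** When the pyriform route fires, the
  reported overscan count is the index of the deepest sinus-positive
  patch plus one (every slice at or above the sinus level lies above the
  cords); the closed-lumen route reports the length of the leading
  closed run. Both are patch-window-limited (≤ 10 slices) and therefore
  lower bounds.
* **Airway locator.** The largest in-window air component that does not
  touch the image border; border exclusion is what separates the trachea
  from the air surrounding the patient.
* **Per-case ROC score.** The maximum per-side excess length in mm.
  Because the two sides have different thresholds (9 vs 3 mm), a single
  combined score cannot separate cohorts containing inferior-only
  overscans near threshold; the separability tests therefore use
  superior-only cohorts, and mixed cohorts yield AUC marginally below 1.
* **Opposite-side disagreement** (e.g. superior overscan with inferior
  underscan) is reported as status `mixed`; dose accrues only on sides
  decided as overscan; missing CTDI_vol leaves the dose "not
  computable" rather than guessed.

## Segmentation backends

**Classical (reference).** Deterministic thresholding plus 3-D connected
components. Thyroid cartilage: among components > 150 HU, the vertebral
column is the one spanning the most slices; the cartilage is the
largest remaining component anterior to it. Kidneys: components in a
[0, 90] HU soft-tissue window, excluding the largest (the body itself),
restricted to the posterior half; the two largest survivors are the
kidneys, which works because the kidneys are isolated from the rest of
the soft tissue by their retroperitoneal fat. Holes are filled; specks
below 50 voxels (200 for the kidney window) are dropped.

**Trainable (optional).** A per-pixel classifier — a small MLP (one
hidden layer, 24 units) over a 10-feature stack per pixel: normalized
HU (clipped to [−1000, 400], min-max scaled; slices larger than
`input_size` = 256 are downsampled), Gaussian-smoothed intensities at
σ = 2/4/8 px, the local contrast x − G₈(x), a 17-px neighborhood
minimum (capsule proximity), Sobel gradient magnitude, normalized row
and column, and the slice mean. Training follows the standard
small-data recipe: per-iteration random augmentation (rotation within
5°, translation within 5 px), two-class binary cross-entropy, and early
stopping on a tuning set — the returned parameters are those of the
best tuning loss, with `patience = 0` returning the first iteration's
parameters. Class-balanced pixel sampling uses 4 negatives per positive
so the 0.5 call threshold stays strict. Volume predictions drop 3-D
components below 50 voxels, aggregating per-slice outputs into
volumetric information. Everything is seeded and bit-reproducible.
Dice is aggregated per patient over the 3-D mask; the empty-vs-empty
case is defined as DSC = 1 so landmark-absent cases are well-behaved.

## The phantom generator

The generator emulates exactly the cues the rules inspect, as a
piecewise-constant HU model on a head-to-abdomen stack: body soft
tissue 40 HU inside an elliptical body outline; airway tube −1000 HU
down to a carina level, optionally closed (soft tissue) over a
configurable "closed vocal cord" band; paired pyriform air pockets
−1000 HU lateral to the airway above the cartilage; thyroid cartilage
as a 400 HU partial (anteriorly closed) ring around the airway;
lung parenchyma −850 HU; vertebral column 400 HU on every slice;
paired kidney ellipsoids 35 HU inside a −100 HU retroperitoneal fat
capsule. Additive Gaussian noise (default σ = 20 HU; an LDCT stress
setting of 60 HU is available) is applied after composition, and HU are
clipped to [−1000, 2000] — the air floor mirrors how CT numbers
saturate, and keeps the airway window's lower bound meaningful under
noise. The HU palette is chosen so the literal rule thresholds
discriminate without modification.

Default anatomical spans (z anchored at the cartilage top, inferior
positive, all configurable): pyriform [−20, −6) mm, cartilage [0, 12)
mm, lungs [12, 252) mm, kidneys [258, 358) mm, carina at 90 mm. Organ
dimensions are plausible adult defaults, not fitted to any population.
Two layout choices keep the rule-based detections and the geometric
truth consistent outside narrow ambiguous bands: the lung top coincides
with the cartilage bottom (so a scan starting below the cartilage lands
in lung and is caught by the parenchyma rule), and the lung base ends
just above the kidney top (so a scan ending between them is acceptable
under both definitions).

Scan coverage is set by two signed margins (mm above the cartilage top,
mm beyond the kidney bottom), rendered to whole slices by truncation
toward zero — a partial slice cannot be reconstructed. Ground-truth
labels are a pure function of the realized margins and the active
thresholds: superior overscan ⇔ margin > τ_superior; inferior overscan
⇔ margin > τ_inferior; superior underscan ⇔ the scan top lies below the
cartilage bottom; inferior underscan ⇔ the scan bottom lies above the
lung base. The kidney bottom is the most inferior voxel of either
kidney, mirroring the "last kidney" rule.

Cohorts draw the tagged-case count as `round(n × prevalence)`
(defaults mirror audit prevalences of 22.4% internal / 32% external),
split tagged cases 60/30/10 between superior-only, inferior-only and
both-sided overscan, and render about 1% of untagged cases as
underscans (underscan is rare in practice). Overscan margins are drawn
at least `margin_gap` = 2 mm beyond the threshold and acceptable
margins at least 2 mm inside it, so labels are unambiguous; underscan
margins place the offending slice well inside the lung. Per-case
CTDI_vol is log-normal with mean ≈ 2.4 mGy and SD ≈ 1.7 mGy, matching
reported screening-LDCT dose levels. All draws derive from a single
seed and are bit-reproducible.

**What the phantoms do not emulate** — and hence what passing tests do
not show about real data: reconstruction kernels, beam hardening,
tin-filter spectra, vendor-specific iterative reconstruction, deformable
or population-variable anatomy, and segmentation failure modes of real
LDCT. Perfect phantom-cohort accuracy demonstrates that the decision
logic is faithful to its rules, not that the pipeline reaches any
particular accuracy on patients.

## Statistics

Implemented in `overscanqa.stats` on 2×2 algorithm-vs-gold tables:

* accuracy (tp+tn)/n, sensitivity tp/(tp+fn), specificity tn/(tn+fp),
  each with the exact Clopper-Pearson interval (beta quantiles; lower
  bound 0 at 0 successes, upper bound 1 at n successes). A logit-scale
  Wald interval is available behind a flag. Zero-denominator metrics
  are returned flagged undefined.
* Cohen's κ = (p_o − p_e)/(1 − p_e) with marginal-product expected
  agreement; degenerate-margin perfect agreement returns 1.
* Fisher's exact test, two-sided by the probability-mass criterion
  (the sum of hypergeometric probabilities not exceeding the observed
  table's) — verified against full enumeration for every table with
  n ≤ 30.
* ROC by threshold sweep: a case is called at score > τ, one point per
  τ (default grid: the unique scores), endpoints (0,0)/(1,1) appended,
  AUC by the trapezoid rule — equal to the probability of correct
  ranking, verified by brute-force pair counting.
* Univariate odds ratios as the cross-product ratio (identical to the
  single-binary-covariate logistic estimate, verified against a fitted
  logistic regression), Wald CI and p on the log scale,
  Haldane-Anscombe +0.5 on zero cells; multi-level covariates as dummy
  contrasts against a reference level.
* Workload reduction = 100 × (1 − overscan prevalence): the fraction of
  scans needing no human review when only alerted cases are checked.

Display rounding follows the field's reporting style: percentages to
two decimals, κ and odds ratios to three. (On the 210-case table the
computed κ is 0.9076, which rounds to 0.908.)

## Problem sizes and numerical notes

Test and reproduction runs use phantom stacks of 128×128 pixels at 3 mm
spacing and 1 mm slices (≈ 360–430 slices); the decision-fidelity suite
uses 200 phantoms with ground-truth masks, the classical-segmentation
suite 20 noise-free phantoms, and the trainable-backend check a 50/10
train/tune split on compact (short-lung) phantoms — sizes chosen as the
package's own desk-scale defaults. The acceptance script runs the full
three-stage pipeline on 210- and 50-phantom cohorts.

Known limitations: the classical kidney backend degrades under the
σ = 60 HU noise stress (interior dropout pulls DSC toward ~0.7) — the
decision stage tolerates this because landmark presence, not mask
quality, drives the rules; truth labels are undefined ambiguously when
a scan boundary falls inside a landmark (e.g. mid-cartilage starts are
labelled acceptable by convention); the patch fallback cannot measure
overscan lengths beyond its ten-slice window; and the generator's
margins are drawn clear of the thresholds, so near-threshold behaviour
is exercised only by the dedicated boundary tests.
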