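# Methods

## Problem and model

In locally advanced lung cancer treated with (chemo)radiotherapy, respecting
the usual organ-at-risk constraints does not fully protect against grade ≥ 2
acute pulmonary toxicity (APT, radiation pneumonitis), because the lung is
functionally heterogeneous. `pmapdose` implements the analysis pipeline
around a voxel-cluster sub-region of the posterior right lung ("Pmap") whose
mean biologically effective dose (DMeanPmap) predicts APT: the sub-region is
carried from a reference thoracic phantom into the patient lattice, the DVH
metric panel is computed for an initial and a re-optimised plan, plan-pair
success is adjudicated under explicit rules, and the APT risk class
(probability ≥ 8%, DMeanPmap ≥ 30.3 Gy BED — both inclusive) is compared
before and after optimisation.

Core quantities, in the field's standard notation:

* **BED** — linear-quadratic biologically effective dose, evaluated voxelwise
  with the voxel's own per-fraction dose:
  `BED(v) = D(v) · (1 + (D(v)/n) / (α/β))`, with α/β = 3 Gy for normal
  tissue and 10 Gy for tumour. The voxelwise form is the standard
  interpretation when a dose map (rather than a uniform organ dose) is
  converted; BED ≥ D always, with equality as α/β → ∞.
* **Vx_y** — percent of VOI *y* receiving ≥ x Gy; an exact inclusive voxel
  count (ties at the threshold count as covered), never interpolated from a
  binned curve.
* **Dq%** — the largest dose received by at least q% of the VOI, linearly
  interpolated on a cumulative DVH with 0.1 Gy bins (so D100% is the minimum
  VOI dose to within one bin).
* **IC** = PIV/PTV (prescription isodose volume over PTV volume), PIV taken
  over the whole grid (no body contour exists in the data model).
  **HIV** = D95%/D5% over the PTV, always in (0, 1].
* **DICE** = 2|A∩B|/(|A|+|B|); two empty masks give 0 with a warning so ROC
  analyses stay computable.

Only the Pmap mean dose (and its 30.3 Gy threshold) is evaluated in BED
(α/β = 3); all other panel metrics are physical dose, with an `all_bed`
switch for a fully converted panel. A voxel is in or out of a structure —
no partial-volume DVH weighting — which is a known deviation source versus
treatment-planning-system DVHs.

## Success rules and cohorts

Patients enter the analysis when their predicted APT probability is ≥ 8%.
With DMeanPmap-initial ≥ 30.3 Gy, re-optimisation succeeds when the
optimised DMeanPmap drops below 30.3 Gy **and** PTV coverage is maintained
**and** all organ-at-risk constraints hold (Cohort 1 on success, Cohort 2 on
failure). Below 30.3 Gy (Cohort 3), success is a ≥ 20% relative DMeanPmap
reduction with coverage maintained. "Coverage maintained" is
operationalised as optimised PTV95 ≥ min(95%, initial PTV95 − 1.0 point):
plans that started below the nominal 95% floor only need to stay within one
point of their own starting coverage (a strict floor would fail plans that
were accepted clinically). The shipped OAR bounds (2Lungs V20 ≤ 35%, cord
Dmax ≤ 45 Gy, heart V40 ≤ 30%) are generic lung-RT constraints and fully
overridable — they are defaults, not a reproduction of any specific
protocol appendix.

Adjudication returns machine-readable reasons for every violated criterion;
success is monotone in the optimised Pmap dose by construction.

## Risk model

The published APT model (an ensemble over 11 features with DMeanPmap
carrying ~36% importance) was never released, so the package exposes a
pluggable interface: a pure threshold rule, a maximum-likelihood logistic
surrogate over the same 11 features (statsmodels `Logit`), and external
JSON-serialised weights. The surrogate makes no claim to reproduce the
original model's probabilities; it exists so synthetic studies have a known
ground truth. Standardised |weight| shares (|w_j|·SD_j, normalised) are
reported as an importance analogue. AJCC stage is encoded ordinally
(I=0 … IV=5, configurable).

## Statistics

* Plan-set panels are compared arm versus arm, unpaired, mirroring published
  plan-comparison tables: two-sample t-test when both arms pass Shapiro-Wilk
  at α = 0.05 (constant samples count as non-normal), otherwise Mann-Whitney
  U; the test used is recorded per metric. Means carry t-based CI95.
* Because the plans are in fact paired, the reclassification summary uses
  properly paired tests: exact McNemar on risk-class transitions and
  Wilcoxon signed-rank on the probabilities. Median CI95s use a seeded
  percentile bootstrap (2000 resamples).
* The PTV-Pmap DICE is evaluated as a predictor of optimisation *failure*
  (a large target/sub-region overlap leaves the optimiser no room): ROC via
  scikit-learn, AUC in that orientation, cutoff by maximising the Youden
  index J = sens + spec − 1, ties broken toward the smallest cutoff.

## Sub-region transfer

The elastic phantom-to-patient registration is consumed, not computed.
Identity and affine transforms resample masks by inverse-lookup
nearest-neighbour sampling (no holes, label integrity); dense displacement
fields, which have no closed-form inverse, are applied as a forward
nearest-neighbour splat of the true voxels. Registration quality is the
DICE of the hybrid lungs ∪ heart VOI, the same structure used to drive the
registration clinically. Affine round-trips retain DICE ≥ 0.95 on regions
of ≥ 500 voxels (nearest-neighbour discretisation loss only).

## Synthetic data

No clinical inputs are public, so the generator defines the study
conditions end-to-end on a 64³ lattice at 4 mm isotropic (the planning-grid
resolution is a package choice; clinical grids are typically 2-4 mm):

* **Phantom** — lung ellipsoids, heart ellipsoid (subtracted from the
  lungs), posterior midline cord cylinder, spherical PTV inside the right
  (homolateral) lung, and the Pmap sub-region as a box confined to the
  posterior right lung. Anatomy invariants (PTV ⊂ LungH, Pmap posterior,
  cord disjoint from lungs) are validated at construction.
* **Plan painter** — the inverse VMAT optimisation is out of scope; its
  *outcome* is emulated. Initial plan: 1.02 × prescription inside a
  two-voxel-dilated, Gaussian-blurred (σ = 3 mm) PTV, combined by voxelwise
  max with a broad posterior Gaussian bath (σ = 40 mm) centred on the Pmap
  whose amplitude (`posterior_spill`) sets the initial DMeanPmap, plus
  seeded 0.5 Gy voxel noise. Optimised plan: the same deterministic dose
  times a smooth attenuation field equal to `1 − r` over the dilated Pmap
  (falling off over 25 mm), with PTV voxels reset to their initial values
  and fresh noise. The Pmap physical mean therefore drops by ≈ r except
  where PTV and Pmap overlap — which is precisely the mechanism that makes
  high-DICE plans fail adjudication, reproducing the qualitative
  DICE-failure association without simulating an optimiser.
* **Cohorts** — hierarchically seeded per patient: PTV position/radius
  jitter; a two-mode spill mixture calibrated so the high mode gives initial
  DMeanPmap(BED) ≈ 40 Gy (SD ≈ 4.4) and the low mode ≈ 15 Gy, the two
  strata the threshold separates; per-patient reduction targets
  N(0.35, 0.05). The low-dose stratum draws worse clinical covariates
  (COPD 0.8, smoking 0.95, MEVS ≈ 48%) — confounding by indication — which
  is what lets a patient sit below the dose threshold yet above the 8%
  predicted-risk cutoff; a single logistic model on dose alone cannot
  produce that branch. APT outcomes are Bernoulli draws from an explicit
  logistic model whose probabilities are also the pipeline's "predicted"
  probabilities.
* A fast, image-free `sample_feature_table` draws the 11 features from
  parametric marginals matched to the painter's output, for model-recovery
  experiments (n = 2000) where painting every patient adds nothing.

What the generator does **not** emulate: CT intensities, beam/arc geometry,
scatter, inter-fraction motion, realistic DVH shapes outside the panel's
range, or the true joint distribution of clinical covariates. Passing tests
therefore demonstrate the correctness of the *analysis* under controlled
conditions, not clinical performance of the risk model.

## Numerical choices and degenerate inputs

* Lattice equality tolerance 1e-6 mm; axis order (z, y, x), voxel-centred
  world coordinates, 0-based indices.
* DVH bin width 0.1 Gy; Vx thresholds inclusive; Dq% as above.
* Empty structures raise explicit errors rather than returning NaN; a
  zero-dose PTV makes HIV undefined (reported as NaN with a warning from
  the panel computation, after guarding against sub-bin interpolation
  reporting a spuriously positive D5%).
* Shapiro-Wilk is undefined on constant samples — they route to
  Mann-Whitney; two identical constant arms report p = 1.
* Exact McNemar with zero discordant pairs gives p = 1; Wilcoxon on
  all-zero differences is defined as p = 1.
* All simulation randomness flows from one master seed through
  `numpy.random.SeedSequence` spawning; derived seeds stay below 2³¹.

## Problem sizes

Default analyses run on 64³ grids with a 100-patient synthetic cohort
(≈ 10 s end-to-end) and n = 2000 tabular cohorts for parameter recovery —
sizes at which every DVH quantity can also be brute-force verified.

## Known limitations

* The reported probabilities come from the logistic surrogate, not the
  unpublished clinical ensemble; absolute probability levels are not
  comparable to clinical reports.
* PIV (hence IC) is not body-restricted.
* Nearest-neighbour transfer quantises thin structures on coarse grids.
* The unpaired plan-set comparison inherits the conservatism of ignoring
  pairing; the paired alternative is always reported alongside.
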