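# Methods

This note records the models implemented in `lesionfactors`, the
assumptions behind them, the parameters that matter, and the places where
the design was genuinely open and a choice had to be made.

## Disconnection measurement

A streamline atlas is a set of named tracts, each a bundle of 3-D
polylines in template mm coordinates. A lesion mask is a binary grid with
a voxel-to-mm affine. A streamline is *disconnected* by a mask when at
least one voxel it traverses lies inside the mask; the tract-level
statistic is

    pct(tract) = 100 · #{disconnected streamlines} / #{streamlines in tract}.

Rasterization samples each polyline segment at spacing ≤ `step_mm`
(endpoints included), maps samples through the inverse affine, and takes
the nearest integer voxel index (voxel-center convention, 0-based).
Defaults and consequences:

- `step_mm` defaults to half the smallest voxel dimension, which
  guarantees consecutive samples land in the same or adjacent voxels, so
  no voxel along the path is stepped over. Corner-grazing voxels whose
  intersection with the path is shorter than the step may still be
  missed; the test suite checks that rasterization at the default step is
  exactly reproduced by an independent loop oracle and contained in a
  10× denser sampling.
- The single-voxel contact rule (no minimum-overlap threshold) is the
  standard disconnectome convention; "passing through" is otherwise
  underspecified.
- Percent disconnection is monotone under mask dilation and invariant to
  re-sampling of the polyline points.

The canonical 70-name tract registry (65 bundles, the corpus callosum
replaced by five segments: anterior frontal, posterior frontal, parietal,
temporal, occipital) is a naming schema for interoperability; synthetic
atlases use its first `n_tracts` names. Exact anatomical boundaries of
the callosal segmentation are not reproducible from published
descriptions, so the segment labels are configurable.

## Lesion mapping

Volumes are voxel count × |det(affine₃ₓ₃)| / 1000, reported in cm³.
ICV normalization multiplies by the cohort mean intracranial volume and
divides by the subject's. Territory volumes tally mask voxels within each
of 10 vascular-territory codes (6 supratentorial, 4 infratentorial);
the dominant territory is the argmax with ties broken toward the smallest
code (deterministic and documented).

The bullseye parcellation assigns every white-matter voxel a relative
depth d = dv / (dv + dc), where dv and dc are Euclidean distance
transforms (mm) to the ventricle and cortex masks, and bins d into four
half-open quartile layers [0, .25), [.25, .5), [.5, .75), [.75, 1]
(d = 1 falls in layer 4). The source bullseye method uses four
equidistant relative-distance layers without printed edges; quartiles are
the natural reading. Parcel code = (lobe − 1) · 4 + layer, lobes 1–9,
codes 1–36.

## Latent disconnection factors

Percent-disconnection profiles are discretized to counts by
`round(scale · pct)` with `scale = 10` (0.1% resolution). The cited
topic-model framework requires count data but the discretization is
unstated in the source analyses; the scale is configurable and a
robustness test verifies loadings are insensitive to it (θ correlation
> 0.95 between scale 1 and 10). Subjects with all-zero profiles carry no
information and are excluded from fitting, with uniform loadings in the
output and a logged warning.

The model is smoothed LDA: θ_d ~ Dirichlet(α), token factors
z ~ Cat(θ_d), tracts t ~ Cat(β_z). Fitting is mean-field variational EM:

- E-step: per subject, iterate responsibilities
  φ(t,k) ∝ exp(E[log θ_k]) · β_{k,t} and Dirichlet parameters
  γ_k = α + Σ_t c_t φ(t,k) to a fixed point.
- M-step: β_{k,t} ∝ η + Σ_d c_{d,t} φ_d(t,k) (MAP update under a
  Dirichlet smoothing prior).
- The tracked objective (reported as `elbo`) is the variational bound
  plus the β prior term; both steps increase it, and the suite asserts it
  is non-decreasing within 1e-6 relative tolerance.

Hyperparameters are not stated in the source analyses. Defaults:
symmetric α = 1/K (subject-level sparsity that scales with K) and
η = 0.01 (sparse tract signatures); both configurable and recorded in
model metadata. Initialization draws factor signatures as mixtures of the
empirical tract frequencies and seeded near-one-hot Dirichlet(η) spikes,
which breaks factor symmetry deterministically per seed. Convergence:
relative bound change < 1e-5 (default) or 200 EM iterations.

**Stability selection.** The stability of K is the mean, over all pairs
of `n_runs` independently initialized fits, of the matched Pearson
correlation between factor signatures, with matching by optimal
assignment (Hungarian algorithm), clipped to [0, 1]. K is the argmax,
ties toward smaller K (parsimony). The exact stability statistic and run
count used by the source analyses are not published; pairwise
optimal-assignment correlation over restarts is a standard
reproducibility index, and the choice is recorded in output metadata.
An independent cross-check against scikit-learn's variational LDA (an
implementation we never call in library code) verifies that both
recover the same signatures on well-separated corpora.

## Association statistics

- **Impairment rule**: PSCI = 1 iff any cognitive domain summary z-score
  ≤ −1.5 (threshold inclusive, configurable). The threshold is read as
  *minus* 1.5 SD: the positive sign that sometimes appears in print would
  classify nearly everyone as impaired, and the norm-based references
  behind the rule use −1.5 SD.
- **Logistic models**: maximum likelihood by IRLS/Newton (statsmodels),
  Wald standard errors, OR = exp(β̂), 95% CI = exp(β̂ ± 1.96·SE). Wald
  intervals are used for determinism; published CIs of this kind are
  often profile-likelihood and will not match Wald exactly, but the OR
  point estimates are the comparable surface. Perfect separation is
  raised as a flagged error, rank deficiency rejected.
- **Likelihood-ratio test**: χ² = 2·(ℓ_full − ℓ_reduced), df = number of
  added parameters (1 for one added loading), upper-tail χ² p-value.
  Nesting violations (negative χ² beyond tolerance) are rejected.
- **FDR**: Benjamini–Hochberg step-up, applied within each analysis
  family (per timepoint in the factor scan), not globally; family
  membership is recorded in the outputs.
- **CCA**: first canonical pair from the SVD of the whitened
  cross-covariance; significance from a row-permutation null with
  perm_p = (1 + #{r_perm ≥ r_obs}) / (n_perm + 1) — the p-value has a
  floor of 1/(n_perm+1) and its null distribution is discrete uniform.
  With q = 1 the statistic reduces exactly to the multiple correlation
  coefficient (tested).
- **Longitudinal model**: random-intercept logistic regression with fixed
  effects intercept, loading, time (0 = month 6, 1 = month 36),
  loading × time, age, education, and b_i ~ N(0, σ²) per subject. The
  marginal likelihood integrates b_i by adaptive Gauss–Hermite quadrature
  (default 15 nodes): nodes are re-centered at each subject's posterior
  mode (Newton search) and re-scaled by the Laplace curvature, so the
  node count is adequate even for extreme subjects; doubling the nodes
  moves fixed effects by < 1e-3 (tested). The likelihood is flat in
  log σ near the σ → 0 boundary, so optimization starts from both a
  near-degenerate and a moderate σ and keeps the better optimum; at the
  boundary the fixed effects coincide with a plain logistic fit (tested
  at n = 400 subjects). Missing timepoints contribute available-case
  likelihood; cross-sectional fits use listwise deletion.

## The synthetic study

The generator produces the *study conditions* the pipeline is validated
under; its defaults are fixed, not tuning knobs.

**Template.** Nested ellipsoids on a 48×56×48 grid of 2 mm voxels: an
outer brain ellipsoid whose outermost two-voxel shell is "cortex", a
central ventricular ellipsoid, 9 lobar sectors (8 supratentorial angular
sectors + 1 infratentorial), and 10 vascular territories partitioning the
brain volume. This is deliberately not an anatomical template:
registration is out of scope and every geometry-dependent computation
only needs internal consistency (all 36 bullseye parcels are achievable,
verified across seeds).

**Lesions.** Infarcts are single compact ellipsoidal blobs confined to a
randomly drawn territory (middle-artery territories most likely, mirroring
the ~83% middle-cerebral predominance of minor stroke), radii lognormal so
that volumes average ≈ 10 cm³ with a heavy tail; pairwise overlap across
subjects is low. WMH are periventricular shells — all white-matter voxels
within a per-subject rim distance (1.5–6 mm, widened ×1.3 anteriorly for
frontal predominance) of the ventricle — so overlap across subjects is
high. The generated contrast (mean pairwise Dice ≈ 0.002 for infarcts vs
≈ 0.7 for WMH) reproduces the qualitative overlap asymmetry of such
cohorts; no quantitative overlap statistic exists to match, so the
Dice contrast is asserted only as an ordering.

**Disconnection corpora.** Two routes by design. The *model* route draws
counts exactly from the factor model: β rows ~ Dirichlet with strong
disjoint-block bias (concentration 2.0 on a factor's own tract block,
0.05 elsewhere), θ rows ~ Dirichlet(1/3), counts ~
Multinomial(1000, θ_d β). Estimator failures on this route are
attributable to the estimator. The *geometric* route (lesions →
disconnectome → pseudo-count encoding) exercises the full measurement
chain; it carries no planted factor structure, because linking lesion
geometry to latent factors would require anatomy the template does not
have. Defaults: 105 subjects, 24 tracts, K_true = 3, matching the scale
and selected K of the emulated cohort.

**Cognition.** Domain z-scores at months 6 and 36 are
baseline − w_d · θ[causal] + confound terms + shared ability + noise,
with the causal weights concentrated on attention/executive, language and
visuospatial domains (the profile reported for WMH-driven disconnection)
and scaled so the induced log-odds of impairment per unit loading
approximates `effect_beta` (default log 10, i.e. a planted OR ≈ 10; the
probit-to-logit factor 1.7 makes this a deliberate approximation, and
large-sample fits recover slopes within ~10% of the target). Age ~
N(63, 12) and education ~ N(12, 4) enter both the z-scores and nothing
else; PSCI is *computed* from the z-scores by the threshold rule, never
assigned. Domain baselines are fixed so default prevalence sits near the
emulated cohort (~52% at month 6, ~38% at month 36); the shared-ability
term gives the observed mix of converters in both directions. MoCA is a
noisy correlate of overall ability. Lesion volumes in the cohort table
are lognormal with the cohort's printed moments.

**What passing tests do and do not show.** The exact-model corpus makes
parameter recovery a clean test of the estimator, not of the
measurement chain; the geometric route tests the measurement chain, not
recovery. Real WMH disconnection profiles have anatomical correlation
structure, registration error, and segmentation noise that no part of the
generator emulates — results here validate the machinery, not clinical
effect sizes.

**Compositional leakage.** Within one K-factor model the loadings sum
to 1, so sibling loadings of a strongly causal factor are negatively
correlated with it (pairwise correlation −1/(K−1) for symmetric
Dirichlet) and inherit roughly half its association strength with
opposite sign — visible in the worked example and in published
cross-sectional tables of this design (a second factor significant with
opposite sign, strongly anti-correlated with the causal one). True-null
behaviour is therefore evaluated on the *infarct* model's factors, whose
loadings are generated independently of outcome; sibling WMH factors are
reported but are not nulls.

## Problem sizes

The default test and validation sizes are chosen to keep the full suite
in minutes on one CPU while leaving Monte-Carlo error well below the
asserted margins: recovery studies use 300 subjects and 20 (tests) or 12
(acceptance script) replicates; type-I calibration uses 500 replicates
(300 for the mixed model, 150 subjects × 2 timepoints each); BH
calibration 5000 null batches of 20 tests; CCA calibration 500 replicates
of 199 permutations; end-to-end detection 50 replicates at the default
cohort size. Pipeline defaults (K range 2–6, 5 restarts, 1999
permutations) complete a full synthetic run in well under a minute.

## Known limitations

- The template is geometric, not anatomical; lobes and territories are
  sectors, and bullseye parcels should not be interpreted anatomically.
- Streamline bundles are splines, not tractography; tract names from the
  registry label synthetic geometry.
- The geometric corpus route and the planted-outcome route are not
  linked; no synthetic subject's lesions *cause* their factor loadings.
- Wald inference throughout; no profile-likelihood or bootstrap CIs, no
  Firth correction under near-separation (separation is flagged, not
  repaired).
- The longitudinal model supports a scalar random intercept only (no
  random slopes), matching the target analysis.
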