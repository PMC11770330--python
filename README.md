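# lesionfactors

Tract-based lesion disconnectome mapping, latent disconnection factors,
and cognitive-outcome statistics for stroke cohorts — packaged as a
tested, fully synthetic-data-driven pipeline.

## The problem

After a minor ischemic stroke, over a third of patients develop
post-stroke cognitive impairment (PSCI), yet lesion *volume* is a poor
predictor of who. A more mechanistic view asks which white-matter
connections a lesion interrupts: a small lesion in a connectional
bottleneck can disconnect far more cortex than a large one elsewhere.
This package implements that analysis chain for two lesion kinds — acute
infarcts and chronic white matter hyperintensities (WMH) — against a
normative streamline tract atlas:

1. **Lesion mapping** — intracranial-volume-normalized lesion volumes,
   per-vascular-territory volumes (6 supratentorial + 4 infratentorial
   codes), voxelwise incidence maps, and a *bullseye* WMH parcellation:
   9 lobar sectors crossed with 4 concentric relative-depth layers
   between ventricle and cortex (36 parcels; layer 1 periventricular,
   layer 4 juxtacortical).
2. **Disconnectome** — for each atlas tract, the percent of its
   streamlines passing through the lesion mask:
   `pct(tract) = 100 · #{disconnected streamlines} / #{streamlines}`.
   A canonical 70-tract naming registry is provided (65 bundles with the
   corpus callosum represented by 5 segments).
3. **Latent factors** — latent Dirichlet allocation (LDA) over
   discretized disconnection profiles. Subjects are documents, tracts are
   words; the model estimates factor signatures β = Pr(Tract | Factor)
   and subject loadings θ = Pr(Factor | Participant) by mean-field
   variational EM. The number of factors K is chosen by *stability*:
   reproducibility of matched factor signatures across random restarts.
4. **Association statistics** — the any-domain z ≤ −1.5 impairment rule;
   per-factor logistic models of PSCI adjusted for age and education with
   Benjamini–Hochberg FDR; nested-model likelihood-ratio tests; first
   canonical correlation between the four cognitive domain z-scores and a
   loading, with a row-permutation null; and a longitudinal
   random-intercept logistic model (adaptive Gauss–Hermite quadrature)
   of status at months 6 and 36.

Because patient imaging of this kind is not openly shareable, the
`synth` module generates every input — template geometry, streamline
atlas, lesion masks, disconnection corpora with *planted* factors, and
cognitive outcomes with a planted causal effect — so that each stage is
testable end to end against known ground truth. See `docs/methods.md`
for the generative models and their deliberate limits.

## Worked example

```python
import numpy as np
from lesionfactors import (SynthConfig, sample_disconnection_corpus, sample_cognition,
                           DisconnectionCorpus, select_k, fit_lda, factor_load_share, lr_test)
from lesionfactors.pipeline import factor_association_scan

cfg = SynthConfig(seed=7)                      # 105 subjects, 24 tracts, 3 planted factors
counts, truth = sample_disconnection_corpus(cfg)
cohort = sample_cognition(truth.theta_true, cfg, seed=8)
corpus = DisconnectionCorpus(counts=counts)

report = select_k(corpus, k_min=2, k_max=6, n_runs=6, seed=0)
print("stability by K:", {k: round(s, 3) for k, s in zip(report.k_values, report.stability)})
print("selected K =", report.selected_k)

model = fit_lda(corpus, report.selected_k, seed=0)
top, share = factor_load_share(model.beta[1], top_k=10, tract_names=corpus.tract_names)
print(f"factor 2: top-10 tracts carry {share:.0%} of the disconnection load")

scan = factor_association_scan(cohort, {"wmh": model.theta})
print(scan[scan.timepoint == 36][["factor", "or", "p", "p_adj", "reject"]].round(4).to_string(index=False))

chi2, p = lr_test(-56.829, -60.977, df_diff=1)
print(f"added-value LRT: chi2 = {chi2:.2f}, p = {p:.4f}")
```

Output:

```
stability by K: {2: 0.88, 3: 1.0, 4: 0.787, 5: 0.811, 6: 0.797}
selected K = 3
factor 2: top-10 tracts carry 100% of the disconnection load
 factor     or      p  p_adj  reject
      1 0.1439 0.0110 0.0164    True
      2 0.7280 0.5878 0.5878   False
      3 9.4726 0.0019 0.0056    True
added-value LRT: chi2 = 8.30, p = 0.0040
```

Reading it: restart stability peaks at K = 3, the planted number of
factors. The planted causal factor is recovered (here as estimated
factor 3, OR ≈ 9.5 per unit loading for month-36 impairment, surviving
FDR). Factor 1 shows the mirror-image *negative* association that
compositional loadings force on the siblings of a causal factor — the
same pattern the cross-sectional tables of such studies show. Factor
signatures are block-sparse, so ten tracts carry essentially the whole
load of a factor. The likelihood-ratio test, computed here from the
published log-likelihoods of the nested month-36 models, shows the
factor's added value over MoCA, WMH volume, age and education.

The same chain is available from the shell:

```
lesionfactors run-all --out run --seed 1
lesionfactors report --run run
```

which writes per-stage outputs (NIfTI masks and maps, CSV profiles and
tables, JSON model summaries), a checksummed `manifest.json`, and a
Markdown report with per-factor top-tract tables.

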