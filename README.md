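# lespat

Two-tier spatio-temporal analysis of enhancing brain lesions.

**Tier 1** describes each delineated lesion by rotation-invariant shape
features — the sorted eigenvalues of the covariance of its voxel coordinates
(in mm) plus a hollowness index H = A / A_fill that separates ring-enhancing
(H < 1) from focal (H = 1) lesions. Lesions are tracked across time points
and across two contrast agents (Gd and USPIO) by voxel overlap, each
trajectory becomes a fixed-layout feature vector (absent blocks zero-filled),
and the trajectories are clustered with self-tuning spectral clustering (or a
K-means baseline). The number of clusters is estimated by fusing four
validity indices — Dunn, Calinski-Harabasz, the gap statistic and the
Laplacian eigengap of the affinity matrix — as the nearest-integer mean of
their votes. Cluster significance is assessed with a centroid-separation
statistic under randomization and permutation null models.

**Tier 2** summarises each patient by the cardinalities of the lesion-pattern
clusters and fits a no-intercept least-squares regression of a follow-up
outcome volume (chronic hypointense lesion load) on those counts, evaluated
by leave-one-patient-out and leave-one-lesion-out R².

A synthetic-cohort generator emulates the study structure end to end
(25 patients, 2 time points, ~100 Gd / ~24 USPIO lesions, three archetypal
lesion patterns C1/C2/C3, patient groups A/B/C) with known ground truth, so
the full pipeline is testable without any imaging data.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (the 50-seed
end-to-end recovery test takes a few minutes); the rest of the suite runs in
under a minute.

## CLI

The console script `lespat` exposes the pipeline stages:

```sh
lespat simulate out/ --seed 1            # synthetic cohort: masks + outcomes + truth
lespat extract-features out/masks feats.tsv
lespat estimate-k feats.tsv --seed 1
lespat cluster feats.tsv labels.csv --k 3 --algorithm spectral --seed 1
lespat separation-test feats.tsv labels.csv --n-perm 10000 --seed 1
lespat run-all out/masks out/outcomes.csv report/ --seed 1
lespat grid out/masks out/outcomes.csv --seed 1
```

Input masks are integer-labeled NIfTI volumes named
`<patient>_<t>_<agent>.nii[.gz]` (agent `gd` or `uspio`), assumed
co-registered; outcomes are a CSV with columns
`patient_id,hypointense_m24_ml,tll_m24_ml[,group]`.

## Library example

```python
from lespat import CohortSpec, PipelineConfig, run_pipeline, sample_cohort

cohort = sample_cohort(CohortSpec(seed=1))
result = run_pipeline(cohort.observations, cohort.outcomes, PipelineConfig(seed=1))
print(result.validity.votes, result.validity.fused_k)
print(result.model.cluster_sizes(), result.fit.beta, result.fit.r2_loo_patient)
```
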