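# slpattern

Searchlight pattern classification of structural gray-matter volume maps,
with exact binomial and label-permutation cluster inference, covariate-
adjusted post-hoc statistics, and a synthetic cohort generator for
end-to-end testing without patient data.

The pipeline classifies two clinical response groups (medication-resistant
vs medication-sensitive pain, MRP/MSP) from smoothed modulated gray-matter
maps on a common voxel grid:

1. **Searchlight SVM** — at every mask voxel, a sphere of configurable
   physical radius (default 5 mm; 171 voxels on the default 1.5 mm
   isotropic grid) supplies features for an RBF-kernel SVM (C=1,
   gamma=1/V). Leave-one-out cross-validation with leakage-free per-fold
   standardization yields a whole-mask accuracy map.
2. **Binomial inference** — accuracies are converted to exact Bi(n, 0.5)
   upper-tail p-values; suprathreshold voxels (default p < 1e-4) are
   grouped into 18-connected components and size-filtered (default ≥ 50
   voxels).
3. **Permutation validation** — each cluster's LOOCV accuracy is compared
   against label-shuffled reruns (default 1000), with add-one p-values.
4. **Post-hoc statistics** — voxel-wise OLS t-maps with age/gender
   covariates inside detected clusters, Monte-Carlo cluster-extent
   (smoothed-noise simulation) correction, and Spearman correlation of
   cluster mean volume with the pre/post VAS change.
5. **Clinical table** — group summaries with Welch/Student t-tests,
   chi-square for gender, and a noncentral-t sample-size utility.

## Tests

```
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including
multi-minute simulation suites (chance calibration, effect recovery,
permutation calibration, Monte-Carlo threshold monotonicity). One clause
is expected to fail by design: LOOCV with an SVM at n≈15/group is biased
*below* chance on null data (the held-out subject's class is always the
training minority), so the null mask-mean accuracy is ~0.42, not 0.5.
The clause is asserted at its stated band rather than weakened. The bias
makes the binomial cluster inference conservative, and the
zero-false-positive-cluster check passes.

## CLI

All maps are NIfTI-1 (3D, or 4D subject stacks ordered like the subject
CSV); subject tables are CSV with columns
`id,group,age,gender,pre_vas,post_vas,pre_psqi,post_psqi`.

```
# generate a synthetic cohort from a YAML spec
slpattern simulate --config cohort.yaml --out data/

# whole-mask LOOCV accuracy map
slpattern searchlight --volumes data/volumes.nii.gz --mask data/mask.nii.gz \
    --subjects data/subjects.csv --radius-mm 5 --out accuracy.nii.gz

# binomial p-map, clusters, permutation validation
slpattern infer --accuracy accuracy.nii.gz --mask data/mask.nii.gz \
    --volumes data/volumes.nii.gz --subjects data/subjects.csv \
    --voxel-alpha 1e-4 --min-size 50 --connectivity 18 \
    --permutations 1000 --seed 7 --out clusters.json --label-out clusters.nii.gz

# covariate-adjusted t-tests with Monte-Carlo extent correction
slpattern posthoc --volumes data/volumes.nii.gz --mask data/mask.nii.gz \
    --subjects data/subjects.csv --clusters clusters.nii.gz \
    --covariates age,gender --voxel-p 0.01 --alpha 0.05 \
    --mc-iterations 1000 --fwhm-mm 8 --seed 7 --out posthoc.json

# demographic/clinical comparison table
slpattern table1 --subjects data/subjects.csv --out table1.csv

# everything from one config, with seeded reproducibility
slpattern run --config pipeline.yaml
```

A pipeline YAML looks like:

```yaml
synthetic:
  n1: 14
  n2: 15
  grid: {shape: [20, 20, 20], voxel_size: 1.5, mask_margin: 2}
  blobs:
    - {center: [10, 10, 10], radius_mm: 6.0, d: 2.0}
radius_mm: 5.0
inference: {voxel_alpha: 1.0e-4, min_size: 50, connectivity: 18, n_permutations: 1000}
extent: {voxel_p: 0.01, alpha: 0.05, n_iterations: 1000, fwhm_mm: 8.0}
seed: 7
out_dir: out/
```

(Replace `synthetic:` with `input: {volumes: ..., mask: ..., subjects: ...}`
to analyze existing data.)

## Notes

- A single global seed derives all stage seeds; identical configs produce
  byte-identical reports.
- The searchlight uses scikit-learn's low-level libsvm binding for speed
  (~60x over the public estimator at these tiny problem sizes), with a
  public-API fallback and an equivalence test.
- Exact conventions (inclusive sphere boundary, P(X ≥ k) tails, ≥ 50
  cluster size, add-one permutation p) are documented in the module
  docstrings and covered by tests; alternatives are exposed as flags.
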