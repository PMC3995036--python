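# mixshape

Comparing groups of brain images voxel by voxel with *t*-tests only compares
means and is fragile to inter-subject spatial variability.  An alternative is
to compare the *shapes* of each subject's whole-brain distribution of a
scalar measure — for example fractional anisotropy (FA) from diffusion tensor
imaging, whose brain-wide distribution shifts with demyelination, injury and
normal aging.  `mixshape` implements a Gaussian-mixture approach to this
problem for researchers analysing subjects × voxels matrices of scalar
measurements:

1. **Voxelwise standardization.**  Raw measurements are z-scored per voxel
   across subjects, `z_ij = (x_ij − x̄_j) / s_j`, removing regional
   location/scale heterogeneity (e.g. deep vs peripheral white matter FA).
2. **One pooled mixture fit.**  All voxels of all subjects are pooled and fit
   with an *m*-component Gaussian mixture under an equal-variance constraint,

   `f(z) = Σ_k τ(k) · φ((z − μ_k)/σ) / σ`,  `μ_1 < … < μ_m`,

   by an EM algorithm; the number of components is chosen by AIC with
   `d = 2m` parameters.
3. **Subject- and group-level densities a posteriori.**  Each observation
   gets a posterior membership probability
   `τ_ij(k) = τ(k)φ_k(z_ij) / Σ_l τ(l)φ_l(z_ij)`; voxel-averaging gives
   subject mixing probabilities `τ_i(k)`, subject-averaging gives group
   mixing probabilities `τ*_g(k)` with between-subject standard errors.
   Because the components are shared, subjects and groups differ *only* in
   these weights, so distribution shape is summarized by a few directly
   comparable numbers.
4. **Nonparametric comparison.**  Subject-level mixing probabilities are
   compared between groups with Kruskal–Wallis rank tests (pairwise against a
   reference group, plus an omnibus test; optional Holm adjustment).

A synthetic-cohort generator with full ground truth (shared components,
subject-specific mixing probabilities, affine per-voxel raw-scale
heterogeneity) supports simulation studies of every stage.

## Worked example

Generate an FA-like cohort (4 groups × 7 subjects, 20,000 voxels, two
Gaussian components at μ = (−0.26, 0.78), σ = 0.87, group-level τ(2) falling
from 0.272 to 0.213 with age-group index) and run the full pipeline:

```sh
mixshape generate --preset paper_like --seed 1 --out cohort/
mixshape fit --input cohort/matrix.csv --groups cohort/groups.csv \
             --m 1,2,3 --seed 1 --out results/
```

or equivalently in Python:

```python
import mixshape as ms

cohort = ms.generate_cohort(ms.scenario_presets()["paper_like"])
Z, _ = ms.standardize(cohort.raw)
fit, aic_table = ms.select_m(Z, [1, 2, 3], restarts=5, seed=1)
profile = ms.compute_profile(Z, fit.params, cohort.groups)
tests = ms.tests_table(
    ms.pairwise_vs_reference(profile.subject_tau, cohort.groups, Z.subject_ids)
)
```

On the standardized-truth matrix of the seed-1 cohort the two-component fit
prints

```
mu = [-0.257414  0.781398]   sigma = 0.870668
tau = [0.753342  0.246658]
group tau(2):  0.253835  0.252258  0.247206  0.233334
KW group1 vs group4: p = 0.0040    omnibus: p = 0.0034
```

i.e. the fit recovers the generative component means and shared standard
deviation to sampling precision, the fourth group's weight on the high-mean
component is visibly lower (its FA-like distribution is shifted down and more
positively skewed), and the rank tests detect that difference.  Output tables
(`fit_params.csv`, `aic_table.csv`, `subject_mixing.csv`, `group_mixing.csv`,
`tests.csv`) and a JSON run summary are written to `--out`.

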