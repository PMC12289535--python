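# Methods

## The problem

In QSPR/QSAR and related regression modelling, a sample with a large
cross-validated prediction error is an "outlier sample" — but that label
alone does not say what to *do* with it. Two very different situations
produce the same symptom:

* **Consistent outlier (CO).** The sample's x–y relationship agrees with
  the rest of the data; it is merely extreme (often an extrapolation in x).
  A better model, or more data, could explain it. It should be kept — it is
  the most informative sample in the set.
* **Inconsistent outlier (ICO).** No model of the current features can
  reconcile the sample's y with the other samples. This signals a data
  error (wrong structure, transcription mistake) or a missing descriptor.
  Keeping it in training actively degrades predictions of everything else.

The package quantifies the distinction and labels flagged samples.

## The ICO-likeness index

For a candidate sample A in a dataset of n samples:

1. Run outer cross-validation on the full dataset with A available to every
   training partition. Under leave-one-out (LOO, the default) A is also
   held out once; its own prediction error is recorded but never enters the
   index. With k < n outer folds A is instead pinned into the training side
   of every fold.
2. Run outer cross-validation on the dataset *minus* A, under the same fold
   plan restricted to the remaining samples — every sample keeps the fold
   index it had in step 1, so the two runs differ only in A's presence.
3. MAE_wOS = mean absolute error of the step-1 outer predictions over all
   samples except A.
4. MAE_woOS = mean absolute error of the step-2 outer predictions over the
   identical sample set.
5. **ICO-likeness(A) = MAE_wOS − MAE_woOS.**

A large positive value means training with A hurts the prediction of every
other sample — the ICO signature. Values near zero or negative mean A is
consistent (its presence is neutral or helpful): a CO. Because both MAEs
average over exactly the same samples and fold geometry, the difference
isolates A's influence; the scorer asserts the sample-set identity and
raises rather than compare mismatched averages.

Scoring every sample this way amounts to a triple cross-validation (the
candidate loop around a double cross-validation). Because hyperparameter
selection runs inside each outer training partition (for the Gaussian
process backend, the marginal-likelihood maximisation inside each fold fit
is that inner loop), the outer errors are honest prediction errors.

### Candidate pre-filter

Scoring all n samples costs n additional cross-validations. For large
datasets, `top_k` restricts scoring to the samples with the largest outer
absolute errors (ties broken by ascending sample id). The robust
classification rule below uses the scored records as its reference
population, so small `top_k` trades reference quality for speed; scoring
everything is recommended when affordable.

### Classification rule

The CO/ICO decision needs a threshold on ICO-likeness. The default
`robust_z` rule labels a record ICO when its score exceeds

    median + multiplier × MAD        (multiplier default 3)

over all scored records, with MAD the raw (unscaled) median absolute
deviation from the median. Median/MAD are used precisely because the few
very large ICO scores being hunted must not inflate the reference level.
When the MAD is zero and all scores are equal, nothing exceeds the cutoff
and everything is CO (logged). An `absolute_threshold` rule is available
when a domain-specific cutoff is known. The rule choice and multiplier are
this package's own reproducible surrogate for a visual decision; they are
deliberately configurable.

### Multiple pre-detected outliers

If several outliers are already known, scoring them in each other's
presence would let one outlier mask another. `multi_outlier_screen` removes
all of them first, then adds each back alone and scores it against the
clean base, so the records are mutually independent. The without-candidate
cross-validation is identical for every outlier and is cached.

## Regression backends

The default backend is Gaussian-process regression with covariance

    k(x_i, x_j) = θ0 · exp(−(θ1/2)·‖x_i − x_j‖²) + θ2,

implemented as scikit-learn's `ConstantKernel × RBF + ConstantKernel` with
θ1 = 1/ℓ². Because real data are noisy and the kernel alone would force
interpolation, an observation-noise variance (a `WhiteKernel` term, bounds
1e−8…1e2) is fitted jointly with the three kernel hyperparameters; this is
an extension of the printed kernel, not part of it. Hyperparameters are
chosen by maximising the log marginal likelihood from `n_restarts` starts
(default 10; the first from fixed initial values θ0 = 1, ℓ = 1, θ2 = 1,
noise 1e−6, the rest drawn with a seeded generator), making every fit
deterministic and order-independent to numerical precision.

Features are autoscaled (centered, unit variance; zero-variance columns are
centered only) and the target is centered/scaled inside each training fit,
from training data only — with one isotropic length-scale this is what
makes multi-descriptor inputs commensurable.

Any object with the backend contract (`fit(X, y)` returning a handle with
`predict(X)`) can substitute. The bundled ordinary-least-squares backend
exists chiefly as an exactly solvable oracle: its leave-one-out predictions
can be recomputed by hand or by explicit per-sample refits, which the test
suite does. Minimum training sizes: 3 samples for GPR, 2 for OLS (two
points determine a line; the tiny-data oracle tests rely on this).

## Synthetic benchmarks

The reference system is y = sin(x) on the grid x = z/6, z = 0…44 — 45
noiseless samples covering roughly 1.2 periods, curved enough that a linear
model fails and a GPR interpolates almost perfectly. Two single-outlier
injections define the benchmark pair:

* **inconsistent** (default x = 3.0, Δy = +1.5): an interior point shifted
  off the curve — an ICO by construction, since no function of x can pass
  through it and the neighbouring on-curve points;
* **consistent** (default x = 9.0): a point exactly on the curve but ~1.7
  units beyond the sampled range — extreme, unpredictable from the training
  range, yet perfectly consistent.

The injected coordinates are configurable; the defaults are this package's
choice of a representative interior/exterior pair. The generator
reproduces the grid bit-exactly (the grid is computed by division when
1/x_scale is an integer, so x = z/6 holds to the last bit) and injection
never perturbs base rows. Gaussian target noise is available
(`noise_sd`, default 0) for robustness experiments only.

What the benchmarks do *not* emulate: multivariate correlated descriptors,
heteroscedastic noise, clustered designs, or multiple simultaneous
outliers of mixed type. Passing them shows the machinery is correct and
that the index separates the two constructed outlier types under an
accurate backend; it does not by itself validate behaviour on noisy,
high-dimensional chemistry data.

## Numerical choices and degenerate inputs

* Fold plans: assignable samples are shuffled with a seeded generator and
  dealt round-robin, so fold sizes differ by at most one; plans are
  deterministic in (ids, k, seed). Restriction after excluding a sample
  preserves all other fold indices exactly and commutes.
* R² on a subset uses the subset's own target mean; a zero-variance subset
  has undefined R² (reported as NaN; the MAE remains valid).
* MAE is used rather than RMSE because the evaluation set contains no
  outliers by construction (the candidate is excluded), so robustness to
  extreme errors is not needed and the plain average is the cleanest
  comparison.
* If removing a candidate leaves fewer samples than the backend minimum,
  the scorer raises instead of silently reusing the full dataset.
* Candidate ranking ties break by ascending sample id; classification
  preserves input order.
* All randomness (fold shuffling, GPR restarts) flows from explicit seeds;
  reruns with the same configuration are byte-identical.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the full benchmark pair at
its native size — 46 samples, leave-one-out, every sample scored, i.e.
46 + 46 × 45 GPR fits per dataset — with 3 optimizer starts per fit, which
on the smooth noiseless sine data reaches the same optimum as 10 starts.
A shared cache reuses the without-candidate cross-validation wherever the
reduced dataset and partition coincide (the corruption-magnitude sweep
reuses the 45-sample base run across Δy ∈ {0.5, 1, 2}). Oracle-equivalence
checks use 20 random datasets with n ≤ 12 where OLS is exactly solvable.

## Known limitations

* The diagnostic inherits the backend's quality: with a backend that
  underfits (e.g. a straight line through a sine), normal samples already
  have large errors and the contrast between the two MAEs shrinks. The
  dataset-level DCV MAE/R² reported alongside the records indicate whether
  the backend is adequate.
* ICO-likeness is a per-sample deletion diagnostic; two nearby ICOs can
  partially mask each other unless screened via `multi_outlier_screen`
  with both flagged.
* The robust_z rule assumes the scored population is mostly normal; if
  most scored candidates are genuine ICOs the reference level is inflated
  and the rule turns conservative. Conversely, when the backend is nearly
  exact and *no* real ICO exists, all scores are numerically ≈ 0, the MAD
  is tiny, and the rule can flag samples whose scores exceed the cutoff by
  a physically meaningless margin (e.g. 10⁻⁶); inspecting the score
  magnitudes in the report disambiguates.
* With an inconsistent outlier in the training data the GPR marginal
  likelihood becomes multimodal: some optimizer starts select a
  high-noise solution that smooths over all samples. Different restart
  seeds can therefore change the *magnitude* of MAE_wOS (and of the
  injected sample's ICO-likeness) substantially. This works in the
  diagnostic's favour — the with-candidate run degrades while the
  without-candidate run stays sharp — but absolute score values should
  not be compared across seeds or backends.
* k-fold (k < n) mode pins the candidate into training, so the candidate's
  own outer error is not produced by that run; rankings should come from a
  prior plain cross-validation (the pipeline does this automatically).
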