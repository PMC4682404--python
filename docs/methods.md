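# Methods

This note documents the model implemented by `depca`, the choices made
where the design was genuinely open, the synthetic data the tests run on,
and the numerical conventions.

## The model

Let `S` be the item-by-sample matrix of normalized expression levels
(log-scale units), with `n` samples and `m` items. The analysis proceeds
in four steps.

**1. Reference centering.** A per-item reference `r` is the item-wise
mean of a designated sample set: the control group when the design has
one, otherwise all samples (grand mean). The centered matrix is

    X[k, l] = S[l, k] − r[l]        (samples × items)

Missing cells are replaced by exactly 0, as are all cells of *excluded*
items (items removed by the ANOVA filter, or whose reference could not be
computed because every designated cell was missing). Zero means "no
difference from the reference", so the replacement moves scores toward
the origin and never manufactures a signal — the fail-safe direction for
screening applications. `m_f`, the number of functional items, is a
property of the matrix: items not excluded. Per-sample missing cells are
zero-filled but do **not** reduce `m_f`; a single global `m_f` keeps the
scaling well defined (a per-sample variant is never needed because the
zero fill already shrinks the affected scores).

**2. Training matrix.** `T` has one row per experimental group: the
mean (default), trimmed mean or median of the group's centered samples.
`T` is **not** re-centered before decomposition — the reference already
fixed the center of rotation, and subtracting `T`'s column means again
would silently move the origin back to the grand mean of the groups. A
group can instead be *expanded*, contributing each of its samples as a
separate row; this deliberately reproduces group bias (used in testing
and for diagnosing biased designs), because each extra row pulls the axes
toward that group.

**3. Axis identification.** `T = U_T D_T V_T*` by singular value
decomposition. Axes with singular value below `1e-12 ×` the largest are
numerically null and dropped, so they cannot pollute scaled scores with
noise amplified from rounding error. Each axis is only defined up to
sign; the sign is fixed deterministically: the loading of largest
absolute value in each column of `V_T` is made positive (ties broken by
lowest item index), and the corresponding column of `U_T` is negated with
it, so the factorization is unchanged and shared axis files are
reproducible without manual intervention.

**4. Scores and scaling.** Sample scores `Y_s = X V_T`, item scores
`Y_i = T* U_T`. Because `V_T`'s columns have unit norm, an individual
loading is of order `m_f^(−1/2)`, and the inner product of a row of `X`
with a loading column — a sum of `m_f` terms — grows like `m_f^(1/2)`
for data whose per-item magnitude is stable under item selection. Scaled
scores divide this growth out:

    Z_s = m_f^(−1/2) Y_s        Z_i = n_t^(−1/2) Y_i

leaving the *average per-item (per-row) contribution*. The ratios between
axes are retained (the singular values are not cancelled). Consequences,
each verified by a test: duplicating every item `k` times multiplies
`Y_s` by `√k` exactly and leaves `Z_s` unchanged; replicating training
rows does the same to `Y_i`/`Z_i`; scaled sample and item scores share
one size unit and can be presented jointly; and scores computed on
different item subsets have comparable ranges.

**Projection of new data.** A stored axis model carries `V_T`, `D_T`,
`U_T`, the reference vector, `n_t` and `m_f`. New matrices are matched to
the model by item id: model items absent from the new matrix contribute 0
(scores shrink toward the origin, never away), and matrix items absent
from the model are dropped with a logged count. Unknown samples are
classified by Euclidean distance, in scaled component space over a
configurable number of leading axes (default all retained), to each
training representative; ties go to the earlier training row.

**Degenerate configuration.** With one group per sample, mean
representative and grand-mean reference, `T = X` and the procedure
reduces exactly to textbook SVD-PCA of the column-centered matrix; a test
checks score agreement with an independent PCA to 1e−8.

## The ANOVA filter

When probe-level data are available (each gene measured by several probes
across all samples), genes are screened with the additive two-factor
fixed-effects model

    value = overall level + probe sensitivity + group effect + error

and the F test for the group factor at α = 0.01 (the conventional F
p-value; no multiplicity correction by default, with an optional
Benjamini–Hochberg mode). Genes with < 2 probes, < 2 groups or no
residual degree of freedom are untestable and never positive. Negative
genes are passed to the zero-replacement step. Implementation: residual
sums of squares via QR projections of the shared design matrices,
vectorized over all genes with the same probe count; a test cross-checks
p-values against a per-gene OLS ANOVA (statsmodels) and an explicit
sum-of-squares decomposition. A one-way gene-level fallback
(`anova_group_test_gene_level`) is provided for data without probes; it
cannot model probe sensitivity and is labeled an approximation.

## Synthetic designed experiments

The generator (`depca.synthetic`) emulates the two validation settings
the method targets — a developmental time course and a toxicology panel
of repeated chemical treatments:

    value[item, sample] = baseline_item
                        + loadings_item · latent[group]
                        + loadings_item · jitter_sample   (heterogeneous items)
                        + within-group noise               (variable group)
                        + spike                            (outlier samples)
                        + Normal(0, noise_sd)

Groups occupy positions on `n_latent` (default 2) latent axes, so the
true component structure is low-rank and every geometric claim can be
checked against ground truth. Defaults, chosen once as realistic study
conditions: 7 groups × 5 replicates, 200 items of which 150 are
informative with N(0, 1) loadings, individual noise sd 0.5 (log-scale
units), baseline N(8, 1), and latent group displacements of magnitude
1.5 = 3 × noise sd. The deterministic toxicology layout places the
control at the origin, three "toxic" groups sharing a large displacement
on latent axis 1 with spread along axis 2, and three "nontoxic" groups
near the control — the geometry used for the held-out-classification and
bias tests. A within-group-variable group receives extra per-sample
Gaussian noise (default sd 1.5) on all informative items: individual
differences spread over many items, which is the noise mode the method is
designed to resist, rather than single-item outliers (available
separately as outlier spikes).

What the generator does *not* emulate: array-specific artifacts (spatial
effects, cross-hybridization), heavy-tailed or correlated noise,
mean–variance coupling, and batch effects. Passing tests therefore
demonstrate the algebraic and statistical properties of the method under
its own assumptions, not performance on any particular real platform.

## Numerical conventions and problem sizes

* All text output uses `%.12g`, so shared axis files round-trip
  bit-exactly at that precision; `NA`/empty on input mean missing.
* Factorization contracts (orthonormality, reconstruction, projection
  consistency) are asserted at 1e−10 on instances up to 20 × 500; the
  scaling law at relative error 1e−9; textbook-PCA equivalence at 1e−8
  (sign-aligned per axis).
* Trimmed-mean representative: default trim fraction 0.2 per tail;
  groups with fewer than 5 samples fall back to the mean with a warning,
  and a fraction that would trim away a whole group is an error.
* Every stochastic routine takes an explicit seed; there is no hidden
  global random state, and a fixed config + seed reproduces outputs
  byte-identically.
* The verification suite and `scripts/acceptance.py` use moderate problem
  sizes — 10 × 200 matrices for the scaling law, 10,000 genes for filter
  calibration, 50 simulation replicates for the classification and bias
  checks, 20 for range stability — sizes at which the Monte-Carlo
  standard errors are small compared with the effects being measured.

## Known limitations

* The group-effect filter assumes additive probe and group effects with
  homoscedastic Gaussian error; strong probe × group interaction would
  inflate the residual and reduce power.
* `m_f` is global; experiments in which different samples have massively
  different missingness patterns will see affected samples' scores shrink
  toward the origin (by design), which is conservative but not corrected.
* Classification is nearest-representative with Euclidean distance in
  component space; it inherits the axes' linearity and does not model
  within-group covariance.
* Robust SVD variants are deliberately not implemented: with noise
  arising from small individual differences across many items rather than
  outliers in single items, averaging replicates into training rows is
  the effective defense, and a comparison hook is all that is reserved.
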