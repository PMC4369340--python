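# Methods

`craniopgls` implements a phylogenetic comparative analysis of linear
cranial morphometrics for a clade of related species measured at the
specimen level: shape extraction by log-shape ratios, ordination by
covariance PCA, phylogenetic signal by Blomberg's *K* and its
multivariate extension *K*_mult, and hypothesis tests by distance-based
phylogenetic generalized least squares (D-PGLS) with permutation
inference. This note records the model, the numerical choices, the
defaults and their rationale, and the limitations of what the synthetic
tests demonstrate.

## Size and shape

Each specimen carries *p* = 10 positive linear measurements
*x₁…x_p* (mm). Size is the geometric mean
*g* = (∏ⱼ xⱼ)^(1/p), and shape is the vector of log-shape ratios
*zⱼ* = log(xⱼ/g). By construction Σⱼ zⱼ = 0, so the shape matrix has
rank ≤ *p* − 1, and *z* is invariant to uniform rescaling of the
specimen — size carries the scale exactly. Species means are arithmetic
means of the log-shape ratios (transform first, then average); averaging
raw measurements first and transforming after is available by computing
shape from externally averaged tables, but the transform-first order is
the package default because the log-shape ratios are the analysis
currency throughout.

Specimens with missing or non-positive measurements are dropped with a
warning (strict mode raises instead); an optional boolean adult flag
drops juveniles with a logged count. Facial tilt (FT) — the angle
between the upper diastema line and the occipital plane, in degrees — is
ingested as data and analyzed in degrees; no implicit unit conversion.

## Ordination

PCA is an eigendecomposition of the sample covariance matrix
(*n* − 1 denominator) of the column-centred data. Covariance, not
correlation: the log-shape ratios share one scale. The zero-sum
constraint forces one null eigenvalue; the null axis is retained with
proportion 0 rather than silently removed. Eigenvector signs are
basis-arbitrary, so each loading column is flipped to make its
largest-magnitude entry positive and published loadings should be
compared by magnitude. Components whose relative eigenvalue gap is
below 1e−8 are flagged as tied; their internal order is not meaningful.

## Brownian motion and the phylogenetic covariance

A rooted tree with branch lengths implies, under Brownian motion (BM),
tip covariance **C** with C_ij equal to the shared root-to-tip path
length of tips *i* and *j*. `PhyloTree.vcv()` computes **C** in one tree
traversal. The whitening transform **P** = **C**^(−1/2) is obtained by
eigendecomposition; eigenvalues below `tol` (default 1e−10 × largest)
are excluded, giving pseudo-inverse behaviour when zero-length branches
make **C** singular, and any eigenvalue below −`tol` raises. Newick
parsing is strict — every non-root edge must carry a branch length, and
quoted labels or comments are rejected — because silently defaulted
branch lengths or mangled taxon names corrupt comparative datasets.
Taxon matching between tables and tree is exact (whitespace-trimmed,
case-sensitive), and the Newick tip order is the canonical row order of
every matrix.

## Phylogenetic signal

For a univariate species-mean vector **x**,

K = [ (x−â1)ᵀ(x−â1) / (x−â1)ᵀC⁻¹(x−â1) ] / E,
E = [tr(C) − N/(1ᵀC⁻¹1)] / (N−1),

with â the phylogenetically weighted mean (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹x. K = 1 is
the BM expectation; K < 1 means relatives resemble each other less than
BM predicts. *K*_mult replaces squared deviations with squared Euclidean
distances across all traits, numerator Σᵢ‖Yᵢ−â‖² and denominator the
same after whitening by **P**, divided by the same trait-count-free E.
Both statistics are evaluated through **P** rather than a separate
linear solve, which makes the single-trait reduction *K*_mult ≡ *K*
exact to machine precision and inherits the pseudo-inverse handling of
singular **C**. Significance: species means are shuffled among the tips,
the statistic recomputed, and the observed value counted among the
permutations, p = (1 + #{perm ≥ obs})/(n_perm + 1); ties count as ≥
(conservative), and p can never be 0. The null hypothesis of this test
is *no* signal — exchangeable tips — so its type-I error is calibrated
against iid traits, and BM-structured traits are the alternative.

## D-PGLS

Responses (N×p species means) and the single-term design matrix
(intercept plus dummy-coded factor with alphabetically first reference
level, or a raw covariate) are premultiplied by **P** and fitted by OLS
in the whitened space. Sums of squares are trace-based: SS_total is the
summed squared residual of the intercept-only whitened fit, SS_resid of
the full whitened fit, SS_model their difference;
F = (SS_model/df_model)/(SS_resid/df_resid) and R² = SS_model/SS_total.
For p = 1 the coefficients are numerically identical to explicit GLS,
(XᵀC⁻¹X)⁻¹XᵀC⁻¹y; the trace construction is what keeps the test defined
when p approaches N (no Wilks/Pillai statistics are offered). Only
single-term models are supported, so Type-I/Type-III distinctions never
arise.

### Permutation inference

Two schemes are implemented; both count the observed F among the
permutations.

* `permutation="tips"` (default): rows of the **raw** species means are
  reassigned to tips, X and **C** fixed. This is the classically printed
  scheme for D-PGLS, and it is an exact test when tip values are
  exchangeable under the null. When the response is phylogenetically
  correlated it is **not** calibrated: measured on a structured 16-tip
  tree with BM responses and groups painted on clades it rejects a true
  null at ≈ 0.30 instead of 0.05, while with group labels assigned at
  random it is conservative (≈ 0.01). The parametric F of the whitened
  model is exact in both cases, so the defect is the reference
  distribution, not the fit.
* `permutation="rrpp"`: residual randomization — the residuals of the
  intercept-only whitened model are permuted and the F recomputed
  (the null fitted values lie in the design span and cancel from both
  quadratic forms). This keeps the type-I error nominal on structured
  trees in both labelling regimes and is the recommended scheme for
  confirmatory use; `tips` remains the default for fidelity to the
  method as commonly published.

Both schemes draw uniform random permutations from a single integer
seed; permutations are vectorized, so 1000 permutations of a 16 × 10
response cost milliseconds.

## Synthetic studies

`simulate_study` generates every pipeline input with the structure the
analysis assumes. Trees are pure-birth (Yule, unit rate), rescaled to
unit height, with terminal branches extended by the Exp(n) waiting time
to the next unrealised speciation; draws whose shortest branch is below
2% of tree height are rejected and redrawn, because published
supermatrix phylogenies are resolved with non-negligible branch lengths
and near-zero branches make **C** ill-conditioned (species means then
carry sampling noise that the BM model cannot absorb, degenerating the
GLS fit). Set `min_branch_frac=0` for unconditioned Yule trees.

Defaults emulate a 16-species leporid-style design: 2–12 specimens per
species; locomotor composition 3 generalized / 10 saltatorial / 3
cursorial with 9 of 16 burrowers; facial tilt built as group base means
44.0 / 37.2 / 36.3° plus a BM deviation of variance 4 deg² per unit
height plus within-species noise of SD 5.5°, so the specimen-level group
SD is ≈ √(4 + 5.5²) ≈ 5.8°, in the mid-5s like typical cranial-angle
data. Shape evolves as BM on the log scale (variance 0.02 log² per unit
height per variable) around realistic adult cranial root values, with an
additional isometric log-size walk (variance 0.04) shared by all ten
measurements — the shape ratios must remove it exactly — and
within-species log-normal noise of SD 0.04. Group labels are assigned
uniformly at random by default, or painted onto blocks contiguous in
tip order (`group_mode="clades"`) to confound ecology with ancestry;
the contrast between the two modes is what demonstrates why
phylogenetic and ordinary ANOVA differ. These defaults are fixtures for
testing, not empirical claims.

What the generator does **not** emulate: measurement error correlated
across variables, juvenile contamination, unequal within-species
variances, non-Brownian evolution (no OU, no early burst, no rate
shifts), or missing data patterns. Passing tests therefore demonstrate
algebraic correctness and statistical calibration under the stated
model, not robustness to violations of it.

## Numerical choices and degenerate inputs

* `inv_sqrt` tolerance: 1e−10 × largest eigenvalue; below-tolerance
  eigendirections are excluded (pseudo-inverse); eigenvalues < −tol
  raise "matrix not PSD".
* Constant traits (zero variance) raise rather than return K = ∞ or
  F of 0/0; constant design factors (single level) raise at design
  construction; rank deficiency after whitening raises at model
  construction.
* Eigenvalue ties in PCA are flagged when the relative gap < 1e−8.
* p-values are observed-inclusive, so min p = 1/(n_perm + 1).
* All CSV output uses 6 significant digits; Newick output uses 12.
* One seed per entry point; the pipeline splits its seed
  deterministically per stage, so a single integer reproduces the whole
  report byte-for-byte.

## Problem sizes used in the shipped checks

The self-contained acceptance checks run at 16 taxa (500 null
simulations × 199 permutations for the type-I and K-calibration
experiments, 10 000 replicates for the simulator covariance check),
matching the study scale while completing in seconds. The same
machinery accepts user-supplied data of arbitrary size through
`craniopgls run`.

## Known limitations

* Brownian motion only: no Pagel's λ, OU, or measurement-error models.
* Single-term models: no interactions, no ANCOVA.
* The default `tips` permutation scheme inherits the calibration defect
  described above; use `rrpp` when the predictor may align with clades.
* Reproducing a published study's exact statistics requires that
  study's specimen data and pruned tree as inputs; the packaged ecology
  fixture supplies only the species-level design (locomotor class,
  burrowing, specimen counts).
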