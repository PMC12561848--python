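# Methods

## Data model and scope

All analyses consume a *balanced* long-format table: g genotypes (the
enzymes assayed) × e environments (water temperatures) × r complete
blocks, one observation per combination. Balance is a hard precondition;
missing or duplicated cells raise errors naming the combination, and no
imputation is attempted. Labels are opaque: numeric-looking temperature
labels are never interpreted ordinally in any computation — only their
given ordering is used, and only for display.

## Split-plot ANOVA

The observation model is

    y_mnp = μ + a_p + g_mn + h_mp + ε_mnp

with blocks p, main-plot (temperature) levels m, sub-plot (enzyme) levels
n, main-plot error h_mp ~ N(0, σ_h²) shared by all enzymes in one
(temperature, block) main plot, and sub-plot error ε ~ N(0, σ²). Sums of
squares use the standard balanced decomposition: blocks and the main
factor from their marginal means, the main-plot error from the
(temperature × block) cell means after removing block and temperature
effects, the sub factor and interaction from treatment cell means, and the
sub-plot error as the remainder. F(main) = MS(main)/MS(main-plot error);
F(sub) and F(interaction) use MS(sub-plot error). The blocks row carries
no F or p, matching standard reporting of this design. p-values are
upper-tail F probabilities at full precision; the report formatter renders
values below 0.001 as `<0.001`.

Designs need g ≥ 2, e ≥ 2 and r ≥ 2; with r = 1 the main-plot error
stratum has zero df and the fit refuses rather than silently pooling.

## AMMI

Cell means over blocks are decomposed as μ + ρ_g + ψ_e + residual; the
doubly-centered residual matrix is decomposed by SVD. Axis n carries
SS = r·θ_n² and Gollob df = g + e − 1 − 2n; the df of all min(g−1, e−1)
axes sum exactly to the interaction df (g−1)(e−1).

Design choices:

- **Pooled error.** The AMMI table pools blocks and both split-plot error
  strata into a single error row with df = ger − 1 − (ge − 1) = ge(r−1);
  every systematic row (treatment, genotype, environment, interaction,
  each IPCA axis) is F-tested against its MS. Cornelius-type or
  resampling tests for axis significance are out of scope.
- **Retained axes.** `n_axes` defaults to 2 — the convention of two-axis
  biplot work, and the structure (IPCA1, IPCA2, residual) used in
  published AMMI tables of this kind of study, including designs where
  more axes would have positive Gollob df. `n_axes=None` retains every
  axis with positive Gollob df, in which case axis SS + residual SS still
  conserve the interaction SS exactly.
- **Sign convention.** SVD signs are arbitrary; each axis is oriented so
  its largest-magnitude environment score is positive (first such entry
  on ties), making scores reproducible across platforms.
- **Percent columns.** Genotype, environment and interaction rows are
  percent of *total* SS; IPCA rows are percent of *interaction* SS. This
  dual convention is the one under which the bundled reference tables
  reproduce exactly.
- **Degenerate input.** A constant table yields zero SS everywhere; axes
  are retained with θ = 0 and F reported as 0 rather than undefined.

Significance flags are assigned strictly by comparing the computed p to
the threshold. (One bundled reference table marks an IPCA row with a
1%-level flag while printing p = 0.3338; the recomputed p confirms 0.3338,
so the flag appears to be a typesetting slip — the harness compares the
numbers, not the stars.)

## GGE biplot

The cell-mean table is environment-centered only — column means removed,
genotype main effect retained — with no scaling by environment standard
deviations, and decomposed by SVD. Markers use the partitioning
genotype = θ^f·ξ, environment = θ^(1−f)·η with f = 0.5 by default
(configurable to 0 and 1). All sector winners and rankings reported by the
views are driven by genotype·environment inner products, which equal
θ·ξ·η summed over axes and are therefore invariant to f.

Numerical choices:

- Singular values below eps·max(g, e)·θ₁ are truncated to exactly zero;
  otherwise θ^f with f < 1 inflates numerical noise (θ ≈ 1e−16 becomes a
  visible 1e−8 coordinate) and corrupts the degenerate-case geometry.
- The environment-relationship angles are arccos of normalized inner
  products of the 2-D environment markers; pairs involving a zero-length
  vector are reported as NaN, not an error.
- The convex hull needs ≥ 3 genotype markers in general position; on
  collinear or too-few markers the which-won-where view warns and falls
  back to direct inner-product winners (the hull-sector winner is in any
  case the genotype maximizing the inner product with the environment
  vector, which is how winners are computed throughout).
- Sector ties within 1e−9 of the maximal inner product report all tied
  genotypes, ordered by genotype order; rankings break ties by genotype
  order (stable sort).
- The average-environment (AEC) axis is the unit vector toward the mean
  environment marker; if that mean has essentially zero length (≤ 1e−9 of
  the largest environment marker) the mean-vs-stability and ideal-entry
  views raise, since the axis direction is meaningless.
- With a rank-2 (or lower) centered table the two-axis model is exact:
  reconstruction, winners-equal-argmax, and projection-ranking-equals-
  row-mean-ranking all hold to 1e−8 and are tested. This covers every
  g ≤ 3 design (environment-centering leaves rank ≤ g−1) and every e ≤ 2
  design; for larger tables the views are the standard rank-2
  approximation.

## Synthetic data

The generator draws from exactly the model the split-plot ANOVA assumes:

    y_gep = μ + block_p + geno_g + env_e + gxe_ge + h_ep + ε_gep

with Gaussian noise throughout and the main-plot draw h shared within each
(environment, block) pair — the feature that makes the main-plot stratum
estimable. Defaults mirror a realistic enzyme-activity trial: g = 4,
e = 5, r = 6 (the common four-antioxidant × five-temperature × six-block
layout), μ = 100 activity units, σ_sub = 1.0, σ_main = 0.5, σ_block = 0.5
— noise SDs chosen so that block and main-plot variation are present but
subordinate to the sub-plot residual, as in assay data where technical
replication dominates. Effect vectors must be centered and the interaction
doubly centered, so generating parameters coincide with the estimands.

`make_effects_for_target_ss` inverts the closed-form expected sums of
squares: given target percentages of total SS for genotype, environment
and interaction, it solves for the total via the expected pooled-error SS,
subtracts each row's noise inflation (e.g. (g−1)σ² for the genotype row),
and scales polynomial-contrast effect patterns to hit the remaining
structural SS. Expected shares then equal the targets exactly in the
formulas and to Monte-Carlo accuracy in simulation; a nonzero target below
its noise floor is rejected as infeasible, and exact-zero targets mean "no
structural effect". The planted interaction is a deterministic rank-k
matrix built from orthonormal polynomial contrasts with configurable
per-axis shares (default 0.9/0.1, an IPCA1-dominant spectrum like those
seen in real enzyme panels).

What the generator does *not* emulate: enzyme kinetics or any
temperature–response curve shape (environment labels are arbitrary),
non-Gaussian or heteroscedastic noise, unbalanced or missing data, and
correlations among enzymes beyond what the planted low-rank interaction
induces. Passing recovery tests therefore demonstrate that the estimators
are correct and calibrated under the assumed model, not that the model
describes any particular real dataset.

## Validation harness

Six reference ANOVA summaries (three split-plot, three AMMI) from a
large-yellow-croaker cold-stress enzyme study are bundled as SS/df
fixtures with their printed MS/F/p/% values kept as strings. The harness
recomputes every derived cell from SS and df alone and requires agreement
within one unit in the last printed digit — the printed tables round
intermediate mean squares, so exact half-ulp rounding is not always
attainable (e.g. one recomputed p of 0.9789 against a printed 0.9788). A
printed `<0.001` is checked as an upper bound and a printed `0` as
p < 1e−4. All 114 comparable cells reproduce.

## Problem sizes

The statistical calibration tests use the study-sized design (4 × 5 × 6):
200 simulation seeds for SS-share recovery (±2 percentage points on the
mean) and 2000 null replicates for the type-I error of the sub-plot F test
(accepted band 0.03–0.07 at α = 0.05, ≈ ±4 binomial SDs). Oracle
equivalence runs on 102 random designs with g, e, r ≤ 4 at 1e−8 relative
tolerance. These sizes give stable checks while keeping the full suite
under a minute of compute.

## Known limitations

- Balanced complete-block designs only; no covariates, no REML variance
  components, no post hoc multiple comparisons.
- AMMI axis tests use Gollob df with the pooled error, which is known to
  be liberal for later axes; treat IPCA p-values as descriptive.
- GGE geometry is strictly two-dimensional; when the first two axes
  explain little variance the views can mislead, and `var_explained_`
  should be inspected first.
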