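# Methods

## Models

Every computation in this package is an instance of one weighted
mixed-model family. Observations (real or pseudo) on a set of units with
random effects `u` and incidence `X_r` satisfy

    y = X b + X_r u + e,   u ~ N(0, Ω σ²_u),   e ~ N(0, D⁻¹ σ²_e),

with diagonal weight matrix `D`. The coefficient matrix of Henderson's
equations is

    LHS = [[X'DX, X'D X_r], [X_r'D X, X_r'D X_r + λ Ω⁻¹]],  λ = σ²_e/σ²_u,

and reliabilities need only the random-effect block of `LHS⁻¹` (prediction
error variances), never the right-hand side. The families used:

| family | units | X_r | Ω |
|---|---|---|---|
| PBLUP (Step 1) | all animals | identity (records→animals) | A |
| weighted PBLUP (Steps 2, 4, 7, reverse) | all animals | I | A |
| SNPBLUP, no RPG (blended Step 3) | genotyped | Z | I_m |
| SNPBLUP with RPG (direct Step 3) | genotyped | W=[√(1−ω)Z, √ω I] | blockdiag(I_m, A₂₂) |
| GBLUP (either Step 3 route) | genotyped | I | G or G_ω |
| ssGBLUP (exact oracle) | all animals | I | H |

Reliability of animal *i* is `1 − λ·PEV-coordinate/K_ii`, where the
denominator `K_ii` is the diagonal of the model's own relationship matrix:
`1 + F_i` for pedigree-based models and for non-genotyped animals in the
exact oracle, `G_ii` for the marker-only model, `(G_ω)_ii` for models
carrying the RPG effect. Using each model's own diagonal puts approximate
and exact reliabilities on the same scale, which is what the comparison
statistics assume. For marker-effect models the PEV coordinate is the
quadratic form `W_i C^{uu} W_i'` in the covariate row of animal *i*.

Model equivalences used as correctness oracles (and enforced by tests to
1e-8): SNPBLUP ≡ GBLUP(ZZ') when ZZ' is invertible; SNPBLUP-with-RPG ≡
GBLUP(G_ω); with every animal genotyped and shared weights, both ≡ the
exact single-step model.

## Parameters

- `σ²_u`, `σ²_e` (trait units²): additive and residual variances; only the
  ratio λ enters reliabilities. Synthetic default h² = 0.4 on a unit
  phenotypic variance, so λ = 1.5.
- `ω ∈ [0,1]`: residual polygenic fraction of the additive variance,
  default 0.3 — the share of genetic variance the markers do not capture,
  modelled through pedigree relationships among genotyped animals.
- ERC floor 0.01 (effective records): lower bound applied when combining
  weights (Step 6) so that no equation becomes numerically empty; the
  number of floored values is logged.
- Reverse-reliability tolerance 1e-5 on r², at most 100 sweeps.

## Centering and scaling of markers

Dosages are centered by twice the allele frequency and the whole matrix is
divided by the single scalar √(2Σp_i(1−p_i)) (VanRaden's first method), so
G = ZZ' is on the scale of A. Frequencies default to those observed in the
genotyped animals; an external base-population frequency file can override
them. With observed frequencies the columns of Z sum to zero, so ZZ' is
exactly singular (null vector **1**) — the reason the blended path defaults
to the marker-effect formulation, which never inverts ZZ'. Where a GBLUP on
a singular matrix is explicitly requested, a logged ridge of 1e-8 is added
only if the caller permits it. Missing dosages are mean-imputed to 2p
before centering; monomorphic markers must be removed first
(`GenotypeSet.drop_monomorphic`).

## Reverse reliability

Given target reliabilities for a subset of animals, the reverse operation
finds nonnegative weights for the weighted animal model (mean + additive
effect over the full pedigree) that reproduce them. Because weights cannot
be negative this is a complementarity problem: at the solution each animal
either meets its target or sits at weight zero with relatives alone already
exceeding the target. Targets of the second kind arise routinely in Step 4
— a dam whose Step-1 reliability is fully explained by her progeny's
weights — and any algorithm must handle them.

The solver is a projected Newton iteration. One factorization of the
weighted MME yields both the exact current reliabilities and, from the same
inverse columns, the exact Jacobian

    ∂r²_i/∂d_j = λ (C_{i,μ} + C_{ij})² / (1 + F_i),

where the mean-column term appears because a weight enters the mean
equation as well (omitting it breaks convergence — it is not a minor
correction). Far from the solution, damped (0.8) diagonal Newton steps are
taken; once the worst residual is below 1e-3, full Newton steps with a
backtracking line search finish quadratically (typically < 25 sweeps
total). Updates are projected onto d ≥ 0 with an active set, and per-sweep
growth is capped at 10× so that a target that *saturates* (unreachable even
as d → ∞, e.g. a single weighted animal whose record is confounded with the
mean) ends in a clean convergence error rather than overflow. The scalar
case d = λr²/(1−r²) is exact at the starting value.

The scheme-C progeny-information proxy performs its two reversals under the
no-mean model: measuring information against a known mean keeps unrelated
animals exactly decoupled, which the differencing requires. It is a
synthetic stand-in for the Interbull effective-daughter-contribution
convention, and its imperfection — information reaching an animal through
removed records but not through its own progeny is still attributed to
progeny — is why scheme C is reported but not held to strict agreement.
The reduced Step-1 refit behind it removes the records of genotyped
animals having a genotyped parent and restores each such animal's own
records for its own reliability by a rank-k Woodbury update of its inverse
diagonal (a record contributes a rank-one term v v' to the LHS, v being
its design row).

## Exact oracle and comparability

The exact reliabilities invert the single-step animal model built on
`H⁻¹ = A⁻¹ + [0; G_ω⁻¹ − A₂₂⁻¹]`, with the general mean and one weight per
record. Step 1, by contrast, carries contemporary-group fixed effects, so
each record there loses a little information to the group mean. The
approximation chain therefore starts from slightly poorer information than
the oracle assumes; at default group sizes (~50 records/level) the effect
is below the noise of the comparison and shows up, if at all, as a slope
marginally above 1.

## Synthetic populations

The generator produces what the method assumes and nothing more: discrete
non-overlapping generations with random mating (sexes alternate by birth
order so mating never fails; sires and dams drawn with replacement from the
previous generation), founder marker alleles at frequencies uniform on
[0.05, 0.5] gene-dropped through the pedigree, an RPG component gene-dropped
as founder N(0, ωσ²_u) deviations plus inbreeding-adjusted Mendelian terms
(so the simulated genetic covariance is exactly (1−ω)σ²_u·ZZ' + ωσ²_u·A),
one record per recorded animal with a contemporary-group effect, and
genotyping probability increasing with generation (∝ (gen+1)²) to mimic the
young-genotyped cohorts of dairy programs. Defaults: 120 founders, 5
generations × 60 matings × 6 offspring → 1,920 animals, 20% genotyped
(384), 50% recorded, 1,000 markers, 20 fixed levels, h² = 0.4, ω = 0.3.
All draws flow from one integer seed through named `default_rng` streams.

What the generator does **not** emulate: linkage disequilibrium and finite
QTL architectures (markers are the causal loci), selection, overlapping
generations, genotyping-by-merit, repeated or missing records, multi-trait
structure. Passing the end-to-end checks therefore shows the approximation
tracks the exact single-step computation when the model is true; it does
not measure robustness to model misspecification on real data.

## Numerical choices

- Dense Cholesky factorization up to 5,000 equations; sparse LU with
  column-selected inverse above (identical results to 1e-8 by test).
- Full-inverse requests on dense factors go through LAPACK Cholesky
  inversion; inverse blocks for small subsets solve unit columns instead.
- Reliabilities are clipped to [0, 1−1e-12] and a value below −1e-10
  raises, signalling an ill-conditioned system; clip counts are logged.
- A⁻¹ uses Henderson's rules with exact inbreeding from the Meuwissen–Luo
  ancestor traversal, so it is the true inverse of the tabular A also for
  inbred pedigrees. Unknown parents are unrelated non-inbred founders; no
  genetic groups.
- Step-1 fixed effects use cell-means coding (one cell per observed level,
  no separate mean), which keeps the fixed block full-rank by construction.

## Problem sizes

Unit and oracle tests run on pedigrees of 3–300 animals with 40–200
markers. The end-to-end replication uses the default 1,920-animal scenario
over five seeds (≈20 s per seed end to end, including the exact oracle);
these sizes were chosen to keep the full validation cycle interactive while
being large enough that the genotyped/non-genotyped/young structure of a
real evaluation is present.

## Known limitations

- Single trait throughout; per-lactation analyses are separate runs.
- The Step-1 engine is exact (dense inversion) and thus desk-scale;
  externally computed Step-1 reliabilities can be supplied through the
  config to mimic production use with an approximation in front.
- Scheme C is a documented proxy, not the Interbull EDC computation.
- No PCG/iterative solvers; the package targets method validation, not
  half-million-animal production runs.
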