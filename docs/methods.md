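# Methods

## Model and decomposition

Observations are `Y_ij = f(x_i, g_j) + eps_ij`, `i = 1..n` positions shared
by all subjects, `j = 1..s` subjects each carrying a binary group label.
`f` lives in the tensor product of an m-th order *homogeneous* (periodic)
Sobolev space on [0,1] and the two-point group space. Averaging operators on
each margin split `f` into

    f = f00 + f10(x) + f01(g) + f11(x, g),

and parallelism of the two group curves is exactly `f11 = 0`. The marginal
kernels are

- position mean: constant 1;
- position contrast: `K1(x,z) = (-1)^(m-1) k_{2m}(frac(z-x))`, `k_r = B_r/r!`
  scaled Bernoulli polynomials (closed forms for m = 1, 2, 3; default m = 2,
  the cubic-smoothing-spline analogue). `K1` is positive semi-definite,
  integrates to zero in each argument, and its Gram spectrum decays like
  `i^(-2m)` (verified empirically in the suite: log–log slope −3.9 ± 0.3 at
  n = 500);
- group mean: 1/2; group contrast: `1(g = g') - 1/2`.

Products of these give the four component kernels K00, K01, K10, K11
(position-contrast kernels carry the printed factor 1/2).

## Estimation

With `S = [1, g - 1/2]` spanning the unpenalized subspace and
`R = theta10 K10 + theta11 K11` the penalized kernel (theta's set by trace
equalization, `theta_b * tr(K_b) = 1`, so both penalized blocks enter the
penalty with unit trace), the penalized least-squares problem

    min_{d,c}  (1/ns) ||y - S d - R c||^2 + lam c' R c

has the classical solution through `M = R + ns*lam*I`:

    d = (S'M^-1S)^-1 S'M^-1 y,
    c = M^-1 (I - S (S'M^-1S)^-1 S'M^-1) y,
    f11_hat = K11 c   (the constant scale theta11 is not folded in).

Note the matrix-form objective printed with 1/(ns)-scaled kernel matrices is
off by a factor ns in the penalty relative to the functional form; we fix
the λ-parametrization via `M = R + ns*lam*I`, which makes λ the weight of
the roughness functional against the *mean* squared error. The closed form
is verified against an independent minimizer of the objective (stacked
least-squares on `[S, R; 0, sqrt(lam) R^{1/2}]`) to 1e-6 relative on random
small designs. A caution for readers of the single-coefficient ("alpha")
parametrization over the full composite kernel: with finite unpenalized
scales it is a *slightly different* estimator (relative difference ~1e-3);
the (d, c) form above is the one whose f11 component has the closed form.

The noise variance is `sigma2_hat = y'(I-A)^2 y / Tr(I-A)` with the
symmetric smoother `A` (note `(I-A)y = ns*lam*c` exactly). The λ at which
sigma2 is evaluated is chosen by GCV on the same grid; an alternative
(pilot λ at the testing-optimal rate, refreshed once) inflates sigma2 by
20–60% at realistic n because the large smooth main effect leaks into the
residual, which both deflates size (0.01 vs the nominal 0.05 in the parallel
null scenario) and costs power; GCV gives sigma2 = 1.00 ± 0.03 across all
iid scenarios and is the standard estimation-oriented choice.

## Test and calibration

The Wald statistic is `T = ||f11_hat||^2 / ns`. For group-balanced designs
the group-contrast direction is exactly orthogonal to the subject-mean
direction, so f00, f10 and f01 cancel from `f11_hat` *identically* — the
null moments

    mu = sigma^2 Tr(Delta)/ns,  sd^2 = 2 sigma^4 Tr(Delta^2)/ns^2,
    Delta = M^-1 K11^2 M^-1,

depend only on the design, λ and sigma^2 (Wilks phenomenon; asserted
bit-exactly in the suite by injecting arbitrary parallel structure). The
decision is two-sided: reject when `|T - mu| >= z_{alpha/2} sd`. Because T
is a nonnegative quadratic form, two-sidedness effectively prices the
rejection at the right tail's alpha/2, which is what keeps the empirical
size near 0.05 even where the Gaussian approximation is rough (below).

λ is selected by the testing-oriented rule: the smallest grid λ with
`lambda >= sd(lambda)` — the crossing of the penalty scale with the null
standard deviation, balancing smoothing bias against the statistic's
spread. The default grid is 50 log-spaced points in [1e-8, 1]. As printed
with a strict "<" the rule would select the arbitrary grid lower bound
(sd(λ) is nonincreasing), so the crossing is the only non-degenerate
reading. The constant multiplying sd in the crossing is genuinely free in
the underlying theory; we use 1. Sensitivity: in the frequency-difference
scenario (Setting 2, n = 200) the selected λ* gives effective dimension ~2
and power 0.90, while fixed λ one to two decades smaller gives 0.94–1.00;
shrinking the constant, however, pushes the correlated-noise and
change-point scenarios 5–10 points *above* their reference values, so 1 is
kept as the best single compromise.

## Computation

For complete, balanced designs all component matrices factorize as
(subject-space matrix) ⊗ (position Gram), the active subject directions are
the all-ones vector and the signed group contrast, and after one n × n
symmetric eigendecomposition every λ-dependent quantity — fits, effective
degrees of freedom, GCV, Tr(Delta), Tr(Delta²), the statistic — costs O(n)
to O(n²). The dense reference implementation (Cholesky of M, no explicit
inverses, jitter 1e-10 tr(M)/ns on the diagonal) is retained for unbalanced
designs and as the oracle in equivalence tests; spectral and dense paths
agree to 1e-10.

## Synthetic data

Seven scenarios cover magnitude, frequency, combined, non-constant
magnitude, pure parallel shift (size), AR(1)-correlated noise, and a
non-smooth change-point truth; base curve `2.5 sin(3 pi x)(1 - x)`, noise
sd 1, positions iid U(0,1) (evenly spaced midpoints for the correlated and
change-point scenarios). The non-constant magnitude knob enters as the
exponent `(1-x)^(1+delta3)`; the change-point truth is
`2.5 sin(2 pi x) 1{x<0.5} + (1 + delta5 1{case})(x-1) 1{x>=0.5}`.

Each group contains **two** independent curves by default (s = 4). With a
single curve per group the published power of the frequency-difference
scenario (0.98 at n = 200, also for the permutation benchmark) exceeds what
any test can deliver except a near-perfectly aligned oracle, while with two
curves per group the whole table set reproduces to within a few points;
the generator therefore defaults to two. Replicate r of a power run uses
seed base + r; every run is bit-reproducible from its seed.

What the generators do *not* emulate: heteroscedastic or heavy-tailed
noise, missing cells, unbalanced group sizes, within-subject correlation
beyond AR(1), and position-dependent sampling density. Passing tests
therefore speak to the calibration and power of the statistic under clean
sampling, not to robustness against those features.

## Known limitations

- **Gaussian null is a tail approximation at λ\*.** The testing-optimal λ
  keeps the effective dimension very small (~2–8 even at n = 1000), so the
  standardized null statistic retains chi-square skewness and fails a KS
  test against N(0,1) at 1000 replicates; normality does hold at fixed λ
  with larger effective dimension (verified in the suite at effective
  dimension ≈ 56). Size control survives because the two-sided rule prices
  only the right tail.
- **Correlated noise inflates size.** AR(1) noise with rho = 0.5 has
  low-frequency spectral density 3x the marginal variance, exactly where the
  statistic lives; any sigma2 estimating the marginal variance leaves the
  test anti-conservative under such noise (the GCV sigma2 partially absorbs
  the correlation). Power under AR(1) reproduces reference behaviour; sizes
  do not, and users with strongly autocorrelated residuals should prefer the
  permutation engine on whitened residuals or subject-level replication.
- **Permutation and Wald p-values differ in the null bulk** (one-sided
  resampling vs two-sided normal on a skewed form); they agree in the
  decision-relevant tail.
- Binary groups and a single continuous coordinate only; positions must form
  a complete grid across subjects (missing cells are rejected, not imputed).
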