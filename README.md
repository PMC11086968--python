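# parcurve

Nonparametric parallelism testing for paired curves via smoothing-spline ANOVA.

## The problem

Many case–control designs produce *curves*: DNA-methylation levels along
genome position, BOLD signal over time, expression over a time course. A
recurring question is whether the case and control curves are **parallel** —
differing at most by a vertical shift — or whether their *shapes* diverge.
Parallel curves mean the group effect is a constant offset; nonparallel
curves mean the group interacts with position/time, which is usually the
biologically interesting signal (e.g. a differentially methylated region).

parcurve models observations

    Y_ij = f(x_i, g_j) + eps_ij,      x_i in [0,1],  g_j in {0,1},

with `f` in a tensor-product reproducing kernel Hilbert space and the
functional ANOVA decomposition

    f = f00 + f10(x) + f01(g) + f11(x, g),

where `f00` is the grand mean, `f10` the shared curve shape, `f01` the group
shift, and `f11` the **nonparallel effect**. Parallelism is exactly
`H0: f11 = 0`.

## The test

The continuous margin uses the m-th order periodic Sobolev kernel built from
scaled Bernoulli polynomials, `K1(x, z) = (-1)^(m-1) k_{2m}(z - x)` with
`k_r = B_r/r!` (default m = 2, the cubic-spline analogue); the group margin
uses the two-point mean/contrast kernels (constant 1/2 and
`1(g = g') - 1/2`). `f` is fitted by penalized least squares; the
interaction estimate has the closed form

    f11_hat = K11 M^-1 (I - S (S'M^-1S)^-1 S'M^-1) y,     M = R + ns*lam*I,

with `S` the unpenalized design (intercept + group contrast) and
`R = theta10*K10 + theta11*K11` the trace-equalized penalty kernel. The Wald
statistic is

    T = ||f11_hat||^2 / ns,

whose null distribution is asymptotically Gaussian with moments

    mu = sigma^2 Tr(Delta)/ns,   sd^2 = 2 sigma^4 Tr(Delta^2)/ns^2,
    Delta = M^-1 K11^2 M^-1,

*free of the nuisance components* f00, f10, f01 (a Wilks-type phenomenon),
so the decision rule `|T - mu| >= z_{alpha/2} sd` needs no resampling. The
smoothing parameter is chosen by the testing-oriented rule
`lambda* = min{lambda : lambda >= sd(lambda)}` (the crossing of the penalty
scale with the statistic's null standard deviation), and `sigma^2` by the
GCV-selected fit on the same grid. A within-position permutation benchmark
with the same statistic is included.

For complete, group-balanced designs every matrix factorizes into (subject
space) x (position space), so the whole pipeline runs from a single n x n
symmetric eigendecomposition — Monte-Carlo power studies at n = 1000 take
well under a second per replicate.

## Worked example

```python
from parcurve import SimulationSetting, generate, parallelism_test, permutation_test

# two curves per group, n = 300 shared positions, constant magnitude
# difference delta1 = 1 between case and control
setting = SimulationSetting(setting_id=1, n=300, delta1=1.0, seed=7)
points = generate(setting)

res = parallelism_test(points, alpha=0.05)
print(res.statistic, res.z, res.p_value, res.lambda_star, res.reject)
```

prints (exactly, for this seed):

```
statistic   T = 0.0016577
null mean  mu = 0.000139351
null sd    sd = 0.000135063
z             = 11.2418
p-value       = 2.54e-29
lambda*       = 0.000176
sigma2_hat    = 0.9896
edf           = 5.39
reject at 5%  = True
permutation p = 0.001996
```

The statistic sits 11 null standard deviations above its null mean — the
curves are emphatically nonparallel (they were simulated with a magnitude
difference). The permutation benchmark (500 permutations) agrees at its
resolution floor of 1/501. The estimated noise variance 0.99 recovers the
simulation's sigma = 1, and the fit spends ~5 effective degrees of freedom.

The same test from the shell, plus region scanning with BH FDR control:

```
parcurve test data.tsv --case-label case --control-label control
parcurve scan data.tsv regions.bed --out results.tsv
parcurve simulate --setting 1 --n 300 --delta1 1.0 --reps 200 --seed 1
```

`scan` tests each BED region separately (positions rescaled to [0,1] within
the region) and reports Benjamini–Hochberg q-values across regions; regions
with too few positions are reported as NA, never silently dropped.

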