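# Methods

## Generative model for synthetic arrays

The simulator emulates a paired single-channel miRNA microarray
experiment: each of `n_patients` patients contributes one scar and one
normal-skin array over `n_mirnas` probes. On the log2 scale the true
expression of miRNA *g* on the array of patient *i*, condition *c*, is

    L = mu_g + b_i + delta_g * 1[c = scar] + eps,

with `mu_g ~ N(baseline_mean, baseline_sd^2)` per-miRNA baselines,
`b_i ~ N(0, patient_sd^2)` per-patient random effects shared by both of
a patient's arrays, `eps ~ N(0, noise_sd^2)` residual noise, and a
planted signed effect `delta_g` that is nonzero for `n_true_de` miRNAs.
A fraction `frac_down` of the planted effects are negative (lowered in
scar). The raw scanner intensity is

    raw = (2^L + background_level) * 2^{f_a(L)},

an additive background plus a smooth multiplicative per-array bias
`f_a`, a degree-2 Chebyshev polynomial in `L` (rescaled to [-1, 1])
with per-array random coefficients, normalized so its sup-norm is at
most `bias_amplitude`. The bias is multiplicative on the raw scale —
additive on the log scale — which is exactly the distortion MA-lowess
normalization removes; it exercises the preprocessing non-trivially.

Under this model the per-patient paired difference for a null miRNA is
`N(0, 2 * noise_sd^2)` — the patient effect cancels — so the paired
t-test is exact, and planted miRNAs separate the two condition groups,
so distance-correlation screening is expected to rank them highly.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_mirnas` | 513 | the analyzable probe count of the study design emulated |
| `n_patients` | 9 | the study's paired sample size |
| `n_true_de` | 20 | a few percent of probes, typical for a focused contrast |
| `frac_down` | 0.75 | most differential miRNAs lowered in scar tissue |
| `effect_log2` | 1.5 | a 2.8-fold change, detectable but not trivial at n = 9 |
| `baseline_mean`, `baseline_sd` | 8, 2 | log2 intensities centred near 256 with a realistic dynamic range |
| `patient_sd` | 0.5 | between-patient variation of the same order as noise |
| `noise_sd` | 0.5 | residual log2 SD typical of array replicates |
| `background_level` | 50 | a modest fraction of the median raw signal (~256) |
| `bias_amplitude` | 0.5 | up to ±0.5 log2 of smooth per-array distortion |

`effect_log2` is documented as the mean |log2 fold change| of planted
miRNAs and implemented as a fixed magnitude (a degenerate distribution
with that mean); this keeps planted effects exactly recoverable and the
generator deterministic given a seed. Age/sex covariates are not
simulated; the downstream analysis never uses them.

What the generator does **not** emulate: probe-level replicate spots,
spatial artifacts, dye effects, heavy-tailed or intensity-dependent
noise, and correlation between miRNAs. Passing tests therefore show the
pipeline's statistical machinery is correct under its stated
assumptions, not that real arrays meet those assumptions.

## Preprocessing

Background is subtracted (globally or per array) and clamped at a raw
floor of 1.0 so the subsequent log2 is finite; the number of floored
values is logged. Normalization is MA-lowess against a median
pseudo-array: for array *a* with log2 values `x_a` and reference `r`
(per-miRNA median over arrays), a robust locally weighted regression of
`M = x_a − r` on `A = (x_a + r)/2` (span 0.3, 3 robustness iterations;
both configurable, fit via statsmodels lowess) is subtracted from
`x_a`. The median reference is deterministic and order-independent, and
costs one fit per array rather than a cycle of pairwise fits.

One pass is applied per array. A locally weighted smoother is not a
projection, so re-applying the operation refits residual noise (at
scale roughly `noise_sd / sqrt(span * n_mirnas)`) rather than leaving
the matrix fixed; iterating fit-and-subtract sweeps to a fixed point
was evaluated and rejected — the robust weights oscillate between
sweeps and edge windows amplify, so the iteration diverges on small
matrices. The operative contract, asserted in the tests, is that a
second application's corrections are a small fraction (< 25%) of the
first pass's and leave every array's median M within ±0.05 of zero.

The detection filter keeps rows exceeding `min_signal` (default
`log2(2 * floor)`, one doubling above the floor) in at least
`ceil(min_fraction * n_arrays)` arrays (default half). The original
probe-set-to-513 inclusion rule is not public, so the filter is
explicit and configurable; removed row counts are logged.

## Differential expression

Per-miRNA paired t-tests on log2 differences, two-sided, df = n − 1.
Zero-variance rows are retained so the multiple-testing denominator m
stays well defined: sd = 0 with mean = 0 yields (t = 0, p = 1); sd = 0
with mean ≠ 0 yields (t = ±inf, p = 0) and a logged warning. "q-value"
means the BH step-up adjusted p-value (parameter-free, reproducible;
via statsmodels `multipletests`); Storey's pi0-estimated variant is
available as `fdr_method="storey"` with the single-lambda (0.5)
estimator. Fold change is reported anti-logged (`2^mean_diff`) and the
column labelled explicitly. Output rows are sorted by p, ties broken by
miRNA id, so results are byte-stable.

## DC-SIS

The squared distance covariance is the V-statistic from double-centred
pairwise distance matrices; tiny negative rounding residues are clamped
at 0, and dCor² is defined as 0 when either marginal distance variance
vanishes (constant input). The V-statistic (biased) form is used rather
than the unbiased U-statistic, matching the original screening
formulation; its O(1/m) positive bias is visible in the independence
simulations and is why those checks use a loose bound. The screening
response is the 0/1 scar indicator over all arrays; the paired
structure is deliberately ignored (the screen is defined for i.i.d.
samples), so the model-size rule uses n = number of arrays by default
(`n_rule="pairs"` switches to patients for sensitivity analysis). The
logarithm in d = multiplier * floor(n / log n) is natural, the
convention of the sure-independence-screening literature; the base and
multiplier are configurable. Ties in omega are broken lexicographically
by id so output is platform-independent. At n = 18 arrays the default
rule gives d = 36; at n = 9 patients, d = 24.

## Over-representation

Standard GMT input; duplicate members collapse; the universe defaults
to the union of annotated genes (configurable, since reference-set
choices differ between tools). p = P(X ≥ k) including the observed k,
computed with scipy's hypergeometric survival function; q by the same
BH routine as the differential stage. Query genes outside the universe
are dropped and counted in the log. Mapping miRNAs to target genes is
out of scope; a user-supplied miRNA-to-gene table can bridge the stages.

## Reporting

Percentages are 100 * count / n_selected rounded half-up to one
decimal. miRNAs with an exactly zero mean difference go to a separate
logged `unchanged` bucket rather than being forced into the two-way
split, which presumes no exact zeros. The report stage re-asserts the
structural invariant that FDR-significant miRNAs are t-test-significant
and reports (without asserting) whether they are DC-SIS-selected.

## Problem sizes in the test suite and acceptance script

Screening recovery uses 100 seeds of 500 miRNAs x 9 patients with 10
planted 1.5-log2 effects at noise 0.5; type-I error uses 10 x 10,000
null miRNAs; FDR control uses 50 seeds of 500 miRNAs with 10% true
effects; bias removal uses three 513 x 18 datasets at bias amplitude
0.5. Recovery, type-I and FDR simulations set `background_level=0` and
`bias_amplitude=0` so the stated noise level is exactly the one
analysed; preprocessing distortions are exercised separately by the
normalization checks. These sizes give stable estimates (binomial SE
about 3% on the recovery fraction, 0.07% on the type-I rate) while the
whole suite runs in well under a minute.

## Known limitations

- The headline selection counts of any particular real experiment are
  not reproducible from simulation; only the arithmetic and the
  statistical properties of the methods are checked.
- Storey's pi0 estimate with a single lambda is crude for small m.
- DC-SIS p-values / permutation thresholds are not implemented; the
  screen returns ranks and a top-d cut only.
- No moderated-variance (shrinkage) t-test; the traditional paired t is
  the point of comparison.
- Lowess normalization assumes most miRNAs are non-differential; with a
  large differential fraction the robust fit can absorb part of the
  signal (mild attenuation is visible in simulations when planted rows
  exceed a few percent of probes).
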