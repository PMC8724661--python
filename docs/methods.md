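# Methods

## Model

For subject $i = 1,\dots,n$ with $n_i$ repeated measurements, the
conditional $\tau$-quantile of the response is modelled as

$$
Q_\tau(y_{ij} \mid x_{ij}, b_i) = x_{ij}^\top \beta_\tau + z_{ij}^\top b_i ,
$$

with Gaussian random effects $b_i \sim N_r(0, \Psi)$ independent across
subjects.  Estimation is by maximum likelihood under asymmetric-Laplace
(ALD) residuals,

$$
y_{ij} = x_{ij}^\top \beta_\tau + z_{ij}^\top b_i + \varepsilon_{ij},
\qquad \varepsilon_{ij} \sim \mathrm{ALD}(0, \sigma, \tau),
$$

whose density
$f(u) = \frac{\tau(1-\tau)}{\sigma}\exp\{-\rho_\tau(u/\sigma)\}$
is built on the check loss $\rho_\tau(u) = u(\tau - I\{u < 0\})$.  Because
$\mathrm{ALD}(0,\sigma,\tau)$ has its $\tau$-quantile at zero, maximizing
this likelihood targets the conditional quantile; it is a working
likelihood, not a claim about the true error law.  The parameters are
$\theta = (\beta_\tau, \sigma, \Psi)$, estimated separately at each
quantile level.

The default design mirrors a longitudinal CD4-count analysis: fixed
effects (intercept, time in months, $\sqrt{\text{time}}$, baseline BMI,
baseline log viral load, an antiretroviral-treatment indicator that
switches on at treatment start, and baseline age), random effects
(intercept, time, $\sqrt{\text{time}}$).

## SAEM estimation (`qlmm.saem`)

The random effects are missing data; the fit alternates:

**E-step (simulation).**  Per iteration, `m` draws of each subject's $b_i$
are produced by a random-walk Metropolis–Hastings chain on the conditional
posterior $p(b_i \mid y_i, \theta)$, warm-started at the previous
iteration's last state, with a shared proposal scale adapted toward a 30%
acceptance rate during the memory-free phase.  Subjects are updated in a
single vectorized pass over zero-padded arrays.

**Stochastic approximation.**  The usual SA recursion on sufficient
statistics does not apply directly because the check loss is not quadratic
in $b_i$.  Instead the recursion is realized on a weighted pool of draw
batches: at iteration $k$ with step size $\delta_k$, every stored batch
weight is multiplied by $1 - \delta_k$, the new batch enters with weight
$\delta_k / m$ per draw, and batches with negligible weight are pruned.
Any pool-weighted average of a per-draw statistic then equals the SA
recursion applied to that statistic exactly, including non-quadratic ones.

**Step-size schedule.**  With cut point $\lfloor cW \rfloor$ of a total of
$W$ iterations,

$$
\delta_k = 1 \text{ for } k \le \lfloor cW \rfloor, \qquad
\delta_k = \frac{1}{k - \lfloor cW \rfloor} \text{ afterwards.}
$$

During the first phase ($\delta_k = 1$) each update wipes the pool, so the
algorithm is exactly Monte-Carlo EM; afterwards the $1/k$-type decay
averages the stochastic fluctuations (Robbins–Monro).

**M-steps.**  Given the pool:

- $\beta$ minimizes the pool-weighted check loss.  Small stacked problems
  are solved exactly as a linear program (sparse interior-point via HiGHS);
  above a row limit an iteratively-reweighted least squares scheme with an
  annealed smoothing floor ($10^{-6} \to 10^{-12}$) is used.
- $\sigma$ has the closed form: the pool-weighted mean per-observation
  check loss (the unique stationary point of the ALD likelihood in
  $\sigma$).
- $\Psi$ is the pool-weighted second moment of the draws, SA-smoothed and
  projected to the symmetric positive-definite cone with an eigenvalue
  floor.

**Initialization.**  $\beta^{(0)}$ is the fixed-effects-only check-loss
fit.  $\Psi^{(0)}$ defaults to a moment estimate: the covariance of
per-subject least-squares projections of the $\beta^{(0)}$-residuals onto
each subject's random-effects design, floored to be positive definite.
(A flat $0.1 I$ start is available via `psi_init="identity"`, but with the
heavy-tailed check-loss geometry it can leave $\Psi$ nearly frozen when the
truth is far from $0.1 I$.)

## Marginal likelihood and model selection (`qlmm.inference`)

The marginal log-likelihood integrates the random effects out per subject
by importance sampling with a defensive mixture proposal

$$
q_i = \tfrac12\, N(\hat b_i, C_i) + \tfrac12\, N(0, \Psi),
$$

where $\hat b_i$ and $C_i$ are the posterior mean and a $1.5\times$
inflated posterior covariance taken from the SAEM draw pool (SPD-floored).
The prior component bounds the importance weights, preventing the weight
degeneracy a prior-only or posterior-only proposal exhibits here; at the
default $M = 600$ draws the estimator was verified against adaptive
quadrature (relative error $< 0.5\%$ for $r = 1$) and against $M$-doubling
sweeps for $r = 3$ (bias within 0.5 log-likelihood units).  With no random
effects the computation is exact.

Model selection reports AIC $= -2\ell + 2p$, BIC $= -2\ell + p\ln N$ and
HQC $= -2\ell + 2p\ln\ln N$ with $N$ the number of observations and $p$
the number of fixed effects plus distinct elements of $\Psi$; whether
$\sigma$ is counted is exposed as `include_sigma`, since both conventions
appear in published tables for this model family.
`compare_random_structures` fits each candidate random-effects structure
with a common seed and ranks by AIC.

Standard errors for $\beta$ use the Louis observed-information identity
with the pool draws; the non-differentiable check-loss score is smoothed
with a Gaussian kernel of bandwidth $h = 0.5\,\hat\sigma N^{-1/5}$.  A
parametric bootstrap is available as an alternative (`method="bootstrap"`).

## Synthetic cohort generator (`qlmm.simulate`)

`generate_cohort` emulates a longitudinal CD4 study: 235 subjects on a
monthly visit grid with per-subject follow-up spanning roughly 2–61 months
(median near 29, about 7,000 observations in total), baseline BMI from a
truncated normal matching a mean of 28.9 on [17.9, 54.9], baseline log
viral load with median near 10.3, age with median 25 on [18, 59], and a
treatment indicator switching on at a per-subject start month.  Responses
follow the model above with recorded truth (`TruthRecord`); error families
`ald`, `gaussian` and `t3` are supported, each centred so its
$\tau$-quantile is zero.  The generator matches marginal summaries and the
visit process only — it makes no claim to reproduce subject-level
correlation structure of any real cohort beyond the fitted model's own.

Two experiment harnesses sit on top: `recovery_experiment`
(simulate-and-refit bias/RMSE/coverage per parameter) and
`selection_experiment` (does the criterion pick the generating random
structure).  For the selection experiment the generating dispersion
defaults to `SELECTION_PSI = diag(16, 0.25, 9)`.  This is deliberately
large: within a subject the intercept is nearly collinear with
span{$t$, $\sqrt t$} and $\sqrt t$ with span{$1$, $t$}, and the
ALD(0, 1, 0.5) error variance is 8, so a Gaussian-KL power calculation
shows weak variance components are informationally invisible — the
per-subject evidence must exceed the AIC penalty for the extra $\Psi$
parameters before any criterion can detect them.

## Problem sizes

Test and acceptance problem sizes are chosen to fit a single-CPU budget:
recovery uses 8 replicates of 100 subjects with 2–10 visits; the selection
study uses 5 replicates of 60 subjects (four fits each at $W = 100$,
roughly 80 s per replicate).  The statistical assertions use Monte-Carlo
standard errors computed from the replicate counts actually run, so the
checks remain honest at these sizes.  The `analysis/` drivers run slightly
larger versions of the same studies.

## Limitations

- The ALD is a working likelihood; the "likelihood" entering AIC/BIC is
  therefore also a working quantity, which is the standard practice for
  this model class but worth remembering when comparing across families.
- Fits at different $\tau$ are separate; nothing prevents crossing of
  estimated quantile surfaces.
- Louis standard errors rely on kernel-smoothing a non-smooth score;
  coverage was checked by simulation at the default designs, not proven.
- The importance-sampling log-likelihood is simulation-based; criterion
  differences smaller than its Monte-Carlo error (order 0.1–0.5 units at
  the defaults) are not interpretable.
- The MH E-step uses a shared adapted scale, not per-subject adaptation;
  very unbalanced designs may mix unevenly.
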