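# Methods

## Data model and notation

One analysis works on a single ground-truth stratum (different-source items
for false positives; the machinery is symmetric for same-source / false
negatives). Examiner `i` of `I` is assigned `J_i` items; `y_ij = 1` if their
definitive decision on item `j` would be an error, `r_ij = 1` if a definitive
decision was returned. Sufficient statistics per examiner are `J_i`, the
response count `R_i`, and the observed error count `E_i = sum of y_ij` over
the observed items. `I*` counts examiners with `R_i > 0`.

Inconclusive decisions are either counted as observed-correct answers (the
prevalent convention in black-box studies) or as missing; "no value"
determinations and unanswered items are missing under both policies. The
pooled non-response rate `1 - R_tot/J` deliberately drops the unit/item
distinction, because the published analyses do. Examiners enrolled but
returning no record at all are dropped by default (matching the restriction
of analyses to participants who returned something) and can be included with
`include_unit_nonrespondents=True`.

All Beta distributions use the mean/concentration parameterization
`Beta(mu*tau, (1-mu)*tau)`: `mu` is the population mean, `tau` the
concentration (larger = more homogeneous examiners).

## The three models

* **Naive** (complete data, `I*` examiners, observed items only):
  `y_ij ~ Bern(p_i)`, `p_i ~ Beta(mu_p tau_p, (1-mu_p) tau_p)`. A Bayesian
  stand-in for what studies currently report.
* **Ignorable** (all `I` examiners, all `J_i` items): adds
  `r_ij ~ Bern(pi_i)` with its own Beta population, independent of `y_ij`.
  Missingness affects precision, not location.
* **Non-ignorable** (selection model): the response probability depends on
  the latent error — `r_ij | y_ij=0 ~ Bern(pi1_i)`,
  `r_ij | y_ij=1 ~ Bern(pi2_i)`, with three independent Beta populations.
  `mu_pi2 << mu_pi1` encodes "errors go unanswered".

The observed-data likelihood of `(E_i, R_i)` for the selection model is, per
examiner,

```
C(J_i,R_i) C(R_i,E_i) (p_i pi2_i)^E_i ((1-p_i) pi1_i)^(R_i-E_i)
    [p_i (1-pi2_i) + (1-p_i)(1-pi1_i)]^(J_i-R_i)
```

— each unanswered item is a mixture of a suppressed error and a suppressed
correct answer.

## Empirical Bayes for the selection model

Fully Bayesian fitting of the six hyperparameters is only weakly identified
at realistic non-response rates (the `mu`/`tau` pairs mix very slowly and
drift to boundaries), so the selection model is fit by empirical Bayes:
integrate `p_i, pi1_i, pi2_i` out of the likelihood against their Beta
populations, and maximize the resulting marginal likelihood over the six
hyperparameters. Expanding the mixture term binomially turns the triple
integral into a finite sum over the latent missing-error count
`z_i in 0..J_i-R_i` of products of Beta functions. The sum is computed
exactly (never truncated) in log space via log-sum-exp; rows with identical
`(J, R, E)` are collapsed with multiplicities, which makes the evaluation
cost independent of `I` for fixed designs.

Optimization works on the unconstrained scale (logit `mu`, log `tau`) with
L-BFGS-B from multiple dispersed starts — stratified so that `mu_pi2` starts
both near zero and near `mu_pi1`, because the surface is multimodal when
response and error rates are correlated — followed by a Nelder–Mead polish
of the best optimum (the surface is near-flat along some directions when
selection hyperparameters approach a boundary). The default is 20 starts.
Estimates within 1e-3 of the conventional truncation box
(`mu` in (0.001, 0.999), `tau` > 0.001) are flagged in the result rather
than hidden: boundary MLEs are a finding, not a numerical accident.

**Identifiability caveat.** The product `p * pi2` is well identified by the
observed error counts, but `p` and `pi2` separately are identified only
through the missing-item mixture term. At high non-response with strongly
selective missingness the profile likelihood has a genuine ridge: very
different `(mu_p, mu_pi2)` pairs fit essentially equally well, and the
global MLE need not sit near the generating values even at `I = 2000`. The
package's recovery tests therefore run in a regime with modest non-response
(mean response ≈ 0.86) and moderately separated response blocks
(`mu_p=0.1, tau_p=5, mu_pi1=0.9, tau_pi1=10, mu_pi2=0.5, tau_pi2=10`),
where the MLE is stable; this mirrors the empirical observation that these
models fit cleanly on simulated data with lower non-response and weaker
error/response coupling, and poorly otherwise.

## Samplers

All conditionals are conjugate, so the samplers are plain Gibbs with data
augmentation — no generic MCMC engine, no slice sampling, and therefore no
need for the truncated priors that generic engines require to avoid
numerical failure (truncation remains available in `PriorSpec`).

* Naive: `p_i | · ~ Beta(a_p + E_i, b_p + R_i - E_i)`; when the
  hyperparameters are sampled, `(mu_p, tau_p)` move in a joint random-walk
  Metropolis step on the (logit, log) scale, with the transform Jacobian,
  targeting the product of Beta densities times a Beta(1,1) prior on `mu`
  and a Gamma(shape 2, rate 0.5) prior on `tau`. Proposal scale adapts
  toward a 0.2–0.45 acceptance rate during burn-in only and is frozen
  afterwards, so detailed balance holds for every retained draw.
* Ignorable: adds `pi_i | · ~ Beta(a_pi + R_i, b_pi + J_i - R_i)` and a
  second Metropolis block. Under ignorability the missing `y_ij` carry no
  information about `p_i`, so its update uses observed errors only.
* Non-ignorable (hyperparameters fixed at the EB MLE): per sweep,
  `z_i ~ Binomial(J_i - R_i, q_i)` with
  `q_i = p_i(1-pi2_i) / [p_i(1-pi2_i) + (1-p_i)(1-pi1_i)]`, then
  `p_i | · ~ Beta(a_p + E_i + z_i, b_p + J_i - E_i - z_i)`,
  `pi1_i | · ~ Beta(a_1 + R_i - E_i, b_1 + J_i - R_i - z_i)`,
  `pi2_i | · ~ Beta(a_2 + E_i, b_2 + z_i)`. A fully Bayesian variant that
  also samples the six hyperparameters exists behind an explicit
  `experimental=True` flag and requires user-supplied informative priors,
  reflecting that diffuse defaults do not identify it.

Defaults reproduce the published analysis settings: 2 chains, 15 000
iterations / 5 000 burn-in for the naive and ignorable models; 40 000 /
10 000 (inconclusives observed) and 60 000 / 10 000 (inconclusives missing)
for the non-ignorable model. Per-chain streams derive from one master seed
(`SeedSequence(seed, spawn_key=(chain,))`); identical configurations are
bit-for-bit reproducible. Beta draws are clipped to
`[1e-12, 1 - 1e-12]` to keep downstream logs finite.

Convergence is assessed by (i) the nonoverlapping batch-means Monte Carlo
standard error per probability parameter — batch size `floor(sqrt(n))`,
MCSE = sd(batch means)/sqrt(#batches) — with threshold 0.01, and (ii) the
Brooks–Gelman multivariate potential scale reduction factor over all
monitored probability parameters, threshold 1.1 (naive/ignorable) or 1.2
(non-ignorable). If the pooled within-chain covariance is singular the
maximum univariate PSRF is used and flagged.

## The posterior-predictive error proportion PE

`PE` is the proportion of errors expected in a *new* study with the same
assignment and response pattern. Per retained posterior draw, one PE draw is
simulated:

* naive: `E_i ~ Bin(R_i, p_i)`, `PE = sum E_i / R_tot` over the `I*`
  responders — the study "is" the observed items;
* ignorable: `E_i_obs ~ Bin(R_i, p_i pi_i)`,
  `E_i_mis ~ Bin(J_i - R_i, p_i (1 - pi_i))`, `PE = total / J`;
* non-ignorable: the same two binomials with `pi2_i` in both roles.

Summaries are the predictive mean and the equal-tailed 95% interval of the
PE draws (quantiles recomputable exactly from the persisted draws). Note the
semantics: observed error counts are *re-drawn*, not conditioned on, and the
realized response split `(R_i, J_i - R_i)` is held fixed while the
error/response coincidence is re-simulated. A consequence worth knowing:
for the ignorable model the predictive mean of the per-item error indicator
is `p_i [R_i pi_i + (J_i - R_i)(1 - pi_i)]/J_i`, which is below `p_i`
whenever `pi_i` is mid-range; with homogeneous mid-range response
probabilities the ignorable PE mean therefore sits visibly below the naive
one, while with the strongly dispersed response propensities these studies
actually exhibit the two agree closely (as the published comparison shows).

The Clopper–Pearson baseline inverts the binomial tail probabilities through
Beta quantiles (`lower = Beta^{-1}(alpha/2; x, n-x+1)`, `upper =
Beta^{-1}(1-alpha/2; x+1, n-x)`), with the conventional endpoint handling at
`x = 0` and `x = n`. Reported percentages are rounded to one decimal
(round-half-even), with full-precision values retained in machine outputs.

## Synthetic data generator

`generate_study` draws, per examiner, `p_i` and the response block(s) from
the configured truth, then `y_ij ~ Bern(p_i)` and `r_ij` from `pi1_i` or
`pi2_i` according to `y_ij`; records are emitted exactly for `r_ij = 1`.
Mechanisms: `mcar` (one common, fixed response probability), `ignorable`
(`pi1 = pi2` drawn per examiner), `nonignorable` (separate blocks). An
optional relabelling layer turns a fraction of returned decisions into
inconclusives (default independent of `y_ij`; an odds-multiplier knob makes
error items more inconclusive-prone) and then a fraction of the remainder
into no-value outcomes. Every examiner has an independent substream of the
master seed, so increasing `I` never perturbs earlier examiners, and the
latent truth tables are retained so tests can tally panels against them.

`palmar_print_fixture` emulates the missingness regime of the motivating
palmar-print study's different-source stratum: 226 examiners × 22 items,
non-ignorable truth `(mu_p=0.2, tau_p=7.1, mu_pi1=0.6, tau_pi1=0.4,
mu_pi2=0.01, tau_pi2=3.5)` — low mean error rate, widely dispersed response
propensities, errors almost never answered — with 30% of returned decisions
relabelled inconclusive and 5% no-value (chosen to put the as-correct vs
as-missing response-count ratio in the observed ballpark). It is synthetic:
it reproduces the *regime* (dimensions, non-response level, selection
strength), not the real study's crossed item design, item-difficulty
structure, or its exact counts, so model outputs on the fixture are
illustrative, not estimates of the real study's error rates.

What passing tests on synthetic data do show: the likelihood code matches
independent quadrature/enumeration oracles; the samplers target their
posteriors; the EB optimizer finds the MLE; the pipeline is deterministic
under seeds. What they cannot show: that the selection model's assumptions
(conditional independence given examiner effects, Beta populations, no item
effects) hold for any real study.

## Numerical and design choices

* Marginal likelihood: `log Beta` via `gammaln`; inner `z`-sums via
  log-sum-exp with masking; unique-row aggregation.
* Quadrature oracle (tests): tensor-product Gauss–Jacobi rules with the
  Beta weights built into the rule, exact for the polynomial integrands and
  stable for `tau < 1` endpoint singularities.
* The beta-binomial → binomial concentration check uses `tau = 1e8`;
  beyond that, `betaln` round-off at huge arguments exceeds the check's
  1e-6 tolerance.
* Chain-length and problem-size choices in the test-suite and acceptance
  script (2-examiner toys for oracle comparisons; `I = 2000`, 20 seeds,
  5 starts for recovery; thinning 5/10 on the full-length non-ignorable
  chains, which keeps the retained-draw arrays tens of MB) are the
  package's own balance of Monte Carlo error against run time; all stated
  tolerances are met at these sizes.
* CLI persistence: hyperparameter draws, PE draws, per-examiner posterior
  summaries and convergence reports are always written; full per-examiner
  draw tables (which reach hundreds of MB at published-analysis scale) are
  behind `--save-draws`. The EB hyperparameter file is written before
  sampling begins. Exit codes: 0 success, 2 input error, 3 convergence
  thresholds unmet (artifacts retained).

## Known limitations

* No covariate modelling (examiner demographics, item difficulty) — the
  selection model leans entirely on observed error and response counts, and
  inherits the `p·pi2` ridge described above.
* Inconclusives are a policy choice, not a modelled outcome; the generator's
  relabelling layer supports sensitivity studies but the likelihoods never
  see an "inconclusive" category.
* Unit and item non-response are pooled, as in the published analyses;
  examiners who return nothing contribute no likelihood information beyond
  their assigned counts.
* `PE` conditions on the realized response split; it is not the marginal
  per-item error probability `E[p]`.
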