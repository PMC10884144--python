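# Methods

## Model

`adahmm` implements a two-state mixed hidden-Markov model (MHMM) for
anti-drug-antibody (ADA) production. The hidden state of subject *i*
at observation record *t* is S_NOADA (no production) or S_ADA
(production). Subjects are drug-naive at entry, so the chain starts in
S_NOADA deterministically and no stationary distribution is estimated;
the first record's likelihood is its emission density under S_NOADA
alone. Discrete time steps are *observation records*, not calendar
days: the transition matrix applies once per record regardless of the
sampling interval, mirroring the per-record forward recursion the
model is defined by. Consequences of this convention are discussed
under Limitations.

Emissions are bivariate Gaussian over the weighted PK residual and the
ADA assay measurement, with state-specific modes, a state-specific
correlation ρ_s, and a single variance per variable shared across
states. Sharing the variances is deliberate: a free ADA variance in
S_NOADA would collapse toward zero (most ADA values sit at the LLOQ)
and make the likelihood diverge. Records missing one component use
the exact Gaussian marginal of the present component; fully missing
records contribute likelihood 1 and propagate the filtered state
probabilities through the transition matrix only.

The two free transition probabilities are parameterised as logits.
Subject-level random effects (IIV) can enter additively on the
transition logits and on the emission modes — one η per observed
variable, shifting both states' modes of that variable jointly, since
the random effect carries no state index. When the ADA modes are fixed
to their clinical anchors (0.6 U/mL = assay LLOQ in S_NOADA,
2.4 U/mL = clinical positivity threshold in S_ADA), mode IIV applies to
the PK-residual modes only. The six supported variants cross
estimated-vs-fixed ADA modes with IIV on {modes + transitions,
transitions, none}.

## Estimation

Per-subject likelihoods use a scaled forward recursion: filtered
probabilities are renormalised at every record and the log normalisers
accumulate, so no unnormalised products are ever formed. Subjects with
random effects are marginalised by adaptive Gauss–Hermite quadrature:
a vectorised damped (modified) Newton pass locates each subject's joint
random-effect mode, a finite-difference Hessian supplies the local
curvature, and a product Hermite grid (default 9 nodes per dimension)
is re-centred and re-scaled accordingly. The population log-likelihood
is maximised directly with L-BFGS-B on an unconstrained scale (log
variances, atanh correlations, identity on modes and logits), from
`n_multistart` starts — the first at the default initial values (modes
0 / −1, ADA modes 0.6 / 2.4, variances 1 / 2, ρ = 0, π = 0.05 / 0.01),
the rest jittered ±50% on the natural scale under the user's seed.
Convergence uses the optimiser's relative objective-change criterion
(1e-9). Transition estimates within 1e-6 of 0 or 1 are flagged as
boundary solutions. Standard errors come from a central
finite-difference Hessian of the negative log-likelihood in the
unconstrained space, delta-method mapped to the natural scale and
reported as RSE% = 100·SE/|estimate|; a non-positive-definite Hessian
yields no SEs (the analogue of a failed covariance step) rather than an
exception. This direct-maximisation scheme targets the same estimand as
EM-type algorithms; algorithmic parity with any particular estimation
software is not a goal.

Viterbi decoding is a post-hoc step at the fitted parameters, with the
same forced S_NOADA start. Ties are broken toward S_NOADA —
conservative, in that it never manufactures an ADA call from an exact
tie — and for variants with IIV each subject's MAP random effects are
plugged in first.

A note on decoupling: with ρ_s = 0 the bivariate *emission*
density factorises exactly into the two univariate normals, and this
additivity extends to whole-sequence log-likelihoods whenever the
hidden path is pinned (single-record series, or π_NOADA→ADA = 0). It
does **not** extend to general sequences, because the two channels
share one hidden path: for two records the bivariate likelihood is
f1N·g1N·[(1−p)·f2N·g2N + p·f2A·g2A] while the product of the two
univariate-model likelihoods is f1N[(1−p)f2N+p·f2A] ·
g1N[(1−p)g2N+p·g2A]; these differ unless p(1−p)(f2N−f2A)(g2N−g2A) = 0.
The test suite therefore asserts the record-level identity and the
degenerate sequence cases, which are the mathematically sound forms.

## The PK stage

The upstream population-PK model is a one-compartment model with
first-order absorption (single ka, no IIV on ka — the minimal
structure consistent with subcutaneous dosing of a molecule with a
~14-day half-life), apparent clearance CL/F and central volume V/F,
a power of body weight (reference 70 kg) on CL/F and proportional
Japanese-ethnicity shifts on CL/F and V/F, log-normal IIV on CL/F and
V/F, and proportional residual error. Defaults (CL/F 0.35 L/day, V/F
7 L, ka 0.35 /day, ω² 0.09, σ 0.15) give a terminal half-life near two
weeks with ~30% between-subject variability — representative values
for a PEGylated antibody fragment.

The model is fitted to first-occasion data only (all records strictly
before the second distinct dose time; a single-dose study is entirely
occasion 1), where subjects are still ADA-free, by maximising a
Laplace-approximated marginal likelihood: a vectorised damped-Newton
inner step finds each subject's MAP η jointly across the cohort, and
the Laplace correction uses the finite-difference Hessian at the mode.
Empirical-Bayes (MAP) individual parameters from that fit predict all
later occasions; subjects without occasion-1 PK data shrink fully to
their covariate-adjusted typical values. The weighted residual is
IWRES = (DV − IPRED)/(σ·IPRED), the standard proportional-error form,
whose SD is ~1 under a correct model. Pre-first-dose samples have
IPRED = 0 and no defined residual; they are flagged and their PK
component treated as missing downstream. Below-LLOQ values are
substituted by the limits themselves (0.41 µg/mL PK, 0.6 U/mL ADA), not
treated as censored — matching the data convention the model assumes.

## Synthetic cohorts

The generator emulates a six-study subcutaneous-dosing programme
(~840 subjects): a Q4W dose-ranging study (50–800 mg), two Q2W studies
with 400 mg loading doses at weeks 0/2/4, two fixed-dose 400 mg Q4W
studies, and a small dense-sampling single-dose study without ADA
measurements. Weights are log-normal (median 70 kg, 20% CV), Japanese
ethnicity is Bernoulli (10%). Each subject's hidden chain starts in
S_NOADA and evolves per scheduled record at configurable transition
probabilities (defaults 0.03 / 0.003). While in S_ADA the subject's
CL/F is inflated by a configurable factor (default ×2) — the paper-gap
choice for *how* production feeds back on PK; the model only requires
that an ADA-blind PK model over-predict, and the inflation applies to
the concentration at the current record given the current state (no
carry-over of past clearance history). ADA measurements draw from the
state's Gaussian (optional log-normal switch for heavy right tails,
off by default) and are floored at the 0.6 U/mL LLOQ; PK observations
get proportional error and the 0.41 µg/mL LLOQ substitution.
Pre-first-dose records carry no PK observation. Randomness flows from
one seed through per-study/per-subject spawned substreams, so datasets
are byte-reproducible.

Parameter-recovery experiments sample from the MHMM itself
(`sample_mhmm`), i.e. pure Gaussian emissions without the LLOQ floor:
the floor is an assay/display rule, and flooring roughly half of the
S_NOADA ADA values would bias the shared ADA variance downward by ~2×,
confounding recovery of the parameters the experiment is about. The
floor is applied exactly where it belongs — in the cohort simulator
(assay realism) and in posterior-predictive simulation from a fitted
model, where simulated ADA values below 0.6 are set to 0.6.

What passing tests show, and what they do not: the synthetic data are
generated by the very model family being fitted (plus the PK stage's
known covariate forms), so recovery results demonstrate correctness of
the likelihood, optimiser and decoder — not robustness to the
heavy-tailed ADA distributions, assay drug-interference, dropout or
model misspecification present in real trial data.

## Evaluation conventions

Clinical classification calls a subject ADA positive when any assay
record exceeds 2.4 U/mL. Persistent vs transient is codified as: a
positive subject whose last two or more ADA records are below threshold
is transient, otherwise persistent — an explicit stand-in for the
manual profile inspection such classifications usually rely on.
Time-to-event comparison averages, over clinically positive subjects,
the first above-threshold time and the first decoded (or true) S_ADA
time. Distribution checks bin records in 28-day windows by default and
compare observed 5/50/95 percentiles with the across-replicate envelope
of the same percentiles.

## Numerical choices and test problem sizes

- Forward/Viterbi: per-record max-shifted exponentials; log-domain
  dynamic programming for Viterbi.
- Inner Newton (PK Laplace and HMM quadrature): central differences
  (h = 1e-4 / 1e-3), eigenvalue-modified steps (|λ| floored), step
  halving with rejection of non-improving steps, η clipped to ±40 in
  the PK objective to keep exp() finite during line searches.
- Quadrature stability: 9 vs 15 nodes moves the toy-data marginal
  log-likelihood by < 1e-4; a 1-D random-effect toy agrees with a
  100k-point trapezoid integral to ~1e-7.
- Recovery experiments use 840×8 (trial-scale) and 5000×20 (enlarged,
  to accumulate ~10⁴ production-state exposures for the rare reversion
  probability); the PK recovery/residual checks use a 260-subject
  cohort with 16 occasion-1 samples so that empirical-Bayes error is
  negligible and the IWRES spread genuinely reflects σ.
- Monte-Carlo tolerances in tests are derived from binomial/normal
  sampling SEs at the stated sizes (typically 3–4 SEs).

## Limitations

- Per-record (not per-day) transitions mean unevenly sampled subjects
  experience more "transition opportunities" per unit time where
  sampling is dense; no interval-length adjustment is applied.
- With sparse first-occasion sampling, empirical-Bayes estimation
  error inflates later-occasion IWRES beyond SD 1 and adds a small
  positive (Jensen-type) bias — visible in the simulator's sparse
  designs and consistent with a positive fitted no-production mode.
- The ADA→PK feedback in the generator (memoryless ×2 clearance
  inflation) is a stand-in; nothing in the estimator depends on it.
- Estimating ADA modes freely (variants 1, 3, 5) can let the
  production state drift into an outlier-catching role when true
  transitions are absent; the clinically anchored variants are the
  robust default, which is why variant 6 is the package default.
- No covariates on transition probabilities, no >2-state or
  semi-Markov extensions, no censored-likelihood BLQ handling.
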