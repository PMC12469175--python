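# Methods

This note documents the models implemented in `persistlin`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model

A tracked experiment is a forest of `CellRecord`s (id, parent, founder
lineage / barcode, birth and end times in hours, end event). Time starts at
plating (t = 0); the drug arrives at `t_drug` (default 48 h) and
observation ends at `t_end` (default 120 h). Events at exactly `t_drug`
count as post-drug. Cells alive at `t_end` are censored there; downstream a
*persister* is a cell censored alive at `t_end`. Two tracking modes exist:
`full_tree` (both daughters tracked) and `forward_lineage` (one random
daughter tracked; the other is kept as an untracked stub so divisions stay
countable). The generator can round event times down to the 0.5 h snapshot
grid to mimic 30-minute imaging; all downstream code accepts continuous
times.

Exclusion filters follow standard practice for these experiments:
*never-dividers* (founders with no division over their whole trajectory,
removed with their single-node lineage) and cells dying before drug
addition (record removed). The filter is idempotent. Removing a pre-drug
death can leave a division with one recorded child, so the
two-children-per-division check is strict-mode only.

## Event-time distributions

Intermitotic times (IMT) and apoptosis times (AT) are modelled as
Exponentially Modified Gaussians (EMG): Normal(mu, sigma) + Exp(lam), mean
mu + 1/lam. Density and survival are evaluated in log space via the scaled
complementary error function (`erfcx`) and `log_ndtr` + `logaddexp`; the
hazard h = f/S is then stable arbitrarily far into the exponential tail,
where it tends to lam. Single-EMG fits use L-BFGS-B with 8 moment-perturbed
restarts and box constraints mu in [-50, 200] h, sigma in [1e-3, 100] h,
lam in [1e-4, 10] /h; two-component mixture fits (7 parameters) use direct
likelihood optimization from quantile-split starts, with components ordered
by mean and a boundary flag when the weight collapses within 0.01 of 0
or 1. Model comparison uses AIC (not AICc; sample sizes here make the
difference small, but this is a deliberate convention). Fits use uncensored
durations only.

## Growth prediction

The asymptotic rate gamma of an age-structured population solves the
Euler-Lotka equation 1 = 2 ∫ phi(x) e^(-gamma x) dx, with phi(x) = b(x)
exp(-∫_0^x (b + mu_d)), b the division hazard and mu_d the death hazard.
G(gamma) is strictly decreasing, so the root is unique; it is found by
Brent's method on a bracket expanded geometrically from ±10/(mean IMT).
Quadrature: the cumulative hazard uses the trapezoid rule on a grid of step
min(0.05 h, sigma/10) out to the age where net survival < 1e-12; the outer
integrals use Simpson's rule (closed-form cases reproduce to ~1e-11
relative). A degenerate deterministic-IMT model (phi a point mass at T) is
special-cased: gamma = ln 2 / T. The inverse-mean-IMT baseline 1/mean(IMT)
is provided as the comparison estimator; it is exact only for exponential
IMTs. The empirical rate is the OLS slope of log counts vs time.

Founder starting ages are inferred from residual times r to first
division. The renewal conditional likelihood L(a) ∝ f(a + r)/S(a) plateaus
at large a (the EMG tail is memoryless), so the bare likelihood carries no
tail information; the default weights it by the stationary age prior of a
growing culture, e^(-gamma a) S(a), giving per-cell posteriors
f(a + r) e^(-gamma a). The population-level age distribution is the
normalized mean (not product) of per-cell curves, since founders have
independent ages. `prior="flat"` recovers the bare-likelihood rule; for a
near-exponential IMT the likelihood is flat in a and the result is flagged
uninformative.

## Competing risks

After drug, division and death race within each cell and only the earlier
event is seen, biasing both observed time distributions short. For
exponential clocks the closed-form corrected estimators are
lam_m = N_m / sum t_i and lam_a = N_a / sum t_i (sum over events of both
types). For EMG clocks the model has 8 parameters: two EMGs, a quiescence
probability q (quiescent cells neither divide nor die) and a drug-action
delay tau. Per-cell likelihood terms: division (1-q) f_m(u) S_a(u), death
(1-q) f_a(u) S_m(u), censoring q + (1-q) S_m(u) S_a(u), with u measured on
an effective clock starting at max(birth, t_drug + tau); events that would
precede the clock start have likelihood zero. Straddlers (born pre-drug)
accrue no hazard before t_drug + tau and their pre-drug ageing is ignored —
the simplest convention consistent with a pure action delay.

Inference is component-wise Gaussian random-walk Metropolis-Hastings under
uniform priors (mu in [0, 100] h, sigma in (0, 50] h, lam in (1e-4, 10] /h,
q in [0, 1], tau in [0, 24] h), proposal scales tuned to 20-40% acceptance
during burn-in, split-R-hat (arviz) as the convergence diagnostic.

**Identifiability.** Under any pure-delay clock, tau + EMG(mu, sigma, lam)
is distributionally identical to EMG(mu + tau, sigma, lam), censoring terms
included: the delay lies on an exact likelihood ridge with the two EMG
locations, truncated above by the earliest observed event. The sampler
therefore includes a ridge-aligned joint proposal
(tau + d, mu_m - d, mu_a - d); without it split-R-hat sits near 2, with it
below 1.02. Consequently (i) posterior summaries of tau and the locations
should be read jointly, and (ii) parameter-recovery studies must place the
truth in the interior of the identified set — i.e. use event-time
distributions with negligible mass near zero, so the earliest event arrives
well after tau. With truths on the boundary (e.g. a death-time EMG with
mass near 0 and tau equal to the earliest-event bound), 90% intervals
necessarily miss the delay and the absorbed locations; this is a property
of the model, not the sampler.

## Fate models M0-M3

All models share a discrete-time pre-drug engine (default dt = 0.05 h):
each live cell divides in a step with probability 1 - exp(-h(age) dt) from
the pre-drug IMT hazard; M1/M3 additionally switch every live cell between
S' (sensitive) and P' (pre-persister) with per-step probability k dt
(validated k dt < 0.01), daughters inheriting the mother's state. Founder
states default to the stationary fraction k_sp/(k_sp + k_ps); founder ages
default to 0, or to fresh draws from the stationary renewal age
distribution e^(-gamma a) S(a) with `initial_ages="stationary"`.

- **M0** continues stepping after drug with competing division and death
  hazards; the event type is chosen by the hazard ratio. Cells extant at
  drug restart their post-drug clock at age 0 (matching the
  competing-risks clock convention). Population slopes agree with the
  Euler-Lotka rate of the same hazards within Monte-Carlo error.
- **M1** fixes fates by state at drug time (S' dies; P' divides or stays);
  post-drug daughters re-draw from the P' rules.
- **M2** assigns fates i.i.d. from a concentration-dependent (die, divide,
  stay) triple; no states anywhere.
- **M3** draws fates from a state-conditioned fate matrix F; daughters of
  post-drug divisions inherit the drug-time state and re-draw from F.

For M1-M3, waiting times to an assigned fate are drawn directly from the
post-drug IMT or AT EMG — with a single non-competing hazard this is
exactly the dt -> 0 limit of the stepping scheme and avoids its O(dt)
bias. "Stay" cells are censored at `t_end` and never divide (the strict
reading of survival-without-division); events scheduled beyond `t_end` are
censored. Barcodes (founder lineage ids) propagate unchanged.

## Lineage statistics

End fates follow each drug-time cell forward, choosing one tracked daughter
uniformly at random per division, to death (0) or censoring (1); the number
of scored cells equals the drug-time census, so post-drug proliferation
cannot inflate dispersion. Kinship is the generation depth of the most
recent common ancestor among drug-time cells (1 = sisters, 2 = first
cousins, ...); association is the symmetrized Pearson (phi) correlation
over within-class pairs, with a null from random different-founder pairs
and bootstrap percentile CIs. The exact pairing rules of published figures
are not specified; this choice is documented rather than inferred.

The Luria-Delbrück test computes the variance-to-mean ratio (VMR, unbiased
sample variance) of per-founder-lineage persister counts; the binomial
null under i.i.d. fate assignment is 1 - p. Replicates vary the random
daughter choices on fixed data, or re-simulate from a configuration.

Barcode diversity uses the Shannon index -sum p_i ln p_i (natural log).
`delta_sdi` compares censuses just before drug and 72 h after; because the
post census is much smaller and plug-in entropy is biased low in small
samples, both censuses get the Miller-Madow correction (+(S-1)/2N) by
default, so exchangeable thinning is centred on zero.

## Synthetic datasets

`hct116_like`: full-tree M3, 49 founders (~2.5 doublings to a few hundred
cells at drug time), 48 h drug-free + 72 h drug, symmetric state switching
at 9e-3 /h, fate rows S' = (0.9125, 0.05, 0.0375) and
P' = (0.35, 0.10, 0.55), 0.5 h snapshot rounding, 13 never-divider
founders (10/13 dying post-drug) and no pre-drug deaths. Founders start
mid-cycle (stationary ages). Pre-drug IMT: EMG(13, 2.5, 0.15), mean
~19.7 h. Post-drug IMT: EMG(20, 5, 0.10), mean 30 h. Post-drug AT:
EMG(10, 4, 0.12), mean ~18 h — calibrated so that this recipe reproduces
the published first-phase decay rate of drug-treated HCT116 populations
(~ -0.029 /h), the stated matching condition of the simulation whose
dispersion statistics we compare against. Under these conditions the
100-replicate LD ensemble gives a mean VMR ~1.4 (replicate 95% interval
roughly 1.0-1.9, covering the published 1.6) against a binomial null of
~0.67.

`u2os_like`: forward-lineage M2 at three dose labels sharing identical
post-drug IMT/AT distributions; dose enters only through the fate triple
(die, divide, stay) = (0.13, 0.43, 0.44) / (0.28, 0.31, 0.41) /
(0.60, 0.23, 0.17) for Low/Medium/High, chosen from the published fate
tallies of the corresponding doses. Founder counts 247/262/316, ~2.5%
pre-drug deaths, a few never-dividers per label — matching the published
summary-table structure. Decay is single-phase and ordered by dose.

`barcode_config`: the barcode-diversity experiment runs M3 with a 144 h
(~7 generation) pre-drug window, because barcoding studies label cells many
generations before treatment and the diversity verdict depends on the
generations available for state decorrelation. With switching at 9e-3 /h,
states decorrelate from founder states over that window: the "SimExpt"
condition changes diversity by less than one replicate standard deviation,
the "no_trans" condition (frozen states) loses diversity at ~5 replicate
standard deviations, and the state-independent "control" is centred on
zero. With only ~2.5 pre-drug generations even the control drops —
barcode-diversity readouts on shallow lineages are biased, which is worth
knowing when interpreting such experiments.

What the generator does *not* emulate: microscopy segmentation/tracking
errors, cells entering or leaving the field of view (published tables
include late-appearing lineages; the generator starts all founders at
t = 0), sequencing-level barcode noise (PCR, collisions), spatial effects,
and drug pharmacokinetics beyond the action delay. Passing tests therefore
demonstrate internal consistency of the inference chain under the stated
generative assumptions, not robustness to those real-data artefacts.

## Problem sizes

Default test and reproduction scales were chosen to keep full runs on a
laptop-class single core in minutes: 100-replicate LD and barcode
ensembles, 20-seed simulation-vs-Euler-Lotka comparisons, and MCMC
recovery with 2 chains of 4000 post-burn-in draws on n = 500 cells across
20 replicates. Chain counts and draws are parameters; production-quality
posteriors should use the 4-chain, 50k-draw defaults of `MCMCSettings`.

## Known limitations

- The delay/location ridge makes `tau_delay` only jointly identified (see
  above); report mu + tau if a location summary is needed.
- Mixture fitting uses direct optimization, not EM; with heavily
  overlapping components the weight is weakly identified (boundary flag).
- Forward-lineage tables cannot provide daughter-pair statistics or
  full-tree lineage correlations; these are reported as absent, not zero.
- The M3 "stay" fate never divides later; a slow-cycling persister phase
  would require an additional fate class.
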