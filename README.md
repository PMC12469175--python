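# persistlin

Single-cell lineage kinetics and drug-persister population dynamics.

When cancer cells are treated with a DNA-damaging drug such as cisplatin,
the population typically shows a fast exponential decay followed by a
plateau of *drug-tolerant persisters*. `persistlin` is a toolkit for asking
whether those fates are decided by the drug at exposure time or inherited
from cell states that existed before treatment, using only quantities a
time-lapse microscopy experiment measures: per-cell division and death
times, lineage trees, and population counts. It is aimed at quantitative
cell biologists and modellers working with single-cell tracking or
lineage-barcoding data.

The toolkit provides:

- a validated **lineage table** model (full-tree and forward-lineage
  tracking, exclusion filters, census and duration extraction);
- **EMG machinery**: the Exponentially Modified Gaussian
  (Normal(μ, σ) + Exp(λ)) for intermitotic and apoptosis times, with
  log-space density/survival/hazard, MLE, 2-component mixtures and AIC
  comparison;
- **growth prediction** via the Euler-Lotka equation
  1 = 2 ∫ φ(x) e^(−γx) dx, φ(x) = b(x) e^(−∫(b+μ_d)), against the
  inverse-mean baseline and the regression slope of log N(t);
- **competing-risks correction** of post-drug division/death times:
  closed-form estimators λ̂ = N_type / Σtᵢ for exponential clocks, and
  Metropolis-Hastings MCMC for the 8-parameter EMG model (two EMGs +
  quiescence probability q + drug-action delay τ);
- stochastic **fate models M0-M3**: age-structured competition (M0), pure
  pre-drug states (M1), pure drug-induced fates (M2), and heritable states
  with a state-conditioned fate matrix (M3), with barcode propagation;
- **lineage statistics**: end-fate correlations by kinship, barcode
  Shannon diversity (SDI = −Σ pᵢ ln pᵢ), and the Luria-Delbrück
  variance-to-mean ratio (VMR) of per-lineage persister counts against its
  binomial null 1 − p;
- **synthetic datasets** emulating the two experimental designs (full-tree
  HCT116-style, forward-lineage U2OS-style at three doses), exactly
  reproducible from their manifests.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

Simulate an HCT116-like experiment and run the Luria-Delbrück fluctuation
test on the heritable-state model:

```python
import numpy as np
from persistlin import (hct116_like, hct116_config, apply_exclusions,
                        summary_counts, ld_test)

table, manifest = hct116_like(seed=1)
kept, report = apply_exclusions(table)
print(report.n_never_dividers, len(kept.extant_at_drug()))
# 13 302        <- 13 never-divider founders removed; 302 cells at drug time

ld = ld_test(hct116_config(), n_reps=100, seed=1)
print(round(ld.mean_vmr, 2), round(ld.binomial_null, 2))
# 1.41 0.67
print(tuple(round(v, 2) for v in ld.vmr_interval()))
# (1.01, 1.91)
```

Reading the output: the simulated census grows from 49 founders to ~300
cells over two drug-free days. The dispersion of persister counts across
founder lineages (mean VMR 1.41, replicate 95% interval 1.01-1.91) sits
well above the binomial null 0.67 that i.i.d. drug-time fate assignment
would produce — the signature of heritable pre-drug states. A model with
i.i.d. fates (M2) instead yields a VMR close to its binomial null.

The same analyses are available from the command line:

```bash
persistlin synth hct116 --seed 1 --out data/
persistlin summarize data/hct116_like.csv
persistlin ld-test --simulate --n-reps 100 --seed 1
persistlin fit-emg durations.csv --mixture
```

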