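# cyclebayes

Bayesian integration of heterogeneous expression measurements for an ODE
model of cell-cycle transcription in budding yeast.

Mechanistic models of gene regulation are chronically underdetermined: no
single measurement type constrains all kinetic parameters. `cyclebayes`
implements a data-integration pipeline for the cyclic transcription of the
budding-yeast cyclins (*CLN3*, *CLN2*, *CLB5*, *CLB2*) driven by the
transcription-factor subunits SWI4 (SBF), NDD1 (Mcm1-Fkh), SWI5 (Swi/Snf),
HCM1 and the repressor YOX1.  Two qualitatively different data channels are
fitted jointly:

* **relative time-course data** — log-ratios of synchronized to
  unsynchronized mRNA expression, informative about dynamics but not scale;
* **absolute steady-state data** — population-average mRNA and protein
  concentrations, modeled as trajectory time averages over two cell cycles.

Because the model lives in physical units (micromolar, seconds), the
posterior rate estimates can afterwards be compared with independent
measurements of degradation, transcription and translation rates.  The
package is aimed at systems-biology practitioners who want a tested,
reusable reference implementation of this inference recipe, with a
synthetic-data generator providing known ground truth for every stage.

## Model

For each gene *i* with activator protein `P_act(i)`, transcript `m_i` and
protein `P_i` (both in uM):

```
dm_i/dt = (beta_i + alpha_i * P_act(i)) * f_i(t)  -  deltam * m_i
dP_i/dt = kappa * m_i  -  deltap_i * P_i * g_i(t)
```

with Hill repression `f = 1 / (1 + (P_inh / K)^h)` for genes with a
transcriptional inhibitor (g likewise for inhibited protein degradation),
shared mRNA degradation rate `deltam` and shared translation rate `kappa`.
Four nested network variants are provided (`build_model(1..4)`): the
seven-gene core, + HCM1, + the YOX1 negative-feedback loop, + inhibition of
NDD1 degradation by CLN2.  Variant 4 sustains ~80-min transcriptional
oscillations at the shipped ground-truth preset.

Inference uses uniform priors on log10 scale, Student-t(3) error models on
both channels (one inferred scale each) and parallel-tempered MCMC: 32
chains on the quadratic inverse-temperature ladder `beta_i = (i/31)^2`
tempering the likelihood only, 0.99 swap probability, automated parameter
blocking from the empirical correlation of recent draws, and per-block
proposal scales adapted toward 0.23 acceptance during burn-in.  Posterior
checks include predictive bands, R² against a per-experiment-mean null, a
cross-validated smoothing-spline reference R², and credible-interval-width
accounting against the prior ranges.

## Worked example

Generate the reduced single-gene benchmark study (committed preset truth,
both data channels) and run a desk-scale inference:

```python
import numpy as np
from cyclebayes import make_ladder, run_pt
from cyclebayes.sampler import count_round_trips
from cyclebayes.synth import reduced_benchmark

post, truth, design = reduced_benchmark(seed=1)   # preset truth, both channels
out = run_pt(post, make_ladder(16, swap_prob=0.9), burn_in=10_000,
             n_samples=30_000, subsample=20, seed=1)

print(f"{'parameter':<12}{'truth':>8}{'median':>9}{'90% CI':>18}")
for j, name in enumerate(post.free_names):
    lo, med, hi = np.quantile(out.draws[:, j], [0.05, 0.5, 0.95])
    print(f"{name:<12}{truth[name]:>8.2f}{med:>9.2f}    [{lo:6.2f}, {hi:6.2f}]")
print(f"swap acceptance: {out.swap_rate:.2f}; "
      f"round trips: {count_round_trips(out.ledger)[1]}")
```

Output:

```
parameter      truth   median            90% CI
beta_GENE1     -5.70    -5.76    [ -5.96,  -5.46]
m0_GENE1       -3.70    -3.81    [ -4.03,  -3.53]
deltam         -3.00    -2.97    [ -3.10,  -2.82]
kappa          -1.30    -1.12    [ -1.60,  -0.73]
swap acceptance: 0.75; round trips: 44
```

All values are log10 of the linear rates/concentrations: the posterior
medians recover the generating basal transcription rate (`beta`, uM/s),
initial transcript concentration (`m0`, uM), mRNA degradation rate
(`deltam`, 1/s) and translation rate (`kappa`, 1/s) to well within a third
of a decade, and the replica round-trip count shows the temperature ladder
is mixing.  Fitting the time-course channel alone leaves `beta` and
`kappa` essentially at their priors (CI widths > 4 decades); adding the
absolute channel shrinks them to ~0.5 — the package's core demonstration
that integrating both measurement types determines parameters neither can
constrain alone.

The same pipeline is available from the shell for the full model variants:

```sh
cyclebayes synth   --config run.yaml   # ground truth + all three channels
cyclebayes infer   --config run.yaml   # PT-MCMC, writes draws.tsv + metadata
cyclebayes check   --config run.yaml   # predictive bands, R² set, CI widths
cyclebayes compare --config run.yaml   # MAP rates vs validation rates
```

`cyclebayes synth` also exports the configured network variant as SBML
Level 3 (`model.sbml.xml`).

## Layout

| module | contents |
| --- | --- |
| `cyclebayes.model` | network variants, parameters, priors, ODE right-hand side |
| `cyclebayes.simulate` | two-cycle integration, time averages, time rescaling |
| `cyclebayes.likelihood` | datasets, t(3) channel likelihoods, tempered posterior |
| `cyclebayes.sampler` | PT-MCMC, auto-blocking, adaptive scaling, round trips |
| `cyclebayes.checking` | predictive bands, R² set, spline reference, CI widths |
| `cyclebayes.validation` | time-averaged rates, MAP, comparison with rate data |
| `cyclebayes.synth` | ground-truth presets and all three synthetic channels |
| `cyclebayes.io` / `cyclebayes.cli` | delimited readers/writers, SBML export, CLI |

See `docs/methods.md` for the modeling and numerical details.
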