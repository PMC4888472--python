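# nsdlsm — latent-state modelling of net squared displacement

`nsdlsm` classifies broad-scale animal movement strategies — **migration**,
**dispersal**, **nomadism** and **sedentarism** — from daily GPS
trajectories.  It is aimed at movement ecologists with multi-month to
multi-year telemetry records (one or more positions per day, projected
coordinates) who want an objective, reproducible alternative to fitting
idealized displacement curves or eyeballing displacement plots.

## The model

For a path with daily positions $(x_t, y_t)$, the net squared displacement
is the squared straight-line distance to the path origin,

$$\mathrm{NSD}_t = (x_t - x_1)^2 + (y_t - y_1)^2 ,$$

range-standardized to $[0,1]$ per individual.  The standardized series is
modelled as a hidden Markov model with $M = 3$ latent movement modes:

* modes 1 and 2 — **encamped** modes (concentrated, recurrent space use),
  with free Gaussian emissions $N(\mu_i, \sigma_i)$, $i = 1, 2$;
* mode 3 — an **exploratory** mode (transient travel between ranges),
  with a *pseudo-uniform* emission: a Gaussian with fixed
  $\mu_3 = 0.5,\ \sigma_3 = 1$, nearly flat over $[0,1]$.

Mode dynamics follow a first-order Markov chain with a $3\times 3$
row-stochastic switching matrix $Q$, $q_{ij} = \Pr(I_{t+1}=j \mid I_t=i)$.
Because the chain carries the mode through days without data, gaps in the
record need no imputation.  Estimation is by multi-start
expectation-maximization (a Gibbs sampler with Gelman-Rubin convergence
checks is available for posterior credible intervals), the latent modes
are decoded from the forward-backward marginals, and the encamped labels
are canonicalized so mode 1 is the encamped mode occupied first.

Classification applies fixed cut-offs to the diagonal of $Q$ (reported as
Dirichlet(1,1,1) posterior medians of the transition counts) plus the
**M2 criterion** — whether the animal ever re-entered the first encamped
mode after occupying the second:

| label      | rule                                                       |
|------------|------------------------------------------------------------|
| dispersal  | $q_{11}>0.95,\ q_{22}>0.95,\ q_{33}>0.85$, never left mode 2 |
| migration  | same cut-offs, left mode 2 at least once                   |
| nomadic    | $q_{11}>0.95,\ q_{22}>0.90,\ q_{33}\le 0.85$               |
| sedentary  | $q_{22}\le 0.90,\ q_{33}\le 0.90$                          |
| uncertain  | anything else (flagged for inspection)                     |

The package also ships the classical comparison method (nonlinear
least-squares fits of constant / linear / sigmoid / double-sigmoid NSD
curves with AIC selection), Cohen's kappa for scoring both classifiers
against known labels, and simulators that generate the four stereotyped
strategies for validation.

## Worked example

Simulate one migratory year (365 daily fixes) and classify it:

```sh
nsdlsm simulate --strategy migration --n 1 --seed 11 --out demo
nsdlsm classify --input demo/sim_migration_520846937.csv --seed 11 --out demo/report.json
```

The report contains, for this animal:

```json
{
  "label": "migration",
  "q11": 0.986,
  "q22": 0.972,
  "q33": 0.954,
  "departed_mode2": true
}
```

with per-365-day evidence `n_12 = 1`, `n_21 = 1` and
`time_in_mode = [196, 92, 77]` days.  Read: both encamped modes are very
sticky (the animal stays in a range with daily probability ≈0.97–0.99),
the exploratory mode is persistent enough to be a genuine travel phase
rather than noise ($q_{33} > 0.85$), and the animal moved to its second
range and back exactly once — the migration signature.  The same pipeline
runs on real data: a CSV with columns `animal_id,timestamp,x,y`
(ISO-8601 timestamps, projected meters; Movebank-style exports work via a
column mapping).

Other subcommands: `nsdlsm fit` (parameters + decoded modes per animal),
`nsdlsm baseline` (curve-fit classification), `nsdlsm compare`
(head-to-head kappas on simulated data) and `nsdlsm start-sensitivity`
(robustness of a label to re-anchoring the series start).

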