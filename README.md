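# resikit

Ligand residence times from learned reaction coordinates and infrequent
metadynamics.

Unbinding of a drug-like ligand from its protein is a rare event: residence
times range from nanoseconds to minutes while plain molecular dynamics reaches
microseconds. `resikit` implements the semi-automated protocol that makes
such kinetics computable: a **State Predictive Information Bottleneck (SPIB)**
learns a two-dimensional *linear* reaction coordinate (RC) from trial
metadynamics trajectories, successive rounds of well-tempered metadynamics
refine it, and **infrequent metadynamics** along the converged RC yields
unbiased residence times through the acceleration-factor rescaling

```
alpha(t) * t = ∫₀ᵗ exp( V(s, t') / kBT ) dt'
```

where `V(s, t')` is the instantaneous metadynamics bias.  The rescaled
first-passage times from ~10–12 independent runs are fitted to an exponential
CDF, `1 − exp(−t/τ)`; τ is the residence time.  A two-sample
Kolmogorov–Smirnov test against the fitted exponential guards the Poisson
(rare-event) assumption — `p > 0.05` flags a reliable estimate — and a
percentile bootstrap supplies the 95% confidence interval.

The package is aimed at enhanced-sampling practitioners: it reads and writes
PLUMED COLVAR/HILLS tables, exports the learned RC as a ready-to-run PLUMED
input script, and ships a 2-D Langevin toy engine with analytic multi-well
potentials so every stage of the pipeline can be validated against
brute-force ground truth on a laptop.

## Modules

| module | what it does |
|---|---|
| `resikit.toy_engine` | overdamped Langevin + well-tempered/infrequent metadynamics on analytic 2-D potentials; brute-force MFPT oracle |
| `resikit.featurize` | order parameters (ligand-COM ↔ Cα distances, H-bond distances), dissociation filtering |
| `resikit.spib_core` | the SPIB: linear encoder, mixture-of-Gaussians prior, state-label refinement, RC export |
| `resikit.kinetics` | acceleration-factor quadrature, exponential-CDF τ fit, KS reliability test, bootstrap CI |
| `resikit.plumed_io` | COLVAR/HILLS readers/writers, bias reconstruction, PLUMED script export |
| `resikit.protocol` | the round-based driver: trial biasing → SPIB rounds → stopping rule → iMetaD production |

## Worked example

Recover the escape time of a particle trapped behind a ~7.5 kBT barrier on
the built-in triple-well surface, using 20 infrequent-metadynamics runs, and
compare with the brute-force answer from 300 unbiased runs:

```python
import numpy as np
from resikit import toy_engine as te, kinetics as kin

pot = te.triple_well()                      # bound well + 2 metastable wells
oracle = te.unbiased_mfpt(pot, te.LangevinConfig(n_steps=5_000_000, seed=0),
                          n_runs=300, seed=11)

sched = te.MetadSchedule(pace=5000, height0=1.0, sigma=(0.3, 0.3),
                         bias_factor=8.0, mode="infrequent")
traces = []
for s in np.random.SeedSequence(77).generate_state(20) % 2**31:
    traj = te.simulate_escape(pot, te.LangevinConfig(n_steps=2_000_000, seed=int(s)),
                              sched=sched)
    traces.append(kin.BiasTrace(times=traj.times, bias=traj.bias_values, kBT=1.0,
                                transition_index=len(traj.times) - 1 if traj.escaped else None))

fit = kin.residence_report(traces, n_boot=1000, seed=1)
print(f"unbiased MFPT : {oracle.mean:.1f} ± {oracle.stderr:.1f}")
print(fit.summary())
```

Output (toy time units):

```
unbiased MFPT : 101.8 ± 5.7
residence time tau = 137.26
95% bootstrap CI   = [90.11, 189.867]
KS statistic       = 0.1889
KS p-value         = 0.4226 (reliable: Poisson requires p > 0.05)
events / censored  = 20 / 0
```

The biased runs finish in a fraction of the unbiased wall time (mean ≈ 28
time units instead of ≈ 102), yet the rescaled τ lands within a factor of
1.4 of the brute-force mean, and the KS p-value of 0.42 confirms the
rescaled times are still exponentially distributed — the bias did not
corrupt the transition statistics.

The full round-based protocol (trial CV → SPIB → production) runs from the
shell:

```bash
resikit run-protocol --runner toy --seed 0 --out results/
resikit simulate --potential triple-well --mode infrequent --pace 5000 --seed 1 --out colvar.dat
resikit export-plumed --rc results/rc.json --ops ops.json --mode infrequent --pace 5000
```

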