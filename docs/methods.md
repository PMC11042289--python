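# Methods

## The model

### Infrequent metadynamics and the acceleration factor

Well-tempered metadynamics deposits repulsive Gaussians of initial height
`h₀` every `pace` steps along a collective variable (CV) `s`; each deposited
height is tempered by the bias already present,
`h = h₀·exp(−V(s,t)/((γ−1)·kBT))`, with bias factor `γ > 1` (`γ = ∞` disables
tempering).  When deposition is *infrequent* — rare on the timescale of a
barrier crossing, so that transition states remain essentially bias-free —
the unbiased first-passage time can be recovered from a biased run by the
time rescaling

    t_acc = ∫₀ᵗ exp(V(s, t')/kBT) dt' ,

evaluated up to the transition.  We integrate with left-rectangle quadrature
on the recorded grid (bias held at its last recorded value between records),
matching how PLUMED logs the instantaneous bias.  Since `V ≥ 0`, the
accelerated time is never below the wall time, and with `V ≡ 0` it equals the
wall time exactly.

Rare-event escape is Poissonian, so the accelerated first-passage times
across independent runs should be exponential.  We fit the characteristic
time τ by least squares of the empirical CDF (`i/n` at the i-th order
statistic) against `1 − exp(−t/τ)`; the sample-mean MLE is exposed alongside
for comparison.  Reliability is assessed with a two-sample Kolmogorov–Smirnov
test between the observed times and 10⁴ draws from the fitted exponential
(fixed internal seed, so the test is a deterministic function of its inputs);
`p > 0.05` supports the Poisson picture.  A one-sample variant is available
behind a flag.  The 95% confidence interval is a percentile bootstrap over
resampled event sets, with τ refitted on every resample.  Censored runs
(no transition) are counted and reported but excluded from the fit; a
warning fires when more than half the runs are censored, since the fitted τ
is then biased low.

### The SPIB reaction coordinate

The State Predictive Information Bottleneck learns a low-dimensional
bottleneck variable that is maximally predictive of the system's metastable
state a lag time Δt into the future while minimally informative about the
instantaneous configuration.  Concretely, for input features `x_t` (order
parameters) and state labels `y_{t+Δt}`:

- **Encoder** — *linear*: `z = W x̃ + b + σ·ε`, where `x̃` is the per-OP
  z-scored input, `σ` a learned shared diagonal standard deviation and
  `ε ~ N(0, I)` (reparameterization).  Linearity is a deliberate modelling
  restriction: the converged posterior mean is then an explicit affine
  function of the OPs that metadynamics can bias directly.
- **Decoder** — one hidden tanh layer (width 64) with softmax output over
  the candidate states; the paper-level method does not pin the decoder
  architecture, and a single hidden layer is the smallest decoder that can
  carve nonlinear state boundaries in the latent plane.
- **Prior** — a mixture of Gaussians anchored at the encoder images of
  learned pseudo-inputs (VampPrior construction), `r(z) = Σ_k ω_k N(z; μ(u_k), σ²)`,
  with pseudo-inputs initialized at k-means centers.  This is the mechanism
  that lets the number of metastable states emerge rather than being fixed.

The objective per time-lagged pair is
`−log q(y_{t+Δt}|z) + β·(log p(z|x_t) − log r(z))`.
Training alternates a few epochs of Adam with *label refinement*: every
frame is relabelled by the decoder's most probable state at the posterior
mean, empty states are dropped (dropped states stay dropped, so the state
count is monotone non-increasing), and the loop stops when fewer than 0.5%
of labels change or after 20 refinements.  Initial labels come from k-means
with `K0` clusters on the pooled z-scored features.  Time-lagged pairs never
straddle trajectory boundaries.  Biased (metadynamics) training trajectories
enter **unweighted**: reweighting by Boltzmann factors would suppress exactly
the high-energy intermediate states the coordinate needs to resolve.

The network is small and fixed, so the forward and backward passes are
written directly in numpy with hand-derived gradients (validated against
finite differences in the test suite to ~1e-9 relative error) and a
hand-rolled Adam optimizer; training is deterministic given the seed.

Expected Δt behaviour, which the tests exercise on a three-well fixture:
a lag shorter than every dwell time resolves all metastable states; a lag
beyond the slowest relaxation sees a single state; in between, states that
interconvert faster than the lag merge.

### The round-based protocol

1. **Trial round.** Independent well-tempered runs biased along
   caller-chosen trial variables.  Runs whose dissociation criterion never
   fires are *trapped* and excluded from training.
2. **SPIB rounds.** Train SPIB on all dissociated trajectories accumulated
   so far, export the 2-D linear RC, and launch 8 well-tempered runs biased
   along it.  The mean accelerated time of the dissociated runs measures
   coordinate quality — a good coordinate dissociates with little wasted
   bias, a poor one inflates `∫exp(βV)` by roughly `exp(β·wasted bias)`.
   These WT-round accelerated times quantify the RC; they are not kinetics.
3. **Stopping.** "No longer decreases" is operationalized as: the latest
   SPIB round's mean accelerated time improves on the best previous SPIB
   round by less than 10% (relative), or the round budget (default 5) is
   spent.  Only SPIB rounds enter the comparison — the trial round
   bootstraps training data but measures no learned coordinate, and its
   run-to-run noise should not gate convergence — so at least two SPIB
   rounds always run.
4. **Production.** 12 infrequent-metadynamics runs (default) along the RC
   of the round with the *minimum* mean accelerated time, then the
   exponential fit / KS test / bootstrap described above.

Rounds are executed through a pluggable *runner*
(`runner(cv, schedule, seed) → RunResult`); the toy engine implements it
in-process, and real-MD users implement it by shelling out to their engine
with the exported PLUMED script.  Everything derives from one master seed.
The fallback for systems whose distance OPs fail to produce dissociation is
to feed the trial CVs themselves as the SPIB feature set — with the runner
abstraction this is just a different feature map, not a separate code path.

## The toy engine and what it does (not) emulate

The synthetic substrate is overdamped Euler–Maruyama dynamics,
`x ← x − dt·∇(U+V)/friction + sqrt(2·kBT·dt/friction)·η`, on sums of
inverted Gaussian wells in 2-D (toy units: kBT = 1, friction = 1,
dt = 1e-3).  An optional harmonic confinement keeps equilibrium fixtures
recurrent; escape fixtures omit it.  Metadynamics hills live in the space of
an affine CV `s = M x + c`, so a learned linear RC folds directly into the
engine.  Hills are summed directly (no grid cache) — exactness over speed;
the integrator is compiled with numba.  The bias is recorded every step by
default so the rescaling integral has maximal resolution; the stride is
configurable to emulate coarser COLVAR output.

Three fixtures define the study conditions:

- **triple-well** (rate recovery): bound well at the origin behind a ≈7.5 kBT
  first saddle (well depths are scaled ×1.30 so the flood-fill-measured
  saddle height matches the nominal barrier), two metastable wells on the
  exit path, escape at 3 bound-well widths.  Unbiased MFPT ≈ 100 toy time
  units — large enough for rare-event statistics, small enough that a
  300-run brute-force oracle takes seconds.
- **three-state** (state discovery): a fast-exchanging pair of wells
  (dwell ≈ 20 recorded frames) plus one deep well (dwell ≈ 200 frames)
  under confinement, so lag ladders spanning 20–2000 frames cross both
  relaxation times.
- **channel** (protocol improvement): escape runs along +y while two decoy
  wells along x soak up bias deposited on the deliberately poor trial
  variable `x` — the toy analogue of biasing a hydrogen bond orthogonal to
  the true dissociation pathway.

What the toy does *not* emulate: high-dimensional orthogonal degrees of
freedom, diffusion anisotropy, multiple distinct dissociation pathways, and
force-field error.  Passing tests therefore demonstrate the correctness and
internal consistency of the machinery (rescaling, fitting, testing, state
discovery, round logic) — not that any particular protein–ligand estimate
is accurate.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `MetadSchedule.pace` | 500 (WT) / 5000 (iMetaD) | steps | infrequent mode differs only by rarer deposition |
| `MetadSchedule.height0` | 1.0–1.2 | kJ/mol (≡kBT) | ≈1 kBT hills: fast filling without swamping barriers |
| `MetadSchedule.bias_factor` | 8 | – | tempering cap ≈ (1−1/γ)·ΔF; ∞ = non-tempered |
| `SPIBConfig.lag` | per study | frames | the resolution knob for state discovery |
| `SPIBConfig.beta_ib` | 1e-2 | – | weak compression; large enough to prune spurious states |
| `SPIBConfig.K0` | 6 (4 in the toy studies) | – | upper bound on discoverable states |
| `refinement_tolerance` | 0.005 | fraction | label fixed-point threshold |
| `ProtocolConfig.n_wt_runs_per_round` | 8 | – | per-round WT batch |
| `ProtocolConfig.n_imetad_runs` | 12 | – | production batch (10–12 typical) |
| `stop_rel_improvement` | 0.10 | – | operationalizes "no longer decreases" |
| `rc_sigma_frac` | 0.2 | – | hill width = 0.2 × RC std over the training pool |

Distances are nm (PLUMED convention) for real systems; `kB` in kJ/(mol·K)
is provided for kelvin-based temperatures.

## Numerical choices

- τ fit: golden-section search on log τ (bracket mean/200..mean×200,
  60 iterations), vectorized across bootstrap resamples.  Degenerate
  resamples (all times equal) fall back to the sample mean.
- KS test: two-sample against 10⁴ fitted-exponential draws with a fixed
  internal seed — deterministic and calibrated (~5% rejection under the
  null at n = 12).  Note the published protocol refits τ on the tested
  sample, which makes the KS conservative (the Lilliefors effect); the
  calibration study therefore passes the generating τ.
- Bootstrap coverage is validated at 100 events per synthetic experiment,
  where the percentile method's own small-sample undercoverage is modest;
  at n ≈ 12 (production scale) percentile intervals are known to run a few
  points below nominal — an inherent property of the method.
- Argmax ties in label refinement break to the lowest state index.
  Restart overlap in COLVAR files resolves keep-first.  Script export
  renders 12 significant digits; COLVAR/HILLS render 17 (`%.17g`), making
  write→read round trips value-identical.
- Feature series handed to SPIB by the toy runner are subsampled (stride 20)
  relative to the bias record; the transition frame maps back onto the
  full-resolution trace for the rescaling integral.

## Known limitations

- The linear encoder cannot represent curved reaction coordinates; that is
  the method's own trade-off for a directly biasable RC.
- Accelerated times from *frequent* (WT) deposition are used only to rank
  coordinates, never as kinetics; only the infrequent-mode production runs
  feed the residence-time estimate.
- No pathway clustering: heterogeneous dissociation channels are pooled
  into a single τ.
- The engine is strictly 2-D overdamped with isotropic friction; no
  underdamped integrators or many-particle systems.
- `n_pseudo` defaults to `K0`; strongly anisotropic state populations may
  warrant more pseudo-inputs than states.
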