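"""Semi-automated residence-time protocol: trial biasing -> SPIB -> production.

The driver mirrors the round structure used for protein--ligand unbinding:

1. *Trial round*: independent well-tempered metadynamics runs biased along
   caller-chosen trial variables (hydrogen bonds or ligand--protein
   distances in real systems; a bare coordinate in the toy).  Runs where the
   dissociation criterion never fires are trapped and excluded.
2. *SPIB rounds*: train the information bottleneck on all dissociated
   trajectories accumulated so far (bias ignored — training pairs are
   unweighted), export the learned 2-D linear reaction coordinate, and run a
   batch of well-tempered metadynamics biased along it.  The mean
   accelerated time of the dissociated runs quantifies the coordinate: a
   better coordinate dissociates with less bias and so a smaller rescaled
   time.  Rounds repeat until that mean stops improving.
3. *Production*: infrequent metadynamics (rare deposition) along the best
   round's coordinate, followed by the exponential fit / KS reliability
   analysis that yields the residence time.

Each round is executed through a pluggable *runner*: a callable
``runner(cv, schedule, seed) -> RunResult``.  The built-in :class:`ToyRunner`
wraps the Langevin toy engine; real-MD users implement the same contract by
shelling out to their engine with an exported PLUMED script.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import kinetics, spib_core
from .featurize import FeatureTrajectory, filter_dissociated
from .kinetics import BiasTrace, ExponentialFit
from .spib_core import RCSpec, SPIBConfig
from .toy_engine import (
    HalfPlaneEscape,
    LangevinConfig,
    LinearCV,
    MetadSchedule,
    RadialEscape,
    ToyPotential,
    channel_potential,
    simulate_escape,
)

__all__ = [
    "ProtocolConfig",
    "RunResult",
    "RoundSummary",
    "ProtocolState",
    "ToyRunner",
    "run_trial_round",
    "run_spib_round",
    "stopping_rule",
    "run_production",
    "run_protocol",
    "toy_channel_protocol",
]

_PHASES = ("trial", "spib_rounds", "production", "done")


@dataclass
class RunResult:
    """One biased run as seen by the protocol: bias series + feature series.

    ``feature_stride`` maps feature frames back onto bias-trace records
    (feature frame j sits at trace index ``j * feature_stride``): the bias is
    kept at full resolution for the acceleration integral while the feature
    series fed to SPIB is subsampled.
    """

    bias_trace: BiasTrace
    features: FeatureTrajectory
    escaped: bool
    feature_stride: int = 1


@dataclass(frozen=True)
class ProtocolConfig:
    """Round-structure settings (defaults follow the published protocol scale)."""

    trial_cvs: tuple[LinearCV, ...]
    dissociation_label: str
    dissociation_threshold: float
    spib: SPIBConfig
    wt_sched: MetadSchedule
    imetad_sched: MetadSchedule
    n_trial_runs_per_cv: int = 4
    n_wt_runs_per_round: int = 8
    n_imetad_runs: int = 12
    max_rounds: int = 5
    stop_rel_improvement: float = 0.10
    rc_sigma_frac: float = 0.2  # hill width as a fraction of the RC std
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.trial_cvs:
            raise ValueError("at least one trial CV is required")
        if self.n_wt_runs_per_round < 1:
            raise ValueError("n_wt_runs_per_round must be >= 1")
        if self.n_imetad_runs < 3:
            raise ValueError("n_imetad_runs must be >= 3 for the exponential fit")
        if not (0.0 < self.stop_rel_improvement < 1.0):
            raise ValueError("stop_rel_improvement must be in (0, 1)")


@dataclass
class RoundSummary:
    """Bookkeeping for one round of biased runs."""

    index: int
    kind: str  # "trial" | "spib"
    rc: Optional[RCSpec]
    escaped_flags: list[bool]
    wall_times: list[float]
    accelerated_times: list[float]  # dissociated runs only
    failed: bool = False

    @property
    def n_dissociated(self) -> int:
        return len(self.accelerated_times)

    @property
    def mean_accelerated_time(self) -> float:
        if not self.accelerated_times:
            raise ValueError(f"round {self.index} has no dissociated runs")
        return float(np.mean(self.accelerated_times))


@dataclass
class ProtocolState:
    """Ordered round summaries plus the accumulated training pool."""

    rounds: list[RoundSummary] = field(default_factory=list)
    phase: str = "trial"
    dissociated_features: list[FeatureTrajectory] = field(default_factory=list)
    models: list = field(default_factory=list)
    final_fit: Optional[ExponentialFit] = None

    def advance(self, phase: str) -> None:
        if _PHASES.index(phase) < _PHASES.index(self.phase):
            raise ValueError(f"phase cannot move backwards: {self.phase} -> {phase}")
        self.phase = phase

    @property
    def spib_rounds(self) -> list[RoundSummary]:
        return [r for r in self.rounds if r.kind == "spib" and not r.failed]

    def best_spib_round(self) -> RoundSummary:
        rounds = [r for r in self.spib_rounds if r.accelerated_times]
        if not rounds:
            raise ValueError("no successful SPIB round available")
        return min(rounds, key=lambda r: r.mean_accelerated_time)


# ---------------------------------------------------------------------------
# toy runner
# ---------------------------------------------------------------------------

@dataclass
class ToyRunner:
    """Executes protocol runs on the 2-D Langevin toy engine.

    The feature map is the identity on the toy coordinates (labels ``x`` and
    ``y``), so a learned reaction coordinate — an affine map of features —
    folds directly into the engine's linear-CV bias.
    """

    potential: ToyPotential
    langevin: LangevinConfig
    escape_test: object
    record_stride: int = 1
    feature_stride: int = 20  # feature frames per bias record
    feature_labels: tuple[str, str] = ("x", "y")

    def __call__(self, cv: LinearCV, sched: MetadSchedule, seed: int) -> RunResult:
        cfg = replace(self.langevin, seed=int(seed))
        traj = simulate_escape(
            self.potential, cfg, sched=sched, escape_test=self.escape_test,
            cv=cv, record_stride=self.record_stride,
        )
        fs = max(1, self.feature_stride)
        idx = np.arange(0, len(traj.times), fs)
        if traj.escaped and idx[-1] != len(traj.times) - 1:
            idx = np.append(idx, len(traj.times) - 1)  # keep the escape frame
        features = FeatureTrajectory(
            times=traj.times[idx],
            values=traj.positions[idx],
            labels=self.feature_labels,
        )
        trans = len(traj.times) - 1 if traj.escaped else None
        trace = BiasTrace(
            times=traj.times, bias=traj.bias_values, kBT=cfg.kBT,
            transition_index=trans,
        )
        return RunResult(bias_trace=trace, features=features, escaped=traj.escaped,
                         feature_stride=fs)


def rc_to_cv(rc: RCSpec) -> LinearCV:
    """Fold an RCSpec into an engine-ready affine CV (identity feature map only)."""
    matrix = rc.coefficients / rc.scale
    offset = rc.offsets - matrix @ rc.mean
    return LinearCV(matrix=np.asarray(matrix), offset=np.asarray(offset),
                    labels=tuple(f"rc{i + 1}" for i in range(matrix.shape[0])))


def _round_seeds(master: int, round_tag: int, n: int) -> np.ndarray:
    return np.random.SeedSequence([master, round_tag]).generate_state(n) % (2**31)


def _collect_round(
    results: Sequence[RunResult],
    cfg: ProtocolConfig,
    index: int,
    kind: str,
    rc: Optional[RCSpec],
) -> tuple[RoundSummary, list[FeatureTrajectory]]:
    kept, _ = filter_dissociated(
        [r.features for r in results], cfg.dissociation_label,
        cfg.dissociation_threshold,
    )
    acc = []
    for r in results:
        if r.features.dissociated:
            n_rec = len(r.bias_trace.times)
            r.bias_trace.transition_index = min(
                r.features.dissociation_frame * r.feature_stride, n_rec - 1
            )
            acc.append(kinetics.accelerated_time(r.bias_trace))
    summary = RoundSummary(
        index=index, kind=kind, rc=rc,
        escaped_flags=[r.escaped for r in results],
        wall_times=[float(r.bias_trace.times[-1]) for r in results],
        accelerated_times=acc,
    )
    return summary, kept


# ---------------------------------------------------------------------------
# protocol operations
# ---------------------------------------------------------------------------

def run_trial_round(
    cfg: ProtocolConfig,
    runner: Callable[[LinearCV, MetadSchedule, int], RunResult],
) -> tuple[list[FeatureTrajectory], RoundSummary]:
    """Initial well-tempered runs biased along the trial variables.

    Launches ``n_trial_runs_per_cv`` independent runs per trial CV with
    distinct seeds; the dissociated subset (criterion OP exceeding the
    threshold) becomes the first SPIB training pool.  Raises when nothing
    dissociates — the manual fallback is longer runs or different trial
    variables.
    """
    results: list[RunResult] = []
    for c, cv in enumerate(cfg.trial_cvs):
        seeds = _round_seeds(cfg.seed, 1000 + c, cfg.n_trial_runs_per_cv)
        for s in seeds:
            results.append(runner(cv, cfg.wt_sched, int(s)))
    summary, kept = _collect_round(results, cfg, index=0, kind="trial", rc=None)
    return kept, summary


def run_spib_round(
    state: ProtocolState,
    cfg: ProtocolConfig,
    runner: Callable[[LinearCV, MetadSchedule, int], RunResult],
) -> ProtocolState:
    """One iteration of SPIB training plus a batch of WT metadynamics on its RC.

    Trains on *all* dissociated trajectories accumulated across rounds,
    exports the linear RC, sets the hill widths to ``rc_sigma_frac`` times
    the RC standard deviation over the training pool, runs
    ``n_wt_runs_per_round`` biased runs and appends the round summary.
    """
    if not state.dissociated_features:
        raise ValueError("no dissociated trajectories available for SPIB training")
    index = len(state.rounds)
    state.advance("spib_rounds")
    try:
        spib_cfg = replace(cfg.spib, seed=cfg.spib.seed + index)
        model = spib_core.train_spib(state.dissociated_features, spib_cfg)
        rc = spib_core.export_rc(model)
    except Exception as exc:
        raise RuntimeError(f"SPIB training failed in round {index}: {exc}") from exc

    pool = np.vstack([f.values for f in state.dissociated_features])
    rc_vals = rc.apply(pool)
    sigma = tuple(
        float(max(cfg.rc_sigma_frac * s, 1e-3)) for s in rc_vals.std(axis=0)
    )
    sched = replace(cfg.wt_sched, sigma=sigma)
    cv = rc_to_cv(rc)

    seeds = _round_seeds(cfg.seed, 2000 + index, cfg.n_wt_runs_per_round)
    results = [runner(cv, sched, int(s)) for s in seeds]
    try:
        summary, kept = _collect_round(results, cfg, index=index, kind="spib", rc=rc)
    except ValueError as exc:
        raise RuntimeError(f"round {index}: {exc}") from exc
    state.rounds.append(summary)
    state.models.append(model)
    state.dissociated_features.extend(kept)
    return state


def stopping_rule(
    summaries: Sequence[RoundSummary],
    stop_rel_improvement: float = 0.10,
    max_rounds: int = 5,
) -> bool:
    """True when the mean accelerated time has stopped improving.

    "No longer decreases" is operationalized as: the latest SPIB round's mean
    accelerated time improves on the best previous SPIB round by less than
    ``stop_rel_improvement`` (relative), or the SPIB round budget is spent.
    Only SPIB rounds enter the comparison — the trial round bootstraps the
    training data but its accelerated time does not measure any learned
    coordinate, and its run-to-run noise should not gate convergence — so at
    least two SPIB rounds are always performed.
    """
    spib = [s for s in summaries if s.kind == "spib" and not s.failed]
    if not spib:
        raise ValueError("stopping rule needs at least one completed SPIB round")
    if len(spib) >= max_rounds:
        return True
    means = [s.mean_accelerated_time for s in spib]
    if len(means) < 2:
        return False
    best_prev = min(means[:-1])
    improvement = (best_prev - means[-1]) / best_prev
    return improvement < stop_rel_improvement


def run_production(
    state: ProtocolState,
    cfg: ProtocolConfig,
    runner: Callable[[LinearCV, MetadSchedule, int], RunResult],
) -> ExponentialFit:
    """Infrequent-metadynamics production on the best round's coordinate.

    The RC with the smallest mean accelerated time is selected, ~10-12
    independent rare-deposition runs are launched, and the accelerated
    first-passage times go through the exponential fit, KS reliability test
    and bootstrap CI.  Censored runs are counted, not fitted.
    """
    best = state.best_spib_round()
    rc = best.rc
    pool = np.vstack([f.values for f in state.dissociated_features])
    rc_vals = rc.apply(pool)
    sigma = tuple(
        float(max(cfg.rc_sigma_frac * s, 1e-3)) for s in rc_vals.std(axis=0)
    )
    sched = replace(cfg.imetad_sched, sigma=sigma)
    cv = rc_to_cv(rc)
    state.advance("production")

    seeds = _round_seeds(cfg.seed, 9000, cfg.n_imetad_runs)
    traces: list[BiasTrace] = []
    n_transitions = 0
    for s in seeds:
        res = runner(cv, sched, int(s))
        tr = res.bias_trace
        if res.escaped:
            # transition frame from the dissociation criterion, like every round
            col = res.features.column(cfg.dissociation_label)
            above = np.nonzero(col > cfg.dissociation_threshold)[0]
            tr.transition_index = (
                min(int(above[0]) * res.feature_stride, len(tr.times) - 1)
                if len(above) else None
            )
        else:
            tr.transition_index = None
        if tr.transition_index is not None:
            n_transitions += 1
        traces.append(tr)
    if n_transitions < 3:
        raise RuntimeError(
            f"only {n_transitions} production runs dissociated; at least 3 are "
            "needed for the exponential fit — lengthen the runs"
        )
    fit = kinetics.residence_report(traces, seed=cfg.seed)
    state.final_fit = fit
    state.advance("done")
    return fit


def run_protocol(
    cfg: ProtocolConfig,
    runner: Callable[[LinearCV, MetadSchedule, int], RunResult],
) -> ProtocolState:
    """Full pipeline: trial round, SPIB rounds until the stopping rule, production."""
    state = ProtocolState()
    kept, trial_summary = run_trial_round(cfg, runner)
    state.rounds.append(trial_summary)
    state.dissociated_features.extend(kept)

    while True:
        state = run_spib_round(state, cfg, runner)
        if stopping_rule(
            state.rounds, cfg.stop_rel_improvement, max_rounds=cfg.max_rounds
        ):
            break
    run_production(state, cfg, runner)
    return state


# ---------------------------------------------------------------------------
# ready-made toy studies
# ---------------------------------------------------------------------------

def three_state_training_data(
    seed: int = 1,
    n_steps: int = 2_000_000,
    stride: int = 30,
) -> FeatureTrajectory:
    """Unbiased trajectory on the three-state potential, as SPIB input.

    The recording stride makes one frame 0.03 time units: the fast A<->B
    exchange then dwells ~20 frames per well and the slow well ~200, so lag
    ladders spanning 20..2000 frames probe both sides of each relaxation.
    """
    from .toy_engine import RadialEscape, three_state_potential

    pot = three_state_potential()
    cfg = LangevinConfig(n_steps=n_steps, seed=seed, start=(-0.9, 0.0))
    traj = simulate_escape(
        pot, cfg, escape_test=RadialEscape((0.0, 0.0), 1e9), record_stride=stride
    )
    return FeatureTrajectory(times=traj.times, values=traj.positions,
                             labels=("x", "y"))


def three_state_spib_config(lag: int, seed: int = 0) -> SPIBConfig:
    """SPIB settings used for state discovery on the three-state fixture."""
    return SPIBConfig(lag=lag, K0=4, seed=seed, epochs_per_refinement=6,
                      max_refinements=10, batch_size=1024)

def toy_channel_protocol(
    seed: int = 0,
    n_steps: int = 600_000,
    master_cfg: Optional[dict] = None,
) -> tuple[ProtocolConfig, ToyRunner]:
    """Channel-potential study: trial CV deliberately orthogonal to the exit path.

    The bound well sits at the origin and the escape channel runs along +y,
    but the trial variable is the x coordinate — the toy analogue of biasing
    a hydrogen bond that is not the real dissociation coordinate.  SPIB then
    has to discover a coordinate with a y component to beat the trial round's
    mean accelerated time.
    """
    pot = channel_potential()
    escape = HalfPlaneEscape(normal=(0.0, 1.0), threshold=2.4)
    langevin = LangevinConfig(dt=1e-3, kBT=1.0, friction=1.0, n_steps=n_steps,
                              start=(0.0, 0.0))
    runner = ToyRunner(potential=pot, langevin=langevin, escape_test=escape,
                       record_stride=1, feature_stride=20)
    overrides = master_cfg or {}
    cfg = ProtocolConfig(
        trial_cvs=(LinearCV.axis((1.0, 0.0), label="trial_x"),),
        dissociation_label="y",
        dissociation_threshold=2.4,
        spib=SPIBConfig(lag=25, K0=4, seed=seed, epochs_per_refinement=6,
                        max_refinements=8, batch_size=1024),
        wt_sched=MetadSchedule(pace=1000, height0=1.0, sigma=(0.35,),
                               bias_factor=8.0, mode="well_tempered"),
        imetad_sched=MetadSchedule(pace=5000, height0=1.0, sigma=(0.35,),
                                   bias_factor=8.0, mode="infrequent"),
        seed=seed,
        **overrides,
    )
    return cfg, runner
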