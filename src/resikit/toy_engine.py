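"""Two-dimensional Langevin toy systems with well-tempered / infrequent metadynamics.

The engine provides analytic multi-well potentials (sums of inverted Gaussians),
an overdamped Euler--Maruyama integrator, and a metadynamics bias built from
Gaussian hills deposited along a (possibly linear-combination) collective
variable.  It supplies ground-truth escape kinetics for validating the
residence-time machinery: the same bias-rescaling formula that recovers ligand
unbinding times from infrequent metadynamics can be checked here against
brute-force unbiased first-passage times.

Units are "toy" units throughout: energies in kJ/mol with ``kBT`` given
directly (defaults ``kBT = 1``), lengths dimensionless, friction an inverse
time scale.  ``KB_KJ_PER_MOL_K`` is provided for callers who work in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/(mol K)

__all__ = [
    "KB_KJ_PER_MOL_K",
    "Well",
    "ToyPotential",
    "LangevinConfig",
    "MetadSchedule",
    "HillList",
    "LinearCV",
    "RadialEscape",
    "HalfPlaneEscape",
    "ToyTrajectory",
    "FirstPassageResult",
    "potential_energy",
    "potential_gradient",
    "deposit_hill",
    "evaluate_bias",
    "simulate_escape",
    "unbiased_mfpt",
    "triple_well",
    "three_state_potential",
    "channel_potential",
]


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Well:
    """One inverted-Gaussian well: ``-depth * exp(-|x-center|^2 / (2 width^2))``."""

    center: tuple[float, float]
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"well depth must be > 0, got {self.depth}")
        if self.width <= 0:
            raise ValueError(f"well width must be > 0, got {self.width}")


@dataclass(frozen=True)
class ToyPotential:
    """Smooth multi-well potential: a sum of inverted Gaussian wells.

    An optional harmonic confinement ``0.5 k |x - c|^2`` keeps equilibrium
    fixtures recurrent (without it the potential is flat far from the wells
    and an unbiased walker eventually diffuses away).  Escape fixtures leave
    ``confinement_k = 0``.
    """

    wells: tuple[Well, ...]
    label: str = "toy"
    confinement_k: float = 0.0
    confinement_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.wells) < 2:
            raise ValueError("a toy potential needs at least 2 wells")
        if self.confinement_k < 0:
            raise ValueError("confinement_k must be >= 0")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        centers = np.array([w.center for w in self.wells], dtype=np.float64)
        depths = np.array([w.depth for w in self.wells], dtype=np.float64)
        widths = np.array([w.width for w in self.wells], dtype=np.float64)
        return centers, depths, widths

    @property
    def bound_well(self) -> Well:
        """Deepest well; the toy analogue of the ligand-bound pose."""
        return max(self.wells, key=lambda w: w.depth)


def potential_energy(pot: ToyPotential, x: Sequence[float]) -> float:
    """Energy (kJ/mol) at position ``x``: sum of the inverted-Gaussian wells."""
    xv = np.asarray(x, dtype=np.float64)
    centers, depths, widths = pot.arrays()
    d2 = np.sum((xv[None, :] - centers) ** 2, axis=1)
    e = float(np.sum(-depths * np.exp(-d2 / (2.0 * widths**2))))
    if pot.confinement_k > 0:
        cc = np.asarray(pot.confinement_center)
        e += 0.5 * pot.confinement_k * float(np.sum((xv - cc) ** 2))
    return e


def potential_gradient(pot: ToyPotential, x: Sequence[float]) -> np.ndarray:
    """Analytic gradient of :func:`potential_energy` at ``x``."""
    xv = np.asarray(x, dtype=np.float64)
    centers, depths, widths = pot.arrays()
    diff = xv[None, :] - centers
    d2 = np.sum(diff**2, axis=1)
    g = depths * np.exp(-d2 / (2.0 * widths**2)) / widths**2
    out = np.sum(g[:, None] * diff, axis=0)
    if pot.confinement_k > 0:
        out = out + pot.confinement_k * (xv - np.asarray(pot.confinement_center))
    return out


def triple_well(barrier: float = 7.5) -> ToyPotential:
    """Triple-well escape fixture: deep bound well plus two metastable wells.

    ``barrier`` is the escape barrier out of the bound well in energy units
    (kBT when ``kBT = 1``).  Because the neighbouring well's tail lifts the
    bound minimum, the well depths are scaled by 1.30 so that the *actual*
    saddle height above the bound minimum (measured by flood fill on a fine
    grid) matches the nominal value to within a few percent.  Escape is
    usually declared at 3 bound-well widths from the origin, just beyond the
    first saddle.
    """
    d = 1.30 * barrier
    return ToyPotential(
        wells=(
            Well(center=(0.0, 0.0), depth=d, width=0.5),
            Well(center=(1.7, 0.55), depth=0.45 * d, width=0.45),
            Well(center=(2.9, -0.3), depth=0.3 * d, width=0.45),
        ),
        label=f"triple-well(barrier={barrier:g})",
    )


def three_state_potential() -> ToyPotential:
    """Three-well system with one fast-exchanging pair, for state discovery.

    Wells A and B (left/right) exchange over a low barrier; well C (top) is
    separated by a higher barrier, so the A<->B relaxation is much faster than
    A,B <-> C.  All barriers are low enough that an unbiased trajectory visits
    every well many times at desk scale.
    """
    return ToyPotential(
        wells=(
            Well(center=(-0.9, 0.0), depth=3.5, width=0.60),
            Well(center=(0.9, 0.0), depth=3.5, width=0.60),
            Well(center=(0.0, 2.0), depth=7.0, width=0.50),
        ),
        label="three-state",
        confinement_k=0.9,
        confinement_center=(0.0, 0.4),
    )


def channel_potential() -> ToyPotential:
    """Bound well with an escape channel along +y; x is a poor coordinate.

    Mimics a ligand whose dissociation pathway is orthogonal to an obvious
    trial variable: the escape route climbs out of the bound well along +y,
    while two decoy wells along x soak up any bias deposited on the x
    coordinate.  Biasing x therefore builds a large, mostly useless bias
    (escape stays thermally limited), whereas a coordinate with a y
    component drives dissociation directly — so the mean accelerated time
    separates a poor coordinate from a good one by roughly exp(wasted bias).
    """
    return ToyPotential(
        wells=(
            Well(center=(0.0, 0.0), depth=7.5, width=0.55),
            Well(center=(-1.4, 0.0), depth=4.5, width=0.5),
            Well(center=(1.4, 0.0), depth=4.5, width=0.5),
            Well(center=(0.0, 1.9), depth=3.0, width=0.5),
        ),
        label="channel",
        confinement_k=1.2,
        confinement_center=(0.0, 0.4),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LangevinConfig:
    """Overdamped Langevin integration settings (toy units)."""

    dt: float = 1e-3
    kBT: float = 1.0
    friction: float = 1.0
    n_steps: int = 100_000
    seed: int = 0
    start: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.kBT <= 0:
            raise ValueError(f"kBT must be > 0, got {self.kBT}")
        if self.friction <= 0:
            raise ValueError(f"friction must be > 0, got {self.friction}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class MetadSchedule:
    """Metadynamics deposition schedule.

    ``bias_factor`` is the well-tempered gamma; ``math.inf`` disables
    tempering (every hill is deposited at ``height0``).  Infrequent
    metadynamics differs from the well-tempered mode only by a larger
    ``pace`` so that deposition is rare on the transition-path timescale.
    """

    pace: int
    height0: float
    sigma: tuple[float, ...]
    bias_factor: float = math.inf
    mode: str = "well_tempered"

    def __post_init__(self) -> None:
        if self.pace < 1:
            raise ValueError(f"pace must be >= 1, got {self.pace}")
        if self.height0 <= 0:
            raise ValueError(f"height0 must be > 0, got {self.height0}")
        sig = tuple(float(s) for s in np.atleast_1d(np.asarray(self.sigma, dtype=float)))
        if any(s <= 0 for s in sig):
            raise ValueError("all hill widths (sigma) must be > 0")
        object.__setattr__(self, "sigma", sig)
        if not (self.bias_factor > 1):
            raise ValueError(f"bias_factor must be > 1 (or inf), got {self.bias_factor}")
        if self.mode not in ("well_tempered", "infrequent"):
            raise ValueError(f"unknown metadynamics mode {self.mode!r}")


@dataclass
class HillList:
    """Ordered record of deposited Gaussian hills in CV space."""

    times: np.ndarray
    centers: np.ndarray  # (n_hills, n_cv)
    sigmas: np.ndarray   # (n_hills, n_cv)
    heights: np.ndarray

    @classmethod
    def empty(cls, n_cv: int) -> "HillList":
        return cls(
            times=np.empty(0),
            centers=np.empty((0, n_cv)),
            sigmas=np.empty((0, n_cv)),
            heights=np.empty(0),
        )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_cv(self) -> int:
        return self.centers.shape[1]


@dataclass(frozen=True)
class LinearCV:
    """Affine collective variable ``s = M x + offset`` on the 2-D toy coordinates."""

    matrix: np.ndarray  # (n_cv, 2)
    offset: np.ndarray  # (n_cv,)
    labels: tuple[str, ...] = ()

    @classmethod
    def identity(cls) -> "LinearCV":
        return cls(matrix=np.eye(2), offset=np.zeros(2), labels=("cv1", "cv2"))

    @classmethod
    def axis(cls, direction: Sequence[float], label: str = "cv1") -> "LinearCV":
        m = np.asarray(direction, dtype=float).reshape(1, 2)
        return cls(matrix=m, offset=np.zeros(1), labels=(label,))

    @property
    def n_cv(self) -> int:
        return self.matrix.shape[0]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.matrix.T + self.offset


@dataclass(frozen=True)
class RadialEscape:
    """Escape when ``|x - center| > radius`` (ligand-dissociation cutoff analogue)."""

    center: tuple[float, float]
    radius: float

    def __call__(self, x: np.ndarray) -> bool:
        return bool(np.linalg.norm(np.asarray(x) - np.asarray(self.center)) > self.radius)


@dataclass(frozen=True)
class HalfPlaneEscape:
    """Escape when ``normal . x > threshold`` (directional exit channel)."""

    normal: tuple[float, float]
    threshold: float

    def __call__(self, x: np.ndarray) -> bool:
        return bool(float(np.dot(self.normal, x)) > self.threshold)


def default_escape(pot: ToyPotential) -> RadialEscape:
    """Default dissociation predicate: 3 bound-well widths from the bound center."""
    w = pot.bound_well
    return RadialEscape(center=w.center, radius=3.0 * w.width)


@dataclass
class ToyTrajectory:
    """Recorded toy run: positions, CV values and instantaneous bias energy."""

    times: np.ndarray
    positions: np.ndarray      # (n_rec, 2)
    cv_values: np.ndarray      # (n_rec, n_cv)
    bias_values: np.ndarray    # V(s_t, t), kJ/mol, >= 0
    escaped: bool
    escape_step: Optional[int]
    hills: HillList
    dt: float
    kBT: float

    @property
    def wall_time(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class FirstPassageResult:
    """Unbiased mean first-passage time with its standard error."""

    mean: float
    stderr: float
    times: np.ndarray

    def __iter__(self):
        return iter((self.mean, self.stderr))


# ---------------------------------------------------------------------------
# hill bookkeeping (reference-path implementations)
# ---------------------------------------------------------------------------

def evaluate_bias(hills: HillList, s: Sequence[float]) -> float:
    """Metadynamics bias ``V(s)``: direct sum of all deposited Gaussian hills."""
    if len(hills) == 0:
        return 0.0
    sv = np.asarray(s, dtype=float)
    z2 = np.sum(((sv[None, :] - hills.centers) / hills.sigmas) ** 2, axis=1)
    return float(np.sum(hills.heights * np.exp(-0.5 * z2)))


def deposit_hill(
    hills: HillList,
    s: Sequence[float],
    t: float,
    sched: MetadSchedule,
    kBT: float,
) -> HillList:
    """Append one hill at CV position ``s`` and time ``t``.

    In well-tempered mode the deposited height is damped by the bias already
    present at the deposition point: ``h = height0 * exp(-V(s,t) / ((gamma-1) kBT))``.
    With ``bias_factor = inf`` every hill keeps the full ``height0``.
    """
    if len(hills) and t <= hills.times[-1]:
        raise ValueError(
            f"hill time must increase: got t={t} after t={hills.times[-1]}"
        )
    sv = np.asarray(s, dtype=float)
    if len(hills) and sv.shape[0] != hills.n_cv:
        raise ValueError("CV dimensionality mismatch with existing hills")
    v_here = evaluate_bias(hills, sv)
    if math.isinf(sched.bias_factor):
        h = sched.height0
    else:
        h = sched.height0 * math.exp(-v_here / ((sched.bias_factor - 1.0) * kBT))
    sig = np.asarray(sched.sigma, dtype=float)
    if sig.shape[0] != sv.shape[0]:
        sig = np.full(sv.shape[0], sig[0])
    return HillList(
        times=np.append(hills.times, t),
        centers=np.vstack([hills.centers, sv[None, :]]) if len(hills) else sv[None, :].copy(),
        sigmas=np.vstack([hills.sigmas, sig[None, :]]) if len(hills) else sig[None, :].copy(),
        heights=np.append(hills.heights, h),
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

_ESC_NONE, _ESC_RADIAL, _ESC_HALFPLANE = 0, 1, 2


@njit(cache=True)
def _bias_and_grad(s, hc, hs, hh, nh):
    v = 0.0
    g0 = 0.0
    g1 = 0.0
    ncv = s.shape[0]
    for i in range(nh):
        z2 = 0.0
        for d in range(ncv):
            u = (s[d] - hc[i, d]) / hs[i, d]
            z2 += u * u
        e = hh[i] * math.exp(-0.5 * z2)
        v += e
        g0 += -e * (s[0] - hc[i, 0]) / (hs[i, 0] * hs[i, 0])
        if ncv > 1:
            g1 += -e * (s[1] - hc[i, 1]) / (hs[i, 1] * hs[i, 1])
    return v, g0, g1


@njit(cache=True)
def _bias_only(s, hc, hs, hh, nh):
    v = 0.0
    ncv = s.shape[0]
    for i in range(nh):
        z2 = 0.0
        for d in range(ncv):
            u = (s[d] - hc[i, d]) / hs[i, d]
            z2 += u * u
        v += hh[i] * math.exp(-0.5 * z2)
    return v


@njit(cache=True)
def _pot_grad(x0, x1, wc, wd, ww, ck, cc0, cc1):
    g0 = ck * (x0 - cc0)
    g1 = ck * (x1 - cc1)
    for i in range(wc.shape[0]):
        dx0 = x0 - wc[i, 0]
        dx1 = x1 - wc[i, 1]
        w2 = ww[i] * ww[i]
        e = wd[i] * math.exp(-(dx0 * dx0 + dx1 * dx1) / (2.0 * w2)) / w2
        g0 += e * dx0
        g1 += e * dx1
    return g0, g1


@njit(cache=True)
def _escaped(x0, x1, esc_kind, ea0, ea1, ec):
    if esc_kind == 1:
        d0 = x0 - ea0
        d1 = x1 - ea1
        return d0 * d0 + d1 * d1 > ec * ec
    elif esc_kind == 2:
        return ea0 * x0 + ea1 * x1 > ec
    return False


@njit(cache=True)
def _run_metad(wc, wd, ww, ck, cc0, cc1, x0_in, x1_in, dt, kBT, friction, n_steps, seed,
               pace, height0, sigma, gamma, M, coff,
               esc_kind, ea0, ea1, ec, record_stride):
    """Euler--Maruyama with metadynamics along s = M x + coff.

    Returns (n_rec, rec_t, rec_x, rec_s, rec_v, escaped, escape_step,
    n_hills, hill_t, hill_c, hill_h, err) with err: 0 ok, 1 NaN position.
    """
    np.random.seed(seed)
    ncv = M.shape[0]
    max_hills = (n_steps // pace + 1) if pace > 0 else 0
    hill_t = np.zeros(max_hills)
    hill_c = np.zeros((max_hills, ncv))
    hill_h = np.zeros(max_hills)
    hs = np.zeros((max_hills, ncv))
    nh = 0

    n_rec_max = n_steps // record_stride + 3
    rec_t = np.zeros(n_rec_max)
    rec_x = np.zeros((n_rec_max, 2))
    rec_s = np.zeros((n_rec_max, ncv))
    rec_v = np.zeros(n_rec_max)

    x0 = x0_in
    x1 = x1_in
    s = np.zeros(ncv)
    noise_amp = math.sqrt(2.0 * kBT * dt / friction)
    inv_gamma_term = 0.0
    if gamma > 0.0:  # finite bias factor; gamma <= 0 encodes infinity
        inv_gamma_term = 1.0 / ((gamma - 1.0) * kBT)

    # initial record at t = 0
    for d in range(ncv):
        s[d] = M[d, 0] * x0 + M[d, 1] * x1 + coff[d]
        rec_s[0, d] = s[d]
    rec_t[0] = 0.0
    rec_x[0, 0] = x0
    rec_x[0, 1] = x1
    rec_v[0] = 0.0
    n_rec = 1

    escaped = False
    escape_step = -1
    err = 0

    for step in range(1, n_steps + 1):
        for d in range(ncv):
            s[d] = M[d, 0] * x0 + M[d, 1] * x1 + coff[d]
        v = 0.0
        gs0 = 0.0
        gs1 = 0.0
        if nh > 0:
            v, gs0, gs1 = _bias_and_grad(s, hill_c, hs, hill_h, nh)
        if pace > 0 and step % pace == 0:
            if inv_gamma_term > 0.0:
                h = height0 * math.exp(-v * inv_gamma_term)
            else:
                h = height0
            hill_t[nh] = step * dt
            for d in range(ncv):
                hill_c[nh, d] = s[d]
                hs[nh, d] = sigma[d]
            hill_h[nh] = h
            nh += 1

        gu0, gu1 = _pot_grad(x0, x1, wc, wd, ww, ck, cc0, cc1)
        # chain rule: dV/dx = M^T dV/ds
        gb0 = M[0, 0] * gs0
        gb1 = M[0, 1] * gs0
        if ncv > 1:
            gb0 += M[1, 0] * gs1
            gb1 += M[1, 1] * gs1
        x0 = x0 - dt * (gu0 + gb0) / friction + noise_amp * np.random.normal()
        x1 = x1 - dt * (gu1 + gb1) / friction + noise_amp * np.random.normal()

        if not (math.isfinite(x0) and math.isfinite(x1)):
            err = 1
            break

        esc_now = _escaped(x0, x1, esc_kind, ea0, ea1, ec)
        if step % record_stride == 0 or esc_now or step == n_steps:
            for d in range(ncv):
                s[d] = M[d, 0] * x0 + M[d, 1] * x1 + coff[d]
            v_rec = _bias_only(s, hill_c, hs, hill_h, nh) if nh > 0 else 0.0
            rec_t[n_rec] = step * dt
            rec_x[n_rec, 0] = x0
            rec_x[n_rec, 1] = x1
            for d in range(ncv):
                rec_s[n_rec, d] = s[d]
            rec_v[n_rec] = v_rec
            n_rec += 1
        if esc_now:
            escaped = True
            escape_step = step
            break

    return (n_rec, rec_t, rec_x, rec_s, rec_v, escaped, escape_step,
            nh, hill_t, hill_c, hs, hill_h, err)


@njit(cache=True)
def _run_fpt(wc, wd, ww, ck, cc0, cc1, x0_in, x1_in, dt, kBT, friction, n_steps, seed,
             esc_kind, ea0, ea1, ec):
    """Lean unbiased first-passage kernel: escape step, -1 no escape, -2 NaN."""
    np.random.seed(seed)
    x0 = x0_in
    x1 = x1_in
    noise_amp = math.sqrt(2.0 * kBT * dt / friction)
    for step in range(1, n_steps + 1):
        g0, g1 = _pot_grad(x0, x1, wc, wd, ww, ck, cc0, cc1)
        x0 = x0 - dt * g0 / friction + noise_amp * np.random.normal()
        x1 = x1 - dt * g1 / friction + noise_amp * np.random.normal()
        if not (math.isfinite(x0) and math.isfinite(x1)):
            return -2
        if _escaped(x0, x1, esc_kind, ea0, ea1, ec):
            return step
    return -1


# ---------------------------------------------------------------------------
# public simulation API
# ---------------------------------------------------------------------------

def _escape_code(escape_test) -> tuple[int, float, float, float]:
    if isinstance(escape_test, RadialEscape):
        return _ESC_RADIAL, escape_test.center[0], escape_test.center[1], escape_test.radius
    if isinstance(escape_test, HalfPlaneEscape):
        return _ESC_HALFPLANE, escape_test.normal[0], escape_test.normal[1], escape_test.threshold
    return _ESC_NONE, 0.0, 0.0, 0.0


def simulate_escape(
    pot: ToyPotential,
    cfg: LangevinConfig,
    sched: Optional[MetadSchedule] = None,
    escape_test: Optional[Callable[[np.ndarray], bool]] = None,
    cv: Optional[LinearCV] = None,
    record_stride: int = 1,
) -> ToyTrajectory:
    """Run one (possibly biased) Langevin trajectory until escape or ``n_steps``.

    The overdamped Euler--Maruyama update is
    ``x <- x - dt * grad(U + V) / friction + sqrt(2 kBT dt / friction) * eta``
    with standard-normal ``eta``.  When ``sched`` is given, Gaussian hills are
    deposited every ``pace`` steps along the collective variable ``cv``
    (identity by default), and the instantaneous bias ``V(s_t, t)`` is recorded
    at every recorded frame so that the acceleration-factor integral can be
    evaluated at full resolution.

    ``escape_test`` may be any predicate on position.  :class:`RadialEscape`
    and :class:`HalfPlaneEscape` are evaluated inside the compiled kernel every
    step; other callables are applied to the recorded frames (use
    ``record_stride=1`` for step-exact escape detection).
    """
    if escape_test is None:
        escape_test = default_escape(pot)
    if cv is None:
        cv = LinearCV.identity()
    wc, wd, ww = pot.arrays()
    M = np.ascontiguousarray(cv.matrix, dtype=np.float64)
    coff = np.ascontiguousarray(cv.offset, dtype=np.float64)

    if sched is None:
        pace, height0, gamma = 0, 1.0, 0.0
        sigma = np.ones(M.shape[0])
    else:
        pace, height0 = sched.pace, sched.height0
        gamma = 0.0 if math.isinf(sched.bias_factor) else sched.bias_factor
        sigma = np.asarray(sched.sigma, dtype=np.float64)
        if sigma.shape[0] != M.shape[0]:
            if sigma.shape[0] == 1:
                sigma = np.full(M.shape[0], sigma[0])
            else:
                raise ValueError("sigma length must match CV dimensionality")

    esc_kind, ea0, ea1, ec = _escape_code(escape_test)
    custom_escape = esc_kind == _ESC_NONE

    (n_rec, rec_t, rec_x, rec_s, rec_v, escaped, escape_step,
     nh, hill_t, hill_c, hill_s, hill_h, err) = _run_metad(
        wc, wd, ww,
        pot.confinement_k, pot.confinement_center[0], pot.confinement_center[1],
        float(cfg.start[0]), float(cfg.start[1]),
        cfg.dt, cfg.kBT, cfg.friction, cfg.n_steps, int(cfg.seed) % (2**31),
        pace, height0, sigma, gamma, M, coff,
        esc_kind, ea0, ea1, ec, record_stride,
    )
    if err == 1:
        raise RuntimeError(
            f"position became non-finite; the time step dt={cfg.dt} is too "
            "large for this potential/friction"
        )

    times = rec_t[:n_rec].copy()
    pos = rec_x[:n_rec].copy()
    cvs = rec_s[:n_rec].copy()
    vb = rec_v[:n_rec].copy()
    esc = bool(escaped)
    esc_step: Optional[int] = int(escape_step) if escaped else None

    if custom_escape:
        hit = [i for i in range(n_rec) if escape_test(pos[i])]
        if hit:
            k = hit[0]
            times, pos, cvs, vb = times[: k + 1], pos[: k + 1], cvs[: k + 1], vb[: k + 1]
            esc = True
            esc_step = int(round(times[k] / cfg.dt))
            keep = hill_t[:nh] <= times[k]
            nh = int(np.sum(keep))

    hills = HillList(
        times=hill_t[:nh].copy(),
        centers=hill_c[:nh].copy(),
        sigmas=hill_s[:nh].copy(),
        heights=hill_h[:nh].copy(),
    )
    return ToyTrajectory(
        times=times, positions=pos, cv_values=cvs, bias_values=vb,
        escaped=esc, escape_step=esc_step, hills=hills,
        dt=cfg.dt, kBT=cfg.kBT,
    )


def unbiased_mfpt(
    pot: ToyPotential,
    cfg: LangevinConfig,
    escape_test: Optional[Callable[[np.ndarray], bool]] = None,
    n_runs: int = 100,
    seed: int = 0,
) -> FirstPassageResult:
    """Brute-force unbiased mean first-passage time over independent runs.

    Ground-truth oracle for the bias-rescaled estimates.  Every run must
    escape within ``cfg.n_steps``; otherwise the mean would be censored and an
    error is raised instead.
    """
    if escape_test is None:
        escape_test = default_escape(pot)
    esc_kind, ea0, ea1, ec = _escape_code(escape_test)
    if esc_kind == _ESC_NONE:
        raise ValueError(
            "unbiased_mfpt requires a RadialEscape or HalfPlaneEscape predicate"
        )
    wc, wd, ww = pot.arrays()
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    fpts = np.empty(n_runs)
    for i in range(n_runs):
        step = _run_fpt(
            wc, wd, ww,
            pot.confinement_k, pot.confinement_center[0], pot.confinement_center[1],
            float(cfg.start[0]), float(cfg.start[1]),
            cfg.dt, cfg.kBT, cfg.friction, cfg.n_steps, int(seeds[i]),
            esc_kind, ea0, ea1, ec,
        )
        if step == -2:
            raise RuntimeError(
                f"position became non-finite; the time step dt={cfg.dt} is too large"
            )
        if step == -1:
            raise RuntimeError(
                f"run {i} did not escape within n_steps={cfg.n_steps}; increase "
                "n_steps or lower the barrier"
            )
        fpts[i] = step * cfg.dt
    mean = float(np.mean(fpts))
    stderr = float(np.std(fpts, ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else 0.0
    return FirstPassageResult(mean=mean, stderr=stderr, times=fpts)
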