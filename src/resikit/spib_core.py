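"""State Predictive Information Bottleneck: a 2-D linear reaction coordinate.

SPIB learns a low-dimensional bottleneck variable chi that is maximally
predictive of the system's metastable state a lag time Dt into the future
while carrying minimal information about the instantaneous configuration.
The encoder here is *linear* (an affine map of the z-scored input order
parameters with a learned shared diagonal variance), so the converged
bottleneck doubles as an explicit collective variable that metadynamics can
bias.  The decoder — a single tanh hidden layer with softmax output —
predicts the state label at t + Dt; the prior over the bottleneck is a
mixture of Gaussians anchored at learned pseudo-inputs (VampPrior style),
which is what lets the number of metastable states emerge during training:
frames are periodically relabelled by the decoder's most probable state at
the posterior mean, empty states are dropped, and training continues until
the labels reach a fixed point.

Increasing Dt coarsens the result: states that interconvert faster than Dt
become indistinguishable to the predictor and merge, until at very large Dt
the whole configuration space is a single metastable state.

The network is small and its architecture fixed, so forward and backward
passes are written directly in numpy (gradients are verified against finite
differences in the test suite) and optimized with Adam.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .featurize import FeatureTrajectory

__all__ = [
    "SPIBConfig",
    "MixturePrior",
    "StateLabels",
    "TrainedSPIB",
    "RCSpec",
    "init_labels",
    "make_pairs",
    "spib_loss",
    "refine_labels",
    "train_spib",
    "export_rc",
    "project",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SPIBConfig:
    """Training settings.

    ``lag`` is the prediction delay Dt in frames; ``beta_ib`` weighs the
    information-bottleneck (compression) term against state prediction;
    ``K0`` is the initial number of candidate states (k-means init), which
    can only shrink during refinement.
    """

    lag: int
    latent_dim: int = 2
    beta_ib: float = 1e-2
    K0: int = 6
    n_pseudo: Optional[int] = None  # defaults to K0
    hidden_dim: int = 64
    epochs_per_refinement: int = 8
    max_refinements: int = 20
    refinement_tolerance: float = 0.005
    learning_rate: float = 3e-3
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1 frame")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.K0 < 2:
            raise ValueError("K0 must be >= 2")
        if self.beta_ib < 0:
            raise ValueError("beta_ib must be >= 0")
        if not (0.0 < self.refinement_tolerance < 1.0):
            raise ValueError("refinement_tolerance must be in (0, 1)")

    @property
    def n_pseudo_eff(self) -> int:
        return self.K0 if self.n_pseudo is None else self.n_pseudo


@dataclass
class MixturePrior:
    """Mixture-of-Gaussians prior anchored at encoder images of pseudo-inputs."""

    pseudo_inputs: np.ndarray  # (n_pseudo, n_ops), normalized feature space
    logits: np.ndarray         # (n_pseudo,)

    @property
    def weights(self) -> np.ndarray:
        w = np.exp(self.logits - logsumexp(self.logits))
        return w / w.sum()


@dataclass
class StateLabels:
    """Per-trajectory metastable-state labels, compacted to [0, K)."""

    labels: list[np.ndarray]
    K: int

    def __post_init__(self) -> None:
        pooled = np.concatenate(self.labels) if self.labels else np.empty(0, int)
        if pooled.size and (pooled.min() < 0 or pooled.max() >= self.K):
            raise ValueError("labels must lie in [0, K)")

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.labels)


def _compact(raw_per_traj: list[np.ndarray]) -> tuple[StateLabels, np.ndarray]:
    """Compact raw (K0-space) labels to [0, K); returns labels + the kept raw ids."""
    pooled = np.concatenate(raw_per_traj)
    kept = np.unique(pooled)
    out = [np.searchsorted(kept, arr).astype(int) for arr in raw_per_traj]
    return StateLabels(labels=out, K=len(kept)), kept


@dataclass
class RCSpec:
    """Frozen, deterministic form of the learned 2-D linear reaction coordinate.

    ``apply(X)`` computes ``coefficients @ ((x - mean) / scale) + offsets``
    row-wise: exactly the encoder posterior mean, with the z-score
    normalization of the training pool baked in.
    """

    labels: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    coefficients: np.ndarray  # (latent_dim, n_ops)
    offsets: np.ndarray       # (latent_dim,)

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - self.mean) / self.scale) @ self.coefficients.T + self.offsets

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.labels),
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist(),
                "coefficients": self.coefficients.tolist(),
                "offsets": self.offsets.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RCSpec":
        d = json.loads(text)
        return cls(
            labels=tuple(d["labels"]),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            offsets=np.asarray(d["offsets"], dtype=float),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RCSpec":
        return cls.from_json(Path(path).read_text())


@dataclass
class TrainedSPIB:
    """Converged SPIB model: encoder, decoder, prior, labels and history."""

    params: dict
    mean: np.ndarray
    scale: np.ndarray
    op_labels: tuple[str, ...]
    config: SPIBConfig
    active_states: np.ndarray        # raw state ids still populated
    labels: StateLabels
    raw_labels: list[np.ndarray]     # labels in original K0 index space
    history: dict

    @property
    def K(self) -> int:
        return self.labels.K

    @property
    def prior(self) -> MixturePrior:
        return MixturePrior(
            pseudo_inputs=self.params["U"].copy(), logits=self.params["omega"].copy()
        )

    def normalize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.scale

    def save(self, path: Union[str, Path]) -> None:
        """Single-archive JSON checkpoint (RC + decoder + prior + labels)."""
        payload = {
            "params": {k: v.tolist() for k, v in self.params.items()},
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "op_labels": list(self.op_labels),
            "config": {
                k: (None if v is None else v)
                for k, v in self.config.__dict__.items()
            },
            "active_states": self.active_states.tolist(),
            "labels": [arr.tolist() for arr in self.labels.labels],
            "K": self.labels.K,
            "raw_labels": [arr.tolist() for arr in self.raw_labels],
            "history": self.history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedSPIB":
        d = json.loads(Path(path).read_text())
        return cls(
            params={k: np.asarray(v, dtype=float) for k, v in d["params"].items()},
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            op_labels=tuple(d["op_labels"]),
            config=SPIBConfig(**d["config"]),
            active_states=np.asarray(d["active_states"], dtype=int),
            labels=StateLabels(
                labels=[np.asarray(a, dtype=int) for a in d["labels"]], K=d["K"]
            ),
            raw_labels=[np.asarray(a, dtype=int) for a in d["raw_labels"]],
            history=d["history"],
        )


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _as_matrices(features: Sequence) -> tuple[list[np.ndarray], tuple[str, ...]]:
    mats: list[np.ndarray] = []
    labels: Optional[tuple[str, ...]] = None
    for f in features:
        if isinstance(f, FeatureTrajectory):
            mats.append(f.values)
            lab = tuple(f.labels)
        else:
            arr = np.atleast_2d(np.asarray(f, dtype=float))
            mats.append(arr)
            lab = tuple(f"op{j}" for j in range(arr.shape[1]))
        if labels is None:
            labels = lab
        elif labels != lab:
            raise ValueError("all trajectories must share the same OP labels")
    if not mats:
        raise ValueError("no trajectories supplied")
    return mats, labels


def init_labels(features: Sequence, K0: int, seed: int = 0) -> StateLabels:
    """Initial state labels: k-means with ``K0`` centers on pooled z-scored rows."""
    mats, _ = _as_matrices(features)
    pooled = np.vstack(mats)
    if K0 > pooled.shape[0]:
        raise ValueError(f"K0={K0} exceeds the {pooled.shape[0]} available frames")
    if K0 == 1:
        return StateLabels(labels=[np.zeros(len(m), dtype=int) for m in mats], K=1)
    mean = pooled.mean(axis=0)
    scale = np.maximum(pooled.std(axis=0), 1e-8)
    km = KMeans(n_clusters=K0, n_init=4, random_state=seed)
    pooled_lab = km.fit_predict((pooled - mean) / scale)
    out, start = [], 0
    for m in mats:
        out.append(pooled_lab[start : start + len(m)].astype(int))
        start += len(m)
    return StateLabels(labels=out, K=K0)


def make_pairs(
    features: Sequence,
    labels: Sequence[np.ndarray],
    lag: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-lagged training pairs ``(X_t, y_{t+lag})``, never across trajectories.

    Each trajectory of length ``n`` contributes ``n - lag`` pairs; trajectories
    shorter than ``lag + 1`` are skipped with a warning.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    mats, _ = _as_matrices(features)
    if len(mats) != len(labels):
        raise ValueError("need one label array per trajectory")
    xs, ys = [], []
    for i, (m, lab) in enumerate(zip(mats, labels)):
        lab = np.asarray(lab)
        if len(lab) != len(m):
            raise ValueError(f"trajectory {i}: label length mismatch")
        if len(m) <= lag:
            warnings.warn(
                f"trajectory {i} has {len(m)} frames <= lag {lag}: skipped",
                stacklevel=2,
            )
            continue
        xs.append(m[:-lag])
        ys.append(lab[lag:])
    if not xs:
        raise ValueError("no trajectory is longer than the lag: zero training pairs")
    return np.vstack(xs), np.concatenate(ys)


# ---------------------------------------------------------------------------
# network forward / backward
# ---------------------------------------------------------------------------

def _init_params(cfg: SPIBConfig, n_ops: int, pseudo_init: np.ndarray,
                 rng: np.random.Generator) -> dict:
    L, H, K0 = cfg.latent_dim, cfg.hidden_dim, cfg.K0
    return {
        "W": 0.1 * rng.standard_normal((L, n_ops)),
        "b": np.zeros(L),
        "logvar": np.full(L, math.log(0.1)),
        "U": pseudo_init.copy(),
        "omega": np.zeros(pseudo_init.shape[0]),
        "W1": rng.standard_normal((H, L)) / math.sqrt(L),
        "b1": np.zeros(H),
        "W2": rng.standard_normal((K0, H)) / math.sqrt(H),
        "b2": np.zeros(K0),
    }


def _forward(params: dict, X: np.ndarray, y: np.ndarray, eps: np.ndarray,
             beta_ib: float, want_grads: bool = True):
    """Loss (and gradients) of the SPIB objective on one batch.

    loss = mean_b [ -log q(y | z) + beta_ib * (log p(z|x) - log r(z)) ]
    with z = mu(x) + sigma * eps (reparameterization) and
    r(z) = sum_k w_k N(z; mu(u_k), sigma^2).
    """
    W, b, logvar = params["W"], params["b"], params["logvar"]
    U, omega = params["U"], params["omega"]
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    B = X.shape[0]
    L = W.shape[0]

    sigma = np.exp(0.5 * logvar)
    mu = X @ W.T + b                          # (B, L)
    z = mu + sigma * eps                      # (B, L)

    # decoder
    a1 = z @ W1.T + b1
    h = np.tanh(a1)
    logits = h @ W2.T + b2                    # (B, K0)
    logits_max = logits.max(axis=1, keepdims=True)
    lse = logits_max[:, 0] + np.log(np.sum(np.exp(logits - logits_max), axis=1))
    ce = lse - logits[np.arange(B), y]        # (B,)

    # posterior log-density at the sample
    log_q = -0.5 * np.sum(_LOG2PI + logvar + eps**2, axis=-1) * np.ones(B)

    # mixture prior at the sample
    mu_k = U @ W.T + b                        # (P, L)
    log_w = omega - logsumexp(omega)
    diff = z[:, None, :] - mu_k[None, :, :]   # (B, P, L)
    var = sigma**2
    log_nk = -0.5 * np.sum(_LOG2PI + logvar + diff**2 / var, axis=2)  # (B, P)
    a_k = log_w[None, :] + log_nk
    a_max = a_k.max(axis=1, keepdims=True)
    log_r = a_max[:, 0] + np.log(np.sum(np.exp(a_k - a_max), axis=1))

    loss = float(np.mean(ce + beta_ib * (log_q - log_r)))
    if not np.isfinite(loss):
        raise FloatingPointError(
            "SPIB loss became non-finite: lower the learning rate or check the "
            "input normalization"
        )
    if not want_grads:
        return loss, None

    grads = {k: np.zeros_like(v) for k, v in params.items()}

    # --- cross-entropy branch ---
    p = np.exp(logits - logits_max)
    p /= p.sum(axis=1, keepdims=True)
    dlogits = p.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads["W2"] += dlogits.T @ h
    grads["b2"] += dlogits.sum(axis=0)
    dh = dlogits @ W2
    da1 = dh * (1.0 - h**2)
    grads["W1"] += da1.T @ z
    grads["b1"] += da1.sum(axis=0)
    dz = da1 @ W1                             # (B, L)

    # --- log q branch: depends only on logvar (eps is fixed) ---
    grads["logvar"] += -0.5 * beta_ib * np.ones(L)

    # --- -log r branch ---
    gamma = np.exp(a_k - a_max)
    gamma /= gamma.sum(axis=1, keepdims=True)  # (B, P) responsibilities
    coeff = beta_ib / B
    # dz from -log r: +beta * sum_k gamma_k (z - mu_k) / var
    dz += coeff * np.einsum("bp,bpl->bl", gamma, diff) / var
    # d mu_k: -beta * gamma_k (z - mu_k) / var, summed over batch
    dmu_k = -coeff * np.einsum("bp,bpl->pl", gamma, diff / var)
    # d logvar via log N_k: -beta * sum gamma * (-0.5) (1 - diff^2/var)
    dlv_nk = -0.5 * (1.0 - diff**2 / var)      # (B, P, L)
    grads["logvar"] += -coeff * np.einsum("bp,bpl->l", gamma, dlv_nk)
    # d omega: -beta * (gamma_j - w_j)
    w_prior = np.exp(log_w)
    grads["omega"] += -coeff * (gamma.sum(axis=0) - B * w_prior)

    # --- chain rule into encoder parameters ---
    grads["W"] += dz.T @ X + dmu_k.T @ U
    grads["b"] += dz.sum(axis=0) + dmu_k.sum(axis=0)
    # z depends on logvar through sigma: dz/dlogvar_d = 0.5 sigma_d eps_d
    grads["logvar"] += np.sum(dz * (0.5 * sigma * eps), axis=0)
    # mu_k depends on logvar only through nothing (same W,b); U gradient:
    grads["U"] += dmu_k @ W

    return loss, grads


def spib_loss(
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    eps: np.ndarray,
    beta_ib: float,
) -> float:
    """SPIB objective on a batch of normalized inputs with fixed noise ``eps``.

    With ``beta_ib = 0`` this reduces to the prediction cross-entropy alone.
    """
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    loss, _ = _forward(params, X, np.asarray(y, dtype=int), eps, beta_ib,
                       want_grads=False)
    return loss


def spib_loss_grads(params, X, y, eps, beta_ib):
    """Loss and analytic parameter gradients (verified against finite differences)."""
    return _forward(params, X, np.asarray(y, dtype=int), eps, beta_ib, want_grads=True)


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# label refinement and training
# ---------------------------------------------------------------------------

def _decode_raw(params: dict, Xn: np.ndarray, active: np.ndarray) -> np.ndarray:
    """Most probable state at the posterior mean, restricted to active states.

    Ties break to the lowest state index (argmax on the masked logits).
    """
    mu = Xn @ params["W"].T + params["b"]
    h = np.tanh(mu @ params["W1"].T + params["b1"])
    logits = h @ params["W2"].T + params["b2"]
    masked = np.full_like(logits, -np.inf)
    masked[:, active] = logits[:, active]
    return np.argmax(masked, axis=1)


def refine_labels(model: TrainedSPIB, features: Sequence) -> StateLabels:
    """Relabel every frame by the decoder's most probable state at the posterior mean.

    States left with no members are dropped and the indices compacted, so the
    state count can only stay or shrink from refinement to refinement.
    """
    mats, _ = _as_matrices(features)
    raw = [
        _decode_raw(model.params, model.normalize(m), model.active_states)
        for m in mats
    ]
    labels, _ = _compact(raw)
    return labels


def train_spib(features: Sequence, cfg: SPIBConfig) -> TrainedSPIB:
    """Train SPIB with alternating gradient descent and on-the-fly relabelling.

    The loop: fit the encoder/decoder/prior on time-lagged pairs for a few
    epochs, relabel all frames by the decoder at the posterior mean, drop
    empty states, rebuild the pairs, and repeat until fewer than
    ``refinement_tolerance`` of the labels change (or ``max_refinements``).
    Biased training data enter unweighted: reweighting high-energy
    intermediates by their Boltzmann factors would drown them in noise.
    """
    mats, op_labels = _as_matrices(features)
    pooled = np.vstack(mats)
    mean = pooled.mean(axis=0)
    scale = np.maximum(pooled.std(axis=0), 1e-8)
    mats_n = [(m - mean) / scale for m in mats]

    init = init_labels(features, cfg.K0, seed=cfg.seed)
    raw_labels = [arr.copy() for arr in init.labels]  # K0-space == compact at init

    rng = np.random.default_rng(cfg.seed)
    km = KMeans(n_clusters=cfg.n_pseudo_eff, n_init=4, random_state=cfg.seed)
    km.fit(np.vstack(mats_n))
    params = _init_params(cfg, pooled.shape[1], km.cluster_centers_, rng)
    opt = _Adam(params, lr=cfg.learning_rate)
    active = np.arange(cfg.K0)

    history: dict = {"loss": [], "states_per_refinement": [], "label_change": []}

    for refinement in range(cfg.max_refinements):
        X, y = make_pairs(mats_n, raw_labels, cfg.lag)
        n = X.shape[0]
        for _ in range(cfg.epochs_per_refinement):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                eps = rng.standard_normal((len(idx), cfg.latent_dim))
                loss, grads = _forward(params, X[idx], y[idx], eps, cfg.beta_ib)
                opt.step(params, grads)
                epoch_loss += loss * len(idx)
            history["loss"].append(epoch_loss / n)

        new_raw = [_decode_raw(params, m, active) for m in mats_n]
        changed = sum(
            int(np.sum(a != b)) for a, b in zip(new_raw, raw_labels)
        ) / sum(len(a) for a in raw_labels)
        raw_labels = new_raw
        active = np.unique(np.concatenate(raw_labels))
        history["states_per_refinement"].append(int(len(active)))
        history["label_change"].append(float(changed))
        if changed < cfg.refinement_tolerance:
            break

    labels, kept = _compact(raw_labels)
    return TrainedSPIB(
        params=params,
        mean=mean,
        scale=scale,
        op_labels=op_labels,
        config=cfg,
        active_states=kept,
        labels=labels,
        raw_labels=raw_labels,
        history=history,
    )


# ---------------------------------------------------------------------------
# projection and export
# ---------------------------------------------------------------------------

def project(model: TrainedSPIB, X: np.ndarray) -> np.ndarray:
    """Encoder posterior mean for raw (un-normalized) feature rows."""
    return model.normalize(X) @ model.params["W"].T + model.params["b"]


def export_rc(model: TrainedSPIB) -> RCSpec:
    """Freeze the learned linear reaction coordinate into a deterministic spec.

    The spec composes the training-pool z-scoring with the encoder's affine
    map, so ``RCSpec.apply`` reproduces :func:`project` exactly.
    """
    return RCSpec(
        labels=model.op_labels,
        mean=model.mean.copy(),
        scale=model.scale.copy(),
        coefficients=model.params["W"].copy(),
        offsets=model.params["b"].copy(),
    )
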