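"""Order parameters for SPIB training: ligand-COM/C-alpha distances and H-bonds.

The input features for reaction-coordinate learning are deliberately simple
distance metrics: the pairwise distance between the ligand's center of mass
and the C-alpha atom of every third protein residue (flexible terminal
regions excluded), optionally augmented with hydrogen-bond donor--acceptor
distances.  Keeping the feature count below ~100 keeps the learned linear
coordinate stable when it is subsequently biased; a warning is raised past
that point.

Distances are in nm (PLUMED convention).  The module operates on plain
coordinate records, so no trajectory files are needed for testing; real
DCD/XTC readers can adapt their frames into :class:`StructureModel` records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "OPDefinition",
    "FeatureTrajectory",
    "ligand_com",
    "build_distance_ops",
    "evaluate_ops",
    "filter_dissociated",
]

MAX_STABLE_OPS = 100  # above this, metadynamics on the learned RC destabilizes


@dataclass(frozen=True)
class Atom:
    name: str
    coord: tuple[float, float, float]
    mass: float = 1.0


@dataclass(frozen=True)
class Residue:
    index: int
    name: str
    ca: tuple[float, float, float]
    terminal: bool = False


@dataclass
class StructureModel:
    """One frame of a protein--ligand system: residue C-alphas plus ligand atoms.

    ``protein_atoms`` optionally carries named non-C-alpha atoms (keyed
    ``(residue_index, atom_name)``) so hydrogen-bond distances can be defined.
    """

    residues: list[Residue]
    ligand: list[Atom]
    protein_atoms: dict[tuple[int, str], Atom] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError("residue indices must be unique and ordered")
        if not self.ligand:
            raise ValueError("ligand must have at least one atom")
        if all(a.mass <= 0 for a in self.ligand):
            raise ValueError("ligand needs at least one atom with positive mass")

    def residue_by_index(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")


@dataclass(frozen=True)
class OPDefinition:
    """One order parameter.

    kinds:
      - ``com_calpha_distance``: |ligand COM - C-alpha of residue_index|
      - ``hbond_distance``: |ligand atom - protein atom| for a donor/acceptor pair
      - ``custom_cv``: values supplied externally (toy systems, precomputed CVs)
    """

    kind: str
    label: str
    residue_index: Optional[int] = None
    protein_atom: Optional[tuple[int, str]] = None
    ligand_atom: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("com_calpha_distance", "hbond_distance", "custom_cv"):
            raise ValueError(f"unknown OP kind {self.kind!r}")
        if self.kind == "com_calpha_distance" and self.residue_index is None:
            raise ValueError("com_calpha_distance needs residue_index")
        if self.kind == "hbond_distance" and (
            self.protein_atom is None or self.ligand_atom is None
        ):
            raise ValueError("hbond_distance needs protein_atom and ligand_atom")


@dataclass
class FeatureTrajectory:
    """Time-ordered matrix of OP values for one trajectory (SPIB substrate)."""

    times: np.ndarray
    values: np.ndarray  # (n_frames, n_ops), nm
    labels: tuple[str, ...]
    dissociated: bool = False
    dissociation_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_frames, n_ops)")
        if self.values.shape[0] != len(self.times):
            raise ValueError("times and values disagree on frame count")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must match the number of OP columns")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("OP labels must be unique")
        if self.dissociated and (
            self.dissociation_frame is None
            or not (0 <= self.dissociation_frame < self.n_frames)
        ):
            raise ValueError("dissociated trajectories need a valid dissociation_frame")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_ops(self) -> int:
        return self.values.shape[1]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.labels.index(label) if isinstance(self.labels, list) else tuple(self.labels).index(label)
        except ValueError as exc:
            raise KeyError(f"no OP labelled {label!r}") from exc
        return self.values[:, j]


def ligand_com(ligand: Sequence[Atom]) -> np.ndarray:
    """Mass-weighted center of mass of the ligand atoms."""
    if not ligand:
        raise ValueError("empty ligand")
    masses = np.array([a.mass for a in ligand], dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total ligand mass must be > 0")
    coords = np.array([a.coord for a in ligand], dtype=float)
    return (masses[:, None] * coords).sum(axis=0) / total


def build_distance_ops(
    model: StructureModel,
    stride: int = 3,
    exclude_terminal: bool = True,
) -> list[OPDefinition]:
    """Ligand-COM to C-alpha distance OPs for every ``stride``-th residue.

    Residues flagged terminal (flexible tails) are skipped when
    ``exclude_terminal`` is set.  Emits a warning when the OP count reaches
    :data:`MAX_STABLE_OPS`, past which the downstream biasing protocol is
    empirically less stable.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if len(model.residues) < stride:
        raise ValueError("model has fewer residues than the stride")
    ops: list[OPDefinition] = []
    for r in model.residues:
        if exclude_terminal and r.terminal:
            continue
        if r.index % stride != 0:
            continue
        ops.append(
            OPDefinition(
                kind="com_calpha_distance",
                label=f"d_com_ca{r.index}",
                residue_index=r.index,
            )
        )
    if not ops:
        raise ValueError(
            "no residues selected: relax the stride or the terminal exclusion"
        )
    if len(ops) >= MAX_STABLE_OPS:
        warnings.warn(
            f"{len(ops)} OPs selected; the biasing protocol is most stable with "
            f"fewer than {MAX_STABLE_OPS} OPs — consider a larger stride",
            stacklevel=2,
        )
    return ops


def _evaluate_one(frame: StructureModel, op: OPDefinition) -> float:
    if op.kind == "com_calpha_distance":
        try:
            res = frame.residue_by_index(op.residue_index)
        except KeyError as exc:
            raise KeyError(f"OP {op.label!r}: {exc}") from exc
        return float(np.linalg.norm(ligand_com(frame.ligand) - np.asarray(res.ca)))
    if op.kind == "hbond_distance":
        try:
            pa = frame.protein_atoms[op.protein_atom]
        except KeyError as exc:
            raise KeyError(
                f"OP {op.label!r}: protein atom {op.protein_atom} not in frame"
            ) from exc
        la = next((a for a in frame.ligand if a.name == op.ligand_atom), None)
        if la is None:
            raise KeyError(f"OP {op.label!r}: ligand atom {op.ligand_atom!r} not in frame")
        return float(np.linalg.norm(np.asarray(pa.coord) - np.asarray(la.coord)))
    raise KeyError(f"OP {op.label!r}: kind {op.kind!r} cannot be evaluated from frames")


def evaluate_ops(
    frames: Sequence[StructureModel],
    ops: Sequence[OPDefinition],
    times: Optional[Sequence[float]] = None,
) -> FeatureTrajectory:
    """Evaluate every OP on every frame; columns follow the order of ``ops``."""
    if not frames:
        raise ValueError("no frames supplied")
    if times is None:
        times = np.arange(len(frames), dtype=float)
    values = np.empty((len(frames), len(ops)))
    for i, frame in enumerate(frames):
        for j, op in enumerate(ops):
            values[i, j] = _evaluate_one(frame, op)
    return FeatureTrajectory(
        times=np.asarray(times, dtype=float),
        values=values,
        labels=tuple(op.label for op in ops),
    )


def filter_dissociated(
    trajs: Sequence[FeatureTrajectory],
    criterion_label: str,
    threshold: float,
) -> tuple[list[FeatureTrajectory], list[FeatureTrajectory]]:
    """Split trajectories into dissociated and trapped sets.

    A trajectory is dissociated when the criterion OP first exceeds
    ``threshold``; its ``dissociation_frame`` is set to that first-crossing
    frame.  Trapped trajectories are excluded from reaction-coordinate
    training.  Raises when nothing dissociates, which in real use means the
    trial runs were too short or the trial variables too poor.
    """
    kept: list[FeatureTrajectory] = []
    excluded: list[FeatureTrajectory] = []
    for traj in trajs:
        col = traj.column(criterion_label)
        above = np.nonzero(col > threshold)[0]
        if len(above):
            traj.dissociated = True
            traj.dissociation_frame = int(above[0])
            kept.append(traj)
        else:
            traj.dissociated = False
            traj.dissociation_frame = None
            excluded.append(traj)
    if not kept:
        raise ValueError(
            "no trajectory dissociated under the criterion "
            f"{criterion_label!r} > {threshold}; run longer trials or change "
            "the trial variables"
        )
    return kept, excluded
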