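"""PLUMED-dialect text I/O: COLVAR/HILLS tables and input-script export.

COLVAR and HILLS files are whitespace-delimited tables whose column names come
from a leading ``#! FIELDS ...`` header.  Restarted runs re-emit the header
mid-file and may overlap in time; the reader concatenates such blocks and
drops overlap rows keep-first.  The writer renders full-precision values so
write -> read round trips are value-identical.

``write_plumed`` exports a learned two-dimensional linear reaction coordinate
(an :class:`~resikit.spib_core.RCSpec`) plus a metadynamics schedule as a
PLUMED input script: ligand COM, one DISTANCE per order parameter, two
COMBINE lines carrying the (normalization-folded) linear coefficients, a
METAD directive and a PRINT of the bias.  ``check_script`` and
``evaluate_script_rc`` provide an internal consistency checker so exported
scripts can be validated without running PLUMED.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ColvarTable",
    "HillsTable",
    "PlumedScript",
    "read_colvar",
    "read_hills",
    "write_colvar",
    "write_hills",
    "trajectory_to_colvar",
    "hills_to_text",
    "reconstruct_bias",
    "write_plumed",
    "check_script",
    "evaluate_script_rc",
]


@dataclass
class ColvarTable:
    """Parsed COLVAR file: named numeric columns with a strictly increasing time."""

    names: tuple[str, ...]
    data: np.ndarray  # (n_rows, n_cols)
    source: str = "<text>"

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(self.names):
            raise ValueError("header name count must equal column count")
        if "time" not in self.names:
            raise ValueError("COLVAR table must contain a 'time' column")
        t = self.column("time")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("time column must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError as exc:
            raise KeyError(f"no column {name!r} in {self.source}") from exc
        return self.data[:, j]

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


@dataclass
class HillsTable:
    """Parsed HILLS file: one deposited Gaussian per row."""

    cv_names: tuple[str, ...]
    times: np.ndarray
    centers: np.ndarray  # (n_hills, n_cv)
    sigmas: np.ndarray   # (n_hills, n_cv)
    heights: np.ndarray
    bias_factor: Optional[float] = None
    source: str = "<text>"

    def __post_init__(self) -> None:
        if len(self.times) and np.any(np.diff(self.times) < 0):
            raise ValueError("hill times must be non-decreasing")
        if np.any(self.heights <= 0):
            raise ValueError("hill heights must be > 0")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PlumedScript:
    """Rendered PLUMED input with a provenance checksum of the exported RC."""

    text: str
    rc_checksum: str

    def __str__(self) -> str:
        return self.text


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _iter_source(source: Union[str, Path]) -> tuple[list[str], str]:
    if isinstance(source, Path):
        return source.read_text().splitlines(), str(source)
    if isinstance(source, str) and "\n" in source:
        return source.splitlines(), "<text>"
    return Path(source).read_text().splitlines(), str(source)


def _parse_table(source: Union[str, Path]) -> tuple[tuple[str, ...], np.ndarray, str]:
    lines, origin = _iter_source(source)
    names: Optional[tuple[str, ...]] = None
    rows: list[list[float]] = []
    last_time_col: Optional[int] = None
    block_start = 0  # first row index of the current (restart) block
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            tokens = line.split()
            if len(tokens) >= 2 and tokens[1] == "FIELDS":
                new_names = tuple(tokens[2:])
                if names is None:
                    names = new_names
                elif new_names != names:
                    raise ValueError(
                        f"{origin}:{lineno}: restart header fields differ from the first block"
                    )
                else:
                    block_start = len(rows)  # restart: overlap rows handled below
                if "time" in names:
                    last_time_col = names.index("time")
            continue  # other '#! SET ...' metadata lines are ignored
        if names is None:
            raise ValueError(f"{origin}:{lineno}: data before any '#! FIELDS' header")
        parts = line.split()
        if len(parts) != len(names):
            raise ValueError(
                f"{origin}:{lineno}: ragged row has {len(parts)} values, "
                f"expected {len(names)}"
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{origin}:{lineno}: non-numeric value") from exc
        # keep-first on restart overlap: drop rows that do not advance time
        if (
            last_time_col is not None
            and block_start > 0
            and len(rows) >= block_start
            and rows
            and vals[last_time_col] <= rows[block_start - 1][last_time_col]
        ):
            continue
        rows.append(vals)
    if names is None:
        raise ValueError(f"{origin}: missing '#! FIELDS' header")
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, len(names)))
    return names, data, origin


def read_colvar(source: Union[str, Path]) -> ColvarTable:
    """Read a COLVAR file (path, or the text itself when it contains newlines)."""
    names, data, origin = _parse_table(source)
    return ColvarTable(names=names, data=data, source=origin)


def read_hills(source: Union[str, Path]) -> HillsTable:
    """Read a HILLS file into per-hill records.

    Expects the PLUMED layout ``time <cv...> <sigma_cv...> height [biasf]``.
    An empty body (header only) is a valid, empty table.
    """
    names, data, origin = _parse_table(source)
    if names[0] != "time":
        raise ValueError(f"{origin}: first HILLS field must be 'time'")
    rest = list(names[1:])
    has_biasf = rest and rest[-1] in ("biasf", "bias_factor")
    if has_biasf:
        rest = rest[:-1]
    if not rest or rest[-1] != "height":
        raise ValueError(f"{origin}: HILLS fields must contain 'height'")
    rest = rest[:-1]
    if len(rest) % 2 != 0:
        raise ValueError(f"{origin}: unpaired CV/sigma columns in HILLS header")
    n_cv = len(rest) // 2
    cv_names = tuple(rest[:n_cv])
    for k in range(n_cv):
        if rest[n_cv + k] != f"sigma_{cv_names[k]}":
            raise ValueError(
                f"{origin}: expected sigma_{cv_names[k]}, got {rest[n_cv + k]!r}"
            )
    times = data[:, 0] if data.size else np.empty(0)
    centers = data[:, 1 : 1 + n_cv] if data.size else np.empty((0, n_cv))
    sigmas = data[:, 1 + n_cv : 1 + 2 * n_cv] if data.size else np.empty((0, n_cv))
    heights = data[:, 1 + 2 * n_cv] if data.size else np.empty(0)
    biasf = float(data[0, -1]) if (has_biasf and data.size) else None
    return HillsTable(
        cv_names=cv_names, times=times, centers=centers, sigmas=sigmas,
        heights=heights, bias_factor=biasf, source=origin,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_colvar(names: Sequence[str], data: np.ndarray,
                 path: Optional[Union[str, Path]] = None) -> str:
    """Render (and optionally write) a COLVAR table at full precision."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != len(names):
        raise ValueError("column count must match the number of names")
    lines = ["#! FIELDS " + " ".join(names)]
    for row in data:
        lines.append(" ".join(_fmt(v) for v in row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def trajectory_to_colvar(traj, labels: Optional[Sequence[str]] = None,
                         path: Optional[Union[str, Path]] = None) -> str:
    """COLVAR text for a toy trajectory: ``time <cv...> metad.bias``."""
    cvs = np.atleast_2d(traj.cv_values)
    n_cv = cvs.shape[1]
    if labels is None:
        labels = [f"cv{k + 1}" for k in range(n_cv)]
    names = ["time", *labels, "metad.bias"]
    data = np.column_stack([traj.times, cvs, traj.bias_values])
    return write_colvar(names, data, path=path)


def hills_to_text(hills, cv_names: Optional[Sequence[str]] = None,
                  bias_factor: Optional[float] = None,
                  path: Optional[Union[str, Path]] = None) -> str:
    """HILLS text for a :class:`~resikit.toy_engine.HillList` or :class:`HillsTable`."""
    if isinstance(hills, HillsTable):
        cv_names = cv_names or hills.cv_names
        times, centers, sigmas, heights = hills.times, hills.centers, hills.sigmas, hills.heights
        bias_factor = bias_factor if bias_factor is not None else hills.bias_factor
    else:
        times, centers, sigmas, heights = hills.times, hills.centers, hills.sigmas, hills.heights
    centers = np.atleast_2d(centers)
    n_cv = centers.shape[1] if len(times) else (len(cv_names) if cv_names else 1)
    if cv_names is None:
        cv_names = [f"cv{k + 1}" for k in range(n_cv)]
    names = ["time", *cv_names, *[f"sigma_{c}" for c in cv_names], "height"]
    if bias_factor is not None:
        names.append("biasf")
    sigmas = np.atleast_2d(sigmas)
    lines = ["#! FIELDS " + " ".join(names)]
    for i in range(len(times)):
        row = [times[i], *centers[i], *sigmas[i], heights[i]]
        if bias_factor is not None:
            row.append(bias_factor)
        lines.append(" ".join(_fmt(v) for v in row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# bias reconstruction
# ---------------------------------------------------------------------------

def reconstruct_bias(
    hills: HillsTable,
    times: np.ndarray,
    cv_values: np.ndarray,
    convention: str = "deposited",
) -> np.ndarray:
    """Rebuild ``V(s_t, t)`` along a CV path from the deposited hills.

    Only hills deposited at or before each frame's time contribute.  The
    ``convention`` flag covers the two well-tempered HILLS height conventions
    found in the wild: ``"deposited"`` sums the stored heights directly (the
    convention this package writes), ``"rescaled"`` multiplies stored heights
    by ``gamma / (gamma - 1)`` (tables whose stored heights are the
    free-energy increments).
    """
    times = np.asarray(times, dtype=float)
    cv_values = np.atleast_2d(np.asarray(cv_values, dtype=float))
    if cv_values.shape[0] != len(times):
        raise ValueError("times and cv_values disagree on frame count")
    if len(hills) == 0:
        return np.zeros(len(times))
    if cv_values.shape[1] != hills.centers.shape[1]:
        raise ValueError(
            f"CV dimensionality mismatch: path has {cv_values.shape[1]}, "
            f"hills have {hills.centers.shape[1]}"
        )
    heights = hills.heights.copy()
    if convention == "rescaled":
        if hills.bias_factor is None or not (hills.bias_factor > 1):
            raise ValueError("'rescaled' convention needs a finite bias factor > 1")
        heights = heights * hills.bias_factor / (hills.bias_factor - 1.0)
    elif convention != "deposited":
        raise ValueError(f"unknown convention {convention!r}")

    # number of hills active at each frame (hill time <= frame time)
    n_active = np.searchsorted(hills.times, times, side="right")
    out = np.zeros(len(times))
    chunk = max(1, int(2_000_000 // max(len(hills), 1)))
    for start in range(0, len(times), chunk):
        stop = min(start + chunk, len(times))
        z2 = np.sum(
            ((cv_values[start:stop, None, :] - hills.centers[None, :, :])
             / hills.sigmas[None, :, :]) ** 2,
            axis=2,
        )
        g = heights[None, :] * np.exp(-0.5 * z2)  # (frames, hills)
        cums = np.cumsum(g, axis=1)
        for i in range(start, stop):
            k = n_active[i]
            out[i] = cums[i - start, k - 1] if k > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# PLUMED script export
# ---------------------------------------------------------------------------

def _rc_checksum(rc) -> str:
    payload = json.dumps(
        {
            "labels": list(rc.labels),
            "mean": np.asarray(rc.mean).tolist(),
            "scale": np.asarray(rc.scale).tolist(),
            "coefficients": np.asarray(rc.coefficients).tolist(),
            "offsets": np.asarray(rc.offsets).tolist(),
        },
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _fmt12(x: float) -> str:
    return f"{x:.12g}"


def write_plumed(
    rc,
    ops: Sequence,
    metad,
    temp: float,
    mode: str = "well_tempered",
    ligand_atoms: Optional[Sequence[int]] = None,
    calpha_serials: Optional[dict] = None,
    atom_serials: Optional[dict] = None,
    print_stride: int = 500,
) -> PlumedScript:
    """Export a learned 2-D linear RC plus a metadynamics schedule as PLUMED input.

    The per-OP z-score normalization is folded into the COMBINE coefficients:
    ``rc_i = sum_j (C_ij / s_j) * (d_j - m_j) + b_i``, rendered with the means
    as COMBINE ``PARAMETERS`` and the constant ``b_i`` absorbed into the
    parameter of the largest-coefficient argument, so the scripted variable
    equals the RCSpec output exactly.  Atom serials for the ligand COM, the
    C-alpha atoms and any H-bond atoms are explicit inputs (system-specific
    detail that no learned object carries).

    ``mode`` selects well-tempered or infrequent metadynamics; the directives
    differ only through the schedule's pace and bias factor.
    """
    from .spib_core import RCSpec  # noqa: F401  (documented return partner)

    if mode not in ("well_tempered", "infrequent"):
        raise ValueError(f"unknown mode {mode!r}")
    op_by_label = {op.label: op for op in ops}
    missing = [lab for lab in rc.labels if lab not in op_by_label]
    if missing:
        raise ValueError(f"RC inputs without an OP definition: {missing}")
    ligand_atoms = list(ligand_atoms) if ligand_atoms else [1]
    calpha_serials = calpha_serials or {}
    atom_serials = atom_serials or {}

    checksum = _rc_checksum(rc)
    lines = [
        f"# resikit export — 2-D linear reaction coordinate (rc checksum {checksum})",
        "UNITS LENGTH=nm ENERGY=kj/mol",
        "lig: COM ATOMS=" + ",".join(str(a) for a in ligand_atoms),
    ]
    for lab in rc.labels:
        op = op_by_label[lab]
        if op.kind == "com_calpha_distance":
            serial = calpha_serials.get(op.residue_index, op.residue_index)
            lines.append(f"{lab}: DISTANCE ATOMS=lig,{serial}")
        elif op.kind == "hbond_distance":
            pa = atom_serials.get(op.protein_atom, 1)
            la = atom_serials.get(("ligand", op.ligand_atom), 2)
            lines.append(f"{lab}: DISTANCE ATOMS={pa},{la}")
        else:  # custom_cv: assume the variable is defined upstream by the user
            lines.append(f"# {lab}: custom CV — define upstream and keep this label")

    coef = np.asarray(rc.coefficients, dtype=float)
    mean = np.asarray(rc.mean, dtype=float)
    scale = np.asarray(rc.scale, dtype=float)
    offs = np.asarray(rc.offsets, dtype=float)
    rc_labels = []
    for i in range(coef.shape[0]):
        c = coef[i] / scale
        params = mean.copy()
        j_star = int(np.argmax(np.abs(c)))
        if c[j_star] == 0:
            raise ValueError(f"RC component {i} has all-zero coefficients")
        # absorb the affine offset b_i into one PARAMETER:
        # sum_j c_j (d_j - p_j) = sum_j c_j (d_j - m_j) + b_i
        params[j_star] = mean[j_star] - offs[i] / c[j_star]
        name = f"rc{i + 1}"
        rc_labels.append(name)
        lines.append(
            f"{name}: COMBINE ARG=" + ",".join(rc.labels)
            + " COEFFICIENTS=" + ",".join(_fmt12(v) for v in c)
            + " PARAMETERS=" + ",".join(_fmt12(v) for v in params)
            + " PERIODIC=NO"
        )

    sig = np.atleast_1d(np.asarray(metad.sigma, dtype=float))
    if sig.shape[0] != len(rc_labels):
        sig = np.full(len(rc_labels), sig[0])
    metad_parts = [
        "metad: METAD ARG=" + ",".join(rc_labels),
        "SIGMA=" + ",".join(_fmt12(v) for v in sig),
        f"HEIGHT={_fmt12(metad.height0)}",
        f"PACE={metad.pace}",
    ]
    if math.isfinite(metad.bias_factor):
        metad_parts.append(f"BIASFACTOR={_fmt12(metad.bias_factor)}")
    metad_parts.append(f"TEMP={_fmt12(temp)}")
    metad_parts.append("FILE=HILLS")
    lines.append(" ".join(metad_parts))
    lines.append(
        "PRINT ARG=" + ",".join(rc_labels) + ",metad.bias "
        f"STRIDE={print_stride} FILE=COLVAR"
    )
    return PlumedScript(text="\n".join(lines) + "\n", rc_checksum=checksum)


def check_script(script: Union[PlumedScript, str]) -> None:
    """Verify every label referenced in the script is defined on an earlier line."""
    text = script.text if isinstance(script, PlumedScript) else script
    defined = {"lig"}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("UNITS"):
            continue
        label = None
        if ":" in line.split()[0]:
            label = line.split()[0].rstrip(":")
        for token in line.split():
            if token.startswith("ARG="):
                for ref in token[4:].split(","):
                    base = ref.split(".")[0]
                    if base not in defined:
                        raise ValueError(
                            f"line {lineno}: reference to undefined label {ref!r}"
                        )
            if token.startswith("ATOMS="):
                for ref in token[6:].split(","):
                    if not ref.isdigit() and ref not in defined and not ref.startswith("@"):
                        raise ValueError(
                            f"line {lineno}: reference to undefined label {ref!r}"
                        )
        if label:
            defined.add(label)


def evaluate_script_rc(
    script: Union[PlumedScript, str],
    op_values: dict,
) -> np.ndarray:
    """Evaluate the script's COMBINE reaction-coordinate lines on OP values.

    Internal checker used to confirm the exported coefficients reproduce the
    RCSpec numerically; ``op_values`` maps each DISTANCE label to a value.
    """
    text = script.text if isinstance(script, PlumedScript) else script
    out = []
    for raw in text.splitlines():
        line = raw.strip()
        parts = line.split()
        if len(parts) < 2 or not parts[0].endswith(":") or parts[1] != "COMBINE":
            continue
        kv = {p.split("=")[0]: p.split("=", 1)[1] for p in parts[2:] if "=" in p}
        args = kv["ARG"].split(",")
        coeffs = np.array([float(v) for v in kv["COEFFICIENTS"].split(",")])
        params = np.array([float(v) for v in kv.get("PARAMETERS", "0").split(",")]) \
            if "PARAMETERS" in kv else np.zeros(len(args))
        vals = np.array([op_values[a] for a in args], dtype=float)
        out.append(float(np.sum(coeffs * (vals - params))))
    return np.asarray(out)
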