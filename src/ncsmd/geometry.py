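"""Superposition, RMSD, time series and centers of mass.

Least-squares rigid-body superposition is the determinant-corrected Kabsch
algorithm (no mirror solutions). Partial RMSD follows the convention used
throughout the NCS-1 analysis: the transform is fitted on one atom set (the
protein-core backbone, residues 11–174) and the deviation is then measured
on another set without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structures import (
    NCS1_SEGMENTS,
    AtomIndexSet,
    BACKBONE_ATOMS,
    SegmentTable,
    Structure,
    Trajectory,
    paired_selection,
)

__all__ = [
    "SuperpositionResult",
    "TimeSeries",
    "kabsch",
    "superpose",
    "rmsd_partial",
    "rmsd_series",
    "smooth_series",
    "com",
    "com_distance_series",
    "compare_structures",
    "dihedral",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform mapping the mobile onto the reference frame:
    ``x ↦ rotation @ x + translation``."""

    rotation: np.ndarray  # 3×3, proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, over the fit set after transformation

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class TimeSeries:
    """Values sampled at strictly increasing times (ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with R·mobile + t ≈ reference.

    Raises on fewer than 3 points or a collinear point set (the rotation is
    then under-determined).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {P.shape} and {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to superpose, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    for X, which in ((P0, "mobile"), (Q0, "reference")):
        s = np.linalg.svd(X, compute_uv=False)
        if s[1] <= 1e-8 * max(1.0, s[0]):
            raise ValueError(f"{which} fit points are collinear; superposition is ill-defined")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def _as_pair(
    fit_set: AtomIndexSet | tuple[AtomIndexSet, AtomIndexSet]
) -> tuple[AtomIndexSet, AtomIndexSet]:
    if isinstance(fit_set, AtomIndexSet):
        return fit_set, fit_set
    a, b = fit_set
    return a, b


def superpose(
    mobile: Structure,
    reference: Structure,
    fit_set: AtomIndexSet | tuple[AtomIndexSet, AtomIndexSet],
) -> SuperpositionResult:
    """Kabsch superposition of ``mobile`` onto ``reference`` over the fit set.

    ``fit_set`` is either a single :class:`AtomIndexSet` (same indices apply
    to both structures) or a pair ``(mobile_set, reference_set)`` of
    equal-length sets whose correspondence is element-by-element.
    """
    fm, fr = _as_pair(fit_set)
    if len(fm) != len(fr):
        raise ValueError(f"fit sets differ in length: {len(fm)} vs {len(fr)}")
    R, t, rmsd = kabsch(mobile.positions[fm.indices], reference.positions[fr.indices])
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def rmsd_partial(
    mobile: Structure,
    reference: Structure,
    fit_set: AtomIndexSet | tuple[AtomIndexSet, AtomIndexSet],
    measure_set: AtomIndexSet | tuple[AtomIndexSet, AtomIndexSet],
) -> float:
    """RMSD over ``measure_set`` after fitting the transform on ``fit_set``
    only (no refitting on the measured atoms)."""
    sup = superpose(mobile, reference, fit_set)
    mm, mr = _as_pair(measure_set)
    if len(mm) == 0 or len(mr) == 0:
        raise ValueError("empty measure set")
    if len(mm) != len(mr):
        raise ValueError(f"measure sets differ in length: {len(mm)} vs {len(mr)}")
    moved = sup.transform(mobile.positions[mm.indices])
    diff = moved - reference.positions[mr.indices]
    return float(np.sqrt((diff**2).sum() / len(mm)))


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit_set: AtomIndexSet | tuple[AtomIndexSet, AtomIndexSet],
    measure_set: AtomIndexSet | tuple[AtomIndexSet, AtomIndexSet] | None = None,
    label: str = "RMSD",
) -> TimeSeries:
    """Per-frame superpose-then-RMSD against a fixed reference.

    When ``measure_set`` is given, each frame's RMSD is the partial RMSD over
    it (fit on ``fit_set``); otherwise the fit-set RMSD itself is reported.
    """
    fm, fr = _as_pair(fit_set)
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.topology.with_positions(traj.frames[i])
        try:
            if measure_set is None:
                values[i] = superpose(frame, reference, (fm, fr)).rmsd
            else:
                values[i] = rmsd_partial(frame, reference, (fm, fr), measure_set)
        except ValueError as exc:
            raise ValueError(f"frame {i}: {exc}") from exc
    return TimeSeries(times=traj.times, values=values, label=label, units="Å")


def smooth_series(series: TimeSeries, window: int = 51) -> TimeSeries:
    """Centered moving average; edges use truncated windows, so the output
    has the same length. ``window`` must be odd (1 = identity). Cosmetic
    only — never used in statistics."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    v = series.values
    h = window // 2
    out = np.empty_like(v)
    for i in range(v.size):
        out[i] = v[max(0, i - h): i + h + 1].mean()
    return TimeSeries(series.times, out, label=f"{series.label} (smoothed w={window})", units=series.units)


def com(
    structure: Structure,
    atom_set: AtomIndexSet | None = None,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Center of mass (default) or geometric centroid of an atom set."""
    idx = np.arange(structure.n_atoms) if atom_set is None else atom_set.indices
    if idx.size == 0:
        raise ValueError("empty atom set")
    coords = structure.positions[idx]
    if not mass_weighted:
        return coords.mean(axis=0)
    w = structure.masses[idx]
    total = w.sum()
    if not total > 0:
        raise ValueError("zero total mass; use mass_weighted=False for a geometric centroid")
    return (coords * w[:, None]).sum(axis=0) / total


def com_distance_series(
    traj: Trajectory,
    set_a: AtomIndexSet,
    set_b: AtomIndexSet,
    mass_weighted: bool = True,
    label: str = "COM distance",
) -> TimeSeries:
    """Per-frame Euclidean distance between the centers of mass of two atom
    sets (e.g. the L3 tail vs the whole protein)."""
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("empty atom set")
    if mass_weighted:
        wa = traj.topology.masses[set_a.indices]
        wb = traj.topology.masses[set_b.indices]
        if not (wa.sum() > 0 and wb.sum() > 0):
            raise ValueError("zero total mass in a COM set")
        wa, wb = wa / wa.sum(), wb / wb.sum()
    else:
        wa = np.full(len(set_a), 1.0 / len(set_a))
        wb = np.full(len(set_b), 1.0 / len(set_b))
    ca = np.einsum("fij,i->fj", traj.frames[:, set_a.indices, :], wa)
    cb = np.einsum("fij,i->fj", traj.frames[:, set_b.indices, :], wb)
    values = np.linalg.norm(ca - cb, axis=1)
    return TimeSeries(times=traj.times, values=values, label=label, units="Å")


def compare_structures(
    mobile: Structure,
    reference: Structure,
    segments: Iterable[str] = ("PC",),
    fit: str | Iterable[str] = "PC",
    atom_class: str = "backbone",
    *,
    table: SegmentTable = NCS1_SEGMENTS,
    backbone_atoms: Sequence[str] = BACKBONE_ATOMS,
) -> dict[str, float]:
    """Total and partial backbone RMSDs between two structures.

    The transform is fitted once on the ``fit`` segments (protein core by
    default); each requested segment's RMSD is then measured without
    refitting. Atom correspondence is by residue id and atom name.
    """
    fit_segments = [fit] if isinstance(fit, str) else list(fit)
    fit_pair = paired_selection(
        mobile, reference, fit_segments, atom_class, table=table, backbone_atoms=backbone_atoms
    )
    out: dict[str, float] = {}
    for seg in segments:
        measure_pair = paired_selection(
            mobile, reference, [seg], atom_class, table=table, backbone_atoms=backbone_atoms
        )
        out[seg] = rmsd_partial(mobile, reference, fit_pair, measure_pair)
    return out


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, IUPAC sign convention."""
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x, y = n1 @ n2, m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))
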