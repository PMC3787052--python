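"""NOE back-calculation and restraint-violation statistics.

An NOE restraint couples two groups of equivalent protons with an upper
distance bound. Because NOE intensities scale as r⁻⁶, a restraint with
equivalent protons (methyl groups, degenerate methylenes) is scored through
an effective distance obtained by summing r⁻⁶ over all proton pairs of the
two groups:

    r_eff = ( Σ_{p∈i, q∈j} r_pq⁻⁶ )^(−1/6)

For an ensemble the per-frame Σ r⁻⁶ is additionally averaged over frames
before taking the −1/6 power (time averaging by the sixth power).

Violation rule, applied literally: a restraint is violated when the
(time-averaged) effective distance exceeds the upper bound by more than a
0.6 Å margin; the violation magnitude V is however measured from the raw
upper bound (V = r_eff − upper, not r_eff − upper − 0.6). The summary
statistic ⟨V⟩ averages V over the violated restraints only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import Structure, Trajectory

__all__ = [
    "NOERestraint",
    "NOERecord",
    "NOEReport",
    "effective_distance",
    "time_averaged_distance",
    "score",
    "noe_report",
    "DEFAULT_MARGIN",
]

#: Violation margin added to the upper bound before flagging, Å.
DEFAULT_MARGIN = 0.6


@dataclass(frozen=True)
class NOERestraint:
    """Two groups of equivalent protons plus an upper distance bound (Å).

    Each group is one residue id with one or more atom names; the groups
    must be non-empty and disjoint.
    """

    res_i: int
    atoms_i: tuple[str, ...]
    res_j: int
    atoms_j: tuple[str, ...]
    upper: float
    id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms_i or not self.atoms_j:
            raise ValueError(f"restraint {self.id!r}: proton groups must be non-empty")
        gi = {(self.res_i, a) for a in self.atoms_i}
        gj = {(self.res_j, a) for a in self.atoms_j}
        if gi & gj:
            raise ValueError(f"restraint {self.id!r}: proton groups overlap")
        if not self.upper > 0:
            raise ValueError(f"restraint {self.id!r}: upper bound must be > 0")

    @property
    def n_pairs(self) -> int:
        return len(self.atoms_i) * len(self.atoms_j)


def _group_indices(structure: Structure, res: int, atoms: Sequence[str], rid: str) -> np.ndarray:
    idx = []
    for name in atoms:
        hits = np.nonzero((structure.residue_ids == res) & (structure.names == name))[0]
        if hits.size == 0:
            raise KeyError(
                f"restraint {rid!r}: atom {name!r} of residue {res} not found in {structure.label!r}"
            )
        idx.append(int(hits[0]))
    return np.array(idx, dtype=int)


def _sum_inv_r6(coords: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> float:
    diff = coords[idx_i][:, None, :] - coords[idx_j][None, :, :]
    r2 = (diff**2).sum(axis=-1)
    return float((r2**-3).sum())


def effective_distance(
    structure: Structure, restraint: NOERestraint, *, combine: str = "sum"
) -> float:
    """r⁻⁶-weighted effective distance (Å) of one restraint on one
    conformation.

    ``combine='sum'`` (default) sums r⁻⁶ over the proton-pair cross product;
    ``combine='mean'`` divides by the number of pairs, the convention of some
    other NOE software, kept for cross-checks.
    """
    idx_i = _group_indices(structure, restraint.res_i, restraint.atoms_i, restraint.id)
    idx_j = _group_indices(structure, restraint.res_j, restraint.atoms_j, restraint.id)
    s = _sum_inv_r6(structure.positions, idx_i, idx_j)
    if combine == "mean":
        s /= restraint.n_pairs
    elif combine != "sum":
        raise ValueError(f"combine must be 'sum' or 'mean', got {combine!r}")
    return s ** (-1.0 / 6.0)


def time_averaged_distance(
    traj: Trajectory,
    restraint: NOERestraint,
    stride: float | None = None,
    window: float | None = None,
    *,
    combine: str = "sum",
) -> float:
    """Sixth-power time-averaged effective distance over sampled frames:
    r̄ = ( mean over frames of Σ r⁻⁶ )^(−1/6)."""
    frame_idx = traj.sample_indices(stride_ps=stride, window_ns=window)
    idx_i = _group_indices(traj.topology, restraint.res_i, restraint.atoms_i, restraint.id)
    idx_j = _group_indices(traj.topology, restraint.res_j, restraint.atoms_j, restraint.id)
    s = np.mean([_sum_inv_r6(traj.frames[f], idx_i, idx_j) for f in frame_idx])
    if combine == "mean":
        s /= restraint.n_pairs
    elif combine != "sum":
        raise ValueError(f"combine must be 'sum' or 'mean', got {combine!r}")
    return float(s ** (-1.0 / 6.0))


def score(
    r_eff: float, upper: float, margin: float = DEFAULT_MARGIN
) -> tuple[bool, float | None]:
    """Apply the violation rule to one effective distance.

    Violated iff ``r_eff > upper + margin``; the violation magnitude is then
    ``V = r_eff − upper`` (measured from the raw upper bound, not the
    margin-augmented one). Returns ``(False, None)`` when satisfied.
    """
    if not upper > 0:
        raise ValueError(f"upper bound must be > 0, got {upper}")
    if margin < 0:
        raise ValueError(f"margin must be ≥ 0, got {margin}")
    if r_eff > upper + margin:
        return True, float(r_eff - upper)
    return False, None


@dataclass(frozen=True)
class NOERecord:
    """Per-restraint scoring outcome."""

    id: str
    res_i: int
    res_j: int
    r_eff: float
    upper: float
    violated: bool
    violation: float | None  # Å; None when satisfied


@dataclass
class NOEReport:
    """Scoring of a whole restraint list against a structure or ensemble.

    ``fraction_satisfied`` is 1 − n_violated/n_total; ``mean_violation`` is
    ⟨V⟩ averaged over the violated restraints only and is None when nothing
    is violated. Restraints whose protons are absent from the model appear
    in ``missing`` only when scoring was run with ``skip_missing``.
    """

    records: list[NOERecord]
    missing: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_violated(self) -> int:
        return sum(1 for r in self.records if r.violated)

    @property
    def fraction_satisfied(self) -> float:
        return 1.0 - self.n_violated / self.n_total

    @property
    def mean_violation(self) -> float | None:
        v = [r.violation for r in self.records if r.violated]
        return float(np.mean(v)) if v else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "res_i": [r.res_i for r in self.records],
                "res_j": [r.res_j for r in self.records],
                "r_eff": [r.r_eff for r in self.records],
                "upper": [r.upper for r in self.records],
                "violated": [r.violated for r in self.records],
                "violation": [r.violation for r in self.records],
            }
        )

    def summary(self) -> str:
        mv = self.mean_violation
        return (
            f"{self.n_total} restraints: {self.n_total - self.n_violated} satisfied "
            f"({100 * self.fraction_satisfied:.1f}%), {self.n_violated} violated"
            + (f", <V> = {mv:.2f} Å" if mv is not None else "")
            + (f"; {len(self.missing)} skipped (missing protons)" if self.missing else "")
        )


def noe_report(
    ensemble: Trajectory | Structure,
    restraints: Sequence[NOERestraint],
    stride: float | None = None,
    window: float | None = None,
    *,
    margin: float = DEFAULT_MARGIN,
    combine: str = "sum",
    skip_missing: bool = False,
) -> NOEReport:
    """Score every restraint against a structure or trajectory.

    A restraint referencing protons absent from the model is a hard error by
    default; with ``skip_missing`` it is excluded from the statistics and
    listed in the report's ``missing`` field instead.
    """
    if not restraints:
        raise ValueError("empty restraint list")
    records: list[NOERecord] = []
    skipped: list[str] = []
    for rst in restraints:
        try:
            if isinstance(ensemble, Trajectory):
                r_eff = time_averaged_distance(ensemble, rst, stride, window, combine=combine)
            else:
                r_eff = effective_distance(ensemble, rst, combine=combine)
        except KeyError:
            if skip_missing:
                skipped.append(rst.id)
                continue
            raise
        violated, v = score(r_eff, rst.upper, margin)
        records.append(
            NOERecord(
                id=rst.id,
                res_i=rst.res_i,
                res_j=rst.res_j,
                r_eff=r_eff,
                upper=rst.upper,
                violated=violated,
                violation=v,
            )
        )
    if not records:
        raise ValueError("no scorable restraints (all referenced missing protons)")
    return NOEReport(records=records, missing=skipped)
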