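"""Inter-residue nonbonded energies and energy maps.

The pair potential is the standard Coulomb + Lennard-Jones sum with the
CHARMM cubic switching function tapering interactions smoothly between an
inner (10 Å) and outer (12 Å) cutoff:

    E(r) = S(r) · [ C·qᵢqⱼ/r + εᵢⱼ((Rmin/r)¹² − 2(Rmin/r)⁶) ]

with C = 332.0636 kcal·Å/(mol·e²), geometric-mean εᵢⱼ = √(εᵢεⱼ) and
Rmin = Rmin/2ᵢ + Rmin/2ⱼ (CHARMM combining rules). The long-range part of
the electrostatics is deliberately neglected: a residue pair contributes
only when its minimum inter-atomic distance is within the outer cutoff.

An inter-residue energy map (IEM) is the arithmetic time average of the
residue-pair energies over frames sampled every ``stride`` ps across the
final ``window`` ns of a trajectory. Entries below −30 kcal/mol flag salt
bridges; the full interaction-class binning follows the conventional
reading of such maps (hydrogen bonds between −15 and −2 kcal/mol, strong
polar/weak ionic between −30 and −15, ionic below −30).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structures import NonbondedParams, Structure, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyMap",
    "InteractionClass",
    "SaltBridge",
    "switching",
    "atom_pair_energy",
    "residue_pair_energy",
    "compute_iem",
    "classify_energy",
    "classify_map",
    "filter_map",
    "conserved_bridges",
]

#: Coulomb conversion constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636

DEFAULT_R_ON = 10.0  # Å, switching starts
DEFAULT_R_OFF = 12.0  # Å, nonbonded cutoff


def switching(r, r_on: float = DEFAULT_R_ON, r_off: float = DEFAULT_R_OFF):
    """CHARMM switching function: 1 below ``r_on``, 0 beyond ``r_off`` and a
    C¹-continuous cubic taper in between."""
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r * r, r_on * r_on, r_off * r_off
    s = (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / (off2 - on2) ** 3
    out = np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, s))
    return out if out.ndim else float(out)


def _pair_terms(q_i, q_j, eps_i, eps_j, rh_i, rh_j, r):
    eps = np.sqrt(eps_i * eps_j)
    rmin = rh_i + rh_j
    ratio6 = (rmin / r) ** 6
    return COULOMB_CONSTANT * q_i * q_j / r + eps * (ratio6 * ratio6 - 2.0 * ratio6)


def atom_pair_energy(
    params: NonbondedParams,
    atom_i: tuple[str, str],
    atom_j: tuple[str, str],
    r: float,
    *,
    r_on: float = DEFAULT_R_ON,
    r_off: float = DEFAULT_R_OFF,
) -> float:
    """Switched Coulomb + LJ energy (kcal/mol) of one atom pair at distance
    ``r`` Å. Atoms are given as (residue_name, atom_name) keys into the
    parameter table; an unparameterized atom is an error."""
    if not r > 0:
        raise ValueError(f"distance must be positive, got {r}")
    pi = params.get(*atom_i)
    pj = params.get(*atom_j)
    if r >= r_off:
        return 0.0
    e = _pair_terms(pi.charge, pj.charge, pi.epsilon, pj.epsilon, pi.rmin_half, pj.rmin_half, r)
    return float(switching(r, r_on, r_off) * e)


# ---------------------------------------------------------------------------
# Residue-pair energies
# ---------------------------------------------------------------------------

# covalent-bond inference thresholds (Å); enough for backbone + pseudo-atoms
_BOND_MAX_HEAVY = 1.9
_BOND_MAX_H = 1.3


def _bond_graph(coords: np.ndarray, elements: Sequence[str]) -> list[list[int]]:
    d = cdist(coords, coords)
    n = len(elements)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            thr = _BOND_MAX_H if ("H" in (elements[i], elements[j])) else _BOND_MAX_HEAVY
            if 0.0 < d[i, j] < thr:
                adj[i].append(j)
                adj[j].append(i)
    return adj


def _bonded_exclusion_mask(
    topology: Structure,
    idx_i: np.ndarray,
    idx_j: np.ndarray,
    n_bonds: int,
) -> np.ndarray:
    """Boolean (len_i × len_j) mask of atom pairs within ``n_bonds`` covalent
    bonds of each other, with bonds inferred by distance on the topology
    coordinates of the two residues' atoms."""
    union = np.concatenate([idx_i, idx_j])
    coords = topology.positions[union]
    elements = [topology.elements[k] for k in union]
    adj = _bond_graph(coords, elements)
    ni = len(idx_i)
    mask = np.zeros((ni, len(idx_j)), dtype=bool)
    for a in range(ni):
        # BFS bounded at n_bonds
        dist = {a: 0}
        queue = deque([a])
        while queue:
            u = queue.popleft()
            if dist[u] == n_bonds:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        for b in range(len(idx_j)):
            if dist.get(ni + b, n_bonds + 1) <= n_bonds:
                mask[a, b] = True
    return mask


def _param_arrays(topology: Structure, params: NonbondedParams):
    q = np.empty(topology.n_atoms)
    eps = np.empty(topology.n_atoms)
    rh = np.empty(topology.n_atoms)
    for i in range(topology.n_atoms):
        p = params.get(topology.residue_names[i], topology.names[i])
        q[i], eps[i], rh[i] = p.charge, p.epsilon, p.rmin_half
    return q, eps, rh


def residue_pair_energy(
    coords: np.ndarray,
    topology: Structure,
    params: NonbondedParams,
    res_i: int,
    res_j: int,
    *,
    exclude_bonded: bool = True,
    n_excluded_bonds: int = 3,
    r_on: float = DEFAULT_R_ON,
    r_off: float = DEFAULT_R_OFF,
    _cache: dict | None = None,
) -> float:
    """Total switched nonbonded energy (kcal/mol) between two residues in one
    frame, summed over all atom pairs (one atom from each residue).

    Atom pairs separated by ≤ ``n_excluded_bonds`` covalent bonds (the 1-2,
    1-3 and 1-4 pairs across the peptide bond of sequence-adjacent residues)
    are excluded so that bonded-term geometry does not masquerade as a
    nonbonded contact. Returns exactly 0 when the minimum inter-residue atom
    distance exceeds the outer cutoff.
    """
    if res_i == res_j:
        raise ValueError("residue pair energy requires two distinct residues")
    cache = _cache if _cache is not None else {}
    if "byres" not in cache:
        cache["byres"] = {rid: idx for (ch, rid), idx in topology.atom_indices_by_residue().items()}
        cache["params"] = _param_arrays(topology, params)
    byres = cache["byres"]
    for r in (res_i, res_j):
        if r not in byres:
            raise KeyError(f"residue id {r} not present in topology")
    q, eps, rh = cache["params"]
    idx_i, idx_j = byres[res_i], byres[res_j]
    d = cdist(coords[idx_i], coords[idx_j])
    if d.min() > r_off:
        return 0.0
    e = _pair_terms(
        q[idx_i][:, None], q[idx_j][None, :],
        eps[idx_i][:, None], eps[idx_j][None, :],
        rh[idx_i][:, None], rh[idx_j][None, :],
        d,
    )
    e = e * switching(d, r_on, r_off)
    e[d >= r_off] = 0.0
    if exclude_bonded and abs(res_i - res_j) == 1:
        excl_key = ("excl", res_i, res_j, n_excluded_bonds)
        if excl_key not in cache:
            cache[excl_key] = _bonded_exclusion_mask(topology, idx_i, idx_j, n_excluded_bonds)
        e[cache[excl_key]] = 0.0
    return float(e.sum())


@dataclass
class EnergyMap:
    """Residue-by-residue matrix of time-averaged interaction energies.

    Symmetric, diagonal stored as 0 by convention and excluded from
    classification and filtering. ``metadata`` records the sampling protocol
    (stride in ps, window in ns, cutoff in Å, number of frames averaged).
    """

    residue_ids: list[int]
    residue_names: list[str]
    values: np.ndarray  # n×n, kcal/mol
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be ({n}, {n}), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite energy entries")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("energy map must be symmetric")

    def energy(self, res_i: int, res_j: int) -> float:
        i = self.residue_ids.index(res_i)
        j = self.residue_ids.index(res_j)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residue_ids, columns=self.residue_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="residue")

    @classmethod
    def from_tsv(cls, path) -> "EnergyMap":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [int(c) for c in df.columns]
        return cls(residue_ids=ids, residue_names=["UNK"] * len(ids), values=df.to_numpy())


def compute_iem(
    traj: Trajectory,
    params: NonbondedParams,
    stride: float = 50.0,
    window: float = 100.0,
    exclude_ids: Iterable[int] = (),
    *,
    exclude_bonded: bool = True,
    n_excluded_bonds: int = 3,
    r_on: float = DEFAULT_R_ON,
    r_off: float = DEFAULT_R_OFF,
) -> EnergyMap:
    """Time-averaged inter-residue energy map.

    Residue-pair energies are evaluated on frames sampled every ``stride`` ps
    over the final ``window`` ns and averaged arithmetically. Residues listed
    in ``exclude_ids`` (e.g. bound ions retained in the topology) are absent
    from the matrix altogether.
    """
    frame_idx = traj.sample_indices(stride_ps=stride, window_ns=window)
    excluded = set(exclude_ids)
    residues = [
        (rid, rname)
        for ch, rid, rname in traj.topology.residues()
        if rid not in excluded
    ]
    ids = [rid for rid, _ in residues]
    names = [rname for _, rname in residues]
    n = len(ids)
    cache: dict = {}
    values = np.zeros((n, n))
    for f in frame_idx:
        coords = traj.frames[f]
        for a in range(n):
            for b in range(a + 1, n):
                e = residue_pair_energy(
                    coords,
                    traj.topology,
                    params,
                    ids[a],
                    ids[b],
                    exclude_bonded=exclude_bonded,
                    n_excluded_bonds=n_excluded_bonds,
                    r_on=r_on,
                    r_off=r_off,
                    _cache=cache,
                )
                values[a, b] += e
    values /= len(frame_idx)
    values = values + values.T  # symmetric; diagonal stays 0
    return EnergyMap(
        residue_ids=ids,
        residue_names=names,
        values=values,
        metadata={
            "stride_ps": stride,
            "window_ns": window,
            "cutoff_A": r_off,
            "n_frames": int(len(frame_idx)),
        },
    )


class InteractionClass(Enum):
    """Interaction-strength bins of an energy-map entry (kcal/mol).

    Boundaries at 0, −2, −15 and −30; each bin edge belongs to the
    more-negative class (so −30 is ionic, −2 is hydrogen-bond-like and
    exactly 0 is weak)."""

    REPULSIVE = "repulsive"  # > 0
    WEAK = "weak"  # (−2, 0]
    HBOND_LIKE = "hbond_like"  # (−15, −2]
    STRONG_POLAR = "strong_polar"  # (−30, −15]
    IONIC = "ionic"  # ≤ −30


def classify_energy(e: float) -> InteractionClass:
    if e > 0:
        return InteractionClass.REPULSIVE
    if e > -2:
        return InteractionClass.WEAK
    if e > -15:
        return InteractionClass.HBOND_LIKE
    if e > -30:
        return InteractionClass.STRONG_POLAR
    return InteractionClass.IONIC


def classify_map(emap: EnergyMap) -> np.ndarray:
    """Elementwise interaction classes; diagonal entries are None (the
    self-energy is not defined)."""
    n = len(emap.residue_ids)
    out = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            out[i, j] = None if i == j else classify_energy(float(emap.values[i, j]))
    return out


@dataclass(frozen=True)
class SaltBridge:
    """A residue pair whose time-averaged interaction energy falls below the
    salt-bridge threshold (strictly)."""

    res_i: int
    res_j: int
    name_i: str
    name_j: str
    energy: float  # kcal/mol
    conserved: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = " (conserved)" if self.conserved else ""
        return f"{self.name_i}{self.res_i}:{self.name_j}{self.res_j} {self.energy:.1f} kcal/mol{tag}"


def filter_map(emap: EnergyMap, threshold: float = -30.0) -> list[SaltBridge]:
    """Residue pairs with energy strictly below ``threshold`` (default −30
    kcal/mol, the operational salt-bridge criterion), each reported once with
    res_i < res_j, sorted by energy (most negative first)."""
    if not threshold < 0:
        raise ValueError(f"threshold must be negative, got {threshold}")
    out = []
    n = len(emap.residue_ids)
    for i in range(n):
        for j in range(i + 1, n):
            e = float(emap.values[i, j])
            if e < threshold:
                out.append(
                    SaltBridge(
                        res_i=emap.residue_ids[i],
                        res_j=emap.residue_ids[j],
                        name_i=emap.residue_names[i],
                        name_j=emap.residue_names[j],
                        energy=e,
                    )
                )
    return sorted(out, key=lambda b: b.energy)


def conserved_bridges(
    map_a: EnergyMap, map_b: EnergyMap, threshold: float = -30.0
) -> list[SaltBridge]:
    """Salt bridges present (strictly below ``threshold``) in BOTH maps.

    The reported energy is the mean of the two maps' entries for the pair.
    """
    bridges_a = {(b.res_i, b.res_j): b for b in filter_map(map_a, threshold)}
    bridges_b = {(b.res_i, b.res_j): b for b in filter_map(map_b, threshold)}
    out = []
    for pair in sorted(set(bridges_a) & set(bridges_b)):
        ba, bb = bridges_a[pair], bridges_b[pair]
        out.append(
            SaltBridge(
                res_i=ba.res_i,
                res_j=ba.res_j,
                name_i=ba.name_i,
                name_j=ba.name_j,
                energy=0.5 * (ba.energy + bb.energy),
                conserved=True,
            )
        )
    return sorted(out, key=lambda b: b.energy)
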