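"""Seeded synthetic structures, trajectories, parameters and restraints.

Every downstream operator in this package is exercised offline on inputs
with planted ground truth built here:

* an ideal α-helix backbone (φ = −57°, ψ = −47°, standard bond geometry),
  optionally with amide protons, standing in for the helical segments of a
  real calcium-sensor fold;
* oppositely charged pseudo-atom pairs planted at salt-bridge separation,
  together with a matching nonbonded parameter table, so the energy-map
  pipeline has an exactly known answer;
* trajectories of seeded isotropic Gaussian fluctuations around a reference
  conformation (optionally with a rigid drift of a terminal segment, the
  toy analogue of a tail docking motion);
* restraint lists with an exactly known violated subset and violation depth.

All generators are deterministic for a fixed seed (numpy's PCG64
``default_rng``). The fluctuation model is deliberately simple — isotropic,
uncorrelated Gaussian displacements — because the analysis operators under
test are agnostic to the dynamics that produced the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import gemmi
import numpy as np

from .noe import DEFAULT_MARGIN, NOERestraint
from .structures import (
    AtomRecord,
    NBParam,
    NonbondedParams,
    SegmentTable,
    Structure,
    Trajectory,
)

__all__ = [
    "SynthSpec",
    "build_helix",
    "plant_salt_bridge",
    "make_trajectory",
    "make_restraints",
    "rotate_segment",
    "bridge_system",
    "noe_system",
    "two_state_system",
]

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_C_N_H = 120.8, 119.3
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, dihed: float) -> np.ndarray:
    """NeRF placement: position of atom D given A, B, C, the C–D bond length,
    the B–C–D angle and the A–B–C–D dihedral (degrees)."""
    ang, tor = np.radians(angle), -np.radians(dihed)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _mass(element: str) -> float:
    return float(gemmi.Element(element).weight)


def build_helix(
    sequence: Sequence[str],
    *,
    chain: str = "A",
    start_id: int = 1,
    add_amide_hydrogens: bool = False,
    label: str = "ideal-helix",
) -> Structure:
    """Ideal α-helix backbone for a sequence of 3-letter residue names.

    Each residue carries atoms N, CA, C, O (plus the amide H for residues
    after the first when ``add_amide_hydrogens`` is set). Backbone dihedrals
    are exactly φ = −57°, ψ = −47°, ω = 180°, which places the i→i+4
    carbonyl-oxygen-to-amide-nitrogen hydrogen-bond partners near 3 Å.
    """
    sequence = list(sequence)
    if len(sequence) < 4:
        raise ValueError(f"a helix needs at least 4 residues, got {len(sequence)}")
    for name in sequence:
        if name.upper() not in _STANDARD_RESIDUES:
            raise ValueError(f"unknown residue name {name!r}")

    atoms: list[AtomRecord] = []
    serial = 1

    def add(name: str, rid: int, rname: str, pos: np.ndarray, element: str) -> None:
        nonlocal serial
        atoms.append(
            AtomRecord(
                serial=serial,
                name=name,
                residue_name=rname.upper(),
                residue_id=rid,
                chain=chain,
                position=np.asarray(pos, dtype=float),
                mass=_mass(element),
                element=element,
            )
        )
        serial += 1

    # first residue seeds the frame
    n_prev = np.array([0.0, 0.0, 0.0])
    ca_prev = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(_A_N_CA_C)
    c_prev = ca_prev + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    positions: list[dict[str, np.ndarray]] = [{"N": n_prev, "CA": ca_prev, "C": c_prev}]
    for _ in range(1, len(sequence)):
        n_i = _place(positions[-1]["N"], positions[-1]["CA"], positions[-1]["C"], _B_C_N, _A_CA_C_N, _PSI)
        ca_i = _place(positions[-1]["CA"], positions[-1]["C"], n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place(positions[-1]["C"], n_i, ca_i, _B_CA_C, _A_N_CA_C, _PHI)
        positions.append({"N": n_i, "CA": ca_i, "C": c_i})

    for i, rname in enumerate(sequence):
        rid = start_id + i
        p = positions[i]
        add("N", rid, rname, p["N"], "N")
        if add_amide_hydrogens and i > 0:
            prev = positions[i - 1]
            o_prev = _place(prev["N"], prev["CA"], prev["C"], _B_C_O, _A_CA_C_O, _PSI + 180.0)
            h = _place(o_prev, prev["C"], p["N"], _B_N_H, _A_C_N_H, 180.0)
            add("H", rid, rname, h, "H")
        add("CA", rid, rname, p["CA"], "C")
        add("C", rid, rname, p["C"], "C")
        # carbonyl O anti to the next amide nitrogen (dihedral N-CA-C-O = psi+180)
        add("O", rid, rname, _place(p["N"], p["CA"], p["C"], _B_C_O, _A_CA_C_O, _PSI + 180.0), "O")

    return Structure.from_atoms(atoms, label=label)


# ---------------------------------------------------------------------------
# Planted salt bridges
# ---------------------------------------------------------------------------

POSITIVE_SITE = "XP"  # pseudo-atom name carrying the positive charge
NEGATIVE_SITE = "XN"


def plant_salt_bridge(
    structure: Structure,
    res_i: int,
    res_j: int,
    distance: float = 3.0,
    charges: tuple[float, float] = (1.0, -1.0),
    *,
    base_epsilon: float = 0.05,
    base_rmin_half: float = 1.8,
) -> tuple[Structure, NonbondedParams]:
    """Plant an ionic contact between two residues and emit matching
    parameters.

    One charged pseudo-atom is attached to each residue, the pair placed
    ``distance`` Å apart on the line between the residues' CA atoms. The
    returned parameter table covers every (residue, atom) of the new
    structure: pseudo-atoms carry the requested charges, everything else is
    neutral with a small LJ well depth, so the planted contact is the only
    interaction that can cross an ionic threshold.
    """
    if res_i == res_j:
        raise ValueError("salt-bridge residues must be distinct")
    ids = set(int(r) for r in structure.residue_ids)
    for r in (res_i, res_j):
        if r not in ids:
            raise ValueError(f"residue {r} not in structure (ids {min(ids)}..{max(ids)})")

    def ca_of(res: int) -> np.ndarray:
        hit = np.nonzero((structure.residue_ids == res) & (structure.names == "CA"))[0]
        if hit.size == 0:
            raise ValueError(f"residue {res} has no CA atom to anchor a pseudo-site")
        return structure.positions[int(hit[0])]

    ca_i, ca_j = ca_of(res_i), ca_of(res_j)
    axis = ca_j - ca_i
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    mid = 0.5 * (ca_i + ca_j)
    # keep the charged sites clear of the backbone: displace the pair outward
    # from the molecular centroid so neither site clashes with intervening
    # residues (a clash would add huge spurious LJ terms to third residues)
    out = mid - structure.positions.mean(axis=0)
    out -= (out @ axis) * axis
    out_norm = np.linalg.norm(out)
    if out_norm > 1e-9:
        out /= out_norm
    else:  # centroid on the axis: any perpendicular will do
        out = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(out) < 1e-9:
            out = np.cross(axis, [0.0, 1.0, 0.0])
        out /= np.linalg.norm(out)
    anchor = mid + 5.0 * out
    pos_i = anchor - 0.5 * distance * axis
    pos_j = anchor + 0.5 * distance * axis

    q_i, q_j = charges
    name_i = POSITIVE_SITE if q_i >= 0 else NEGATIVE_SITE
    name_j = POSITIVE_SITE if q_j >= 0 else NEGATIVE_SITE
    if name_i == name_j:
        raise ValueError("planted charges must have opposite signs")

    atoms = structure.atoms
    max_serial = int(structure.serials.max())
    new_atoms: list[AtomRecord] = []
    for atom in atoms:
        new_atoms.append(atom)
        if atom.residue_id == res_i and atom.name == "CA":
            rname_i = atom.residue_name
        if atom.residue_id == res_j and atom.name == "CA":
            rname_j = atom.residue_name
    # append pseudo-atoms at the end of their residues' chains (atom order by
    # residue is preserved by inserting right after each residue's last atom)
    def insert_after_residue(records: list[AtomRecord], res: int, new: AtomRecord) -> list[AtomRecord]:
        last = max(i for i, a in enumerate(records) if a.residue_id == res)
        return records[: last + 1] + [new] + records[last + 1 :]

    pa = AtomRecord(
        serial=max_serial + 1, name=name_i, residue_name=rname_i, residue_id=res_i,
        chain=structure.chains[0], position=pos_i, mass=12.0, element="C",
    )
    pb = AtomRecord(
        serial=max_serial + 2, name=name_j, residue_name=rname_j, residue_id=res_j,
        chain=structure.chains[0], position=pos_j, mass=12.0, element="C",
    )
    new_atoms = insert_after_residue(new_atoms, res_i, pa)
    new_atoms = insert_after_residue(new_atoms, res_j, pb)
    planted = Structure.from_atoms(new_atoms, label=structure.label + "+bridge")

    pos_charge = q_i if q_i >= 0 else q_j
    neg_charge = q_j if q_i >= 0 else q_i
    entries: dict[tuple[str, str], NBParam] = {}
    for a in planted.atoms:
        key = (a.residue_name, a.name)
        if key in entries:
            continue
        if a.name == POSITIVE_SITE:
            charge = pos_charge
        elif a.name == NEGATIVE_SITE:
            charge = neg_charge
        else:
            charge = 0.0
        entries[key] = NBParam(charge=charge, epsilon=base_epsilon, rmin_half=base_rmin_half)
    return planted, NonbondedParams(entries)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class SynthSpec:
    """Conditions for a synthetic trajectory.

    ``fluctuation_amplitude`` is the per-coordinate standard deviation (Å) of
    the isotropic Gaussian displacements; ``drift_segment``/``drift_vector``
    optionally translate a named segment linearly from 0 to the full vector
    across the frames, emulating a tail drifting relative to a fixed core.
    """

    n_frames: int = 50
    dt: float = 50.0  # ps
    fluctuation_amplitude: float = 0.1  # Å
    seed: int = 0
    drift_segment: str | None = None
    drift_vector: tuple[float, float, float] | None = None
    segments: SegmentTable | None = None

    def __post_init__(self) -> None:
        if self.fluctuation_amplitude < 0:
            raise ValueError("fluctuation amplitude must be ≥ 0")
        if self.n_frames < 1 or self.dt <= 0:
            raise ValueError("need n_frames ≥ 1 and dt > 0")
        if (self.drift_segment is None) != (self.drift_vector is None):
            raise ValueError("drift_segment and drift_vector must be given together")


def make_trajectory(spec: SynthSpec, base: Structure) -> Trajectory:
    """Seeded Gaussian-fluctuation trajectory around a reference conformation."""
    rng = np.random.default_rng(spec.seed)
    frames = base.positions[None, :, :] + rng.normal(
        0.0, spec.fluctuation_amplitude, size=(spec.n_frames, base.n_atoms, 3)
    ) if spec.fluctuation_amplitude > 0 else np.repeat(
        base.positions[None, :, :], spec.n_frames, axis=0
    ).astype(float)
    if spec.drift_segment is not None:
        if spec.segments is None:
            raise ValueError("a SegmentTable is required to resolve the drift segment")
        lo, hi = spec.segments.range(spec.drift_segment)
        mask = (base.residue_ids >= lo) & (base.residue_ids <= hi)
        if not mask.any():
            raise ValueError(f"drift segment {spec.drift_segment!r} matches no atoms")
        vec = np.asarray(spec.drift_vector, dtype=float)
        progress = (
            np.zeros(1) if spec.n_frames == 1 else np.linspace(0.0, 1.0, spec.n_frames)
        )
        frames = frames.copy()
        frames[:, mask, :] += progress[:, None, None] * vec[None, None, :]
    return Trajectory(topology=base, frames=frames, dt=spec.dt)


def rotate_segment(
    structure: Structure,
    first_residue: int,
    angle_deg: float,
    axis: Sequence[float] = (0.0, 0.0, 1.0),
) -> Structure:
    """Rigidly rotate all residues ≥ ``first_residue`` about an axis through
    the CA of ``first_residue`` — a hinge-bend conformer generator."""
    hit = np.nonzero((structure.residue_ids == first_residue) & (structure.names == "CA"))[0]
    if hit.size == 0:
        raise ValueError(f"residue {first_residue} has no CA atom")
    pivot = structure.positions[int(hit[0])]
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
    mask = structure.residue_ids >= first_residue
    pos = structure.positions.copy()
    pos[mask] = (pos[mask] - pivot) @ R.T + pivot
    return structure.with_positions(pos, label=structure.label + f"+hinge{angle_deg:g}")


# ---------------------------------------------------------------------------
# Restraints with planted violations
# ---------------------------------------------------------------------------


def make_restraints(
    structure: Structure,
    n: int,
    violated_fraction: float,
    depth: float,
    seed: int,
    *,
    margin: float = DEFAULT_MARGIN,
    slack: float = 1.0,
    min_sequence_separation: int = 2,
) -> list[NOERestraint]:
    """Single-pair restraints with an exactly known violated subset.

    ``round(n · violated_fraction)`` restraints (a seeded choice of which)
    get ``upper = r_eff − depth − margin`` so they are violated by
    construction with planted violation V = depth + margin; the rest get
    ``upper = r_eff + slack`` and are satisfied with margin to spare. On the
    static structure the planted truth is exact; on a fluctuating ensemble
    it holds up to the noise of the time-averaged distances.
    """
    if not 0.0 <= violated_fraction <= 1.0:
        raise ValueError("violated fraction must be in [0, 1]")
    if depth < 0:
        raise ValueError("violation depth must be ≥ 0")
    if len(set(int(r) for r in structure.residue_ids)) < 2:
        raise ValueError("need at least 2 residues to build restraints")

    # candidate sites: protons when present, else backbone heavy atoms
    has_h = bool(np.any(structure.elements == "H"))
    site_mask = (
        structure.elements == "H"
        if has_h
        else np.isin(structure.names, ["N", "CA", "C", "O"])
    )
    sites = np.nonzero(site_mask)[0]
    min_r = depth + margin + 0.5  # keeps planted uppers safely positive
    cand: list[tuple[int, int, float]] = []
    for ii, a in enumerate(sites):
        for b in sites[ii + 1 :]:
            if abs(int(structure.residue_ids[a]) - int(structure.residue_ids[b])) < min_sequence_separation:
                continue
            r = float(np.linalg.norm(structure.positions[a] - structure.positions[b]))
            if r >= min_r:
                cand.append((int(a), int(b), r))
    if len(cand) < n:
        raise ValueError(f"only {len(cand)} candidate proton pairs for {n} restraints")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cand), size=n, replace=False)
    n_violated = int(round(n * violated_fraction))
    violated_slots = set(rng.choice(n, size=n_violated, replace=False).tolist())

    restraints: list[NOERestraint] = []
    for slot, c in enumerate(chosen):
        a, b, r = cand[int(c)]
        upper = r - depth - margin if slot in violated_slots else r + slack
        restraints.append(
            NOERestraint(
                res_i=int(structure.residue_ids[a]),
                atoms_i=(structure.names[a],),
                res_j=int(structure.residue_ids[b]),
                atoms_j=(structure.names[b],),
                upper=upper,
                id=f"synth{slot:04d}{'v' if slot in violated_slots else 's'}",
            )
        )
    return restraints


# ---------------------------------------------------------------------------
# Ready-made study systems
# ---------------------------------------------------------------------------


def bridge_system(seed: int = 0):
    """Helix with one planted Glu/Lys-like ionic contact plus a matching
    parameter table and a short fluctuation trajectory.

    Returns ``(traj, params, (res_i, res_j))`` where the residue pair is the
    planted bridge — the only pair whose time-averaged energy can fall below
    the −30 kcal/mol ionic threshold.
    """
    base = build_helix(["ALA"] * 20, label="bridge-host")
    planted, params = plant_salt_bridge(base, 5, 12, distance=3.0)
    spec = SynthSpec(n_frames=25, dt=50.0, fluctuation_amplitude=0.05, seed=seed)
    return make_trajectory(spec, planted), params, (5, 12)


def noe_system(seed: int = 0, n: int = 200, violated_fraction: float = 0.2, depth: float = 0.3):
    """Helix with amide protons, a restraint list with a planted violated
    subset, and a fluctuating ensemble.

    Returns ``(structure, ensemble, restraints)``. On the static structure
    the violated fraction is exact and every planted violation equals
    depth + 0.6 Å; on the ensemble both hold within sampling noise.
    """
    base = build_helix(["ALA"] * 30, add_amide_hydrogens=True, label="noe-host")
    restraints = make_restraints(base, n, violated_fraction, depth, seed)
    spec = SynthSpec(n_frames=30, dt=50.0, fluctuation_amplitude=0.06, seed=seed + 1)
    return base, make_trajectory(spec, base), restraints


def two_state_system(seed: int = 0, n_per_state: int = 20):
    """Trajectory visiting two well-separated conformers of one helix.

    The second conformer is a 100° hinge bend of the terminal half, giving
    an inter-conformer backbone RMSD around 5 Å while the within-state
    Gaussian noise keeps intra-state pairwise RMSDs a fraction of an Å.
    Returns ``(traj, state_labels)`` with frames 0..n−1 in state A and
    n..2n−1 in state B.
    """
    base = build_helix(["ALA"] * 24, label="two-state")
    bent = rotate_segment(base, 13, 100.0, axis=(0.0, 1.0, 0.0))
    amp = 0.1
    tr_a = make_trajectory(SynthSpec(n_frames=n_per_state, fluctuation_amplitude=amp, seed=seed), base)
    tr_b = make_trajectory(SynthSpec(n_frames=n_per_state, fluctuation_amplitude=amp, seed=seed + 1), bent)
    frames = np.concatenate([tr_a.frames, tr_b.frames])
    labels = np.array([0] * n_per_state + [1] * n_per_state)
    return Trajectory(topology=base, frames=frames, dt=50.0), labels
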