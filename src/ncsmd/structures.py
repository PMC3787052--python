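"""Structures, ensembles and tabular inputs.

This module owns the in-memory containers used everywhere else — a
:class:`Structure` (one conformation), a :class:`Trajectory` (ordered frames
sharing a topology) — plus the NCS-1 segment registry, atom selections, and
readers/writers for PDB files and the two bespoke tabular formats
(nonbonded parameters and NOE restraints).

Conventions
-----------
* Residue numbering is the author numbering of the PDB file, taken at face
  value (the protein core of NCS-1 is residues 11–174).
* Heteroatoms (waters, ions, glycols) are excluded on read by default.
* Alternate locations: the highest-occupancy conformer is kept; ties go to
  altloc ``A``. Insertion codes are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "SegmentTable",
    "NCS1_SEGMENTS",
    "AtomIndexSet",
    "NonbondedParams",
    "NBParam",
    "BACKBONE_ATOMS",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "paired_selection",
    "read_params",
    "write_params",
    "read_restraints",
    "write_restraints",
]

#: Default backbone atom set. The alternatives {N, CA, C} and {CA} can be
#: passed to :func:`select` via ``backbone_atoms``.
BACKBONE_ATOMS: tuple[str, ...] = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, coordinates and mass."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    position: np.ndarray  # shape (3,), Å
    mass: float  # amu
    element: str

    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_id, self.name)


class Structure:
    """One conformation stored as parallel numpy arrays.

    Atom identity arrays (``names``, ``residue_ids`` …) are shared between a
    structure and any structure derived from it via :meth:`with_positions`.
    """

    def __init__(
        self,
        *,
        label: str,
        serials: np.ndarray,
        names: np.ndarray,
        residue_names: np.ndarray,
        residue_ids: np.ndarray,
        chains: np.ndarray,
        elements: np.ndarray,
        positions: np.ndarray,
        masses: np.ndarray,
    ) -> None:
        self.label = label
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.chains = np.asarray(chains, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.positions = np.asarray(positions, dtype=float)
        self.masses = np.asarray(masses, dtype=float)
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: Sequence[AtomRecord], label: str = "") -> "Structure":
        if not atoms:
            raise ValueError("a Structure must contain at least one atom")
        return cls(
            label=label,
            serials=np.array([a.serial for a in atoms]),
            names=np.array([a.name for a in atoms], dtype=object),
            residue_names=np.array([a.residue_name for a in atoms], dtype=object),
            residue_ids=np.array([a.residue_id for a in atoms]),
            chains=np.array([a.chain for a in atoms], dtype=object),
            elements=np.array([a.element for a in atoms], dtype=object),
            positions=np.array([a.position for a in atoms], dtype=float),
            masses=np.array([a.mass for a in atoms]),
        )

    def _validate(self) -> None:
        n = len(self.names)
        if n == 0:
            raise ValueError("a Structure must contain at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be ({n}, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        keys = self.atom_keys()
        if len(set(keys)) != n:
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k!r} in structure")
                seen.add(k)
        # residue ids non-decreasing within each chain, in atom order
        for ch in dict.fromkeys(self.chains):
            rid = self.residue_ids[self.chains == ch]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue ids decrease within chain {ch!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """(chain, residue_id, atom_name) per atom, in atom order."""
        return list(zip(self.chains, (int(r) for r in self.residue_ids), self.names))

    @property
    def atoms(self) -> list[AtomRecord]:
        return [
            AtomRecord(
                serial=int(self.serials[i]),
                name=self.names[i],
                residue_name=self.residue_names[i],
                residue_id=int(self.residue_ids[i]),
                chain=self.chains[i],
                position=self.positions[i].copy(),
                mass=float(self.masses[i]),
                element=self.elements[i],
            )
            for i in range(self.n_atoms)
        ]

    def residues(self) -> list[tuple[str, int, str]]:
        """Unique (chain, residue_id, residue_name), in atom order."""
        out: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for i in range(self.n_atoms):
            k = (self.chains[i], int(self.residue_ids[i]))
            if k not in seen:
                seen.add(k)
                out.append((self.chains[i], int(self.residue_ids[i]), self.residue_names[i]))
        return out

    def atom_indices_by_residue(self) -> dict[tuple[str, int], np.ndarray]:
        out: dict[tuple[str, int], list[int]] = {}
        for i in range(self.n_atoms):
            out.setdefault((self.chains[i], int(self.residue_ids[i])), []).append(i)
        return {k: np.array(v, dtype=int) for k, v in out.items()}

    def with_positions(self, positions: np.ndarray, label: str | None = None) -> "Structure":
        return Structure(
            label=self.label if label is None else label,
            serials=self.serials,
            names=self.names,
            residue_names=self.residue_names,
            residue_ids=self.residue_ids,
            chains=self.chains,
            elements=self.elements,
            positions=np.asarray(positions, dtype=float),
            masses=self.masses,
        )

    def subset(self, indices: np.ndarray, label: str | None = None) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(
            label=self.label if label is None else label,
            serials=self.serials[idx],
            names=self.names[idx],
            residue_names=self.residue_names[idx],
            residue_ids=self.residue_ids[idx],
            chains=self.chains[idx],
            elements=self.elements[idx],
            positions=self.positions[idx],
            masses=self.masses[idx],
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nres = len(self.residues())
        return f"<Structure {self.label!r}: {self.n_atoms} atoms, {nres} residues>"


@dataclass
class Trajectory:
    """Ordered frames sharing one atom topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``dt`` is the time
    between consecutive frames in ps.
    """

    topology: Structure
    frames: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames must be (n_frames, {self.topology.n_atoms}, 3), "
                f"got {self.frames.shape}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("a Trajectory must contain at least one frame")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps, starting at 0."""
        return np.arange(self.n_frames) * float(self.dt)

    def frame(self, i: int) -> Structure:
        return self.topology.with_positions(self.frames[i])

    def sample_indices(self, stride_ps: float | None = None, window_ns: float | None = None) -> np.ndarray:
        """Frame indices for the analysis protocol: every ``stride_ps`` over
        the final ``window_ns`` of the trajectory (both optional).

        The stride must be a multiple of ``dt``; the window is measured back
        from the last frame.
        """
        t = self.times
        lo = 0
        if window_ns is not None:
            if window_ns <= 0:
                raise ValueError("window must be positive")
            t0 = t[-1] - window_ns * 1000.0
            lo = int(np.searchsorted(t, t0 - 1e-9))
        step = 1
        if stride_ps is not None:
            ratio = stride_ps / self.dt
            step = int(round(ratio))
            if step < 1 or abs(ratio - step) > 1e-9:
                raise ValueError(f"stride {stride_ps} ps is not a multiple of dt={self.dt} ps")
        idx = np.arange(lo, self.n_frames, step)
        if idx.size == 0:
            raise ValueError("empty frame sample")
        return idx


# ---------------------------------------------------------------------------
# Segment registry
# ---------------------------------------------------------------------------


def _normalize_segment(name: str) -> str:
    return name.replace("β", "B").replace("Β", "B").upper()


@dataclass(frozen=True)
class SegmentTable:
    """Named inclusive residue ranges used for selections and partial RMSD."""

    entries: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        norm = {}
        for name, (lo, hi) in self.entries.items():
            if lo > hi:
                raise ValueError(f"segment {name!r}: first residue {lo} > last {hi}")
            norm[_normalize_segment(name)] = (int(lo), int(hi))
        object.__setattr__(self, "entries", norm)

    def range(self, name: str) -> tuple[int, int]:
        key = _normalize_segment(name)
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"unknown segment {name!r}; known: {', '.join(sorted(self.entries))}"
            ) from None

    def residues(self, names: Iterable[str]) -> set[int]:
        out: set[int] = set()
        for name in names:
            lo, hi = self.range(name)
            out.update(range(lo, hi + 1))
        return out

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def __contains__(self, name: str) -> bool:
        return _normalize_segment(name) in self.entries


#: NCS-1 segment registry: helices H1–H9, strands β1–β6 (keys B1–B6), loops
#: L1–L3, protein core PC (residues 11–174) and hinge loop HL (S93–D98).
#: ``L3`` is the C-terminal tail 175–187; ``L3_METHODS`` is the wider
#: D176–D190 variant of the same tail also used in the field.
NCS1_SEGMENTS = SegmentTable(
    {
        "H1": (11, 18),
        "H2": (24, 34),
        "H3": (45, 54),
        "H4": (62, 72),
        "H5": (82, 93),
        "H6": (98, 108),
        "H7": (118, 132),
        "H8": (146, 155),
        "H9": (166, 174),
        "B1": (42, 44),
        "B2": (58, 60),
        "B3": (79, 81),
        "B4": (115, 117),
        "B5": (136, 138),
        "B6": (163, 165),
        "L1": (56, 61),
        "L2": (133, 145),
        "L3": (175, 187),
        "PC": (11, 174),
        "HL": (93, 98),
        "L3_METHODS": (176, 190),
    }
)


@dataclass(frozen=True)
class AtomIndexSet:
    """Indices into a Structure's atom list, with the selection expression
    that produced them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("duplicate indices in selection")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def __iter__(self) -> Iterator[int]:
        return iter(int(i) for i in self.indices)


def select(
    structure: Structure,
    segments: str | Iterable[str],
    atom_class: str = "backbone",
    *,
    table: SegmentTable = NCS1_SEGMENTS,
    backbone_atoms: Sequence[str] = BACKBONE_ATOMS,
) -> AtomIndexSet:
    """Select atoms of ``structure`` inside the union of named segments.

    ``segments`` may also be ``"ALL"`` for every residue. ``atom_class`` is
    one of ``backbone`` (atoms named N, CA, C, O by default), ``heavy``
    (non-hydrogen), ``all`` or ``protons``. An empty selection is an error,
    never a silent empty set.
    """
    if isinstance(segments, str):
        segments = [segments]
    segments = list(segments)
    if any(_normalize_segment(s) == "ALL" for s in segments):
        resid_mask = np.ones(structure.n_atoms, dtype=bool)
    else:
        wanted = table.residues(segments)
        resid_mask = np.isin(structure.residue_ids, sorted(wanted))

    if atom_class == "backbone":
        cls_mask = np.isin(structure.names, list(backbone_atoms))
    elif atom_class == "heavy":
        cls_mask = structure.elements != "H"
    elif atom_class == "protons":
        cls_mask = structure.elements == "H"
    elif atom_class == "all":
        cls_mask = np.ones(structure.n_atoms, dtype=bool)
    else:
        raise ValueError(f"unknown atom_class {atom_class!r}")

    idx = np.nonzero(resid_mask & cls_mask)[0]
    expr = f"segments={'+'.join(_normalize_segment(s) for s in segments)};atom_class={atom_class}"
    if idx.size == 0:
        raise ValueError(f"selection {expr!r} matched no atoms in {structure.label!r}")
    return AtomIndexSet(idx, expr)


def paired_selection(
    a: Structure,
    b: Structure,
    segments: str | Iterable[str],
    atom_class: str = "backbone",
    *,
    table: SegmentTable = NCS1_SEGMENTS,
    backbone_atoms: Sequence[str] = BACKBONE_ATOMS,
) -> tuple[AtomIndexSet, AtomIndexSet]:
    """Corresponding selections on two structures.

    Correspondence is by (residue_id, atom_name) — and additionally by chain
    when both structures have several chains — restricted to atoms present in
    both. The two returned index sets are aligned element-by-element and
    sorted by key, so repeated calls give the same order.
    """
    sel_a = select(a, segments, atom_class, table=table, backbone_atoms=backbone_atoms)
    sel_b = select(b, segments, atom_class, table=table, backbone_atoms=backbone_atoms)
    use_chain = len(set(a.chains)) > 1 and len(set(b.chains)) > 1

    def keymap(s: Structure, sel: AtomIndexSet) -> dict:
        out = {}
        for i in sel.indices:
            k = (int(s.residue_ids[i]), s.names[i])
            if use_chain:
                k = (s.chains[i],) + k
            if k in out:
                raise ValueError(f"ambiguous atom key {k!r} in {s.label!r}")
            out[k] = int(i)
        return out

    ka, kb = keymap(a, sel_a), keymap(b, sel_b)
    common = sorted(set(ka) & set(kb))
    if not common:
        raise ValueError(
            f"no common atoms between {a.label!r} and {b.label!r} for {sel_a.expression!r}"
        )
    expr = sel_a.expression + ";paired"
    return (
        AtomIndexSet(np.array([ka[k] for k in common]), expr),
        AtomIndexSet(np.array([kb[k] for k in common]), expr),
    )


# ---------------------------------------------------------------------------
# PDB input / output (via gemmi)
# ---------------------------------------------------------------------------

_BLANK_ALTLOC = ("", " ", "\x00")


def _convert_residue(res: gemmi.Residue, chain_name: str, out: list[AtomRecord]) -> None:
    if res.seqid.icode not in _BLANK_ALTLOC:
        raise ValueError(
            f"insertion code {res.seqid.icode!r} at {chain_name}/{res.seqid.num} is unsupported"
        )
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    for name, alts in by_name.items():
        # keep highest occupancy; tie broken toward altloc 'A'
        atom = sorted(alts, key=lambda at: (-at.occ, at.altloc if at.altloc not in _BLANK_ALTLOC else "A"))[0]
        out.append(
            AtomRecord(
                serial=atom.serial,
                name=name,
                residue_name=res.name,
                residue_id=res.seqid.num,
                chain=chain_name,
                position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                mass=float(atom.element.weight),
                element=atom.element.name,
            )
        )


def _model_to_structure(
    model: gemmi.Model,
    chain: str | None,
    keep_het: bool,
    label: str,
) -> Structure:
    chain_names = [ch.name for ch in model]
    if chain is not None and chain not in chain_names:
        raise ValueError(f"chain {chain!r} not found; file has chains {chain_names}")
    atoms: list[AtomRecord] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            if res.het_flag == "H" and not keep_het:
                continue
            _convert_residue(res, ch.name, atoms)
    if not atoms:
        raise ValueError(f"no atoms read from {label!r} (chain={chain!r}, keep_het={keep_het})")
    return Structure.from_atoms(atoms, label=label)


def read_structure(
    path: str | Path,
    model_index: int = 1,
    chain: str | None = None,
    *,
    keep_het: bool = False,
) -> Structure:
    """Read one model (1-based ``model_index``) from a PDB file.

    Hydrogens are retained if present; HETATM records (waters, ions, glycols)
    are excluded unless ``keep_het`` is set. A missing model or chain raises
    an error naming what the file does contain.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if model_index < 1 or model_index > len(st):
        raise ValueError(
            f"model {model_index} not found in {path}; file has {len(st)} model(s)"
        )
    label = f"{Path(path).stem}"
    if chain is not None:
        label += f":{chain}"
    if len(st) > 1:
        label += f"#m{model_index}"
    return _model_to_structure(st[model_index - 1], chain, keep_het, label)


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structures[0].label or "ncsmd"
    for m, s in enumerate(structures, start=1):
        model = gemmi.Model(m)
        current_chain: gemmi.Chain | None = None
        current_res: gemmi.Residue | None = None
        for i in range(s.n_atoms):
            ch_name = s.chains[i]
            if current_chain is None or current_chain.name != ch_name:
                current_chain = gemmi.Chain(ch_name)
                model.add_chain(current_chain)
                current_chain = model[len(model) - 1]
                current_res = None
            rid = int(s.residue_ids[i])
            if current_res is None or current_res.seqid.num != rid:
                res = gemmi.Residue()
                res.name = s.residue_names[i]
                res.seqid = gemmi.SeqId(rid, " ")
                res.het_flag = "A"
                current_chain.add_residue(res)
                current_res = current_chain[len(current_chain) - 1]
            atom = gemmi.Atom()
            atom.name = s.names[i]
            atom.serial = int(s.serials[i])
            x, y, z = s.positions[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            atom.occ = 1.0
            try:
                atom.element = gemmi.Element(s.elements[i])
            except Exception:
                atom.element = gemmi.Element("X")
            current_res.add_atom(atom)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a single-model PDB file."""
    _to_gemmi([structure]).write_pdb(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB file (MODEL/ENDMDL per frame)."""
    frames = [traj.topology.with_positions(traj.frames[i]) for i in range(traj.n_frames)]
    _to_gemmi(frames).write_pdb(str(path))


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    dt: float,
    *,
    chain: str | None = None,
    keep_het: bool = False,
) -> Trajectory:
    """Read frames from one or more (multi-model) PDB files, in file order.

    All models must share one atom topology; the topology of the trajectory
    is the first model. A mismatch raises an error naming the first
    mismatching atom.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    topology: Structure | None = None
    ref_keys: list[tuple[str, int, str]] | None = None
    frames: list[np.ndarray] = []
    for path in paths:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        for m in range(1, len(st) + 1):
            s = _model_to_structure(st[m - 1], chain, keep_het, f"{Path(path).stem}#m{m}")
            if topology is None:
                topology = s
                ref_keys = s.atom_keys()
            else:
                keys = s.atom_keys()
                if keys != ref_keys:
                    n = min(len(keys), len(ref_keys))
                    for i in range(n):
                        if keys[i] != ref_keys[i]:
                            raise ValueError(
                                f"topology mismatch in {path} model {m}: atom {i} is "
                                f"{keys[i]} but topology has {ref_keys[i]}"
                            )
                    raise ValueError(
                        f"topology mismatch in {path} model {m}: "
                        f"{len(keys)} atoms vs {len(ref_keys)} in topology"
                    )
            frames.append(s.positions)
    if topology is None:
        raise ValueError("no models found in input files")
    return Trajectory(topology=topology, frames=np.stack(frames), dt=dt)


# ---------------------------------------------------------------------------
# Nonbonded parameter table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NBParam:
    """Per-atom nonbonded parameters: partial charge (e), LJ well depth
    epsilon (kcal/mol, ≥0) and LJ Rmin/2 (Å, >0)."""

    charge: float
    epsilon: float
    rmin_half: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"negative epsilon {self.epsilon}")
        if not self.rmin_half > 0:
            raise ValueError(f"rmin_half must be > 0, got {self.rmin_half}")


class NonbondedParams:
    """Total lookup (residue_name, atom_name) → :class:`NBParam`.

    A missing entry is a hard error — never a silent zero.
    """

    def __init__(self, entries: Mapping[tuple[str, str], NBParam]) -> None:
        self._entries = dict(entries)

    def get(self, residue_name: str, atom_name: str) -> NBParam:
        try:
            return self._entries[(residue_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no nonbonded parameters for atom {atom_name!r} of residue {residue_name!r}"
            ) from None

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


PARAMS_HEADER = "# residue atom charge epsilon rmin_half"


def read_params(path: str | Path) -> NonbondedParams:
    """Read a whitespace-delimited nonbonded parameter table.

    Format: comment lines start with ``#``; data rows are
    ``residue atom charge epsilon rmin_half`` with charge in e, epsilon in
    kcal/mol and Rmin/2 in Å.
    """
    entries: dict[tuple[str, str], NBParam] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}: {raw!r}")
        res, atom = parts[0], parts[1]
        try:
            charge, eps, rmin_half = (float(x) for x in parts[2:])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numeric field in {raw!r}") from None
        key = (res, atom)
        if key in entries:
            raise ValueError(f"{path}:{lineno}: duplicate parameter entry for {key}")
        try:
            entries[key] = NBParam(charge, eps, rmin_half)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return NonbondedParams(entries)


def write_params(params: NonbondedParams, path: str | Path) -> None:
    lines = [PARAMS_HEADER]
    for (res, atom), p in sorted(params.items()):
        lines.append(f"{res} {atom} {p.charge:.6g} {p.epsilon:.6g} {p.rmin_half:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# NOE restraint table
# ---------------------------------------------------------------------------

RESTRAINTS_HEADER = "# res_i atoms_i res_j atoms_j upper_A"


def read_restraints(path: str | Path):
    """Read a whitespace-delimited NOE restraint table.

    Format: ``res_i atoms_i res_j atoms_j upper_Å`` with atom groups
    comma-separated for equivalent protons, e.g. ``12 HB1,HB2,HB3 15 HN 4.5``.
    Returns a list of :class:`ncsmd.noe.NOERestraint`.
    """
    from .noe import NOERestraint  # local import to avoid a cycle

    restraints = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}: {raw!r}")
        try:
            res_i, res_j = int(parts[0]), int(parts[2])
            upper = float(parts[4])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed field in {raw!r}") from None
        if not upper > 0:
            raise ValueError(f"{path}:{lineno}: upper bound must be > 0, got {upper}")
        restraints.append(
            NOERestraint(
                res_i=res_i,
                atoms_i=tuple(parts[1].split(",")),
                res_j=res_j,
                atoms_j=tuple(parts[3].split(",")),
                upper=upper,
                id=f"noe{lineno}",
            )
        )
    return restraints


def write_restraints(restraints, path: str | Path) -> None:
    lines = [RESTRAINTS_HEADER]
    for r in restraints:
        lines.append(
            f"{r.res_i} {','.join(r.atoms_i)} {r.res_j} {','.join(r.atoms_j)} {r.upper:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
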