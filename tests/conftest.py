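import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def pdb_atom_line(
    serial,
    name,
    resname,
    chain,
    resid,
    x,
    y,
    z,
    *,
    occ=1.0,
    b=0.0,
    element="C",
    altloc=" ",
    icode=" ",
    record="ATOM",
):
    """Column-correct PDB ATOM/HETATM line."""
    name_field = name if len(name) == 4 else f" {name:<3}"
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc}{resname:>3} {chain}{resid:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    """Write a PDB file from a list of text lines; returns the path."""

    counter = {"n": 0}

    def _write(lines, name=None):
        counter["n"] += 1
        path = tmp_path / (name or f"fixture{counter['n']}.pdb")
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


@pytest.fixture
def tiny_pdb(write_pdb):
    """Three-atom single-model PDB."""
    return write_pdb(
        [
            pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0),
            pdb_atom_line(3, "C", "ALA", "A", 1, 2.0, 1.4, 0.0),
        ]
    )


def make_multimodel_lines(coords_per_model):
    """MODEL/ENDMDL blocks around a 2-atom topology with given coordinates."""
    lines = []
    for m, coords in enumerate(coords_per_model, start=1):
        lines.append(f"MODEL     {m:>4}")
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                pdb_atom_line(i, ["N", "CA"][i - 1], "GLY", "A", 1, x, y, z, element=["N", "C"][i - 1])
            )
        lines.append("ENDMDL")
    return lines


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
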