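"""Pair energies, switching, energy maps, classification and bridges."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ncsmd import (
    COULOMB_CONSTANT,
    atom_pair_energy,
    bridge_system,
    classify_energy,
    classify_map,
    compute_iem,
    conserved_bridges,
    filter_map,
    residue_pair_energy,
    switching,
)
from ncsmd.energetics import EnergyMap, InteractionClass
from ncsmd.structures import NBParam, NonbondedParams, Trajectory


def params_of(*entries):
    return NonbondedParams({k: NBParam(*v) for k, v in entries})


class TestAtomPairEnergy:
    def test_coulomb_closed_form(self):
        p = params_of((("A", "P"), (1.0, 0.0, 1.0)), (("A", "M"), (-1.0, 0.0, 1.0)))
        e = atom_pair_energy(p, ("A", "P"), ("A", "M"), 5.0)
        assert e == pytest.approx(-COULOMB_CONSTANT / 5.0)
        assert e == pytest.approx(-66.41, abs=0.01)

    def test_zero_beyond_cutoff(self):
        p = params_of((("A", "P"), (1.0, 0.5, 2.0)), (("A", "M"), (-1.0, 0.5, 2.0)))
        assert atom_pair_energy(p, ("A", "P"), ("A", "M"), 12.5) == 0.0

    def test_lj_minimum(self):
        p = params_of((("A", "X"), (0.0, 0.1, 2.0)),)
        # Rmin = 4.0; at r = Rmin the LJ term is exactly −sqrt(εε) = −0.1
        assert atom_pair_energy(p, ("A", "X"), ("A", "X"), 4.0) == pytest.approx(-0.1)

    def test_unparameterized_atom_is_an_error(self):
        p = params_of((("A", "X"), (0.0, 0.1, 2.0)),)
        with pytest.raises(KeyError, match="'Y'"):
            atom_pair_energy(p, ("A", "X"), ("A", "Y"), 3.0)

    @given(
        q=st.floats(-1.0, 1.0),
        eps=st.floats(0.01, 0.3),
        rh=st.floats(1.0, 2.5),
    )
    def test_switching_makes_energy_continuous_at_both_cutoffs(self, q, eps, rh):
        p = params_of((("A", "X"), (q, eps, rh)), (("A", "Y"), (-q, eps, rh)))

        def e(r):
            return atom_pair_energy(p, ("A", "X"), ("A", "Y"), r)

        h = 1e-7
        assert abs(e(10.0 - h) - e(10.0 + h)) < 1e-5
        assert abs(e(12.0 - h) - e(12.0 + h)) < 1e-5
        assert e(12.0) == 0.0

    def test_switching_function_shape(self):
        r = np.linspace(8, 13, 200)
        s = switching(r)
        assert np.all(s[r <= 10.0] == 1.0)
        assert np.all(s[r >= 12.0] == 0.0)
        mid = s[(r > 10) & (r < 12)]
        assert np.all((mid > 0) & (mid < 1))
        assert np.all(np.diff(mid) < 0)  # monotone taper


class TestResiduePairEnergy:
    def test_symmetry_and_distance_cutoff(self):
        traj, params, (ri, rj) = bridge_system(0)
        coords = traj.frames[0]
        top = traj.topology
        e_ij = residue_pair_energy(coords, top, params, ri, rj)
        e_ji = residue_pair_energy(coords, top, params, rj, ri)
        assert e_ij == pytest.approx(e_ji, abs=1e-12)
        assert e_ij < -30.0  # planted ionic contact
        # residues at opposite helix ends are > 13 Å apart -> exactly 0
        assert residue_pair_energy(coords, top, params, 1, 20) == 0.0

    def test_same_residue_rejected(self):
        traj, params, _ = bridge_system(0)
        with pytest.raises(ValueError, match="distinct"):
            residue_pair_energy(traj.frames[0], traj.topology, params, 3, 3)

    def test_matches_naive_double_loop_oracle(self, rng):
        """Vectorized energy equals an independently coded atom-pair loop."""
        traj, params, _ = bridge_system(3)
        top = traj.topology
        byres = {rid: idx for (ch, rid), idx in top.atom_indices_by_residue().items()}

        def naive(coords, ra, rb):
            total = 0.0
            for a in byres[ra]:
                pa = params.get(top.residue_names[a], top.names[a])
                for b in byres[rb]:
                    pb = params.get(top.residue_names[b], top.names[b])
                    r = float(np.linalg.norm(coords[a] - coords[b]))
                    if r >= 12.0:
                        continue
                    if r <= 10.0:
                        s = 1.0
                    else:
                        s = ((144 - r * r) ** 2 * (144 + 2 * r * r - 300)) / (144 - 100) ** 3
                    eps = np.sqrt(pa.epsilon * pb.epsilon)
                    rmin = pa.rmin_half + pb.rmin_half
                    total += s * (
                        332.0636 * pa.charge * pb.charge / r
                        + eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
                    )
            return total

        pairs = [(5, 12), (5, 8), (2, 4), (10, 13)]  # non-adjacent: no exclusions
        for f in range(traj.n_frames):
            for ra, rb in pairs:
                got = residue_pair_energy(traj.frames[f], top, params, ra, rb)
                assert got == pytest.approx(naive(traj.frames[f], ra, rb), abs=1e-9)

    def test_adjacent_residue_bonded_pairs_excluded(self):
        traj, params, _ = bridge_system(0)
        top = traj.topology
        with_excl = residue_pair_energy(traj.frames[0], top, params, 7, 8)
        without = residue_pair_energy(
            traj.frames[0], top, params, 7, 8, exclude_bonded=False
        )
        assert with_excl != pytest.approx(without)  # the 1-2/1-3/1-4 terms are real


class TestEnergyMap:
    def test_identical_frames_equal_single_frame_map(self):
        traj, params, _ = bridge_system(0)
        frozen = Trajectory(topology=traj.topology, frames=np.repeat(traj.frames[:1], 4, axis=0), dt=50.0)
        one = Trajectory(topology=traj.topology, frames=traj.frames[:1], dt=50.0)
        m_many = compute_iem(frozen, params, stride=50.0, window=100.0)
        m_one = compute_iem(one, params, stride=50.0, window=100.0)
        assert np.allclose(m_many.values, m_one.values, atol=1e-12)

    def test_map_is_average_of_per_frame_maps(self):
        traj, params, _ = bridge_system(1)
        sub = Trajectory(topology=traj.topology, frames=traj.frames[:10], dt=50.0)
        avg = compute_iem(sub, params, stride=50.0, window=100.0)
        per_frame = [
            compute_iem(
                Trajectory(topology=traj.topology, frames=sub.frames[i : i + 1], dt=50.0),
                params, stride=50.0, window=100.0,
            ).values
            for i in range(10)
        ]
        assert np.allclose(avg.values, np.mean(per_frame, axis=0), atol=1e-9)

    def test_default_protocol_uses_every_frame_of_a_matching_trajectory(self):
        # dt = 50 ps, 2000 frames -> 99.95 ns span: stride 50 ps over the
        # last 100 ns samples all of them
        traj, params, _ = bridge_system(0)
        long = Trajectory(
            topology=traj.topology,
            frames=np.repeat(traj.frames[:1], 2000, axis=0),
            dt=50.0,
        )
        assert len(long.sample_indices(stride_ps=50.0, window_ns=100.0)) == 2000

    def test_symmetry_and_zero_diagonal(self):
        traj, params, _ = bridge_system(2)
        m = compute_iem(traj, params)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0.0)

    def test_excluded_residues_absent(self):
        traj, params, _ = bridge_system(0)
        m = compute_iem(traj, params, exclude_ids=[1, 2])
        assert 1 not in m.residue_ids and 2 not in m.residue_ids

    def test_monotone_dilution_empties_the_map(self):
        """Scaling all coordinates outward pushes every entry to zero."""
        traj, params, _ = bridge_system(0)
        m0 = compute_iem(traj, params)
        scaled = Trajectory(topology=traj.topology.with_positions(traj.topology.positions * 20.0),
                            frames=traj.frames * 20.0, dt=traj.dt)
        m1 = compute_iem(scaled, params)
        assert np.abs(m0.values).max() > 30.0
        assert np.all(m1.values == 0.0)


class TestClassification:
    @pytest.mark.parametrize(
        "e,cls",
        [
            (-35.0, InteractionClass.IONIC),
            (-30.0, InteractionClass.IONIC),  # edge joins the more-negative class
            (-20.0, InteractionClass.STRONG_POLAR),
            (-15.0, InteractionClass.STRONG_POLAR),
            (-10.0, InteractionClass.HBOND_LIKE),
            (-2.0, InteractionClass.HBOND_LIKE),
            (-1.0, InteractionClass.WEAK),
            (0.0, InteractionClass.WEAK),
            (5.0, InteractionClass.REPULSIVE),
        ],
    )
    def test_bin_boundaries(self, e, cls):
        assert classify_energy(e) is cls

    @given(st.floats(-200.0, 50.0, allow_nan=False))
    def test_bins_partition_the_line(self, e):
        assert isinstance(classify_energy(e), InteractionClass)

    def test_classify_map_skips_diagonal(self):
        m = EnergyMap([1, 2], ["ALA", "GLY"], np.array([[0.0, -40.0], [-40.0, 0.0]]))
        classes = classify_map(m)
        assert classes[0, 0] is None
        assert classes[0, 1] is InteractionClass.IONIC


def toy_map(entries, ids=(1, 2, 3, 4, 5, 6)):
    n = len(ids)
    v = np.zeros((n, n))
    for (i, j), e in entries.items():
        a, b = ids.index(i), ids.index(j)
        v[a, b] = v[b, a] = e
    return EnergyMap(list(ids), ["UNK"] * n, v)


class TestBridges:
    def test_strict_threshold_filter(self):
        m = toy_map({(1, 2): -35.0, (3, 4): -20.0, (5, 6): +5.0})
        bridges = filter_map(m, -30.0)
        assert [(b.res_i, b.res_j) for b in bridges] == [(1, 2)]
        assert filter_map(toy_map({(1, 2): -30.0}), -30.0) == []  # strictly below

    def test_conserved_requires_both_maps(self):
        a = toy_map({(1, 2): -35.0, (3, 4): -32.0})
        b = toy_map({(1, 2): -31.0, (3, 4): -29.0})
        cons = conserved_bridges(a, b, -30.0)
        assert [(c.res_i, c.res_j) for c in cons] == [(1, 2)]
        assert cons[0].conserved
        assert cons[0].energy == pytest.approx(-33.0)

    def test_planted_bridge_recovered_exactly(self):
        traj, params, planted = bridge_system(0)
        bridges = filter_map(compute_iem(traj, params), -30.0)
        assert [(b.res_i, b.res_j) for b in bridges] == [planted]

    def test_map_tsv_roundtrip(self, tmp_path):
        m = toy_map({(1, 3): -12.5, (2, 4): 3.25})
        p = tmp_path / "iem.tsv"
        m.to_tsv(p)
        back = EnergyMap.from_tsv(p)
        assert back.residue_ids == m.residue_ids
        assert np.allclose(back.values, m.values)
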