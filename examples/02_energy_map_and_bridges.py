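"""Inter-residue energy map with a planted salt bridge.

Plants one oppositely charged contact on a helix, computes the
time-averaged inter-residue energy map (IEM) over a fluctuating
trajectory, classifies its entries and extracts salt bridges with the
< -30 kcal/mol criterion.
"""

from collections import Counter

from ncsmd import bridge_system, classify_map, compute_iem, conserved_bridges, filter_map

traj, params, planted = bridge_system(seed=0)
emap = compute_iem(traj, params, stride=50.0, window=100.0)

print(f"map over {len(emap.residue_ids)} residues, {emap.metadata['n_frames']} frames averaged")
print(f"energy range: {emap.values.min():.1f} .. {emap.values.max():.1f} kcal/mol")

classes = classify_map(emap)
counts = Counter(c.value for row in classes for c in row if c is not None)
print("interaction classes (off-diagonal entries):", dict(counts))

bridges = filter_map(emap, threshold=-30.0)
print("salt bridges (< -30 kcal/mol):", [str(b) for b in bridges])
print(f"planted pair was {planted}")

# a second, independently seeded run of the same system: the bridge is conserved
traj2, params2, _ = bridge_system(seed=1)
emap2 = compute_iem(traj2, params2, stride=50.0, window=100.0)
print("conserved across runs:", [str(b) for b in conserved_bridges(emap, emap2)])
print()
print("Exactly the planted ionic contact crosses the ionic threshold; all")
print("other entries are weak dispersion terms within a few kcal/mol of 0.")
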