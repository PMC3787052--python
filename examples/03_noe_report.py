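"""NOE back-calculation and violation statistics with planted ground truth.

Builds a helix with amide protons, a 200-restraint list in which exactly
20% are violated by construction (violation depth 0.3 A beyond the 0.6 A
margin), and scores the list against the static structure and against a
fluctuating ensemble with sixth-power time averaging.
"""

from ncsmd import noe_report, noe_system

structure, ensemble, restraints = noe_system(seed=0, n=200, violated_fraction=0.2, depth=0.3)

rep_static = noe_report(structure, restraints)
print("static structure :", rep_static.summary())

rep_ens = noe_report(ensemble, restraints, stride=50.0, window=100.0)
print("ensemble average :", rep_ens.summary())

worst = rep_ens.to_frame().sort_values("violation", ascending=False).head(3)
print("\nthree largest violations (r_eff vs upper, A):")
print(worst[["id", "res_i", "res_j", "r_eff", "upper", "violation"]].to_string(index=False))
print()
print("80% satisfaction and <V> ~ 0.9 A match the planted truth: violated")
print("restraints were given uppers 0.9 A below the true effective distance.")
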