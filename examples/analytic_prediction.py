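"""The analytic fluid-market prediction: reward = relative contribution.

Prints the equilibrium division for a few dyads and verifies Aristotle's
proportionality identity (equal output/input ratios for both parties).
"""

from equisim import equilibrium_reward

print("p_dm  p_partner  reward_to_dm  dm_share_per_unit_time")
for p_dm, p_pt in [(2.0, 1.0), (1.0, 2.0), (1.0, 1.0), (2.0, 2.0),
                   (1.5, 1.2)]:
    r = equilibrium_reward(p_dm, p_pt)
    total = p_dm + p_pt
    print(f"{p_dm:4.1f}  {p_pt:9.1f}  {r:12.4f}  {r * total:8.4f}")
    # output/input is identical for the two roles: that's equity
    assert abs(r * total / p_dm - (1 - r) * total / p_pt) < 1e-12

print("\nA high producer (b=2) paired with a low producer (a=1) takes")
print(f"{equilibrium_reward(2, 1):.4f} of the 3 resources produced per unit")
print("time, i.e. exactly its own productivity of 2 — its opportunity cost.")
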