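"""Follow one agent's knowledge of a resource through doses and decay.

Each information dose applies beta' = lambda * beta^eps * (1 - beta) + beta;
stronger sources have smaller exponents (Doctor 0.05 ... Peer 0.9). Between
doses knowledge recedes geometrically (beta <- lambda^dt * beta).
"""

import pandas as pd

import crxsim as cx

params = cx.KnowledgeParams()  # lambda = 0.991, default source exponents

print("one dose at beta = 0.5, by source:")
for source in ("Doctor", "Nurse", "ClinicalStaff", "Use", "Peer"):
    print(f"  {source:<14} -> {cx.boost(0.5, source, params):.6f}")

# A week in the life of one (agent, resource) pair: a referral list at hour
# 10, a peer mention at hour 60, first-hand use at hour 100.
doses = pd.DataFrame({"hour": [10, 60, 100],
                      "source": ["Doctor", "Peer", "Use"]})
traj = cx.beta_trajectory(doses, params, t_end=167)
for h in (9, 10, 59, 60, 99, 100, 167):
    print(f"hour {h:3d}: beta = {traj.loc[h, 'beta']:.4f}")

# Expect jumps at hours 10/60/100 (largest for the clinical dose) and a
# ~0.9% per-hour decline everywhere else.
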