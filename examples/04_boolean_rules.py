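"""From binarized transitions to minimal logic rules.

Builds a generalized truth table for a target gene driven by OR logic,
minimizes it with Quine–McCluskey (don't-cares absorbed) and simulates the
resulting Boolean network.
"""

import numpy as np

from grnbool.boolean import (
    BooleanNetwork,
    GeneralizedTruthTable,
    minimize_qm,
    simulate,
)

# generalized truth table of target = r1 OR r2, with input 11 never observed
tt = GeneralizedTruthTable(
    target=2, regulators=(0, 1),
    rows={0b00: 0, 0b01: 1, 0b10: 1},  # word bit i = state of regulator i
)
rule = minimize_qm(tt)
print("minimized rule for G3:", rule.to_string(["G1", "G2", "G3"]))
# The unobserved input combination is a don't-care, so the two specified
# 1-rows merge into the single-literal terms of an OR.

rules = [
    minimize_qm(GeneralizedTruthTable(0, (2,), rows={0: 1, 1: 0})),  # G1 = !G3
    minimize_qm(GeneralizedTruthTable(1, (0,), rows={0: 0, 1: 1})),  # G2 = G1
    rule,
]
bn = BooleanNetwork(rules, ["G1", "G2", "G3"])
traj = simulate(bn, np.array([1, 0, 0]), steps=5)
print("synchronous trajectory from (1,0,0):")
for state in traj:
    print(" ", state.tolist())
# Each row is the network state after one synchronous update of all genes.
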