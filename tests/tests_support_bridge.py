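"""Independent dense linear solve of the five-resistor bridge equations,
used as the oracle for the circuit module. The system is written directly
from the two loop equations, the collected serosal current, and the two
internal node laws (I3 oriented cell→lis), and solved with a general dense
routine — no reuse of the package's matrix."""

import numpy as np


def dense_bridge_solve(R1, R2, R3, R4, R5, dI):
    rows = []
    rhs = []
    # loop lumen -> cell -> lis -> lumen
    rows.append([R1, 0.0, R3, -R4, 0.0]); rhs.append(0.0)
    # loop cell -> lis -> serosa -> cell
    rows.append([0.0, -R2, R3, 0.0, R5]); rhs.append(0.0)
    # all injected current is collected at the serosal bath
    rows.append([0.0, 1.0, 0.0, 0.0, 1.0]); rhs.append(dI)
    # cell node and lis node
    rows.append([1.0, -1.0, -1.0, 0.0, 0.0]); rhs.append(0.0)
    rows.append([0.0, 0.0, 1.0, 1.0, -1.0]); rhs.append(0.0)
    A = np.asarray(rows, dtype=float)
    q, r = np.linalg.qr(A)  # dense orthogonal factorization
    return np.linalg.solve(r, q.T @ np.asarray(rhs))
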