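"""Independent brute-force oracles shared by the test suite."""

import numpy as np


def moran_absorption_oracle(matrix, invader, resident, n, intensity):
    """Absorption probability at fixation from the full (n+1)-state chain."""
    i, r = matrix.index(invader), matrix.index(resident)
    P_ = matrix.payoffs
    a, b, c, d = P_[i, i], P_[i, r], P_[r, i], P_[r, r]
    M = np.zeros((n + 1, n + 1))
    M[0, 0] = M[n, n] = 1.0
    for k in range(1, n):
        pi_i = (a * (k - 1) + b * (n - k)) / (n - 1)
        pi_r = (c * k + d * (n - k - 1)) / (n - 1)
        f_i = 1 - intensity + intensity * pi_i
        f_r = 1 - intensity + intensity * pi_r
        tot = k * f_i + (n - k) * f_r
        up = (k * f_i / tot) * ((n - k) / n)
        down = ((n - k) * f_r / tot) * (k / n)
        M[k, k + 1] = up
        M[k, k - 1] = down
        M[k, k] = 1 - up - down
    # absorption probabilities: solve (I - Q) h = R_fix on transient states
    h = np.linalg.solve(np.eye(n - 1) - M[1:n, 1:n], M[1:n, n])
    return h[0]
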