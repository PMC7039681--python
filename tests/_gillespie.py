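"""Independent continuous-time Gillespie oracle for the two-state promoter.

Simulates the exact jump process (promoter OFF<->ON at rates alpha/beta,
transcription at gamma while ON, unit-rate degradation) and records the mRNA
count at a fixed horizon T, long enough for stationarity (mRNA correlations
decay at the degradation rate, so T >> 1 suffices).  Used only as a test
oracle for the stationary Poisson-Beta sampler and pmf.
"""

import numba
import numpy as np


@numba.njit(cache=True)
def _simulate_one(alpha, beta, gamma, T, on, m, seed_state):
    t = 0.0
    while True:
        r_switch = alpha if on == 0 else beta
        r_tx = gamma if on == 1 else 0.0
        r_deg = float(m)
        total = r_switch + r_tx + r_deg
        dt = np.random.exponential(1.0 / total) if total > 0 else T
        if t + dt >= T:
            return m
        t += dt
        u = np.random.random() * total
        if u < r_switch:
            on = 1 - on
        elif u < r_switch + r_tx:
            m += 1
        else:
            m -= 1


@numba.njit(cache=True)
def gillespie_stationary_sample(alpha, beta, gamma, n_samples, T, seed):
    """n_samples independent stationary draws of the telegraph mRNA count."""
    np.random.seed(seed)
    p_on = alpha / (alpha + beta)
    out = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        on = 1 if np.random.random() < p_on else 0
        out[i] = _simulate_one(alpha, beta, gamma, T, on, 0, 0)
    return out


def total_variation(a, b):
    """TV distance between the empirical distributions of two count samples."""
    a = np.asarray(a)
    b = np.asarray(b)
    hi = int(max(a.max(), b.max())) + 1
    pa = np.bincount(a, minlength=hi) / a.size
    pb = np.bincount(b, minlength=hi) / b.size
    return 0.5 * float(np.abs(pa - pb).sum())
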