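"""Independent oracle implementations used only by the tests.

These deliberately share no code with the package's simulation or fitting
paths: an event-driven (exact exponential waiting time) two-state sampler,
a numeric ODE integrator for the FRAP bleach/recovery system, and
brute-force per-pixel summation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def event_driven_occupancy(kon: float, koff: float, c: float, duration: float,
                           frame_rate: float, n_sites: int,
                           rng: np.random.Generator,
                           p0: float = 0.0) -> np.ndarray:
    """Exact continuous-time two-state simulation, sampled at frame times.

    Each site independently alternates exponential dwell times: empty with
    rate ``kon*c`` to bound, bound with rate ``koff`` to empty.  Returns
    the bound-site count per frame, shape ``(n_frames,)``.
    """
    n_frames = int(np.floor(duration * frame_rate)) + 1
    times = np.arange(n_frames) / frame_rate
    counts = np.zeros(n_frames, dtype=np.int64)
    k_on_eff = kon * c
    for _ in range(n_sites):
        bound = rng.random() < p0
        t = 0.0
        idx = 0
        while t <= duration:
            rate = koff if bound else k_on_eff
            if rate <= 0:
                dwell = np.inf
            else:
                dwell = rng.exponential(1.0 / rate)
            t_next = t + dwell
            # record current state for all frames before the transition
            nxt = np.searchsorted(times, min(t_next, duration), side="right")
            if bound:
                counts[idx:nxt] += 1
            idx = nxt
            t = t_next
            bound = not bound
    return counts


def frap_recovery_ode(kon: float, koff: float, c: float,
                      times: np.ndarray) -> np.ndarray:
    """Fluorescent-bound fraction after an instantaneous full bleach.

    Three-state system (empty E, fluorescent-bound F, bleached-bound B),
    starting from the pre-pulse steady state with all bound molecules
    bleached: E' = -kon*c*E + koff*(F+B); F' = kon*c*E - koff*F;
    B' = -koff*B.  Integrated numerically, no closed form used.
    """
    kc = kon * c
    b_star = kc / (kc + koff)

    def rhs(_t, y):
        e, f, b = y
        return [-kc * e + koff * (f + b), kc * e - koff * f, -koff * b]

    sol = solve_ivp(rhs, (times[0], times[-1]), [1.0 - b_star, 0.0, b_star],
                    t_eval=times, rtol=1e-10, atol=1e-12)
    return sol.y[1]


def brute_force_roi_sum(stack: np.ndarray, x0: int, x1: int,
                        y0: int, y1: int) -> np.ndarray:
    """Per-frame ROI sum by explicit python loops over pixels."""
    out = np.zeros(stack.shape[0], dtype=np.int64)
    for f in range(stack.shape[0]):
        s = 0
        for y in range(y0, y1):
            for x in range(x0, x1):
                s += int(stack[f, y, x])
        out[f] = s
    return out


def student_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook equal-variance two-sample two-sided t-test, via the formula."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    tstat = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return float(2 * tdist.sf(abs(tstat), df))
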