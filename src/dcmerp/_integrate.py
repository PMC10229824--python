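"""Compiled fixed-step integrator for the coupled delay system.

All coupling between populations is delayed by at least one integration
step, so each receptor channel reduces to a linear second-order system
driven by a known (piecewise-linear) input over one step; the first-order
hold discretization is then exact per channel and the only approximation
is the sampling of the sigmoid rates and the linear interpolation of the
delayed state history.
"""

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _drive(k, n_pop, c_from, c_to, c_ch, c_gain, c_delay, ex_in, Vhist, r, linearize):
    """Synaptic drive u[pop, channel] at step k from delayed history."""
    u = np.zeros((n_pop, 2))
    for c in range(c_from.shape[0]):
        s = k - c_delay[c]
        if s <= 0.0:
            continue
        i0 = int(np.floor(s))
        w = s - i0
        if w > 0.0:
            Vd = (1.0 - w) * Vhist[i0, c_from[c]] + w * Vhist[i0 + 1, c_from[c]]
        else:
            Vd = Vhist[i0, c_from[c]]
        if linearize == 1:
            rate = 0.25 * r * Vd
        else:
            rate = 1.0 / (1.0 + np.exp(-r * Vd)) - 0.5
        u[c_to[c], c_ch[c]] += c_gain[c] * rate
    for p in range(n_pop):
        u[p, 0] += ex_in[k, p]
    return u


@njit(cache=True)
def integrate(n_steps, n_pop, Ad, B0, B1, c_from, c_to, c_ch, c_gain, c_delay,
              ex_in, r, linearize):
    """Advance the full system; returns composite V history (n_steps+1, n_pop)."""
    x = np.zeros((n_pop, 2, 2))  # (population, channel, [V, dV/dt])
    Vhist = np.zeros((n_steps + 1, n_pop))
    u_cur = _drive(0, n_pop, c_from, c_to, c_ch, c_gain, c_delay, ex_in, Vhist,
                   r, linearize)
    for k in range(n_steps):
        # delayed terms at k+1 reference history at or before step k
        u_next = _drive(k + 1, n_pop, c_from, c_to, c_ch, c_gain, c_delay,
                        ex_in, Vhist, r, linearize)
        for p in range(n_pop):
            for ch in range(2):
                v = x[p, ch, 0]
                w = x[p, ch, 1]
                x[p, ch, 0] = (Ad[p, ch, 0, 0] * v + Ad[p, ch, 0, 1] * w
                               + B0[p, ch, 0] * u_cur[p, ch] + B1[p, ch, 0] * u_next[p, ch])
                x[p, ch, 1] = (Ad[p, ch, 1, 0] * v + Ad[p, ch, 1, 1] * w
                               + B0[p, ch, 1] * u_cur[p, ch] + B1[p, ch, 1] * u_next[p, ch])
            Vhist[k + 1, p] = x[p, 0, 0] + x[p, 1, 0]
            if not np.isfinite(Vhist[k + 1, p]):
                Vhist[k + 1 :, p] = np.nan
                return Vhist
        u_cur = u_next
    return Vhist
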