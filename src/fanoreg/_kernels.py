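"""Tight inner loops for the exact (direct-method) Gillespie simulators.

Compiled with numba when available; the pure-Python fallback runs the same
code paths unchanged (the decorator becomes a no-op), so small workloads
stay correct without the JIT.  Each kernel seeds NumPy's global/legacy RNG
once, which numba maps to its own per-thread generator -- identical
(model, plan, seed) inputs therefore reproduce bit-for-bit on a given
backend.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


@njit(cache=True)
def bd_endpoints(birth, death, x0, t_end, n_cells, seed):
    """Endpoint states of ``n_cells`` independent birth-death trajectories.

    ``birth[n]`` is the propensity of ``n -> n+1`` (zero at the cap by
    construction), ``death[n]`` the total propensity of ``n -> n-1``.
    Returns the endpoint array and the number of arrivals at the cap.
    """
    np.random.seed(seed)
    cap = birth.shape[0] - 1
    out = np.empty(n_cells, dtype=np.int64)
    cap_hits = 0
    for c in range(n_cells):
        x = x0
        t = 0.0
        while True:
            a_birth = birth[x]
            a_total = a_birth + death[x]
            if a_total <= 0.0:
                break  # absorbing state; endpoint is x
            t += np.random.exponential(1.0 / a_total)
            if t >= t_end:
                break
            if np.random.random() * a_total < a_birth:
                x += 1
                if x >= cap:
                    cap_hits += 1
            else:
                x -= 1
        out[c] = x
    return out, cap_hits


@njit(cache=True)
def bd_thinned(birth, death, x0, burn_in, spacing, n_samples, seed):
    """Thinned samples along one birth-death trajectory, ``spacing`` apart."""
    np.random.seed(seed)
    cap = birth.shape[0] - 1
    out = np.empty(n_samples, dtype=np.int64)
    cap_hits = 0
    x = x0
    t = 0.0
    next_sample = burn_in
    k = 0
    while k < n_samples:
        a_birth = birth[x]
        a_total = a_birth + death[x]
        if a_total <= 0.0:
            while k < n_samples:
                out[k] = x
                k += 1
            break
        dt = np.random.exponential(1.0 / a_total)
        while k < n_samples and t + dt >= next_sample:
            out[k] = x
            k += 1
            next_sample += spacing
        t += dt
        if np.random.random() * a_total < a_birth:
            x += 1
            if x >= cap:
                cap_hits += 1
        else:
            x -= 1
    return out, cap_hits


@njit(cache=True)
def multistep_endpoints(k_stages, stage_rate, deg_rate, t_end, n_cells, seed):
    """Endpoint mRNA counts for the k-stage cycle model.

    The gene advances through ``k_stages`` exponential stages at
    ``stage_rate`` each; completing the last stage resets the cycle and
    releases one transcript.  Each transcript decays at ``deg_rate``.
    """
    np.random.seed(seed)
    out = np.empty(n_cells, dtype=np.int64)
    for c in range(n_cells):
        stage = 0
        m = 0
        t = 0.0
        while True:
            a_stage = stage_rate
            a_deg = deg_rate * m
            a_total = a_stage + a_deg
            t += np.random.exponential(1.0 / a_total)
            if t >= t_end:
                break
            if np.random.random() * a_total < a_stage:
                stage += 1
                if stage == k_stages:
                    stage = 0
                    m += 1
            else:
                m -= 1
        out[c] = m
    return out


@njit(cache=True)
def telegraph_endpoints(k_on, k_off, rho_on, rho_off, deg, t_end, n_cells, seed):
    """Endpoint mRNA counts for the two-state (on/off) transcription model."""
    np.random.seed(seed)
    out = np.empty(n_cells, dtype=np.int64)
    for c in range(n_cells):
        on = True
        m = 0
        t = 0.0
        while True:
            a_switch = k_off if on else k_on
            a_tx = rho_on if on else rho_off
            a_deg = deg * m
            a_total = a_switch + a_tx + a_deg
            if a_total <= 0.0:
                break
            t += np.random.exponential(1.0 / a_total)
            if t >= t_end:
                break
            u = np.random.random() * a_total
            if u < a_switch:
                on = not on
            elif u < a_switch + a_tx:
                m += 1
            else:
                m -= 1
        out[c] = m
    return out
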