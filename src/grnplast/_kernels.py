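"""JIT-compiled Euler integrators for the regulatory dynamics.

Both kernels integrate  dg_i/dt = R(h_i)/(K_M + R(h_i)) - mu*g_i  with
the Ramp function R and declare a per-environment steady state when
every gene's concentration change over a window of Euler steps is at
most ``tol * max(g_i, floor)``.  The per-gene relative test (rather
than normalising by the largest concentration in the snapshot) keeps a
gene that is still drifting through the phenotype-readout region from
being frozen prematurely just because another gene is large; ``floor``
is therefore set at the phenotype threshold.  A fully decayed network
passes the test once every concentration is far below the floor.
Batched over environments so an entire reaction norm is integrated in
one call.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def integrate_classical(
    B, env_input, g, mu, km, dt, max_steps, window, tol, floor
):  # pragma: no cover - exercised through dynamics.develop
    """Integrate the matrix model for each environment in the batch.

    B          : (ng, ng) interaction matrix, B[i, j] = effect of j on i.
    env_input  : (n_env, ng) additive environmental input per gene.
    g          : (n_env, ng) initial concentrations, overwritten in place
                 with the final state.
    Returns (stable flags, steps used, minimum concentration seen).
    """
    n_env, ng = g.shape
    stable = np.zeros(n_env, np.bool_)
    steps = np.zeros(n_env, np.int64)
    g_min = np.zeros(n_env, np.float64)
    tmp = np.empty(ng, np.float64)
    prev = np.empty(ng, np.float64)
    for e in range(n_env):
        ge = g[e]
        mn = ge[0]
        for i in range(ng):
            if ge[i] < mn:
                mn = ge[i]
        for i in range(ng):
            prev[i] = ge[i]
        ok = False
        n = 0
        while n < max_steps:
            for i in range(ng):
                h = env_input[e, i]
                for j in range(ng):
                    h += B[i, j] * ge[j]
                if h > 0.0:
                    prod = h / (km + h)
                else:
                    prod = 0.0
                tmp[i] = ge[i] + dt * (prod - mu * ge[i])
            for i in range(ng):
                ge[i] = tmp[i]
                if ge[i] < mn:
                    mn = ge[i]
            n += 1
            if n % window == 0:
                settled = True
                for i in range(ng):
                    scale = ge[i] if ge[i] > floor else floor
                    if abs(ge[i] - prev[i]) > tol * scale:
                        settled = False
                        break
                if settled:
                    ok = True
                    break
                for i in range(ng):
                    prev[i] = ge[i]
        stable[e] = ok
        steps[e] = n
        g_min[e] = mn
    return stable, steps, g_min


@njit(cache=False)
def integrate_tensor(
    B3, ef_pad, g, mu, km, dt, max_steps, window, tol, floor
):  # pragma: no cover - exercised through dynamics.develop
    """Integrate the second-order (tensor) model for each environment.

    B3     : (ng, ng, ng) tensor, B3[i, j, k] = contribution of gene k to
             the j -> i interaction strength.
    ef_pad : (n_env, ng) environmental factors padded with zeros beyond
             the first ne genes; they modulate interactions via
             u_k = g_k + EF_k.
    """
    n_env, ng = g.shape
    stable = np.zeros(n_env, np.bool_)
    steps = np.zeros(n_env, np.int64)
    g_min = np.zeros(n_env, np.float64)
    tmp = np.empty(ng, np.float64)
    prev = np.empty(ng, np.float64)
    u = np.empty(ng, np.float64)
    for e in range(n_env):
        ge = g[e]
        mn = ge[0]
        for i in range(ng):
            if ge[i] < mn:
                mn = ge[i]
        for i in range(ng):
            prev[i] = ge[i]
        ok = False
        n = 0
        while n < max_steps:
            for k in range(ng):
                u[k] = ge[k] + ef_pad[e, k]
            for i in range(ng):
                h = 0.0
                for j in range(ng):
                    s = 0.0
                    for k in range(ng):
                        s += B3[i, j, k] * u[k]
                    h += ge[j] * s
                if h > 0.0:
                    prod = h / (km + h)
                else:
                    prod = 0.0
                tmp[i] = ge[i] + dt * (prod - mu * ge[i])
            for i in range(ng):
                ge[i] = tmp[i]
                if ge[i] < mn:
                    mn = ge[i]
            n += 1
            if n % window == 0:
                settled = True
                for i in range(ng):
                    scale = ge[i] if ge[i] > floor else floor
                    if abs(ge[i] - prev[i]) > tol * scale:
                        settled = False
                        break
                if settled:
                    ok = True
                    break
                for i in range(ng):
                    prev[i] = ge[i]
        stable[e] = ok
        steps[e] = n
        g_min[e] = mn
    return stable, steps, g_min
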