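"""Numba-compiled fixed-step RK4 integrators for the circuit ODE systems.

Two kernels: a generic connection-list integrator used by the laminar
circuit (one second-order transform per connection, optional vesicle pool
per excitatory connection, extrinsic input injected into a designated
transform), and a compact integrator for the classical three-transform
Jansen–Rit topology.  Both advance at a fixed step (1 ms by default) and
record population membrane potentials and pool occupancies at every step.

All arguments are plain scalars/arrays so the kernels cache cleanly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_CLIP = 700.0


@njit(cache=True, fastmath=False)
def _sig(u, e0, r, u0, offset):
    a = r * (u0 - u)
    if a > _EXP_CLIP:
        a = _EXP_CLIP
    elif a < -_EXP_CLIP:
        a = -_EXP_CLIP
    return 2.0 * e0 / (1.0 + np.exp(a)) - offset


@njit(cache=True, fastmath=False)
def _input_rate(t, onsets, P0, w, n):
    s = 0.0
    for k in range(onsets.shape[0]):
        d = t - onsets[k]
        if d > 0.0:
            x = d / w
            if x < n + 80.0:  # tail below ~1e-12 of peak
                s += P0 * x**n * np.exp(-x)
    return s


@njit(cache=True, fastmath=False)
def _lccm_deriv(
    t, y, z, A, dy, dz, dA, u, S,
    src, tgt, sign, C, tau, H, hab,
    pool_src, n1, n2,
    input_idx, C1, P0, w, nexp, onsets,
    e0, r, u0, offset, Qmax, n_pop,
):
    ncon = src.shape[0]
    for p in range(n_pop):
        u[p] = 0.0
    for c in range(ncon):
        u[tgt[c]] += sign[c] * y[c]
    for p in range(n_pop):
        S[p] = _sig(u[p], e0, r, u0, offset)
    for c in range(ncon):
        q = C[c] * S[src[c]]
        if hab[c] >= 0:
            q *= A[hab[c]]
        if c == input_idx:
            q += C1 * _input_rate(t, onsets, P0, w, nexp)
        dy[c] = z[c]
        dz[c] = (H[c] / tau[c]) * q - (2.0 / tau[c]) * z[c] - y[c] / (tau[c] * tau[c])
    for j in range(pool_src.shape[0]):
        Q = S[pool_src[j]]
        if Q < 0.0:
            Q = 0.0
        dA[j] = n2[j] * (1.0 - A[j]) - n1[j] * (Q / Qmax) * A[j]


@njit(cache=True, fastmath=False)
def integrate_lccm(
    src, tgt, sign, C, tau, H, hab, pool_src, n1, n2,
    input_idx, C1, P0, w, nexp, onsets,
    e0, r, u0, Qmax,
    t0, dt, nt, n_pop,
):
    """RK4 trajectory; returns (u_traj [nt, n_pop], A_traj [nt, n_pool])."""
    ncon = src.shape[0]
    npool = pool_src.shape[0]
    offset = 2.0 * e0 / (1.0 + np.exp(min(r * u0, _EXP_CLIP)))

    y = np.zeros(ncon)
    z = np.zeros(ncon)
    A = np.ones(npool)
    u = np.zeros(n_pop)
    S = np.zeros(n_pop)

    k1y = np.zeros(ncon); k1z = np.zeros(ncon); k1A = np.zeros(npool)
    k2y = np.zeros(ncon); k2z = np.zeros(ncon); k2A = np.zeros(npool)
    k3y = np.zeros(ncon); k3z = np.zeros(ncon); k3A = np.zeros(npool)
    k4y = np.zeros(ncon); k4z = np.zeros(ncon); k4A = np.zeros(npool)

    u_traj = np.zeros((nt, n_pop))
    A_traj = np.zeros((nt, npool))

    for i in range(nt):
        t = t0 + i * dt
        # record state before stepping
        for p in range(n_pop):
            u[p] = 0.0
        for c in range(ncon):
            u[tgt[c]] += sign[c] * y[c]
        for p in range(n_pop):
            u_traj[i, p] = u[p]
        for j in range(npool):
            A_traj[i, j] = A[j]
        if i == nt - 1:
            break

        _lccm_deriv(t, y, z, A, k1y, k1z, k1A, u, S, src, tgt, sign, C, tau, H, hab,
                    pool_src, n1, n2, input_idx, C1, P0, w, nexp, onsets,
                    e0, r, u0, offset, Qmax, n_pop)
        _lccm_deriv(t + 0.5 * dt, y + 0.5 * dt * k1y, z + 0.5 * dt * k1z, A + 0.5 * dt * k1A,
                    k2y, k2z, k2A, u, S, src, tgt, sign, C, tau, H, hab,
                    pool_src, n1, n2, input_idx, C1, P0, w, nexp, onsets,
                    e0, r, u0, offset, Qmax, n_pop)
        _lccm_deriv(t + 0.5 * dt, y + 0.5 * dt * k2y, z + 0.5 * dt * k2z, A + 0.5 * dt * k2A,
                    k3y, k3z, k3A, u, S, src, tgt, sign, C, tau, H, hab,
                    pool_src, n1, n2, input_idx, C1, P0, w, nexp, onsets,
                    e0, r, u0, offset, Qmax, n_pop)
        _lccm_deriv(t + dt, y + dt * k3y, z + dt * k3z, A + dt * k3A,
                    k4y, k4z, k4A, u, S, src, tgt, sign, C, tau, H, hab,
                    pool_src, n1, n2, input_idx, C1, P0, w, nexp, onsets,
                    e0, r, u0, offset, Qmax, n_pop)

        for c in range(ncon):
            y[c] += dt / 6.0 * (k1y[c] + 2.0 * k2y[c] + 2.0 * k3y[c] + k4y[c])
            z[c] += dt / 6.0 * (k1z[c] + 2.0 * k2z[c] + 2.0 * k3z[c] + k4z[c])
        for j in range(npool):
            A[j] += dt / 6.0 * (k1A[j] + 2.0 * k2A[j] + 2.0 * k3A[j] + k4A[j])

    return u_traj, A_traj


@njit(cache=True, fastmath=False)
def _jrm_deriv(
    t, s, A, ds, dA,
    C_pe, C_ep, C_pi, C_ip, tau0, tau1, tau2, He, Hi,
    hab0, hab1, n1, n2,
    C1, P0, w, nexp, onsets,
    e0, r, u0, offset, Qmax,
):
    # s = (y0, z0, y1, z1, y2, z2); transform 0: PC output (drives EIN & IIN),
    # transform 1: excitatory input to PC, transform 2: inhibitory input to PC
    u_pc = s[2] - s[4]
    u_ein = C_pe * s[0]
    u_iin = C_pi * s[0]
    S_pc = _sig(u_pc, e0, r, u0, offset)
    S_ein = _sig(u_ein, e0, r, u0, offset)
    S_iin = _sig(u_iin, e0, r, u0, offset)

    q0 = S_pc
    if hab0:
        q0 *= A[0]
    q1 = C_ep * S_ein
    if hab1:
        q1 *= A[1]
    q1 += C1 * _input_rate(t, onsets, P0, w, nexp)
    q2 = C_ip * S_iin

    ds[0] = s[1]
    ds[1] = (He / tau0) * q0 - (2.0 / tau0) * s[1] - s[0] / (tau0 * tau0)
    ds[2] = s[3]
    ds[3] = (He / tau1) * q1 - (2.0 / tau1) * s[3] - s[2] / (tau1 * tau1)
    ds[4] = s[5]
    ds[5] = (Hi / tau2) * q2 - (2.0 / tau2) * s[5] - s[4] / (tau2 * tau2)

    Q0 = S_pc if S_pc > 0.0 else 0.0
    Q1 = S_ein if S_ein > 0.0 else 0.0
    dA[0] = n2[0] * (1.0 - A[0]) - n1[0] * (Q0 / Qmax) * A[0] if hab0 else 0.0
    dA[1] = n2[1] * (1.0 - A[1]) - n1[1] * (Q1 / Qmax) * A[1] if hab1 else 0.0


@njit(cache=True, fastmath=False)
def integrate_jrm(
    C_pe, C_ep, C_pi, C_ip, tau0, tau1, tau2, He, Hi,
    hab0, hab1, n1, n2,
    C1, P0, w, nexp, onsets,
    e0, r, u0, Qmax,
    t0, dt, nt,
):
    """RK4 trajectory; returns (u_traj [nt, 3] = (EIN, PC, IIN), A_traj [nt, 2])."""
    offset = 2.0 * e0 / (1.0 + np.exp(min(r * u0, _EXP_CLIP)))
    s = np.zeros(6)
    A = np.ones(2)
    k1s = np.zeros(6); k1A = np.zeros(2)
    k2s = np.zeros(6); k2A = np.zeros(2)
    k3s = np.zeros(6); k3A = np.zeros(2)
    k4s = np.zeros(6); k4A = np.zeros(2)
    u_traj = np.zeros((nt, 3))
    A_traj = np.zeros((nt, 2))

    for i in range(nt):
        t = t0 + i * dt
        u_traj[i, 0] = C_pe * s[0]
        u_traj[i, 1] = s[2] - s[4]
        u_traj[i, 2] = C_pi * s[0]
        A_traj[i, 0] = A[0]
        A_traj[i, 1] = A[1]
        if i == nt - 1:
            break

        _jrm_deriv(t, s, A, k1s, k1A, C_pe, C_ep, C_pi, C_ip, tau0, tau1, tau2,
                   He, Hi, hab0, hab1, n1, n2, C1, P0, w, nexp, onsets,
                   e0, r, u0, offset, Qmax)
        _jrm_deriv(t + 0.5 * dt, s + 0.5 * dt * k1s, A + 0.5 * dt * k1A, k2s, k2A,
                   C_pe, C_ep, C_pi, C_ip, tau0, tau1, tau2,
                   He, Hi, hab0, hab1, n1, n2, C1, P0, w, nexp, onsets,
                   e0, r, u0, offset, Qmax)
        _jrm_deriv(t + 0.5 * dt, s + 0.5 * dt * k2s, A + 0.5 * dt * k2A, k3s, k3A,
                   C_pe, C_ep, C_pi, C_ip, tau0, tau1, tau2,
                   He, Hi, hab0, hab1, n1, n2, C1, P0, w, nexp, onsets,
                   e0, r, u0, offset, Qmax)
        _jrm_deriv(t + dt, s + dt * k3s, A + dt * k3A, k4s, k4A,
                   C_pe, C_ep, C_pi, C_ip, tau0, tau1, tau2,
                   He, Hi, hab0, hab1, n1, n2, C1, P0, w, nexp, onsets,
                   e0, r, u0, offset, Qmax)

        for j in range(6):
            s[j] += dt / 6.0 * (k1s[j] + 2.0 * k2s[j] + 2.0 * k3s[j] + k4s[j])
        for j in range(2):
            A[j] += dt / 6.0 * (k1A[j] + 2.0 * k2A[j] + 2.0 * k3A[j] + k4A[j])

    return u_traj, A_traj
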