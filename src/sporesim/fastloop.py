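"""Compiled inner loop for the reaching task.

One call advances the closed loop by one slow interval (100 fast steps):
render, event camera, spike encoding, network, fast plasticity traces, motor
decoding, environment and reward — all inside a single JIT-compiled kernel so
that half-hour desk-scale runs finish in seconds.  The kernel consumes
pre-drawn uniform variates and a pre-drawn pool of reset positions, which
makes it bit-reproducible from the run seed and lets the plain-NumPy
reference loop (``sporesim.experiment``) replay the identical trajectory; an
equivalence test holds the two engines together.

State arrays are mutated in place; slow parameter updates, annealing and
snapshotting stay outside in Python.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["reaching_chunk"]


@njit(cache=True)
def reaching_chunk(steps, ball, ref, centers, centers_row, w_inh,
                   y_in, scalars, w_eff, w3, e3, g3, a, cosb, sinb,
                   uniforms, pool, pool_idx, rewards, resets, plastic,
                   dt, limit, target_r2, ball_radius, pixel_size,
                   threshold, decay_psp, decay_a, inv_tau_e, inv_tau_g,
                   tau_r, rho0, delta_u, u_cap, p_noise, w_noise,
                   w_exp_motor, v_gain, v_lim, beta_lim, r_coef, r_exp):
    n = centers.shape[0]
    n_vis = n * n
    n_in = y_in.shape[0]
    n_motor = a.shape[0]
    mult = w3.shape[2]
    row_counts = np.empty(n, dtype=np.int64)
    col_counts = np.empty(n, dtype=np.int64)
    vis_counts = np.empty(n_vis, dtype=np.int64)
    dz = np.empty(n_motor)
    spikes = np.empty(n_motor)

    for k in range(steps):
        # --- render the ball disc and run the event-camera diff ---
        for i in range(n):
            row_counts[i] = 0
            col_counts[i] = 0
        for r in range(n):
            dy = centers_row[r] - ball[1]
            for c in range(n):
                dx = centers[c] - ball[0]
                val = (math.sqrt(dx * dx + dy * dy) - ball_radius) / pixel_size + 0.5
                if val < 0.0:
                    val = 0.0
                elif val > 1.0:
                    val = 1.0
                cnt = 0
                if abs(val - ref[r, c]) > threshold:
                    ref[r, c] = val
                    cnt = 1
                vis_counts[r * n + c] = cnt
                row_counts[r] += cnt
                col_counts[c] += cnt
        # --- input PSP traces (visual, then row-axis, then column-axis) ---
        for i in range(n_vis):
            y_in[i] = y_in[i] * decay_psp + vis_counts[i]
        for i in range(n):
            y_in[n_vis + i] = y_in[n_vis + i] * decay_psp + row_counts[i]
            y_in[n_vis + n + i] = y_in[n_vis + n + i] * decay_psp + col_counts[i]
        # --- exploration chain: noise source -> exploration neuron ---
        noise_spike = 1.0 if uniforms[k, 0] < p_noise else 0.0
        scalars[0] = scalars[0] * decay_psp + noise_spike
        u_exp = w_noise * scalars[0] + np.dot(w_inh, y_in[:n_vis])
        if u_exp > u_cap:
            u_exp = u_cap
        rho_exp = rho0 * math.exp(u_exp / delta_u)
        exp_spike = 1.0 if uniforms[k, 1] < 1.0 - math.exp(-rho_exp * dt) else 0.0
        scalars[1] = scalars[1] * decay_psp + exp_spike
        # --- motor potentials, rates, spikes ---
        for m in range(n_motor):
            u = w_exp_motor * scalars[1]
            for i in range(n_in):
                u += w_eff[i, m] * y_in[i]
            if u > u_cap:
                u = u_cap
            rho = rho0 * math.exp(u / delta_u)
            p_spike = 1.0 - math.exp(-rho * dt)
            s = 1.0 if uniforms[k, 2 + m] < p_spike else 0.0
            spikes[m] = s
            # compensator = spike probability of the sampled Bernoulli process,
            # keeping the eligibility spike term exactly mean-zero at any rate
            dz[m] = s - p_spike
        # --- fast plasticity traces with the smoothed global reward ---
        if plastic:
            r_sm = scalars[2]
            for i in range(n_in):
                yi = y_in[i]
                for m in range(n_motor):
                    dzm = dz[m]
                    for j in range(mult):
                        e = e3[i, m, j] + dt * (-e3[i, m, j] * inv_tau_e) \
                            + w3[i, m, j] * yi * dzm
                        e3[i, m, j] = e
                        g3[i, m, j] = g3[i, m, j] + dt * (-g3[i, m, j] * inv_tau_g
                                                          + r_sm * e)
        # --- motor activities and population-vector command ---
        vx = 0.0
        vy = 0.0
        for m in range(n_motor):
            a[m] = a[m] * decay_a + spikes[m]
            vx += cosb[m] * a[m]
            vy += sinb[m] * a[m]
        vx *= v_gain
        vy *= v_gain
        # --- directional reward ---
        speed = math.hypot(vx, vy)
        reward = 0.0
        if speed > v_lim:
            gx = -ball[0]
            gy = -ball[1]
            gnorm = math.hypot(gx, gy)
            r_beta = 0.0
            if gnorm >= 1e-12:
                cosang = (vx * gx + vy * gy) / (speed * gnorm)
                if cosang > 1.0:
                    cosang = 1.0
                elif cosang < -1.0:
                    cosang = -1.0
                berr = math.acos(cosang)
                if berr < beta_lim:
                    r_beta = 1.0 - berr / beta_lim
            reward = r_coef * speed * (r_beta + 1.0) ** r_exp
        # --- environment step with wall clamping and goal reset ---
        ball[0] = min(max(ball[0] + vx * dt, -limit), limit)
        ball[1] = min(max(ball[1] + vy * dt, -limit), limit)
        if ball[0] * ball[0] + ball[1] * ball[1] <= target_r2:
            idx = pool_idx[0] % pool.shape[0]
            ball[0] = pool[idx, 0]
            ball[1] = pool[idx, 1]
            pool_idx[0] += 1
            resets[k] = 1
        rewards[k] = reward
        scalars[2] = scalars[2] + (dt / tau_r) * (reward - scalars[2])
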