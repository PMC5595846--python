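"""Numba inner loop of the instrument twin.

One control step (duration ``dtc``, typically 0.1 ms) performs, in order:

1. controller update (position ramp, or gain-scheduled PI on load error
   driving piezo velocity) using the load *measured* on the previous step;
2. optional stick-slip transmission between commanded piezo position and
   effective probe base position (needle-shaft friction artifact);
3. quasi-static force balance: solve ``k d = F_contact(h)`` for the
   cantilever deflection d, with ``h = p - d - z_surface`` and the contact
   force given by the hereditary Hertz form
   ``F = c_geom (G_tot eps + memory)``, ``eps = h^(3/2)``,
   each Maxwell branch advanced by its exact exponential update;
4. measurement: ``d_meas = sens * d + noise + drift``, ``F_meas = k d_meas``;
5. optional debounced contact detection (approach segments);
6. decimated recording of (z_p, d_meas, h_true).

The gain-scheduled PI uses the twin's own plant linearization
``g = k S / (k + S)`` (series springs, S the instantaneous contact
stiffness), so a fixed fraction ``alpha`` of the load error is corrected per
step regardless of sample stiffness; this keeps the closed-loop time constant
at ``dtc / alpha`` across the supported modulus range.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_POSITION = 0
MODE_LOAD = 1

FAULT_NONE = 0
FAULT_RANGE = 1  # load setpoint unreachable within piezo travel
FAULT_DIVERGED = 2  # deflection diverged / non-finite

# State vector layout (mutated in place by integrate_segment).
IDX_ZP = 0  # commanded piezo position [m]
IDX_P = 1  # effective probe base position after stick-slip [m]
IDX_EPS = 2  # contact strain h^(3/2) [m^1.5]
IDX_INTEG = 3  # PI integrator [N s]
IDX_U = 4  # indentation depth h [m]
IDX_FMEAS = 5  # last measured load [N]
IDX_STUCK = 6  # stick-slip friction state (1.0 = stuck)
IDX_DWELL = 7  # consecutive slow-command steps (junction formation timer)
IDX_VAVG = 8  # smoothed commanded carriage velocity [m/s]
STATE_SIZE = 9


@njit(cache=True)
def _solve_depth(depth_max, k, c_geom, g_tot, c0, u_start):
    """Root of ``k (depth_max - u) - c_geom (g_tot u^1.5 + c0) = 0`` on [0, depth_max].

    Safeguarded Newton (the residual is strictly decreasing in u).
    """
    lo = 0.0
    hi = depth_max
    u = u_start
    if u <= lo or u >= hi:
        u = 0.5 * hi
    for _ in range(60):
        f = k * (depth_max - u) - c_geom * (g_tot * u**1.5 + c0)
        if f > 0.0:
            lo = u
        else:
            hi = u
        fp = -k - c_geom * g_tot * 1.5 * np.sqrt(u)
        step = f / fp
        u_new = u - step
        if u_new <= lo or u_new >= hi:
            u_new = 0.5 * (lo + hi)
        if abs(u_new - u) < 1e-16 + 1e-13 * u_new:
            u = u_new
            break
        u = u_new
    return u


@njit(cache=True)
def integrate_segment(
    mode,
    setpoint,  # float64[n] load setpoints [N] (LOAD mode)
    speed,  # piezo velocity [m/s] (POSITION mode)
    n_steps,
    dtc,
    # probe / plant
    k,
    sens,
    c_geom,  # 8 sqrt(R) / (3 (1 - nu))
    rigid,  # glass substrate: h == 0, d = max(p - z_surface, 0)
    g_e,
    branch_decay,  # exp(-dtc/tau_i)
    branch_gain,  # G_i (tau_i/dtc) (1 - exp(-dtc/tau_i))
    sigma,  # float64[nb] branch stresses, mutated
    b_sum,  # sum(branch_gain) + eta/dtc
    z_surface,
    travel,
    v_max,
    # controller
    alpha,
    t_i,
    g_floor,
    integ_limit,
    n_fault,
    # measurement
    noise,  # float64[n] deflection noise [m]
    drift_rate,
    t0,
    # stick-slip transmission
    ss_on,
    ss_v_stick,
    ss_breakaway,
    ss_n_dwell,
    ss_v_beta,  # EMA coefficient of the smoothed commanded velocity
    # contact detection
    detect,
    f_threshold,
    n_debounce,
    # state and outputs
    state,  # float64[STATE_SIZE], mutated
    decim,
    gstep0,
    rec_zp,
    rec_d,
    rec_h,
):
    """Integrate one protocol segment; see module docstring for the step order.

    Returns ``(n_recorded, n_done, detect_step, fault)`` where ``detect_step``
    is the first control step of the debounced threshold run (-1 if none) and
    ``n_done`` the number of control steps executed (< n_steps only on early
    stop at contact or on fault).
    """
    z_p = state[IDX_ZP]
    p = state[IDX_P]
    eps = state[IDX_EPS]
    integ = state[IDX_INTEG]
    u = state[IDX_U]
    f_meas = state[IDX_FMEAS]
    stuck = state[IDX_STUCK] > 0.5
    dwell = int(state[IDX_DWELL])
    v_avg = state[IDX_VAVG]
    nb = sigma.shape[0]
    g_tot = g_e + b_sum

    n_rec = 0
    fault = FAULT_NONE
    clamp_count = 0
    above_count = 0
    detect_step = -1
    n_done = 0

    for i in range(n_steps):
        t_abs = t0 + i * dtc
        # -- 1. controller --------------------------------------------------
        if mode == MODE_POSITION:
            dz = speed * dtc
        else:
            err = setpoint[i] - f_meas
            integ += err * dtc
            if integ > integ_limit:
                integ = integ_limit
            elif integ < -integ_limit:
                integ = -integ_limit
            if rigid:
                g_plant = k
            else:
                s_contact = c_geom * g_tot * 1.5 * np.sqrt(u)
                g_plant = k * s_contact / (k + s_contact)
            if g_plant < g_floor:
                g_plant = g_floor
            dz = (alpha / g_plant) * (err + integ / t_i)
            v_lim = v_max * dtc
            if dz > v_lim:
                dz = v_lim
            elif dz < -v_lim:
                dz = -v_lim
        z_p += dz
        clamped = False
        if z_p < 0.0:
            z_p = 0.0
            clamped = True
        elif z_p > travel:
            z_p = travel
            clamped = True
        if mode == MODE_LOAD:
            if clamped:
                clamp_count += 1
                if clamp_count > n_fault:
                    fault = FAULT_RANGE
                    n_done = i
                    break
            else:
                clamp_count = 0

        # -- 2. stick-slip transmission ------------------------------------
        if ss_on:
            # Rate-state static friction on the smoothed carriage speed: the
            # junction only sets after the commanded speed has stayed below
            # v_stick for a dwell time (brief turning-point crossings at
            # high frequency never stick); once stuck, only transmission
            # wind-up beyond the breakaway distance releases the probe,
            # after which the junction must re-form from scratch.
            v_gate = dz / dtc
            # feedback wind-up spikes around slip events are not sliding;
            # clip them so they cannot reset the junction-formation timer
            v_cap = 3.0 * ss_v_stick
            if v_gate > v_cap:
                v_gate = v_cap
            elif v_gate < -v_cap:
                v_gate = -v_cap
            v_avg += ss_v_beta * (v_gate - v_avg)
            if stuck:
                if abs(z_p - p) > ss_breakaway:
                    # momentary slip; the junction re-forms immediately while
                    # the carriage is still slow, so dwell is NOT reset here
                    p = z_p
                    stuck = False
            else:
                if abs(v_avg) < ss_v_stick:
                    dwell += 1
                    if dwell >= ss_n_dwell:
                        stuck = True
                else:
                    dwell = 0
                if not stuck:
                    p = z_p
        else:
            p = z_p

        # -- 3. force balance ----------------------------------------------
        depth_max = p - z_surface
        if rigid:
            u = 0.0
            d = depth_max if depth_max > 0.0 else 0.0
        else:
            # memory part of the hereditary force at this step
            acc = 0.0
            for j in range(nb):
                acc += branch_decay[j] * sigma[j]
            c0 = acc - b_sum * eps
            if depth_max <= 0.0:
                u = 0.0
            else:
                u = _solve_depth(depth_max, k, c_geom, g_tot, c0, u)
            eps_new = u**1.5
            d_eps = eps_new - eps
            for j in range(nb):
                sigma[j] = branch_decay[j] * sigma[j] + branch_gain[j] * d_eps
            eps = eps_new
            d = depth_max - u if depth_max > 0.0 else 0.0

        # -- 4. measurement -------------------------------------------------
        d_meas = sens * d + noise[i] + drift_rate * t_abs
        f_meas = k * d_meas
        if not np.isfinite(d) or abs(d) > 5e-5:
            fault = FAULT_DIVERGED
            n_done = i
            break

        # -- 5. contact detection -------------------------------------------
        hit = False
        if detect:
            if f_meas > f_threshold:
                above_count += 1
                if above_count >= n_debounce:
                    detect_step = i - n_debounce + 1
                    hit = True
            else:
                above_count = 0

        # -- 6. decimated recording -----------------------------------------
        if (gstep0 + i) % decim == 0:
            rec_zp[n_rec] = z_p
            rec_d[n_rec] = d_meas
            rec_h[n_rec] = u
            n_rec += 1

        n_done = i + 1
        if hit:
            break

    state[IDX_ZP] = z_p
    state[IDX_P] = p
    state[IDX_EPS] = eps
    state[IDX_INTEG] = integ
    state[IDX_U] = u
    state[IDX_FMEAS] = f_meas
    state[IDX_STUCK] = 1.0 if stuck else 0.0
    state[IDX_DWELL] = float(dwell)
    state[IDX_VAVG] = v_avg
    return n_rec, n_done, detect_step, fault
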