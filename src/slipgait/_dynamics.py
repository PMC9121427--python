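"""Numba-jitted hybrid integrator for the bipedal SLIP model.

Implements an adaptive Dormand-Prince 4(5) stepper with event detection
(touchdown, liftoff, apex, fall) and exact discrete resets, specialized to
the 8-dimensional continuous state

    y = [x, y, alpha_l, alpha_r, xdot, ydot, alphadot_l, alphadot_r]

in normalized units (m = lo = g = 1).  Events are bracketed on accepted
steps, pre-located on the cubic Hermite interpolant and polished by Newton
iterations on single Runge-Kutta substeps, so the event residual is
resolved to integrator accuracy (~1e-12).

This module is private; :mod:`slipgait.hybrid_sim` provides the public
surface.  Everything here is plain floats/arrays so the whole stride
simulation runs inside one jitted call.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# terminal / status codes
STATUS_OK = 0          # stride completed at the terminal apex
STATUS_FELL = 1        # y reached 0
STATUS_PREMATURE = 2   # touchdown while the leg still rotated anteriorly
STATUS_OVERFLOW = 3    # more leg events than a simple stride allows
STATUS_UNDERFLOW = 4   # step size underflow
STATUS_TIME_CAP = 5    # exceeded the wall-clock-free time cap
STATUS_DEGENERATE = 6  # stance geometry left the admissible region
STATUS_EVENT = 7       # stopped at the first event (single-phase mode)

# event channel codes
EV_TD_L = 0
EV_LO_L = 1
EV_TD_R = 2
EV_LO_R = 3
EV_APEX = 4
EV_FALL = 5

_HALF_PI = math.pi / 2.0


@njit(cache=True)
def _rhs(yv, ml, mr, k, om2, phl, phr):
    """Continuous dynamics; stance legs follow the twice-differentiated
    holonomic constraint, swing legs the driven-pendulum equation."""
    y = yv[1]
    al = yv[2]
    ar = yv[3]
    vx = yv[4]
    vy = yv[5]
    wl = yv[6]
    wr = yv[7]

    Fx = 0.0
    Fy = 0.0
    if ml == 1:
        ca = math.cos(al)
        f = k * (1.0 - y / ca)
        Fx -= f * math.sin(al)
        Fy += f * ca
    if mr == 1:
        ca = math.cos(ar)
        f = k * (1.0 - y / ca)
        Fx -= f * math.sin(ar)
        Fy += f * ca
    ax = Fx
    ay = Fy - 1.0

    out = np.empty(8)
    out[0] = vx
    out[1] = vy
    out[2] = wl
    out[3] = wr
    out[4] = ax
    out[5] = ay
    if ml == 1:
        ta = math.tan(al)
        ca = math.cos(al)
        out[6] = -2.0 * wl * wl * ta - 2.0 * wl * vy / y - (ax + ay * ta) * ca * ca / y
    else:
        out[6] = -(ax * math.cos(al) + (1.0 + ay) * math.sin(al)) - om2 * (al - phl)
    if mr == 1:
        ta = math.tan(ar)
        ca = math.cos(ar)
        out[7] = -2.0 * wr * wr * ta - 2.0 * wr * vy / y - (ax + ay * ta) * ca * ca / y
    else:
        out[7] = -(ax * math.cos(ar) + (1.0 + ay) * math.sin(ar)) - om2 * (ar - phr)
    return out


@njit(cache=True)
def _rk_substep(y0, f0, h, ml, mr, k, om2, phl, phr):
    """One Dormand-Prince step of size h from y0 (k1 = f0 given).
    Returns (y_new, f_new, err_vector)."""
    k1 = f0
    k2 = _rhs(y0 + h * (0.2 * k1), ml, mr, k, om2, phl, phr)
    k3 = _rhs(y0 + h * (3.0 / 40.0 * k1 + 9.0 / 40.0 * k2), ml, mr, k, om2, phl, phr)
    k4 = _rhs(
        y0 + h * (44.0 / 45.0 * k1 - 56.0 / 15.0 * k2 + 32.0 / 9.0 * k3),
        ml, mr, k, om2, phl, phr,
    )
    k5 = _rhs(
        y0
        + h
        * (
            19372.0 / 6561.0 * k1
            - 25360.0 / 2187.0 * k2
            + 64448.0 / 6561.0 * k3
            - 212.0 / 729.0 * k4
        ),
        ml, mr, k, om2, phl, phr,
    )
    k6 = _rhs(
        y0
        + h
        * (
            9017.0 / 3168.0 * k1
            - 355.0 / 33.0 * k2
            + 46732.0 / 5247.0 * k3
            + 49.0 / 176.0 * k4
            - 5103.0 / 18656.0 * k5
        ),
        ml, mr, k, om2, phl, phr,
    )
    y1 = y0 + h * (
        35.0 / 384.0 * k1
        + 500.0 / 1113.0 * k3
        + 125.0 / 192.0 * k4
        - 2187.0 / 6784.0 * k5
        + 11.0 / 84.0 * k6
    )
    k7 = _rhs(y1, ml, mr, k, om2, phl, phr)
    err = h * (
        71.0 / 57600.0 * k1
        - 71.0 / 16695.0 * k3
        + 71.0 / 1920.0 * k4
        - 17253.0 / 339200.0 * k5
        + 22.0 / 525.0 * k6
        - 1.0 / 40.0 * k7
    )
    return y1, k7, err


@njit(cache=True)
def _err_norm(err, y0, y1, rtol, atol):
    s = 0.0
    for i in range(8):
        sc = atol + rtol * max(abs(y0[i]), abs(y1[i]))
        e = err[i] / sc
        s += e * e
    return math.sqrt(s / 8.0)


@njit(cache=True)
def _event_g(ch, yv):
    """Scalar event function per channel; events trigger on + -> <=0."""
    if ch == EV_TD_L:
        return yv[1] - math.cos(yv[2])
    elif ch == EV_LO_L:
        return 1.0 - yv[1] / math.cos(yv[2])
    elif ch == EV_TD_R:
        return yv[1] - math.cos(yv[3])
    elif ch == EV_LO_R:
        return 1.0 - yv[1] / math.cos(yv[3])
    elif ch == EV_APEX:
        return yv[5]
    else:  # EV_FALL
        return yv[1]


@njit(cache=True)
def _event_gdot(ch, yv, fv):
    if ch == EV_TD_L:
        return yv[5] + math.sin(yv[2]) * yv[6]
    elif ch == EV_LO_L:
        ca = math.cos(yv[2])
        return -(yv[5] / ca + yv[1] * math.sin(yv[2]) * yv[6] / (ca * ca))
    elif ch == EV_TD_R:
        return yv[5] + math.sin(yv[3]) * yv[7]
    elif ch == EV_LO_R:
        ca = math.cos(yv[3])
        return -(yv[5] / ca + yv[1] * math.sin(yv[3]) * yv[7] / (ca * ca))
    elif ch == EV_APEX:
        return fv[5]
    else:
        return yv[5]


@njit(cache=True)
def _hermite_g(ch, s, h, y0, f0, y1, f1):
    """Event function on the cubic Hermite interpolant at fraction s of the step."""
    h00 = (2.0 * s - 3.0) * s * s + 1.0
    h10 = ((s - 2.0) * s + 1.0) * s
    h01 = (3.0 - 2.0 * s) * s * s
    h11 = (s - 1.0) * s * s
    yv = np.empty(8)
    for i in range(8):
        yv[i] = h00 * y0[i] + h10 * h * f0[i] + h01 * y1[i] + h11 * h * f1[i]
    return _event_g(ch, yv)


@njit(cache=True)
def _locate_event(ch, t0, h, y0, f0, y1, f1, ml, mr, k, om2, phl, phr):
    """Refine the crossing time of channel ``ch`` inside an accepted step.

    Bisection on the Hermite interpolant brackets the root; Newton
    iterations on exact RK substeps from (t0, y0) polish it.  Returns the
    event time."""
    lo = 0.0
    hi = 1.0
    glo = _event_g(ch, y0)
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        gm = _hermite_g(ch, mid, h, y0, f0, y1, f1)
        if (glo > 0.0) == (gm > 0.0):
            lo = mid
            glo = gm
        else:
            hi = mid
    te = t0 + 0.5 * (lo + hi) * h
    for _ in range(4):
        dt = te - t0
        if dt <= 0.0:
            dt = 1e-16
        ye, fe, _e = _rk_substep(y0, f0, dt, ml, mr, k, om2, phl, phr)
        g = _event_g(ch, ye)
        gd = _event_gdot(ch, ye, fe)
        if gd == 0.0:
            break
        step = g / gd
        te_new = te - step
        if te_new < t0:
            te_new = t0
        elif te_new > t0 + h:
            te_new = t0 + h
        if abs(te_new - te) < 1e-15 * max(1.0, abs(te)):
            te = te_new
            break
        te = te_new
    return te


@njit(cache=True)
def _sim_fixed_times(
    y_init,
    ml0,
    mr0,
    xcl0,
    xcr0,
    k,
    om,
    phl,
    phr,
    rtol,
    atol,
    seq,
    times,
    store,
    max_steps,
):
    """Integrate a stride whose event schedule is prescribed.

    ``seq`` holds the four touchdown/liftoff channels in order and
    ``times`` their times plus the stride time T (times[4]).  The
    touchdown resets and mode switches are applied at the scheduled
    instants regardless of foot height — the boundary-value residual is
    responsible for driving the foot-height conditions to zero.  Ground
    crossings of swing feet between scheduled events (scuffing of a
    massless leg) are not events in this formulation; the minimum swing
    foot clearance is tracked as a diagnostic.

    Returns: status, y_end, ev_states (4,8 pre-transition), td_w_minus (2,),
    min_clearance, max_swing_amp, max_swing_excursion, n_rec, t_hist,
    y_hist, f_hist, mode_hist.
    """
    om2 = om * om
    y = y_init.copy()
    ml = ml0
    mr = mr0
    xcl = xcl0
    xcr = xcr0
    ev_states = np.zeros((4, 8))
    td_w_minus = np.full(2, np.nan)
    min_clear = 1e30
    max_amp = 0.0
    max_exc = 0.0   # swing excursion relative to the neutral angle
    status = STATUS_OK

    nbuf = max_steps if store else 2
    t_hist = np.empty(nbuf)
    y_hist = np.empty((nbuf, 8))
    f_hist = np.empty((nbuf, 8))
    mode_hist = np.empty((nbuf, 2), dtype=np.int64)
    n_rec = 0

    # schedule sanity
    t_prev = 0.0
    for i in range(5):
        if times[i] < t_prev - 1e-12 or not np.isfinite(times[i]):
            return (
                STATUS_OVERFLOW, y, ev_states, td_w_minus, min_clear, max_amp,
                0.0, 0, t_hist[:0], y_hist[:0], f_hist[:0], mode_hist[:0],
            )
        t_prev = max(t_prev, times[i])

    t = 0.0
    f = _rhs(y, ml, mr, k, om2, phl, phr)
    if store:
        t_hist[0] = t
        y_hist[0] = y
        f_hist[0] = f
        mode_hist[0, 0] = ml
        mode_hist[0, 1] = mr
        n_rec = 1

    h = 1e-4
    for phase in range(5):
        t_stop = times[phase]
        # integrate this phase
        while t < t_stop - 1e-13:
            if h > t_stop - t:
                h = t_stop - t
            y1, f1, err = _rk_substep(y, f, h, ml, mr, k, om2, phl, phr)
            en = _err_norm(err, y, y1, rtol, atol)
            if not np.isfinite(en):
                en = 2.0
            if en > 1.0:
                h *= max(0.2, 0.9 * en ** -0.2)
                if h < 1e-13:
                    status = STATUS_UNDERFLOW
                    break
                continue
            t = t + h
            y = y1
            f = f1
            if store and n_rec < max_steps:
                t_hist[n_rec] = t
                y_hist[n_rec] = y
                f_hist[n_rec] = f
                mode_hist[n_rec, 0] = ml
                mode_hist[n_rec, 1] = mr
                n_rec += 1
            if y[1] <= 0.0:
                status = STATUS_FELL
                break
            if ml == 0:
                c = y[1] - math.cos(y[2])
                if c < min_clear:
                    min_clear = c
                if abs(y[2]) > max_amp:
                    max_amp = abs(y[2])
                if abs(y[2] - phl) > max_exc:
                    max_exc = abs(y[2] - phl)
            elif abs(y[2]) >= 1.5707:
                status = STATUS_DEGENERATE
                break
            if mr == 0:
                c = y[1] - math.cos(y[3])
                if c < min_clear:
                    min_clear = c
                if abs(y[3]) > max_amp:
                    max_amp = abs(y[3])
                if abs(y[3] - phr) > max_exc:
                    max_exc = abs(y[3] - phr)
            elif abs(y[3]) >= 1.5707:
                status = STATUS_DEGENERATE
                break
            h *= min(5.0, max(0.2, 0.9 * en ** -0.2))
        if status != STATUS_OK:
            break
        if phase == 4:
            break
        # scheduled transition
        ch = seq[phase]
        ev_states[phase] = y
        if ch == EV_TD_L or ch == EV_TD_R:
            leg = 0 if ch == EV_TD_L else 1
            if (leg == 0 and ml != 0) or (leg == 1 and mr != 0):
                status = STATUS_OVERFLOW
                break
            a = y[2 + leg]
            if abs(a) >= _HALF_PI or y[1] <= 0.0:
                status = STATUS_DEGENERATE
                break
            td_w_minus[leg] = y[6 + leg]
            ta = math.tan(a)
            ca = math.cos(a)
            y[6 + leg] = -(y[4] + y[5] * ta) * ca * ca / y[1]
            if leg == 0:
                ml = 1
                xcl = y[0] + y[1] * ta
            else:
                mr = 1
                xcr = y[0] + y[1] * ta
        else:
            leg = 0 if ch == EV_LO_L else 1
            if (leg == 0 and ml != 1) or (leg == 1 and mr != 1):
                status = STATUS_OVERFLOW
                break
            if leg == 0:
                ml = 0
                xcl = np.nan
            else:
                mr = 0
                xcr = np.nan
        f = _rhs(y, ml, mr, k, om2, phl, phr)
        if store and n_rec < max_steps:
            t_hist[n_rec] = t
            y_hist[n_rec] = y
            f_hist[n_rec] = f
            mode_hist[n_rec, 0] = ml
            mode_hist[n_rec, 1] = mr
            n_rec += 1
        h = min(h, 1e-3)

    return (
        status, y, ev_states, td_w_minus, min_clear, max_amp, max_exc,
        n_rec, t_hist[:n_rec], y_hist[:n_rec], f_hist[:n_rec], mode_hist[:n_rec],
    )


@njit(cache=True)
def _sim_core(
    y_init,
    ml0,
    mr0,
    xcl0,
    xcr0,
    k,
    om,
    phl,
    phr,
    rtol,
    atol,
    t_cap,
    events_before_stop,
    stop_on_any_event,
    max_events,
    premature_w,
    store,
    max_steps,
    seq,
):
    """Integrate the hybrid system from an anchor point.

    Terminates at the first apex (ydot crossing zero from above) once
    ``events_before_stop`` leg events have occurred, or on failure.

    ``seq`` (int64 array of event channels) switches on guided shooting:
    only the next prescribed touchdown/liftoff channel is monitored (plus
    fall, and the terminal apex once the sequence is exhausted).  Guided
    strides are a search device for root solving across event-order
    changes; validity is always re-checked with free event detection.

    Returns
    -------
    status, t_end, y_end, ml, mr, xcl, xcr,
    ev_times[4] (ltd, llo, rtd, rlo; nan if absent), n_ev, max_swing_amp,
    n_rec, t_hist, y_hist, f_hist, mode_hist, ev_log (time, channel)
    """
    om2 = om * om
    y = y_init.copy()
    ml = ml0
    mr = mr0
    xcl = xcl0
    xcr = xcr0
    t = 0.0
    ev_times = np.full(4, np.nan)
    ev_log_t = np.full(max_events + 1, np.nan)
    ev_log_c = np.full(max_events + 1, -1)
    n_ev = 0
    n_log = 0
    max_amp = 0.0
    status = STATUS_TIME_CAP

    nbuf = max_steps if store else 2
    t_hist = np.empty(nbuf)
    y_hist = np.empty((nbuf, 8))
    f_hist = np.empty((nbuf, 8))
    mode_hist = np.empty((nbuf, 2), dtype=np.int64)
    n_rec = 0

    f = _rhs(y, ml, mr, k, om2, phl, phr)
    if store:
        t_hist[0] = t
        y_hist[0] = y
        f_hist[0] = f
        mode_hist[0, 0] = ml
        mode_hist[0, 1] = mr
        n_rec = 1

    h = 1e-4
    done = False
    while not done:
        if t >= t_cap:
            status = STATUS_TIME_CAP
            break
        if h > t_cap - t:
            h = t_cap - t
        # --- attempt a step -------------------------------------------------
        y1, f1, err = _rk_substep(y, f, h, ml, mr, k, om2, phl, phr)
        en = _err_norm(err, y, y1, rtol, atol)
        if not np.isfinite(en):
            en = 2.0
        if en > 1.0:
            h *= max(0.2, 0.9 * en ** -0.2)
            if h < 1e-13:
                status = STATUS_UNDERFLOW
                done = True
            continue

        # --- event detection on the accepted step --------------------------
        guided = seq.shape[0] > 0
        if guided:
            # prescribed-channel consistency check
            if n_ev < seq.shape[0]:
                nxt = seq[n_ev]
                bad = (
                    (nxt == EV_TD_L and ml != 0)
                    or (nxt == EV_LO_L and ml != 1)
                    or (nxt == EV_TD_R and mr != 0)
                    or (nxt == EV_LO_R and mr != 1)
                )
                if bad:
                    status = STATUS_OVERFLOW
                    break
        ev_ch = np.empty(6, dtype=np.int64)
        ev_te = np.empty(6)
        n_hit = 0
        for ch in range(6):
            if guided and ch <= EV_LO_R:
                if n_ev >= seq.shape[0] or ch != seq[n_ev]:
                    continue
            if ch == EV_TD_L and ml != 0:
                continue
            if ch == EV_LO_L and ml != 1:
                continue
            if ch == EV_TD_R and mr != 0:
                continue
            if ch == EV_LO_R and mr != 1:
                continue
            g0 = _event_g(ch, y)
            g1 = _event_g(ch, y1)
            if g0 > 1e-13 and g1 <= 0.0:
                te = _locate_event(ch, t, h, y, f, y1, f1, ml, mr, k, om2, phl, phr)
                ev_ch[n_hit] = ch
                ev_te[n_hit] = te
                n_hit += 1

        if n_hit > 0:
            # earliest event (ties within 1e-9 processed together)
            te_min = ev_te[0]
            for i in range(1, n_hit):
                if ev_te[i] < te_min:
                    te_min = ev_te[i]
            dt = te_min - t
            if dt <= 0.0:
                dt = 1e-16
            ye, fe, _e = _rk_substep(y, f, dt, ml, mr, k, om2, phl, phr)

            # record the pre-event point
            if store and n_rec < max_steps:
                t_hist[n_rec] = te_min
                y_hist[n_rec] = ye
                f_hist[n_rec] = fe
                mode_hist[n_rec, 0] = ml
                mode_hist[n_rec, 1] = mr
                n_rec += 1

            if ye[1] <= 0.0:
                t = te_min
                y = ye
                status = STATUS_FELL
                break

            hit_fall = False
            hit_apex = False
            # touchdowns before liftoffs
            for phase_pass in range(2):
                for i in range(n_hit):
                    if ev_te[i] > te_min + 1e-9:
                        continue
                    ch = ev_ch[i]
                    if ch == EV_FALL:
                        hit_fall = True
                        continue
                    if ch == EV_APEX:
                        hit_apex = True
                        continue
                    is_td = ch == EV_TD_L or ch == EV_TD_R
                    if (phase_pass == 0) != is_td:
                        continue
                    if n_log <= max_events:
                        ev_log_t[n_log] = te_min
                        ev_log_c[n_log] = ch
                        n_log += 1
                    if is_td:
                        leg = 0 if ch == EV_TD_L else 1
                        a = ye[2 + leg]
                        w_minus = ye[6 + leg]
                        if w_minus > premature_w and not guided:
                            status = STATUS_PREMATURE
                            done = True
                        if abs(a) >= _HALF_PI:
                            status = STATUS_DEGENERATE
                            done = True
                        if done:
                            break
                        # holonomic velocity reset and anchor placement
                        ta = math.tan(a)
                        ca = math.cos(a)
                        ye[6 + leg] = -(ye[4] + ye[5] * ta) * ca * ca / ye[1]
                        xc_new = ye[0] + ye[1] * ta
                        if leg == 0:
                            ml = 1
                            xcl = xc_new
                        else:
                            mr = 1
                            xcr = xc_new
                    else:
                        leg = 0 if ch == EV_LO_L else 1
                        if leg == 0:
                            ml = 0
                            xcl = np.nan
                        else:
                            mr = 0
                            xcr = np.nan
                    # first occurrence only; a repeat breaks the stride pattern
                    slot = ch
                    if np.isnan(ev_times[slot]):
                        ev_times[slot] = te_min
                        n_ev += 1
                    else:
                        status = STATUS_OVERFLOW
                        done = True
                        break
                if done:
                    break
            t = te_min
            y = ye
            if hit_fall:
                status = STATUS_FELL
                break
            if done:
                break
            if hit_apex and n_ev >= events_before_stop:
                status = STATUS_OK
                done = True
            if stop_on_any_event:
                status = STATUS_EVENT
                done = True
            if n_ev > max_events:
                status = STATUS_OVERFLOW
                done = True
            f = _rhs(y, ml, mr, k, om2, phl, phr)
            if store and n_rec < max_steps:
                t_hist[n_rec] = t
                y_hist[n_rec] = y
                f_hist[n_rec] = f
                mode_hist[n_rec, 0] = ml
                mode_hist[n_rec, 1] = mr
                n_rec += 1
            if done:
                break
            # keep the remainder of the step modest after a mode switch
            h = min(h, max(1e-6, 0.5 * h))
            continue

        # --- plain accepted step -------------------------------------------
        t = t + h
        y = y1
        f = f1
        if store and n_rec < max_steps:
            t_hist[n_rec] = t
            y_hist[n_rec] = y
            f_hist[n_rec] = f
            mode_hist[n_rec, 0] = ml
            mode_hist[n_rec, 1] = mr
            n_rec += 1
        elif store:
            status = STATUS_OVERFLOW
            break

        # track swing amplitude; guard stance geometry
        if ml == 0:
            if abs(y[2]) > max_amp:
                max_amp = abs(y[2])
        else:
            if abs(y[2]) >= 1.5707:
                status = STATUS_DEGENERATE
                break
        if mr == 0:
            if abs(y[3]) > max_amp:
                max_amp = abs(y[3])
        else:
            if abs(y[3]) >= 1.5707:
                status = STATUS_DEGENERATE
                break
        if y[1] <= 0.0:
            status = STATUS_FELL
            break

        h *= min(5.0, max(0.2, 0.9 * en ** -0.2))

    return (
        status,
        t,
        y,
        ml,
        mr,
        xcl,
        xcr,
        ev_times,
        n_ev,
        max_amp,
        n_rec,
        t_hist[:n_rec],
        y_hist[:n_rec],
        f_hist[:n_rec],
        mode_hist[:n_rec],
        ev_log_t[:n_log],
        ev_log_c[:n_log],
    )
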