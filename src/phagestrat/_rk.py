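"""Compiled adaptive Cash-Karp 5(4) integrator for the chemostat ODE system.

The right-hand side here is a numba-compiled twin of
:func:`phagestrat.core_model.derivatives` (the test suite asserts the two
agree to machine precision on random states).  An embedded Runge-Kutta 5(4)
pair with standard proportional step-size control integrates the system,
stepping exactly onto every requested output time.  The lysogenic/lytic
growth switch is evaluated inside every RHS call; the step controller absorbs
the resulting discontinuity by shrinking steps near the switch.
"""

import numpy as np
from numba import njit

# strategy codes (must match core_model.STRATEGY_CODES)
NONE, LYTIC, PTW, PTL = 0, 1, 2, 3

# parameter vector indices (must match core_model.PARAM_FIELDS)
# 0:x 1:y1 2:y2 3:N_H 4:i_norm 5:c 6:n 7:s_max 8:d 9:D 10:N0 11:SH 12:r 13:H
# 14:s_switch 15:a 16:T   (+ shunt flag passed separately)

_TWO_PI = 2.0 * np.pi


@njit(cache=False)
def _rhs(t, y, strat, p, shunt, dy):
    x = p[0]; y1 = p[1]; y2 = p[2]; NH = p[3]; i_ads = p[4]; c = p[5]
    n = p[6]; smax = p[7]; d = p[8]; D = p[9]; N0 = p[10]; SH = p[11]
    r = p[12]; H = p[13]; ssw = p[14]; a = p[15]; T = p[16]

    N = y[6]
    if N < 0.0:
        N = 0.0

    if a > 0.0:
        Dt = a * D * np.sin(_TWO_PI * t / T) + D
    else:
        Dt = D
    dN = Dt * (N0 - N)

    for k in range(2):
        B = y[k]
        if B < 0.0:
            B = 0.0
        I = y[2 + k]
        if I < 0.0:
            I = 0.0
        P = y[4 + k]
        if P < 0.0:
            P = 0.0
        yk = y1 if k == 0 else y2
        G = x * yk * N / (N + NH)

        if strat == NONE:
            dy[k] = G * B - x * B
            dy[2 + k] = 0.0
            dy[4 + k] = 0.0
            dN -= G * B
            continue

        if strat == LYTIC:
            s_k = smax
        elif strat == PTL:
            tot = B + I
            s_k = smax * tot * tot / (tot * tot + SH)
        else:  # PTW
            tot = (B + I) * r
            s_k = smax / (tot * tot + H)

        grow = (strat == PTW or strat == PTL) and s_k <= ssw

        infection = i_ads * B * P
        dy[k] = G * B - x * B - infection
        dIk = (1.0 + c) * infection - x * I - s_k * I
        if grow:
            dIk += G * I
        dy[2 + k] = dIk
        dy[4 + k] = n * s_k * I - c * infection - d * P
        dN -= G * B
        if grow:
            dN -= G * I
        if shunt:
            dN += (1.0 - n) * s_k * I
    dy[6] = dN


# Cash-Karp 5(4) tableau
_A21 = 0.2
_A31 = 3.0 / 40.0; _A32 = 9.0 / 40.0
_A41 = 0.3; _A42 = -0.9; _A43 = 1.2
_A51 = -11.0 / 54.0; _A52 = 2.5; _A53 = -70.0 / 27.0; _A54 = 35.0 / 27.0
_A61 = 1631.0 / 55296.0; _A62 = 175.0 / 512.0; _A63 = 575.0 / 13824.0
_A64 = 44275.0 / 110592.0; _A65 = 253.0 / 4096.0
_C2 = 0.2; _C3 = 0.3; _C4 = 0.6; _C5 = 1.0; _C6 = 0.875
_B1 = 37.0 / 378.0; _B3 = 250.0 / 621.0; _B4 = 125.0 / 594.0; _B6 = 512.0 / 1771.0
_E1 = _B1 - 2825.0 / 27648.0
_E3 = _B3 - 18575.0 / 48384.0
_E4 = _B4 - 13525.0 / 55296.0
_E5 = -277.0 / 14336.0
_E6 = _B6 - 0.25

_H_MIN = 1e-10
_MAX_REJECTS = 200


@njit(cache=False)
def integrate(strat, p, shunt, y0, t_end, out_step, rtol, atol):
    """Integrate from t=0 to t_end, sampling every out_step hours.

    Returns ``(times, states, status, t_fail)``; status 0 = success,
    1 = step-size underflow or non-finite state at time ``t_fail`` (remaining
    samples are NaN).
    """
    n_out = int(np.floor(t_end / out_step + 1e-9)) + 1
    ts = np.empty(n_out)
    ys = np.empty((n_out, 7))
    y = y0.copy()
    ts[0] = 0.0
    ys[0] = y

    k1 = np.empty(7); k2 = np.empty(7); k3 = np.empty(7)
    k4 = np.empty(7); k5 = np.empty(7); k6 = np.empty(7)
    ytmp = np.empty(7)
    y5 = np.empty(7)

    t = 0.0
    h = min(out_step, 1.0)
    status = 0
    t_fail = 0.0

    for iout in range(1, n_out):
        t_target = iout * out_step
        if t_target > t_end:
            t_target = t_end
        rejects = 0
        while t < t_target - 1e-9:
            capped = h > t_target - t
            hs = t_target - t if capped else h

            _rhs(t, y, strat, p, shunt, k1)
            for j in range(7):
                ytmp[j] = y[j] + hs * _A21 * k1[j]
            _rhs(t + _C2 * hs, ytmp, strat, p, shunt, k2)
            for j in range(7):
                ytmp[j] = y[j] + hs * (_A31 * k1[j] + _A32 * k2[j])
            _rhs(t + _C3 * hs, ytmp, strat, p, shunt, k3)
            for j in range(7):
                ytmp[j] = y[j] + hs * (_A41 * k1[j] + _A42 * k2[j] + _A43 * k3[j])
            _rhs(t + _C4 * hs, ytmp, strat, p, shunt, k4)
            for j in range(7):
                ytmp[j] = y[j] + hs * (_A51 * k1[j] + _A52 * k2[j]
                                       + _A53 * k3[j] + _A54 * k4[j])
            _rhs(t + _C5 * hs, ytmp, strat, p, shunt, k5)
            for j in range(7):
                ytmp[j] = y[j] + hs * (_A61 * k1[j] + _A62 * k2[j] + _A63 * k3[j]
                                       + _A64 * k4[j] + _A65 * k5[j])
            _rhs(t + _C6 * hs, ytmp, strat, p, shunt, k6)

            err = 0.0
            ok = True
            for j in range(7):
                y5[j] = y[j] + hs * (_B1 * k1[j] + _B3 * k3[j]
                                     + _B4 * k4[j] + _B6 * k6[j])
                if not np.isfinite(y5[j]):
                    ok = False
                    break
                ej = hs * (_E1 * k1[j] + _E3 * k3[j] + _E4 * k4[j]
                           + _E5 * k5[j] + _E6 * k6[j])
                ymag = abs(y[j])
                if abs(y5[j]) > ymag:
                    ymag = abs(y5[j])
                sc = atol + rtol * ymag
                e = ej / sc
                err += e * e
            if not ok:
                # non-finite trial state: retry with a smaller step
                h = hs * 0.1
                rejects += 1
                if h < _H_MIN or rejects > _MAX_REJECTS:
                    status = 1
                    t_fail = t
                    break
                continue
            err = np.sqrt(err / 7.0)

            if err <= 1.0:
                t += hs
                for j in range(7):
                    y[j] = y5[j]
                rejects = 0
                if err == 0.0:
                    fac = 5.0
                else:
                    fac = 0.9 * err ** -0.2
                    if fac > 5.0:
                        fac = 5.0
                if not capped:
                    h = hs * fac
                elif fac > 1.0 and hs * fac > h:
                    h = hs * fac
            else:
                fac = 0.9 * err ** -0.25
                if fac < 0.1:
                    fac = 0.1
                h = hs * fac
                rejects += 1
                if h < _H_MIN or rejects > _MAX_REJECTS:
                    status = 1
                    t_fail = t
                    break
        if status != 0:
            for jout in range(iout, n_out):
                ts[jout] = jout * out_step
                for j in range(7):
                    ys[jout, j] = np.nan
            break
        ts[iout] = t_target
        ys[iout] = y

    return ts, ys, status, t_fail
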