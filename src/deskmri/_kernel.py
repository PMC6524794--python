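"""Numba time-stepping kernel.

One compiled loop advances every isochromat through every timeline step:
rotation about the rotating-frame effective field (RF + off-resonance),
transverse decay, longitudinal recovery (single pool) or a two-pool
exchange/saturation update (Bloch-McConnell), with signal recording at ADC
flags and per-spin recording at single-point recorder flags.

Per-spin rotation/relaxation coefficients are cached in two slots keyed on
the step's ``(dt, gx, gy, gz, |B1|, phase(B1))``; consecutive steps under a
constant RF raster bin or the alternating ADC/idle pattern of a readout then
reuse the cached trigonometry.  The cache is bypassed when motion is active
(positions, hence off-resonance, change every step).
"""

import numpy as np
from numba import njit

_TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def run_timeline(
    dts, t0s, gx, gy, gz, b1m, b1p, adc_idx, crush, rec_idx,
    px0, py0, pz0, t1, t2, m0, db0, sens,
    mt_on, mt_flag, mt_k, mt_kr, mt_w0, mt_t1s, m0s,
    motion_kind, mo_ax, mo_ay, mo_az, mo_amp, mo_theta, mo_cx, mo_cy, mo_freq,
    gamma, mx, my, mz, mzs, adc_out, rec_out,
):
    n_steps = dts.shape[0]
    n = t1.shape[0]
    n_coil = sens.shape[0]
    use_cache = motion_kind == 0

    # two cached coefficient slots
    key = np.full((2, 6), np.nan)
    valid = np.zeros(2, np.int64)
    lru = 0
    cnx = np.empty((2, n)); cny = np.empty((2, n)); cnz = np.empty((2, n))
    cca = np.empty((2, n)); csa = np.empty((2, n))
    ce1 = np.empty((2, n)); ce2 = np.empty((2, n))
    if mt_on:
        cE11 = np.empty((2, n)); cE12 = np.empty((2, n))
        cE21 = np.empty((2, n)); cE22 = np.empty((2, n))
        cp1 = np.empty((2, n)); cp2 = np.empty((2, n))
    else:
        cE11 = np.empty((1, 1)); cE12 = np.empty((1, 1))
        cE21 = np.empty((1, 1)); cE22 = np.empty((1, 1))
        cp1 = np.empty((1, 1)); cp2 = np.empty((1, 1))

    px = px0.copy(); py = py0.copy(); pz = pz0.copy()

    for s in range(n_steps):
        dt = dts[s]
        if crush[s]:
            for i in range(n):
                mx[i] = 0.0
                my[i] = 0.0
        a = adc_idx[s]
        if a >= 0:
            for c in range(n_coil):
                acc = 0.0j
                for i in range(n):
                    acc += sens[c, i] * (mx[i] + 1j * my[i])
                adc_out[c, a] = acc
        r = rec_idx[s]
        if r >= 0:
            for i in range(n):
                rec_out[r, i] = mx[i] + 1j * my[i]

        if motion_kind != 0:
            t = t0s[s]
            if motion_kind == 1:
                d = mo_amp * np.sin(_TWO_PI * mo_freq * t)
                for i in range(n):
                    px[i] = px0[i] + mo_ax * d
                    py[i] = py0[i] + mo_ay * d
                    pz[i] = pz0[i] + mo_az * d
            else:
                th = mo_theta * np.sin(_TWO_PI * mo_freq * t)
                cth = np.cos(th)
                sth = np.sin(th)
                for i in range(n):
                    dx = px0[i] - mo_cx
                    dy = py0[i] - mo_cy
                    px[i] = cth * dx - sth * dy + mo_cx
                    py[i] = sth * dx + cth * dy + mo_cy

        # locate / build the coefficient slot for this step
        slot = -1
        if use_cache:
            for q in range(2):
                if valid[q] == 1 and key[q, 0] == dt and key[q, 1] == gx[s] \
                        and key[q, 2] == gy[s] and key[q, 3] == gz[s] \
                        and key[q, 4] == b1m[s] and key[q, 5] == b1p[s]:
                    slot = q
                    break
        if slot < 0:
            slot = lru if use_cache else 0
            bm = b1m[s]
            bp = b1p[s]
            if bm > 0.0:
                fx = gamma * bm * np.cos(bp)
                fy = gamma * bm * np.sin(bp)
            else:
                fx = 0.0
                fy = 0.0
            if mt_on:
                w = np.pi * (gamma * bm) * (gamma * bm)
            else:
                w = 0.0
            for i in range(n):
                fz = gamma * (gx[s] * px[i] + gy[s] * py[i] + gz[s] * pz[i]) + db0[i]
                if bm > 0.0:
                    f = np.sqrt(fx * fx + fy * fy + fz * fz)
                    if f > 0.0:
                        nx = fx / f; ny = fy / f; nz = fz / f
                    else:
                        nx = 0.0; ny = 0.0; nz = 1.0
                    ang = -_TWO_PI * f * dt
                else:
                    nx = 0.0; ny = 0.0; nz = 1.0
                    ang = -_TWO_PI * fz * dt
                cnx[slot, i] = nx; cny[slot, i] = ny; cnz[slot, i] = nz
                cca[slot, i] = np.cos(ang)
                csa[slot, i] = np.sin(ang)
                ce1[slot, i] = np.exp(-dt / t1[i])
                ce2[slot, i] = np.exp(-dt / t2[i])
                if mt_on and mt_flag[i] == 1:
                    wi = w * mt_w0[i]
                    a11 = -(1.0 / t1[i] + mt_k[i])
                    a12 = mt_kr[i]
                    a21 = mt_k[i]
                    a22 = -(1.0 / mt_t1s[i] + mt_kr[i] + wi)
                    c1 = m0[i] / t1[i]
                    c2 = m0s[i] / mt_t1s[i]
                    det = a11 * a22 - a12 * a21
                    p1 = -(a22 * c1 - a12 * c2) / det
                    p2 = -(-a21 * c1 + a11 * c2) / det
                    tr = a11 + a22
                    disc = np.sqrt((a11 - a22) * (a11 - a22) + 4.0 * a12 * a21)
                    l1 = 0.5 * (tr + disc)
                    l2 = 0.5 * (tr - disc)
                    if disc > 1e-12:
                        g1 = np.exp(l1 * dt)
                        g2 = np.exp(l2 * dt)
                        cE11[slot, i] = (g1 * (a11 - l2) - g2 * (a11 - l1)) / disc
                        cE12[slot, i] = (g1 - g2) * a12 / disc
                        cE21[slot, i] = (g1 - g2) * a21 / disc
                        cE22[slot, i] = (g1 * (a22 - l2) - g2 * (a22 - l1)) / disc
                    else:
                        g1 = np.exp(l1 * dt)
                        cE11[slot, i] = g1 * (1.0 + (a11 - l1) * dt)
                        cE12[slot, i] = g1 * a12 * dt
                        cE21[slot, i] = g1 * a21 * dt
                        cE22[slot, i] = g1 * (1.0 + (a22 - l1) * dt)
                    cp1[slot, i] = p1
                    cp2[slot, i] = p2
            if use_cache:
                key[slot, 0] = dt; key[slot, 1] = gx[s]; key[slot, 2] = gy[s]
                key[slot, 3] = gz[s]; key[slot, 4] = b1m[s]; key[slot, 5] = b1p[s]
                valid[slot] = 1
        if use_cache:
            lru = 1 - slot

        # advance every spin: rotation (Rodrigues), T2 decay, longitudinal update
        for i in range(n):
            x = mx[i]; y = my[i]; z = mz[i]
            nx = cnx[slot, i]; ny = cny[slot, i]; nz = cnz[slot, i]
            ca = cca[slot, i]; sa = csa[slot, i]
            om = 1.0 - ca
            dot = nx * x + ny * y + nz * z
            x2 = x * ca + (ny * z - nz * y) * sa + nx * dot * om
            y2 = y * ca + (nz * x - nx * z) * sa + ny * dot * om
            z2 = z * ca + (nx * y - ny * x) * sa + nz * dot * om
            e2i = ce2[slot, i]
            mx[i] = x2 * e2i
            my[i] = y2 * e2i
            if mt_on and mt_flag[i] == 1:
                zs = mzs[i]
                p1 = cp1[slot, i]; p2 = cp2[slot, i]
                mz[i] = p1 + cE11[slot, i] * (z2 - p1) + cE12[slot, i] * (zs - p2)
                mzs[i] = p2 + cE21[slot, i] * (z2 - p1) + cE22[slot, i] * (zs - p2)
            else:
                e1i = ce1[slot, i]
                mz[i] = z2 * e1i + m0[i] * (1.0 - e1i)
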