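"""Implicit cable integrator on branched trees (numba kernel).

A theta-method step (theta = 1: backward Euler; theta = 0.5:
Crank-Nicolson) solves the symmetric tree-tridiagonal system by Hines
elimination (children are numbered after their parents, so a single
reverse sweep folds every branch onto the root).  Gating variables are
advanced first with Rush-Larsen exponential updates read from pre-computed
voltage tables; the ionic current is then linear in the new voltage, so
the voltage step is implicit.  Crank-Nicolson is second-order accurate and
removes most of the numerical damping of fast AP upstrokes at a 10 µs
step; backward Euler is the robust default for equilibration.

Units: mV, ms, nA, µS, nF (so C/dt is in µS and g·V in nA).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = -1


@njit(cache=True, fastmath=True)
def integrate(
    n_steps,
    parent,
    gax,
    gdiag_pass,
    cdt,
    gl,
    el,
    gnabar,
    gkbar,
    ena,
    ek,
    istim,
    inj_index,
    rec_index,
    theta,
    v,
    m,
    h,
    nn,
    tab_vmin,
    tab_dvinv,
    minf_t,
    mfac_t,
    hinf_t,
    hfac_t,
    ninf_t,
    nfac_t,
    out_v,
    record_stride,
):
    """Advance the model ``n_steps`` and record ``v[rec_index]``.

    ``gdiag_pass`` holds g_leak plus the sum of axial conductances at each
    compartment (the passive diagonal of the conductance operator).
    Returns STATUS_OK or the step index at which the solution left
    [-200, 200] mV / became non-finite.
    """
    n = v.shape[0]
    d = np.empty(n)
    rhs = np.empty(n)
    mdiag = np.empty(n)
    ntab = minf_t.shape[0]
    gl_el = gl * el
    omt = 1.0 - theta

    for t in range(n_steps):
        # --- gating update (Rush-Larsen via table lookup with lerp)
        for i in range(n):
            if gnabar[i] > 0.0 or gkbar[i] > 0.0:
                x = (v[i] - tab_vmin) * tab_dvinv
                if x < 0.0:
                    x = 0.0
                elif x > ntab - 1.001:
                    x = ntab - 1.001
                k = int(x)
                f = x - k
                mi = minf_t[k] + f * (minf_t[k + 1] - minf_t[k])
                mf = mfac_t[k] + f * (mfac_t[k + 1] - mfac_t[k])
                hi = hinf_t[k] + f * (hinf_t[k + 1] - hinf_t[k])
                hf = hfac_t[k] + f * (hfac_t[k + 1] - hfac_t[k])
                ni = ninf_t[k] + f * (ninf_t[k + 1] - ninf_t[k])
                nf = nfac_t[k] + f * (nfac_t[k + 1] - nfac_t[k])
                m[i] = mi + (m[i] - mi) * mf
                h[i] = hi + (h[i] - hi) * hf
                nn[i] = ni + (nn[i] - ni) * nf

        # --- assemble (C/dt + theta*M) V_new = (C/dt) V_old
        #       - (1-theta)*M V_old + sources, M the conductance operator
        for i in range(n):
            gna = gnabar[i] * m[i] * m[i] * m[i] * h[i]
            gk = gkbar[i] * nn[i]
            mdiag[i] = gdiag_pass[i] + gna + gk
            d[i] = cdt[i] + theta * mdiag[i]
            rhs[i] = cdt[i] * v[i] + gl_el[i] + gna * ena + gk * ek - omt * mdiag[i] * v[i]
        if omt > 0.0:
            for i in range(1, n):
                p = parent[i]
                rhs[i] += omt * gax[i] * v[p]
                rhs[p] += omt * gax[i] * v[i]
        rhs[inj_index] += istim[t]

        # --- Hines elimination (leaves -> root), then back-substitution
        for i in range(n - 1, 0, -1):
            g = theta * gax[i]
            f = g / d[i]
            p = parent[i]
            d[p] -= f * g
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + theta * gax[i] * v[parent[i]]) / d[i]

        if record_stride > 0 and t % record_stride == 0:
            out_v[t // record_stride] = v[rec_index]
        if t % 1000 == 0:
            vr = v[rec_index]
            if not np.isfinite(vr) or vr > 200.0 or vr < -200.0:
                return t
    return STATUS_OK
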