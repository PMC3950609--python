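"""Compiled inner loop of the compartmental simulator.

One backward-Euler (or Crank-Nicolson) step consists of: exact exponential
advance of the first-order gates at frozen voltage, one implicit step of the
coupled (h_T, d) pair, exact advance of the calcium shell at frozen Ca
current, then an implicit solve of the tree-structured voltage system with
the ionic conductances frozen at the new gating values (Hines elimination:
one O(N) backward sweep, one O(N) forward sweep; compartments are ordered so
every parent index precedes its children).

The membrane-level formulas duplicate :mod:`rgcsim.membrane` in compiled
form; a unit test pins the two implementations against each other.

Internal units: mV, ms, nF (capacitance), uS (conductance), nA (current),
M (calcium); with these, C/dt * V and g * V are both in nA.
"""

import math

import numpy as np
from numba import njit

__all__ = ["integrate"]


@njit(cache=True, inline="always")
def _ramp(x, a, b):
    if abs(x) < 1e-6:
        bx = b * x
        return (a / b) * (1.0 + 0.5 * bx + bx * bx / 12.0)
    return -a * x / math.expm1(-b * x)


@njit(cache=True, inline="always")
def _exp_update(x, alpha, beta, dt):
    s = alpha + beta
    x_inf = alpha / s
    return x_inf + (x - x_inf) * math.exp(-dt * s)


@njit(cache=True)
def integrate(V, m, h, c, n, a, hA, l, mT, hT, dg, p, Ca,
              parent, gax, cap,
              gNa, gCaD, gK, gKA, gKCaM, gL, gH, gNaP, gT,
              area, dt, nsteps, use_cn,
              stim_comps, stim_amps,
              rec_idx, recV, rec_cur, curOut,
              VK, VL, Vh, VT, VNa,
              Cae, Cadiss, Cares, tauCa, ca_coef, rt2f):
    """Advance ``nsteps`` steps in place, recording site voltages.

    ``gCaD`` is the HVA Ca density in S/cm^2 (needed for the shell source
    term); all other channel arrays are absolute conductances in uS.
    ``ca_coef`` is 3/(2 F r) pre-scaled so that ca_coef * I_Ca[mA/cm^2] is in
    M/ms.  ``curOut`` receives the nine soma current densities (mA/cm^2)
    when ``rec_cur`` is true.  Returns the step index at which the soma
    voltage became non-finite, or -1 on success.
    """
    N = V.shape[0]
    diag = np.empty(N)
    rhs = np.empty(N)
    VCa = np.empty(N)
    gCa = np.empty(N)
    for j in range(N):
        VCa[j] = rt2f * math.log(Cae / Ca[j])
        gCa[j] = gCaD[j] * area[j] * 1e6  # uS
    inv_diss2 = 1.0 / (Cadiss * Cadiss)
    dte = dt * 0.5 if use_cn else dt

    for i in range(nsteps):
        for j in range(N):
            v = V[j]
            # fast Na
            am = _ramp(v + 30.0, 0.6, 0.1)
            bm = 20.0 * math.exp(-(v + 55.0) / 18.0)
            m[j] = _exp_update(m[j], am, bm, dt)
            ah = 0.4 * math.exp(-(v + 50.0) / 20.0)
            bh = 6.0 / (1.0 + math.exp(-0.1 * (v + 20.0)))
            h[j] = _exp_update(h[j], ah, bh, dt)
            # delayed rectifier
            if gK[j] > 0.0:
                an = _ramp(v + 40.0, 0.02, 0.1)
                bn = 0.4 * math.exp(-(v + 50.0) / 80.0)
                n[j] = _exp_update(n[j], an, bn, dt)
            # A-type
            if gKA[j] > 0.0:
                aa = _ramp(v + 90.0, 0.006, 0.1)
                ba = 0.1 * math.exp(-(v + 30.0) / 10.0)
                a[j] = _exp_update(a[j], aa, ba, dt)
                aha = 0.04 * math.exp(-(v + 70.0) / 20.0)
                bha = 0.6 / (1.0 + math.exp(-0.1 * (v + 40.0)))
                hA[j] = _exp_update(hA[j], aha, bha, dt)
            # h-current
            if gH[j] > 0.0:
                al = math.exp(0.08316 * (v + 75.0))
                bl = math.exp(0.033264 * (v + 75.0))
                l[j] = _exp_update(l[j], al, bl, dt)
            # T-type activation + two-closed-state inactivation
            if gT[j] > 0.0:
                denom = 1.7 + math.exp(-(v + 28.8) / 13.5)
                amt = 1.0 / denom
                bmt = math.exp(-(v + 63.0) / 7.8) / denom
                mT[j] = _exp_update(mT[j], amt, bmt, dt)
                aht = math.exp(-(v + 160.3) / 17.8)
                root = math.sqrt(0.25 + math.exp((v + 83.5) / 6.3))
                bht = aht * (root - 0.5)
                ad = ((1.0 + math.exp((v + 37.4) / 30.0))
                      / (240.0 * (0.5 + root)))
                bd = ad * root
                a11 = 1.0 + dt * (aht + bht)
                a12 = dt * aht
                a21 = dt * bd
                a22 = 1.0 + dt * (ad + bd)
                r1 = hT[j] + dt * aht
                r2 = dg[j] + dt * bd
                det = a11 * a22 - a12 * a21
                ht_new = (r1 * a22 - a12 * r2) / det
                d_new = (a11 * r2 - a21 * r1) / det
                hT[j] = min(1.0, max(0.0, ht_new))
                dg[j] = min(1.0, max(0.0, d_new))
            # persistent Na
            if gNaP[j] > 0.0:
                p_inf = 1.0 / (1.0 + math.exp(-(v + 48.0) / 10.0))
                if v < -40.0:
                    taup = 0.025 + 0.14 * math.exp((v + 40.0) / 10.0)
                else:
                    taup = 0.02 + 0.145 * math.exp(-(v + 40.0) / 10.0)
                p[j] = p_inf + (p[j] - p_inf) * math.exp(-dt / taup)
            # HVA Ca gate + calcium shell
            if gCaD[j] > 0.0:
                ac = _ramp(v + 13.0, 0.3, 0.1)
                bc = 10.0 * math.exp(-(v + 38.0) / 18.0)
                c[j] = _exp_update(c[j], ac, bc, dt)
                ica = gCaD[j] * c[j] ** 3 * (v - VCa[j])  # mA/cm^2
                ca_inf = Cares + tauCa * (-ca_coef * ica)
                ca = ca_inf + (Ca[j] - ca_inf) * math.exp(-dt / tauCa)
                if ca < 1e-12:
                    ca = 1e-12
                Ca[j] = ca
                VCa[j] = rt2f * math.log(Cae / ca)

        # ---- implicit voltage solve (tree) -------------------------------
        for j in range(N):
            v = V[j]
            gna = gNa[j] * m[j] ** 3 * h[j]
            gca = gCa[j] * c[j] ** 3
            x = Ca[j] * Ca[j] * inv_diss2
            gkca = gKCaM[j] * x / (1.0 + x)
            gk = gK[j] * n[j] ** 4 + gKA[j] * a[j] ** 3 * hA[j] + gkca
            gh_ = gH[j] * l[j]
            gt = gT[j] * mT[j] ** 3 * hT[j]
            gp = gNaP[j] * p[j]
            gsum = gL[j] + gna + gca + gk + gh_ + gt + gp
            gE = (gL[j] * VL + gna * VNa + gca * VCa[j] + gk * VK
                  + gh_ * Vh + gt * VT + gp * VNa)
            cd = cap[j] / dte
            diag[j] = cd + gsum
            rhs[j] = cd * v + gE
        for k in range(stim_comps.shape[0]):
            rhs[stim_comps[k]] += stim_amps[k, i]
        for j in range(1, N):
            diag[j] += gax[j]
            diag[parent[j]] += gax[j]
        for j in range(N - 1, 0, -1):
            f = gax[j] / diag[j]
            pj = parent[j]
            diag[pj] -= f * gax[j]
            rhs[pj] += f * rhs[j]
        sol0 = rhs[0] / diag[0]
        if use_cn:
            V[0] = 2.0 * sol0 - V[0]
        else:
            V[0] = sol0
        # forward sweep needs the *solved* potentials, so keep them in rhs
        rhs[0] = sol0
        for j in range(1, N):
            solj = (rhs[j] + gax[j] * rhs[parent[j]]) / diag[j]
            rhs[j] = solj
            if use_cn:
                V[j] = 2.0 * solj - V[j]
            else:
                V[j] = solj

        if not math.isfinite(V[0]):
            return i
        for s in range(rec_idx.shape[0]):
            recV[s, i + 1] = V[rec_idx[s]]
        if rec_cur:
            v0 = V[0]
            inv_area0 = 1e-6 / area[0]
            x0 = Ca[0] * Ca[0] * inv_diss2
            curOut[0, i + 1] = gL[0] * inv_area0 * (v0 - VL)
            curOut[1, i + 1] = (gNa[0] * m[0] ** 3 * h[0] * inv_area0
                                * (v0 - VNa))
            curOut[2, i + 1] = gCa[0] * c[0] ** 3 * inv_area0 * (v0 - VCa[0])
            curOut[3, i + 1] = gK[0] * n[0] ** 4 * inv_area0 * (v0 - VK)
            curOut[4, i + 1] = (gKA[0] * a[0] ** 3 * hA[0] * inv_area0
                                * (v0 - VK))
            curOut[5, i + 1] = (gKCaM[0] * x0 / (1.0 + x0) * inv_area0
                                * (v0 - VK))
            curOut[6, i + 1] = gH[0] * l[0] * inv_area0 * (v0 - Vh)
            curOut[7, i + 1] = (gT[0] * mT[0] ** 3 * hT[0] * inv_area0
                                * (v0 - VT))
            curOut[8, i + 1] = gNaP[0] * p[0] * inv_area0 * (v0 - VNa)
    return -1
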