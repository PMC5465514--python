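"""Compiled per-cell integration kernel.

Scalar transcription of the TNNP06 update in :mod:`cardioviz._tnnp06`,
jitted with numba for the inner loops of the single-cell and tissue
drivers. One step of the kernel agrees with the vectorized numpy reference
to floating-point roundoff (asserted in the test suite).

Parameter row layout of the ``(NPAR, n)`` array (see PAR_NAMES):
g_Na, g_K1, g_to, g_Kr, g_Ks, g_CaL, k_NaCa, P_NaK, g_pCa, g_pK, g_bCa, g_bNa.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._tnnp06 import (
    ALPHA_NACA, BUFC, BUFSR, BUFSS, CAO, CAPACITANCE, EC, FARADAY, GAMMA_NACA,
    K1_PRIME, K2_PRIME, K3, K4, KBUFC, KBUFSR, KBUFSS, KM_CA, KM_K, KM_NA,
    KM_NAI, KO, KPCA, KSAT, KUP, MAXSR, MINSR, NAO, P_KNA, RTONF, VC, VLEAK,
    VMAXUP, VREL, VSR, VSS, VXFER,
)

PAR_NAMES = ("g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL",
             "k_NaCa", "P_NaK", "g_pCa", "g_pK", "g_bCa", "g_bNa")
NPAR = len(PAR_NAMES)
PAR_IDX = {name: i for i, name in enumerate(PAR_NAMES)}


@njit(cache=True, fastmath=False)
def step_cells(S, P, is_endo, istim, ext, dt, cm):  # pragma: no cover - jitted
    """Advance all cells one step of ``dt`` (ms), in place.

    S : (19, n) state, P : (12, n) parameters, is_endo : (n,) uint8,
    istim : (n,) stimulus pA/pF, ext : (n,) extra dVm/dt (diffusion), mV/ms.
    """
    n = S.shape[1]
    sqrt_ko = math.sqrt(KO / 5.4)
    for i in range(n):
        Vm = S[0, i]
        m = S[1, i]; h = S[2, i]; j = S[3, i]
        xr1 = S[4, i]; xr2 = S[5, i]; xs = S[6, i]
        r = S[7, i]; s = S[8, i]
        d = S[9, i]; f = S[10, i]; f2 = S[11, i]; fcass = S[12, i]
        rbar = S[13, i]
        Cai = S[14, i]; CaSR = S[15, i]; CaSS = S[16, i]
        Nai = S[17, i]; Ki = S[18, i]

        # --- reversal potentials
        E_Na = RTONF * math.log(NAO / Nai)
        E_K = RTONF * math.log(KO / Ki)
        E_Ks = RTONF * math.log((KO + P_KNA * NAO) / (Ki + P_KNA * Nai))
        E_Ca = 0.5 * RTONF * math.log(CAO / Cai)

        # --- currents
        I_Na = P[0, i] * m ** 3 * h * j * (Vm - E_Na)

        a_K1 = 0.1 / (1.0 + math.exp(0.06 * (Vm - E_K - 200.0)))
        b_K1 = ((3.0 * math.exp(0.0002 * (Vm - E_K + 100.0))
                 + math.exp(0.1 * (Vm - E_K - 10.0)))
                / (1.0 + math.exp(-0.5 * (Vm - E_K))))
        I_K1 = P[1, i] * (a_K1 / (a_K1 + b_K1)) * sqrt_ko * (Vm - E_K)

        I_to = P[2, i] * r * s * (Vm - E_K)
        I_Kr = P[3, i] * sqrt_ko * xr1 * xr2 * (Vm - E_K)
        I_Ks = P[4, i] * xs ** 2 * (Vm - E_Ks)

        z = 2.0 * (Vm - 15.0) / RTONF
        if abs(z) < 1e-8:
            ratio = 1.0  # limit of z/(e^z - 1)
        else:
            ratio = z / math.expm1(z)
        I_CaL = (P[5, i] * d * f * f2 * fcass * 2.0 * FARADAY * ratio
                 * (0.25 * CaSS * math.exp(z) - CAO))

        ex1 = math.exp(GAMMA_NACA * Vm / RTONF)
        ex2 = math.exp((GAMMA_NACA - 1.0) * Vm / RTONF)
        I_NaCa = (P[6, i]
                  * (ex1 * Nai ** 3 * CAO - ex2 * NAO ** 3 * Cai * ALPHA_NACA)
                  / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
                     * (1.0 + KSAT * ex2)))

        I_NaK = (P[7, i] * KO * Nai
                 / ((KO + KM_K) * (Nai + KM_NA))
                 / (1.0 + 0.1245 * math.exp(-0.1 * Vm / RTONF)
                    + 0.0353 * math.exp(-Vm / RTONF)))

        I_pCa = P[8, i] * Cai / (Cai + KPCA)
        I_pK = P[9, i] * (Vm - E_K) / (1.0 + math.exp((25.0 - Vm) / 5.98))
        I_bCa = P[10, i] * (Vm - E_Ca)
        I_bNa = P[11, i] * (Vm - E_Na)

        I_ion = (I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL
                 + I_NaCa + I_NaK + I_pCa + I_pK + I_bCa + I_bNa)

        # --- calcium cycling fluxes
        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / CaSR) ** 2)
        k1 = K1_PRIME / kcasr
        k2 = K2_PRIME * kcasr
        o_gate = k1 * CaSS ** 2 * rbar / (K3 + k1 * CaSS ** 2)
        I_rel = VREL * o_gate * (CaSR - CaSS)
        I_leak = VLEAK * (CaSR - Cai)
        I_up = VMAXUP / (1.0 + (KUP / Cai) ** 2)
        I_xfer = VXFER * (CaSS - Cai)

        stim = istim[i]
        d_rbar = -k2 * CaSS * rbar + K4 * (1.0 - rbar)
        buf_c = 1.0 / (1.0 + BUFC * KBUFC / (Cai + KBUFC) ** 2)
        d_Cai = buf_c * ((I_leak - I_up) * VSR / VC + I_xfer
                         - (I_bCa + I_pCa - 2.0 * I_NaCa)
                         * CAPACITANCE / (2.0 * VC * FARADAY))
        buf_sr = 1.0 / (1.0 + BUFSR * KBUFSR / (CaSR + KBUFSR) ** 2)
        d_CaSR = buf_sr * (I_up - I_rel - I_leak)
        buf_ss = 1.0 / (1.0 + BUFSS * KBUFSS / (CaSS + KBUFSS) ** 2)
        d_CaSS = buf_ss * (-I_CaL * CAPACITANCE / (2.0 * VSS * FARADAY)
                           + I_rel * VSR / VSS - I_xfer * VC / VSS)
        d_Nai = -(I_Na + I_bNa + 3.0 * I_NaK + 3.0 * I_NaCa) \
            * CAPACITANCE / (VC * FARADAY)
        d_Ki = -(I_K1 + I_to + I_Kr + I_Ks + I_pK + stim
                 - 2.0 * I_NaK) * CAPACITANCE / (VC * FARADAY)

        # --- Rush-Larsen gate updates
        m_inf = 1.0 / (1.0 + math.exp((-56.86 - Vm) / 9.03)) ** 2
        a_m = 1.0 / (1.0 + math.exp((-60.0 - Vm) / 5.0))
        b_m = (0.1 / (1.0 + math.exp((Vm + 35.0) / 5.0))
               + 0.1 / (1.0 + math.exp((Vm - 50.0) / 200.0)))
        tau_m = a_m * b_m

        h_inf = 1.0 / (1.0 + math.exp((Vm + 71.55) / 7.43)) ** 2
        if Vm < -40.0:
            a_h = 0.057 * math.exp(-(Vm + 80.0) / 6.8)
            b_h = 2.7 * math.exp(0.079 * Vm) + 3.1e5 * math.exp(0.3485 * Vm)
            a_j = ((-2.5428e4 * math.exp(0.2444 * Vm)
                    - 6.948e-6 * math.exp(-0.04391 * Vm))
                   * (Vm + 37.78) / (1.0 + math.exp(0.311 * (Vm + 79.23))))
            b_j = (0.02424 * math.exp(-0.01052 * Vm)
                   / (1.0 + math.exp(-0.1378 * (Vm + 40.14))))
        else:
            a_h = 0.0
            b_h = 0.77 / (0.13 * (1.0 + math.exp(-(Vm + 10.66) / 11.1)))
            a_j = 0.0
            b_j = (0.6 * math.exp(0.057 * Vm)
                   / (1.0 + math.exp(-0.1 * (Vm + 32.0))))
        tau_h = 1.0 / (a_h + b_h)
        tau_j = 1.0 / (a_j + b_j)

        xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - Vm) / 7.0))
        tau_xr1 = (450.0 / (1.0 + math.exp((-45.0 - Vm) / 10.0))
                   * 6.0 / (1.0 + math.exp((Vm + 30.0) / 11.5)))
        xr2_inf = 1.0 / (1.0 + math.exp((Vm + 88.0) / 24.0))
        tau_xr2 = (3.0 / (1.0 + math.exp((-60.0 - Vm) / 20.0))
                   * 1.12 / (1.0 + math.exp((Vm - 60.0) / 20.0)))
        xs_inf = 1.0 / (1.0 + math.exp((-5.0 - Vm) / 14.0))
        tau_xs = (1400.0 / math.sqrt(1.0 + math.exp((5.0 - Vm) / 6.0))
                  * 1.0 / (1.0 + math.exp((Vm - 35.0) / 15.0)) + 80.0)
        r_inf = 1.0 / (1.0 + math.exp((20.0 - Vm) / 6.0))
        tau_r = 9.5 * math.exp(-((Vm + 40.0) ** 2) / 1800.0) + 0.8
        if is_endo[i]:
            s_inf = 1.0 / (1.0 + math.exp((Vm + 28.0) / 5.0))
            tau_s = 1000.0 * math.exp(-((Vm + 67.0) ** 2) / 1000.0) + 8.0
        else:
            s_inf = 1.0 / (1.0 + math.exp((Vm + 20.0) / 5.0))
            tau_s = (85.0 * math.exp(-((Vm + 45.0) ** 2) / 320.0)
                     + 5.0 / (1.0 + math.exp((Vm - 20.0) / 5.0)) + 3.0)
        d_inf = 1.0 / (1.0 + math.exp((-8.0 - Vm) / 7.5))
        tau_d = ((1.4 / (1.0 + math.exp((-35.0 - Vm) / 13.0)) + 0.25)
                 * 1.4 / (1.0 + math.exp((Vm + 5.0) / 5.0))
                 + 1.0 / (1.0 + math.exp((50.0 - Vm) / 20.0)))
        f_inf = 1.0 / (1.0 + math.exp((Vm + 20.0) / 7.0))
        tau_f = (1102.5 * math.exp(-((Vm + 27.0) ** 2) / 225.0)
                 + 200.0 / (1.0 + math.exp((13.0 - Vm) / 10.0))
                 + 180.0 / (1.0 + math.exp((Vm + 30.0) / 10.0)) + 20.0)
        f2_inf = 0.67 / (1.0 + math.exp((Vm + 35.0) / 7.0)) + 0.33
        tau_f2 = (562.0 * math.exp(-((Vm + 27.0) ** 2) / 240.0)
                  + 31.0 / (1.0 + math.exp((25.0 - Vm) / 10.0))
                  + 80.0 / (1.0 + math.exp((Vm + 30.0) / 10.0)))
        q = 1.0 / (1.0 + (CaSS / 0.05) ** 2)
        fcass_inf = 0.6 * q + 0.4
        tau_fcass = 80.0 * q + 2.0

        S[1, i] = m_inf - (m_inf - m) * math.exp(-dt / tau_m)
        S[2, i] = h_inf - (h_inf - h) * math.exp(-dt / tau_h)
        S[3, i] = h_inf - (h_inf - j) * math.exp(-dt / tau_j)
        S[4, i] = xr1_inf - (xr1_inf - xr1) * math.exp(-dt / tau_xr1)
        S[5, i] = xr2_inf - (xr2_inf - xr2) * math.exp(-dt / tau_xr2)
        S[6, i] = xs_inf - (xs_inf - xs) * math.exp(-dt / tau_xs)
        S[7, i] = r_inf - (r_inf - r) * math.exp(-dt / tau_r)
        S[8, i] = s_inf - (s_inf - s) * math.exp(-dt / tau_s)
        S[9, i] = d_inf - (d_inf - d) * math.exp(-dt / tau_d)
        S[10, i] = f_inf - (f_inf - f) * math.exp(-dt / tau_f)
        S[11, i] = f2_inf - (f2_inf - f2) * math.exp(-dt / tau_f2)
        S[12, i] = fcass_inf - (fcass_inf - fcass) * math.exp(-dt / tau_fcass)

        # --- forward Euler updates
        S[13, i] = rbar + dt * d_rbar
        S[14, i] = Cai + dt * d_Cai
        S[15, i] = CaSR + dt * d_CaSR
        S[16, i] = CaSS + dt * d_CaSS
        S[17, i] = Nai + dt * d_Nai
        S[18, i] = Ki + dt * d_Ki
        S[0, i] = Vm + dt * (-(I_ion + stim) / cm + ext[i])
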