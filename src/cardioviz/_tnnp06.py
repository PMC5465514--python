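"""Human ventricular myocyte model of ten Tusscher & Panfilov (2006).

Vectorized numpy reference formulation of the 12-current human ventricular
cell model (TNNP06): fast sodium, L-type calcium, transient outward, rapid
and slow delayed rectifier, inward rectifier, Na+/Ca2+ exchanger, Na+/K+
pump, plateau and background currents, plus CICR calcium cycling between
the subspace, cytosol and sarcoplasmic reticulum.

Constants and rate formulations follow the 2006 epicardial/endocardial/
mid-myocardial variants of the model (Am J Physiol Heart Circ Physiol
291:H1088-H1100). Units: mV, ms, mM, pA/pF.

State vector layout (first axis of a ``(NVAR, n)`` float64 array):

====  =======  ==========================================
idx   name     meaning
====  =======  ==========================================
0     Vm       transmembrane potential, mV
1     m        I_Na activation gate
2     h        I_Na fast inactivation gate
3     j        I_Na slow inactivation gate
4     xr1      I_Kr activation gate
5     xr2      I_Kr inactivation gate
6     xs       I_Ks activation gate
7     r        I_to activation gate
8     s        I_to inactivation gate
9     d        I_CaL activation gate
10    f        I_CaL voltage inactivation gate
11    f2       I_CaL slow voltage inactivation gate
12    fcass    I_CaL subspace-Ca inactivation gate
13    rbar     fraction of non-adapted RyR (R' of CICR)
14    Cai      free cytosolic Ca2+, mM
15    CaSR     free sarcoplasmic-reticulum Ca2+, mM
16    CaSS     free dyadic-subspace Ca2+, mM
17    Nai      intracellular Na+, mM
18    Ki       intracellular K+, mM
====  =======  ==========================================
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# physical constants and fixed model parameters
# ---------------------------------------------------------------------------

R_GAS = 8314.472  # mJ/(mol K)
T_KELVIN = 310.0
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * T_KELVIN / FARADAY  # mV

# extracellular concentrations, mM
KO = 5.4
CAO = 2.0
NAO = 140.0

# cell geometry (volumes in uL) and whole-cell capacitance (uF)
VC = 0.016404
VSR = 0.001094
VSS = 0.00005468
CAPACITANCE = 0.185

# calcium buffering
BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025

# SERCA / leak / transfer / CICR
VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1_PRIME = 0.15
K2_PRIME = 0.045
K3 = 0.060
K4 = 0.005
EC = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038

# exchanger / pump parameters
KNACA = 1000.0
KM_NAI = 87.5
KM_CA = 1.38
KSAT = 0.1
GAMMA_NACA = 0.35
ALPHA_NACA = 2.5
KM_K = 1.0
KM_NA = 40.0
KPCA = 0.0005
P_KNA = 0.03

NVAR = 19

VAR_NAMES = (
    "Vm", "m", "h", "j", "xr1", "xr2", "xs", "r", "s",
    "d", "f", "f2", "fcass", "rbar", "Cai", "CaSR", "CaSS", "Nai", "Ki",
)
IDX = {name: i for i, name in enumerate(VAR_NAMES)}

#: gates integrated by the Rush-Larsen exponential update (HH-type, all
#: voltage dependent except fcass which relaxes toward a CaSS-set target)
RL_GATES = ("m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2")

CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kr", "I_Ks", "I_CaL",
    "I_NaCa", "I_NaK", "I_pCa", "I_pK", "I_bCa", "I_bNa",
)

# default maximal conductances/permeabilities, keyed as in CellParameters;
# g_to and g_Ks depend on the transmural cell class.
G_NA = 14.838      # nS/pF
G_K1 = 5.405
G_KR = 0.153
G_CAL = 0.0000398  # cm^3/(uF s)
G_PCA = 0.1238
G_PK = 0.0146
G_BNA = 0.00029
G_BCA = 0.000592
G_TO = {"endo": 0.073, "mid": 0.294, "epi": 0.294}
G_KS = {"endo": 0.392, "mid": 0.098, "epi": 0.392}
P_NAK = 2.724

# published (paced steady-state) initial conditions of the epicardial
# variant; the packaged quiescent states are obtained by relaxing these.
PUBLISHED_INITIAL = np.array([
    -85.23,     # Vm
    0.00172,    # m
    0.7444,     # h
    0.7045,     # j
    0.00621,    # xr1
    0.4712,     # xr2
    0.0095,     # xs
    2.42e-8,    # r
    0.999998,   # s
    3.373e-5,   # d
    0.7888,     # f
    0.9755,     # f2
    0.9953,     # fcass
    0.9073,     # rbar
    0.000126,   # Cai
    3.64,       # CaSR
    0.00036,    # CaSS
    8.604,      # Nai
    136.89,     # Ki
])


# ---------------------------------------------------------------------------
# gating-variable rates: steady state and time constant per gate
# ---------------------------------------------------------------------------

def gate_steady_tau(Vm, is_endo):
    """Steady states and time constants of the 11 voltage-dependent gates.

    Parameters
    ----------
    Vm : ndarray
        Membrane potential, mV.
    is_endo : ndarray of bool
        Endocardial cells use distinct ``s``-gate kinetics.

    Returns
    -------
    dict mapping gate name -> (n_inf, tau_n) arrays (dimensionless, ms).
    """
    Vm = np.asarray(Vm, dtype=np.float64)
    is_endo = np.broadcast_to(np.asarray(is_endo, dtype=bool), Vm.shape)
    out = {}

    m_inf = 1.0 / (1.0 + np.exp((-56.86 - Vm) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + np.exp((-60.0 - Vm) / 5.0))
    b_m = 0.1 / (1.0 + np.exp((Vm + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((Vm - 50.0) / 200.0))
    out["m"] = (m_inf, a_m * b_m)

    h_inf = 1.0 / (1.0 + np.exp((Vm + 71.55) / 7.43)) ** 2
    low = Vm < -40.0
    a_h = np.where(low, 0.057 * np.exp(-(Vm + 80.0) / 6.8), 0.0)
    b_h = np.where(
        low,
        2.7 * np.exp(0.079 * Vm) + 3.1e5 * np.exp(0.3485 * Vm),
        0.77 / (0.13 * (1.0 + np.exp(-(Vm + 10.66) / 11.1))),
    )
    out["h"] = (h_inf, 1.0 / (a_h + b_h))

    a_j = np.where(
        low,
        (-2.5428e4 * np.exp(0.2444 * Vm) - 6.948e-6 * np.exp(-0.04391 * Vm))
        * (Vm + 37.78) / (1.0 + np.exp(0.311 * (Vm + 79.23))),
        0.0,
    )
    b_j = np.where(
        low,
        0.02424 * np.exp(-0.01052 * Vm) / (1.0 + np.exp(-0.1378 * (Vm + 40.14))),
        0.6 * np.exp(0.057 * Vm) / (1.0 + np.exp(-0.1 * (Vm + 32.0))),
    )
    out["j"] = (h_inf, 1.0 / (a_j + b_j))  # j_inf == h_inf in TNNP06

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - Vm) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - Vm) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((Vm + 30.0) / 11.5))
    out["xr1"] = (xr1_inf, a_xr1 * b_xr1)

    xr2_inf = 1.0 / (1.0 + np.exp((Vm + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - Vm) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((Vm - 60.0) / 20.0))
    out["xr2"] = (xr2_inf, a_xr2 * b_xr2)

    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - Vm) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - Vm) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((Vm - 35.0) / 15.0))
    out["xs"] = (xs_inf, a_xs * b_xs + 80.0)

    r_inf = 1.0 / (1.0 + np.exp((20.0 - Vm) / 6.0))
    tau_r = 9.5 * np.exp(-((Vm + 40.0) ** 2) / 1800.0) + 0.8
    out["r"] = (r_inf, tau_r)

    s_inf_epi = 1.0 / (1.0 + np.exp((Vm + 20.0) / 5.0))
    tau_s_epi = (85.0 * np.exp(-((Vm + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + np.exp((Vm - 20.0) / 5.0)) + 3.0)
    s_inf_endo = 1.0 / (1.0 + np.exp((Vm + 28.0) / 5.0))
    tau_s_endo = 1000.0 * np.exp(-((Vm + 67.0) ** 2) / 1000.0) + 8.0
    out["s"] = (np.where(is_endo, s_inf_endo, s_inf_epi),
                np.where(is_endo, tau_s_endo, tau_s_epi))

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - Vm) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - Vm) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((Vm + 5.0) / 5.0))
    c_d = 1.0 / (1.0 + np.exp((50.0 - Vm) / 20.0))
    out["d"] = (d_inf, a_d * b_d + c_d)

    f_inf = 1.0 / (1.0 + np.exp((Vm + 20.0) / 7.0))
    tau_f = (1102.5 * np.exp(-((Vm + 27.0) ** 2) / 225.0)
             + 200.0 / (1.0 + np.exp((13.0 - Vm) / 10.0))
             + 180.0 / (1.0 + np.exp((Vm + 30.0) / 10.0)) + 20.0)
    out["f"] = (f_inf, tau_f)

    f2_inf = 0.67 / (1.0 + np.exp((Vm + 35.0) / 7.0)) + 0.33
    tau_f2 = (562.0 * np.exp(-((Vm + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + np.exp((25.0 - Vm) / 10.0))
              + 80.0 / (1.0 + np.exp((Vm + 30.0) / 10.0)))
    out["f2"] = (f2_inf, tau_f2)

    return out


def fcass_steady_tau(CaSS):
    """Subspace-calcium inactivation gate target and time constant."""
    CaSS = np.asarray(CaSS, dtype=np.float64)
    q = 1.0 / (1.0 + (CaSS / 0.05) ** 2)
    return 0.6 * q + 0.4, 80.0 * q + 2.0


# ---------------------------------------------------------------------------
# ionic currents
# ---------------------------------------------------------------------------

def ionic_currents(S, g):
    """All 12 membrane currents of the model, pA/pF.

    Parameters
    ----------
    S : ndarray, shape (NVAR, n)
        State array (see module docstring for the layout).
    g : dict
        Conductances/permeabilities per cell: scalars or (n,) arrays with
        keys ``g_Na g_K1 g_to g_Kr g_Ks g_CaL k_NaCa P_NaK g_pCa g_pK
        g_bCa g_bNa``. RV-epicardial scaling is folded into ``g_Ks``/``g_to``
        by the caller.

    Returns
    -------
    dict mapping current name (see CURRENT_NAMES) -> (n,) array, pA/pF.
    """
    Vm = S[IDX["Vm"]]
    Nai, Ki, Cai, CaSS = S[IDX["Nai"]], S[IDX["Ki"]], S[IDX["Cai"]], S[IDX["CaSS"]]

    E_Na = RTONF * np.log(NAO / Nai)
    E_K = RTONF * np.log(KO / Ki)
    E_Ks = RTONF * np.log((KO + P_KNA * NAO) / (Ki + P_KNA * Nai))
    E_Ca = 0.5 * RTONF * np.log(CAO / Cai)

    out = {}
    out["I_Na"] = g["g_Na"] * S[IDX["m"]] ** 3 * S[IDX["h"]] * S[IDX["j"]] * (Vm - E_Na)

    a_K1 = 0.1 / (1.0 + np.exp(0.06 * (Vm - E_K - 200.0)))
    b_K1 = ((3.0 * np.exp(0.0002 * (Vm - E_K + 100.0)) + np.exp(0.1 * (Vm - E_K - 10.0)))
            / (1.0 + np.exp(-0.5 * (Vm - E_K))))
    xk1_inf = a_K1 / (a_K1 + b_K1)
    out["I_K1"] = g["g_K1"] * xk1_inf * np.sqrt(KO / 5.4) * (Vm - E_K)

    out["I_to"] = g["g_to"] * S[IDX["r"]] * S[IDX["s"]] * (Vm - E_K)
    out["I_Kr"] = g["g_Kr"] * np.sqrt(KO / 5.4) * S[IDX["xr1"]] * S[IDX["xr2"]] * (Vm - E_K)
    out["I_Ks"] = g["g_Ks"] * S[IDX["xs"]] ** 2 * (Vm - E_Ks)

    # GHK-like driving term of I_CaL. With z = 2(Vm-15)F/RT the current is
    # g * d f f2 fcass * 2 F * [z/(e^z - 1)] * (0.25 CaSS e^z - Cao);
    # z/(e^z - 1) -> 1 as z -> 0 removes the singularity at Vm = 15 mV.
    z = 2.0 * (Vm - 15.0) / RTONF
    small = np.abs(z) < 1e-8
    zs = np.where(small, 1.0, z)
    ratio = np.where(small, 1.0, zs / np.expm1(zs))
    out["I_CaL"] = (g["g_CaL"] * S[IDX["d"]] * S[IDX["f"]] * S[IDX["f2"]] * S[IDX["fcass"]]
                    * 2.0 * FARADAY * ratio * (0.25 * CaSS * np.exp(z) - CAO))

    ex1 = np.exp(GAMMA_NACA * Vm / RTONF)
    ex2 = np.exp((GAMMA_NACA - 1.0) * Vm / RTONF)
    out["I_NaCa"] = (g["k_NaCa"]
                     * (ex1 * Nai ** 3 * CAO - ex2 * NAO ** 3 * Cai * ALPHA_NACA)
                     / ((KM_NAI ** 3 + NAO ** 3) * (KM_CA + CAO)
                        * (1.0 + KSAT * ex2)))

    out["I_NaK"] = (g["P_NaK"] * KO * Nai
                    / ((KO + KM_K) * (Nai + KM_NA))
                    / (1.0 + 0.1245 * np.exp(-0.1 * Vm / RTONF)
                       + 0.0353 * np.exp(-Vm / RTONF)))

    out["I_pCa"] = g["g_pCa"] * Cai / (Cai + KPCA)
    out["I_pK"] = g["g_pK"] * (Vm - E_K) / (1.0 + np.exp((25.0 - Vm) / 5.98))
    out["I_bCa"] = g["g_bCa"] * (Vm - E_Ca)
    out["I_bNa"] = g["g_bNa"] * (Vm - E_Na)
    return out


def total_ionic_current(S, g):
    """Sum of the 12 currents, pA/pF (Eq. of the monodomain reaction term)."""
    cur = ionic_currents(S, g)
    tot = cur["I_Na"]
    for name in CURRENT_NAMES[1:]:
        tot = tot + cur[name]
    return tot


# ---------------------------------------------------------------------------
# calcium cycling and time derivatives of the non-gate variables
# ---------------------------------------------------------------------------

def calcium_fluxes(S):
    """SR release/uptake/leak/transfer fluxes (mM/ms) and the RyR rate k2*CaSS."""
    Cai, CaSR, CaSS = S[IDX["Cai"]], S[IDX["CaSR"]], S[IDX["CaSS"]]
    rbar = S[IDX["rbar"]]
    kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC / CaSR) ** 2)
    k1 = K1_PRIME / kcasr
    k2 = K2_PRIME * kcasr
    o_gate = k1 * CaSS ** 2 * rbar / (K3 + k1 * CaSS ** 2)
    I_rel = VREL * o_gate * (CaSR - CaSS)
    I_leak = VLEAK * (CaSR - Cai)
    I_up = VMAXUP / (1.0 + (KUP / Cai) ** 2)
    I_xfer = VXFER * (CaSS - Cai)
    return {"I_rel": I_rel, "I_leak": I_leak, "I_up": I_up, "I_xfer": I_xfer,
            "k2": k2}


def concentration_derivatives(S, currents, fluxes, I_stim):
    """Forward-Euler right-hand sides of rbar, Cai, CaSR, CaSS, Nai, Ki."""
    Cai, CaSR, CaSS = S[IDX["Cai"]], S[IDX["CaSR"]], S[IDX["CaSS"]]
    rbar = S[IDX["rbar"]]
    c = currents
    f = fluxes

    d_rbar = -f["k2"] * CaSS * rbar + K4 * (1.0 - rbar)

    buf_c = 1.0 / (1.0 + BUFC * KBUFC / (Cai + KBUFC) ** 2)
    d_Cai = buf_c * ((f["I_leak"] - f["I_up"]) * VSR / VC + f["I_xfer"]
                     - (c["I_bCa"] + c["I_pCa"] - 2.0 * c["I_NaCa"])
                     * CAPACITANCE / (2.0 * VC * FARADAY))

    buf_sr = 1.0 / (1.0 + BUFSR * KBUFSR / (CaSR + KBUFSR) ** 2)
    d_CaSR = buf_sr * (f["I_up"] - f["I_rel"] - f["I_leak"])

    buf_ss = 1.0 / (1.0 + BUFSS * KBUFSS / (CaSS + KBUFSS) ** 2)
    d_CaSS = buf_ss * (-c["I_CaL"] * CAPACITANCE / (2.0 * VSS * FARADAY)
                       + f["I_rel"] * VSR / VSS - f["I_xfer"] * VC / VSS)

    d_Nai = -(c["I_Na"] + c["I_bNa"] + 3.0 * c["I_NaK"] + 3.0 * c["I_NaCa"]) \
        * CAPACITANCE / (VC * FARADAY)
    d_Ki = -(c["I_K1"] + c["I_to"] + c["I_Kr"] + c["I_Ks"] + c["I_pK"] + I_stim
             - 2.0 * c["I_NaK"]) * CAPACITANCE / (VC * FARADAY)

    return {"rbar": d_rbar, "Cai": d_Cai, "CaSR": d_CaSR, "CaSS": d_CaSS,
            "Nai": d_Nai, "Ki": d_Ki}


def step_states_numpy(S, g, is_endo, I_stim, dt, Cm=1.0, ext=None):
    """Advance an array of cells by one step (reference implementation).

    Hodgkin-Huxley gates use the Rush-Larsen exponential update; fcass uses
    the same exponential form with its CaSS-driven target; rbar, the
    concentrations and Vm use forward Euler. ``ext`` (pA/pF-equivalent,
    i.e. mV/ms) is an optional extra dVm/dt term (tissue diffusion).

    Returns a new state array; the input is not modified.
    """
    S = np.asarray(S, dtype=np.float64)
    out = S.copy()
    Vm = S[IDX["Vm"]]

    currents = ionic_currents(S, g)
    I_ion = currents["I_Na"]
    for name in CURRENT_NAMES[1:]:
        I_ion = I_ion + currents[name]
    fluxes = calcium_fluxes(S)
    deriv = concentration_derivatives(S, currents, fluxes, I_stim)

    rates = gate_steady_tau(Vm, is_endo)
    for gate in RL_GATES:
        n_inf, tau = rates[gate]
        i = IDX[gate]
        out[i] = n_inf - (n_inf - S[i]) * np.exp(-dt / tau)
    fc_inf, fc_tau = fcass_steady_tau(S[IDX["CaSS"]])
    out[IDX["fcass"]] = fc_inf - (fc_inf - S[IDX["fcass"]]) * np.exp(-dt / fc_tau)

    for name in ("rbar", "Cai", "CaSR", "CaSS", "Nai", "Ki"):
        out[IDX[name]] = S[IDX[name]] + dt * deriv[name]

    dvm = -(I_ion + I_stim) / Cm
    if ext is not None:
        dvm = dvm + ext
    out[IDX["Vm"]] = Vm + dt * dvm
    return out
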