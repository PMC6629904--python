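"""Mahajan-Shiferaw rabbit ventricular myocyte model.

A 26-variable rabbit ventricular model: the transmembrane potential, ten
Hodgkin-Huxley gates (sodium m/h/j, rapid and slow delayed-rectifier
activation xr/xs1/xs2, transient-outward activation/inactivation
xtos/ytos/xtof/ytof), seven concentration/flux variables (cytosolic,
submembrane, SR, averaged junctional-SR and dyadic calcium, the whole-cell SR
release flux, and intracellular sodium), two troponin buffer occupancies, and
six occupancies of the 7-state Markov chain of the L-type calcium channel
(the open probability is the complement of the six tracked states).

Equations follow the model's original publication (a Shannon-type rabbit
model with reworked calcium cycling); they are not re-derived here.  The ten
HH gates are the dynamic variables of the quasi-active linearization; the
calcium/sodium/Markov block is the auxiliary vector P.

Membrane currents are returned in uA for a cell of capacitance
C = 3.1e-4 uF; rate laws are generic over floats and dual numbers.
"""

from __future__ import annotations

import numpy as np

from ..dual import exp, log, sqrt
from .base import IonicModel, MembraneState

__all__ = ["Mahajan"]

# physical constants
F = 96.485      # C/mmol
RGAS = 8.314    # J/(mol K)
TEMP = 308.0    # K
FONRT = F * 1000.0 / (RGAS * TEMP * 1000.0)  # 1/mV  (= F/RT with V in mV)
WCA = 8.0313    # conversion between Ca flux (uM/ms) and current (uA/uF)

# external ion concentrations (mM)
XNAO = 136.0
XKI = 140.0
XKO = 5.40
CAO = 1.8


class Mahajan(IonicModel):
    name = "mahajan"
    C = 3.1e-4  # uF, standard ventricular cell

    gate_names = ("m", "h", "j", "xr", "xs1", "xs2",
                  "xtos", "ytos", "xtof", "ytof")
    aux_names = ("Ca_i", "Ca_s", "Ca_SR", "Ca_JSR", "Ca_dyad", "J_rel",
                 "Na_i", "trop_i", "trop_s",
                 "c1", "c2", "i1Ca", "i1Ba", "i2Ca", "i2Ba")
    current_names = ("I_Na", "I_K1", "I_Kr", "I_Ks",
                     "I_tos", "I_tof", "I_CaL", "I_NaCa", "I_NaK")

    # maximal conductances (mS/uF) and transporter strengths
    g_Na = 12.0
    g_K1 = 0.3
    g_Kr = 0.0125
    g_Ks = 0.1386
    g_tos = 0.04
    g_tof = 0.11
    g_NaK = 1.5        # uA/uF
    g_NaCa = 0.84      # uM/ms
    g_Ca = 182.0       # mmol/(cm C); L-type strength
    p_Ca = 0.00054     # cm/s, L-type permeability

    # calcium cycling
    v_up = 0.4         # uM/ms
    c_up = 0.5         # uM
    g_leak = 0.00002069
    k_j = 50.0
    tau_d = 4.0        # ms, submembrane <-> cytosol diffusion
    tau_ps = 0.5       # ms, dyad <-> submembrane
    tau_a = 100.0      # ms, SR -> averaged junctional SR
    tau_r = 30.0       # ms, release-flux relaxation
    cstar = 90.0       # uM, SR-load gain break point
    av = 11.3
    ax = 0.3576        # 1/mV, steepness of the graded-release voltage gate
    g_rel = 2.0        # release gain; calibrated to whole-cell behavior
    gdyad = 500.0      # dyadic junction strength; calibrated with g_rel
    rel_dyad = 10.0    # release contribution to dyadic Ca; calibrated

    # buffers
    bcal, xkcal = 24.0, 7.0
    srmax, srkd = 47.0, 0.6
    bmem, kmem = 15.0, 0.3
    bsar, ksar = 42.0, 13.0
    btrop = 70.0
    xkon, xkoff = 0.0327, 0.0196

    # Markov L-type constants
    taupo = 1.0
    r1, r2 = 0.3, 3.0
    s1t, k1t = 0.00195, 0.00413
    k2, k2t = 1.03615e-4, 0.00224
    s6 = 8.0
    sx, sy, syr = 3.0, 4.0, 11.32
    vx = vy = vyr = -40.0
    tau3 = 3.0
    cat = 3.0
    cpt = 6.09365
    tca = 78.0329

    prNaK = 0.01833
    xkmko, xkmnai = 1.5, 12.0

    # ------------------------------------------------------------------ gates

    def gate_kinetics(self, V):
        # -- sodium m, h, j (Luo-Rudy style formulation)
        dv = V + 47.13
        if abs(float(dv)) < 1e-6:
            am = 3.2 * (1.0 + 0.05 * dv)
        else:
            am = 0.32 * dv / (1.0 - exp(-0.1 * dv))
        bm = 0.08 * exp(-V / 11.0)
        if V < -40.0:
            ah = 0.135 * exp((80.0 + V) / -6.8)
            bh = 3.56 * exp(0.079 * V) + 3.1e5 * exp(0.35 * V)
            aj = ((-1.2714e5 * exp(0.2444 * V) - 3.474e-5 * exp(-0.04391 * V))
                  * (V + 37.78) / (1.0 + exp(0.311 * (V + 79.23))))
            bj = 0.1212 * exp(-0.01052 * V) / (1.0 + exp(-0.1378 * (V + 40.14)))
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + exp((V + 10.66) / -11.1)))
            aj = 0.0
            bj = 0.3 * exp(-2.535e-7 * V) / (1.0 + exp(-0.1 * (V + 32.0)))
        m_eq, tau_m = am / (am + bm), 1.0 / (am + bm)
        h_eq, tau_h = ah / (ah + bh), 1.0 / (ah + bh)
        j_eq, tau_j = aj / (aj + bj), 1.0 / (aj + bj)

        # -- rapid delayed rectifier activation xr
        if abs(float(V) + 7.0) > 1e-3:
            xkrv1 = 0.00138 * (V + 7.0) / (1.0 - exp(-0.123 * (V + 7.0)))
        else:
            xkrv1 = 0.00138 / 0.123
        if abs(float(V) + 10.0) > 1e-3:
            xkrv2 = 0.00061 * (V + 10.0) / (exp(0.145 * (V + 10.0)) - 1.0)
        else:
            xkrv2 = 0.00061 / 0.145
        tau_xr = 1.0 / (xkrv1 + xkrv2)
        xr_eq = 1.0 / (1.0 + exp(-(V + 50.0) / 7.5))

        # -- slow delayed rectifier xs1, xs2
        xs1_eq = 1.0 / (1.0 + exp(-(V - 1.5) / 16.7))
        if abs(float(V) + 30.0) > 1e-3:
            tau_xs1 = 1.0 / (0.0000719 * (V + 30.0) / (1.0 - exp(-0.148 * (V + 30.0)))
                             + 0.000131 * (V + 30.0) / (exp(0.0687 * (V + 30.0)) - 1.0))
        else:
            tau_xs1 = 1.0 / (0.0000719 / 0.148 + 0.000131 / 0.0687)
        xs2_eq = xs1_eq
        tau_xs2 = 4.0 * tau_xs1

        # -- transient outward (slow and fast components)
        rt1 = -(V + 3.0) / 15.0
        rt2 = (V + 33.5) / 10.0
        rt3 = (V + 60.0) / 10.0
        xtos_eq = 1.0 / (1.0 + exp(rt1))
        ytos_eq = 1.0 / (1.0 + exp(rt2))
        tau_xtos = 9.0 / (1.0 + exp(-rt1)) + 0.5
        tau_ytos = 3000.0 / (1.0 + exp(rt3)) + 30.0
        xtof_eq = xtos_eq
        ytof_eq = ytos_eq
        tau_xtof = 3.5 * exp(-(V / 30.0) * (V / 30.0)) + 1.5
        tau_ytof = 20.0 / (1.0 + exp(rt2)) + 20.0

        f_eq = [m_eq, h_eq, j_eq, xr_eq, xs1_eq, xs2_eq,
                xtos_eq, ytos_eq, xtof_eq, ytof_eq]
        tau = [tau_m, tau_h, tau_j, tau_xr, tau_xs1, tau_xs2,
               tau_xtos, tau_ytos, tau_xtof, tau_ytof]
        return f_eq, tau

    # --------------------------------------------------------------- currents

    def _currents(self, V, gates, P):
        """All membrane currents (uA/uF) plus shared intermediates."""
        m, h, j, xr, xs1, xs2, xtos, ytos, xtof, ytof = gates
        ci, cs, cj, cjp, cp, xir, nai = P[0], P[1], P[2], P[3], P[4], P[5], P[6]
        c1, c2, xi1ca, xi1ba, xi2ca, xi2ba = P[9], P[10], P[11], P[12], P[13], P[14]

        ek = log(XKO / XKI) / FONRT
        ena = log(XNAO / nai) / FONRT

        # fast sodium
        xina = self.g_Na * h * j * m * m * m * (V - ena)

        # inward rectifier
        aki = 1.02 / (1.0 + exp(0.2385 * (V - ek - 59.215)))
        bki = ((0.49124 * exp(0.08032 * (V - ek + 5.476))
                + exp(0.06175 * (V - ek - 594.31)))
               / (1.0 + exp(-0.5143 * (V - ek + 4.753))))
        xkin = aki / (aki + bki)
        xik1 = self.g_K1 * sqrt(XKO / 5.4) * xkin * (V - ek)

        # delayed rectifiers
        rg = 1.0 / (1.0 + exp((V + 33.0) / 22.4))
        xikr = self.g_Kr * sqrt(XKO / 5.4) * xr * rg * (V - ek)
        eks = log((XKO + self.prNaK * XNAO) / (XKI + self.prNaK * nai)) / FONRT
        gksx = 0.433 * (1.0 + 0.8 / (1.0 + (0.5 / ci) ** 3))
        xiks = self.g_Ks * gksx * xs1 * xs2 * (V - eks)

        # transient outward
        rs_inf = 1.0 / (1.0 + exp((V + 33.5) / 10.0))
        xitos = self.g_tos * xtos * (ytos + 0.5 * rs_inf) * (V - ek)
        xitof = self.g_tof * xtof * ytof * (V - ek)

        # L-type calcium (GHK flux through Markov open state)
        po = 1.0 - c1 - c2 - xi1ca - xi1ba - xi2ca - xi2ba
        cpm = cp / 1000.0  # dyadic Ca in mM
        za = V * 2.0 * FONRT
        factor1 = 4.0 * self.p_Ca * F * FONRT
        if abs(float(za)) < 1e-3:
            rxa = factor1 * (cpm * exp(za) - 0.341 * CAO) / (2.0 * FONRT)
        else:
            rxa = V * factor1 * (cpm * exp(za) - 0.341 * CAO) / (exp(za) - 1.0)
        jca = self.g_Ca * po * rxa          # uM/ms
        xica = 2.0 * WCA * jca

        # Na/Ca exchanger (senses submembrane calcium, in mM)
        csm = cs / 1000.0
        zw3 = (nai ** 3 * CAO * exp(V * 0.35 * FONRT)
               - XNAO ** 3 * csm * exp(V * (0.35 - 1.0) * FONRT))
        zw4 = 1.0 + 0.2 * exp(V * (0.35 - 1.0) * FONRT)
        aloss = 1.0 / (1.0 + (0.3 / cs) ** 3)
        yz1 = 1.3 * nai ** 3 + 87.5 ** 3 * csm
        yz2 = 12.3 ** 3 * CAO * (1.0 + csm / 0.0036)
        yz3 = 0.0036 * XNAO ** 3 * (1.0 + (nai / 12.3) ** 3)
        yz4 = nai ** 3 * CAO + XNAO ** 3 * csm
        jnaca = self.g_NaCa * aloss * zw3 / (zw4 * (yz1 + yz2 + yz3 + yz4))
        xinaca = WCA * jnaca

        # Na/K pump
        sigma = (exp(XNAO / 67.3) - 1.0) / 7.0
        fnak = 1.0 / (1.0 + 0.1245 * exp(-0.1 * V * FONRT)
                      + 0.0365 * sigma * exp(-V * FONRT))
        xinak = (self.g_NaK * fnak * (1.0 / (1.0 + self.xkmnai / nai))
                 * XKO / (XKO + self.xkmko))

        cur = {"I_Na": xina, "I_K1": xik1, "I_Kr": xikr, "I_Ks": xiks,
               "I_tos": xitos, "I_tof": xitof, "I_CaL": xica,
               "I_NaCa": xinaca, "I_NaK": xinak}
        aux = {"po": po, "rxa": rxa, "jca": jca, "jnaca": jnaca, "xina": xina,
               "xinak": xinak}
        return cur, aux

    def per_current(self, V, gates, P):
        cur, _ = self._currents(V, gates, P)
        return {k: self.C * v for k, v in cur.items()}

    # --------------------------------------------- auxiliary (P) dynamics

    def _markov_rates(self, V, cp):
        """Transition rates of the L-type Markov chain at (V, dyadic Ca)."""
        poinf = 1.0 / (1.0 + exp(-(V - 0.0) / self.s6))
        alpha = poinf / self.taupo
        beta = (1.0 - poinf) / self.taupo
        fca = 1.0 / (1.0 + (self.cat / cp) ** 3)
        s1 = 0.0182688 * fca
        k1 = 0.024168 * fca
        s2 = s1 * (self.r1 / self.r2) * (self.k2 / k1)
        s2t = self.s1t * (self.r1 / self.r2) * (self.k2t / self.k1t)
        poi = 1.0 / (1.0 + exp(-(V - self.vx) / self.sx))
        k3 = (1.0 - poi) / self.tau3
        k3t = k3
        prv = 1.0 - 1.0 / (1.0 + exp(-(V - self.vy) / self.sy))
        recov = 10.0 + 4954.0 * exp(V / 15.6)
        tau_ca = self.tca / (1.0 + (cp / self.cpt) ** 4) + 0.1
        tauca = (recov - tau_ca) * prv + tau_ca
        tauba = (recov - 450.0) * prv + 450.0
        Ps = 1.0 / (1.0 + exp(-(V - self.vyr) / self.syr))
        k6 = fca * Ps / tauca
        k5 = (1.0 - Ps) / tauca
        k6t = Ps / tauba
        k5t = (1.0 - Ps) / tauba
        k4 = k3 * (alpha / beta) * (k1 / self.k2) * (k5 / k6)
        k4t = k3t * (alpha / beta) * (self.k1t / self.k2t) * (k5t / k6t)
        return dict(alpha=alpha, beta=beta, s1=s1, s2=s2, s2t=s2t,
                    k1=k1, k3=k3, k3t=k3t, k4=k4, k4t=k4t,
                    k5=k5, k5t=k5t, k6=k6, k6t=k6t)

    def _aux_rates(self, V, gates, P, aux):
        ci, cs, cj, cjp, cp, xir, nai = P[0], P[1], P[2], P[3], P[4], P[5], P[6]
        tropi, trops = P[7], P[8]
        c1, c2, xi1ca, xi1ba, xi2ca, xi2ba = P[9], P[10], P[11], P[12], P[13], P[14]
        po, rxa, jca, jnaca = aux["po"], aux["rxa"], aux["jca"], aux["jnaca"]

        # SR uptake / leak / diffusion
        jup = self.v_up * ci * ci / (ci * ci + self.c_up * self.c_up)
        jleak = (self.g_leak * (cj * cj / (cj * cj + self.k_j * self.k_j))
                 * (cj * 16.667 - ci))
        jd = (cs - ci) / self.tau_d

        # graded SR release: gain piecewise in the averaged junctional load,
        # gated by a voltage sigmoid that shuts the release off at diastolic
        # potentials, driven by the L-type trigger (open probability times
        # single-channel flux)
        if cjp < 50.0:
            qq = 0.0
        elif cjp < self.cstar:
            qq = cjp - 50.0
        else:
            qq = self.av * cjp + (1.0 - self.av) * self.cstar - 50.0
        Qr = cj * qq / self.cstar
        sig = exp(self.ax * (V + 30.0))
        spark = self.g_rel * po * Qr * abs(rxa) * sig / (1.0 + sig)
        xicap = self.gdyad * po * abs(rxa)

        dcj = -xir + jup - jleak
        dxir = spark - xir * (1.0 - self.tau_r * dcj / cj) / self.tau_r
        dcjp = (cj - cjp) / self.tau_a
        # dyadic calcium: fed by the release flux and the local L-type flux,
        # relaxing to the submembrane pool
        dcp = self.rel_dyad * xir + xicap - (cp - cs) / self.tau_ps

        # troponin binding fluxes
        xbi = self.xkon * ci * (self.btrop - tropi) - self.xkoff * tropi
        xbs = self.xkon * cs * (self.btrop - trops) - self.xkoff * trops

        # instantaneous buffering factors
        def _ib(c):
            return 1.0 / (1.0
                          + self.bcal * self.xkcal / (self.xkcal + c) ** 2
                          + self.srmax * self.srkd / (self.srkd + c) ** 2
                          + self.bmem * self.kmem / (self.kmem + c) ** 2
                          + self.bsar * self.ksar / (self.ksar + c) ** 2)

        dcs = _ib(cs) * (50.0 * (xir - jd - jca + jnaca) - xbs)
        dci = _ib(ci) * (jd - jup + jleak - xbi)

        dnai = -(aux["xina"] + 3.0 * aux["xinak"] + 3.0 * WCA * jnaca) / (WCA * 1000.0)

        # Markov L-type occupancies
        r = self._markov_rates(V, cp)
        dc1 = (r["alpha"] * c2 + self.k2 * xi1ca + self.k2t * xi1ba
               + self.r2 * po
               - (r["beta"] + self.r1 + self.k1t + r["k1"]) * c1)
        dc2 = (r["beta"] * c1 + r["k5"] * xi2ca + r["k5t"] * xi2ba
               - (r["k6"] + r["k6t"] + r["alpha"]) * c2)
        dxi1ca = (r["k1"] * c1 + r["k4"] * xi2ca + r["s1"] * po
                  - (r["k3"] + self.k2 + r["s2"]) * xi1ca)
        dxi1ba = (self.k1t * c1 + r["k4t"] * xi2ba + self.s1t * po
                  - (r["k3t"] + self.k2t + r["s2t"]) * xi1ba)
        dxi2ca = r["k3"] * xi1ca + r["k6"] * c2 - (r["k5"] + r["k4"]) * xi2ca
        dxi2ba = r["k3t"] * xi1ba + r["k6t"] * c2 - (r["k5t"] + r["k4t"]) * xi2ba

        return [dci, dcs, dcj, dcjp, dcp, dxir, dnai, xbi, xbs,
                dc1, dc2, dxi1ca, dxi1ba, dxi2ca, dxi2ba]

    def aux_rates(self, V, gates, P):
        _, aux = self._currents(V, gates, P)
        return self._aux_rates(V, gates, P, aux)

    def rhs(self, V, gates, P, I_ext: float = 0.0):
        cur, aux = self._currents(V, gates, P)
        itot = (cur["I_Na"] + cur["I_K1"] + cur["I_Kr"] + cur["I_Ks"]
                + cur["I_tos"] + cur["I_tof"] + cur["I_CaL"]
                + cur["I_NaCa"] + cur["I_NaK"])
        dV = -itot + I_ext / self.C  # currents are uA/uF; I_ext is uA
        return dV, self._aux_rates(V, gates, P, aux)

    def resting_state(self) -> MembraneState:
        # quiescent equilibrium located by settling the model for 20 s
        gates = np.array([9.686770837e-4, 0.9919137829, 0.9946407589,
                          6.437825209e-3, 4.740133892e-3, 4.739548536e-3,
                          3.495134598e-3, 0.9956390332, 3.49514447e-3,
                          0.9956331609])
        P = np.array([0.1244996407, 0.1205587544, 91.22121678, 91.3047684,
                      0.120738119, 2.533827184e-12, 12.09619313,
                      12.04217535, 11.72489572,
                      1.689045762e-5, 0.9854929807, 2.570181065e-7,
                      3.11413376e-5, 9.430462898e-7, 0.01445609844])
        return MembraneState(-87.79318137667745, gates, P, 0.0)
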