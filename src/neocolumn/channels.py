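"""Hodgkin-Huxley-style channel kinetics.

Each channel is described by its gating variables, their voltage-dependent
steady states and time constants, and an ohmic current I = gbar * prod(gates)
* (v - e_rev).  The inventory covers the mechanisms of the column model:

- ``na``  : fast transient sodium (m^3 h), action-potential upstroke
  (Traub & Miles rate functions, threshold parameter ``vT``).
- ``kdr`` : fast delayed-rectifier potassium (n^4), repolarization.
- ``km``  : muscarine-sensitive slow potassium (p), spike-frequency
  adaptation (Pospischil-style M-current).
- ``kca`` : calcium-dependent potassium (q), after-hyperpolarization;
  activation rate proportional to intracellular [Ca2+].
- ``cal`` : high-threshold L-type calcium (m^2 h).
- ``cat`` : low-threshold T-type calcium (m^2 h), rebound/burst generator.
- ``hcn`` : hyperpolarization-activated cation current (q), with a
  depolarized reversal (-35 mV).

Intracellular calcium follows a first-order decay toward a baseline with
influx proportional to the total Ca current (the "Ca decay" pump).

All voltages are mV, times ms, concentrations mM.  Gating updates use the
exponential-Euler scheme: x <- xinf + (x - xinf) * exp(-dt / taux), which
keeps every gate in [0, 1] for any dt.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GateKinetics",
    "CHANNEL_GATES",
    "CHANNEL_REVERSAL",
    "gate_steady_tau",
    "CA_BASELINE",
    "CA_DEPTH_UM",
    "CA_TAU_MS",
    "ca_influx_rate",
]

# reversal potentials (mV); Ca treated ohmically with a fixed Nernst-like value
E_NA = 50.0
E_K = -90.0
E_CA = 120.0
E_HCN = -35.0

# calcium dynamics (first-order extrusion toward baseline)
CA_BASELINE = 1e-4  # mM
CA_DEPTH_UM = 0.1   # submembrane shell depth, um
CA_TAU_MS = 20.0    # decay time constant, ms
_FARADAY = 96485.309  # C/mol


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x=0 patched."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 - x[small] / y / 2.0)
    xs = x[~small]
    out[~small] = xs / np.expm1(xs / y)
    return out


# ---------------------------------------------------------------------------
# rate functions, one pair (inf, tau) per gate
# ---------------------------------------------------------------------------

_VT = -55.0  # spike-threshold shift for the Traub-Miles Na/K rates


def _na_m(v):
    u = v - _VT
    a = 0.32 * _vtrap(13.0 - u, 4.0)
    b = 0.28 * _vtrap(u - 40.0, 5.0)
    tau = 1.0 / (a + b)
    return a * tau, tau


def _na_h(v):
    u = v - _VT
    a = 0.128 * np.exp((17.0 - u) / 18.0)
    b = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    tau = 1.0 / (a + b)
    return a * tau, tau


def _kdr_n(v):
    u = v - _VT
    a = 0.032 * _vtrap(15.0 - u, 5.0)
    b = 0.5 * np.exp((10.0 - u) / 40.0)
    tau = 1.0 / (a + b)
    return a * tau, tau


_KM_TAU_MAX = 1000.0  # ms (slow M-current; carries spike-frequency adaptation)


def _km_p(v):
    inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tau = _KM_TAU_MAX / (
        3.3 * (np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
    )
    return inf, tau


def _cal_m(v):
    a = 0.055 * _vtrap(-27.0 - v, 3.8)
    b = 0.94 * np.exp((-75.0 - v) / 17.0)
    tau = 1.0 / (a + b)
    return a * tau, tau


def _cal_h(v):
    a = 4.57e-4 * np.exp((-13.0 - v) / 50.0)
    b = 6.5e-3 / (1.0 + np.exp((-15.0 - v) / 28.0))
    tau = 1.0 / (a + b)
    return a * tau, tau


def _cat_m(v):
    inf = 1.0 / (1.0 + np.exp(-(v + 57.0) / 6.2))
    tau = 0.612 + 1.0 / (
        np.exp(-(v + 132.0) / 16.7) + np.exp((v + 16.8) / 18.2)
    )
    return inf, tau


def _cat_h(v):
    inf = 1.0 / (1.0 + np.exp((v + 81.0) / 4.0))
    v = np.asarray(v, dtype=float)
    tau = np.where(
        v < -81.0,
        np.exp((v + 467.0) / 66.6),
        28.0 + np.exp(-(v + 22.0) / 10.5),
    )
    return inf, tau


def _hcn_q(v):
    inf = 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))
    tau = 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))
    return inf, tau


class GateKinetics:
    """One gating variable: exponent and its (inf, tau) rate function."""

    def __init__(self, name, power, rates, ca_dependent=False):
        self.name = name
        self.power = power
        self.rates = rates
        self.ca_dependent = ca_dependent


def _kca_q(v, ca):
    # Destexhe-style Ca-activated K: alpha ~ [Ca]^2, beta constant, so the
    # channel is essentially shut at the ~1e-4 mM baseline concentration
    a = 2.0e4 * ca * ca    # /ms (ca in mM)
    b = 0.03               # /ms
    tau = np.maximum(1.0 / (a + b), 0.5)
    return a * tau, tau


CHANNEL_GATES: dict[str, list[GateKinetics]] = {
    "na": [GateKinetics("m", 3, _na_m), GateKinetics("h", 1, _na_h)],
    "kdr": [GateKinetics("n", 4, _kdr_n)],
    "km": [GateKinetics("p", 1, _km_p)],
    "kca": [GateKinetics("q", 1, _kca_q, ca_dependent=True)],
    "cal": [GateKinetics("m", 2, _cal_m), GateKinetics("h", 1, _cal_h)],
    "cat": [GateKinetics("m", 2, _cat_m), GateKinetics("h", 1, _cat_h)],
    "hcn": [GateKinetics("q", 1, _hcn_q)],
}

CHANNEL_REVERSAL = {
    "na": E_NA,
    "kdr": E_K,
    "km": E_K,
    "kca": E_K,
    "cal": E_CA,
    "cat": E_CA,
    "hcn": E_HCN,
}

CA_CHANNELS = ("cal", "cat")


def gate_steady_tau(channel: str, gate: GateKinetics, v, ca=None):
    """Steady state and time constant of one gate at voltage v (and [Ca])."""
    if gate.ca_dependent:
        return gate.rates(v, ca)
    return gate.rates(v)


def resting_membrane_potential(
    mechanisms: dict[str, float], Rm: float, e_leak: float
) -> float:
    """Resting voltage of a membrane patch with the given channel densities.

    Because conductance densities are uniform across a cell's compartments,
    the cell-wide resting state is spatially uniform and solves the scalar
    zero-current condition (gates at steady state, [Ca] at baseline).
    """
    from scipy.optimize import brentq

    def f(v):
        va = np.array([v])
        i = (v - e_leak) / Rm
        for name, gbar in mechanisms.items():
            open_frac = 1.0
            for gate in CHANNEL_GATES[name]:
                inf, _ = gate_steady_tau(
                    name, gate, va, np.array([CA_BASELINE])
                )
                open_frac *= float(inf[0]) ** gate.power
            i += gbar * open_frac * (v - CHANNEL_REVERSAL[name])
        return i

    # bracket the hyperpolarized root (above ~-50 mV the Na window current
    # can flip the sign again; scan upward from -95 for the first crossing)
    lo = -95.0
    flo = f(lo)
    for hi in np.arange(-94.0, -39.0, 1.0):
        fhi = f(hi)
        if flo * fhi <= 0:
            return brentq(f, lo, hi, xtol=1e-8)
        lo, flo = hi, fhi
    raise RuntimeError("no resting potential found in [-95, -40] mV")


def ca_influx_rate(i_ca_nA, area_cm2):
    """d[Ca]/dt (mM/ms) produced by an inward Ca current.

    i_ca is the ohmic Ca current in nA (positive = outward); influx into a
    submembrane shell of depth CA_DEPTH_UM.  Only inward current adds Ca.
    """
    # mol/ms = (i [A]) / (2 F); volume [L] = area * depth
    vol_L = area_cm2 * (CA_DEPTH_UM * 1e-4) * 1e-3  # cm^3 -> L
    rate = -(i_ca_nA * 1e-9) / (2.0 * _FARADAY) / vol_L * 1e-3  # mM/ms
    return np.maximum(rate, 0.0)
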