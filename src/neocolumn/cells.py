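"""Neuron templates: reduced-morphology pyramidal neurons and basket cells.

The column model contains three cell classes:

- ``L23Pyr`` — layer 2/3 pyramidal neuron, 8 compartments (soma, apical
  trunk, one apical dendrite, apical tuft, apical oblique, and a basal
  tree of three compartments).
- ``L5Pyr``  — layer 5 pyramidal neuron, 9 compartments (one extra apical
  dendrite section; longer apical path, hence larger dipole contribution).
- ``Basket`` — fast-spiking inhibitory interneuron, a single somatic
  compartment.  Its radial dendritic geometry contributes nothing to the
  primary current dipole, so only the soma is modeled.

The apical chain runs soma -> trunk -> Adend1 (-> Adend2) -> tuft along the
+Z (cortical depth) axis; the oblique dendrite leaves the soma horizontally
(no vertical component); Bdend1 points down (-Z) and Bdend2/3 branch from it
at 45 degrees below horizontal.  Compartment dimensions are the final model
values (the published reduction already includes the 1.3 human-scaling
factor applied to the cat-derived morphologies).

Membrane: Rm = 23,474 ohm*cm^2 for both pyramidal classes, Cm = 0.85 (L5)
and 0.6195 (L2/3) uF/cm^2, Ra = 200 ohm*cm.  Maximal channel conductances
are constant across the soma and dendrites of a cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNEL_GATES

__all__ = [
    "CompartmentGeometry",
    "PassiveProperties",
    "CellTemplate",
    "CELL_CLASSES",
    "build_cell_template",
    "axial_resistance",
    "input_resistance",
    "current_clamp_protocol",
]

CELL_CLASSES = ("L23Pyr", "L5Pyr", "Basket")

V_REST = -65.0  # mV, uniform initialization


@dataclass(frozen=True)
class CompartmentGeometry:
    """One cylindrical compartment of a reduced morphology.

    ``angle_from_vertical`` fixes the signed vertical extent used by the
    dipole calculation: 0 deg = along +Z for apical sections, 90 deg =
    horizontal (no dipole contribution), and basal sections point downward.
    """

    name: str
    length: float            # um
    diameter: float          # um
    parent: str | None       # parent compartment name (None for soma)
    angle_from_vertical: float  # degrees
    downward: bool = False   # True if the section points toward -Z

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"compartment {self.name!r}: length and diameter must be > 0"
            )

    @property
    def area_cm2(self) -> float:
        """Cylinder side area in cm^2 (1 um^2 = 1e-8 cm^2)."""
        return math.pi * self.length * self.diameter * 1e-8

    @property
    def cross_section_cm2(self) -> float:
        return math.pi * (self.diameter * 1e-4 / 2.0) ** 2

    @property
    def delta_z(self) -> float:
        """Signed vertical extent (um) from parent end to distal end."""
        dz = self.length * math.cos(math.radians(self.angle_from_vertical))
        if abs(dz) < 1e-9 * self.length:
            dz = 0.0  # horizontal sections contribute exactly zero
        return -dz if self.downward else dz


@dataclass(frozen=True)
class PassiveProperties:
    Rm: float  # ohm*cm^2
    Cm: float  # uF/cm^2
    Ra: float  # ohm*cm
    e_leak: float = V_REST  # mV

    def __post_init__(self):
        if self.Rm <= 0 or self.Cm <= 0 or self.Ra <= 0:
            raise ValueError("passive properties must be strictly positive")


@dataclass
class CellTemplate:
    """Geometry + passive + active-mechanism description of one cell class."""

    cell_class: str
    compartments: list[CompartmentGeometry]
    passive: PassiveProperties
    mechanisms: dict[str, float]  # channel name -> gbar (S/cm^2), uniform
    synapse_sites: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compartment names")
        byname = set(names)
        for c in self.compartments:
            if c.parent is not None and c.parent not in byname:
                raise ValueError(f"unknown parent {c.parent!r} of {c.name!r}")
        for ch in self.mechanisms:
            if ch not in CHANNEL_GATES:
                raise ValueError(f"unknown channel {ch!r}")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def compartment(self, name: str) -> CompartmentGeometry:
        for c in self.compartments:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def is_pyramidal(self) -> bool:
        return self.cell_class in ("L23Pyr", "L5Pyr")

    def apical_path_length(self) -> float:
        """Total length of the soma->tuft apical chain (um)."""
        total = 0.0
        for c in self.compartments:
            if c.name.startswith("Adend") and c.name != "Adend_oblique":
                total += c.length
        return total

    def passive_copy(self) -> "CellTemplate":
        """Template with all active conductances removed (leak only)."""
        return CellTemplate(
            cell_class=self.cell_class,
            compartments=list(self.compartments),
            passive=self.passive,
            mechanisms={},
            synapse_sites=dict(self.synapse_sites),
        )


# --- Table of final compartment dimensions (length um, diameter um) -------

_L23_GEOMETRY = [
    # name, L, d, parent, angle, downward
    ("soma", 22.1, 23.4, None, 0.0, False),
    ("Adend_trunk", 59.5, 4.3, "soma", 0.0, False),
    ("Adend1", 306.0, 4.1, "Adend_trunk", 0.0, False),
    ("Adend_tuft", 238.0, 3.4, "Adend1", 0.0, False),
    ("Adend_oblique", 340.0, 3.9, "soma", 90.0, False),
    ("Bdend1", 85.0, 4.3, "soma", 0.0, True),
    ("Bdend2", 255.0, 2.7, "Bdend1", 45.0, True),
    ("Bdend3", 255.0, 2.7, "Bdend1", 45.0, True),
]

_L5_GEOMETRY = [
    ("soma", 39.0, 28.9, None, 0.0, False),
    ("Adend_trunk", 102.0, 10.2, "soma", 0.0, False),
    ("Adend1", 680.0, 7.5, "Adend_trunk", 0.0, False),
    ("Adend2", 680.0, 4.9, "Adend1", 0.0, False),
    ("Adend_tuft", 425.0, 3.4, "Adend2", 0.0, False),
    ("Adend_oblique", 255.0, 5.1, "soma", 90.0, False),
    ("Bdend1", 85.0, 6.8, "soma", 0.0, True),
    ("Bdend2", 255.0, 8.5, "Bdend1", 45.0, True),
    ("Bdend3", 255.0, 8.5, "Bdend1", 45.0, True),
]

_BASKET_GEOMETRY = [
    ("soma", 39.0, 20.0, None, 0.0, False),
]

# --- Active conductances (S/cm^2), tuned to the firing phenotypes ---------
# L5: intrinsically bursting (Na/K + T/L-type Ca + KCa + HCN)
# L2/3: regular spiking with adaptation (Na/K + Km)
# Basket: fast regular spiking (Na/K only)

_L23_MECH = {
    "na": 0.18,
    "kdr": 0.01,
    "km": 5.0e-4,
}

_L5_MECH = {
    "na": 0.16,
    "kdr": 0.01,
    "km": 5.0e-4,
    "kca": 5.0e-3,
    "cal": 1.0e-4,
    "cat": 5.0e-4,
    "hcn": 1.0e-5,
}

_BASKET_MECH = {
    "na": 0.10,
    "kdr": 0.02,
}

_PYR_SITES = {
    "proximal": ["Bdend1", "Bdend2", "Bdend3", "Adend_oblique"],
    "distal": ["Adend_tuft"],
    "soma": ["soma"],
}

_BASKET_SITES = {"soma": ["soma"]}


def build_cell_template(cell_class: str) -> CellTemplate:
    """Construct the template for one of the three cell classes."""
    if cell_class == "L23Pyr":
        geom, mech, sites = _L23_GEOMETRY, _L23_MECH, _PYR_SITES
        passive = PassiveProperties(Rm=23474.0, Cm=0.6195, Ra=200.0)
    elif cell_class == "L5Pyr":
        geom, mech, sites = _L5_GEOMETRY, _L5_MECH, _PYR_SITES
        passive = PassiveProperties(Rm=23474.0, Cm=0.85, Ra=200.0)
    elif cell_class == "Basket":
        geom, mech, sites = _BASKET_GEOMETRY, _BASKET_MECH, _BASKET_SITES
        # basket leak chosen for a fast-spiking phenotype; interneuron
        # passive values are not part of the published parameter set
        passive = PassiveProperties(Rm=10000.0, Cm=0.85, Ra=200.0)
    else:
        raise ValueError(
            f"unknown cell class {cell_class!r}; expected one of {CELL_CLASSES}"
        )
    comps = [
        CompartmentGeometry(n, L, d, p, ang, down)
        for (n, L, d, p, ang, down) in geom
    ]
    return CellTemplate(
        cell_class=cell_class,
        compartments=comps,
        passive=passive,
        mechanisms=dict(mech),
        synapse_sites={k: list(v) for k, v in sites.items()},
    )


def axial_resistance(
    comp_a: CompartmentGeometry, comp_b: CompartmentGeometry, Ra: float
) -> float:
    """Axial resistance between the centers of two adjacent compartments.

    Standard cable discretization: the two half-cylinders in series,
    r = Ra * (L_a/2 / A_a + L_b/2 / A_b), returned in megaohms.  Symmetric
    in its two arguments.
    """
    if comp_a.diameter <= 0 or comp_b.diameter <= 0:
        raise ValueError("zero-diameter compartment")
    r_ohm = Ra * (
        (comp_a.length * 1e-4 / 2.0) / comp_a.cross_section_cm2
        + (comp_b.length * 1e-4 / 2.0) / comp_b.cross_section_cm2
    )
    return r_ohm / 1e6


def input_resistance(
    template: CellTemplate,
    I: float = -0.05,
    duration: float = 500.0,
    dt: float = 0.025,
    tol_mV: float = 1e-3,
) -> float:
    """Somatic input resistance (MΩ) from a small current step.

    Active conductances are disabled (leak-only membrane); the step is run
    to steady state and R_in = ΔV_ss / |I|.  Raises if the voltage has not
    settled by the end of the step.
    """
    from .engine import simulate_single_cell

    passive = template.passive_copy()
    t, v = simulate_single_cell(
        passive, duration=duration, dt=dt, i_soma=I, i_start=0.0
    )
    v_soma = v[:, 0]
    # settled: last 10% of the trace moves less than tol
    tail = v_soma[int(0.9 * len(v_soma)):]
    if np.ptp(tail) > tol_mV:
        raise RuntimeError(
            f"input-resistance step did not reach steady state: "
            f"tail drift {np.ptp(tail):.3g} mV over the last 10% of {duration} ms"
        )
    dv = v_soma[-1] - v_soma[0]
    return abs(dv / I)  # mV / nA = MΩ


def current_clamp_protocol(
    template: CellTemplate,
    amplitude: float = 1.0,
    duration: float = 100.0,
    dt: float = 0.025,
    onset: float = 50.0,
    threshold: float = 0.0,
) -> np.ndarray:
    """Somatic spike times under a somatic current step (full active model).

    The clamp switches on at ``onset`` (after a settling period) and lasts
    ``duration`` ms.  Returns spike times in ms relative to clamp onset.
    """
    from .engine import detect_spikes, simulate_single_cell

    t, v = simulate_single_cell(
        template,
        duration=onset + duration + 20.0,
        dt=dt,
        i_soma=amplitude,
        i_start=onset,
        i_stop=onset + duration,
    )
    spikes = detect_spikes(t, v[:, 0], threshold=threshold)
    return spikes - onset
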