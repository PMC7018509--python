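"""Primary current dipole from intracellular axial currents.

The dipole moment of one pyramidal neuron is the sum, over adjacent
compartment pairs, of the axial current i_axial = (v_i - v_j) / r_axial
multiplied by the signed vertical (Z) separation of the pair.  Horizontal
(oblique) segments contribute nothing; basal segments at 45 degrees below
horizontal contribute with per-unit-length factor -sqrt(2)/2.  Basket cells
contribute exactly zero by construction (radial dendrites).  The network
dipole is the sum over all pyramidal neurons, attributed per layer; only Z
*differences* enter, so absolute layer depths are irrelevant.

Units: v in mV, r_axial in MOhm gives i_axial in nA; times the separation
in um gives fAm; traces are reported in nAm (1 nAm = 1e6 fAm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cells import CellTemplate, axial_resistance

__all__ = [
    "FAM_PER_NAM",
    "DipoleTrace",
    "pair_dipole_contribution",
    "cell_dipole",
    "scale_dipole",
    "implied_neuron_count",
]

FAM_PER_NAM = 1e6  # nA*um = fAm; 1e6 fAm = 1 nAm


@dataclass
class DipoleTrace:
    """A dipole time series with per-layer attribution."""

    times: np.ndarray       # ms
    aggregate: np.ndarray   # nAm
    L2: np.ndarray | None = None
    L5: np.ndarray | None = None
    scaling: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.aggregate = np.asarray(self.aggregate, dtype=float)
        if self.aggregate.shape != self.times.shape:
            raise ValueError("dipole values and time grid must match")

    @property
    def has_layers(self) -> bool:
        return self.L2 is not None and self.L5 is not None


def pair_dipole_contribution(
    v_i: float, v_j: float, r_axial: float, delta_z: float
) -> float:
    """Dipole moment (fAm) of one adjacent compartment pair.

    ``delta_z`` is the signed vertical displacement (um) from compartment i
    to compartment j; the contribution is (v_i - v_j)/r * (z_j - z_i):
    current flowing from i to j counts as positive when it flows upward.
    The result is symmetric under swapping the two compartments.
    """
    if r_axial <= 0:
        raise ValueError("r_axial must be > 0")
    i_axial = (v_i - v_j) / r_axial  # nA, flowing from i to j
    return i_axial * delta_z


def cell_dipole(voltages: dict[str, float], template: CellTemplate) -> float:
    """Dipole moment (fAm) of one cell from its compartment voltages.

    Sums pair contributions over all parent-child compartment pairs.
    Basket cells (single compartment, radial geometry) return exactly 0.
    """
    if not template.is_pyramidal:
        return 0.0
    total = 0.0
    for comp in template.compartments:
        if comp.parent is None:
            continue
        parent = template.compartment(comp.parent)
        r = axial_resistance(parent, comp, template.passive.Ra)
        # delta_z from parent to child is comp.delta_z
        total += pair_dipole_contribution(
            voltages[comp.parent], voltages[comp.name], r, comp.delta_z
        )
    return total


def scale_dipole(trace: DipoleTrace, factor: float) -> DipoleTrace:
    """Multiply a dipole trace by a population scaling factor."""
    if factor <= 0:
        raise ValueError("scaling factor must be > 0")
    return DipoleTrace(
        times=trace.times.copy(),
        aggregate=trace.aggregate * factor,
        L2=None if trace.L2 is None else trace.L2 * factor,
        L5=None if trace.L5 is None else trace.L5 * factor,
        scaling=trace.scaling * factor,
    )


def implied_neuron_count(factor: float, n_pyramidal: int) -> int:
    """Number of contributing neurons implied by a dipole scaling factor."""
    if factor <= 0:
        raise ValueError("scaling factor must be > 0")
    return int(round(factor * n_pyramidal))
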