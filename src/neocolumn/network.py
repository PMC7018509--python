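"""Network construction: cell placement, connectivity rules, synapses.

Pyramidal neurons (PNs) of both layers sit on the same regular n_x x n_y
grid in the XY plane (arbitrary grid units); basket interneurons are
interleaved on every third lattice node, giving the canonical 3:1
pyramidal-to-interneuron ratio per layer.  Connectivity is all-to-all
between synaptically coupled populations, with synaptic weights falling off
with XY distance d as exp(-d^2 / lambda^2) and delays growing as the
inverse, exp(+d^2 / lambda^2); the space constant lambda is specific to the
(pre, post) population pair.

Inhibitory synapses onto PNs target the soma; excitatory synapses onto PNs
target the basal and oblique dendrites; all synapses onto basket cells
target their single somatic compartment.  Cross-layer connections are
limited to L2/3 PN -> L5 PN, L2/3 basket -> L5 PN, and L2/3 PN -> L5
basket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POPULATIONS",
    "ReceptorKinetics",
    "RECEPTORS",
    "CellInfo",
    "NetworkConfig",
    "ConnectivityRule",
    "Synapse",
    "Network",
    "place_cells",
    "default_connectivity_rules",
    "distance_weight",
    "distance_delay",
    "build_connectivity",
    "synaptic_current",
    "biexp_norm",
    "biexp_peak_time",
    "build_network",
]

POPULATIONS = ("L2_pyramidal", "L2_basket", "L5_pyramidal", "L5_basket")

_POP_CLASS = {
    "L2_pyramidal": "L23Pyr",
    "L2_basket": "Basket",
    "L5_pyramidal": "L5Pyr",
    "L5_basket": "Basket",
}

_POP_LAYER = {
    "L2_pyramidal": "L2",
    "L2_basket": "L2",
    "L5_pyramidal": "L5",
    "L5_basket": "L5",
}


@dataclass(frozen=True)
class ReceptorKinetics:
    """Bi-exponential synaptic conductance kinetics."""

    receptor: str
    tau_rise: float   # ms
    tau_decay: float  # ms
    reversal: float   # mV

    def __post_init__(self):
        if self.tau_rise >= self.tau_decay:
            raise ValueError(
                f"{self.receptor}: tau_rise ({self.tau_rise}) must be "
                f"< tau_decay ({self.tau_decay})"
            )


RECEPTORS: dict[str, ReceptorKinetics] = {
    "ampa": ReceptorKinetics("ampa", 0.5, 1.0, 0.0),
    "nmda": ReceptorKinetics("nmda", 1.0, 20.0, 0.0),
    "gabaa": ReceptorKinetics("gabaa", 0.5, 5.0, -80.0),
    "gabab": ReceptorKinetics("gabab", 1.0, 20.0, -80.0),
}


def biexp_peak_time(kin: ReceptorKinetics) -> float:
    """Time of the conductance peak after a single event (ms)."""
    tr, td = kin.tau_rise, kin.tau_decay
    return tr * td / (td - tr) * math.log(td / tr)


def biexp_norm(kin: ReceptorKinetics) -> float:
    """Normalization N so that a unit-weight event peaks at g = 1."""
    tstar = biexp_peak_time(kin)
    return 1.0 / (math.exp(-tstar / kin.tau_decay) - math.exp(-tstar / kin.tau_rise))


def synaptic_current(
    t_since_spike: float | np.ndarray,
    kinetics: ReceptorKinetics,
    weight: float,
    v_post: float,
) -> float | np.ndarray:
    """Postsynaptic current (nA) at time t after one presynaptic spike.

    g(t) = weight * N * (exp(-t/tau_decay) - exp(-t/tau_rise)), normalized
    so the peak conductance equals ``weight`` (uS); I = g * (v - e_rev).
    Successive spikes superpose linearly.
    """
    t = np.asarray(t_since_spike, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_spike must be >= 0")
    n = biexp_norm(kinetics)
    g = weight * n * (np.exp(-t / kinetics.tau_decay) - np.exp(-t / kinetics.tau_rise))
    i = g * (v_post - kinetics.reversal)
    return float(i) if np.isscalar(t_since_spike) else i


@dataclass(frozen=True)
class CellInfo:
    gid: int
    population: str
    cell_class: str
    layer: str
    x: float
    y: float


@dataclass
class NetworkConfig:
    n_pyr_x: int = 10
    n_pyr_y: int = 10
    cells: list[CellInfo] = field(default_factory=list)
    # multiplicative gain per (pre E/I -> post E/I) pathway
    gains: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("e", "e"): 1.0,
            ("e", "i"): 1.0,
            ("i", "e"): 1.0,
            ("i", "i"): 1.0,
        }
    )

    def population(self, name: str) -> list[CellInfo]:
        return [c for c in self.cells if c.population == name]

    @property
    def n_pyramidal(self) -> int:
        return sum(1 for c in self.cells if c.cell_class != "Basket")


def place_cells(n_pyr_x: int = 10, n_pyr_y: int = 10) -> NetworkConfig:
    """Deterministically place all four populations on the XY lattice.

    PNs occupy every node of the n_x x n_y grid in each layer; basket cells
    occupy every third node (linear index = 1 mod 3), yielding
    round(n_x*n_y/3) interneurons per layer.
    """
    if n_pyr_x <= 0 or n_pyr_y <= 0:
        raise ValueError("grid counts must be positive")
    cells: list[CellInfo] = []
    gid = 0
    basket_nodes = [
        (i % n_pyr_x, i // n_pyr_x)
        for i in range(n_pyr_x * n_pyr_y)
        if i % 3 == 1
    ]
    for pop in POPULATIONS:
        if pop.endswith("pyramidal"):
            coords = [
                (float(x), float(y))
                for y in range(n_pyr_y)
                for x in range(n_pyr_x)
            ]
        else:
            coords = [(float(x), float(y)) for x, y in basket_nodes]
        for x, y in coords:
            cells.append(
                CellInfo(gid, pop, _POP_CLASS[pop], _POP_LAYER[pop], x, y)
            )
            gid += 1
    return NetworkConfig(n_pyr_x=n_pyr_x, n_pyr_y=n_pyr_y, cells=cells)


@dataclass(frozen=True)
class ConnectivityRule:
    pre_population: str
    post_population: str
    receptor: str
    weight: float       # uS at d = 0
    space_constant: float  # lambda, grid units
    target_site: str    # 'soma' | 'proximal' | 'distal'
    base_delay: float = 1.0  # ms at d = 0

    def __post_init__(self):
        if self.space_constant <= 0:
            raise ValueError("space constant must be > 0")
        if self.pre_population not in POPULATIONS:
            raise ValueError(f"unknown population {self.pre_population!r}")
        if self.post_population not in POPULATIONS:
            raise ValueError(f"unknown population {self.post_population!r}")


@dataclass(frozen=True)
class Synapse:
    pre_gid: int
    post_gid: int
    post_compartment: str
    receptor: str
    weight: float  # uS
    delay: float   # ms


# Space constants from the published pathway table; base weights are this
# package's tuned defaults (the publication does not print them), chosen to
# reproduce the evoked-response and rhythm scenarios.
_DEFAULT_RULES = [
    # within L2/3
    ("L2_pyramidal", "L2_pyramidal", "ampa", 5e-4, 3.0, "proximal"),
    ("L2_pyramidal", "L2_pyramidal", "nmda", 5e-4, 3.0, "proximal"),
    ("L2_pyramidal", "L2_basket", "ampa", 5e-4, 3.0, "soma"),
    ("L2_pyramidal", "L2_basket", "nmda", 5e-4, 3.0, "soma"),
    ("L2_basket", "L2_pyramidal", "gabaa", 5e-2, 50.0, "soma"),
    ("L2_basket", "L2_pyramidal", "gabab", 5e-2, 50.0, "soma"),
    ("L2_basket", "L2_basket", "gabaa", 2e-2, 20.0, "soma"),
    # within L5
    ("L5_pyramidal", "L5_pyramidal", "ampa", 5e-4, 3.0, "proximal"),
    ("L5_pyramidal", "L5_pyramidal", "nmda", 5e-4, 3.0, "proximal"),
    ("L5_pyramidal", "L5_basket", "ampa", 5e-4, 3.0, "soma"),
    ("L5_pyramidal", "L5_basket", "nmda", 5e-4, 3.0, "soma"),
    ("L5_basket", "L5_pyramidal", "gabaa", 2.5e-2, 70.0, "soma"),
    ("L5_basket", "L5_pyramidal", "gabab", 2.5e-2, 70.0, "soma"),
    ("L5_basket", "L5_basket", "gabaa", 2e-2, 20.0, "soma"),
    # cross-layer (L2/3 -> L5 only)
    ("L2_pyramidal", "L5_pyramidal", "ampa", 2.5e-4, 3.0, "proximal"),
    ("L2_pyramidal", "L5_basket", "ampa", 2.5e-4, 3.0, "soma"),
    ("L2_basket", "L5_pyramidal", "gabaa", 1e-3, 50.0, "soma"),
]


def default_connectivity_rules() -> list[ConnectivityRule]:
    return [
        ConnectivityRule(pre, post, rec, w, lam, site)
        for (pre, post, rec, w, lam, site) in _DEFAULT_RULES
    ]


_EXC = ("ampa", "nmda")


def _ei(pop: str) -> str:
    return "e" if pop.endswith("pyramidal") else "i"


def distance_weight(d: float, space_constant: float, w_base: float) -> float:
    """Synaptic weight at XY distance d: w_base * exp(-d^2 / lambda^2)."""
    if space_constant <= 0:
        raise ValueError("space constant must be > 0")
    if d < 0:
        raise ValueError("distance must be >= 0")
    return w_base * math.exp(-(d * d) / (space_constant * space_constant))


def distance_delay(d: float, space_constant: float, delay_base: float) -> float:
    """Synaptic delay at XY distance d: delay_base * exp(+d^2 / lambda^2)."""
    if space_constant <= 0:
        raise ValueError("space constant must be > 0")
    if d < 0:
        raise ValueError("distance must be >= 0")
    # cap the exponent: beyond ~700 the delay exceeds any simulation length
    # by hundreds of orders of magnitude and would overflow a float
    ex = min((d * d) / (space_constant * space_constant), 700.0)
    return delay_base * math.exp(ex)


# compartment labels per target site, resolved per cell class
_SITE_COMPARTMENTS = {
    ("L23Pyr", "proximal"): ["Bdend1", "Bdend2", "Bdend3", "Adend_oblique"],
    ("L23Pyr", "distal"): ["Adend_tuft"],
    ("L23Pyr", "soma"): ["soma"],
    ("L5Pyr", "proximal"): ["Bdend1", "Bdend2", "Bdend3", "Adend_oblique"],
    ("L5Pyr", "distal"): ["Adend_tuft"],
    ("L5Pyr", "soma"): ["soma"],
    ("Basket", "soma"): ["soma"],
}


def site_compartments(cell_class: str, site: str) -> list[str]:
    try:
        return list(_SITE_COMPARTMENTS[(cell_class, site)])
    except KeyError:
        raise ValueError(f"no site {site!r} on cell class {cell_class!r}")


def build_connectivity(
    config: NetworkConfig, rules: list[ConnectivityRule] | None = None
) -> list[Synapse]:
    """Expand connectivity rules into the explicit synapse list.

    All-to-all between the rule's populations (self-connections excluded);
    the rule's weight is scaled by the Gaussian distance profile and the
    per-pathway E/I gain factor, the delay by the inverse profile.  The
    weight is divided evenly across the target site's compartments so the
    total synaptic conductance delivered per connection equals the rule
    weight regardless of how many compartments realize the site.
    """
    if rules is None:
        rules = default_connectivity_rules()
    synapses: list[Synapse] = []
    for rule in rules:
        pre_cells = config.population(rule.pre_population)
        post_cells = config.population(rule.post_population)
        if not pre_cells or not post_cells:
            raise ValueError(
                f"rule references empty population: "
                f"{rule.pre_population} -> {rule.post_population}"
            )
        gain = config.gains[(_ei(rule.pre_population), _ei(rule.post_population))]
        post_class = _POP_CLASS[rule.post_population]
        comps = site_compartments(post_class, rule.target_site)
        w_share = 1.0 / len(comps)
        for pre in pre_cells:
            for post in post_cells:
                if pre.gid == post.gid:
                    continue
                d = math.hypot(pre.x - post.x, pre.y - post.y)
                w = distance_weight(d, rule.space_constant, rule.weight) * gain
                delay = distance_delay(d, rule.space_constant, rule.base_delay)
                for comp in comps:
                    synapses.append(
                        Synapse(
                            pre_gid=pre.gid,
                            post_gid=post.gid,
                            post_compartment=comp,
                            receptor=rule.receptor,
                            weight=w * w_share,
                            delay=delay,
                        )
                    )
    return synapses


@dataclass
class Network:
    """Placed cells plus the expanded synapse list."""

    config: NetworkConfig
    rules: list[ConnectivityRule]
    synapses: list[Synapse]

    @property
    def cells(self) -> list[CellInfo]:
        return self.config.cells

    @property
    def n_pyramidal(self) -> int:
        return self.config.n_pyramidal


def build_network(
    n_pyr_x: int = 10,
    n_pyr_y: int = 10,
    rules: list[ConnectivityRule] | None = None,
    gains: dict[tuple[str, str], float] | None = None,
) -> Network:
    config = place_cells(n_pyr_x, n_pyr_y)
    if gains is not None:
        config.gains.update(gains)
    if rules is None:
        rules = default_connectivity_rules()
    # degenerate grids (< 3 nodes) have no basket cells; drop their pathways
    present = {c.population for c in config.cells}
    rules = [
        r for r in rules
        if r.pre_population in present and r.post_population in present
    ]
    synapses = build_connectivity(config, rules)
    return Network(config=config, rules=rules, synapses=synapses)
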