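"""Exogenous drives: evoked, rhythmic, Poisson and tonic inputs.

The column is silent at rest; all activity is driven by layer-specific
exogenous inputs representing thalamic and cortico-cortical afferents
(which are not themselves modeled — only the spike trains they deliver).

Two routing classes exist:

- **proximal** (lemniscal-thalamic style): excitatory synapses on the basal
  and oblique dendrites of pyramidal neurons in both layers, plus the somata
  of basket cells in both layers.  Drives current *up* the apical dendrites
  (positive dipole deflection).
- **distal** (non-lemniscal / cortico-cortical style): excitatory synapses
  on the distal apical tuft of pyramidal neurons in both layers, plus the
  somata of layer 2/3 basket cells only.  Drives current *down* (negative
  deflection).

Randomness is reproducible: every (drive, trial) pair derives its own NumPy
substream from the master seed and the drive's name, so adding or removing
one drive never perturbs the event trains of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .network import Network, site_compartments

__all__ = [
    "DriveEventTrain",
    "EvokedDriveSpec",
    "RhythmicDriveSpec",
    "PoissonDriveSpec",
    "TonicDriveSpec",
    "route_drive",
    "sample_evoked_events",
    "sample_rhythmic_events",
    "sample_poisson_events",
    "sample_drive_events",
    "tonic_current",
]

_EXC_RECEPTORS = ("ampa", "nmda")


@dataclass
class DriveEventTrain:
    """Sorted event times delivered to one synapse."""

    target_gid: int
    target_compartment: str
    receptor: str
    weight: float       # uS
    times: np.ndarray   # ms, sorted, within [0, duration]

    def __post_init__(self):
        self.times = np.sort(np.asarray(self.times, dtype=float))


def _drive_rng(name: str, master_seed: int, trial_index: int) -> np.random.Generator:
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        (int(master_seed) & 0x7FFFFFFF, key, int(trial_index))
    )


def route_drive(drive_class: str, network: Network) -> list[tuple[int, str, str]]:
    """Targets of a proximal or distal drive: (gid, population, compartment).

    Proximal reaches pyramidal basal+oblique dendrites and basket somata in
    both layers; distal reaches pyramidal apical tufts in both layers but
    basket somata in layer 2/3 only.
    """
    if drive_class not in ("proximal", "distal"):
        raise ValueError(
            f"unknown drive class {drive_class!r}; expected proximal or distal"
        )
    targets: list[tuple[int, str, str]] = []
    for cell in network.cells:
        if cell.cell_class == "Basket":
            if drive_class == "distal" and cell.layer == "L5":
                continue
            targets.append((cell.gid, cell.population, "soma"))
        else:
            site = "proximal" if drive_class == "proximal" else "distal"
            for comp in site_compartments(cell.cell_class, site):
                targets.append((cell.gid, cell.population, comp))
    return targets


@dataclass
class EvokedDriveSpec:
    """A transient Gaussian-timed volley of input spikes (one ERP input).

    ``weights`` maps (population, receptor) to the synaptic conductance
    (uS) delivered at each routed compartment; populations absent from the
    map receive nothing.  Distal drives must not weight L5 baskets (they
    are not innervated by the distal pathway).
    """

    name: str
    drive_class: str          # 'proximal' | 'distal'
    start_time_mean: float    # ms
    start_time_stdev: float   # ms
    n_spikes_per_synapse: int = 1
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    synchronous: bool = False
    increment_per_trial: float = 0.0  # ms added to the mean on each trial

    def __post_init__(self):
        if self.start_time_stdev < 0:
            raise ValueError("start-time stdev must be >= 0")
        if self.drive_class == "distal":
            for (pop, _), w in self.weights.items():
                if pop == "L5_basket" and w != 0:
                    raise ValueError(
                        "distal drives carry no L5 basket weight"
                    )


def sample_evoked_events(
    spec: EvokedDriveSpec,
    network: Network,
    trial_index: int = 0,
    master_seed: int = 0,
    duration: float = np.inf,
) -> list[DriveEventTrain]:
    """Sample one trial's event trains for an evoked input.

    Each target cell receives ``n_spikes_per_synapse`` events drawn from
    Normal(mean + trial*increment, stdev); with ``synchronous`` a single
    draw is shared by every cell.  Events outside [0, duration] are dropped.
    """
    rng = _drive_rng(spec.name, master_seed, trial_index)
    mean = spec.start_time_mean + trial_index * spec.increment_per_trial
    targets = route_drive(spec.drive_class, network)
    n = spec.n_spikes_per_synapse
    shared = None
    if spec.synchronous:
        shared = mean + spec.start_time_stdev * rng.standard_normal(n)
    # one time-draw per cell (shared across its compartments and receptors)
    cell_times: dict[int, np.ndarray] = {}
    trains: list[DriveEventTrain] = []
    for gid, pop, comp in targets:
        if gid not in cell_times:
            if shared is not None:
                cell_times[gid] = shared
            else:
                cell_times[gid] = mean + spec.start_time_stdev * rng.standard_normal(n)
        t = cell_times[gid]
        t = t[(t >= 0.0) & (t <= duration)]
        for receptor in _EXC_RECEPTORS:
            w = spec.weights.get((pop, receptor), 0.0)
            if w > 0:
                trains.append(DriveEventTrain(gid, comp, receptor, w, t))
    return trains


@dataclass
class RhythmicDriveSpec:
    """Repeating bursts of input spikes at a set frequency.

    A burst sequence starts at Normal(start_time_mean, start_time_stdev)
    and repeats at 1000/burst_frequency ms until ``stop_time``; each burst
    center emits ``spikes_per_burst`` events jittered by
    Normal(0, burst_stdev).  The full sequence is repeated ``n_bursts``
    times and the repeats accumulate (more repeats = more input and more
    variability).  Burst jitter is shared across target cells by default
    (population-synchronous bursts); set ``per_cell_jitter`` to re-draw the
    jitter per cell.
    """

    name: str
    drive_class: str
    start_time_mean: float
    start_time_stdev: float
    stop_time: float
    burst_frequency: float    # Hz
    burst_stdev: float        # ms
    spikes_per_burst: int = 2
    n_bursts: int = 10
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    delay_offsets: dict[str, float] = field(default_factory=dict)  # ms per population
    per_cell_jitter: bool = False

    def __post_init__(self):
        if self.burst_frequency <= 0:
            raise ValueError("burst frequency must be > 0")


def _rhythmic_times(spec: RhythmicDriveSpec, rng, duration: float) -> np.ndarray:
    period = 1000.0 / spec.burst_frequency
    stop = min(spec.stop_time, duration)
    times = []
    for _ in range(spec.n_bursts):
        t0 = spec.start_time_mean + spec.start_time_stdev * rng.standard_normal()
        center = t0
        while center <= stop:
            jitter = spec.burst_stdev * rng.standard_normal(spec.spikes_per_burst)
            times.append(center + jitter)
            center += period
    if not times:
        return np.empty(0)
    t = np.concatenate(times)
    return t[(t >= 0.0) & (t <= duration)]


def sample_rhythmic_events(
    spec: RhythmicDriveSpec,
    network: Network,
    trial_index: int = 0,
    master_seed: int = 0,
    duration: float = np.inf,
) -> list[DriveEventTrain]:
    rng = _drive_rng(spec.name, master_seed, trial_index)
    targets = route_drive(spec.drive_class, network)
    if np.isinf(duration) and np.isinf(spec.stop_time):
        raise ValueError("rhythmic drive needs a finite stop time or duration")
    base = None
    if not spec.per_cell_jitter:
        base = _rhythmic_times(spec, rng, duration)
    cell_times: dict[int, np.ndarray] = {}
    trains: list[DriveEventTrain] = []
    for gid, pop, comp in targets:
        if gid not in cell_times:
            cell_times[gid] = (
                base if base is not None else _rhythmic_times(spec, rng, duration)
            )
        offset = spec.delay_offsets.get(pop, 0.0)
        t = cell_times[gid] + offset
        t = t[(t >= 0.0) & (t <= duration)]
        for receptor in _EXC_RECEPTORS:
            w = spec.weights.get((pop, receptor), 0.0)
            if w > 0:
                trains.append(DriveEventTrain(gid, comp, receptor, w, t))
    return trains


@dataclass
class PoissonDriveSpec:
    """Noisy somatic excitation: independent Poisson trains per cell.

    ``rates`` maps population name to the Poisson rate (Hz) of the input
    each cell of that population receives at its soma.  ``stop = -1``
    keeps the drive active until the end of the simulation.
    """

    name: str
    rates: dict[str, float] = field(default_factory=dict)
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    start: float = 0.0
    stop: float = -1.0

    def __post_init__(self):
        for pop, r in self.rates.items():
            if r < 0:
                raise ValueError(f"negative Poisson rate for {pop}")


def sample_poisson_events(
    spec: PoissonDriveSpec,
    network: Network,
    trial_index: int = 0,
    master_seed: int = 0,
    duration: float = 1000.0,
) -> list[DriveEventTrain]:
    rng = _drive_rng(spec.name, master_seed, trial_index)
    stop = duration if spec.stop == -1 else min(spec.stop, duration)
    trains: list[DriveEventTrain] = []
    for cell in network.cells:
        rate = spec.rates.get(cell.population, 0.0)
        window = stop - spec.start
        if rate <= 0 or window <= 0:
            times = np.empty(0)
        else:
            n = rng.poisson(rate * window / 1000.0)
            times = spec.start + rng.uniform(0.0, window, size=n)
        for receptor in _EXC_RECEPTORS:
            w = spec.weights.get((cell.population, receptor), 0.0)
            if w > 0:
                trains.append(
                    DriveEventTrain(cell.gid, "soma", receptor, w, times)
                )
    return trains


@dataclass
class TonicDriveSpec:
    """Constant somatic current clamp per cell population."""

    name: str
    amplitudes: dict[str, float] = field(default_factory=dict)  # nA per population
    start: float = 0.0
    stop: float | None = None

    def clamps(self, network: Network) -> list[tuple[int, float, float, float | None]]:
        out = []
        for cell in network.cells:
            amp = self.amplitudes.get(cell.population, 0.0)
            if amp != 0.0:
                out.append((cell.gid, amp, self.start, self.stop))
        return out


def tonic_current(spec: TonicDriveSpec, population: str, t: float) -> float:
    """Clamp current (nA) for one population at time t."""
    amp = spec.amplitudes.get(population, 0.0)
    stop = np.inf if spec.stop is None else spec.stop
    return amp if spec.start <= t < stop else 0.0


def sample_drive_events(
    spec,
    network: Network,
    trial_index: int = 0,
    master_seed: int = 0,
    duration: float = 1000.0,
) -> list[DriveEventTrain]:
    """Dispatch on the drive-spec type and sample one trial's events."""
    if isinstance(spec, EvokedDriveSpec):
        return sample_evoked_events(spec, network, trial_index, master_seed, duration)
    if isinstance(spec, RhythmicDriveSpec):
        return sample_rhythmic_events(spec, network, trial_index, master_seed, duration)
    if isinstance(spec, PoissonDriveSpec):
        return sample_poisson_events(spec, network, trial_index, master_seed, duration)
    raise TypeError(f"unknown drive spec type: {type(spec).__name__}")
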