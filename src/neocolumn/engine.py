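"""Network integration engine.

Time-steps the coupled cable / Hodgkin-Huxley equations for the whole
column with event-driven synapses.  The scheme is the standard staggered
one for compartmental models:

1. gating variables advance one step by exponential Euler at the current
   voltage (unconditionally stable, gates stay in [0, 1]);
2. the voltage equation, linear once the conductances are frozen, advances
   by backward Euler: for every cell a small dense (n_comp x n_comp) system
   is solved; cells of one class are solved as a single batched
   ``numpy.linalg.solve`` call, which is what makes a pure-NumPy network
   simulation practical.

Gate steady states and exponential-decay factors are tabulated on a fine
voltage grid once per (cell class, dt) and looked up by index during the
loop; at the 0.01 mV table resolution the error is far below the
integration error.

Synapses are bi-exponential and event-driven: each receptor keeps two
exponentially decaying state variables per compartment and each delivered
spike increments both, so cost is independent of spike history.

Units: mV, ms, nA, uS, nF, MOhm (a consistent set: uS*mV = nA,
nF*mV/ms = nA, 1/MOhm = uS).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from . import channels as ch
from .cells import CellTemplate, axial_resistance, build_cell_template
from .network import (
    RECEPTORS,
    CellInfo,
    Network,
    biexp_norm,
)

__all__ = [
    "SimulationParams",
    "TrialResult",
    "RunResult",
    "CompiledNetwork",
    "integrate_trial",
    "run_experiment",
    "detect_spikes",
    "simulate_single_cell",
]

_REC_INDEX = {"ampa": 0, "nmda": 1, "gabaa": 2, "gabab": 3}
_REC_NAMES = ("ampa", "nmda", "gabaa", "gabab")

# NMDA Mg-block parameters (Jahr & Stevens form), used only when enabled
_MG_CONC = 1.0  # mM

# voltage grid for tabulated gate kinetics
_VMIN, _VMAX, _DV = -120.0, 60.0, 0.01
_NV = int(round((_VMAX - _VMIN) / _DV)) + 1
_VGRID = _VMIN + _DV * np.arange(_NV)


@dataclass
class SimulationParams:
    """Run-level settings shared by all trials."""

    duration: float = 170.0       # ms
    dt: float = 0.025             # ms
    n_trials: int = 1
    firing_threshold: float = 0.0  # mV, somatic spike detection
    master_seed: int = 0
    settle_window: float = 50.0   # ms excluded from analysis by default
    record_voltages: bool = False
    nmda_mg_block: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration <= self.settle_window:
            raise ValueError("duration must exceed the settling window")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TrialResult:
    """Output of one simulated trial."""

    times: np.ndarray                  # ms
    dipole: np.ndarray                 # aggregate, nAm
    dipole_L2: np.ndarray              # nAm
    dipole_L5: np.ndarray              # nAm
    spikes: list[tuple[int, str, float]]  # (gid, population, time ms)
    soma_voltages: np.ndarray | None = None  # (n_times, n_cells) mV
    all_voltages: np.ndarray | None = None   # (n_times, n_comp) mV
    trial_index: int = 0


@dataclass
class RunResult:
    """Multi-trial experiment: per-trial results plus the trial average."""

    trials: list[TrialResult]
    times: np.ndarray
    mean_dipole: np.ndarray
    mean_dipole_L2: np.ndarray
    mean_dipole_L5: np.ndarray
    scaling: float = 1.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def scaled(self, factor: float) -> "RunResult":
        if factor <= 0:
            raise ValueError("scaling factor must be > 0")
        return RunResult(
            trials=self.trials,
            times=self.times,
            mean_dipole=self.mean_dipole * factor,
            mean_dipole_L2=self.mean_dipole_L2 * factor,
            mean_dipole_L5=self.mean_dipole_L5 * factor,
            scaling=self.scaling * factor,
        )


def detect_spikes(
    times: np.ndarray,
    voltage: np.ndarray,
    threshold: float = 0.0,
    refractory: float = 1.0,
) -> np.ndarray:
    """Upward threshold-crossing times, coalesced within ``refractory`` ms."""
    v = np.asarray(voltage, dtype=float)
    t = np.asarray(times, dtype=float)
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    out: list[float] = []
    for i in up:
        if not out or t[i] - out[-1] > refractory:
            out.append(t[i])
    return np.array(out)


class _GateRuntime:
    """Tabulated kinetics of one gate for a fixed dt."""

    __slots__ = ("key", "power", "ca_dependent", "inf_tab", "efact_tab", "rates")

    def __init__(self, channel: str, gate, dt: float):
        self.key = (channel, gate.name)
        self.power = gate.power
        self.ca_dependent = gate.ca_dependent
        self.rates = gate.rates
        if gate.ca_dependent:
            self.inf_tab = None
            self.efact_tab = None
        else:
            inf, tau = gate.rates(_VGRID)
            self.inf_tab = np.asarray(inf)
            self.efact_tab = -np.expm1(-dt / np.asarray(tau))


class _ChannelRuntime:
    __slots__ = ("name", "gbar_uS", "e_rev", "gates", "is_ca")

    def __init__(self, name: str, gbar_uS: np.ndarray, dt: float):
        self.name = name
        self.gbar_uS = gbar_uS
        self.e_rev = ch.CHANNEL_REVERSAL[name]
        self.gates = [_GateRuntime(name, g, dt) for g in ch.CHANNEL_GATES[name]]
        self.is_ca = name in ch.CA_CHANNELS


class _ClassGroup:
    """All cells of one class, laid out for batched linear solves."""

    def __init__(self, template: CellTemplate, gids: list[int], comp_base: int):
        self.template = template
        self.gids = np.array(gids, dtype=np.int64)
        n_cells = len(gids)
        nc = template.n_compartments
        self.n_cells = n_cells
        self.n_comp = nc
        # global compartment indices, shape (n_cells, n_comp)
        self.idx = comp_base + np.arange(n_cells * nc).reshape(n_cells, nc)

        comps = template.compartments
        name_to_local = {c.name: i for i, c in enumerate(comps)}
        self.comp_names = [c.name for c in comps]
        self.local_index = name_to_local
        area = np.array([c.area_cm2 for c in comps])
        self.area_cm2 = area
        pas = template.passive
        self.C_nF = pas.Cm * area * 1e3
        self.g_leak_uS = area / pas.Rm * 1e6
        self.e_leak = pas.e_leak
        self.gle = self.g_leak_uS * pas.e_leak
        # axial tree: parent local index, coupling conductance uS, dz um
        parent = np.full(nc, -1, dtype=np.int64)
        g_ax = np.zeros(nc)
        dz = np.zeros(nc)
        for i, c in enumerate(comps):
            if c.parent is None:
                continue
            parent[i] = name_to_local[c.parent]
            g_ax[i] = 1.0 / axial_resistance(
                template.compartment(c.parent), c, pas.Ra
            )
            dz[i] = c.delta_z
        self.parent = parent
        self.g_ax_uS = g_ax
        self.dz_um = dz
        # dense axial Laplacian (n_comp x n_comp)
        lap = np.zeros((nc, nc))
        for i in range(nc):
            p = parent[i]
            if p < 0:
                continue
            g = g_ax[i]
            lap[i, i] += g
            lap[p, p] += g
            lap[i, p] -= g
            lap[p, i] -= g
        self.axial_matrix = lap
        self.soma_local = name_to_local["soma"]

        # channels: gbar in uS per compartment (uniform density x area)
        self.channels = {
            name: gbar * area * 1e6
            for name, gbar in template.mechanisms.items()
        }
        self.has_ca = any(c in self.channels for c in ch.CA_CHANNELS)
        # true resting potential of this class (uniform fixed point)
        self.v_rest = ch.resting_membrane_potential(
            template.mechanisms, pas.Rm, pas.e_leak
        )
        self._runtime_cache: dict[float, list[_ChannelRuntime]] = {}

    def runtime(self, dt: float) -> list[_ChannelRuntime]:
        rt = self._runtime_cache.get(dt)
        if rt is None:
            rt = [
                _ChannelRuntime(name, gbar, dt)
                for name, gbar in self.channels.items()
            ]
            self._runtime_cache[dt] = rt
        return rt

    def init_state(self):
        v = np.full((self.n_cells, self.n_comp), self.v_rest)
        gates = {}
        ca = np.full((self.n_cells, self.n_comp), ch.CA_BASELINE)
        for name in self.channels:
            for gate in ch.CHANNEL_GATES[name]:
                inf, _ = ch.gate_steady_tau(name, gate, v, ca)
                gates[(name, gate.name)] = np.array(inf, dtype=float)
        return v, gates, ca


class CompiledNetwork:
    """Flattened, array-based representation of a network ready to run.

    Compile once, run many trials: the compiled object holds only static
    structure (geometry, conductances, synapse routing, kinetics tables);
    per-trial state lives inside :func:`integrate_trial`.
    """

    def __init__(self, cells: list[CellInfo], synapses=(), templates=None):
        if templates is None:
            templates = {}
        self.cells = list(cells)
        self.n_cells = len(cells)
        # group cells by class, preserving gid order within a group
        by_class: dict[str, list[int]] = defaultdict(list)
        for c in cells:
            by_class[c.cell_class].append(c.gid)
        self.groups: list[_ClassGroup] = []
        comp_base = 0
        self._gid_group: dict[int, tuple[_ClassGroup, int]] = {}
        for cls, gids in by_class.items():
            tpl = templates.get(cls) or build_cell_template(cls)
            grp = _ClassGroup(tpl, gids, comp_base)
            comp_base += grp.n_cells * grp.n_comp
            self.groups.append(grp)
            for row, gid in enumerate(gids):
                self._gid_group[gid] = (grp, row)
        self.n_comp_total = comp_base

        self.gid_to_cell = {c.gid: c for c in cells}

        # soma index and population per cell (gid order)
        self.soma_index = np.zeros(self.n_cells, dtype=np.int64)
        self.population = [""] * self.n_cells
        for c in cells:
            grp, row = self._gid_group[c.gid]
            self.soma_index[c.gid] = grp.idx[row, grp.soma_local]
            self.population[c.gid] = c.population

        # dipole bookkeeping: child compartments of pyramidal cells
        sel, par, gax, dz, layer = [], [], [], [], []
        for grp in self.groups:
            if not grp.template.is_pyramidal:
                continue
            lay = 0 if grp.template.cell_class == "L23Pyr" else 1
            for row in range(grp.n_cells):
                for i in range(grp.n_comp):
                    p = grp.parent[i]
                    if p < 0:
                        continue
                    sel.append(grp.idx[row, i])
                    par.append(grp.idx[row, p])
                    gax.append(grp.g_ax_uS[i])
                    dz.append(grp.dz_um[i])
                    layer.append(lay)
        self._dip_child = np.array(sel, dtype=np.int64)
        self._dip_parent = np.array(par, dtype=np.int64)
        self._dip_gax = np.array(gax)
        self._dip_dz = np.array(dz)
        self._dip_L2 = np.array(layer, dtype=bool) if not len(layer) else (
            np.array(layer) == 0
        )
        self._dip_L5 = ~self._dip_L2 if len(layer) else np.array([], dtype=bool)

        # synapse routing: per presynaptic gid -> (state_idx, w*N, delay ms)
        self._norm = np.array([biexp_norm(RECEPTORS[r]) for r in _REC_NAMES])
        out: dict[int, list[tuple[int, float, float]]] = defaultdict(list)
        for syn in synapses:
            if syn.weight <= 0:
                continue
            state = self.state_index(syn.post_gid, syn.post_compartment, syn.receptor)
            w = syn.weight * self._norm[_REC_INDEX[syn.receptor]]
            out[syn.pre_gid].append((state, w, syn.delay))
        self.outgoing = {}
        for gid, lst in out.items():
            arr = np.array(lst, dtype=float)
            self.outgoing[gid] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1],
                arr[:, 2],
            )

    def comp_index(self, gid: int, compartment: str) -> int:
        grp, row = self._gid_group[gid]
        try:
            local = grp.local_index[compartment]
        except KeyError:
            raise ValueError(
                f"cell {gid} ({grp.template.cell_class}) has no "
                f"compartment {compartment!r}"
            )
        return int(grp.idx[row, local])

    def state_index(self, gid: int, compartment: str, receptor: str) -> int:
        return _REC_INDEX[receptor] * self.n_comp_total + self.comp_index(
            gid, compartment
        )

    def template_of(self, gid: int) -> CellTemplate:
        return self._gid_group[gid][0].template


def integrate_trial(
    compiled: CompiledNetwork,
    event_trains,
    params: SimulationParams,
    trial_index: int = 0,
    tonic_clamps=(),
    duration: float | None = None,
    record_all: bool = False,
) -> TrialResult:
    """Integrate one trial and return dipole, spikes and (optionally) voltages.

    ``event_trains`` are exogenous drive events (already sampled);
    ``tonic_clamps`` are (gid, amplitude nA, start ms, stop ms or None)
    somatic current clamps.  Deterministic given its inputs.
    """
    dt = params.dt
    T = params.duration if duration is None else duration
    n_steps = int(round(T / dt))
    ncomp = compiled.n_comp_total

    # --- per-trial state ---------------------------------------------------
    v = np.zeros(ncomp)
    groups = []
    for grp in compiled.groups:
        gv, gates, ca = grp.init_state()
        v[grp.idx] = gv
        groups.append(
            {
                "grp": grp,
                "gates": gates,
                "ca": ca,
                "runtime": grp.runtime(dt),
                # preallocated work buffers
                "g_tot": np.empty((grp.n_cells, grp.n_comp)),
                "ge_tot": np.empty((grp.n_cells, grp.n_comp)),
                "A": np.empty((grp.n_cells, grp.n_comp, grp.n_comp)),
                "dd": np.arange(grp.n_comp),
                "cdt": grp.C_nF / dt,
            }
        )

    # synaptic receptor states, flattened (4 * ncomp,)
    syn_a = np.zeros(4 * ncomp)
    syn_b = np.zeros(4 * ncomp)
    dec_r = np.repeat(
        [math.exp(-dt / RECEPTORS[r].tau_rise) for r in _REC_NAMES], ncomp
    )
    dec_d = np.repeat(
        [math.exp(-dt / RECEPTORS[r].tau_decay) for r in _REC_NAMES], ncomp
    )
    e_rev_flat = np.repeat(
        [RECEPTORS[r].reversal for r in _REC_NAMES], ncomp
    )

    # schedule exogenous events
    pending: dict[int, list] = defaultdict(list)
    norm = compiled._norm
    for train in event_trains:
        if len(train.times) == 0:
            continue
        state = compiled.state_index(
            train.target_gid, train.target_compartment, train.receptor
        )
        w = train.weight * norm[_REC_INDEX[train.receptor]]
        steps = np.round(np.asarray(train.times) / dt).astype(np.int64)
        for s in steps:
            if 0 <= s <= n_steps:
                pending[int(s)].append((np.array([state]), np.array([w])))

    # somatic current clamps: (comp_idx, amp, step_on, step_off)
    clamps = [
        (
            compiled.comp_index(gid, "soma"),
            amp,
            int(round(start / dt)),
            int(round(stop / dt)) if stop is not None else n_steps + 1,
        )
        for (gid, amp, start, stop) in tonic_clamps
    ]

    # --- output buffers ----------------------------------------------------
    times = np.arange(n_steps + 1) * dt
    dip_L2 = np.zeros(n_steps + 1)
    dip_L5 = np.zeros(n_steps + 1)
    spikes: list[tuple[int, str, float]] = []
    last_spike = np.full(compiled.n_cells, -1e9)
    record_soma = params.record_voltages
    if record_soma:
        soma_v = np.zeros((n_steps + 1, compiled.n_cells))
        soma_v[0] = v[compiled.soma_index]
    if record_all:
        all_v = np.zeros((n_steps + 1, ncomp))
        all_v[0] = v
    v_soma_prev = v[compiled.soma_index].copy()

    dip_child = compiled._dip_child
    have_dipole = len(dip_child) > 0

    def dipole_sample(step):
        q = (
            (v[compiled._dip_parent] - v[dip_child])
            * compiled._dip_gax
            * compiled._dip_dz
        )
        dip_L2[step] = q[compiled._dip_L2].sum() * 1e-6
        dip_L5[step] = q[compiled._dip_L5].sum() * 1e-6

    if have_dipole:
        dipole_sample(0)

    thr = params.firing_threshold
    inv_dv = 1.0 / _DV
    use_block = params.nmda_mg_block

    for step in range(1, n_steps + 1):
        t = step * dt

        # deliver synaptic events scheduled for this step
        ev = pending.pop(step, None)
        if ev is not None:
            for state_idx, amounts in ev:
                np.add.at(syn_a, state_idx, amounts)
                np.add.at(syn_b, state_idx, amounts)

        # decay receptor states; conductance = b - a (>= 0)
        syn_a *= dec_r
        syn_b *= dec_d
        g_states = syn_b - syn_a
        if use_block:
            blk = 1.0 / (1.0 + 0.28 * _MG_CONC * np.exp(-0.062 * v))
            g_states[ncomp: 2 * ncomp] *= blk
        gs = g_states.reshape(4, ncomp)
        g_syn = gs.sum(axis=0)
        ge_syn = e_rev_flat.reshape(4, ncomp)[:, 0] @ gs

        # injected currents
        i_inj = None
        for comp_idx, amp, s_on, s_off in clamps:
            if s_on <= step < s_off:
                if i_inj is None:
                    i_inj = np.zeros(ncomp)
                i_inj[comp_idx] += amp

        # advance each class group
        for gstate in groups:
            grp = gstate["grp"]
            gates = gstate["gates"]
            ca = gstate["ca"]
            vg = v[grp.idx]
            vidx = ((np.clip(vg, _VMIN, _VMAX) - _VMIN) * inv_dv + 0.5).astype(
                np.int32
            )
            g_tot = gstate["g_tot"]
            ge_tot = gstate["ge_tot"]
            g_tot[:] = grp.g_leak_uS
            ge_tot[:] = grp.gle
            i_ca = None
            for chan in gstate["runtime"]:
                open_frac = None
                for gate in chan.gates:
                    x = gates[gate.key]
                    if gate.ca_dependent:
                        inf, tau = gate.rates(vg, ca)
                        x += (inf - x) * -np.expm1(-dt / tau)
                    else:
                        x += (gate.inf_tab[vidx] - x) * gate.efact_tab[vidx]
                    f = x if gate.power == 1 else x**gate.power
                    open_frac = f if open_frac is None else open_frac * f
                g = chan.gbar_uS * open_frac
                g_tot += g
                ge_tot += g * chan.e_rev
                if chan.is_ca:
                    ica = g * (vg - ch.E_CA)
                    i_ca = ica if i_ca is None else i_ca + ica
            if i_ca is not None:
                influx = ch.ca_influx_rate(i_ca, grp.area_cm2)
                ca += dt * (influx - (ca - ch.CA_BASELINE) / ch.CA_TAU_MS)
                np.maximum(ca, 0.0, out=ca)

            # synaptic + injected terms for this group's compartments
            g_tot += g_syn[grp.idx]
            ge_tot += ge_syn[grp.idx]
            rhs = gstate["cdt"] * vg + ge_tot
            if i_inj is not None:
                rhs += i_inj[grp.idx]

            if grp.n_comp == 1:
                vnew = rhs / (gstate["cdt"] + g_tot)
            else:
                A = gstate["A"]
                A[:] = grp.axial_matrix
                dd = gstate["dd"]
                A[:, dd, dd] += gstate["cdt"] + g_tot
                vnew = np.linalg.solve(A, rhs[..., None])[..., 0]
            v[grp.idx] = vnew

        # dipole sample
        if have_dipole:
            dipole_sample(step)

        # spikes and synaptic transmission
        v_soma = v[compiled.soma_index]
        crossing = np.flatnonzero(
            (v_soma_prev < thr) & (v_soma >= thr) & (t - last_spike > 1.0)
        )
        for gid in crossing:
            last_spike[gid] = t
            spikes.append((int(gid), compiled.population[gid], t))
            route = compiled.outgoing.get(int(gid))
            if route is not None:
                state_idx, w, delay = route
                tgt_f = step + np.round(delay / dt)
                ok = tgt_f <= n_steps  # events beyond the run are dropped
                if ok.any():
                    tgt = tgt_f[ok].astype(np.int64)
                    sidx = state_idx[ok]
                    wk = w[ok]
                    for s in np.unique(tgt):
                        m = tgt == s
                        pending[int(s)].append((sidx[m], wk[m]))
        v_soma_prev[:] = v_soma
        if record_soma:
            soma_v[step] = v_soma
        if record_all:
            all_v[step] = v

        if step % 400 == 0:
            vmax = np.abs(v).max()
            if not np.isfinite(vmax) or vmax > 1000.0:
                raise RuntimeError(
                    f"numerical blow-up (|v| = {vmax:.3g} mV) at t = {t:.3f} ms"
                )

    return TrialResult(
        times=times,
        dipole=dip_L2 + dip_L5,
        dipole_L2=dip_L2,
        dipole_L5=dip_L5,
        spikes=spikes,
        soma_voltages=soma_v if record_soma else None,
        all_voltages=all_v if record_all else None,
        trial_index=trial_index,
    )


def run_experiment(
    network: Network,
    drive_specs,
    params: SimulationParams,
    compiled: CompiledNetwork | None = None,
    duration: float | None = None,
) -> RunResult:
    """Run ``params.n_trials`` trials with independent drive realizations.

    Each trial re-samples every drive's event trains with the trial index
    threaded into the RNG substream (and into evoked start-time
    increments); the mean dipole is the sample-wise arithmetic mean.
    """
    from .drives import TonicDriveSpec, sample_drive_events

    if compiled is None:
        compiled = CompiledNetwork(network.cells, network.synapses)
    T = params.duration if duration is None else duration
    trials = []
    for k in range(params.n_trials):
        trains = []
        clamps = []
        for spec in drive_specs:
            if isinstance(spec, TonicDriveSpec):
                clamps.extend(spec.clamps(network))
                continue
            trains.extend(
                sample_drive_events(
                    spec, network, trial_index=k,
                    master_seed=params.master_seed, duration=T,
                )
            )
        trials.append(
            integrate_trial(
                compiled, trains, params, trial_index=k,
                tonic_clamps=clamps, duration=T,
            )
        )
    mean = np.mean([tr.dipole for tr in trials], axis=0)
    mean_l2 = np.mean([tr.dipole_L2 for tr in trials], axis=0)
    mean_l5 = np.mean([tr.dipole_L5 for tr in trials], axis=0)
    return RunResult(
        trials=trials,
        times=trials[0].times,
        mean_dipole=mean,
        mean_dipole_L2=mean_l2,
        mean_dipole_L5=mean_l5,
    )


def simulate_single_cell(
    template: CellTemplate,
    duration: float,
    dt: float = 0.025,
    i_soma: float = 0.0,
    i_start: float = 0.0,
    i_stop: float | None = None,
    event_trains=(),
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one isolated cell; returns (times, voltages (n_t, n_comp)).

    Compartment columns follow the template's compartment order.  Used for
    passive characterization, current-clamp protocols and unit tests.
    """
    info = CellInfo(
        gid=0,
        population="isolated",
        cell_class=template.cell_class,
        layer="NA",
        x=0.0,
        y=0.0,
    )
    compiled = CompiledNetwork([info], templates={template.cell_class: template})
    params = SimulationParams(
        duration=duration, dt=dt, settle_window=0.0, record_voltages=False
    )
    clamps = []
    if i_soma != 0.0:
        clamps.append((0, i_soma, i_start, i_stop))
    result = integrate_trial(
        compiled,
        list(event_trains),
        params,
        tonic_clamps=clamps,
        record_all=True,
    )
    return result.times, result.all_voltages
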