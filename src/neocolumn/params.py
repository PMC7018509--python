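"""Plain-text parameter files and dipole trace files.

The parameter dialect is flat ``key: value`` lines grouped into blank-line
separated sections, chosen for human diffability.  Keys mirror the
simulator's dialog-style naming: run settings (``tstop``, ``dt``,
``N_trials`` ...), network structure (``N_pyr_x``, synaptic gains, local
pathway conductances ``gbar_L2Pyr_L2Basket_ampa`` ...), and one key group
per exogenous drive (``t_evprox_1``, ``sigma_t_evprox_1``,
``gbar_evprox_1_L5Pyr_ampa`` ...).  Reading then writing a file preserves
every key-value pair; unknown keys are preserved and reported.

Dipole traces are whitespace-delimited text: ``time_ms  aggregate_nAm``
with optional per-layer columns (``L2_nAm  L5_nAm``) and ``#`` comment
headers, the same layout for recorded data and simulation output so either
can be loaded as the fitting target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .drives import (
    EvokedDriveSpec,
    PoissonDriveSpec,
    RhythmicDriveSpec,
    TonicDriveSpec,
)
from .network import ConnectivityRule, default_connectivity_rules

__all__ = [
    "ParamFile",
    "DipoleDataFile",
    "read_param",
    "write_param",
    "read_dipole",
    "write_dipole",
    "read_spikes",
    "write_spikes",
    "config_from_params",
    "params_from_config",
    "ColumnConfig",
]

_POP_TOKEN = {
    "L2_pyramidal": "L2Pyr",
    "L2_basket": "L2Basket",
    "L5_pyramidal": "L5Pyr",
    "L5_basket": "L5Basket",
}
_TOKEN_POP = {v: k for k, v in _POP_TOKEN.items()}

_GAIN_KEYS = {
    ("e", "e"): "gain_e_e",
    ("e", "i"): "gain_e_i",
    ("i", "e"): "gain_i_e",
    ("i", "i"): "gain_i_i",
}


@dataclass
class ParamFile:
    """Flat key -> value map with stable ordering."""

    values: dict[str, object] = field(default_factory=dict)
    path: str | None = None

    def __getitem__(self, key):
        return self.values[key]

    def get(self, key, default=None):
        return self.values.get(key, default)

    def __contains__(self, key):
        return key in self.values

    def __eq__(self, other):
        if not isinstance(other, ParamFile):
            return NotImplemented
        return self.values == other.values


def _parse_value(text: str):
    text = text.strip()
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def read_param(path) -> ParamFile:
    """Read a parameter file; malformed or duplicate lines are rejected."""
    values: dict[str, object] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(
                    f"{path}:{lineno}: malformed line (expected 'key: value'): "
                    f"{line!r}"
                )
            key, _, val = line.partition(":")
            key = key.strip()
            if not key:
                raise ValueError(f"{path}:{lineno}: empty key")
            if key in values:
                raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
            values[key] = _parse_value(val)
    return ParamFile(values=values, path=str(path))


_SECTION_PREFIXES = [
    ("# run", ("tstop", "dt", "N_trials", "threshold", "prng_", "dipole_",
               "record_", "settle_")),
    ("# network", ("N_pyr_", "gain_", "gbar_L2", "gbar_L5")),
    ("# drives", ("t_ev", "sigma_t_ev", "numspikes_ev", "gbar_ev", "sync_ev",
                  "inc_ev", "t0_input", "tstop_input", "f_input",
                  "f_stdev_input", "events_per_cycle_input", "repeats_input",
                  "gbar_input", "delay_input", "t0_pois", "T_pois",
                  "pois_rate_", "gbar_pois_", "Itonic_")),
]


def _section_of(key: str) -> int:
    for i, (_, prefixes) in enumerate(_SECTION_PREFIXES):
        if any(key.startswith(p) for p in prefixes):
            return i
    return len(_SECTION_PREFIXES)


def write_param(path, params: ParamFile | dict) -> None:
    """Write a parameter file (sections grouped, lossless round trip)."""
    if isinstance(params, ParamFile):
        values = params.values
    else:
        values = params
    sections: dict[int, list[str]] = {}
    for key in values:
        sections.setdefault(_section_of(key), []).append(key)
    with open(path, "w") as fh:
        first = True
        for i in sorted(sections):
            if not first:
                fh.write("\n")
            first = False
            header = (
                _SECTION_PREFIXES[i][0]
                if i < len(_SECTION_PREFIXES)
                else "# other"
            )
            fh.write(header + "\n")
            for key in sections[i]:
                fh.write(f"{key}: {_format_value(values[key])}\n")


@dataclass
class DipoleDataFile:
    """A dipole trace read from or written to disk."""

    times: np.ndarray
    aggregate: np.ndarray
    L2: np.ndarray | None = None
    L5: np.ndarray | None = None

    @property
    def has_layers(self) -> bool:
        return self.L2 is not None and self.L5 is not None


def read_dipole(path) -> DipoleDataFile:
    """Read a 2- or 4-column whitespace-delimited dipole trace."""
    rows = []
    ncol = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncol is None:
                ncol = len(parts)
                if ncol not in (2, 4):
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 or 4 columns, got {ncol}"
                    )
            elif len(parts) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncol})"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows)
    t = arr[:, 0]
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    if ncol == 2:
        return DipoleDataFile(times=t, aggregate=arr[:, 1])
    return DipoleDataFile(
        times=t, aggregate=arr[:, 1], L2=arr[:, 2], L5=arr[:, 3]
    )


def write_dipole(path, trace, header: str | None = None) -> None:
    """Write a dipole trace (RunResult, DipoleDataFile or arrays).

    Writes 4 columns (time, aggregate, L2, L5) when per-layer traces are
    available, 2 otherwise; values carry 6 significant digits.
    """
    times = trace.times
    if hasattr(trace, "mean_dipole"):
        agg = trace.mean_dipole
        l2, l5 = trace.mean_dipole_L2, trace.mean_dipole_L5
    else:
        agg = trace.aggregate
        l2 = getattr(trace, "L2", None)
        l5 = getattr(trace, "L5", None)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        if l2 is not None and l5 is not None:
            fh.write("# time_ms aggregate_nAm L2_nAm L5_nAm\n")
            for row in zip(times, agg, l2, l5):
                fh.write(" ".join(f"{x:.6g}" for x in row) + "\n")
        else:
            fh.write("# time_ms aggregate_nAm\n")
            for t, a in zip(times, agg):
                fh.write(f"{t:.6g} {a:.6g}\n")


def write_spikes(path, trials, header: str | None = None) -> None:
    """Write a spike raster: ``time_ms  gid  population`` per line.

    ``trials`` is an iterable of TrialResult-like objects (each carrying a
    ``spikes`` list of (gid, population, time) tuples); a trial column is
    included when more than one trial is given.
    """
    trials = list(trials)
    multi = len(trials) > 1
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        cols = "# time_ms gid population" + (" trial" if multi else "")
        fh.write(cols + "\n")
        for k, tr in enumerate(trials):
            for gid, pop, t in sorted(tr.spikes, key=lambda s: s[2]):
                row = f"{t:.3f} {gid} {pop}"
                if multi:
                    row += f" {k}"
                fh.write(row + "\n")


def read_spikes(path) -> list[tuple[int, str, float, int]]:
    """Read a spike raster; returns (gid, population, time_ms, trial)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 4 columns"
                )
            t, gid, pop = float(parts[0]), int(parts[1]), parts[2]
            trial = int(parts[3]) if len(parts) == 4 else 0
            out.append((gid, pop, t, trial))
    return out


# ---------------------------------------------------------------------------
# model configuration <-> flat parameter keys
# ---------------------------------------------------------------------------


@dataclass
class ColumnConfig:
    """Everything needed to build and run the column model."""

    n_pyr_x: int = 10
    n_pyr_y: int = 10
    gains: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("e", "e"): 1.0, ("e", "i"): 1.0, ("i", "e"): 1.0, ("i", "i"): 1.0,
        }
    )
    # (pre_pop, post_pop, receptor) -> base weight uS; None = package default
    pathway_weights: dict[tuple[str, str, str], float] = field(default_factory=dict)
    drives: list = field(default_factory=list)
    duration: float = 170.0
    dt: float = 0.025
    n_trials: int = 1
    firing_threshold: float = 0.0
    master_seed: int = 0
    settle_window: float = 50.0
    dipole_scale: float = 1.0
    record_voltages: bool = False

    def connectivity_rules(self) -> list[ConnectivityRule]:
        """Default rule set with this configuration's pathway weights.

        Pathways set to zero weight are dropped (disabled synapses);
        pathways absent from the default set cannot be created here.
        """
        rules = []
        for rule in default_connectivity_rules():
            key = (rule.pre_population, rule.post_population, rule.receptor)
            w = self.pathway_weights.get(key, rule.weight)
            if w > 0:
                rules.append(
                    ConnectivityRule(
                        rule.pre_population, rule.post_population,
                        rule.receptor, w, rule.space_constant,
                        rule.target_site, rule.base_delay,
                    )
                )
        return rules


def _drive_keys(spec) -> dict[str, object]:
    out: dict[str, object] = {}
    if isinstance(spec, EvokedDriveSpec):
        n = spec.name
        out[f"t_{n}"] = spec.start_time_mean
        out[f"sigma_t_{n}"] = spec.start_time_stdev
        out[f"numspikes_{n}"] = spec.n_spikes_per_synapse
        out[f"sync_{n}"] = spec.synchronous
        out[f"inc_{n}"] = spec.increment_per_trial
        for (pop, rec), w in sorted(spec.weights.items()):
            out[f"gbar_{n}_{_POP_TOKEN[pop]}_{rec}"] = w
    elif isinstance(spec, RhythmicDriveSpec):
        n = spec.name
        out[f"t0_input_{n}"] = spec.start_time_mean
        out[f"sigma_t0_input_{n}"] = spec.start_time_stdev
        out[f"tstop_input_{n}"] = spec.stop_time
        out[f"f_input_{n}"] = spec.burst_frequency
        out[f"f_stdev_input_{n}"] = spec.burst_stdev
        out[f"events_per_cycle_input_{n}"] = spec.spikes_per_burst
        out[f"repeats_input_{n}"] = spec.n_bursts
        for (pop, rec), w in sorted(spec.weights.items()):
            out[f"gbar_input_{n}_{_POP_TOKEN[pop]}_{rec}"] = w
        for pop, d in sorted(spec.delay_offsets.items()):
            out[f"delay_input_{n}_{_POP_TOKEN[pop]}"] = d
    elif isinstance(spec, PoissonDriveSpec):
        n = spec.name
        out[f"t0_pois_{n}"] = spec.start
        out[f"T_pois_{n}"] = spec.stop
        for pop, r in sorted(spec.rates.items()):
            out[f"pois_rate_{n}_{_POP_TOKEN[pop]}"] = r
        for (pop, rec), w in sorted(spec.weights.items()):
            out[f"gbar_pois_{n}_{_POP_TOKEN[pop]}_{rec}"] = w
    elif isinstance(spec, TonicDriveSpec):
        n = spec.name
        for pop, a in sorted(spec.amplitudes.items()):
            out[f"Itonic_A_{n}_{_POP_TOKEN[pop]}"] = a
        out[f"Itonic_t0_{n}"] = spec.start
        out[f"Itonic_T_{n}"] = -1.0 if spec.stop is None else spec.stop
    else:
        raise TypeError(f"cannot serialize drive {type(spec).__name__}")
    return out


def params_from_config(config: ColumnConfig) -> ParamFile:
    """Serialize a model configuration to flat parameter keys."""
    values: dict[str, object] = {
        "tstop": config.duration,
        "dt": config.dt,
        "N_trials": config.n_trials,
        "threshold": config.firing_threshold,
        "prng_seedcore": config.master_seed,
        "dipole_scalefctr": config.dipole_scale,
        "settle_window": config.settle_window,
        "record_vsoma": config.record_voltages,
        "N_pyr_x": config.n_pyr_x,
        "N_pyr_y": config.n_pyr_y,
    }
    for pair, key in _GAIN_KEYS.items():
        values[key] = config.gains.get(pair, 1.0)
    for rule in default_connectivity_rules():
        key = (rule.pre_population, rule.post_population, rule.receptor)
        w = config.pathway_weights.get(key, rule.weight)
        values[
            f"gbar_{_POP_TOKEN[rule.pre_population]}_"
            f"{_POP_TOKEN[rule.post_population]}_{rule.receptor}"
        ] = w
    # drive class bookkeeping so the reader can reconstruct spec types
    for spec in config.drives:
        kind = {
            EvokedDriveSpec: "evoked",
            RhythmicDriveSpec: "rhythmic",
            PoissonDriveSpec: "poisson",
            TonicDriveSpec: "tonic",
        }[type(spec)]
        route = getattr(spec, "drive_class", "none")
        values[f"drive_{spec.name}"] = f"{kind}/{route}"
        values.update(_drive_keys(spec))
    return ParamFile(values=values)


def _pop_weights(values, prefix: str) -> dict[tuple[str, str], float]:
    out = {}
    for token, pop in _TOKEN_POP.items():
        for rec in ("ampa", "nmda"):
            key = f"{prefix}_{token}_{rec}"
            if key in values:
                out[(pop, rec)] = float(values[key])
    return out


def config_from_params(params: ParamFile) -> ColumnConfig:
    """Rebuild a model configuration from flat parameter keys.

    Unknown keys are preserved in the file but trigger a warning here so
    typos do not silently change nothing.
    """
    v = dict(params.values)
    consumed = set()

    def take(key, default=None):
        consumed.add(key)
        return v.get(key, default)

    config = ColumnConfig(
        n_pyr_x=int(take("N_pyr_x", 10)),
        n_pyr_y=int(take("N_pyr_y", 10)),
        duration=float(take("tstop", 170.0)),
        dt=float(take("dt", 0.025)),
        n_trials=int(take("N_trials", 1)),
        firing_threshold=float(take("threshold", 0.0)),
        master_seed=int(take("prng_seedcore", 0)),
        settle_window=float(take("settle_window", 50.0)),
        dipole_scale=float(take("dipole_scalefctr", 1.0)),
        record_voltages=bool(take("record_vsoma", False)),
    )
    for pair, key in _GAIN_KEYS.items():
        config.gains[pair] = float(take(key, 1.0))
    for rule in default_connectivity_rules():
        key = (
            f"gbar_{_POP_TOKEN[rule.pre_population]}_"
            f"{_POP_TOKEN[rule.post_population]}_{rule.receptor}"
        )
        if key in v:
            config.pathway_weights[
                (rule.pre_population, rule.post_population, rule.receptor)
            ] = float(take(key))

    drive_decls = sorted(k for k in v if k.startswith("drive_"))
    for decl in drive_decls:
        name = decl[len("drive_"):]
        kind, _, route = str(take(decl)).partition("/")
        if kind == "evoked":
            spec = EvokedDriveSpec(
                name=name,
                drive_class=route,
                start_time_mean=float(take(f"t_{name}", 0.0)),
                start_time_stdev=float(take(f"sigma_t_{name}", 0.0)),
                n_spikes_per_synapse=int(take(f"numspikes_{name}", 1)),
                weights=_pop_weights(v, f"gbar_{name}"),
                synchronous=bool(take(f"sync_{name}", False)),
                increment_per_trial=float(take(f"inc_{name}", 0.0)),
            )
            for key in list(v):
                if key.startswith(f"gbar_{name}_"):
                    consumed.add(key)
        elif kind == "rhythmic":
            spec = RhythmicDriveSpec(
                name=name,
                drive_class=route,
                start_time_mean=float(take(f"t0_input_{name}", 0.0)),
                start_time_stdev=float(take(f"sigma_t0_input_{name}", 0.0)),
                stop_time=float(take(f"tstop_input_{name}", math.inf)),
                burst_frequency=float(take(f"f_input_{name}", 10.0)),
                burst_stdev=float(take(f"f_stdev_input_{name}", 0.0)),
                spikes_per_burst=int(take(f"events_per_cycle_input_{name}", 2)),
                n_bursts=int(take(f"repeats_input_{name}", 10)),
                weights=_pop_weights(v, f"gbar_input_{name}"),
            )
            for token, pop in _TOKEN_POP.items():
                key = f"delay_input_{name}_{token}"
                if key in v:
                    spec.delay_offsets[pop] = float(take(key))
            for key in list(v):
                if key.startswith(f"gbar_input_{name}_"):
                    consumed.add(key)
        elif kind == "poisson":
            rates = {}
            for token, pop in _TOKEN_POP.items():
                key = f"pois_rate_{name}_{token}"
                if key in v:
                    rates[pop] = float(take(key))
            spec = PoissonDriveSpec(
                name=name,
                rates=rates,
                weights=_pop_weights(v, f"gbar_pois_{name}"),
                start=float(take(f"t0_pois_{name}", 0.0)),
                stop=float(take(f"T_pois_{name}", -1.0)),
            )
            for key in list(v):
                if key.startswith(f"gbar_pois_{name}_"):
                    consumed.add(key)
        elif kind == "tonic":
            amplitudes = {}
            for token, pop in _TOKEN_POP.items():
                key = f"Itonic_A_{name}_{token}"
                if key in v:
                    amplitudes[pop] = float(take(key))
            stop = float(take(f"Itonic_T_{name}", -1.0))
            spec = TonicDriveSpec(
                name=name,
                amplitudes=amplitudes,
                start=float(take(f"Itonic_t0_{name}", 0.0)),
                stop=None if stop < 0 else stop,
            )
        else:
            raise ValueError(f"unknown drive kind {kind!r} for {name!r}")
        config.drives.append(spec)

    unknown = set(v) - consumed
    if unknown:
        warnings.warn(
            f"unrecognized parameter keys preserved but unused: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    return config
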