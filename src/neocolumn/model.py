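"""Model-and-results front end for the column simulator.

``ColumnModel`` wraps a :class:`~neocolumn.params.ColumnConfig` (network
structure, drives, run settings); ``simulate()`` returns a
``SimulationResults`` object carrying the per-trial and trial-averaged
dipoles, spike rasters and summary/plot helpers.  ``ERPModel`` couples a
``ColumnModel`` to a recorded (or synthetic) dipole waveform; ``fit()``
runs the stepwise evoked-input optimization and returns an
``ERPFitResults`` with the estimated parameters, the fit history and a
``summary()`` table.

    >>> model = ColumnModel.from_scenario("erp", n_pyr=5)
    >>> res = model.simulate()
    >>> print(res.summary())

The heavy lifting lives in the ``cells`` / ``network`` / ``drives`` /
``engine`` / ``dipole`` / ``analysis`` / ``optimization`` modules; this
module only arranges it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .analysis import Spectrogram, band_peak, morlet_spectrogram, psd, rmse
from .dipole import implied_neuron_count
from .drives import EvokedDriveSpec
from .engine import (
    CompiledNetwork,
    RunResult,
    SimulationParams,
    run_experiment,
)
from .network import Network, build_network
from .optimization import (
    InputTiming,
    OptimizationConfig,
    OptimizationResult,
    ParameterSpec,
    stepwise_optimize,
    timing_bounds,
    weight_bounds,
)
from .params import (
    ColumnConfig,
    DipoleDataFile,
    config_from_params,
    params_from_config,
    read_dipole,
    read_param,
    write_dipole,
    write_param,
)

__all__ = ["ColumnModel", "SimulationResults", "ERPModel", "ERPFitResults"]


class ColumnModel:
    """The neocortical column model: network structure + drives + run plan."""

    def __init__(self, config: ColumnConfig):
        self.config = config
        self._network: Network | None = None
        self._compiled: CompiledNetwork | None = None

    # --- constructors ------------------------------------------------------

    @classmethod
    def from_param_file(cls, path) -> "ColumnModel":
        return cls(config_from_params(read_param(path)))

    @classmethod
    def from_scenario(
        cls, name: str, n_pyr: int = 10, n_trials: int = 1, seed: int = 0
    ) -> "ColumnModel":
        from .scenarios import scenario_config

        return cls(scenario_config(name, n_pyr=n_pyr, n_trials=n_trials, seed=seed))

    # --- structure ---------------------------------------------------------

    @property
    def network(self) -> Network:
        if self._network is None:
            self._network = build_network(
                self.config.n_pyr_x,
                self.config.n_pyr_y,
                rules=self.config.connectivity_rules(),
                gains=self.config.gains,
            )
        return self._network

    @property
    def compiled(self) -> CompiledNetwork:
        if self._compiled is None:
            net = self.network
            self._compiled = CompiledNetwork(net.cells, net.synapses)
        return self._compiled

    @property
    def n_pyramidal(self) -> int:
        return self.network.n_pyramidal

    def simulation_params(self, n_trials=None, seed=None) -> SimulationParams:
        c = self.config
        return SimulationParams(
            duration=c.duration,
            dt=c.dt,
            n_trials=c.n_trials if n_trials is None else n_trials,
            firing_threshold=c.firing_threshold,
            master_seed=c.master_seed if seed is None else seed,
            settle_window=c.settle_window,
            record_voltages=c.record_voltages,
        )

    def with_drives(self, drives) -> "ColumnModel":
        """A model sharing this network but carrying different drives."""
        clone = ColumnModel(replace(self.config, drives=list(drives)))
        clone._network = self._network
        clone._compiled = self._compiled
        return clone

    # --- running -----------------------------------------------------------

    def simulate(self, n_trials=None, seed=None) -> "SimulationResults":
        """Run the experiment and return results (dipoles already scaled)."""
        params = self.simulation_params(n_trials=n_trials, seed=seed)
        run = run_experiment(
            self.network, self.config.drives, params, compiled=self.compiled
        )
        if self.config.dipole_scale != 1.0:
            run = run.scaled(self.config.dipole_scale)
        return SimulationResults(self, run, params)

    def to_param_file(self, path) -> None:
        write_param(path, params_from_config(self.config))


@dataclass
class SimulationResults:
    """Results of a multi-trial simulation of a ColumnModel."""

    model: ColumnModel
    run: RunResult
    params: SimulationParams

    @property
    def times(self) -> np.ndarray:
        return self.run.times

    @property
    def dipole(self) -> np.ndarray:
        """Trial-averaged aggregate dipole (nAm, scaling applied)."""
        return self.run.mean_dipole

    @property
    def analysis_mask(self) -> np.ndarray:
        return self.times >= self.params.settle_window

    def spike_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tr in self.run.trials:
            for _, pop, _ in tr.spikes:
                counts[pop] = counts.get(pop, 0) + 1
        return counts

    def psd(self, segment_ms: float = 1000.0):
        m = self.analysis_mask
        return psd(self.times[m], self.dipole[m], segment_ms=segment_ms)

    def trial_averaged_psd(self, segment_ms: float = 1000.0):
        """Mean of per-trial PSDs (bursty rhythms accumulate, not cancel)."""
        m = self.analysis_mask
        spectra = []
        for tr in self.run.trials:
            f, p = psd(
                self.times[m],
                tr.dipole[m] * self.run.scaling,
                segment_ms=segment_ms,
            )
            spectra.append(p)
        return f, np.mean(spectra, axis=0)

    def band_peak(self, band, trial_averaged: bool = True) -> float:
        f, p = self.trial_averaged_psd() if trial_averaged else self.psd()
        return band_peak(f, p, band)

    def spectrogram(self, frequencies, trial: int | None = None) -> Spectrogram:
        m = self.analysis_mask
        if trial is None:
            from .analysis import average_spectrograms

            specs = [
                morlet_spectrogram(
                    self.times[m], tr.dipole[m] * self.run.scaling, frequencies
                )
                for tr in self.run.trials
            ]
            return average_spectrograms(specs)
        tr = self.run.trials[trial]
        return morlet_spectrogram(
            self.times[m], tr.dipole[m] * self.run.scaling, frequencies
        )

    def implied_neurons(self) -> int:
        return implied_neuron_count(
            max(self.run.scaling, 1e-300), self.model.n_pyramidal
        )

    def to_file(self, path, header: str | None = None) -> None:
        write_dipole(path, self.run, header=header)

    def plot(self, ax=None, show_trials: bool = True):
        """Plot per-trial (gray) and mean (black) dipole traces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if show_trials:
            for tr in self.run.trials:
                ax.plot(
                    tr.times, tr.dipole * self.run.scaling,
                    color="0.7", lw=0.6,
                )
        ax.plot(self.times, self.dipole, color="k", lw=1.2)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("dipole (nAm)")
        return ax

    def summary(self) -> str:
        c = self.model.config
        m = self.analysis_mask
        d = self.dipole[m]
        lines = [
            "Neocortical column simulation",
            "=" * 46,
            f"grid                 {c.n_pyr_x} x {c.n_pyr_y} "
            f"({self.model.n_pyramidal} pyramidal neurons)",
            f"trials               {self.run.n_trials}",
            f"duration             {c.duration:g} ms (dt = {c.dt:g} ms, "
            f"settle {c.settle_window:g} ms)",
            f"drives               "
            + (", ".join(s.name for s in c.drives) or "none"),
            f"dipole scaling       {self.run.scaling:g} "
            f"(implies {self.implied_neurons():,} neurons)",
            f"dipole peak-to-peak  {np.ptp(d):.4g} nAm "
            f"(max {d.max():.4g}, min {d.min():.4g})",
        ]
        counts = self.spike_counts()
        if counts:
            per_trial = {
                k: v / self.run.n_trials for k, v in sorted(counts.items())
            }
            lines.append(
                "spikes/trial         "
                + ", ".join(f"{k}: {v:.0f}" for k, v in per_trial.items())
            )
        else:
            lines.append("spikes/trial         none")
        return "\n".join(lines)


class ERPModel:
    """An evoked-response model: a ColumnModel fitted to a dipole waveform.

    Free parameters are the evoked drives' start-time means and synaptic
    weights.  Timing bounds are +/- ``timing_stdev_mult`` standard
    deviations of each input's jitter; weight bounds are +/-
    ``weight_percent`` % of the initial value (parameters starting at zero
    get [0, ``zero_weight_max``]).
    """

    def __init__(
        self,
        data,
        model: ColumnModel,
        free_timing: bool = True,
        free_weights: bool = True,
        timing_stdev_mult: float = 3.0,
        weight_percent: float = 100.0,
        zero_weight_max: float = 0.1,
        n_trials: int = 1,
    ):
        if isinstance(data, (tuple, list)):
            times, values = data
            data = DipoleDataFile(
                times=np.asarray(times, dtype=float),
                aggregate=np.asarray(values, dtype=float),
            )
        elif isinstance(data, (str, bytes)) or hasattr(data, "__fspath__"):
            data = read_dipole(data)
        self.data = data
        self.model = model
        self.n_trials = n_trials
        self.evoked = [
            d for d in model.config.drives if isinstance(d, EvokedDriveSpec)
        ]
        if not self.evoked:
            raise ValueError("the model carries no evoked drives to fit")
        self.inputs = [
            InputTiming(d.name, d.start_time_mean, d.start_time_stdev)
            for d in self.evoked
        ]
        specs: list[ParameterSpec] = []
        for d in self.evoked:
            if free_timing:
                lo, hi = timing_bounds(
                    d.start_time_mean, d.start_time_stdev, timing_stdev_mult
                )
                specs.append(
                    ParameterSpec(d.name, "start_time_mean",
                                  d.start_time_mean, lo, hi)
                )
            if free_weights:
                for (pop, rec), w in sorted(d.weights.items()):
                    lo, hi = weight_bounds(
                        w, percent=weight_percent, zero_max=zero_weight_max
                    )
                    specs.append(
                        ParameterSpec(d.name, f"weight:{pop}:{rec}", w, lo, hi)
                    )
        self.parameters = specs
        # forward evaluations share the compiled network and time grid
        self._sim_params = model.simulation_params(n_trials=n_trials)
        self._times = (
            np.arange(int(round(model.config.duration / model.config.dt)) + 1)
            * model.config.dt
        )
        self._data_on_grid = np.interp(
            self._times, self.data.times, self.data.aggregate
        )

    def _apply(self, params: dict) -> list[EvokedDriveSpec]:
        drives = []
        for d in self.model.config.drives:
            if not isinstance(d, EvokedDriveSpec):
                drives.append(d)
                continue
            d2 = copy.deepcopy(d)
            for (name, key), val in params.items():
                if name != d.name:
                    continue
                if key == "start_time_mean":
                    d2.start_time_mean = val
                elif key == "start_time_stdev":
                    d2.start_time_stdev = val
                elif key.startswith("weight:"):
                    _, pop, rec = key.split(":")
                    d2.weights[(pop, rec)] = val
                else:
                    raise KeyError(f"unknown parameter key {key!r}")
            drives.append(d2)
        return drives

    def forward(self, params: dict) -> np.ndarray:
        """Mean scaled dipole for one parameter assignment."""
        drives = self._apply(params)
        run = run_experiment(
            self.model.network,
            drives,
            self._sim_params,
            compiled=self.model.compiled,
        )
        return run.mean_dipole * self.model.config.dipole_scale

    def fit(
        self,
        sims_per_step: int = 30,
        final_step_sims: int = 30,
    ) -> "ERPFitResults":
        config = OptimizationConfig(
            inputs=self.inputs,
            parameters=self.parameters,
            sims_per_step={d.name: sims_per_step for d in self.evoked},
            final_step_sims=final_step_sims,
            horizon=self.model.config.duration,
        )
        result = stepwise_optimize(
            self.forward,
            self._times,
            self._data_on_grid,
            config,
            analysis_start=self.model.config.settle_window,
        )
        fitted = self.model.with_drives(self._apply(result.parameters))
        return ERPFitResults(self, result, fitted)


@dataclass
class ERPFitResults:
    """Stepwise-optimization outcome: parameters, fit history, fitted model."""

    erp_model: ERPModel
    optimization: OptimizationResult
    fitted_model: ColumnModel

    @property
    def parameters(self) -> dict:
        return self.optimization.parameters

    @property
    def initial_rmse(self) -> float:
        return self.optimization.initial_rmse

    @property
    def final_rmse(self) -> float:
        return self.optimization.final_rmse

    def refit(self, **kwargs) -> "ERPFitResults":
        """Run a second optimization from the fitted parameters."""
        model2 = ERPModel(
            self.erp_model.data,
            self.fitted_model,
            n_trials=self.erp_model.n_trials,
        )
        return model2.fit(**kwargs)

    def summary(self) -> str:
        initial = {
            (p.input_name, p.key): p.value for p in self.erp_model.parameters
        }
        lines = [
            "Evoked-response fit (stepwise wRMSE + final RMSE polish)",
            "=" * 60,
            f"inputs: {', '.join(i.name for i in self.erp_model.inputs)}",
            f"RMSE: {self.initial_rmse:.4f} -> {self.final_rmse:.4f} "
            f"({self.optimization.n_evaluations} simulations)",
            "",
            f"{'parameter':<42}{'initial':>9}{'fitted':>9}",
            "-" * 60,
        ]
        for (name, key), val in self.parameters.items():
            init = initial.get((name, key))
            lines.append(
                f"{name + '.' + key:<42}{init:>9.4g}{val:>9.4g}"
            )
        lines.append("-" * 60)
        for h in self.optimization.step_history:
            lines.append(
                f"step {h['step']:<12} objective {h['objective']:.4f}  "
                f"window {h['window'][0]:.0f}-{h['window'][1]:.0f} ms  "
                f"{h['n_evals']} sims"
            )
        return "\n".join(lines)
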