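"""Packaged simulation scenarios and the synthetic fixture generator.

Five canonical drive patterns are shipped, mirroring the classic use cases
of the column model:

- ``erp``          : sensory evoked response — proximal volley at ~25 ms,
  distal at ~60 ms, second proximal at ~125 ms (suprathreshold), producing
  the triphasic positive/negative/positive dipole waveform.
- ``alpha``        : ~10 Hz subthreshold proximal and distal burst trains
  arriving in anti-phase (50 ms delay), yielding a continuous alpha rhythm.
- ``beta``         : the same two burst trains arriving simultaneously with
  a stronger distal component; distal bursts that coincide with proximal
  ones break the upward current flow and create brief beta events, so both
  alpha- and beta-band spectral peaks appear.
- ``gamma_ping``   : pyramidal-interneuron gamma — all synapses disabled
  except within-layer PN->basket (AMPA) and basket->PN (GABAA, 5 ms decay)
  plus basket->basket; 140 Hz Poisson AMPA drive to PN somata produces a
  ~50 Hz rhythm paced by the inhibitory decay.
- ``gamma_bursty`` : the PING network with the Poisson rate reduced to
  4 Hz (L2/3) and 5 Hz (L5) and a small NMDA component, producing
  transient gamma bursts rather than a continuous rhythm.

``generate_fixture`` runs a scenario at reduced scale (5x5 pyramidal grid,
3 trials) and writes a parameter file plus a synthetic "recorded" dipole
trace; because the generating parameters are stored in the param file, the
optimizer's recovery tests have exact ground truth with no external data.
"""

from __future__ import annotations

from pathlib import Path

from .drives import EvokedDriveSpec, PoissonDriveSpec, RhythmicDriveSpec
from .params import ColumnConfig, params_from_config, write_dipole, write_param

__all__ = ["SCENARIOS", "scenario_config", "generate_fixture"]

SCENARIOS = ("erp", "alpha", "beta", "gamma_ping", "gamma_bursty")

# pathway weights for the PING configuration: within-layer E->I (AMPA) and
# I->E / I->I (GABAA) only; every other local pathway silenced
_GAMMA_WEIGHTS = {
    ("L2_pyramidal", "L2_pyramidal", "ampa"): 0.0,
    ("L2_pyramidal", "L2_pyramidal", "nmda"): 0.0,
    ("L2_pyramidal", "L2_basket", "ampa"): 5e-3,
    ("L2_pyramidal", "L2_basket", "nmda"): 0.0,
    ("L2_basket", "L2_pyramidal", "gabaa"): 2e-2,
    ("L2_basket", "L2_pyramidal", "gabab"): 0.0,
    ("L2_basket", "L2_basket", "gabaa"): 1e-2,
    ("L5_pyramidal", "L5_pyramidal", "ampa"): 0.0,
    ("L5_pyramidal", "L5_pyramidal", "nmda"): 0.0,
    ("L5_pyramidal", "L5_basket", "ampa"): 5e-3,
    ("L5_pyramidal", "L5_basket", "nmda"): 0.0,
    ("L5_basket", "L5_pyramidal", "gabaa"): 2e-2,
    ("L5_basket", "L5_pyramidal", "gabab"): 0.0,
    ("L5_basket", "L5_basket", "gabaa"): 1e-2,
    ("L2_pyramidal", "L5_pyramidal", "ampa"): 0.0,
    ("L2_pyramidal", "L5_basket", "ampa"): 0.0,
    ("L2_basket", "L5_pyramidal", "gabaa"): 0.0,
}


def _erp_drives() -> list:
    return [
        EvokedDriveSpec(
            "evprox_1", "proximal", 25.0, 2.5, 1,
            weights={
                ("L2_pyramidal", "ampa"): 0.02,
                ("L5_pyramidal", "ampa"): 0.02,
                ("L2_basket", "ampa"): 0.02,
                ("L5_basket", "ampa"): 0.02,
            },
        ),
        EvokedDriveSpec(
            "evdist_1", "distal", 60.0, 3.5, 1,
            weights={
                ("L2_pyramidal", "ampa"): 0.01,
                ("L2_pyramidal", "nmda"): 0.005,
                ("L5_pyramidal", "ampa"): 0.01,
                ("L5_pyramidal", "nmda"): 0.005,
                ("L2_basket", "ampa"): 0.01,
            },
        ),
        EvokedDriveSpec(
            "evprox_2", "proximal", 125.0, 7.0, 1,
            weights={
                ("L2_pyramidal", "ampa"): 0.02,
                ("L5_pyramidal", "ampa"): 0.02,
                ("L2_basket", "ampa"): 0.002,
                ("L5_basket", "ampa"): 0.002,
            },
        ),
    ]


def _rhythmic_drives(distal_delay: float, distal_weight: float,
                     duration: float) -> list:
    prox_w = {("L2_pyramidal", "ampa"): 5e-4, ("L5_pyramidal", "ampa"): 5e-4}
    dist_w = {
        ("L2_pyramidal", "ampa"): distal_weight,
        ("L5_pyramidal", "ampa"): distal_weight,
    }
    return [
        RhythmicDriveSpec(
            "prox", "proximal",
            start_time_mean=50.0, start_time_stdev=5.0, stop_time=duration,
            burst_frequency=10.0, burst_stdev=20.0, spikes_per_burst=2,
            n_bursts=10, weights=prox_w,
        ),
        RhythmicDriveSpec(
            "dist", "distal",
            start_time_mean=50.0 + distal_delay, start_time_stdev=5.0,
            stop_time=duration, burst_frequency=10.0, burst_stdev=10.0,
            spikes_per_burst=2, n_bursts=10, weights=dist_w,
        ),
    ]


def scenario_config(
    name: str, n_pyr: int = 10, n_trials: int = 1, seed: int = 0
) -> ColumnConfig:
    """Build the configuration of a packaged scenario.

    ``n_pyr`` sets the pyramidal grid edge (the full-scale column is
    10x10; fixtures use 5x5).
    """
    if name == "erp":
        # cells initialize at their resting fixed point, so no settling
        # window is needed and the early (25 ms) evoked peak stays inside
        # every analysis and optimization window
        return ColumnConfig(
            n_pyr_x=n_pyr, n_pyr_y=n_pyr, n_trials=n_trials,
            master_seed=seed, duration=170.0, dipole_scale=3000.0,
            settle_window=0.0, drives=_erp_drives(),
        )
    if name == "alpha":
        duration = 710.0
        return ColumnConfig(
            n_pyr_x=n_pyr, n_pyr_y=n_pyr, n_trials=n_trials,
            master_seed=seed, duration=duration, dipole_scale=300000.0,
            drives=_rhythmic_drives(50.0, 5e-4, duration),
        )
    if name == "beta":
        duration = 710.0
        return ColumnConfig(
            n_pyr_x=n_pyr, n_pyr_y=n_pyr, n_trials=n_trials,
            master_seed=seed, duration=duration, dipole_scale=300000.0,
            drives=_rhythmic_drives(0.0, 1e-3, duration),
        )
    if name in ("gamma_ping", "gamma_bursty"):
        bursty = name == "gamma_bursty"
        rates = (
            {"L2_pyramidal": 4.0, "L5_pyramidal": 5.0}
            if bursty
            else {"L2_pyramidal": 140.0, "L5_pyramidal": 140.0}
        )
        weights = {
            ("L2_pyramidal", "ampa"): 0.05,
            ("L5_pyramidal", "ampa"): 0.05,
        }
        if bursty:
            weights[("L2_pyramidal", "nmda")] = 0.01
            weights[("L5_pyramidal", "nmda")] = 0.01
        return ColumnConfig(
            n_pyr_x=n_pyr, n_pyr_y=n_pyr, n_trials=n_trials,
            master_seed=seed, duration=550.0,
            dipole_scale=5.0 if bursty else 1.0,
            pathway_weights=dict(_GAMMA_WEIGHTS),
            drives=[
                PoissonDriveSpec(
                    "pois", rates=rates, weights=weights, start=0.0, stop=-1.0
                )
            ],
        )
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}"
    )


def generate_fixture(
    scenario: str,
    seed: int = 0,
    directory: str | Path = ".",
    n_pyr: int = 5,
    n_trials: int = 3,
) -> tuple[Path, Path]:
    """Simulate a scenario at reduced scale and write (param, dipole) files.

    The dipole file plays the role of "recorded data"; the param file holds
    the exact generating parameters (the ground truth for recovery tests).
    Returns the two paths.
    """
    from .model import ColumnModel

    config = scenario_config(scenario, n_pyr=n_pyr, n_trials=n_trials, seed=seed)
    model = ColumnModel(config)
    result = model.simulate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    param_path = directory / f"{scenario}.param"
    dipole_path = directory / f"{scenario}_dipole.txt"
    write_param(param_path, params_from_config(config))
    write_dipole(
        dipole_path,
        result.run,
        header=(
            f"synthetic fixture: scenario={scenario} seed={seed} "
            f"grid={n_pyr}x{n_pyr} trials={n_trials} scale={config.dipole_scale}"
        ),
    )
    return param_path, dipole_path
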