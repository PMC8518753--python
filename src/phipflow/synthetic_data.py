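"""Synthetic tube-NMR concentration-time datasets.

The tube experiment acquires 19 single-scan proton spectra at 40 s cadence
(t = 0, 40, ..., 720 s) on a solution of 20 mM propargyl acetate and 5 mM
precursor catalyst sparged with hydrogen at 5 bar.  This module emulates
those data: it integrates the clamped-hydrogen kinetic network at chosen
"true" rate constants, maps the trajectory onto the four NMR observables,
and adds independent Gaussian noise representing the shot-to-shot SNR
variation of the spectra.  The intermittent bubble/settle cycle is not
simulated: dissolved hydrogen is idealised as constant at 20 mM, the same
assumption made when fitting.

The generator is the study-conditions oracle for the calibration module:
noiseless output fed back to :func:`~phipflow.calibration.fit_rate_constants`
must recover the generating constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from .calibration import (
    OBSERVABLES,
    InitialConditions,
    TimeSeriesDataset,
    predict_observables,
)
from .reaction_kinetics import CALIBRATED_RATE_CONSTANTS, build_network, integrate

__all__ = [
    "DEFAULT_SCHEDULE",
    "NoiseModel",
    "QualitativeReport",
    "generate_tube_timeseries",
    "qualitative_check",
    "write_generator_sidecar",
]

#: Acquisition schedule: 19 spectra, one every 40 s, 0-720 s.
DEFAULT_SCHEDULE: np.ndarray = np.arange(0.0, 721.0, 40.0)
DEFAULT_SCHEDULE.setflags(write=False)

#: Default additive noise, mM.  The published error bars are small but not
#: quantified; 0.5 mM visually matches their scatter.
DEFAULT_SIGMA_MM: float = 0.5


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian observation noise (same sigma for each observable
    unless a 4-vector is given) with a reproducible seed."""

    sigma_mM: float | tuple[float, ...] = DEFAULT_SIGMA_MM
    seed: int = 0

    def __post_init__(self) -> None:
        sig = np.atleast_1d(np.asarray(self.sigma_mM, dtype=float))
        if np.any(sig < 0):
            raise ValueError("noise sigma must be non-negative")

    def sigma_row(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.sigma_mM, dtype=float)),
            (len(OBSERVABLES),),
        ).astype(float)


def generate_tube_timeseries(
    true_constants: Mapping[str, float] | None = None,
    schedule: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    initial: InitialConditions | None = None,
    sigma_weights_mM: float | None = None,
) -> TimeSeriesDataset:
    """Simulate a tube dataset at the given true rate constants.

    Integrates the clamped-hydrogen network (k6 = 0, thermal hydrogen) from
    the tube initial condition, evaluates the observables on ``schedule``
    (default 19 points, 0-720 s), adds Gaussian noise, and truncates
    negative values at zero.  ``sigma_weights_mM`` overrides the standard
    deviations stored in the dataset (used for fit weighting); by default
    the noise sigma is stored, or unit weights when the noise is zero.
    """
    if true_constants is None:
        true_constants = CALIBRATED_RATE_CONSTANTS
    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must be non-empty")
    if noise is None:
        noise = NoiseModel()
    if initial is None:
        initial = InitialConditions()

    network = build_network(
        dict(true_constants),
        relaxation_enabled=False,
        hydrogen_clamp=initial.hydrogen_clamp_mM,
    )
    times = schedule if schedule[0] == 0 else np.concatenate(([0.0], schedule))
    traj = integrate(network, initial.as_state(), times)
    clean = predict_observables(traj, schedule)

    sigma_row = noise.sigma_row()
    rng = np.random.default_rng(noise.seed)
    noisy = clean + rng.standard_normal(clean.shape) * sigma_row
    noisy = np.clip(noisy, 0.0, None)

    if sigma_weights_mM is not None:
        stored_sigma = np.full_like(clean, float(sigma_weights_mM))
    elif np.all(sigma_row == 0):
        stored_sigma = None
    else:
        stored_sigma = np.broadcast_to(sigma_row, clean.shape).copy()

    return TimeSeriesDataset(
        times=schedule,
        observables=noisy,
        sigma=stored_sigma,
        initial=initial,
    )


@dataclass
class QualitativeReport:
    """Narrative sanity metrics of a default-schedule dataset."""

    propargyl_drop_40s: float       # fractional decrease of [3] at t = 40 s
    allyl_peak_time_s: float        # grid time at which [4] is maximal
    propyl_plateau_time_s: float    # first grid time with [5] >= 95% of final
    degenerate: bool = False


def qualitative_check(data: TimeSeriesDataset) -> QualitativeReport:
    """Compare a dataset with the narrative course of the tube reaction:
    propargyl acetate collapses within the first one or two acquisitions,
    allyl acetate transits through an early maximum, and propyl acetate
    plateaus late in the run."""
    obs = data.observables
    if np.allclose(obs, 0):
        return QualitativeReport(np.nan, np.nan, np.nan, degenerate=True)
    propargyl = obs[:, 0]
    allyl = obs[:, 1]
    propyl = obs[:, 2]
    p0 = propargyl[0]
    drop = np.nan if p0 == 0 else float((p0 - propargyl[1]) / p0) if propargyl.size > 1 else np.nan
    peak_t = float(data.times[np.argmax(allyl)])
    final = propyl[-1]
    if final <= 0:
        plateau_t = np.nan
    else:
        plateau_t = float(data.times[np.argmax(propyl >= 0.95 * final)])
    return QualitativeReport(drop, peak_t, plateau_t)


def write_generator_sidecar(
    path,
    true_constants: Mapping[str, float],
    noise: NoiseModel,
    initial: InitialConditions,
    schedule: np.ndarray,
) -> None:
    """YAML provenance sidecar recording how a synthetic dataset was made."""
    doc = {
        "generator": "phipflow.synthetic_data.generate_tube_timeseries",
        "true_constants_per_mM_s": {k: float(v) for k, v in true_constants.items()},
        "noise_sigma_mM": np.asarray(noise.sigma_row()).tolist(),
        "seed": int(noise.seed),
        "initial": {
            "propargyl0_mM": initial.propargyl0_mM,
            "catalyst0_mM": initial.catalyst0_mM,
            "hydrogen_clamp_mM": initial.hydrogen_clamp_mM,
        },
        "schedule_s": np.asarray(schedule, dtype=float).tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
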