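"""Rate-constant estimation from tube-NMR concentration-time data.

The tube experiment monitors four NMR observables while hydrogen is bubbled
through a solution of propargyl acetate and the rhodium precursor catalyst:
free propargyl acetate [3], allyl acetate [4], propyl acetate [5] and the
precursor catalyst [1].  Dissolved hydrogen is treated as constant (clamped)
at the solubility-derived value, 4 mM/bar x 5 bar = 20 mM.  The five
bimolecular rate constants k1..k5 are estimated by weighted nonlinear least
squares:

    minimise  sum_i ((y_model(t_i; k) - y_obs(t_i)) / sigma_i)^2

with y_model obtained by integrating the clamped-hydrogen kinetic network.
Bound catalyst complexes (3a, 4a) are *not* added to the observables: the
NMR integrals come from chemical-shift regions specific to the free
species.  Confidence intervals are linearised (Wald) intervals from the
Jacobian at the optimum, with the covariance scaled by the reduced
chi-square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .reaction_kinetics import (
    SPECIES_INDEX,
    KineticsError,
    Trajectory,
    build_network,
    integrate,
)

__all__ = [
    "OBSERVABLES",
    "CalibrationError",
    "InitialConditions",
    "TimeSeriesDataset",
    "FitResult",
    "predict_observables",
    "fit_rate_constants",
    "confidence_intervals",
    "dataset_to_csv",
    "dataset_from_csv",
    "fit_result_to_json",
]

#: Observable name -> network species measured by its NMR integral region.
OBSERVABLES: dict[str, str] = {
    "propargyl": "3",
    "allyl": "4",
    "propyl": "5",
    "catalyst": "1",
}
OBSERVABLE_NAMES: tuple[str, ...] = tuple(OBSERVABLES)
_FIT_PARAMS: tuple[str, ...] = ("k1", "k2", "k3", "k4", "k5")


class CalibrationError(RuntimeError):
    """Raised for invalid datasets or failed fits."""


@dataclass(frozen=True)
class InitialConditions:
    """Tube-experiment initial state: substrate, catalyst, hydrogen clamp (mM)."""

    propargyl0_mM: float = 20.0
    catalyst0_mM: float = 5.0
    hydrogen_clamp_mM: float = 20.0

    def as_state(self) -> dict[str, float]:
        return {
            "3": self.propargyl0_mM,
            "1": self.catalyst0_mM,
            "2": self.hydrogen_clamp_mM,
        }


@dataclass
class TimeSeriesDataset:
    """Observed concentration trajectories with per-point uncertainties.

    ``observables`` has one column per entry of :data:`OBSERVABLES`, in
    order (propargyl, allyl, propyl, catalyst).  ``sigma`` may be None
    (unit weights), a scalar, a per-observable 4-vector, or a full
    (n_times, 4) matrix; it is broadcast and stored as a matrix.
    """

    times: np.ndarray
    observables: np.ndarray
    sigma: np.ndarray | None = None
    initial: InitialConditions = field(default_factory=InitialConditions)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.observables = np.asarray(self.observables, dtype=float)
        if self.times.ndim != 1 or np.any(self.times < 0):
            raise CalibrationError("times must be a 1-D non-negative array")
        if np.any(np.diff(self.times) <= 0):
            raise CalibrationError("times must be strictly increasing")
        if self.observables.shape != (self.times.size, len(OBSERVABLES)):
            raise CalibrationError(
                f"observables must have shape ({self.times.size}, {len(OBSERVABLES)})"
            )
        if not np.all(np.isfinite(self.observables)):
            raise CalibrationError("observables must be finite")
        if self.sigma is not None:
            sig = np.broadcast_to(
                np.asarray(self.sigma, dtype=float), self.observables.shape
            ).copy()
            if np.any(sig <= 0):
                raise CalibrationError("sigma must be positive")
            self.sigma = sig

    @property
    def n_points(self) -> int:
        return self.times.size

    def weights(self) -> np.ndarray:
        """Inverse standard deviations (unit weights when sigma is absent)."""
        if self.sigma is None:
            return np.ones_like(self.observables)
        return 1.0 / self.sigma


@dataclass
class FitResult:
    """Estimated rate constants with Wald confidence intervals."""

    estimates: dict[str, float]
    conf_intervals: dict[str, tuple[float, float]]
    covariance: np.ndarray
    wrss: float
    level: float = 0.95
    n_obs: int = 0
    n_iter: int = 0
    success: bool = True
    message: str = ""
    degenerate: bool = False

    @property
    def k_array(self) -> np.ndarray:
        return np.array([self.estimates[p] for p in _FIT_PARAMS])


def predict_observables(
    trajectory: Trajectory, times: np.ndarray | None = None
) -> np.ndarray:
    """Map a trajectory to the four NMR observables at the given times.

    Free species only: propargyl <- [3], allyl <- [4], propyl <- [5],
    catalyst <- [1].  Values are linearly interpolated onto ``times``
    (default: the trajectory's own grid); times outside the trajectory span
    raise.
    """
    if times is None:
        times = trajectory.times
    times = np.asarray(times, dtype=float)
    if times.min() < trajectory.times[0] or times.max() > trajectory.times[-1]:
        raise CalibrationError(
            "observation times fall outside the trajectory span "
            f"[{trajectory.times[0]}, {trajectory.times[-1]}] s"
        )
    out = np.empty((times.size, len(OBSERVABLES)))
    for col, species in enumerate(OBSERVABLES.values()):
        out[:, col] = np.interp(times, trajectory.times, trajectory.species(species))
    return out


def _simulate_observables(
    k: np.ndarray, data: TimeSeriesDataset, rtol: float, atol: float
) -> np.ndarray:
    network = build_network(
        dict(zip(_FIT_PARAMS, k)),
        relaxation_enabled=False,
        hydrogen_clamp=data.initial.hydrogen_clamp_mM,
    )
    times = data.times
    if times[0] > 0:  # integrator grid must start at the initial condition
        times = np.concatenate(([0.0], times))
        traj = integrate(network, data.initial.as_state(), times, rtol=rtol, atol=atol)
        return predict_observables(traj, data.times)
    traj = integrate(network, data.initial.as_state(), times, rtol=rtol, atol=atol)
    return predict_observables(traj)


def fit_rate_constants(
    data: TimeSeriesDataset,
    initial_guess: Mapping[str, float] | Sequence[float] | None = None,
    bounds: tuple[float, float] = (0.0, 10.0),
    level: float = 0.95,
    max_nfev: int = 2000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Weighted nonlinear least-squares fit of k1..k5 to tube data.

    Residuals are (model - observed)/sigma with the model from
    clamped-hydrogen integration of the kinetic network.  Optimisation uses
    bounded trust-region-reflective least squares; the default guess is
    0.01 mM^-1 s^-1 for every constant with bounds [0, 10].
    """
    if data.n_points < 5:
        raise CalibrationError("need at least 5 time points to fit 5 constants")
    if np.allclose(data.observables, 0):
        raise CalibrationError("all-zero data: the fit is singular")

    if initial_guess is None:
        x0 = np.full(len(_FIT_PARAMS), 0.01)
    elif isinstance(initial_guess, Mapping):
        x0 = np.array([initial_guess[p] for p in _FIT_PARAMS], dtype=float)
    else:
        x0 = np.asarray(initial_guess, dtype=float)
    lo, hi = bounds
    if lo < 0:
        raise CalibrationError("bounds must be non-negative")
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise CalibrationError("initial guess outside bounds")

    w = data.weights()

    def residuals(k: np.ndarray) -> np.ndarray:
        pred = _simulate_observables(k, data, rtol, atol)
        return ((pred - data.observables) * w).ravel()

    # diff_step well above the integrator's rtol: the default sqrt(eps) step
    # probes ODE-solver noise and destroys the weakly identified directions
    res = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        method="trf",
        x_scale="jac",
        diff_step=1e-4,
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    wrss = float(2.0 * res.cost)
    n_obs = data.observables.size
    dof = max(n_obs - len(_FIT_PARAMS), 1)

    JTJ = res.jac.T @ res.jac
    degenerate = False
    try:
        cov = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JTJ)
        degenerate = True
    cov = cov * (wrss / dof)
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
        degenerate = True

    estimates = dict(zip(_FIT_PARAMS, map(float, res.x)))
    fit = FitResult(
        estimates=estimates,
        conf_intervals={},
        covariance=cov,
        wrss=wrss,
        level=level,
        n_obs=n_obs,
        n_iter=int(res.nfev),
        success=bool(res.success),
        message=str(res.message),
        degenerate=degenerate,
    )
    fit.conf_intervals = confidence_intervals(fit, level)
    if not res.success:
        err = CalibrationError(f"fit did not converge: {res.message}")
        err.best_so_far = fit  # type: ignore[attr-defined]
        raise err
    return fit


def confidence_intervals(
    fit: FitResult, level: float = 0.95
) -> dict[str, tuple[float, float]]:
    """Linearised Wald intervals: estimate +/- z * SE at the requested level."""
    if not 0 < level < 1:
        raise CalibrationError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    se = np.sqrt(np.clip(np.diag(fit.covariance), 0.0, None))
    if np.any(se == 0):
        fit.degenerate = True
    out: dict[str, tuple[float, float]] = {}
    for i, p in enumerate(_FIT_PARAMS):
        est = fit.estimates[p]
        out[p] = (float(est - z * se[i]), float(est + z * se[i]))
    return out


# ---------------------------------------------------------------------------
# I/O

def dataset_to_csv(data: TimeSeriesDataset, path) -> None:
    """Tidy CSV: time_s, species, concentration_mM, sigma_mM."""
    n = data.n_points
    sig = data.sigma if data.sigma is not None else np.full_like(data.observables, np.nan)
    frame = pd.DataFrame(
        {
            "time_s": np.repeat(data.times, len(OBSERVABLES)),
            "species": np.tile(OBSERVABLE_NAMES, n),
            "concentration_mM": data.observables.ravel(),
            "sigma_mM": sig.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def dataset_from_csv(path, initial: InitialConditions | None = None) -> TimeSeriesDataset:
    frame = pd.read_csv(path)
    wide = frame.pivot(index="time_s", columns="species", values="concentration_mM")
    sig = frame.pivot(index="time_s", columns="species", values="sigma_mM")
    times = wide.index.to_numpy(dtype=float)
    obs = wide[list(OBSERVABLE_NAMES)].to_numpy(dtype=float)
    sigma = sig[list(OBSERVABLE_NAMES)].to_numpy(dtype=float)
    if np.all(np.isnan(sigma)):
        sigma = None
    return TimeSeriesDataset(
        times=times,
        observables=obs,
        sigma=sigma,
        initial=initial or InitialConditions(),
    )


def fit_result_to_json(fit: FitResult, path) -> None:
    doc = {
        "estimates": fit.estimates,
        "conf_intervals": {p: list(ci) for p, ci in fit.conf_intervals.items()},
        "covariance": fit.covariance.tolist(),
        "wrss": fit.wrss,
        "level": fit.level,
        "n_obs": fit.n_obs,
        "success": fit.success,
        "degenerate": fit.degenerate,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
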