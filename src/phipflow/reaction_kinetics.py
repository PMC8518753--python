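"""Mass-action kinetic network for catalytic propargyl acetate hydrogenation.

The reaction system is the simplified homogeneous-catalysis mechanism for
hydrogenation of propargyl acetate over a rhodium (Rh(dppb)(COD)+) catalyst:
a single activation step converts the precursor catalyst to the active
species (releasing cyclooctene), after which the catalytic cycle
hydrogenates propargyl acetate to allyl acetate and, non-selectively, allyl
acetate on to propyl acetate.  Six irreversible reactions over ten species:

    R1:  1  + 2 -> 1a + 6     (catalyst activation,      k1)
    R2:  1a + 3 -> 3a          (substrate coordination,   k2)
    R3:  3a + 2 -> 1a + 4      (first hydrogenation,      k3)
    R4:  1a + 4 -> 4a          (product re-coordination,  k4)
    R5:  4a + 2 -> 1a + 5      (second hydrogenation,     k5)
    R6:  4      -> 4rx         (spin-lattice relaxation,  k6)

Species ``4`` is the *hyperpolarised* allyl acetate; ``4rx`` is its relaxed
counterpart, fed by the first-order relaxation sink R6 (k6 = 1/T1) and
never consumed.  Reactions R1-R5 are bimolecular with rate constants in
mM^-1 s^-1; R6 is unimolecular in s^-1.  Concentrations are in mM, which is
numerically identical to mol m^-3, so the same constants serve both the
well-mixed tube model and the chip transport model.

Hydrogen (species ``2``) can be *clamped*: its time derivative is forced to
zero so the network reproduces a tube experiment with continuous sparging
(constant dissolved H2), while the unclamped network is used when hydrogen
is supplied by membrane transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "DISPLAY_NAMES",
    "ROLES",
    "CATALYST_SPECIES",
    "BACKBONE_SPECIES",
    "CALIBRATED_RATE_CONSTANTS",
    "RELAXATION_RATE_CONSTANT",
    "KineticsError",
    "ReactionNetwork",
    "Trajectory",
    "build_network",
    "mass_action_rhs",
    "reaction_fluxes",
    "rhs_jacobian",
    "integrate",
    "network_to_yaml",
    "network_from_yaml",
    "trajectory_to_csv",
]

#: Canonical species ordering used by every array in the package.
SPECIES: tuple[str, ...] = ("1", "1a", "2", "3", "3a", "4", "4a", "4rx", "5", "6")
SPECIES_INDEX: dict[str, int] = {s: i for i, s in enumerate(SPECIES)}

DISPLAY_NAMES: dict[str, str] = {
    "1": "precursor catalyst Rh(dppb)(COD)+",
    "1a": "active catalyst",
    "2": "hydrogen",
    "3": "propargyl acetate",
    "3a": "catalyst-propargyl complex",
    "4": "allyl acetate (hyperpolarised)",
    "4a": "catalyst-allyl complex",
    "4rx": "allyl acetate (relaxed)",
    "5": "propyl acetate",
    "6": "cyclooctene",
}

ROLES: dict[str, str] = {
    "1": "catalyst",
    "1a": "catalyst",
    "2": "gas",
    "3": "substrate",
    "3a": "catalyst",
    "4": "product",
    "4a": "catalyst",
    "4rx": "sink",
    "5": "product",
    "6": "product",
}

#: Species groups obeying conservation laws along any closed trajectory.
CATALYST_SPECIES: tuple[str, ...] = ("1", "1a", "3a", "4a")
BACKBONE_SPECIES: tuple[str, ...] = ("3", "3a", "4", "4a", "4rx", "5")

# Reactant/product lists, one entry per reaction, in rate-constant order.
_REACTANTS: tuple[tuple[str, ...], ...] = (
    ("1", "2"),
    ("1a", "3"),
    ("3a", "2"),
    ("1a", "4"),
    ("4a", "2"),
    ("4",),
)
_PRODUCTS: tuple[tuple[str, ...], ...] = (
    ("1a", "6"),
    ("3a",),
    ("1a", "4"),
    ("4a",),
    ("1a", "5"),
    ("4rx",),
)

N_SPECIES = len(SPECIES)
N_REACTIONS = len(_REACTANTS)

#: Rate constants calibrated against tube-NMR concentration-time data
#: (k1..k5 in mM^-1 s^-1).  These are the package-wide defaults.
CALIBRATED_RATE_CONSTANTS: dict[str, float] = {
    "k1": 0.0015,
    "k2": 0.5016,
    "k3": 0.0056,
    "k4": 0.0014,
    "k5": 0.0038,
}

#: Nuclear spin-lattice relaxation rate of the hyperpolarised product,
#: k6 = 1/T1 with T1 ~ 7 s for comparable small molecules (s^-1).
RELAXATION_RATE_CONSTANT: float = 0.14


class KineticsError(RuntimeError):
    """Raised for invalid networks, states or integrator failures."""


def _build_stoichiometry() -> np.ndarray:
    S = np.zeros((N_SPECIES, N_REACTIONS), dtype=int)
    for j, (reac, prod) in enumerate(zip(_REACTANTS, _PRODUCTS)):
        for s in reac:
            S[SPECIES_INDEX[s], j] -= 1
        for s in prod:
            S[SPECIES_INDEX[s], j] += 1
    return S

#: Stoichiometry matrix, species x reactions (10 x 6).
STOICHIOMETRY: np.ndarray = _build_stoichiometry()
STOICHIOMETRY.setflags(write=False)

#: Reactant index arrays for mass-action rate laws.  Unimolecular reactions
#: repeat -1 as a sentinel meaning "no second reactant".
_REACTANT_IDX: np.ndarray = np.array(
    [
        [SPECIES_INDEX[r[0]], SPECIES_INDEX[r[1]] if len(r) > 1 else -1]
        for r in _REACTANTS
    ]
)


@dataclass(frozen=True)
class ReactionNetwork:
    """The 6-reaction, 10-species network with its rate constants.

    Parameters
    ----------
    rate_constants
        Array of (k1..k6).  k1..k5 in mM^-1 s^-1, k6 in s^-1.
    relaxation_enabled
        When False, k6 is forced to zero (thermal-hydrogen tube conditions).
    hydrogen_clamp
        When not None, the hydrogen derivative is zeroed and the hydrogen
        concentration held at this value (mM) by :func:`integrate`.
    """

    rate_constants: np.ndarray
    relaxation_enabled: bool = False
    hydrogen_clamp: float | None = None
    stoichiometry: np.ndarray = field(
        default_factory=lambda: STOICHIOMETRY, repr=False
    )

    def __post_init__(self) -> None:
        k = np.asarray(self.rate_constants, dtype=float)
        if k.shape != (N_REACTIONS,):
            raise KineticsError(f"expected {N_REACTIONS} rate constants, got {k.shape}")
        for j, kj in enumerate(k, start=1):
            if kj < 0:
                raise KineticsError(f"rate constant k{j} is negative ({kj})")
        if not self.relaxation_enabled:
            k = k.copy()
            k[5] = 0.0
        k.setflags(write=False)
        object.__setattr__(self, "rate_constants", k)

    @property
    def k(self) -> np.ndarray:
        return self.rate_constants

    @property
    def hydrogen_clamped(self) -> bool:
        return self.hydrogen_clamp is not None

    def with_updates(self, **changes) -> "ReactionNetwork":
        kw = dict(
            rate_constants=self.rate_constants,
            relaxation_enabled=self.relaxation_enabled,
            hydrogen_clamp=self.hydrogen_clamp,
        )
        kw.update(changes)
        return ReactionNetwork(**kw)


def build_network(
    rate_constants: Mapping[str, float] | Sequence[float] | None = None,
    relaxation_enabled: bool = False,
    hydrogen_clamp: float | None = None,
) -> ReactionNetwork:
    """Construct a :class:`ReactionNetwork`.

    ``rate_constants`` may be a mapping with keys ``k1``..``k6`` (missing
    keys default to the calibrated values for k1..k5 and to the relaxation
    rate for k6) or a sequence of six values.  When ``relaxation_enabled``
    is False, k6 is forced to 0.
    """
    if rate_constants is None:
        rate_constants = {}
    if isinstance(rate_constants, Mapping):
        defaults = dict(CALIBRATED_RATE_CONSTANTS, k6=RELAXATION_RATE_CONSTANT)
        unknown = set(rate_constants) - set(defaults)
        if unknown:
            raise KineticsError(f"unknown rate constants: {sorted(unknown)}")
        defaults.update(rate_constants)
        k = np.array([defaults[f"k{j}"] for j in range(1, 7)], dtype=float)
    else:
        k = np.asarray(rate_constants, dtype=float)
    return ReactionNetwork(
        rate_constants=k,
        relaxation_enabled=relaxation_enabled,
        hydrogen_clamp=hydrogen_clamp,
    )


def _check_state(conc: np.ndarray) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    if conc.shape[0] != N_SPECIES:
        raise KineticsError(
            f"state has {conc.shape[0]} species, expected {N_SPECIES}"
        )
    return conc


def reaction_fluxes(conc: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Per-reaction mass-action fluxes v_j = k_j * prod(reactant conc), mM/s.

    ``conc`` may be shape (10,) or (10, n) for vectorised evaluation over
    many states (e.g. every cell of a transport mesh).
    """
    conc = _check_state(conc)
    a = conc[_REACTANT_IDX[:, 0]]
    second = _REACTANT_IDX[:, 1]
    b = np.where(
        (second >= 0)[(slice(None),) + (None,) * (conc.ndim - 1)],
        conc[np.where(second >= 0, second, 0)],
        1.0,
    )
    k = network.k.reshape((N_REACTIONS,) + (1,) * (conc.ndim - 1))
    return k * a * b


def mass_action_rhs(conc: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Time derivative dC/dt = S v(C), mM/s; hydrogen entry zeroed if clamped."""
    v = reaction_fluxes(conc, network)
    dcdt = network.stoichiometry.astype(float) @ v
    if network.hydrogen_clamped:
        dcdt[SPECIES_INDEX["2"]] = 0.0
    return dcdt


def rhs_jacobian(conc: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Analytic Jacobian d(dC/dt)/dC.

    For shape (10,) input returns (10, 10); for (10, n) returns (10, 10, n).
    """
    conc = _check_state(conc)
    tail = conc.shape[1:]
    # dv[j, s] = d v_j / d c_s
    dv = np.zeros((N_REACTIONS, N_SPECIES) + tail)
    k = network.k
    for j in range(N_REACTIONS):
        i0, i1 = _REACTANT_IDX[j]
        if i1 >= 0:
            dv[j, i0] += k[j] * conc[i1]
            dv[j, i1] += k[j] * conc[i0]
        else:
            dv[j, i0] += k[j]
    S = network.stoichiometry.astype(float)
    jac = np.tensordot(S, dv, axes=(1, 0))
    if network.hydrogen_clamped:
        jac[SPECIES_INDEX["2"]] = 0.0
    return jac


@dataclass
class Trajectory:
    """Integrated concentration trajectory on a strictly increasing grid."""

    times: np.ndarray            # (nt,), s
    concentrations: np.ndarray   # (nt, 10), mM
    network: ReactionNetwork

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("trajectory times must be strictly increasing")
        if self.concentrations.shape != (self.times.size, N_SPECIES):
            raise KineticsError("trajectory shape mismatch")

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[:, SPECIES_INDEX[name]]


def integrate(
    network: ReactionNetwork,
    initial: Mapping[str, float] | np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the network with a stiff-capable adaptive method (LSODA).

    ``initial`` is a species->mM mapping (unlisted species start at 0) or a
    10-vector.  If the network clamps hydrogen, the hydrogen entry of the
    initial condition is overridden by the clamp value.  Negative excursions
    smaller than 1e-9 mM are clipped to zero.
    """
    from scipy.integrate import solve_ivp

    if isinstance(initial, Mapping):
        c0 = np.zeros(N_SPECIES)
        for s, v in initial.items():
            c0[SPECIES_INDEX[s]] = v
    else:
        c0 = np.asarray(initial, dtype=float).copy()
    if c0.shape != (N_SPECIES,):
        raise KineticsError("initial state must have 10 species")
    if np.any(c0 < 0):
        raise KineticsError("initial concentrations must be non-negative")
    if network.hydrogen_clamped:
        c0[SPECIES_INDEX["2"]] = network.hydrogen_clamp

    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, c: mass_action_rhs(c, network),
        (times[0], times[-1]),
        c0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
        jac=lambda t, c: rhs_jacobian(c, network),
    )
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else times[0]
        raise KineticsError(f"integration failed at t = {t_fail:.6g} s: {sol.message}")
    conc = sol.y.T.copy()
    small_neg = (conc < 0) & (conc > -1e-9)
    conc[small_neg] = 0.0
    return Trajectory(times=times, concentrations=conc, network=network)


# ---------------------------------------------------------------------------
# serialisation

def _reaction_equation(j: int) -> str:
    lhs = " + ".join(_REACTANTS[j])
    rhs = " + ".join(_PRODUCTS[j])
    return f"{lhs} -> {rhs}"


def network_to_yaml(network: ReactionNetwork) -> str:
    doc = {
        "species": list(SPECIES),
        "relaxation_enabled": bool(network.relaxation_enabled),
        "hydrogen_clamp_mM": (
            None if network.hydrogen_clamp is None else float(network.hydrogen_clamp)
        ),
        "reactions": [
            {"equation": _reaction_equation(j), "rate_constant": float(network.k[j])}
            for j in range(N_REACTIONS)
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def network_from_yaml(text: str) -> ReactionNetwork:
    doc = yaml.safe_load(text)
    if list(doc["species"]) != list(SPECIES):
        raise KineticsError("species list does not match the canonical network")
    reactions = doc["reactions"]
    if len(reactions) != N_REACTIONS:
        raise KineticsError(f"expected {N_REACTIONS} reactions")
    k = np.empty(N_REACTIONS)
    for j, entry in enumerate(reactions):
        eq = "".join(entry["equation"].split())
        expected = "".join(_reaction_equation(j).split())
        if eq != expected:
            raise KineticsError(
                f"reaction {j + 1} equation {entry['equation']!r} does not match "
                f"the canonical network ({_reaction_equation(j)})"
            )
        k[j] = float(entry["rate_constant"])
    return ReactionNetwork(
        rate_constants=k,
        relaxation_enabled=bool(doc.get("relaxation_enabled", False)),
        hydrogen_clamp=doc.get("hydrogen_clamp_mM"),
    )


def trajectory_to_csv(trajectory: Trajectory, path) -> None:
    """Write a trajectory as tidy CSV (time_s, species, concentration_mM)."""
    import pandas as pd

    rows = pd.DataFrame(
        {
            "time_s": np.repeat(trajectory.times, N_SPECIES),
            "species": np.tile(SPECIES, trajectory.times.size),
            "concentration_mM": trajectory.concentrations.ravel(),
        }
    )
    rows.to_csv(path, index=False)
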