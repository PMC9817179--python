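"""Four-state kinetic model of PFA fixation of a phase-separating protein.

A protein of interest (POI) exchanges between an in-puncta state S1 and an
out-of-puncta state S2 with binding rate ``k1`` (S2 -> S1) and dissociation
rate ``k2`` (S1 -> S2).  Adding fixative at t = 0 opens two irreversible
cross-linking channels: S1 -> S3 at rate ``k3`` (fixed in puncta) and
S2 -> S4 at rate ``k4`` (fixed out of puncta).  All rates are first order
(units 1/s) and total molarity is conserved at 1 mol/L.

The fixation artifact is the change in punctate percentage across fixation,

    delta = 100 * S3(inf) / (S3(inf) + S4(inf)) - 100 * S1(0) / (S1(0) + S2(0)),

which this module evaluates exactly: because the unfixed subsystem
(S1, S2) is linear with generator

    M = [[-(k2 + k3), k1], [k2, -(k1 + k4)]],

the time-integrals I = -M^{-1} x0 of the transient give
S3(inf) = k3 * I[0] and S4(inf) = k4 * I[1] without any long integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "RateSet",
    "StateVector",
    "TimeCourse",
    "ArtifactResult",
    "PhaseDiagram",
    "FourStateModel",
    "rates_from_equilibrium",
    "initial_state",
    "simulate_time_course",
    "final_fixed_state",
    "delta_punctate_percentage",
    "sweep_phase_diagram",
]


@dataclass(frozen=True)
class RateSet:
    """First-order rate constants of the four-state fixation model (1/s).

    k1: binding into puncta (S2 -> S1)
    k2: dissociation out of puncta (S1 -> S2)
    k3: in-puncta fixation (S1 -> S3)
    k4: out-of-puncta fixation (S2 -> S4)
    """

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
        if self.k3 + self.k4 <= 0:
            raise ValueError("k3 + k4 must be > 0: fixation never completes otherwise")

    @property
    def keq(self) -> float:
        """Equilibrium constant Keq = k1/k2 = S1_eq/S2_eq."""
        if self.k2 == 0:
            return np.inf
        return self.k1 / self.k2

    @property
    def exchange(self) -> float:
        """Total exchange rate k1 + k2 (1/s)."""
        return self.k1 + self.k2

    @property
    def fixation(self) -> float:
        """Total fixation rate k3 + k4 (1/s)."""
        return self.k3 + self.k4

    @property
    def equilibrium_start_pp(self) -> float:
        """Starting punctate percentage implied by the binding equilibrium,
        100 * k1 / (k1 + k2)."""
        if self.k1 + self.k2 <= 0:
            raise ValueError("k1 + k2 = 0: no binding equilibrium is defined")
        return 100.0 * self.k1 / (self.k1 + self.k2)


@dataclass(frozen=True)
class StateVector:
    """Concentrations (mol/L) of the four species; they must sum to 1."""

    s1: float
    s2: float
    s3: float
    s4: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < -1e-12):
            raise ValueError(f"concentrations must be >= 0, got {vals}")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"total molarity must be 1 mol/L, got {vals.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.s1, self.s2, self.s3, self.s4], dtype=float)

    @property
    def punctate_percentage(self) -> float:
        """Percentage of unfixed POI currently in puncta (0-100)."""
        tot = self.s1 + self.s2
        if tot <= 0:
            raise ZeroDivisionError("no unfixed POI remains")
        return 100.0 * self.s1 / tot


@dataclass
class TimeCourse:
    """Sampled trajectory of the four concentrations.

    times: seconds, strictly increasing, starting at 0.
    states: array of shape (n_times, 4) with columns (s1, s2, s3, s4).
    """

    times: np.ndarray
    states: np.ndarray
    rates: RateSet | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")

    @property
    def totals(self) -> np.ndarray:
        """Total molarity at every sampled time (should be 1 mol/L)."""
        return self.states.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "s1": self.states[:, 0], "s2": self.states[:, 1],
             "s3": self.states[:, 2], "s4": self.states[:, 3]}
        )


@dataclass(frozen=True)
class ArtifactResult:
    """Initial and final punctate percentages and their difference (Eq.-level)."""

    initial_punctate_percentage: float
    final_punctate_percentage: float

    @property
    def delta(self) -> float:
        """Fixation artifact in percentage points (final minus initial)."""
        return self.final_punctate_percentage - self.initial_punctate_percentage


@dataclass
class PhaseDiagram:
    """Artifact magnitude over a (starting punctate %, rate-ratio) grid.

    mode "relative-in-puncta": axis2 is k3:k4 with k3+k4 and k1+k2 held constant.
    mode "relative-overall":   axis2 is (k3+k4):(k1+k2) with k3, k4 held constant.
    """

    axis1: np.ndarray  # starting punctate percentages
    axis2: np.ndarray  # dimensionless rate ratios
    values: np.ndarray  # delta (pp), shape (len(axis2), len(axis1))
    mode: Literal["relative-in-puncta", "relative-overall"]
    constants: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        r, p = np.meshgrid(self.axis2, self.axis1, indexing="ij")
        return pd.DataFrame(
            {"start_pp": p.ravel(), "ratio": r.ravel(), "delta": self.values.ravel()}
        )


def rates_from_equilibrium(start_pp: float, total_exchange: float = 1.0) -> tuple[float, float]:
    """Split a total exchange rate into (k1, k2) realizing a target equilibrium.

    Keq = k1/k2 equals S1_eq/S2_eq, so a starting punctate percentage p maps to
    k1 = (p/100) * (k1+k2) and k2 = (1 - p/100) * (k1+k2); e.g. 0% gives
    (k1, k2) = (0, total), 100% gives (total, 0).
    """
    if not 0 <= start_pp <= 100:
        raise ValueError(f"start_pp must be in [0, 100], got {start_pp}")
    if total_exchange <= 0:
        raise ValueError(f"total_exchange must be > 0, got {total_exchange}")
    k1 = total_exchange * start_pp / 100.0
    return k1, max(total_exchange - k1, 0.0)


def initial_state(start_pp: float) -> StateVector:
    """Equilibrium pre-fixation state: S1 = p/100, S2 = 1 - S1, S3 = S4 = 0."""
    if not 0 <= start_pp <= 100:
        raise ValueError(f"start_pp must be in [0, 100], got {start_pp}")
    s1 = start_pp / 100.0
    return StateVector(s1, 1.0 - s1, 0.0, 0.0)


def _generator_matrix(rates: RateSet) -> np.ndarray:
    """Full 4x4 mass-action generator A with d(state)/dt = A @ state."""
    k1, k2, k3, k4 = rates.k1, rates.k2, rates.k3, rates.k4
    return np.array(
        [
            [-(k2 + k3), k1, 0.0, 0.0],
            [k2, -(k1 + k4), 0.0, 0.0],
            [k3, 0.0, 0.0, 0.0],
            [0.0, k4, 0.0, 0.0],
        ]
    )


def simulate_time_course(
    rates: RateSet, start_pp: float, t_end: float, n_points: int = 200
) -> TimeCourse:
    """Time evolution of (S1, S2, S3, S4) from the pre-fixation equilibrium.

    The system is linear and time invariant, so the state is propagated exactly
    by the matrix exponential of the generator over the uniform output step;
    this conserves total molarity to machine precision at any rate stiffness.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    x0 = initial_state(start_pp).as_array()
    times = np.linspace(0.0, t_end, n_points)
    dt = times[1] - times[0]
    P = expm(_generator_matrix(rates) * dt)
    states = np.empty((n_points, 4))
    states[0] = x0
    for i in range(1, n_points):
        states[i] = P @ states[i - 1]
    np.clip(states, 0.0, None, out=states)
    return TimeCourse(times, states, rates=rates)


def final_fixed_state(rates: RateSet, start_pp: float | None = None) -> tuple[float, float]:
    """Exact t = infinity solution (S3_inf, S4_inf) of the fixation model.

    Solves M @ I = -x0 for the transient time-integrals I of (S1, S2); then
    S3_inf = k3 * I[0], S4_inf = k4 * I[1].  det(M) = k1*k3 + k2*k4 + k3*k4;
    when it vanishes part of the unfixed pool has no path into a fixed state,
    which is an error unless that pool starts empty.

    ``start_pp`` defaults to the binding equilibrium implied by k1/k2 (the
    live cell is equilibrated before fixative is added); only at that start
    does k3 = k4 preserve the punctate percentage exactly.
    """
    k1, k2, k3, k4 = rates.k1, rates.k2, rates.k3, rates.k4
    if start_pp is None:
        start_pp = rates.equilibrium_start_pp
    x0 = initial_state(start_pp)
    s1_0, s2_0 = x0.s1, x0.s2
    det = k1 * k3 + k2 * k4 + k3 * k4
    if det <= 0:
        # k3 + k4 > 0 is guaranteed by RateSet, so exactly one channel is open.
        if k3 > 0:  # k4 == 0 and k1 == 0: S2 mass is stranded unless empty
            if s2_0 == 0:
                return 1.0, 0.0
            raise ValueError("fixation never completes: S2 cannot reach a fixed state")
        if s1_0 == 0:  # k3 == 0 and k2 == 0
            return 0.0, 1.0
        raise ValueError("fixation never completes: S1 cannot reach a fixed state")
    i1 = (s1_0 * (k1 + k4) + s2_0 * k1) / det
    i2 = (s2_0 * (k2 + k3) + s1_0 * k2) / det
    return k3 * i1, k4 * i2


def delta_punctate_percentage(rates: RateSet, start_pp: float | None = None) -> ArtifactResult:
    """Fixation-artifact statistic: final minus initial punctate percentage.

    ``start_pp`` defaults to the equilibrium implied by the rates.
    """
    if start_pp is None:
        start_pp = rates.equilibrium_start_pp
    s3_inf, s4_inf = final_fixed_state(rates, start_pp)
    final_pp = 100.0 * s3_inf / (s3_inf + s4_inf)
    return ArtifactResult(
        initial_punctate_percentage=float(start_pp),
        final_punctate_percentage=final_pp,
    )


DEFAULT_START_PP_GRID = np.arange(0.0, 100.0 + 1e-9, 2.0)
DEFAULT_RATIO_GRID = np.logspace(-2, 2, 41)


def sweep_phase_diagram(
    mode: Literal["relative-in-puncta", "relative-overall"],
    start_pp_grid: Sequence[float] | None = None,
    ratio_grid: Sequence[float] | None = None,
    *,
    total_fixation: float = 0.2,
    total_exchange: float = 1.0,
    k3: float = 1.0,
    k4: float = 2.0,
) -> PhaseDiagram:
    """Artifact sweep over starting punctate percentage and a rate ratio.

    mode "relative-in-puncta": vary k3:k4 at constant k3+k4 (default 0.2) and
    constant k1+k2 (default 1.0).  mode "relative-overall": vary
    (k3+k4):(k1+k2) at constant k3 (default 1.0) and k4 (default 2.0).
    """
    if mode not in ("relative-in-puncta", "relative-overall"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    pps = np.asarray(DEFAULT_START_PP_GRID if start_pp_grid is None else start_pp_grid, float)
    ratios = np.asarray(DEFAULT_RATIO_GRID if ratio_grid is None else ratio_grid, float)
    if pps.size == 0 or ratios.size == 0:
        raise ValueError("sweep grids must be non-empty")
    values = np.empty((ratios.size, pps.size))
    for i, r in enumerate(ratios):
        if mode == "relative-in-puncta":
            # r = k3:k4 with k3 + k4 = total_fixation
            k3_i = total_fixation * r / (1.0 + r)
            k4_i = total_fixation / (1.0 + r)
            exch = total_exchange
        else:
            # r = (k3+k4):(k1+k2) with k3, k4 fixed
            k3_i, k4_i = k3, k4
            exch = (k3 + k4) / r
        for j, pp in enumerate(pps):
            k1, k2 = rates_from_equilibrium(pp, exch)
            rs = RateSet(k1, k2, k3_i, k4_i)
            values[i, j] = delta_punctate_percentage(rs, pp).delta
    constants = (
        {"k3+k4": total_fixation, "k1+k2": total_exchange}
        if mode == "relative-in-puncta"
        else {"k3": k3, "k4": k4}
    )
    return PhaseDiagram(axis1=pps, axis2=ratios, values=values, mode=mode, constants=constants)


class FourStateModel:
    """Convenience wrapper binding a :class:`RateSet` to the model operations."""

    def __init__(self, rates: RateSet):
        self.rates = rates

    @classmethod
    def from_equilibrium(
        cls, start_pp: float, total_exchange: float, k3: float, k4: float
    ) -> "FourStateModel":
        k1, k2 = rates_from_equilibrium(start_pp, total_exchange)
        return cls(RateSet(k1, k2, k3, k4))

    def simulate(self, start_pp: float, t_end: float, n_points: int = 200) -> TimeCourse:
        return simulate_time_course(self.rates, start_pp, t_end, n_points)

    def final_state(self, start_pp: float) -> tuple[float, float]:
        return final_fixed_state(self.rates, start_pp)

    def artifact(self, start_pp: float) -> ArtifactResult:
        return delta_punctate_percentage(self.rates, start_pp)
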