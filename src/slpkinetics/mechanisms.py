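"""Mass-action reaction mechanisms for covalent self-labeling protein tags.

Four mechanisms are supported, all in molar / second units:

* ``model1`` — one-step irreversible bimolecular labeling
  ``P + S -> PS`` with apparent second-order rate constant ``kapp``.
  This description is valid when reactant concentrations are well below
  the dissociation constant of the non-covalent encounter complex.
* ``model2`` — reversible substrate binding followed by an irreversible
  covalent reaction, ``P + S <=> PS* -> PS`` with rate constants
  ``k1`` (association, M^-1 s^-1), ``k_minus1`` (dissociation, s^-1) and
  ``k2`` (covalent step, s^-1).
* ``aging`` — one-step labeling followed by a slow first-order conversion
  of the conjugate, ``P + S -> PSa -> PSb`` (rate ``k3``), used when the
  labeling signal shows a slow second phase.
* ``competition`` — two parallel irreversible labeling reactions sharing
  the protein, ``P + S -> PS`` and ``P + I -> PI``, used to measure rate
  constants of non-fluorescent substrates against a fluorescent probe.

Simulators return :class:`SpeciesTrajectory` objects; closed forms are used
where they exist (model 1) and a stiff-capable adaptive ODE solver
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateParametersModel1",
    "RateParametersModel2",
    "AgingParameters",
    "CompetitionParameters",
    "SpeciesTrajectory",
    "simulate_model1",
    "simulate_model2",
    "simulate_aging",
    "simulate_competition",
    "kd_from_rates",
    "kapp_from_rates",
]

#: default solver tolerances (atol applies to the state scaled by the
#: largest reactant total); k1 up to 1e8 M^-1 s^-1 at nanomolar
#: concentrations makes the model-2 system stiff.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-13


class InvalidParameterError(ValueError):
    """Raised when rate constants or concentrations violate preconditions."""


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a valid trajectory."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise InvalidParameterError(
                f"{name} must be strictly positive and finite, got {value!r}"
            )


def _require_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value < 0:
            raise InvalidParameterError(
                f"{name} must be non-negative and finite, got {value!r}"
            )


@dataclass(frozen=True)
class RateParametersModel1:
    """Apparent second-order rate constant of one-step labeling.

    Parameters
    ----------
    kapp : float
        Apparent second-order labeling rate constant, M^-1 s^-1.
    """

    kapp: float

    def __post_init__(self) -> None:
        _require_positive(kapp=self.kapp)


@dataclass(frozen=True)
class RateParametersModel2:
    """Rate constants of the two-step (bind-then-react) mechanism.

    Attributes
    ----------
    k1 : float
        Bimolecular association rate constant, M^-1 s^-1.
    k_minus1 : float
        Dissociation rate constant of the encounter complex, s^-1.
    k2 : float
        First-order covalent reaction rate constant, s^-1.
    """

    k1: float
    k_minus1: float
    k2: float

    def __post_init__(self) -> None:
        _require_positive(k1=self.k1, k_minus1=self.k_minus1, k2=self.k2)

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant ``k_minus1 / k1`` in M."""
        return self.k_minus1 / self.k1

    @property
    def kapp(self) -> float:
        """Low-concentration apparent second-order constant, M^-1 s^-1."""
        return self.k1 * self.k2 / (self.k_minus1 + self.k2)


@dataclass(frozen=True)
class AgingParameters:
    """One-step labeling followed by slow conjugate conversion PSa -> PSb."""

    kapp: float
    k3: float

    def __post_init__(self) -> None:
        _require_positive(kapp=self.kapp, k3=self.k3)


@dataclass(frozen=True)
class CompetitionParameters:
    """Rate constants of probe (S) and competitor (I) sharing one protein."""

    kapp_S: float
    kapp_I: float

    def __post_init__(self) -> None:
        _require_positive(kapp_S=self.kapp_S, kapp_I=self.kapp_I)


@dataclass(frozen=True)
class SpeciesTrajectory:
    """Time courses of all species of one mechanism.

    Attributes
    ----------
    times : ndarray
        Time points in seconds, non-decreasing.
    concentrations : dict of str -> ndarray
        Molar concentration per species per time point.  Species names are
        ``P``, ``S`` plus mechanism-specific products (``PS``, ``PS_star``,
        ``PSa``, ``PSb``, ``I``, ``PI``).
    initial_totals : dict of str -> float
        Total protein / substrate / competitor put into the reaction, molar.
    """

    times: np.ndarray
    concentrations: Dict[str, np.ndarray]
    initial_totals: Dict[str, float]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or np.any(np.diff(times) < 0):
            raise InvalidParameterError("times must be 1-D and non-decreasing")
        concs = {k: np.asarray(v, dtype=float) for k, v in self.concentrations.items()}
        object.__setattr__(self, "concentrations", concs)
        for name, c in concs.items():
            if c.shape != times.shape:
                raise InvalidParameterError(
                    f"species {name!r} has shape {c.shape}, expected {times.shape}"
                )

    def __getitem__(self, species: str) -> np.ndarray:
        return self.concentrations[species]

    @property
    def species(self) -> Tuple[str, ...]:
        return tuple(self.concentrations)

    def bound_substrate_fraction(self) -> np.ndarray:
        """Fraction of the fluorescent substrate bound or reacted."""
        s_tot = self.initial_totals["S"]
        bound = sum(
            self.concentrations[name]
            for name in ("PS_star", "PS", "PSa", "PSb")
            if name in self.concentrations
        )
        return np.asarray(bound) / s_tot


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise InvalidParameterError("times must be finite and >= 0")
    return times


def model1_product(
    kapp: float, protein_total: float, substrate_total: float, times: np.ndarray
) -> np.ndarray:
    """Closed-form product concentration of the irreversible bimolecular
    reaction ``P + S -> PS``.

    For unequal initial concentrations the integrated rate law is

    ``PS(t) = P0*S0*(exp((P0-S0)*k*t) - 1) / (P0*exp((P0-S0)*k*t) - S0)``

    and for equal concentrations ``C0`` the second-order law

    ``PS(t) = k*t*C0^2 / (1 + k*t*C0)``.

    The equal-concentration branch is taken when the relative difference is
    below 1e-9 to avoid catastrophic cancellation.
    """
    p0, s0, k = protein_total, substrate_total, kapp
    t = np.asarray(times, dtype=float)
    if abs(p0 - s0) / max(p0, s0) < 1e-9:
        c0 = 0.5 * (p0 + s0)
        return k * t * c0**2 / (1.0 + k * t * c0)
    # symmetric in P and S; keep the exponent negative so the expression is
    # overflow-safe at long times and expm1 keeps precision at short ones
    a, b = max(p0, s0), min(p0, s0)
    em1 = np.expm1(-(a - b) * k * t)
    return -a * b * em1 / ((a - b) - b * em1)


def simulate_model1(
    params: RateParametersModel1,
    protein_total: float,
    substrate_total: float,
    times: np.ndarray,
) -> SpeciesTrajectory:
    """Simulate one-step irreversible labeling ``P + S -> PS``."""
    _require_positive(protein_total=protein_total, substrate_total=substrate_total)
    times = _check_times(times)
    ps = model1_product(params.kapp, protein_total, substrate_total, times)
    return SpeciesTrajectory(
        times=times,
        concentrations={
            "P": protein_total - ps,
            "S": substrate_total - ps,
            "PS": ps,
        },
        initial_totals={"P": protein_total, "S": substrate_total},
    )


def _integrate(rhs, y0, times, rtol, atol, label, scale=1.0, jac=None):
    """Integrate with the state scaled to O(1) by the largest total, so the
    absolute tolerance means the same thing from nM to mM inputs.  An
    analytic Jacobian keeps the stiff (BDF) path of LSODA cheap when fast
    binding rates meet long time spans."""
    t = np.asarray(times, dtype=float)

    def rhs_scaled(tt, z):
        return np.asarray(rhs(tt, np.asarray(z) * scale)) / scale

    jac_scaled = None
    if jac is not None:
        # d(f/scale)/d(y/scale) = df/dy: the Jacobian is scale-invariant
        def jac_scaled(tt, z):
            return np.asarray(jac(tt, np.asarray(z) * scale))

    sol = solve_ivp(
        rhs_scaled,
        (0.0, float(t[-1]) if t[-1] > 0 else 1.0),
        np.asarray(y0, dtype=float) / scale,
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
        jac=jac_scaled,
    )
    if not sol.success:
        raise IntegrationError(f"{label}: ODE solver failed: {sol.message}")
    return np.clip(sol.y * scale, 0.0, None)


def simulate_model2(
    params: RateParametersModel2,
    protein_total: float,
    substrate_total: float,
    times: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SpeciesTrajectory:
    """Simulate two-step labeling ``P + S <=> PS* -> PS``.

    The system is reduced to two state variables (``PS*`` and ``PS``) via
    the conservation laws, which keeps mass balance exact to solver
    precision, and integrated with a stiff-capable adaptive solver.
    """
    _require_positive(protein_total=protein_total, substrate_total=substrate_total)
    times = _check_times(times)
    p0, s0 = protein_total, substrate_total
    k1, km1, k2 = params.k1, params.k_minus1, params.k2

    def rhs(_t, y):
        c, x = y  # c = [PS*], x = [PS]
        p = p0 - c - x
        s = s0 - c - x
        v_bind = k1 * p * s - km1 * c
        v_react = k2 * c
        return (v_bind - v_react, v_react)

    def jac(_t, y):
        c, x = y
        p = p0 - c - x
        s = s0 - c - x
        return [[-k1 * (p + s) - km1 - k2, -k1 * (p + s)], [k2, 0.0]]

    y = _integrate(
        rhs, [0.0, 0.0], times, rtol, atol, "model2", scale=max(p0, s0), jac=jac
    )
    c, x = y
    return SpeciesTrajectory(
        times=times,
        concentrations={
            "P": np.clip(p0 - c - x, 0.0, None),
            "S": np.clip(s0 - c - x, 0.0, None),
            "PS_star": c,
            "PS": x,
        },
        initial_totals={"P": p0, "S": s0},
    )


def simulate_aging(
    params: AgingParameters,
    protein_total: float,
    substrate_total: float,
    times: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SpeciesTrajectory:
    """Simulate labeling with a slow second phase ``P + S -> PSa -> PSb``.

    The total conjugate ``PSa + PSb`` follows the model-1 closed form; only
    the interconversion needs numeric integration.
    """
    _require_positive(protein_total=protein_total, substrate_total=substrate_total)
    times = _check_times(times)
    p0, s0 = protein_total, substrate_total
    k, k3 = params.kapp, params.k3

    def rhs(_t, y):
        a, b = y
        p = p0 - a - b
        s = s0 - a - b
        v1 = k * p * s
        v3 = k3 * a
        return (v1 - v3, v3)

    def jac(_t, y):
        a, b = y
        p = p0 - a - b
        s = s0 - a - b
        return [[-k * (p + s) - k3, -k * (p + s)], [k3, 0.0]]

    y = _integrate(
        rhs, [0.0, 0.0], times, rtol, atol, "aging", scale=max(p0, s0), jac=jac
    )
    a, b = y
    return SpeciesTrajectory(
        times=times,
        concentrations={
            "P": np.clip(p0 - a - b, 0.0, None),
            "S": np.clip(s0 - a - b, 0.0, None),
            "PSa": a,
            "PSb": b,
        },
        initial_totals={"P": p0, "S": s0},
    )


def simulate_competition(
    params: CompetitionParameters,
    protein_total: float,
    substrate_total: float,
    competitor_total: float,
    times: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SpeciesTrajectory:
    """Simulate two parallel irreversible labeling reactions sharing P.

    ``P + S -> PS`` (rate ``kapp_S``) and ``P + I -> PI`` (rate ``kapp_I``).
    With ``competitor_total == 0`` the output coincides with
    :func:`simulate_model1`.
    """
    _require_positive(protein_total=protein_total, substrate_total=substrate_total)
    _require_nonnegative(competitor_total=competitor_total)
    times = _check_times(times)
    p0, s0, i0 = protein_total, substrate_total, competitor_total
    ks, ki = params.kapp_S, params.kapp_I

    def rhs(_t, y):
        ps, pi = y
        p = p0 - ps - pi
        s = s0 - ps
        i = i0 - pi
        return (ks * p * s, ki * p * i)

    def jac(_t, y):
        ps, pi = y
        p = p0 - ps - pi
        s = s0 - ps
        i = i0 - pi
        return [[-ks * (p + s), -ks * s], [-ki * i, -ki * (i + p)]]

    y = _integrate(
        rhs,
        [0.0, 0.0],
        times,
        rtol,
        atol,
        "competition",
        scale=max(p0, s0, i0),
        jac=jac,
    )
    ps, pi = y
    return SpeciesTrajectory(
        times=times,
        concentrations={
            "P": np.clip(p0 - ps - pi, 0.0, None),
            "S": np.clip(s0 - ps, 0.0, None),
            "I": np.clip(i0 - pi, 0.0, None),
            "PS": ps,
            "PI": pi,
        },
        initial_totals={"P": p0, "S": s0, "I": i0},
    )


def kd_from_rates(params: RateParametersModel2) -> float:
    """Equilibrium dissociation constant ``Kd = k_minus1 / k1`` (M)."""
    return params.kd


def kapp_from_rates(params: RateParametersModel2) -> float:
    """Apparent second-order labeling rate constant (M^-1 s^-1).

    ``kapp = k1 * k2 / (k_minus1 + k2)`` — the low-concentration limit of
    the two-step mechanism, where the binding site is far from saturated
    and the labeling rate is linear in both reactant concentrations.
    Always bounded above by ``k1``.
    """
    return params.kapp


def rates_from_kd_kapp(kd: float, kapp: float, k2: float) -> RateParametersModel2:
    """Reconstruct (k1, k_minus1) from a dissociation constant, an apparent
    second-order constant and a fixed covalent rate.

    Inverts ``kapp = k1*k2/(k_minus1 + k2)`` with ``k_minus1 = kd*k1``:
    ``k1 = kapp*k2 / (k2 - kapp*kd)``.  Requires ``kapp*kd < k2``.
    """
    _require_positive(kd=kd, kapp=kapp, k2=k2)
    denom = k2 - kapp * kd
    if denom <= 0:
        raise InvalidParameterError(
            "inconsistent targets: kapp*kd must be smaller than k2"
        )
    k1 = kapp * k2 / denom
    return RateParametersModel2(k1=k1, k_minus1=kd * k1, k2=k2)
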