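"""Global nonlinear least-squares estimation of labeling rate constants.

A :class:`GlobalKineticModel` holds a set of FP/anisotropy traces recorded
at different reactant concentrations plus the chosen mechanism, and its
:meth:`~GlobalKineticModel.fit` minimizes the summed squared residuals over
all traces simultaneously.  Rate constants are optimized on a log10 scale
(positivity by construction, sane conditioning over the >6 decades the
rate constants span); the shared bound-state response is fitted together
with the kinetics while the free-dye baseline stays fixed, mirroring how
such data are analyzed in practice.

Uncertainties come from the Jacobian covariance by default and from a
parametric Monte Carlo bootstrap (simulate replicate datasets from the
fitted model at the residual noise level, refit each, discard the worst
few percent by RSS, report percentile intervals) on request.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from . import mechanisms as mech
from .mechanisms import (
    AgingParameters,
    CompetitionParameters,
    InvalidParameterError,
    RateParametersModel1,
    RateParametersModel2,
)
from .signals import KineticTrace, SignalResponse

__all__ = [
    "FitSpec",
    "GlobalKineticModel",
    "KineticFitResults",
    "fit_global",
    "fit_competition",
    "monte_carlo_ci",
    "estimate_dead_time",
    "loglog_correlation",
    "LogLogFit",
    "compare_models",
    "ModelComparison",
]

Z95 = 1.959963984540054

#: default log10 bounds per rate parameter (M^-1 s^-1 or s^-1)
DEFAULT_BOUNDS = {
    "kapp": (1e0, 1e10),
    "k1": (1e2, 1e11),
    "k_minus1": (1e-5, 1e6),
    "k2": (1e-4, 1e4),
    "k3": (1e-6, 1e2),
    "kapp_I": (1e-2, 1e10),
}

RATE_PARAMS = {
    "model1": ("kapp",),
    "model2": ("k1", "k_minus1", "k2"),
    "aging": ("kapp", "k3"),
    "competition": ("kapp_I",),
}


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries best-so-far params."""

    def __init__(self, message: str, best_params: Optional[dict] = None):
        super().__init__(message)
        self.best_params = best_params


@dataclass(frozen=True)
class FitSpec:
    """Recipe for a global kinetic fit.

    Attributes
    ----------
    mechanism : str
        One of ``model1``, ``model2``, ``aging``, ``competition``.
    response : SignalResponse
        Signal mapping; ``r_free`` is treated as the fixed assay baseline.
    fixed : dict
        Parameters held constant (e.g. ``kapp_S`` for competition fits, or
        a rate constant known from an orthogonal experiment).
    bounds : dict
        Per-parameter ``(lower, upper)`` overrides on the natural scale.
    initial : dict
        Per-parameter initial guesses on the natural scale.
    fit_response : bool
        Whether the shared bound-state response is a free parameter.
    fit_substrate_scale : bool
        Fit one shared scale factor on the nominal substrate concentration
        across all traces, to absorb quantification errors of the dye.
    """

    mechanism: str
    response: SignalResponse
    fixed: Dict[str, float] = field(default_factory=dict)
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    initial: Dict[str, float] = field(default_factory=dict)
    fit_response: bool = True
    fit_substrate_scale: bool = False

    def __post_init__(self) -> None:
        if self.mechanism not in RATE_PARAMS:
            raise InvalidParameterError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "competition" and "kapp_S" not in self.fixed:
            raise InvalidParameterError(
                "competition fits require a fixed kapp_S from a prior fit"
            )


def _simulate_condition(
    mechanism: str,
    params: Dict[str, float],
    protein_total: float,
    substrate_total: float,
    competitor_total: float,
    times: np.ndarray,
) -> np.ndarray:
    """Bound-substrate fraction for one concentration condition."""
    if mechanism == "model1":
        ps = mech.model1_product(params["kapp"], protein_total, substrate_total, times)
        return ps / substrate_total
    if mechanism == "model2":
        traj = mech.simulate_model2(
            RateParametersModel2(params["k1"], params["k_minus1"], params["k2"]),
            protein_total,
            substrate_total,
            times,
        )
        return traj.bound_substrate_fraction()
    if mechanism == "aging":
        traj = mech.simulate_aging(
            AgingParameters(params["kapp"], params["k3"]),
            protein_total,
            substrate_total,
            times,
        )
        return traj.bound_substrate_fraction()
    if mechanism == "competition":
        traj = mech.simulate_competition(
            CompetitionParameters(params["kapp_S"], params["kapp_I"]),
            protein_total,
            substrate_total,
            competitor_total,
            times,
        )
        return traj["PS"] / substrate_total
    raise InvalidParameterError(f"unknown mechanism {mechanism!r}")


@dataclass
class KineticFitResults:
    """Point estimates, uncertainties and diagnostics of a global fit.

    ``params`` holds the natural-scale estimates of the free rate constants
    plus, when fitted, ``r_bound`` and ``s_scale``.  ``derived`` carries
    quantities computed from the estimates (for the two-step mechanism the
    dissociation constant ``kd = k_minus1/k1`` and the apparent
    second-order constant ``kapp = k1*k2/(k_minus1+k2)``).
    """

    spec: FitSpec
    traces: List[KineticTrace]
    params: Dict[str, float]
    sd: Dict[str, float]
    ci95: Dict[str, Tuple[float, float]]
    rss: float
    n_obs: int
    residuals: List[np.ndarray]
    converged: bool
    n_starts: int
    identifiability_warning: bool
    covariance_condition: float
    seed: Optional[int] = None
    mc_samples: Optional[Dict[str, np.ndarray]] = None
    mc_n_failed: int = 0

    @property
    def derived(self) -> Dict[str, float]:
        if self.spec.mechanism != "model2":
            return {}
        p = RateParametersModel2(
            self.params["k1"], self.params["k_minus1"], self.params["k2"]
        )
        return {"kd": mech.kd_from_rates(p), "kapp": mech.kapp_from_rates(p)}

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.rss / max(self.n_obs - len(self.params), 1)))

    def predict(self, trace: KineticTrace) -> np.ndarray:
        """Model signal at the times and conditions of ``trace``."""
        return _model_signal(self.spec, self.params, trace)

    def monte_carlo_ci(
        self,
        n_iterations: int = 1000,
        discard_fraction: float = 0.05,
        seed: int = 0,
    ) -> "KineticFitResults":
        """Parametric-bootstrap uncertainties; see :func:`monte_carlo_ci`."""
        return monte_carlo_ci(
            self, n_iterations=n_iterations, discard_fraction=discard_fraction, seed=seed
        )

    def summary(self) -> str:
        lines = [
            f"Global kinetic fit — mechanism {self.spec.mechanism}",
            f"traces: {len(self.traces)}   observations: {self.n_obs}   "
            f"RSS: {self.rss:.6g}   residual SD: {self.residual_sd:.4g}",
            "-" * 72,
            f"{'parameter':>12s} {'estimate':>12s} {'sd':>10s} {'95% CI':>26s}",
        ]
        entries = dict(self.params)
        entries.update(self.derived)
        for name, value in entries.items():
            sd = self.sd.get(name, float("nan"))
            lo, hi = self.ci95.get(name, (float("nan"), float("nan")))
            lines.append(
                f"{name:>12s} {value:>12.5g} {sd:>10.3g} "
                f"[{lo:>11.5g}, {hi:>11.5g}]"
            )
        if self.mc_samples is not None:
            lines.append(
                f"uncertainties: Monte Carlo "
                f"({next(iter(self.mc_samples.values())).size} retained fits)"
            )
        else:
            lines.append("uncertainties: Jacobian covariance (normal approximation)")
        if self.identifiability_warning:
            lines.append(
                "WARNING: parameter covariance is ill-conditioned; individual "
                "rate constants may not be separable at these concentrations"
            )
        return "\n".join(lines)


def _model_signal(spec: FitSpec, params: Dict[str, float], trace: KineticTrace) -> np.ndarray:
    full = dict(spec.fixed)
    full.update(params)
    r_free = spec.response.r_free
    r_bound = full.get("r_bound", spec.response.r_bound)
    s_scale = full.get("s_scale", 1.0)
    times = trace.times + spec.response.delay
    frac = _simulate_condition(
        spec.mechanism,
        full,
        trace.protein_total,
        trace.substrate_total * s_scale,
        trace.competitor_total,
        times,
    )
    return r_free + (r_bound - r_free) * frac + spec.response.offset


class GlobalKineticModel:
    """Statsmodels-style model object for global kinetic fitting.

    Parameters
    ----------
    traces : sequence of KineticTrace
        All traces entering the global fit.  Replicates are fitted
        simultaneously; traces sharing identical conditions and time grids
        are simulated once per residual evaluation.
    spec : FitSpec, optional
        Full fit recipe; alternatively pass ``mechanism`` and ``response``
        and a spec is built with defaults.
    """

    def __init__(
        self,
        traces: Sequence[KineticTrace],
        spec: Optional[FitSpec] = None,
        mechanism: str = "model1",
        response: Optional[SignalResponse] = None,
        **spec_kwargs,
    ):
        traces = list(traces)
        if not traces:
            raise InvalidParameterError("at least one trace is required")
        types = {t.signal_type for t in traces}
        if len(types) > 1:
            raise InvalidParameterError(
                f"all traces must share a signal type, got {sorted(types)}"
            )
        if spec is None:
            if response is None:
                baseline = min(float(t.signal[0]) for t in traces)
                top = max(float(t.signal.max()) for t in traces)
                response = SignalResponse(r_free=baseline, r_bound=top)
            spec = FitSpec(mechanism=mechanism, response=response, **spec_kwargs)
        self.spec = spec
        self.traces = traces
        # group replicate traces by condition so the mechanism is simulated
        # once per condition per residual evaluation
        self._groups: Dict[tuple, List[int]] = {}
        for idx, t in enumerate(traces):
            key = (
                round(t.protein_total, 15),
                round(t.substrate_total, 15),
                round(t.competitor_total, 15),
                t.times.tobytes(),
            )
            self._groups.setdefault(key, []).append(idx)

    # -- parameter vector handling ------------------------------------

    @property
    def free_rate_names(self) -> Tuple[str, ...]:
        return tuple(
            n for n in RATE_PARAMS[self.spec.mechanism] if n not in self.spec.fixed
        )

    @property
    def param_names(self) -> Tuple[str, ...]:
        names = list(self.free_rate_names)
        if self.spec.fit_response:
            names.append("r_bound")
        if self.spec.fit_substrate_scale:
            names.append("s_scale")
        return tuple(names)

    def _bounds(self) -> Dict[str, Tuple[float, float]]:
        sig_lo = min(float(t.signal.min()) for t in self.traces)
        sig_hi = max(float(t.signal.max()) for t in self.traces)
        span = max(sig_hi - sig_lo, 1e-6)
        out = {}
        for name in self.param_names:
            if name == "r_bound":
                default = (sig_lo - 2 * span, sig_hi + 5 * span)
            elif name == "s_scale":
                default = (0.2, 5.0)
            else:
                default = DEFAULT_BOUNDS[name]
            out[name] = self.spec.bounds.get(name, default)
        return out

    def _encode(self, values: Dict[str, float]) -> np.ndarray:
        x = []
        for name in self.param_names:
            v = values[name]
            x.append(np.log10(v) if name in DEFAULT_BOUNDS else v)
        return np.asarray(x)

    def _decode(self, x: np.ndarray) -> Dict[str, float]:
        out = {}
        for name, v in zip(self.param_names, x):
            out[name] = 10.0**v if name in DEFAULT_BOUNDS else v
        return out

    # -- initial guesses ----------------------------------------------

    def _heuristic_kapp(self) -> float:
        """kapp from the half-rise time of each trace under pseudo-first-order
        excess: k_obs ~ kapp * [excess], t_half = ln2 / k_obs."""
        guesses = []
        for t in self.traces:
            sig = t.signal
            lo, hi = sig[0], sig[-1]
            if hi <= lo:
                continue
            mid = 0.5 * (lo + hi)
            above = np.nonzero(sig >= mid)[0]
            if above.size == 0 or t.times[above[0]] <= 0:
                continue
            t_half = t.times[above[0]]
            excess = max(t.protein_total, t.substrate_total)
            guesses.append(np.log(2.0) / (t_half * excess))
        return float(np.median(guesses)) if guesses else 1e4

    def _initial(self) -> Dict[str, float]:
        kapp0 = self._heuristic_kapp()
        sig_hi = max(float(t.signal.max()) for t in self.traces)
        init: Dict[str, float] = {}
        if self.spec.mechanism == "model1":
            init["kapp"] = kapp0
        elif self.spec.mechanism == "aging":
            init["kapp"] = kapp0
            init["k3"] = 5e-3
        elif self.spec.mechanism == "competition":
            init["kapp_I"] = self.spec.fixed["kapp_S"]
        else:  # model2: seed from a model-1 style prefit
            conc = max(max(t.protein_total, t.substrate_total) for t in self.traces)
            init["k1"] = 5.0 * kapp0
            init["k2"] = 1.0
            # place Kd near the lowest assayed concentration
            kd0 = min(max(t.protein_total, t.substrate_total) for t in self.traces) / 3
            init["k_minus1"] = init["k1"] * kd0
            del conc
        if self.spec.fit_response:
            init["r_bound"] = sig_hi
        if self.spec.fit_substrate_scale:
            init["s_scale"] = 1.0
        init.update(self.spec.initial)
        return {k: v for k, v in init.items() if k in self.param_names}

    # -- residuals and fitting ----------------------------------------

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        values = self._decode(x)
        full = dict(self.spec.fixed)
        full.update(values)
        r_free = self.spec.response.r_free
        r_bound = full.get("r_bound", self.spec.response.r_bound)
        s_scale = full.get("s_scale", 1.0)
        out = np.empty(sum(len(t) for t in self.traces))
        offsets = np.cumsum([0] + [len(t) for t in self.traces])
        for key, indices in self._groups.items():
            t0 = self.traces[indices[0]]
            try:
                frac = _simulate_condition(
                    self.spec.mechanism,
                    full,
                    t0.protein_total,
                    t0.substrate_total * s_scale,
                    t0.competitor_total,
                    t0.times + self.spec.response.delay,
                )
            except mech.IntegrationError:
                frac = np.full(len(t0), 1e6)  # reject this parameter region
            model = r_free + (r_bound - r_free) * frac + self.spec.response.offset
            for idx in indices:
                out[offsets[idx] : offsets[idx + 1]] = model - self.traces[idx].signal
        return out

    def fit(
        self,
        n_starts: int = 5,
        seed: Optional[int] = None,
        xtol: float = 1e-10,
        ftol: float = 1e-10,
        max_nfev: int = 400,
    ) -> KineticFitResults:
        """Run the bounded multi-start least-squares optimization.

        The first start uses heuristic initial guesses (half-rise-time kapp;
        a model-1-style seed for the two-step mechanism); remaining starts
        draw rate constants log-uniformly within bounds.  The lowest-RSS
        converged start wins, ties broken by first convergence.
        """
        bounds = self._bounds()
        lo = self._encode({n: bounds[n][0] for n in self.param_names})
        hi = self._encode({n: bounds[n][1] for n in self.param_names})
        init = self._initial()
        x0 = np.clip(self._encode(init), lo + 1e-9, hi - 1e-9)

        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(max(n_starts - 1, 0)):
            x = x0.copy()
            for i, name in enumerate(self.param_names):
                if name in DEFAULT_BOUNDS:
                    x[i] = rng.uniform(lo[i], hi[i])
            starts.append(x)

        def solve(x_start, budget):
            return optimize.least_squares(
                self._residuals,
                x_start,
                bounds=(lo, hi),
                method="trf",
                xtol=xtol,
                ftol=ftol,
                max_nfev=budget,
            )

        # the heuristic start gets the full budget; exploratory random
        # starts get a reduced one and the winner is re-polished if it was
        # an exploratory start that ran out of budget
        explore_nfev = min(150, max_nfev)
        best = None
        best_explored = False
        n_ok = 0
        for i, x_start in enumerate(starts):
            try:
                res = solve(x_start, max_nfev if i == 0 else explore_nfev)
            except Exception:
                continue
            if not np.all(np.isfinite(res.x)):
                continue
            n_ok += int(res.success)
            if best is None or res.cost < best.cost - 1e-15:
                best = res
                best_explored = i > 0
        if best is not None and best_explored:
            try:
                res = solve(best.x, max_nfev)
                if np.all(np.isfinite(res.x)) and res.cost <= best.cost:
                    n_ok += int(res.success)
                    best = res
            except Exception:
                pass
        if best is None:
            raise ConvergenceError("no optimizer start produced a solution")
        if n_ok == 0:
            raise ConvergenceError(
                "optimizer did not converge from any start",
                best_params=self._decode(best.x),
            )

        params = self._decode(best.x)
        rss = float(2 * best.cost)
        n_obs = sum(len(t) for t in self.traces)

        sd, ci, cond = self._uncertainties(best.x, params, rss, n_obs)
        resid = self._residuals(best.x)
        offsets = np.cumsum([0] + [len(t) for t in self.traces])
        per_trace = [
            resid[offsets[i] : offsets[i + 1]] for i in range(len(self.traces))
        ]
        return KineticFitResults(
            spec=self.spec,
            traces=self.traces,
            params=params,
            sd=sd,
            ci95=ci,
            rss=rss,
            n_obs=n_obs,
            residuals=per_trace,
            converged=True,
            n_starts=len(starts),
            identifiability_warning=bool(cond > 1e6),
            covariance_condition=float(cond),
            seed=seed,
        )

    def _jacobian(self, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
        """Central-difference Jacobian with a step wide enough that ODE
        solver noise does not dominate the degenerate directions (which is
        exactly what the identifiability diagnostic needs to see)."""
        cols = []
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += step
            xm[i] -= step
            cols.append((self._residuals(xp) - self._residuals(xm)) / (2 * step))
        return np.column_stack(cols)

    def _uncertainties(self, x, params, rss, n_obs):
        n_par = len(self.param_names)
        dof = max(n_obs - n_par, 1)
        s2 = rss / dof
        jac = self._jacobian(x)
        jtj = jac.T @ jac
        sd: Dict[str, float] = {}
        ci: Dict[str, Tuple[float, float]] = {}
        try:
            cov = s2 * np.linalg.pinv(jtj)
            cond = float(np.linalg.cond(cov))
            diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            cond = np.inf
            diag = np.full(n_par, np.nan)
        for i, name in enumerate(self.param_names):
            if name in DEFAULT_BOUNDS:  # delta method from log10 scale
                sd[name] = params[name] * np.log(10.0) * diag[i]
                half_width = min(Z95 * diag[i], 300.0)  # inf-safe for degenerate fits
                ci[name] = (
                    params[name] * 10.0 ** (-half_width),
                    params[name] * 10.0 ** (half_width),
                )
            else:
                sd[name] = float(diag[i])
                ci[name] = (params[name] - Z95 * diag[i], params[name] + Z95 * diag[i])
        return sd, ci, cond


def fit_global(
    spec: FitSpec,
    traces: Sequence[KineticTrace],
    n_starts: int = 5,
    seed: Optional[int] = None,
) -> KineticFitResults:
    """Functional wrapper: build a :class:`GlobalKineticModel` and fit it."""
    return GlobalKineticModel(traces, spec=spec).fit(n_starts=n_starts, seed=seed)


def fit_competition(
    spec: FitSpec,
    traces: Sequence[KineticTrace],
    n_starts: int = 5,
    seed: Optional[int] = None,
) -> KineticFitResults:
    """Estimate the competitor rate constant across a competitor series.

    ``spec`` must carry the probe's rate constant as fixed ``kapp_S``
    (measured in a prior direct-labeling fit); the global fit then leaves
    only ``kapp_I`` (plus shared response parameters) free.
    """
    if spec.mechanism != "competition":
        raise InvalidParameterError("fit_competition requires mechanism='competition'")
    return fit_global(spec, traces, n_starts=n_starts, seed=seed)


def monte_carlo_ci(
    fit: KineticFitResults,
    n_iterations: int = 1000,
    discard_fraction: float = 0.05,
    seed: int = 0,
) -> KineticFitResults:
    """Parametric-bootstrap standard deviations and 95% CIs.

    Simulates ``n_iterations`` replicate datasets from the fitted model with
    i.i.d. Gaussian noise at each trace's residual SD, refits each starting
    from the point estimate, discards the ``discard_fraction`` of refits
    with the highest RSS and reports per-parameter SDs and percentile 95%
    intervals (derived quantities included).  Deterministic given ``seed``:
    the outer seed fans out to one child seed per iteration.
    """
    if not fit.converged:
        raise ConvergenceError("Monte Carlo CIs require a converged fit")
    spec = fit.spec
    n_par = len(fit.params)
    noise_sd = [
        float(np.sqrt(np.sum(r**2) / max(r.size - n_par / len(fit.traces), 1)))
        for r in fit.residuals
    ]
    model_signals = [fit.predict(t) for t in fit.traces]

    children = np.random.SeedSequence(seed).spawn(n_iterations)
    rows: List[Dict[str, float]] = []
    rss_list: List[float] = []
    n_failed = 0
    for child in children:
        rng = np.random.default_rng(child)
        sim_traces = [
            t.with_signal(m + rng.normal(0.0, s, size=m.size))
            for t, m, s in zip(fit.traces, model_signals, noise_sd)
        ]
        model = GlobalKineticModel(sim_traces, spec=replace(spec, initial=dict(fit.params)))
        try:
            r = model.fit(n_starts=1)
        except ConvergenceError:
            n_failed += 1
            continue
        row = dict(r.params)
        row.update(r.derived)
        rows.append(row)
        rss_list.append(r.rss)

    if n_failed > 0.2 * n_iterations:
        warnings.warn(
            f"{n_failed}/{n_iterations} Monte Carlo refits failed; "
            "uncertainty estimates may be unreliable",
            RuntimeWarning,
        )
    if not rows:
        raise ConvergenceError("all Monte Carlo refits failed")

    order = np.argsort(rss_list)
    keep = order[: max(1, int(np.ceil(len(order) * (1.0 - discard_fraction))))]
    names = list(rows[0])
    samples = {
        name: np.array([rows[i][name] for i in keep]) for name in names
    }
    sd = dict(fit.sd)
    ci = dict(fit.ci95)
    for name, vals in samples.items():
        sd[name] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        ci[name] = (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
    return replace(fit, sd=sd, ci95=ci, mc_samples=samples, mc_n_failed=n_failed)


def estimate_dead_time(
    decay_trace: KineticTrace,
    expected_amplitude: Optional[float] = None,
    baseline: float = 0.0,
) -> float:
    """Instrument dead time from a pseudo-first-order calibration decay.

    Fits ``A * exp(-k * t_obs) + baseline`` to the observed trace (time
    zero at the first recorded point) and returns

        dead_time = ln(A_expected / A_fitted) / k,

    the time the reaction must already have run for the first observed
    amplitude to have decayed from the known initial amplitude
    ``expected_amplitude``.  Without an expected amplitude the offset is
    unidentifiable and an error is raised.
    """
    if expected_amplitude is None:
        raise InvalidParameterError(
            "dead time is unidentifiable without the expected initial "
            "amplitude of the calibration reaction"
        )
    t = decay_trace.times - decay_trace.times[0]
    y = decay_trace.signal - baseline
    if y[0] <= 0:
        raise InvalidParameterError("decay trace must start above baseline")

    # log-linear start, then nonlinear refinement
    pos = y > 0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    k0 = max(-slope, 1e-12)
    a0 = float(np.exp(intercept))

    def resid(theta):
        log_a, log_k = theta
        return np.exp(log_a) * np.exp(-np.exp(log_k) * t) - y

    res = optimize.least_squares(resid, x0=[np.log(a0), np.log(k0)], method="lm")
    a_fit, k_fit = np.exp(res.x)
    model = a_fit * np.exp(-k_fit * t)
    ss_res = float(np.sum((y - model) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0 and 1.0 - ss_res / ss_tot < 0.95:
        raise RuntimeError(
            "calibration trace is not well described by a single exponential "
            f"(R^2 = {1.0 - ss_res / ss_tot:.3f})"
        )
    if expected_amplitude < a_fit:
        return 0.0
    return float(np.log(expected_amplitude / a_fit) / k_fit)


@dataclass(frozen=True)
class LogLogFit:
    """OLS fit of log10(kapp) against log10(Ka) with confidence bands."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    r_squared: float
    band_log_ka: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray

    def predict_log_kapp(self, ka_values) -> np.ndarray:
        return self.intercept + self.slope * np.log10(np.asarray(ka_values, float))


def loglog_correlation(kapp_values, ka_values, n_band: int = 100) -> LogLogFit:
    """Regress log10(kapp) on log10(Ka) with pointwise 95% bands.

    Used to test whether the apparent labeling rate constant of a tag
    tracks the substrate's association constant (slope ~ 1 means labeling
    speed is affinity-controlled).
    """
    import statsmodels.api as sm

    kapp = np.asarray(kapp_values, dtype=float)
    ka = np.asarray(ka_values, dtype=float)
    if kapp.shape != ka.shape or kapp.size < 3:
        raise InvalidParameterError("need >= 3 paired values")
    if np.any(kapp <= 0) or np.any(ka <= 0):
        raise InvalidParameterError("rate and association constants must be > 0")

    x = np.log10(ka)
    y = np.log10(kapp)
    model = sm.OLS(y, sm.add_constant(x))
    fit = model.fit()
    grid = np.linspace(x.min(), x.max(), n_band)
    pred = fit.get_prediction(sm.add_constant(grid)).conf_int(alpha=0.05)
    return LogLogFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_sd=float(fit.bse[1]),
        intercept_sd=float(fit.bse[0]),
        r_squared=float(fit.rsquared),
        band_log_ka=grid,
        band_lower=pred[:, 0],
        band_upper=pred[:, 1],
    )


@dataclass(frozen=True)
class ModelComparison:
    """Comparison of two mechanisms fitted to the same traces."""

    rss_ratio: float  # RSS(model a) / RSS(model b)
    aicc_a: float
    aicc_b: float
    delta_aicc: float  # aicc_a - aicc_b; positive favors model b
    runs_test_p: float  # randomness of the simpler model's residuals
    preferred: str
    threshold: float

    def summary(self) -> str:
        return (
            f"RSS ratio (a/b): {self.rss_ratio:.4g}\n"
            f"AICc a: {self.aicc_a:.2f}   AICc b: {self.aicc_b:.2f}   "
            f"delta: {self.delta_aicc:.2f}\n"
            f"runs-test p (model a residuals): {self.runs_test_p:.3g}\n"
            f"preferred (advisory): {self.preferred}"
        )


def _aicc(rss: float, n: int, k: int) -> float:
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return float(aic)


def compare_models(
    fit_a: KineticFitResults,
    fit_b: KineticFitResults,
    threshold: float = 2.0,
) -> ModelComparison:
    """Compare two fits of the same data (e.g. one-step vs two-step).

    Reports the RSS ratio, the small-sample-corrected AIC difference and a
    Wald-Wolfowitz runs test on the first fit's concatenated residuals — a
    systematic (biphasic) misfit leaves long runs of same-sign residuals.
    The preference is advisory; ``threshold`` is the AICc difference below
    which the models are called indistinguishable.
    """
    from statsmodels.sandbox.stats.runs import runstest_1samp

    if fit_a.n_obs != fit_b.n_obs or len(fit_a.traces) != len(fit_b.traces):
        raise InvalidParameterError("fits must be on identical data")
    for ta, tb in zip(fit_a.traces, fit_b.traces):
        if not np.array_equal(ta.signal, tb.signal):
            raise InvalidParameterError("fits must be on identical data")

    n = fit_a.n_obs
    aicc_a = _aicc(fit_a.rss, n, len(fit_a.params))
    aicc_b = _aicc(fit_b.rss, n, len(fit_b.params))
    delta = aicc_a - aicc_b
    resid_a = np.concatenate(fit_a.residuals)
    if np.allclose(resid_a, resid_a[0]):
        p = 1.0
    else:
        _, p = runstest_1samp(resid_a, cutoff=0.0, correction=False)
    if abs(delta) <= threshold:
        preferred = "indistinguishable"
    else:
        preferred = "b" if delta > 0 else "a"
    return ModelComparison(
        rss_ratio=fit_a.rss / fit_b.rss if fit_b.rss > 0 else np.inf,
        aicc_a=aicc_a,
        aicc_b=aicc_b,
        delta_aicc=delta,
        runs_test_p=float(p),
        preferred=preferred,
        threshold=threshold,
    )
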