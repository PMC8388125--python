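"""Equilibrium FP analysis: binding isotherms, competition curves, free
energies.

Direct titrations of a fluorescent probe against protein are described by
the single-site hyperbola

    FP([P]) = FP_min + (FP_max - FP_min) * [P] / (Kd + [P]),

competition titrations by a four-parameter logistic (4PL) curve whose
midpoint I50 is converted to the competitor's dissociation constant by
solving the exact two-ligand, one-site mass-action equilibrium (ligand and
protein depletion fully accounted for; the classical Cheng-Prusoff
correction is provided only as a cross-check valid when depletion is
negligible).  Free energies follow from Kd via dG = R*T*ln(Kd / 1 M).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .mechanisms import InvalidParameterError

__all__ = [
    "IsothermData",
    "IsothermFit",
    "FourPLFit",
    "CompetitiveSystem",
    "isotherm_predict",
    "fit_isotherm",
    "binding_energy",
    "fourpl_predict",
    "fit_4pl",
    "competitive_equilibrium",
    "bound_probe_fraction",
    "i50_to_kd",
    "kd_to_i50",
    "cheng_prusoff_kd",
]

GAS_CONSTANT = 8.31446261815324e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE = 310.15  # K (37 degC, the assay temperature)


class FitError(RuntimeError):
    """Raised when a least-squares fit fails to converge."""


# ---------------------------------------------------------------------------
# direct binding isotherm
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsothermData:
    """A direct FP titration: probe at fixed (low) total, protein varied.

    ``anchor_point`` optionally carries the FP of the fully reacted dye as
    one extra pseudo-observation at a very high protein concentration,
    pinning the upper plateau when the titration itself does not reach it.
    """

    protein_concentrations: np.ndarray
    fp_values: np.ndarray
    probe_total: float = 50e-9
    anchor_point: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.protein_concentrations, dtype=float)
        fp = np.asarray(self.fp_values, dtype=float)
        object.__setattr__(self, "protein_concentrations", conc)
        object.__setattr__(self, "fp_values", fp)
        if conc.shape != fp.shape:
            raise InvalidParameterError("concentration/FP length mismatch")
        if np.any(conc < 0) or not np.all(np.isfinite(fp)):
            raise InvalidParameterError("concentrations >= 0 and finite FP required")
        if np.unique(conc).size < 4:
            raise InvalidParameterError("need at least 4 distinct concentrations")


@dataclass(frozen=True)
class IsothermFit:
    """Result of a single-site isotherm fit (values in M and FP units)."""

    kd: float
    fp_min: float
    fp_max: float
    sd: dict
    ci95: dict
    rss: float
    flags: tuple = ()

    def summary(self) -> str:
        lines = ["Single-site binding isotherm fit", "-" * 48]
        for name in ("kd", "fp_min", "fp_max"):
            lo, hi = self.ci95[name]
            lines.append(
                f"{name:>8s}  {getattr(self, name):.4g}  sd {self.sd[name]:.2g}"
                f"  95% CI [{lo:.4g}, {hi:.4g}]"
            )
        lines.append(f"     RSS  {self.rss:.4g}")
        for fl in self.flags:
            lines.append(f"    flag  {fl}")
        return "\n".join(lines)


def isotherm_predict(kd: float, fp_min: float, fp_max: float, protein_concentration):
    """Single-site binding hyperbola evaluated at total protein.

    ``FP(0) = fp_min``, ``FP -> fp_max`` at saturation and ``FP(Kd)`` is the
    exact midpoint of the two plateaus.
    """
    if kd <= 0:
        raise InvalidParameterError("kd must be > 0")
    p = np.asarray(protein_concentration, dtype=float)
    return fp_min + (fp_max - fp_min) * p / (kd + p)


def fit_isotherm(data: IsothermData) -> IsothermFit:
    """Fit the single-site isotherm by least squares.

    Replicate FP values at the same concentration may simply be passed as
    repeated observations; the anchor pseudo-point, when present, is
    appended with the same weight as a real observation.
    """
    conc = data.protein_concentrations
    fp = data.fp_values
    flags = []
    if data.anchor_point is not None:
        conc = np.append(conc, data.anchor_point[0])
        fp = np.append(fp, data.anchor_point[1])

    span = fp.max() - fp.min()
    if span < 1e-12 or np.std(fp) < 1e-6 * max(1.0, abs(fp.mean())):
        flags.append("flat_curve")
    fp_min0 = float(fp[np.argmin(conc)])
    fp_max0 = float(fp[np.argmax(conc)])
    if abs(fp_max0 - fp_min0) < 1e-12:
        fp_max0 = fp_min0 + max(span, 1e-3)
    # midpoint crossing as Kd start
    mid = 0.5 * (fp_min0 + fp_max0)
    pos = conc[conc > 0]
    kd0 = float(np.median(pos)) if pos.size else 1e-6
    above = conc[(fp > mid) & (conc > 0)]
    if above.size:
        kd0 = float(np.min(above))

    def resid(theta):
        log_kd, lo, hi = theta
        return isotherm_predict(10.0**log_kd, lo, hi, conc) - fp

    res = optimize.least_squares(
        resid, x0=[np.log10(kd0), fp_min0, fp_max0], method="lm", max_nfev=10000
    )
    if not res.success:
        raise FitError(f"isotherm fit failed: {res.message}")
    log_kd, fp_min_hat, fp_max_hat = res.x
    kd_hat = 10.0**log_kd
    rss = float(res.cost * 2)

    sd_log, sd_lo, sd_hi, cond = _covariance_sd(res.jac, rss, conc.size, 3)
    # delta method for Kd from log10 Kd
    sd_kd = kd_hat * np.log(10.0) * sd_log
    z = 1.959963984540054
    ci = {
        "kd": (10.0 ** (log_kd - z * sd_log), 10.0 ** (log_kd + z * sd_log)),
        "fp_min": (fp_min_hat - z * sd_lo, fp_min_hat + z * sd_lo),
        "fp_max": (fp_max_hat - z * sd_hi, fp_max_hat + z * sd_hi),
    }
    if data.anchor_point is None and kd_hat > 0.5 * conc.max():
        flags.append("upper_plateau_unidentified")
    if cond > 1e8:
        flags.append("ill_conditioned")
    return IsothermFit(
        kd=kd_hat,
        fp_min=fp_min_hat,
        fp_max=fp_max_hat,
        sd={"kd": sd_kd, "fp_min": sd_lo, "fp_max": sd_hi},
        ci95=ci,
        rss=rss,
        flags=tuple(flags),
    )


def _covariance_sd(jac, rss, n_obs, n_par):
    """Standard errors from the Jacobian at the optimum."""
    dof = max(n_obs - n_par, 1)
    s2 = rss / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:
        sds = np.full(n_par, np.nan)
        cond = np.inf
    return (*sds, cond)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------


def binding_energy(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Standard free energy of binding in kJ/mol.

    ``dG = R * T * ln(Kd)`` with Kd expressed relative to the 1 M standard
    state, so ``dG(1 M) = 0`` and tighter binding gives more negative dG.
    """
    if kd <= 0:
        raise InvalidParameterError("kd must be > 0")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be > 0 K")
    return GAS_CONSTANT * temperature * np.log(kd)


# ---------------------------------------------------------------------------
# competition: 4PL and exact equilibrium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit of a competition titration."""

    fp_min: float
    fp_max: float
    i50: float
    hill_slope: float
    sd: dict
    ci95: dict
    rss: float
    lower_fixed: bool = False
    flags: tuple = ()


def fourpl_predict(conc, fp_min: float, fp_max: float, i50: float, hill_slope: float):
    """Descending 4PL curve: upper plateau at low competitor, midpoint at
    I50, lower plateau (free dye) at saturating competitor."""
    c = np.asarray(conc, dtype=float)
    return fp_min + (fp_max - fp_min) / (1.0 + (c / i50) ** hill_slope)


def fit_4pl(
    competitor_concentrations,
    fp_values,
    fix_lower: Optional[float] = None,
) -> FourPLFit:
    """Fit a 4PL dose-response curve to a competition titration.

    ``fix_lower`` pins the lower plateau to the measured FP of the free
    dye, the standard trick when the titration cannot reach full
    displacement.
    """
    conc = np.asarray(competitor_concentrations, dtype=float)
    fp = np.asarray(fp_values, dtype=float)
    if np.unique(conc[conc > 0]).size < 5:
        raise InvalidParameterError("need at least 5 distinct positive concentrations")
    flags = []

    hi0 = float(np.mean(fp[conc <= np.quantile(conc, 0.2)]))
    lo0 = float(fix_lower) if fix_lower is not None else float(np.min(fp))
    mid = 0.5 * (hi0 + lo0)
    below = conc[(fp < mid) & (conc > 0)]
    i50_0 = float(np.min(below)) if below.size else float(np.median(conc[conc > 0]))

    if fix_lower is not None:

        def resid(theta):
            log_i50, hi, slope = theta
            return fourpl_predict(conc, fix_lower, hi, 10.0**log_i50, slope) - fp

        x0 = [np.log10(i50_0), hi0, 1.0]
        names = ["i50", "fp_max", "hill_slope"]
    else:

        def resid(theta):
            log_i50, lo, hi, slope = theta
            return fourpl_predict(conc, lo, hi, 10.0**log_i50, slope) - fp

        x0 = [np.log10(i50_0), lo0, hi0, 1.0]
        names = ["i50", "fp_min", "fp_max", "hill_slope"]

    res = optimize.least_squares(resid, x0=x0, method="lm", max_nfev=20000)
    if not res.success:
        raise FitError(f"4PL fit failed: {res.message}")
    rss = float(res.cost * 2)
    sds = _covariance_sd(res.jac, rss, conc.size, len(x0))
    cond = sds[-1]
    sds = sds[:-1]
    z = 1.959963984540054

    values = dict(zip(names, res.x))
    i50_hat = 10.0 ** values["i50"]
    sd = {}
    ci = {}
    for name, val, s in zip(names, res.x, sds):
        if name == "i50":
            sd[name] = i50_hat * np.log(10.0) * s
            ci[name] = (10.0 ** (val - z * s), 10.0 ** (val + z * s))
        else:
            sd[name] = s
            ci[name] = (val - z * s, val + z * s)
    if fix_lower is not None:
        values["fp_min"] = float(fix_lower)
        sd.setdefault("fp_min", 0.0)
        ci.setdefault("fp_min", (fix_lower, fix_lower))

    lo_hat, hi_hat = values["fp_min"], values["fp_max"]
    if not (conc.min() < i50_hat < conc.max()):
        flags.append("i50_outside_range")
    if abs(hi_hat - lo_hat) < 3 * np.std(fp - np.mean(fp)) / np.sqrt(max(conc.size, 1)):
        flags.append("no_transition")
    return FourPLFit(
        fp_min=lo_hat,
        fp_max=hi_hat,
        i50=i50_hat,
        hill_slope=values["hill_slope"],
        sd=sd,
        ci95=ci,
        rss=rss,
        lower_fixed=fix_lower is not None,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class CompetitiveSystem:
    """Two ligands (fluorescent probe S, competitor I) binding one site."""

    protein_total: float
    probe_total: float
    probe_kd: float
    competitor_total: float
    competitor_kd: float

    def __post_init__(self) -> None:
        for name in ("protein_total", "probe_total", "probe_kd", "competitor_kd"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.competitor_total < 0:
            raise InvalidParameterError("competitor_total must be >= 0")


def competitive_equilibrium(system: CompetitiveSystem) -> dict:
    """Solve the exact two-ligand one-site equilibrium.

    Free protein ``Pf`` is the root of the conservation equation

        Pf + S_tot*Pf/(Kd_S + Pf) + I_tot*Pf/(Kd_I + Pf) = P_tot,

    which is strictly increasing in ``Pf`` and therefore bracketed on
    ``[0, P_tot]``; all depletion effects are exact.  Returns free and
    bound concentrations and the bound fractions of both ligands.
    """
    p_tot, s_tot = system.protein_total, system.probe_total
    i_tot = system.competitor_total
    kd_s, kd_i = system.probe_kd, system.competitor_kd

    def balance(pf):
        return pf + s_tot * pf / (kd_s + pf) + i_tot * pf / (kd_i + pf) - p_tot

    pf = optimize.brentq(balance, 0.0, p_tot, xtol=1e-30, rtol=1e-14, maxiter=300)
    ps = s_tot * pf / (kd_s + pf)
    pi = i_tot * pf / (kd_i + pf)
    return {
        "free_protein": pf,
        "probe_bound": ps,
        "competitor_bound": pi,
        "probe_bound_fraction": ps / s_tot,
        "competitor_bound_fraction": pi / i_tot if i_tot > 0 else 0.0,
    }


def bound_probe_fraction(
    protein_total: float,
    probe_total: float,
    probe_kd: float,
    competitor_total: float = 0.0,
    competitor_kd: float = 1.0,
) -> float:
    """Bound fraction of the probe under the exact competitive equilibrium."""
    system = CompetitiveSystem(
        protein_total=protein_total,
        probe_total=probe_total,
        probe_kd=probe_kd,
        competitor_total=competitor_total,
        competitor_kd=competitor_kd,
    )
    return competitive_equilibrium(system)["probe_bound_fraction"]


def kd_to_i50(
    competitor_kd: float,
    protein_total: float,
    probe_total: float,
    probe_kd: float,
) -> float:
    """Competitor concentration that halves the bound probe fraction."""
    f0 = bound_probe_fraction(protein_total, probe_total, probe_kd)

    def half(log_i):
        f = bound_probe_fraction(
            protein_total, probe_total, probe_kd, 10.0**log_i, competitor_kd
        )
        return f - 0.5 * f0

    return 10.0 ** optimize.brentq(half, -15.0, 3.0, xtol=1e-12, maxiter=300)


def i50_to_kd(
    i50: float,
    protein_total: float,
    probe_total: float,
    probe_kd: float,
) -> float:
    """Convert a measured I50 to the competitor's dissociation constant.

    Finds the ``Kd_I`` for which the exact two-ligand equilibrium predicts
    a 50% reduction of the bound probe fraction at competitor
    concentration ``i50``.  Inverse of :func:`kd_to_i50` by construction.
    """
    if i50 <= 0:
        raise InvalidParameterError("i50 must be > 0")
    f0 = bound_probe_fraction(protein_total, probe_total, probe_kd)

    def excess(log_kd):
        f = bound_probe_fraction(
            protein_total, probe_total, probe_kd, i50, 10.0**log_kd
        )
        return f - 0.5 * f0

    lo, hi = -15.0, 6.0
    if excess(lo) * excess(hi) > 0:
        raise InvalidParameterError(
            "i50 is inconsistent with any positive competitor Kd at these "
            "assay concentrations (likely below the stoichiometric "
            "depletion bound: even an infinitely tight competitor cannot "
            "halve the probe signal at this concentration)"
        )
    return 10.0 ** optimize.brentq(excess, lo, hi, xtol=1e-12, maxiter=300)


def cheng_prusoff_kd(i50: float, probe_total: float, probe_kd: float) -> float:
    """Classical Cheng-Prusoff correction ``Ki = I50 / (1 + [S]/Kd_S)``.

    Valid only when protein and ligand depletion are negligible; provided
    as a cross-check for the exact inversion of :func:`i50_to_kd`.
    """
    return i50 / (1.0 + probe_total / probe_kd)
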