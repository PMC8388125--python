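"""Fluorescence polarization / anisotropy observables.

FP is defined from the polarized emission intensities as

    FP = (I_par - G * I_perp) / (I_par + G * I_perp)

with the instrument grating factor ``G`` correcting for the different
sensitivity of the two detection channels.  Anisotropy uses a 2x weight on
the perpendicular channel,

    r = (I_par - G * I_perp) / (I_par + 2 * G * I_perp),

and the two statistics interconvert exactly via ``r = 2 FP / (3 - FP)``.
Both are dimensionless; millipolarization (mP) is 1000x FP and is handled
on I/O only — all internal arithmetic is in fractional units.

Species trajectories are projected onto an FP/anisotropy trace by
mole-fraction weighting of the fluorescent substrate's states: the
non-covalent complex and the covalent conjugate are assumed to contribute
equally (their rotational correlation is dominated by the protein), and
fluorescence intensity changes on binding are assumed negligible so no
intensity weighting is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional

import numpy as np

from .mechanisms import InvalidParameterError, SpeciesTrajectory

__all__ = [
    "SignalResponse",
    "KineticTrace",
    "fp_from_intensities",
    "fp_to_anisotropy",
    "anisotropy_to_fp",
    "fp_anisotropy_convert",
    "project_signal",
]

#: species that carry the fluorescent substrate bound to protein
BOUND_SPECIES = ("PS_star", "PS", "PSa", "PSb")


class UndefinedSignalError(ValueError):
    """Raised when an FP value cannot be computed (e.g. zero intensity)."""


def fp_from_intensities(
    i_parallel: float, i_perpendicular: float, grating_factor: float = 1.0
) -> float:
    """Fluorescence polarization from polarized emission intensities."""
    i_par = np.asarray(i_parallel, dtype=float)
    i_perp = np.asarray(i_perpendicular, dtype=float)
    if np.any(i_par < 0) or np.any(i_perp < 0):
        raise UndefinedSignalError("intensities must be non-negative")
    denom = i_par + grating_factor * i_perp
    if np.any(denom == 0):
        raise UndefinedSignalError("both intensities are zero: FP undefined")
    return (i_par - grating_factor * i_perp) / denom


def fp_to_anisotropy(fp):
    """Convert polarization to anisotropy, ``r = 2 FP / (3 - FP)``."""
    fp = np.asarray(fp, dtype=float)
    if np.any(np.abs(fp) > 1):
        raise InvalidParameterError("FP must lie in [-1, 1]")
    return 2.0 * fp / (3.0 - fp)


def anisotropy_to_fp(r):
    """Convert anisotropy to polarization, ``FP = 3 r / (2 + r)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < -0.5) or np.any(r > 1.0):
        raise InvalidParameterError("anisotropy must lie in [-0.5, 1]")
    return 3.0 * r / (2.0 + r)


def fp_anisotropy_convert(value, direction: str):
    """Convert between FP and anisotropy.

    ``direction`` is ``"fp_to_anisotropy"`` or ``"anisotropy_to_fp"``; the
    round trip is the identity to floating-point precision.
    """
    if direction == "fp_to_anisotropy":
        return fp_to_anisotropy(value)
    if direction == "anisotropy_to_fp":
        return anisotropy_to_fp(value)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class SignalResponse:
    """Map from species concentrations to an FP or anisotropy signal.

    Attributes
    ----------
    r_free : float
        Signal of the unbound fluorescent substrate (the assay baseline).
    r_bound : float
        Signal shared by the protein-bound states of the substrate; the
        encounter complex and the covalent conjugate are not distinguished.
    offset : float
        Additive baseline correction, default 0.
    dead_time : float
        Instrument dead time in seconds; simulated points earlier than this
        are unobservable and dropped, not interpolated.
    delay : float
        Fixed mixing delay in seconds added to the recorded clock.
    species_weights : dict, optional
        Per-species relative intensity weights (default 1 for fluorescent
        species).  Provided for assays where binding changes brightness;
        competitor species I and PI are non-fluorescent and always weight 0.
    """

    r_free: float
    r_bound: float
    offset: float = 0.0
    dead_time: float = 0.0
    delay: float = 0.0
    species_weights: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.dead_time < 0 or self.delay < 0:
            raise InvalidParameterError("dead_time and delay must be >= 0")
        if not (np.isfinite(self.r_free) and np.isfinite(self.r_bound)):
            raise InvalidParameterError("responses must be finite")

    def with_(self, **kwargs) -> "SignalResponse":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class KineticTrace:
    """One recorded FP or anisotropy time series with its metadata."""

    times: np.ndarray
    signal: np.ndarray
    protein_total: float
    substrate_total: float
    competitor_total: float = 0.0
    signal_type: str = "fp"
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "signal", signal)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if signal.shape != times.shape or not np.all(np.isfinite(signal)):
            raise InvalidParameterError("signal must be finite, same length as times")
        if self.signal_type not in ("fp", "anisotropy"):
            raise InvalidParameterError("signal_type must be 'fp' or 'anisotropy'")
        if min(self.protein_total, self.substrate_total, self.competitor_total) < 0:
            raise InvalidParameterError("concentrations must be >= 0")

    def __len__(self) -> int:
        return self.times.size

    def with_signal(self, signal: np.ndarray, **meta) -> "KineticTrace":
        kwargs = dict(
            times=self.times,
            signal=signal,
            protein_total=self.protein_total,
            substrate_total=self.substrate_total,
            competitor_total=self.competitor_total,
            signal_type=self.signal_type,
            replicate_id=self.replicate_id,
        )
        kwargs.update(meta)
        return KineticTrace(**kwargs)


def project_signal(
    trajectory: SpeciesTrajectory,
    response: SignalResponse,
    substrate_total: Optional[float] = None,
    signal_type: str = "anisotropy",
    replicate_id: str = "r1",
) -> KineticTrace:
    """Project a species trajectory onto an FP/anisotropy trace.

    The signal is the mole-fraction-weighted mixture of the free and bound
    substrate responses,

        signal(t) = r_free * [S]/S_tot + r_bound * (sum of bound)/S_tot
                    + offset,

    with the non-fluorescent competitor species contributing nothing.
    Points earlier than ``response.dead_time`` are dropped and the time
    axis is shifted by ``response.delay``.
    """
    if substrate_total is None:
        substrate_total = trajectory.initial_totals["S"]
    if substrate_total <= 0:
        raise InvalidParameterError("substrate_total must be > 0")

    weights = response.species_weights or {}
    free = trajectory["S"] * weights.get("S", 1.0)
    bound = np.zeros_like(free)
    for name in BOUND_SPECIES:
        if name in trajectory.concentrations:
            bound = bound + trajectory[name] * weights.get(name, 1.0)
    signal = (response.r_free * free + response.r_bound * bound) / substrate_total
    signal = signal + response.offset

    keep = trajectory.times >= response.dead_time
    return KineticTrace(
        times=trajectory.times[keep] + response.delay,
        signal=signal[keep],
        protein_total=trajectory.initial_totals["P"],
        substrate_total=substrate_total,
        competitor_total=trajectory.initial_totals.get("I", 0.0),
        signal_type=signal_type,
        replicate_id=replicate_id,
    )
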