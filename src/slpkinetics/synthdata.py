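"""Synthetic FP/anisotropy datasets with the statistical structure of
real self-labeling-tag experiments.

Three assay families are emulated:

* stopped-flow anisotropy kinetics — protein and substrate mixed 1:1 at
  sub-micromolar concentrations, log-spaced sampling to resolve the fast
  binding phase, instrument dead time truncating the first milliseconds;
* plate-reader FP kinetics and competition kinetics — fixed nanomolar
  substrate against a protein (or competitor) series, linear sampling;
* equilibrium FP titrations — direct isotherms and competition curves.

All generators are pure functions of (design, seed): noise is additive
i.i.d. Gaussian on the signal only (never on times or concentrations), and
every dataset is emitted together with the generating truth so recovery
experiments can score themselves.  Real instrument artifacts other than
dead time, mixing delay and Gaussian noise (drift, photobleaching, mixing
transients) are deliberately not modeled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import mechanisms as mech
from .equilibrium import CompetitiveSystem, IsothermData, competitive_equilibrium, isotherm_predict
from .mechanisms import (
    AgingParameters,
    CompetitionParameters,
    InvalidParameterError,
    RateParametersModel1,
    RateParametersModel2,
)
from .signals import KineticTrace, SignalResponse, project_signal

__all__ = [
    "ExperimentDesign",
    "generate_kinetic_dataset",
    "generate_isotherm_dataset",
    "generate_competition_dataset",
    "write_fixture_bundle",
    "read_fixture_bundle",
    "stopped_flow_design",
    "plate_reader_design",
    "competition_design",
]

SCHEMA_VERSION = 1

#: default additive noise, in signal units: anisotropy SD for stopped flow,
#: FP SD (fraction; 5 mP) for plate-reader kinetics
NOISE_SD_STOPPED_FLOW = 0.002
NOISE_SD_PLATE_READER = 0.005


@dataclass(frozen=True)
class ExperimentDesign:
    """Full recipe for one synthetic kinetic dataset.

    ``conditions`` is the list of (protein_total, substrate_total,
    competitor_total) tuples actually mixed; the time grid is shared by all
    conditions.  ``dead_time`` removes unobservable early points and
    ``delay`` shifts the recorded clock, as in the matching instruments.
    """

    mechanism: str
    true_params: Dict[str, float]
    conditions: Tuple[Tuple[float, float, float], ...]
    t_end: float
    n_points: int = 100
    t_start: Optional[float] = None
    spacing: str = "linear"  # or "log"
    replicates: int = 3
    noise_sd: float = NOISE_SD_PLATE_READER
    response: SignalResponse = field(
        default_factory=lambda: SignalResponse(r_free=0.05, r_bound=0.25)
    )
    signal_type: str = "fp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in ("model1", "model2", "aging", "competition"):
            raise InvalidParameterError(f"unknown mechanism {self.mechanism!r}")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.replicates < 1 or self.n_points < 2:
            raise InvalidParameterError("need >= 1 replicate and >= 2 time points")
        conds = tuple(tuple(float(x) for x in c) for c in self.conditions)
        object.__setattr__(self, "conditions", conds)
        for p0, s0, i0 in conds:
            if p0 <= 0 or s0 <= 0 or i0 < 0:
                raise InvalidParameterError("invalid condition concentrations")
            if self.mechanism == "competition" and len(conds) < 2 and i0 == 0:
                raise InvalidParameterError(
                    "competition designs need a competitor grid"
                )
        if self.mechanism != "competition" and any(i0 > 0 for _, _, i0 in conds):
            raise InvalidParameterError(
                "non-zero competitor requires mechanism='competition'"
            )

    def time_grid(self) -> np.ndarray:
        if self.spacing == "log":
            start = self.t_start if self.t_start else max(self.t_end * 1e-5, 1e-6)
            return np.geomspace(start, self.t_end, self.n_points)
        start = self.t_start if self.t_start is not None else 0.0
        return np.linspace(start, self.t_end, self.n_points)


def _true_params(design: ExperimentDesign):
    p = design.true_params
    if design.mechanism == "model1":
        return RateParametersModel1(p["kapp"])
    if design.mechanism == "model2":
        return RateParametersModel2(p["k1"], p["k_minus1"], p["k2"])
    if design.mechanism == "aging":
        return AgingParameters(p["kapp"], p["k3"])
    return CompetitionParameters(p["kapp_S"], p["kapp_I"])


def generate_kinetic_dataset(
    design: ExperimentDesign,
) -> Tuple[List[KineticTrace], Dict]:
    """Simulate, project and noise-corrupt one kinetic dataset.

    Returns the replicate traces and a truth record holding the design and
    generating parameters.  ``noise_sd == 0`` yields the exact noiseless
    projection; identical seeds yield identical datasets.
    """
    params = _true_params(design)
    times = design.time_grid()
    rng = np.random.default_rng(design.seed)
    traces: List[KineticTrace] = []
    for p0, s0, i0 in design.conditions:
        if design.mechanism == "model1":
            traj = mech.simulate_model1(params, p0, s0, times)
        elif design.mechanism == "model2":
            traj = mech.simulate_model2(params, p0, s0, times)
        elif design.mechanism == "aging":
            traj = mech.simulate_aging(params, p0, s0, times)
        else:
            traj = mech.simulate_competition(params, p0, s0, i0, times)
        clean = project_signal(
            traj, design.response, s0, signal_type=design.signal_type
        )
        for rep in range(design.replicates):
            noise = rng.normal(0.0, design.noise_sd, size=len(clean)) if design.noise_sd else 0.0
            traces.append(clean.with_signal(clean.signal + noise, replicate_id=f"r{rep + 1}"))
    truth = {
        "mechanism": design.mechanism,
        "true_params": dict(design.true_params),
        "design": _design_to_dict(design),
    }
    return traces, truth


def generate_isotherm_dataset(
    kd: float,
    fp_min: float,
    fp_max: float,
    probe_total: float,
    protein_concentrations: Sequence[float],
    noise_sd: float = 0.002,
    replicates: int = 3,
    seed: int = 0,
    anchor_concentration: Optional[float] = None,
) -> Tuple[IsothermData, Dict]:
    """Synthetic direct FP titration from the single-site hyperbola.

    When ``anchor_concentration`` is given, the returned data carry an
    exact anchor pseudo-point at that concentration with the true
    saturating FP (the fully reacted dye's value), as used to pin the
    upper plateau of weak-binding titrations.
    """
    conc = np.asarray(list(protein_concentrations), dtype=float)
    if conc.size == 0:
        raise InvalidParameterError("empty concentration grid")
    rng = np.random.default_rng(seed)
    conc_rep = np.tile(conc, replicates)
    clean = isotherm_predict(kd, fp_min, fp_max, conc_rep)
    fp = clean + rng.normal(0.0, noise_sd, size=clean.size) if noise_sd else clean
    anchor = None
    if anchor_concentration is not None:
        anchor = (float(anchor_concentration), float(fp_max))
    data = IsothermData(
        protein_concentrations=conc_rep,
        fp_values=fp,
        probe_total=probe_total,
        anchor_point=anchor,
    )
    truth = {
        "kd": kd,
        "fp_min": fp_min,
        "fp_max": fp_max,
        "probe_total": probe_total,
        "noise_sd": noise_sd,
        "replicates": replicates,
        "seed": seed,
    }
    return data, truth


def generate_competition_dataset(
    protein_total: float,
    probe_total: float,
    probe_kd: float,
    competitor_kd: float,
    competitor_concentrations: Sequence[float],
    fp_free: float,
    fp_bound: float,
    noise_sd: float = 0.003,
    replicates: int = 3,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict]:
    """Synthetic FP competition titration from the exact two-ligand
    equilibrium.

    The FP at each competitor concentration interpolates between the free
    and bound probe signals by the exact bound-probe fraction; a warning
    flag is recorded in the truth when the grid does not span the
    transition around the expected I50.
    """
    conc = np.asarray(list(competitor_concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    frac = np.array(
        [
            competitive_equilibrium(
                CompetitiveSystem(
                    protein_total=protein_total,
                    probe_total=probe_total,
                    probe_kd=probe_kd,
                    competitor_total=c,
                    competitor_kd=competitor_kd,
                )
            )["probe_bound_fraction"]
            for c in conc
        ]
    )
    clean = fp_free + (fp_bound - fp_free) * frac
    rows = []
    for rep in range(replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=clean.size) if noise_sd else clean
        for c, v in zip(conc, noisy):
            rows.append({"concentration_M": c, "fp": v, "replicate": rep + 1})
    df = pd.DataFrame(rows)
    frac0 = competitive_equilibrium(
        CompetitiveSystem(
            protein_total=protein_total,
            probe_total=probe_total,
            probe_kd=probe_kd,
            competitor_total=0.0,
            competitor_kd=competitor_kd,
        )
    )["probe_bound_fraction"]
    spans = bool(frac.min() < 0.5 * frac0 < frac.max())
    truth = {
        "protein_total": protein_total,
        "probe_total": probe_total,
        "probe_kd": probe_kd,
        "competitor_kd": competitor_kd,
        "fp_free": fp_free,
        "fp_bound": fp_bound,
        "noise_sd": noise_sd,
        "replicates": replicates,
        "seed": seed,
        "grid_spans_transition": spans,
    }
    return df, truth


# ---------------------------------------------------------------------------
# ready-made designs matching the standard assay layouts
# ---------------------------------------------------------------------------


def stopped_flow_design(
    true_params: Dict[str, float],
    concentrations: Sequence[float] = (0.125e-6, 0.25e-6, 0.5e-6, 1e-6),
    t_end: float = 10.0,
    n_points: int = 200,
    dead_time: float = 2e-3,
    noise_sd: float = NOISE_SD_STOPPED_FLOW,
    r_free: float = 0.05,
    r_bound: float = 0.20,
    replicates: int = 3,
    seed: int = 0,
) -> ExperimentDesign:
    """1:1 protein:substrate stopped-flow anisotropy design (two-step
    mechanism), log-spaced sampling from just below the dead time."""
    return ExperimentDesign(
        mechanism="model2",
        true_params=dict(true_params),
        conditions=tuple((c, c, 0.0) for c in concentrations),
        t_end=t_end,
        t_start=max(dead_time / 2, 1e-5),
        n_points=n_points,
        spacing="log",
        replicates=replicates,
        noise_sd=noise_sd,
        response=SignalResponse(r_free=r_free, r_bound=r_bound, dead_time=dead_time),
        signal_type="anisotropy",
        seed=seed,
    )


def plate_reader_design(
    true_params: Dict[str, float],
    protein_concentrations: Sequence[float],
    substrate_total: float = 50e-9,
    t_end: float = 900.0,
    n_points: int = 61,
    noise_sd: float = NOISE_SD_PLATE_READER,
    fp_free: float = 0.05,
    fp_bound: float = 0.25,
    mechanism: str = "model1",
    replicates: int = 3,
    seed: int = 0,
) -> ExperimentDesign:
    """Plate-reader FP kinetics: fixed substrate, protein series, linear
    sampling."""
    return ExperimentDesign(
        mechanism=mechanism,
        true_params=dict(true_params),
        conditions=tuple((p, substrate_total, 0.0) for p in protein_concentrations),
        t_end=t_end,
        n_points=n_points,
        spacing="linear",
        replicates=replicates,
        noise_sd=noise_sd,
        response=SignalResponse(r_free=fp_free, r_bound=fp_bound),
        signal_type="fp",
        seed=seed,
    )


def competition_design(
    true_params: Dict[str, float],
    competitor_concentrations: Sequence[float],
    protein_total: float = 200e-9,
    substrate_total: float = 50e-9,
    t_end: float = 1800.0,
    n_points: int = 61,
    noise_sd: float = NOISE_SD_PLATE_READER,
    fp_free: float = 0.05,
    fp_bound: float = 0.25,
    replicates: int = 3,
    seed: int = 0,
) -> ExperimentDesign:
    """Competitive plate-reader kinetics: fixed probe and protein, varying
    non-fluorescent competitor (zero-competitor control included)."""
    return ExperimentDesign(
        mechanism="competition",
        true_params=dict(true_params),
        conditions=tuple(
            (protein_total, substrate_total, i) for i in competitor_concentrations
        ),
        t_end=t_end,
        n_points=n_points,
        spacing="linear",
        replicates=replicates,
        noise_sd=noise_sd,
        response=SignalResponse(r_free=fp_free, r_bound=fp_bound),
        signal_type="fp",
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------


def _design_to_dict(design: ExperimentDesign) -> Dict:
    d = asdict(design)
    d["response"] = asdict(design.response)
    return d


def _design_from_dict(d: Dict) -> ExperimentDesign:
    d = dict(d)
    resp = dict(d.pop("response"))
    resp.pop("species_weights", None)
    d["conditions"] = tuple(tuple(c) for c in d["conditions"])
    return ExperimentDesign(response=SignalResponse(**resp), **d)


def write_fixture_bundle(
    traces: Sequence[KineticTrace],
    truth: Dict,
    directory,
    unit: str = "fraction",
    temperature_K: float = 310.15,
) -> Path:
    """Write a kinetic dataset as a plain-text fixture bundle.

    Layout: ``manifest.json`` (schema version, trace index, signal unit),
    ``truth.json`` (generating parameters and design) and one
    ``traces/trace_NNN.csv`` (columns ``time_s``, ``signal``) plus sidecar
    ``trace_NNN.json`` with the concentration and instrument metadata per
    trace.  ``unit='mP'`` writes the signal as millipolarization (1000x).
    """
    if unit not in ("fraction", "mP"):
        raise InvalidParameterError("unit must be 'fraction' or 'mP'")
    directory = Path(directory)
    (directory / "traces").mkdir(parents=True, exist_ok=True)
    index = []
    for i, trace in enumerate(traces):
        stem = f"trace_{i:03d}"
        scale = 1000.0 if unit == "mP" else 1.0
        pd.DataFrame(
            {"time_s": trace.times, "signal": trace.signal * scale}
        ).to_csv(directory / "traces" / f"{stem}.csv", index=False)
        resp = (truth.get("design") or {}).get("response") or {}
        sidecar = {
            "protein_total_M": trace.protein_total,
            "substrate_total_M": trace.substrate_total,
            "competitor_total_M": trace.competitor_total,
            "signal_type": trace.signal_type,
            "temperature_K": temperature_K,
            "dead_time_s": resp.get("dead_time", 0.0),
            "delay_s": resp.get("delay", 0.0),
            "replicate_id": trace.replicate_id,
        }
        (directory / "traces" / f"{stem}.json").write_text(
            json.dumps(sidecar, indent=1)
        )
        index.append(stem)
    (directory / "truth.json").write_text(json.dumps(truth, indent=1, default=float))
    manifest = {"schema_version": SCHEMA_VERSION, "traces": index, "signal_unit": unit}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


class BundleError(ValueError):
    """Raised when a fixture bundle is malformed; names the offending field."""


def read_fixture_bundle(directory) -> Tuple[List[KineticTrace], Dict, str]:
    """Read a fixture bundle back; inverse of :func:`write_fixture_bundle`.

    Signals stored in mP are converted back to fractional units; the
    original unit flag is returned so writers can round-trip it.
    """
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise BundleError(f"missing manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("schema_version", "traces", "signal_unit"):
        if key not in manifest:
            raise BundleError(f"manifest.json missing field {key!r}")
    truth_path = directory / "truth.json"
    if not truth_path.exists():
        raise BundleError(f"missing truth.json in {directory}")
    truth = json.loads(truth_path.read_text())
    unit = manifest["signal_unit"]
    scale = 1e-3 if unit == "mP" else 1.0
    traces = []
    for stem in manifest["traces"]:
        csv_path = directory / "traces" / f"{stem}.csv"
        sidecar_path = directory / "traces" / f"{stem}.json"
        if not csv_path.exists():
            raise BundleError(f"missing trace file {csv_path.name}")
        if not sidecar_path.exists():
            raise BundleError(f"missing sidecar {sidecar_path.name}")
        df = pd.read_csv(csv_path)
        for col in ("time_s", "signal"):
            if col not in df.columns:
                raise BundleError(f"{csv_path.name} missing column {col!r}")
        sidecar = json.loads(sidecar_path.read_text())
        for key in ("protein_total_M", "substrate_total_M", "signal_type"):
            if key not in sidecar:
                raise BundleError(f"{sidecar_path.name} missing field {key!r}")
        traces.append(
            KineticTrace(
                times=df["time_s"].to_numpy(),
                signal=df["signal"].to_numpy() * scale,
                protein_total=sidecar["protein_total_M"],
                substrate_total=sidecar["substrate_total_M"],
                competitor_total=sidecar.get("competitor_total_M", 0.0),
                signal_type=sidecar["signal_type"],
                replicate_id=sidecar.get("replicate_id", "r1"),
            )
        )
    return traces, truth, unit
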