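"""Synthetic single-cell F_m′ traces, populations, repeat pairs and movies.

The generator emulates the phenomenology of the four reference
populations used to train the NPQ scoring pipeline:

* *Pop-0*   — no NPQ component: flat traces up to measurement noise.
* *Pop-qE*  — high-energy quenching: a steep F_m′ decay at light onset
  with a transitory maximum (partial relaxation in the light) and rapid
  recovery in the dark.
* *Pop-qT*  — state transitions: a minutes-scale rise of F_m′ in the
  light (LHCII moving to PSII) relaxing over minutes in the dark.
* *Pop-qI*  — photoinhibition: a slow continuous F_m′ decline in the
  light that does not recover during the 15-min dark phase.

Mixed wild-type-like populations co-express qE and qT.  Each cell's
component amplitudes are drawn log-normally around population medians
(cell-to-cell dispersion), and traces carry multiplicative Gaussian
measurement noise.  A noise-free trace is exactly

    F(t) / F0 - 1 = -A_qE · e(t) + A_qT · g(t) - A_qI · h(t)

with e, g, h the unit-amplitude component bases, realizing the linear
combination hypothesis the scoring pipeline rests on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .protocol import Protocol, phase_at, pulse_times

__all__ = [
    "ComponentKinetics",
    "CellParams",
    "PopulationLabel",
    "PopulationSpec",
    "LabeledTraceSet",
    "Movie",
    "DEFAULT_KINETICS",
    "default_population_spec",
    "component_basis",
    "simulate_trace",
    "simulate_population",
    "simulate_repeat_pair",
    "simulate_movie",
]

COMPONENTS = ("qE", "qT", "qI")


class PopulationLabel(str, Enum):
    POP0 = "Pop0"
    POP_QE = "PopQE"
    POP_QT = "PopQT"
    POP_QI = "PopQI"
    WT = "WT"


@dataclass(frozen=True)
class ComponentKinetics:
    """Phenomenological kinetics of one NPQ component.

    ``tau_rise`` / ``tau_relax`` are the induction and relaxation time
    constants (seconds) in the inducing and opposite illumination state.
    For qE, ``transitory_fraction`` f and ``tau_transitory`` describe the
    partial in-light relaxation toward f of the initial maximum (f = 1
    means no transitory maximum).  ``frozen_in_dark`` (qI) freezes the
    component at its light-phase end value during darkness.
    """

    tau_rise: float
    tau_relax: float
    transitory_fraction: float = 1.0
    tau_transitory: float | None = None
    frozen_in_dark: bool = False

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_relax <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.transitory_fraction <= 1.0:
            raise ValueError("transitory_fraction must be in [0, 1]")
        if self.transitory_fraction < 1.0 and (
                self.tau_transitory is None or self.tau_transitory <= 0):
            raise ValueError("transitory kinetics require tau_transitory > 0")


#: Default component kinetics: seconds-scale qE with a transitory
#: maximum, minutes-scale qT, slow non-recovering qI.
DEFAULT_KINETICS: Mapping[str, ComponentKinetics] = {
    "qE": ComponentKinetics(tau_rise=30.0, tau_relax=30.0,
                            transitory_fraction=0.6, tau_transitory=300.0),
    "qT": ComponentKinetics(tau_rise=200.0, tau_relax=300.0),
    "qI": ComponentKinetics(tau_rise=900.0, tau_relax=900.0,
                            frozen_in_dark=True),
}


@dataclass(frozen=True)
class CellParams:
    """Ground-truth parameters of one simulated cell."""

    baseline_F0: float = 100.0
    A_qE: float = 0.0
    A_qT: float = 0.0
    A_qI: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_F0 <= 0:
            raise ValueError("baseline_F0 must be positive")
        if min(self.A_qE, self.A_qT, self.A_qI) < 0:
            raise ValueError("component amplitudes must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def amplitude(self, component: str) -> float:
        return {"qE": self.A_qE, "qT": self.A_qT, "qI": self.A_qI}[component]


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one simulated population.

    ``amplitude_medians`` / ``amplitude_cv`` give per-component log-normal
    medians and coefficients of variation; inactive components have median
    zero.  ``noise_sigma`` is the relative SD of the multiplicative
    per-sample measurement noise.
    """

    label: PopulationLabel
    n_cells: int
    amplitude_medians: Mapping[str, float]
    amplitude_cv: Mapping[str, float]
    noise_sigma: float = 0.02
    baseline_F0: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for comp in COMPONENTS:
            if self.amplitude_medians.get(comp, 0.0) < 0:
                raise ValueError("amplitude medians must be >= 0")


#: Median component amplitudes and dispersions of the reference
#: populations.  Pop-qE cells drop F_m′ by ~45% at the transitory
#: maximum; Pop-qT cells gain ~30%; Pop-qI cells lose ~35% by the end of
#: the light phase.  Dispersions reflect the ~20% (qT) to ~35-40% (qE)
#: cell-to-cell coefficients of variation of these traits.
_POPULATION_DEFAULTS: dict[PopulationLabel, tuple[dict, dict]] = {
    PopulationLabel.POP0: ({}, {}),
    PopulationLabel.POP_QE: ({"qE": 0.45}, {"qE": 0.35}),
    PopulationLabel.POP_QT: ({"qT": 0.30}, {"qT": 0.20}),
    PopulationLabel.POP_QI: ({"qI": 0.35}, {"qI": 0.25}),
    PopulationLabel.WT: ({"qE": 0.35, "qT": 0.30},
                         {"qE": 0.35, "qT": 0.20}),
}


def default_population_spec(label: PopulationLabel | str, n_cells: int,
                            seed: int = 0,
                            noise_sigma: float = 0.02) -> PopulationSpec:
    """Population spec with the default amplitude medians/dispersions."""
    label = PopulationLabel(label)
    medians, cvs = _POPULATION_DEFAULTS[label]
    return PopulationSpec(label=label, n_cells=n_cells,
                          amplitude_medians=dict(medians),
                          amplitude_cv=dict(cvs),
                          noise_sigma=noise_sigma, seed=seed)


@dataclass
class LabeledTraceSet:
    """Matrix of per-cell F_m′ traces with labels and ground truth."""

    traces: np.ndarray                      # (n_cells, T)
    labels: list[str]
    ground_truth: list[CellParams]
    pulse_times: np.ndarray
    metadata: dict = field(default_factory=dict)
    cell_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.shape[1] != len(self.pulse_times):
            raise ValueError("trace length must match the pulse grid")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.traces.shape[0]))

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    def subset(self, idx) -> "LabeledTraceSet":
        idx = np.asarray(idx)
        return LabeledTraceSet(
            traces=self.traces[idx],
            labels=[self.labels[i] for i in idx],
            ground_truth=[self.ground_truth[i] for i in idx],
            pulse_times=self.pulse_times,
            metadata=dict(self.metadata),
            cell_ids=[self.cell_ids[i] for i in idx],
        )

    # -- CSV + sidecar JSON I/O -------------------------------------------

    def to_csv(self, path, sidecar: bool = True) -> None:
        """Write long-format CSV (cell_id, population, repeat, pulse_index,
        time_s, fm_value) plus a ground-truth sidecar JSON."""
        path = Path(path)
        n, T = self.traces.shape
        repeat = self.metadata.get("repeat", 0)
        df = pd.DataFrame({
            "cell_id": np.repeat(self.cell_ids, T),
            "population": np.repeat(self.labels, T),
            "repeat": repeat,
            "pulse_index": np.tile(np.arange(T), n),
            "time_s": np.tile(self.pulse_times, n),
            "fm_value": self.traces.ravel(),
        })
        df.to_csv(path, index=False)
        if sidecar:
            side = {
                "metadata": self.metadata,
                "ground_truth": [
                    {"cell_id": cid, "baseline_F0": gt.baseline_F0,
                     "A_qE": gt.A_qE, "A_qT": gt.A_qT, "A_qI": gt.A_qI,
                     "noise_sigma": gt.noise_sigma}
                    for cid, gt in zip(self.cell_ids, self.ground_truth)
                ],
            }
            path.with_suffix(".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def from_csv(cls, path) -> "LabeledTraceSet":
        path = Path(path)
        df = pd.read_csv(path)
        cell_ids = list(df["cell_id"].drop_duplicates())
        wide = df.pivot(index="cell_id", columns="pulse_index",
                        values="fm_value").loc[cell_ids]
        times = (df.drop_duplicates("pulse_index")
                 .sort_values("pulse_index")["time_s"].to_numpy())
        labels = list(df.drop_duplicates("cell_id")
                      .set_index("cell_id").loc[cell_ids, "population"])
        meta: dict = {"repeat": int(df["repeat"].iloc[0])}
        gts = [CellParams() for _ in cell_ids]
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            meta.update(side.get("metadata", {}))
            by_id = {g["cell_id"]: g for g in side.get("ground_truth", [])}
            gts = [
                CellParams(baseline_F0=by_id[c]["baseline_F0"],
                           A_qE=by_id[c]["A_qE"], A_qT=by_id[c]["A_qT"],
                           A_qI=by_id[c]["A_qI"],
                           noise_sigma=by_id[c]["noise_sigma"])
                if c in by_id else CellParams()
                for c in cell_ids
            ]
        return cls(traces=wide.to_numpy(float), labels=labels,
                   ground_truth=gts, pulse_times=times, metadata=meta,
                   cell_ids=[int(c) for c in cell_ids])


# ---------------------------------------------------------------------------
# Component kinetics
# ---------------------------------------------------------------------------

def _evaluate_component(p: Protocol, component: str, k: ComponentKinetics,
                        times: np.ndarray) -> np.ndarray:
    """Closed-form piecewise evaluation of a component basis at ``times``.

    Each phase integrates continuously from the previous phase's end
    value.  In a light phase a component rises toward 1 with tau_rise
    (for qE modulated by the transitory relaxation toward
    ``transitory_fraction``); in the dark it decays with tau_relax, or
    stays frozen (qI).
    """
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    v0 = 0.0
    for ph in p.phases:
        in_phase = (times >= ph.start) & (times < ph.end)
        if ph is p.phases[-1]:
            in_phase |= times == ph.end
        s = times[in_phase] - ph.start
        if ph.is_light:
            raw = 1.0 - np.exp(-s / k.tau_rise)
            if k.transitory_fraction < 1.0:
                f = k.transitory_fraction
                raw = raw * (f + (1.0 - f) * np.exp(-s / k.tau_transitory))
            out[in_phase] = v0 + (1.0 - v0) * raw
            s_end = ph.duration
            raw_end = 1.0 - np.exp(-s_end / k.tau_rise)
            if k.transitory_fraction < 1.0:
                f = k.transitory_fraction
                raw_end *= f + (1.0 - f) * np.exp(-s_end / k.tau_transitory)
            v0 = v0 + (1.0 - v0) * raw_end
        else:
            if k.frozen_in_dark:
                out[in_phase] = v0
            else:
                out[in_phase] = v0 * np.exp(-s / k.tau_relax)
                v0 = v0 * np.exp(-ph.duration / k.tau_relax)
    return out


def component_basis(p: Protocol, component: str,
                    k: ComponentKinetics | None = None) -> np.ndarray:
    """Unit-amplitude component basis sampled at the pulse times.

    Values lie in [0, 1]; the basis is 0 at t = 0 (no stress before
    light onset).
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; "
                         f"expected one of {COMPONENTS}")
    if k is None:
        k = DEFAULT_KINETICS[component]
    return _evaluate_component(p, component, k, pulse_times(p))


def component_bases(p: Protocol,
                    kinetics: Mapping[str, ComponentKinetics] | None = None,
                    ) -> dict[str, np.ndarray]:
    kinetics = kinetics or DEFAULT_KINETICS
    return {c: component_basis(p, c, kinetics[c]) for c in COMPONENTS}


# ---------------------------------------------------------------------------
# Trace / population simulation
# ---------------------------------------------------------------------------

def _check_positivity(c: CellParams, bases: Mapping[str, np.ndarray],
                      margin: float = 0.0) -> bool:
    return (c.A_qE * bases["qE"].max() + c.A_qI * bases["qI"].max()
            < 1.0 - margin)


def simulate_trace(c: CellParams, p: Protocol,
                   bases: Mapping[str, np.ndarray],
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """One noisy F_m′ trace for a cell with the given ground truth.

    F(t_k) = F0 · (1 − A_qE·e + A_qT·g − A_qI·h) · (1 + ε_k) with i.i.d.
    Gaussian relative noise ε_k.  qT raises F_m′ (state I has the larger
    PSII antenna); qE and qI quench it.
    """
    if not _check_positivity(c, bases):
        raise ValueError("amplitudes violate positivity: "
                         "A_qE·max(e) + A_qI·max(h) must be < 1")
    clean = c.baseline_F0 * (1.0 - c.A_qE * bases["qE"]
                             + c.A_qT * bases["qT"]
                             - c.A_qI * bases["qI"])
    if c.noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        clean = clean * (1.0 + rng.normal(0.0, c.noise_sigma,
                                          size=clean.shape))
    return clean


def _draw_cell_params(spec: PopulationSpec, bases, rng,
                      max_attempts: int = 100) -> CellParams:
    # rejection-resample rare upper-tail draws that would push F_m′
    # non-positive (margin 0.05 keeps traces bounded away from zero)
    for _ in range(max_attempts):
        amps = {}
        for comp in COMPONENTS:
            m = spec.amplitude_medians.get(comp, 0.0)
            if m <= 0:
                amps[comp] = 0.0
                continue
            cv = spec.amplitude_cv.get(comp, 0.0)
            sigma = np.sqrt(np.log1p(cv * cv))
            amps[comp] = m * np.exp(sigma * rng.standard_normal())
        c = CellParams(baseline_F0=spec.baseline_F0, A_qE=amps["qE"],
                       A_qT=amps["qT"], A_qI=amps["qI"],
                       noise_sigma=spec.noise_sigma)
        if _check_positivity(c, bases, margin=0.05):
            return c
    raise RuntimeError("could not draw amplitudes satisfying positivity")


def simulate_population(spec: PopulationSpec, p: Protocol,
                        kinetics: Mapping[str, ComponentKinetics] | None = None,
                        ) -> LabeledTraceSet:
    """Simulate a labeled population; deterministic given ``spec.seed``."""
    bases = component_bases(p, kinetics)
    rng = np.random.default_rng(spec.seed)
    params = [_draw_cell_params(spec, bases, rng)
              for _ in range(spec.n_cells)]
    traces = np.stack([simulate_trace(c, p, bases, rng) for c in params])
    return LabeledTraceSet(
        traces=traces,
        labels=[spec.label.value] * spec.n_cells,
        ground_truth=params,
        pulse_times=pulse_times(p),
        metadata={"seed": spec.seed, "repeat": 0,
                  "population": spec.label.value,
                  "noise_sigma": spec.noise_sigma},
    )


def simulate_repeat_pair(spec: PopulationSpec, p: Protocol,
                         kinetics: Mapping[str, ComponentKinetics] | None = None,
                         ) -> tuple[LabeledTraceSet, LabeledTraceSet]:
    """Two consecutive acquisitions of the same cells.

    Ground-truth amplitudes are identical between repeats (the biological
    state is assumed unchanged); only the measurement-noise realizations
    differ.  Cell order is aligned: index i is the same cell in both.
    """
    bases = component_bases(p, kinetics)
    rng = np.random.default_rng(spec.seed)
    params = [_draw_cell_params(spec, bases, rng)
              for _ in range(spec.n_cells)]
    sets = []
    for repeat in (0, 1):
        traces = np.stack([simulate_trace(c, p, bases, rng)
                           for c in params])
        sets.append(LabeledTraceSet(
            traces=traces,
            labels=[spec.label.value] * spec.n_cells,
            ground_truth=params,
            pulse_times=pulse_times(p),
            metadata={"seed": spec.seed, "repeat": repeat,
                      "population": spec.label.value,
                      "noise_sigma": spec.noise_sigma},
        ))
    return sets[0], sets[1]


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

@dataclass
class Movie:
    """Fluorescence frame stack with per-frame timestamps."""

    frames: np.ndarray            # (n_frames, H, W)
    timestamps: np.ndarray        # seconds
    protocol: Protocol

    def save(self, path) -> None:
        import tifffile
        desc = json.dumps({"timestamps": list(map(float, self.timestamps)),
                           "protocol": self.protocol.to_dict()})
        tifffile.imwrite(path, self.frames.astype(np.float32),
                         description=desc)

    @classmethod
    def load(cls, path) -> "Movie":
        import tifffile
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = json.loads(tf.pages[0].description)
        return cls(frames=frames,
                   timestamps=np.asarray(desc["timestamps"]),
                   protocol=Protocol.from_dict(desc["protocol"]))


def simulate_movie(spec: PopulationSpec, p: Protocol,
                   height: int = 512, width: int = 512,
                   cell_radius_px: int = 6,
                   kinetics=None,
                   background: float = 10.0,
                   photon_noise: float = 0.0,
                   max_attempts: int = 20000,
                   ) -> tuple[Movie, np.ndarray, LabeledTraceSet]:
    """Render a population as a pulse-frame movie with known mask.

    One frame is rendered per saturating pulse (timestamp = pulse time):
    background plus, for every cell, a disk whose intensity is
    proportional to that cell's F_m′ at the pulse.  Cell centers are
    rejection-sampled so disks never overlap; a packing that cannot be
    placed within ``max_attempts`` raises.  Returns the movie, the
    ground-truth label mask (0 = background, cells 1..n in trace order)
    and the underlying trace set.
    """
    ts = simulate_population(spec, p, kinetics)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC311]))
    n = ts.n_cells
    r = cell_radius_px
    centers: list[tuple[int, int]] = []
    attempts = 0
    min_sep2 = (2 * r + 2) ** 2
    while len(centers) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not pack {n} disks of radius {r} into "
                f"{height}x{width} after {max_attempts} attempts")
        attempts += 1
        row = rng.integers(r + 1, height - r - 1)
        col = rng.integers(r + 1, width - r - 1)
        if all((row - cr) ** 2 + (col - cc) ** 2 >= min_sep2
               for cr, cc in centers):
            centers.append((int(row), int(col)))
    mask = np.zeros((height, width), dtype=np.uint16)
    rr, cc = np.mgrid[0:height, 0:width]
    for i, (crow, ccol) in enumerate(centers, start=1):
        disk = (rr - crow) ** 2 + (cc - ccol) ** 2 <= r * r
        mask[disk] = i
    T = ts.traces.shape[1]
    frames = np.full((T, height, width), background, dtype=float)
    for i in range(n):
        disk = mask == i + 1
        frames[:, disk] += ts.traces[i][:, None]
    if photon_noise > 0:
        frames += rng.normal(0.0, photon_noise * np.sqrt(frames))
        np.clip(frames, 0.0, None, out=frames)
    movie = Movie(frames=frames, timestamps=ts.pulse_times.copy(),
                  protocol=p)
    return movie, mask, ts
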