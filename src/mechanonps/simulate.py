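"""Synthetic mechano-NPS current traces with ground truth.

Emulates a 50 kHz four-terminal current recording of cells transiting a
node-pore channel: a slowly drifting baseline, additive Gaussian noise, and
one downward rectangular subpulse per narrow segment the cell occupies.
Subpulse amplitude follows the standard resistive-pulse sizing relation;
post-contraction subpulses carry an exponentially relaxing amplitude deficit
``q(t) = q0 * exp(-t / tau)`` that models the cell's viscoelastic recovery
from its deformed (ellipsoid) shape back to a sphere.

Artifact events (truncated pulses, coincident cells) are generated on request
so that the detector's automatic rejection rules can be exercised against
known labels.

Units: lengths um, velocities um/ms, times ms internally (entry times s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    DeviceGeometry,
    GeometryError,
    effective_pore_diameter,
    nominal_diameter,
    segment_plan,
)
from .preprocess import Trace

__all__ = [
    "AcquisitionConfig",
    "PopulationParams",
    "CellGroundTruth",
    "GroundTruthManifest",
    "SimulationError",
    "sample_cells",
    "subpulse_amplitude",
    "subpulse_schedule",
    "synthesize_trace",
    "simulate_recording",
]

CellLabel = Literal["valid", "artifact_partial", "artifact_coincident"]

#: fraction of the contraction's effective diameter a squeezed cell is capped
#: at when rendering its blockage (a cell wider than the contraction deforms
#: to nearly fill, but not exceed, the cross-section)
SQUEEZE_CAP = 0.93

#: recovery-deficit tolerance used when tabulating the true recovery time
#: in the manifest (matches the analysis default)
TRUE_RECOVERY_TOL = 0.02


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings of the emulated recording."""

    sample_rate_hz: float = 50_000.0
    baseline_current: float = 1.0
    #: std of additive Gaussian noise relative to baseline; the default puts
    #: the pore edge threshold 2e-4 at ~4 sigma of the raw noise
    noise_sd_rel: float = 5e-5
    drift_amplitude_rel: float = 0.01
    drift_timescale_s: float = 10.0
    duration_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise SimulationError("sample_rate_hz must be positive")
        if self.noise_sd_rel < 0:
            raise SimulationError("noise_sd_rel must be non-negative")
        if not self.baseline_current > 0:
            raise SimulationError("baseline_current must be positive")
        if self.duration_s is not None and not self.duration_s > 0:
            raise SimulationError("duration_s must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Distributional model of the simulated cell population.

    Diameters and the recovery constant are lognormal (sizes and relaxation
    times are strictly positive and right-skewed); the contraction slowdown
    is a uniform ratio ``vc / v0``.  ``frac_instantaneous`` is the fraction
    of cells that recover instantaneously (no amplitude deficit, q0 = 0).
    """

    d0_median_um: float | None = None   # None -> device nominal diameter
    d0_sigma_log: float = 0.06
    v0_median_um_per_ms: float = 10.0
    v0_sigma_log: float = 0.12
    vc_ratio_range: tuple[float, float] = (0.35, 0.65)
    tau_median_ms: float = 20.0
    tau_sigma_log: float = 0.3
    q0_range: tuple[float, float] = (0.1, 0.3)
    frac_instantaneous: float = 0.15
    frac_artifact_partial: float = 0.0
    frac_artifact_coincident: float = 0.0
    start_s: float = 1.0
    gap_s: float | None = None          # None -> geometry-dependent default


@dataclass
class CellGroundTruth:
    cell_id: int
    d0_um: float
    v0_um_per_ms: float
    vc_um_per_ms: float
    tau_ms: float
    q0: float
    entry_time_s: float
    recovery_velocity_um_per_ms: float
    label: CellLabel = "valid"
    #: for artifact_partial: number of leading subpulses actually emitted
    n_emitted_subpulses: int | None = None

    def wcdi(self, geometry: DeviceGeometry) -> float:
        """True whole-cell deformability index (vc/v0)(d0/h)."""
        return (self.vc_um_per_ms / self.v0_um_per_ms) * (
            self.d0_um / geometry.channel_height_um)


@dataclass
class GroundTruthManifest:
    cells: list[CellGroundTruth]
    geometry: DeviceGeometry
    acquisition: AcquisitionConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = asdict(c)
            row["true_wcdi"] = c.wcdi(self.geometry)
            row["true_delta_t_r_ms"] = true_recovery_time_ms(c, self.geometry)
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def valid_cells(self) -> list[CellGroundTruth]:
        return [c for c in self.cells if c.label == "valid"]


def subpulse_amplitude(d_eff_um: float, segment_width_um: float,
                       segment_length_um: float, h_um: float) -> float:
    """Relative current drop dI/I of a cell in one narrow segment.

    Standard resistive-pulse relation for a sphere of diameter ``d`` in a
    pore of effective diameter ``D_e`` and length ``L``:
    ``dI/I = d^3 / (D_e^2 L) * 1 / (1 - 0.8 (d/D_e)^3)``,
    strictly increasing in ``d``.
    """
    if d_eff_um <= 0:
        raise GeometryError("cell diameter must be positive")
    de = effective_pore_diameter(segment_width_um, h_um)
    if d_eff_um >= de:
        raise GeometryError(
            f"cell diameter {d_eff_um} um exceeds effective pore diameter {de:.3f} um")
    r3 = (d_eff_um / de) ** 3
    return (d_eff_um ** 3 / (de ** 2 * segment_length_um)) / (1.0 - 0.8 * r3)


def _contraction_effective_diameter(d0_um: float, geometry: DeviceGeometry) -> float:
    return min(d0_um, SQUEEZE_CAP * geometry.contraction_effective_diameter_um)


@dataclass(frozen=True)
class ScheduledSubpulse:
    kind: str
    start_ms: float            # relative to cell entry
    end_ms: float
    amplitude: float           # dI/I
    #: recovery pores only: subpulse midpoint minus contraction exit, ms
    t_since_contraction_exit_ms: float | None = None


def subpulse_schedule(cell: CellGroundTruth, geometry: DeviceGeometry
                      ) -> list[ScheduledSubpulse]:
    """Noise-free subpulse timing and amplitudes for one cell.

    The cell moves at ``v0`` through everything before the contraction, at
    ``vc`` inside it, and at ``recovery_velocity`` afterwards.  Nodes produce
    no subpulse.  Recovery subpulse amplitudes are evaluated at the segment
    midpoint time with the deficit ``q(t) = q0 exp(-t/tau)`` applied to the
    fully-recovered amplitude of that pore.
    """
    g = geometry
    a_ref = subpulse_amplitude(cell.d0_um, g.pore_width_um, g.pore_length_um,
                               g.channel_height_um)
    a_con = subpulse_amplitude(_contraction_effective_diameter(cell.d0_um, g),
                               g.contraction_width_um, g.contraction_length_um,
                               g.channel_height_um)
    a_rec_full = subpulse_amplitude(cell.d0_um, g.pore_width_um,
                                    g.recovery_pore_length_um, g.channel_height_um)
    out: list[ScheduledSubpulse] = []
    t = 0.0
    contraction_exit_ms: float | None = None
    for seg in segment_plan(g).segments:
        if seg.kind == "contraction":
            v = cell.vc_um_per_ms
        elif contraction_exit_ms is None:
            v = cell.v0_um_per_ms
        else:
            v = cell.recovery_velocity_um_per_ms
        dur = seg.length_um / v
        if seg.kind == "reference_pore":
            out.append(ScheduledSubpulse("reference_pore", t, t + dur, a_ref))
        elif seg.kind == "contraction":
            out.append(ScheduledSubpulse("contraction", t, t + dur, a_con))
            contraction_exit_ms = t + dur
        elif seg.kind == "recovery_pore":
            t_mid = t + 0.5 * dur - contraction_exit_ms
            if cell.tau_ms > 0:
                q = cell.q0 * math.exp(-t_mid / cell.tau_ms)
            else:
                q = 0.0
            out.append(ScheduledSubpulse("recovery_pore", t, t + dur,
                                         a_rec_full * (1.0 - q), t_mid))
        t += dur
    return out


def transit_time_ms(cell: CellGroundTruth, geometry: DeviceGeometry) -> float:
    sched = subpulse_schedule(cell, geometry)
    return sched[-1].end_ms


def true_recovery_time_ms(cell: CellGroundTruth, geometry: DeviceGeometry,
                          tolerance: float = TRUE_RECOVERY_TOL) -> float:
    """Model recovery time: first recovery-pore midpoint with q <= tolerance.

    0 if the deficit is already within tolerance at the first recovery pore;
    ``inf`` if it never falls within tolerance at any recovery pore
    (prolonged recovery).
    """
    times = [s.t_since_contraction_exit_ms
             for s in subpulse_schedule(cell, geometry)
             if s.kind == "recovery_pore"]
    for i, t in enumerate(times):
        q = cell.q0 * math.exp(-t / cell.tau_ms) if cell.tau_ms > 0 else 0.0
        if q <= tolerance:
            return 0.0 if i == 0 else t
    return math.inf


def _default_gap_s(geometry: DeviceGeometry) -> float:
    # inter-cell quiet gap: comfortably larger than the detector's default
    # window-merging gap (see detect.default_max_gap_ms)
    from .detect import default_max_gap_ms
    return 1.4 * default_max_gap_ms(geometry) / 1000.0


def sample_cells(geometry: DeviceGeometry, n: int,
                 params: PopulationParams = PopulationParams(),
                 seed: int | np.random.Generator = 0) -> list[CellGroundTruth]:
    """Draw ``n`` cells from the population model with non-overlapping entries.

    Entry times are laid out sequentially with a quiet gap after each transit
    so that distinct valid cells cannot share a detection window.  Cells
    labelled ``artifact_coincident`` are deliberately scheduled inside the
    preceding cell's transit.
    """
    if n < 1:
        raise SimulationError("need n >= 1 cells")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    g = geometry
    d0_med = params.d0_median_um if params.d0_median_um is not None \
        else nominal_diameter(g)
    d0_hi = min(0.95 * g.pore_width_um, 0.92 * g.reference_pore_effective_diameter_um)
    d0_lo = 1.02 * g.contraction_width_um
    if not d0_lo < d0_med < d0_hi:
        raise SimulationError(
            f"d0 median {d0_med:.2f} um infeasible for device {g.device_id} "
            f"(must lie in ({d0_lo:.2f}, {d0_hi:.2f}) um)")
    gap_s = params.gap_s if params.gap_s is not None else _default_gap_s(g)
    n_sub = segment_plan(g).n_subpulses

    cells: list[CellGroundTruth] = []
    clock_s = params.start_s
    prev_valid: CellGroundTruth | None = None
    for i in range(n):
        d0 = float(np.clip(d0_med * math.exp(params.d0_sigma_log * rng.standard_normal()),
                           d0_lo, d0_hi))
        v0 = params.v0_median_um_per_ms * math.exp(
            params.v0_sigma_log * rng.standard_normal())
        vc = v0 * rng.uniform(*params.vc_ratio_range)
        tau = params.tau_median_ms * math.exp(
            params.tau_sigma_log * rng.standard_normal())
        q0 = 0.0 if rng.random() < params.frac_instantaneous \
            else rng.uniform(*params.q0_range)
        u = rng.random()
        label: CellLabel = "valid"
        if i > 0 and u < params.frac_artifact_partial:
            label = "artifact_partial"
        elif i > 0 and u < params.frac_artifact_partial + params.frac_artifact_coincident:
            label = "artifact_coincident"
        cell = CellGroundTruth(
            cell_id=i, d0_um=d0, v0_um_per_ms=v0, vc_um_per_ms=vc,
            tau_ms=tau, q0=q0, entry_time_s=clock_s,
            recovery_velocity_um_per_ms=v0, label=label)
        transit_s = transit_time_ms(cell, g) / 1000.0
        if label == "artifact_coincident" and prev_valid is not None:
            prev_transit_s = transit_time_ms(prev_valid, g) / 1000.0
            cell.entry_time_s = prev_valid.entry_time_s + 0.4 * prev_transit_s
        else:
            if label == "artifact_partial":
                cell.n_emitted_subpulses = int(rng.integers(1, n_sub))
            clock_s = cell.entry_time_s + transit_s + gap_s
            if label == "valid":
                prev_valid = cell
        cells.append(cell)
    return cells


def _add_rect(block: np.ndarray, s0: float, s1: float, amp: float) -> None:
    """Add a rectangle with fractional (sub-sample) edges to a coverage array."""
    n = len(block)
    s0 = max(s0, 0.0)
    s1 = min(s1, float(n))
    if s1 <= s0:
        return
    i0, i1 = int(math.floor(s0)), int(math.floor(s1))
    if i0 == i1:
        block[i0] += amp * (s1 - s0)
        return
    block[i0] += amp * (i0 + 1 - s0)
    block[i0 + 1:i1] += amp
    if i1 < n:
        block[i1] += amp * (s1 - i1)


def synthesize_trace(cells: Sequence[CellGroundTruth], geometry: DeviceGeometry,
                     acquisition: AcquisitionConfig = AcquisitionConfig()
                     ) -> tuple[Trace, GroundTruthManifest]:
    """Render the full current trace and its ground-truth manifest.

    ``trace = I0 * (1 + drift(t)) * (1 - sum of subpulse blockages) + noise``:
    the blockage scales the instantaneous (drifting) current, so the
    normalized drop relative to baseline equals the scheduled dI/I exactly.
    """
    acq = acquisition
    fs = acq.sample_rate_hz
    lead_s = 0.5
    last_exit_s = 0.0
    schedules: list[tuple[CellGroundTruth, list[ScheduledSubpulse]]] = []
    for cell in cells:
        sched = subpulse_schedule(cell, geometry)
        if cell.label == "artifact_partial":
            k = cell.n_emitted_subpulses
            if k is None:
                k = max(1, len(sched) - 1 - geometry.n_recovery_pores)
            sched = sched[:k]
        schedules.append((cell, sched))
        last_exit_s = max(last_exit_s, cell.entry_time_s + sched[-1].end_ms / 1000.0)
    duration_s = acq.duration_s
    if duration_s is None:
        duration_s = last_exit_s + lead_s
    elif cells and duration_s < last_exit_s:
        raise SimulationError(
            f"duration {duration_s} s too short: last cell exits at "
            f"{last_exit_s:.2f} s")
    n = int(round(duration_s * fs))
    if n < 1:
        raise SimulationError("empty trace")

    block = np.zeros(n)
    for cell, sched in schedules:
        base = cell.entry_time_s * fs
        for sp in sched:
            _add_rect(block, base + sp.start_ms / 1000.0 * fs,
                      base + sp.end_ms / 1000.0 * fs, sp.amplitude)

    t = np.arange(n) / fs
    rng = np.random.default_rng(acq.seed)
    phase = rng.uniform(0, 2 * math.pi)
    if acq.drift_amplitude_rel > 0:
        drift = acq.drift_amplitude_rel * (
            0.6 * np.sin(2 * math.pi * t / acq.drift_timescale_s + phase)
            + 0.4 * (2.0 * t / max(duration_s, 1e-9) - 1.0))
    else:
        drift = np.zeros(n)
    samples = acq.baseline_current * (1.0 + drift) * (1.0 - block)
    if acq.noise_sd_rel > 0:
        samples = samples + rng.normal(
            0.0, acq.noise_sd_rel * acq.baseline_current, n)

    trace = Trace(samples, fs, {
        "device_id": geometry.device_id,
        "baseline_current": acq.baseline_current,
        "seed": acq.seed,
        "source": "mechanonps.simulate",
    })
    manifest = GroundTruthManifest(list(cells), geometry, acq)
    return trace, manifest


def simulate_recording(geometry: DeviceGeometry, n_cells: int, seed: int = 0,
                       params: PopulationParams = PopulationParams(),
                       acquisition: AcquisitionConfig | None = None
                       ) -> tuple[Trace, GroundTruthManifest]:
    """Convenience wrapper: sample a population and render its trace.

    The single ``seed`` drives both the population draw and the acquisition
    noise, so the whole recording is reproducible from one integer.
    """
    rng = np.random.default_rng(seed)
    cells = sample_cells(geometry, n_cells, params, rng)
    if acquisition is None:
        acquisition = AcquisitionConfig(seed=seed + 1)
    elif acquisition.seed is None:
        acquisition = replace(acquisition, seed=seed + 1)
    return synthesize_trace(cells, geometry, acquisition)
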