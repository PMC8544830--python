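"""Mechanical phenotypes and QC filters.

From each segmented pulse: initial diameter ``d0`` (reference-pore amplitude
inverted through the sizing relation), free velocity ``v0`` and contraction
velocity ``vc`` (segment length / subpulse duration), the whole-cell
deformability index ``wCDI = (vc / v0) (d0 / h)``, and the viscoelastic
recovery observables: the per-recovery-pore amplitude deficit
``q_i = (a_expected - a_i) / a_expected``, the exponential recovery constant
``tau`` (log-linear fit of q on time since contraction exit), the recovery
time ``dTr`` (time to the first recovery pore with q within tolerance) and
its category: instantaneous (dTr = 0), finite (0 < dTr < 100 ms) or
prolonged (no recovery within the 100 ms window).

QC: statistical outliers are values more than 3 median absolute deviations
(MAD, unscaled) from the sample median — flagged but kept; erroneous
measurements are cells whose reference or contraction velocity falls outside
+-4 MAD computed on the outlier-free subset — excluded from downstream
statistics by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import SegmentedPulse
from .geometry import DeviceGeometry, GeometryError
from .simulate import subpulse_amplitude

__all__ = [
    "CellRecord",
    "PhenotypeParams",
    "diameter_from_amplitude",
    "velocity",
    "compute_wcdi",
    "recovery_deficits",
    "fit_tau",
    "delta_t_r",
    "classify_recovery",
    "flag_statistical_outliers",
    "flag_erroneous",
    "phenotype_pipeline",
    "records_to_dataframe",
]

PROLONGED = math.inf
RECOVERY_WINDOW_MS = 100.0


@dataclass
class CellRecord:
    cell_id: int
    device_id: str
    window_start_s: float
    d0_um: float
    v0_um_per_ms: float
    vc_um_per_ms: float
    wcdi: float
    tau_ms: float | None            # None: instantaneous / unresolvable
    delta_t_r_ms: float             # inf marks prolonged recovery
    recovery_category: str          # instantaneous | finite | prolonged
    statistical_outlier: bool = False
    erroneous: bool = False


@dataclass(frozen=True)
class PhenotypeParams:
    """Tunable analysis constants.

    ``recovery_tolerance`` is the deficit below which a cell counts as
    recovered; ``None`` ties it to the measured amplitude noise,
    ``max(0.02, 3 * noise_sd / a_ref)``, so that dTr = 0 is well defined in
    the presence of noise.  ``noise_floor`` excludes deficits indistinguishable
    from noise from the tau fit.  ``mad_scale`` = 1.0 reproduces the unscaled
    median-absolute-deviation convention (no 1.4826 consistency factor).
    """

    recovery_tolerance: float | None = None
    recovery_window_ms: float = RECOVERY_WINDOW_MS
    noise_floor: float = 2e-3
    outlier_n_mad: float = 3.0
    erroneous_n_mad: float = 4.0
    mad_scale: float = 1.0


def diameter_from_amplitude(rel_amplitude: float, geometry: DeviceGeometry,
                            segment_length_um: float | None = None,
                            tol_um: float = 1e-4) -> float:
    """Invert the sizing relation: diameter producing a given dI/I.

    Bisection on the strictly increasing amplitude relation over
    ``(0, 0.95 * D_e)``; unique to ``tol_um``.
    """
    if segment_length_um is None:
        segment_length_um = geometry.pore_length_um
    de = geometry.reference_pore_effective_diameter_um
    hi = 0.95 * de
    a_hi = subpulse_amplitude(hi, geometry.pore_width_um, segment_length_um,
                              geometry.channel_height_um)
    if not 0 < rel_amplitude < a_hi:
        raise GeometryError(
            f"amplitude {rel_amplitude:.3e} outside invertible range (0, {a_hi:.3e})")
    lo = 0.0
    while hi - lo > tol_um:
        mid = 0.5 * (lo + hi)
        a = subpulse_amplitude(mid, geometry.pore_width_um, segment_length_um,
                               geometry.channel_height_um) if mid > 0 else 0.0
        if a < rel_amplitude:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def velocity(duration_ms: float | Sequence[float],
             segment_length_um: float) -> float:
    """Segment length / transit duration, um/ms; multiple pores averaged."""
    durs = np.atleast_1d(np.asarray(duration_ms, dtype=float))
    if np.any(durs <= 0):
        raise ValueError("subpulse duration must be positive")
    return float(np.mean(segment_length_um / durs))


def compute_wcdi(vc: float, v0: float, d0: float, h: float) -> float:
    """Whole-cell deformability index, (vc / v0) (d0 / h)."""
    if min(vc, v0, d0, h) <= 0:
        raise ValueError("wCDI inputs must all be positive")
    return (vc / v0) * (d0 / h)


def recovery_deficits(segmented: SegmentedPulse, geometry: DeviceGeometry,
                      d0_um: float) -> list[tuple[float, float]]:
    """Per-recovery-pore (time since contraction exit [ms], deficit q).

    The expected fully-recovered amplitude in a recovery pore is the sizing
    relation evaluated at the measured ``d0`` for that pore's length (on
    devices where recovery and reference pores share a length this equals
    the reference amplitude).  Deficits are clipped at 0: noise can make a
    recovered cell look marginally larger than its reference size.
    """
    rec = segmented.recovery_subpulses
    if len(rec) < 2:
        raise ValueError("need at least 2 recovery subpulses")
    a_expected = subpulse_amplitude(d0_um, geometry.pore_width_um,
                                    geometry.recovery_pore_length_um,
                                    geometry.channel_height_um)
    if a_expected <= 0:
        raise ValueError("non-positive expected recovery amplitude")
    exit_s = segmented.contraction.end_s
    out = []
    for sp in rec:
        t_ms = (sp.midpoint_s - exit_s) * 1000.0
        q = max(0.0, (a_expected - sp.amplitude) / a_expected)
        out.append((t_ms, q))
    return out


def fit_tau(deficits: Sequence[tuple[float, float]],
            noise_floor: float = 2e-3) -> float | None:
    """Exponential recovery constant from a log-linear least-squares fit.

    OLS of ``ln q_i`` on ``t_i`` over points with ``q_i > noise_floor``;
    ``tau = -1 / slope``.  Returns None when fewer than 2 points are usable
    or the fitted slope is non-negative (no resolvable relaxation).
    """
    pts = [(t, q) for t, q in deficits if q > noise_floor]
    if len(pts) < 2:
        return None
    t = np.array([p[0] for p in pts])
    lq = np.log([p[1] for p in pts])
    slope = np.polyfit(t, lq, 1)[0]
    if slope >= 0:
        return None
    return float(-1.0 / slope)


def delta_t_r(deficits: Sequence[tuple[float, float]], tolerance: float = 0.02,
              window_ms: float = RECOVERY_WINDOW_MS) -> float:
    """Recovery time: first recovery-pore time with deficit within tolerance.

    0 if the first recovery pore already satisfies it; ``inf`` (prolonged)
    when no pore within ``window_ms`` does.
    """
    if not deficits:
        raise ValueError("deficits must be nonempty")
    for i, (t, q) in enumerate(deficits):
        if q <= tolerance:
            if i == 0:
                return 0.0
            return t if t < window_ms else PROLONGED
    return PROLONGED


def classify_recovery(dtr_ms: float, window_ms: float = RECOVERY_WINDOW_MS) -> str:
    """Partition of recovery times: 0 / (0, window) / everything else."""
    if dtr_ms == 0:
        return "instantaneous"
    if 0 < dtr_ms < window_ms:
        return "finite"
    return "prolonged"


def _mad(x: np.ndarray, scale: float = 1.0) -> tuple[float, float]:
    med = float(np.median(x))
    return med, scale * float(np.median(np.abs(x - med)))


def flag_statistical_outliers(values: Sequence[float], n_mad: float = 3.0,
                              mad_scale: float = 1.0) -> np.ndarray:
    """Mask of values more than ``n_mad`` MADs from the sample median.

    MAD is unscaled by default.  When MAD is 0 (at least half the sample at
    the median), any deviation from the median exceeds ``n_mad * 0`` and is
    flagged; an all-equal sample flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    med, mad = _mad(x, mad_scale)
    return np.abs(x - med) > n_mad * mad


def flag_erroneous(records: Sequence[CellRecord] | pd.DataFrame,
                   params: PhenotypeParams = PhenotypeParams()) -> np.ndarray:
    """Erroneous-measurement mask from reference/contraction velocities.

    Statistical outliers (3 MAD) are excluded per velocity variable first;
    the sample median and MAD of the remaining values then set a +-4 MAD
    cutoff, applied to *all* records.  A record outside the cutoff in either
    velocity is erroneous.  Invariant to record order.
    """
    if isinstance(records, pd.DataFrame):
        v0 = records["v0_um_per_ms"].to_numpy(dtype=float)
        vc = records["vc_um_per_ms"].to_numpy(dtype=float)
    else:
        v0 = np.array([r.v0_um_per_ms for r in records], dtype=float)
        vc = np.array([r.vc_um_per_ms for r in records], dtype=float)
    if len(v0) < 3:
        raise ValueError("need at least 3 records")
    mask = np.zeros(len(v0), dtype=bool)
    for v in (v0, vc):
        inliers = v[~flag_statistical_outliers(v, params.outlier_n_mad,
                                               params.mad_scale)]
        if len(inliers) == 0:
            inliers = v
        med, mad = _mad(inliers, params.mad_scale)
        mask |= np.abs(v - med) > params.erroneous_n_mad * mad
    return mask


def _estimate_amplitude_noise(segmented: SegmentedPulse) -> float:
    # spread of the reference-pore amplitudes is the cheapest unbiased probe
    # of plateau noise available per cell; single-reference devices fall back
    # to zero (tolerance floor applies)
    amps = [s.amplitude for s in segmented.reference_subpulses]
    if len(amps) < 2:
        return 0.0
    return float(np.std(amps, ddof=1))


def phenotype_pipeline(pulses: Sequence[SegmentedPulse],
                       geometry: DeviceGeometry,
                       params: PhenotypeParams = PhenotypeParams()
                       ) -> list[CellRecord]:
    """Segmented pulses -> phenotyped, QC-flagged cell records (deterministic)."""
    records: list[CellRecord] = []
    for i, sp in enumerate(pulses):
        ref = sp.reference_subpulses
        a_ref = float(np.mean([s.amplitude for s in ref]))
        d0 = diameter_from_amplitude(a_ref, geometry)
        v0 = velocity([s.duration_ms for s in ref], geometry.pore_length_um)
        vc = velocity(sp.contraction.duration_ms, geometry.contraction_length_um)
        wcdi = compute_wcdi(vc, v0, d0, geometry.channel_height_um)
        deficits = recovery_deficits(sp, geometry, d0)
        tol = params.recovery_tolerance
        if tol is None:
            noise = _estimate_amplitude_noise(sp)
            a_exp = subpulse_amplitude(d0, geometry.pore_width_um,
                                       geometry.recovery_pore_length_um,
                                       geometry.channel_height_um)
            tol = max(0.02, 3.0 * noise / a_exp)
        tau = fit_tau(deficits, params.noise_floor)
        dtr = delta_t_r(deficits, tol, params.recovery_window_ms)
        records.append(CellRecord(
            cell_id=i, device_id=geometry.device_id,
            window_start_s=sp.start_s, d0_um=d0, v0_um_per_ms=v0,
            vc_um_per_ms=vc, wcdi=wcdi, tau_ms=tau, delta_t_r_ms=dtr,
            recovery_category=classify_recovery(dtr, params.recovery_window_ms)))
    if len(records) >= 3:
        wcdi_out = flag_statistical_outliers(
            [r.wcdi for r in records], params.outlier_n_mad, params.mad_scale)
        taus = [r.tau_ms for r in records if r.tau_ms is not None]
        tau_out = np.zeros(len(records), dtype=bool)
        if len(taus) >= 3:
            sub = flag_statistical_outliers(taus, params.outlier_n_mad,
                                            params.mad_scale)
            it = iter(sub)
            tau_out = np.array([next(it) if r.tau_ms is not None else False
                                for r in records])
        err = flag_erroneous(records, params)
        for r, o1, o2, e in zip(records, wcdi_out, tau_out, err):
            r.statistical_outlier = bool(o1 or o2)
            r.erroneous = bool(e)
    return records


def records_to_dataframe(records: Sequence[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "cell_id": r.cell_id,
            "device_id": r.device_id,
            "window_start_s": r.window_start_s,
            "d0_um": r.d0_um,
            "v0_um_per_ms": r.v0_um_per_ms,
            "vc_um_per_ms": r.vc_um_per_ms,
            "wcdi": r.wcdi,
            "tau_ms": r.tau_ms if r.tau_ms is not None else np.nan,
            "delta_t_r_ms": r.delta_t_r_ms,
            "recovery_category": r.recovery_category,
            "statistical_outlier": r.statistical_outlier,
            "erroneous": r.erroneous,
        })
    return pd.DataFrame(rows)
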