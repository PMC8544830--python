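"""Cell-transit detection on normalized traces.

A cell entering or exiting a pore causes a step change in current, which
appears as an extreme value in the first-order difference of the normalized
trace.  Differences are thresholded (separately for pores and the deeper
contraction segment), supra-threshold runs are merged into edge events,
edges are grouped into candidate windows, and each window is segmented into
subpulses and either auto-accepted or auto-rejected (missing subpulses,
overlapping cells, implausible durations).

Subpulse boundaries are refined to sub-sample precision by locating the
half-amplitude crossing of the filtered edge ramp, so velocities are not
quantized at the downsampled rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import DeviceGeometry, SegmentPlan, segment_plan
from .preprocess import NormalizedTrace

__all__ = [
    "ThresholdConfig",
    "DetectionConfig",
    "EdgeEvent",
    "CandidateWindow",
    "Subpulse",
    "SegmentedPulse",
    "SegmentationError",
    "first_difference",
    "find_edges",
    "propose_windows",
    "segment_subpulses",
    "auto_classify",
    "auto_threshold",
    "detect_cells",
    "default_max_gap_ms",
    "DetectionResult",
]


class SegmentationError(RuntimeError):
    """A candidate window could not be segmented into subpulses."""


@dataclass(frozen=True)
class ThresholdConfig:
    """First-difference thresholds in normalized-drop units."""

    pore_threshold: float = 2e-4
    contraction_threshold: float = 1e-3
    auto_mode: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.pore_threshold <= self.contraction_threshold:
            raise ValueError(
                "require 0 < pore_threshold <= contraction_threshold")


@dataclass(frozen=True)
class DetectionConfig:
    thresholds: ThresholdConfig = ThresholdConfig()
    #: plausible cell velocity range, um/ms; bounds the accepted subpulse
    #: durations and the window-merging gap
    v_min_um_per_ms: float = 2.0
    v_max_um_per_ms: float = 40.0
    #: edges closer than this gap are grouped into one candidate window;
    #: None -> geometry-dependent default (see default_max_gap_ms)
    max_gap_ms: float | None = None
    #: half-width (processed samples) of the search region used to refine an
    #: edge to its half-amplitude crossing; should cover the filter ramp
    edge_refine_halfwidth: int = 14
    auto_set_thresholds: bool = False
    interactive: bool = False
    #: after a first detection pass, re-fit the baseline with pulse windows
    #: masked out (cubic bridging) and re-detect on the re-normalized trace;
    #: removes the residual envelope sag under long pulse trains
    refine_baseline: bool = True
    refine_lambda: float = 1e11


def default_max_gap_ms(geometry: DeviceGeometry, v_min_um_per_ms: float = 2.0
                       ) -> float:
    """Default window-merging gap: longer than any intra-cell edge gap.

    The longest quiet interval between edges of one cell is the contraction
    transit of the slowest plausible cell; 1.2x that keeps one cell per
    window while separating cells spaced farther apart than this gap.
    """
    return 1.2 * geometry.contraction_length_um / v_min_um_per_ms


@dataclass(frozen=True)
class EdgeEvent:
    index: int                 # sample index of the |difference| extremum
    time_s: float
    peak: float                # signed extremum of the first difference
    step: float                # signed sum over the supra-threshold run
    direction: str             # "entering" (drop in current) | "exiting"
    threshold_class: str       # "pore" | "contraction"


@dataclass
class CandidateWindow:
    start: int                 # half-open [start, end), 0-based
    end: int
    edges: list[EdgeEvent]
    status: str = "pending"    # pending | auto_rejected | accepted | user_rejected
    rejection_reason: str | None = None
    window_id: int = -1

    @property
    def start_s(self) -> float:
        return self.edges[0].time_s if self.edges else math.nan


@dataclass(frozen=True)
class Subpulse:
    kind: str
    start_s: float
    end_s: float
    amplitude: float           # mean normalized drop over the central 50%
    duration_ms: float

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class SegmentedPulse:
    subpulses: list[Subpulse]
    window: CandidateWindow

    @property
    def start_s(self) -> float:
        return self.subpulses[0].start_s

    @property
    def reference_subpulses(self) -> list[Subpulse]:
        return [s for s in self.subpulses if s.kind == "reference_pore"]

    @property
    def contraction(self) -> Subpulse:
        return next(s for s in self.subpulses if s.kind == "contraction")

    @property
    def recovery_subpulses(self) -> list[Subpulse]:
        return [s for s in self.subpulses if s.kind == "recovery_pore"]


def first_difference(normalized: NormalizedTrace | np.ndarray) -> np.ndarray:
    x = normalized.samples if isinstance(normalized, NormalizedTrace) else np.asarray(normalized)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return np.diff(x)


def find_edges(differences: np.ndarray, thresholds: ThresholdConfig,
               sample_rate_hz: float = 2500.0) -> list[EdgeEvent]:
    """Merge consecutive same-sign supra-threshold differences into edges.

    An edge's index is the extremum of the run; a positive difference in the
    normalized drop means the current is falling, i.e. the cell is *entering*
    a narrow segment.  Edges whose extremum also exceeds the contraction
    threshold are classed "contraction", the rest "pore".
    """
    d = np.asarray(differences)
    th = thresholds.pore_threshold
    active = np.abs(d) > th
    sign = np.sign(d)
    edges: list[EdgeEvent] = []
    i, n = 0, len(d)
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and active[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        run = d[i:j + 1]
        k = i + int(np.argmax(np.abs(run)))
        peak = float(d[k])
        edges.append(EdgeEvent(
            index=k, time_s=k / sample_rate_hz, peak=peak,
            step=float(run.sum()),
            direction="entering" if peak > 0 else "exiting",
            threshold_class=("contraction"
                             if abs(peak) > thresholds.contraction_threshold
                             else "pore")))
        i = j + 1
    return edges


def propose_windows(edges: list[EdgeEvent], geometry: DeviceGeometry,
                    max_gap_ms: float | None = None,
                    sample_rate_hz: float = 2500.0,
                    margin_samples: int = 45) -> list[CandidateWindow]:
    """Group edges separated by gaps shorter than ``max_gap_ms`` into windows."""
    if max_gap_ms is None:
        max_gap_ms = default_max_gap_ms(geometry)
    if not edges:
        return []
    gap_samples = max_gap_ms / 1000.0 * sample_rate_hz
    windows: list[CandidateWindow] = []
    group = [edges[0]]
    for e in edges[1:]:
        if e.index - group[-1].index < gap_samples:
            group.append(e)
        else:
            windows.append(_make_window(group, margin_samples))
            group = [e]
    windows.append(_make_window(group, margin_samples))
    for wid, w in enumerate(windows):
        w.window_id = wid
    return windows


def _make_window(group: list[EdgeEvent], margin: int) -> CandidateWindow:
    return CandidateWindow(start=max(0, group[0].index - margin),
                           end=group[-1].index + margin + 1,
                           edges=list(group))


def _refine_crossing(x: np.ndarray, idx: int, lo: float, hi: float,
                     rising: bool, halfwidth: int, fs: float) -> float:
    """Sub-sample time where x crosses (lo+hi)/2 near ``idx``."""
    half = 0.5 * (lo + hi)
    a = max(0, idx - halfwidth)
    b = min(len(x), idx + halfwidth + 1)
    seg = x[a:b]
    if rising:
        above = seg >= half
    else:
        above = seg <= half
    # first index in the search region at/after which the ramp has crossed;
    # scan from the center outwards is unnecessary: take the crossing closest
    # to the detected edge index
    cross = np.flatnonzero(above[1:] & ~above[:-1])
    if len(cross) == 0:
        return idx / fs
    j = cross[np.argmin(np.abs(cross + a - idx))]
    x0, x1 = seg[j], seg[j + 1]
    frac = 0.5 if x1 == x0 else (half - x0) / (x1 - x0)
    return (a + j + float(np.clip(frac, 0.0, 1.0))) / fs


def _local_offset(x: np.ndarray, window: CandidateWindow, halfwidth: int
                  ) -> tuple[float, float, float, float]:
    """Residual baseline offset in the quiet margins flanking a window.

    Detrending leaves a small slowly-varying residual in the normalized
    trace; the window's quiet lead-in and lead-out measure it directly.
    Returns (t_pre, offset_pre, t_post, offset_post) in samples, defining a
    linear offset across the window that is subtracted from plateau levels.
    """
    first, last = window.edges[0].index, window.edges[-1].index
    pre_a = max(0, first - 3 * halfwidth)
    pre_b = max(pre_a + 1, first - halfwidth)
    post_a = min(len(x) - 1, last + halfwidth)
    post_b = min(len(x), max(post_a + 1, last + 3 * halfwidth))
    off_pre = float(np.median(x[pre_a:pre_b]))
    off_post = float(np.median(x[post_a:post_b]))
    return 0.5 * (pre_a + pre_b), off_pre, 0.5 * (post_a + post_b), off_post


def segment_subpulses(window: CandidateWindow, normalized: NormalizedTrace,
                      geometry: DeviceGeometry,
                      thresholds: ThresholdConfig = ThresholdConfig(),
                      edge_refine_halfwidth: int = 14) -> SegmentedPulse:
    """Pair entering/exiting edges into subpulses and measure them.

    Edges must strictly alternate entering/exiting.  Kinds are assigned by
    order against the device's segment plan when the count matches; with a
    count mismatch the pulse is still measured (kinds left "unassigned") and
    the decision is deferred to :func:`auto_classify`.  Boundaries are
    refined to the half-amplitude crossing of the filtered ramp; amplitude is
    the mean normalized drop over the central 50 % of the subpulse, minus the
    residual baseline offset interpolated across the window from its quiet
    margins.
    """
    if len(window.edges) < 2:
        raise SegmentationError("window has fewer than 2 edges")
    pairs: list[tuple[EdgeEvent, EdgeEvent]] = []
    open_edge: EdgeEvent | None = None
    for e in window.edges:
        if e.direction == "entering":
            if open_edge is not None:
                raise SegmentationError("unpairable edges: two entering edges in a row")
            open_edge = e
        else:
            if open_edge is None:
                raise SegmentationError("unpairable edges: exiting edge without entry")
            pairs.append((open_edge, e))
            open_edge = None
    if open_edge is not None:
        raise SegmentationError("unpairable edges: unterminated subpulse")

    plan = segment_plan(geometry)
    kinds: list[str]
    if len(pairs) == plan.n_subpulses:
        kinds = list(plan.expected_kinds())
    else:
        kinds = ["unassigned"] * len(pairs)

    x = normalized.samples
    fs = normalized.sample_rate_hz
    t_pre, off_pre, t_post, off_post = _local_offset(x, window,
                                                     edge_refine_halfwidth)
    slope = (off_post - off_pre) / max(t_post - t_pre, 1.0)

    def offset_at(sample: float) -> float:
        return off_pre + slope * (sample - t_pre)

    subpulses: list[Subpulse] = []
    for kind, (e_in, e_out) in zip(kinds, pairs):
        i0, i1 = e_in.index, e_out.index
        span = max(i1 - i0, 1)
        c0 = i0 + int(0.25 * span)
        c1 = max(i0 + int(0.75 * span), c0 + 1)
        base = offset_at(0.5 * (i0 + i1))
        plateau = float(np.mean(x[c0:c1 + 1]))
        if plateau <= base:
            raise SegmentationError("non-positive subpulse plateau")
        t_in = _refine_crossing(x, i0, base, plateau, True,
                                edge_refine_halfwidth, fs)
        t_out = _refine_crossing(x, i1, base, plateau, False,
                                 edge_refine_halfwidth, fs)
        if t_out <= t_in:
            raise SegmentationError("degenerate subpulse after refinement")
        # re-measure the plateau over the refined central 50 %
        dur = t_out - t_in
        r0 = int(round((t_in + 0.25 * dur) * fs))
        r1 = int(round((t_in + 0.75 * dur) * fs))
        if r1 > r0:
            plateau = float(np.mean(x[r0:r1]))
        subpulses.append(Subpulse(kind=kind, start_s=t_in, end_s=t_out,
                                  amplitude=plateau - base,
                                  duration_ms=(t_out - t_in) * 1000.0))
    return SegmentedPulse(subpulses, window)


def auto_classify(window: CandidateWindow, segmented: SegmentedPulse | None,
                  geometry: DeviceGeometry,
                  config: DetectionConfig = DetectionConfig()
                  ) -> tuple[str, str | None]:
    """Classify a window: accept/pend it or reject it with a reason.

    Rejection reasons mirror the failure modes of real recordings: a
    ``missing subpulse`` (truncated/interfered pulse), ``overlap``
    (coincident cells merged into one window), ``unpairable edges``, a
    subpulse ``duration out of bounds`` for the plausible velocity range, or
    a contraction subpulse that does not look like one (``kind mismatch``).
    """
    plan = segment_plan(geometry)
    expected = plan.n_subpulses
    n_pairs_upper = len(window.edges) // 2
    if segmented is None:
        if n_pairs_upper < expected:
            return "auto_rejected", "missing subpulse"
        if n_pairs_upper > expected:
            return "auto_rejected", "overlap"
        return "auto_rejected", "unpairable edges"
    n = len(segmented.subpulses)
    if n < expected:
        return "auto_rejected", "missing subpulse"
    if n > expected:
        return "auto_rejected", "overlap"
    # duration plausibility per segment kind
    seg_lengths = {s.kind: s.length_um for s in plan.subpulse_segments}
    for sp in segmented.subpulses:
        lo = 0.2 * seg_lengths[sp.kind] / config.v_max_um_per_ms
        hi = 5.0 * seg_lengths[sp.kind] / config.v_min_um_per_ms
        if not lo <= sp.duration_ms <= hi:
            return "auto_rejected", "duration out of bounds"
    if segmented.contraction.amplitude < config.thresholds.contraction_threshold:
        return "auto_rejected", "kind mismatch"
    return ("accepted" if config.thresholds.auto_mode else "pending"), None


def auto_threshold(window: CandidateWindow, normalized: NormalizedTrace,
                   defaults: ThresholdConfig = ThresholdConfig()
                   ) -> ThresholdConfig:
    """Thresholds from peak heights in one window: 0.5x median edge magnitude.

    Pore and contraction classes are computed separately; both are floored
    at 3x the estimated noise sd of the first difference (robust MAD
    estimate over the window).  Falls back to the supplied defaults when the
    window has no resolvable entering edges.
    """
    entering = [e for e in window.edges if e.direction == "entering"]
    if not entering:
        return defaults
    d = np.diff(normalized.samples[window.start:window.end])
    noise_sd = 1.4826 * float(np.median(np.abs(d - np.median(d)))) if len(d) else 0.0
    floor = 3.0 * noise_sd
    pore_mags = [abs(e.peak) for e in entering if e.threshold_class == "pore"]
    con_mags = [abs(e.peak) for e in entering if e.threshold_class == "contraction"]
    pore_th = max(0.5 * float(np.median(pore_mags)), floor) if pore_mags \
        else defaults.pore_threshold
    con_th = max(0.5 * float(np.median(con_mags)), floor, pore_th) if con_mags \
        else max(defaults.contraction_threshold, pore_th)
    return ThresholdConfig(pore_threshold=pore_th,
                           contraction_threshold=con_th,
                           auto_mode=defaults.auto_mode)


@dataclass
class DetectionResult:
    accepted: list[SegmentedPulse]
    windows: list[CandidateWindow]
    config: DetectionConfig

    def to_table(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            rows.append({
                "window_id": w.window_id,
                "start_s": w.start_s,
                "n_edges": len(w.edges),
                "status": w.status,
                "rejection_reason": w.rejection_reason,
            })
        return pd.DataFrame(rows)


def _render_window_text(window: CandidateWindow,
                        segmented: SegmentedPulse | None) -> str:
    lines = [f"window {window.window_id}: {len(window.edges)} edges, "
             f"start {window.start_s:.3f} s"]
    if segmented is not None:
        for sp in segmented.subpulses:
            lines.append(f"  {sp.kind:15s} amp={sp.amplitude:.3e} "
                         f"dur={sp.duration_ms:.2f} ms")
    return "\n".join(lines)


def detect_cells(normalized: NormalizedTrace, geometry: DeviceGeometry,
                 config: DetectionConfig = DetectionConfig()
                 ) -> DetectionResult:
    """Full detection: differences -> edges -> windows -> subpulses.

    With ``refine_baseline`` (default) a first pass locates pulse windows,
    the baseline is re-fit with those windows masked out, and detection is
    repeated on the re-normalized trace.  In the default automated mode
    every window passing :func:`auto_classify` is accepted; in interactive
    mode pending windows are rendered as text and the user decides save/skip,
    mirroring the semi-manual review workflow.
    """
    if len(normalized.samples) < 2:
        return DetectionResult([], [], config)
    first = _detect_pass(normalized, geometry, config, interact=False)
    if not (config.refine_baseline and first.windows):
        if config.interactive:
            return _detect_pass(normalized, geometry, config, interact=True)
        return first
    from .preprocess import Trace, masked_baseline, normalize as _normalize
    x = normalized.samples
    mask = np.zeros(len(x), dtype=bool)
    hw = config.edge_refine_halfwidth
    for w in first.windows:
        if w.edges:
            a = max(0, w.edges[0].index - 2 * hw)
            b = min(len(x), w.edges[-1].index + 2 * hw + 1)
            mask[a:b] = True
    y = Trace(normalized.baseline * (1.0 - x), normalized.sample_rate_hz,
              dict(normalized.metadata))
    refined_base = masked_baseline(y, mask, config.refine_lambda)
    refined = _normalize(y, refined_base)
    return _detect_pass(refined, geometry, config, interact=config.interactive)


def _detect_pass(normalized: NormalizedTrace, geometry: DeviceGeometry,
                 config: DetectionConfig, interact: bool) -> DetectionResult:
    fs = normalized.sample_rate_hz
    d = first_difference(normalized)
    edges = find_edges(d, config.thresholds, fs)
    windows = propose_windows(edges, geometry, config.max_gap_ms, fs)
    accepted: list[SegmentedPulse] = []
    for w in windows:
        th = config.thresholds
        if config.auto_set_thresholds:
            th = auto_threshold(w, normalized, config.thresholds)
            local_edges = find_edges(d[w.start:w.end], th, fs)
            w = replace_window_edges(w, local_edges, fs)
        try:
            segmented = segment_subpulses(w, normalized, geometry, th,
                                          config.edge_refine_halfwidth)
        except SegmentationError:
            segmented = None
        status, reason = auto_classify(w, segmented, geometry,
                                       replace(config, thresholds=th))
        if status == "pending" and interact:
            print(_render_window_text(w, segmented))
            ans = input("save this cell? [y/n] ").strip().lower()
            status = "accepted" if ans.startswith("y") else "user_rejected"
        elif status == "pending":
            status = "accepted"
        w.status, w.rejection_reason = status, reason
        if status == "accepted" and segmented is not None:
            accepted.append(segmented)
    return DetectionResult(accepted, windows, config)


def replace_window_edges(window: CandidateWindow, local_edges: list[EdgeEvent],
                         fs: float) -> CandidateWindow:
    """Rebase edges detected inside a window slice back to absolute indices."""
    shifted = [EdgeEvent(index=e.index + window.start,
                         time_s=(e.index + window.start) / fs,
                         peak=e.peak, step=e.step, direction=e.direction,
                         threshold_class=e.threshold_class)
               for e in local_edges]
    return CandidateWindow(start=window.start, end=window.end,
                           edges=shifted, status=window.status,
                           rejection_reason=window.rejection_reason,
                           window_id=window.window_id)
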