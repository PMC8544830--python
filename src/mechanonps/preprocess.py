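"""Raw-current preprocessing chain.

The analysis operates on the *normalized drop-change* in current relative to
baseline.  Raw 50 kHz recordings are (1) low-pass filtered with a
200-sample-wide rectangular moving average, (2) downsampled to 2.5 kHz by
decimation, (3) detrended with asymmetric least squares (AsLS) smoothing, and
(4) normalized as ``x_t = (baseline_t - signal_t) / baseline_t`` so that a
cell occupying a pore produces a positive plateau of height ~ dI/I.

The whole chain is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded

__all__ = [
    "Trace",
    "NormalizedTrace",
    "PreprocessParams",
    "moving_average",
    "downsample",
    "asls_baseline",
    "masked_baseline",
    "normalize",
    "preprocess_pipeline",
]


@dataclass
class Trace:
    """Uniformly sampled current record (arbitrary units) with metadata."""

    samples: np.ndarray
    sample_rate_hz: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class NormalizedTrace:
    """Normalized current drop: ~0 off-pulse, positive during subpulses."""

    samples: np.ndarray
    sample_rate_hz: float
    baseline: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    ``asls_lambda`` is the second-difference smoothness penalty at the
    *downsampled* rate.  It sets the length scale over which the baseline can
    bend (roughly ``lambda**(1/4)`` samples); the default keeps the baseline
    stiff across an entire cell transit (~1 s) while still tracking
    multi-second drift.  ``asls_p`` is the weight given to samples *below*
    the running baseline estimate (pulses are downward in current), so the
    baseline tracks the upper envelope.
    """

    filter_width: int = 200
    downsample_factor: int = 20
    asls_lambda: float = 1e11
    asls_p: float = 0.01
    asls_iters: int = 10


def moving_average(trace: Trace, width: int = 200) -> Trace:
    """Centered rectangular moving average; edges use shrinking windows."""
    if width < 1 or int(width) != width:
        raise ValueError("filter width must be a positive integer")
    n = len(trace)
    if n < width:
        raise ValueError(f"trace length {n} shorter than filter width {width}")
    x = trace.samples
    half_lo = (width - 1) // 2
    half_hi = width // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    out = (cs[hi] - cs[lo]) / (hi - lo)
    return Trace(out, trace.sample_rate_hz, dict(trace.metadata))


def downsample(trace: Trace, factor: int = 20) -> Trace:
    """Keep every ``factor``-th sample starting at index 0."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("downsample factor must be a positive integer")
    factor = int(factor)
    return Trace(trace.samples[::factor].copy(),
                 trace.sample_rate_hz / factor, dict(trace.metadata))


def asls_baseline(trace: Trace, lambda_smooth: float = 1e11,
                  p_asym: float = 0.01, n_iter: int = 10) -> Trace:
    """Asymmetric least squares baseline tracking the upper envelope.

    Iteratively reweighted penalized least squares: minimize
    ``sum w_i (y_i - z_i)^2 + lambda * sum (d2 z)^2`` where after each pass
    samples above the baseline get weight ``1 - p_asym`` and samples below it
    (pulse samples) get ``p_asym``.  Iteration stops early once the weight
    assignment stabilizes.
    """
    y = trace.samples
    if not np.all(np.isfinite(y)):
        raise ValueError("trace contains non-finite samples")
    if not lambda_smooth > 0:
        raise ValueError("lambda_smooth must be positive")
    if not 0 < p_asym < 1:
        raise ValueError("p_asym must lie in (0, 1)")
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for a second-difference penalty")

    # banded upper form of lambda * D2'D2 (pentadiagonal, symmetric)
    ab0 = np.empty((3, n))
    ab0[0, :] = lambda_smooth * 1.0      # second super-diagonal
    ab0[1, :] = lambda_smooth * -4.0     # first super-diagonal
    ab0[2, :] = lambda_smooth * 6.0      # main diagonal
    ab0[2, 0] = ab0[2, -1] = lambda_smooth * 1.0
    ab0[2, 1] = ab0[2, -2] = lambda_smooth * 5.0
    ab0[1, 1] = ab0[1, -1] = lambda_smooth * -2.0

    # solving on the centered signal keeps the right-hand side small, which
    # sidesteps the poor conditioning of W + lambda D'D at large lambda
    mean = float(y.mean())
    yc = y - mean
    w = np.ones(n)
    z = yc
    for _ in range(max(1, int(n_iter))):
        ab = ab0.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * yc)
        w_new = np.where(yc >= z, 1.0 - p_asym, p_asym)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return Trace(z + mean, trace.sample_rate_hz, dict(trace.metadata))


def masked_baseline(trace: Trace, pulse_mask: np.ndarray,
                    lambda_smooth: float = 1e11) -> Trace:
    """Penalized least-squares baseline with pulse samples excluded.

    Samples where ``pulse_mask`` is True get zero weight, so the baseline
    bridges each pulse region with the minimum-curvature (cubic) segment
    anchored by the surrounding quiet data — markedly more accurate under
    long pulse trains than the asymmetric reweighting alone, which is why
    detection uses it as a second pass once pulse windows are known.
    """
    y = trace.samples
    n = len(y)
    if pulse_mask.shape != y.shape:
        raise ValueError("mask must match trace length")
    if pulse_mask.all():
        raise ValueError("mask excludes every sample")
    ab = np.empty((3, n))
    ab[0, :] = lambda_smooth * 1.0
    ab[1, :] = lambda_smooth * -4.0
    ab[2, :] = lambda_smooth * 6.0
    ab[2, 0] = ab[2, -1] = lambda_smooth * 1.0
    ab[2, 1] = ab[2, -2] = lambda_smooth * 5.0
    ab[1, 1] = ab[1, -1] = lambda_smooth * -2.0
    w = (~pulse_mask).astype(float)
    ab[2, :] += w
    mean = float(y[~pulse_mask].mean())
    z = solveh_banded(ab, w * (y - mean)) + mean
    return Trace(z, trace.sample_rate_hz, dict(trace.metadata))


def normalize(trace: Trace, baseline: Trace) -> NormalizedTrace:
    """Normalized drop-change in current relative to baseline."""
    b = baseline.samples
    if np.any(b <= 0):
        raise ValueError("baseline must be strictly positive everywhere")
    x = (b - trace.samples) / b
    return NormalizedTrace(x, trace.sample_rate_hz, b.copy(), dict(trace.metadata))


def preprocess_pipeline(trace: Trace,
                        params: PreprocessParams = PreprocessParams()
                        ) -> NormalizedTrace:
    """Filter -> downsample -> AsLS detrend -> normalize, in that order."""
    filt = moving_average(trace, params.filter_width)
    ds = downsample(filt, params.downsample_factor)
    base = asls_baseline(ds, params.asls_lambda, params.asls_p, params.asls_iters)
    return normalize(ds, base)
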