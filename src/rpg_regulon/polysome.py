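"""Polysome profile (A254 trace) segmentation and polysome:monosome ratio.

A sucrose-gradient absorbance trace is baseline-corrected (linear baseline
through the global minima of the first and last deciles, tolerant of edge
drift), smoothed with a moving average, and segmented at valleys between
prominent local maxima.  The first three peaks are labeled 40S, 60S and 80S
in gradient order; everything to the right of the 80S boundary is the
polysome region (the trace end closes it).  Areas are trapezoidal integrals
of the baseline-corrected signal, and the P:M ratio divides the polysome
area by the 80S (monosome) area - optionally by all three subunit peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "PolysomeTrace",
    "ProfileSegmentation",
    "parse_trace",
    "write_trace",
    "segment_profile",
    "pm_ratio",
]

MIN_POINTS = 20
SUBUNIT_LABELS = ("40S", "60S", "80S")


@dataclass(frozen=True)
class PolysomeTrace:
    position: np.ndarray
    a254: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        sig = np.asarray(self.a254, dtype=float)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "a254", sig)
        if pos.ndim != 1 or pos.shape != sig.shape:
            raise ValueError("position and a254 must be equal-length vectors")
        if len(pos) < MIN_POINTS:
            raise ValueError(f"trace needs >= {MIN_POINTS} points")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(sig))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class Peak:
    label: str
    left: float
    right: float
    apex: float
    area: float


@dataclass
class ProfileSegmentation:
    baseline: np.ndarray
    peaks: list           # ordered Peak list: 40S, 60S, 80S, polysome
    pm_ratio: float

    def peak(self, label: str) -> Peak:
        for p in self.peaks:
            if p.label == label:
                return p
        raise KeyError(label)


def parse_trace(path) -> PolysomeTrace:
    """Read a two-column (position, A254) text trace; '#' lines are comments."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("trace file must have two numeric columns")
    return PolysomeTrace(data[:, 0], data[:, 1])


def write_trace(trace: PolysomeTrace, path) -> None:
    np.savetxt(path, np.column_stack([trace.position, trace.a254]),
               delimiter="\t", header="position\ta254")


def _linear_baseline(trace: PolysomeTrace) -> np.ndarray:
    n = len(trace.position)
    decile = max(1, n // 10)
    i0 = int(np.argmin(trace.a254[:decile]))
    i1 = n - decile + int(np.argmin(trace.a254[n - decile:]))
    x0, y0 = trace.position[i0], trace.a254[i0]
    x1, y1 = trace.position[i1], trace.a254[i1]
    if x1 == x0:
        return np.full(n, min(y0, y1))
    slope = (y1 - y0) / (x1 - x0)
    return y0 + slope * (trace.position - x0)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad: pad + len(values)]
    return out


def segment_profile(trace: PolysomeTrace, smoothing_window: int = 5,
                    min_prominence: float = 0.05,
                    monosome: str = "80S") -> ProfileSegmentation:
    """Segment a trace into 40S/60S/80S/polysome regions and compute P:M.

    ``min_prominence`` is relative to the maximum baseline-corrected signal.
    ``monosome`` chooses the P:M denominator: the 80S peak (default) or
    'all_subunits' for 40S+60S+80S.
    """
    baseline = _linear_baseline(trace)
    corrected = trace.a254 - baseline
    smoothed = _smooth(corrected, smoothing_window)
    peak_idx, _ = find_peaks(smoothed,
                             prominence=min_prominence * smoothed.max())
    if len(peak_idx) < 3:
        raise ValueError(f"only {len(peak_idx)} peaks detected; need >= 3")

    # boundaries: the minimum of the smoothed signal between adjacent apexes
    first3 = peak_idx[:3]
    bounds = [0]
    for left_apex, right_apex in zip(peak_idx[:2], peak_idx[1:3]):
        valley = left_apex + int(np.argmin(smoothed[left_apex:right_apex + 1]))
        bounds.append(valley)
    if len(peak_idx) >= 4:
        a3, a4 = peak_idx[2], peak_idx[3]
        bounds.append(a3 + int(np.argmin(smoothed[a3:a4 + 1])))
    else:
        # no separate polysome apex: 80S ends at its right-hand minimum
        a3 = peak_idx[2]
        bounds.append(a3 + int(np.argmin(smoothed[a3:])))

    x = trace.position
    peaks = []
    for i, label in enumerate(SUBUNIT_LABELS):
        lo, hi = bounds[i], bounds[i + 1]
        seg = slice(lo, hi + 1)
        area = float(np.trapezoid(corrected[seg], x[seg]))
        apex = float(x[first3[i]])
        peaks.append(Peak(label, float(x[lo]), float(x[hi]), apex, max(area, 0.0)))

    poly_lo = bounds[3]
    seg = slice(poly_lo, len(x))
    poly_area = float(np.trapezoid(corrected[seg], x[seg]))
    poly_apex_idx = poly_lo + int(np.argmax(smoothed[poly_lo:]))
    peaks.append(Peak("polysome", float(x[poly_lo]), float(x[-1]),
                      float(x[poly_apex_idx]), max(poly_area, 0.0)))

    if monosome == "80S":
        mono_area = peaks[2].area
    elif monosome == "all_subunits":
        mono_area = sum(p.area for p in peaks[:3])
    else:
        raise ValueError("monosome must be '80S' or 'all_subunits'")
    if mono_area <= 0:
        raise ValueError("monosome area is zero or negative")
    ratio = peaks[3].area / mono_area
    return ProfileSegmentation(baseline, peaks, float(ratio))


def pm_ratio(segmentation: ProfileSegmentation) -> float:
    """Polysome:monosome area ratio of a segmentation."""
    return segmentation.pm_ratio


def plot_profile(trace: PolysomeTrace, segmentation: ProfileSegmentation,
                 path) -> None:
    """Save a figure of the trace with baseline, boundaries and peak labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(trace.position, trace.a254, lw=1.0, color="navy", label="A254")
    ax.plot(trace.position, segmentation.baseline, lw=0.8, ls="--",
            color="grey", label="baseline")
    for peak in segmentation.peaks:
        ax.axvline(peak.left, color="0.8", lw=0.6)
        ax.annotate(peak.label, (peak.apex, ax.get_ylim()[1] * 0.95),
                    ha="center", fontsize=8)
    ax.axvline(segmentation.peaks[-1].right, color="0.8", lw=0.6)
    ax.set_xlabel("gradient position / fraction")
    ax.set_ylabel("A254 (a.u.)")
    ax.set_title(f"P:M ratio = {segmentation.pm_ratio:.2f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
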