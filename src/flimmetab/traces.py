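"""Stimulus-locked quantification of ROI time series.

Operates on per-ROI traces of fitted lifetimes (tau8, ns), intensity ratios
or Delta-F/F percentages, sampled regularly (2-photon frames) or irregularly
(widefield slow cadence with a fast burst around each stimulus).  Provides
the display rebinning used for lifetime series (20-frame averages, single
frames for fast channels in the 10 s after a stimulus), baseline/peak/delta
transient metrics, the Peredox-to-RCaMP response ratio, trapezoidal
area-under-curve over a fixed span, threshold-based inclusion filters and
detection of sudden irreversible baseline steps (an exclusion criterion).

Time convention: stimulus onset defines t = 0 for its train; all windows
are half-open [start, end) in seconds relative to the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LifetimeTrace",
    "TransientMetrics",
    "rebin_trace",
    "transient_metrics",
    "peredox_rcamp_ratio",
    "apply_inclusion_filters",
    "detect_baseline_step",
    "dff_trace",
    "auc_overshoot",
    "fret_ratio_change",
]


@dataclass(frozen=True)
class LifetimeTrace:
    """Time-stamped per-ROI series with stimulus annotations."""

    timestamps: np.ndarray          # s, strictly increasing
    values: np.ndarray              # tau8 (ns), ratio, %dF/F or [O2] (uM)
    roi_id: str = "roi0"
    label: str = ""                 # channel / readout name
    stim_onsets: tuple[float, ...] = ()

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("timestamps and values must be matching 1-D arrays")
        if len(t) == 0:
            raise ValueError("empty trace")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "stim_onsets",
                           tuple(float(s) for s in self.stim_onsets))

    def __len__(self) -> int:
        return len(self.timestamps)

    def window(self, start: float, end: float) -> np.ndarray:
        """Boolean mask of samples with start <= t < end."""
        return (self.timestamps >= start) & (self.timestamps < end)


@dataclass(frozen=True)
class TransientMetrics:
    """Baseline/peak quantification of one stimulus on one trace."""

    roi_id: str
    stim_time: float
    baseline: float
    peak: float
    delta: float                    # peak - baseline, native units
    dff: float | None               # 100*delta/baseline, None if baseline <= 0
    time_to_peak: float             # s after stimulus
    recovery_time: float | None     # s after stimulus; None if no return
    auc: float | None = None        # % * min, filled by auc_overshoot
    included: bool = True
    reasons: tuple[str, ...] = ()


def rebin_trace(trace: LifetimeTrace, window: int = 20,
                fast_span: float = 10.0, fast: bool = False) -> LifetimeTrace:
    """Display rebinning: non-overlapping ``window``-frame means.

    For fast channels (``fast=True``, e.g. the Ca2+ sensor) samples within
    ``fast_span`` seconds after any stimulus are kept as single frames, so
    rapid spikes are not averaged away.  Rebinned timestamps are the mean
    time of the frames in each window; a trailing partial window is
    averaged as-is.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return trace
    t, v = trace.timestamps, trace.values
    in_fast = np.zeros(len(t), dtype=bool)
    if fast:
        for s in trace.stim_onsets:
            in_fast |= (t >= s) & (t < s + fast_span)
    out_t, out_v = [], []
    i = 0
    n = len(t)
    while i < n:
        if in_fast[i]:
            out_t.append(t[i])
            out_v.append(v[i])
            i += 1
            continue
        # group up to `window` consecutive slow frames
        j = i
        while j < n and not in_fast[j] and j - i < window:
            j += 1
        out_t.append(t[i:j].mean())
        out_v.append(v[i:j].mean())
        i = j
    return replace(trace, timestamps=np.asarray(out_t), values=np.asarray(out_v))


def transient_metrics(trace: LifetimeTrace, stim_time: float,
                      baseline_window: tuple[float, float] = (-60.0, 0.0),
                      peak_window: tuple[float, float] = (0.0, 90.0),
                      polarity: str = "positive",
                      recovery_fraction: float = 0.1) -> TransientMetrics:
    """Baseline, peak, delta and timing of one stimulus-locked transient.

    ``baseline_window`` and ``peak_window`` are in seconds relative to the
    stimulus; the baseline is the mean over its window, the peak the
    extremum of the requested polarity in the peak window.  The recovery
    time is the first post-peak time at which the trace re-enters the band
    baseline +/- ``recovery_fraction * |delta|``; None if it never does
    within the trace.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError("polarity must be 'positive' or 'negative'")
    b0, b1 = (stim_time + w for w in baseline_window)
    p0, p1 = (stim_time + w for w in peak_window)
    if b1 > stim_time + 1e-9:
        raise ValueError("baseline window must be wholly pre-stimulus")
    bmask = trace.window(b0, b1)
    pmask = trace.window(p0, p1)
    if not bmask.any() or not pmask.any():
        raise ValueError("baseline or peak window contains no samples")
    baseline = float(trace.values[bmask].mean())
    pv = trace.values[pmask]
    pt = trace.timestamps[pmask]
    idx = int(np.argmax(pv)) if polarity == "positive" else int(np.argmin(pv))
    peak = float(pv[idx])
    t_peak = float(pt[idx])
    delta = peak - baseline
    dff = 100.0 * delta / baseline if baseline > 0 else None

    recovery = None
    band = recovery_fraction * abs(delta)
    after = trace.timestamps > t_peak
    if delta != 0 and after.any():
        back = np.abs(trace.values[after] - baseline) <= band
        if back.any():
            recovery = float(trace.timestamps[after][np.argmax(back)] - stim_time)
    return TransientMetrics(roi_id=trace.roi_id, stim_time=stim_time,
                            baseline=baseline, peak=peak, delta=delta,
                            dff=dff, time_to_peak=t_peak - stim_time,
                            recovery_time=recovery)


def peredox_rcamp_ratio(peredox_m: TransientMetrics,
                        rcamp_m: TransientMetrics) -> float:
    """Metabolic-over-Ca2+ response magnitude, DeltaPeredox/DeltaRCaMP."""
    if rcamp_m.delta <= 0:
        raise ValueError("RCaMP delta must be positive for a defined ratio")
    return peredox_m.delta / rcamp_m.delta


def apply_inclusion_filters(cells: dict[str, TransientMetrics],
                            rules: dict[str, float]):
    """Threshold filters with machine-readable exclusion reasons.

    ``rules`` maps a TransientMetrics field name to its minimum value;
    thresholds are inclusive (a response exactly at threshold is kept,
    matching the printed ">= 0.05 ns" and ">= 1 %" criteria).  Returns
    ``(included_ids, updated_cells)`` where every excluded cell carries
    reasons like ``"delta<0.05"``.
    """
    valid = set(TransientMetrics.__dataclass_fields__)
    for fname in rules:
        if fname not in valid:
            raise KeyError(f"unknown metric field in rule: {fname!r}")
    out = {}
    included = []
    for cid, m in cells.items():
        reasons = []
        for fname, thr in rules.items():
            val = getattr(m, fname)
            if val is None or not val >= thr:
                reasons.append(f"{fname}<{thr:g}")
        ok = not reasons
        out[cid] = replace(m, included=ok, reasons=tuple(reasons))
        if ok:
            included.append(cid)
    return included, out


def detect_baseline_step(trace: LifetimeTrace, step_threshold: float = 0.1,
                         persistence: float = 60.0,
                         return_fraction: float = 0.5):
    """Flag a sudden, irreversible rise of the baseline level.

    Scans consecutive samples for a positive jump >= ``step_threshold``
    after which the trace never returns below
    ``pre_level + return_fraction * step`` within ``persistence`` seconds
    (cells showing such steps are excluded from analysis).  Returns
    ``(flagged, step_time)`` with ``step_time=None`` when clean.
    """
    t, v = trace.timestamps, trace.values
    if t[-1] - t[0] <= persistence:
        raise ValueError("trace shorter than the persistence window")
    dv = np.diff(v)
    for i in np.nonzero(dv >= step_threshold)[0]:
        pre = v[i]
        floor = pre + return_fraction * dv[i]
        horizon = (t > t[i]) & (t <= t[i + 1] + persistence)
        if horizon.any() and np.all(v[horizon] >= floor):
            return True, float(t[i + 1])
    return False, None


def dff_trace(raw: LifetimeTrace,
              baseline_window: tuple[float, float]) -> LifetimeTrace:
    """Percent fluorescence change over the pre-stimulus baseline mean."""
    mask = raw.window(*baseline_window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    f0 = raw.values[mask].mean()
    if f0 <= 0:
        raise ValueError("baseline mean must be positive for dF/F")
    return replace(raw, values=100.0 * (raw.values - f0) / f0,
                   label=(raw.label + "_dff").lstrip("_"))


def auc_overshoot(trace: LifetimeTrace, start: float,
                  span: float = 120.0) -> float:
    """Trapezoidal area of a %dF/F trace over [start, start+span), in %*min.

    Integrates on the actual (possibly irregular) timestamps without
    resampling; the boundary points are obtained by linear interpolation so
    the area covers exactly the requested span.
    """
    t, v = trace.timestamps, trace.values
    end = start + span
    if start < t[0] - 1e-9 or end > t[-1] + 1e-9:
        raise ValueError("trace does not cover the integration span")
    inner = (t > start) & (t < end)
    tt = np.concatenate(([start], t[inner], [end]))
    vv = np.concatenate(([np.interp(start, t, v)], v[inner],
                         [np.interp(end, t, v)]))
    return float(np.trapezoid(vv, tt) / 60.0)


def fret_ratio_change(donor: LifetimeTrace, acceptor: LifetimeTrace,
                      baseline_window: tuple[float, float]) -> LifetimeTrace:
    """Percent change of the donor/acceptor intensity ratio over baseline.

    The FRET readout of the pyruvate sensor: R = donor/acceptor, reported
    as 100*(R_t/R_baseline - 1).
    """
    if not np.array_equal(donor.timestamps, acceptor.timestamps):
        raise ValueError("donor and acceptor must share timestamps")
    if np.any(acceptor.values <= 0):
        raise ValueError("acceptor intensity must be positive throughout")
    r = donor.values / acceptor.values
    mask = donor.window(*baseline_window)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    r0 = r[mask].mean()
    if r0 <= 0:
        raise ValueError("baseline ratio must be positive")
    return replace(donor, values=100.0 * (r / r0 - 1.0), label="fret_ratio_change")
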