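"""Synthetic acquisitions with known ground truth.

Emulates the two acquisition modalities of a dual-biosensor brain-slice
experiment:

* 2-photon FLIM: per-frame TCSPC photon histograms for a green NADH/NAD+
  sensor (Peredox, slow lifetime transients) and a red Ca2+ sensor
  (RCaMP1h, fast spikes), time-locked to electrical stimulus trains of
  25–200 pulses at 50 Hz, with cross-channel bleedthrough at configurable
  coefficients.
* Widefield autofluorescence: NAD(P)H dip-then-overshoot and mirrored FAD+
  waveforms plus a red Ca2+ channel, sampled at 1 frame / 2 s with a 6 Hz
  burst for 10 s starting 2 s before each stimulus; and Clark-electrode O2
  traces on a drifting baseline with two-point calibration standards.

Every generator is a pure function of its parameters and seed.  Photon
arrival times are sampled exactly from the generative model (Gaussian IRF
jitter plus exponential decay, wrapped modulo the laser period), so the
histograms follow the same closed-form wrapped exGaussian the fitting
module evaluates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flim import DecayParams, PhotonHistogram, single_exp_for_tau8, tau8
from .unmix import BleedthroughParams

__all__ = [
    "AcquisitionConfig",
    "StimulusProtocol",
    "GroundTruthWaveform",
    "DualSensorExperiment",
    "WidefieldTraceSet",
    "O2Trace",
    "gen_photon_histogram",
    "gen_dual_sensor_experiment",
    "gen_autofluorescence_traces",
    "gen_o2_trace",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing of one acquisition modality.

    ``laser_period`` 12.5 ns corresponds to the 80 MHz pulsed laser;
    ``burst_span`` is the fast-acquisition window relative to each stimulus
    (widefield: 6 Hz for 10 s starting 2 s before the pulse train).
    """

    laser_period: float = 12.5          # ns
    irf_sigma: float = 0.2              # ns
    irf_t0: float = 2.0                 # ns
    bin_width: float = 0.1              # ns
    n_bins: int = 125
    frame_interval: float = 0.5         # s
    burst_rate: float = 6.0             # Hz
    burst_span: tuple[float, float] = (-2.0, 8.0)   # s, relative to stimulus

    def __post_init__(self):
        if self.laser_period <= 0:
            raise ValueError("laser_period must be positive")
        if self.n_bins * self.bin_width > self.laser_period * (1 + 1e-9):
            raise ValueError("histogram span n_bins*bin_width exceeds laser_period")
        if not (self.burst_span[0] <= 0.0 <= self.burst_span[1]):
            raise ValueError("burst_span must contain the stimulus time (t=0)")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @classmethod
    def two_photon(cls, **kw) -> "AcquisitionConfig":
        return cls(**kw)

    @classmethod
    def widefield(cls, **kw) -> "AcquisitionConfig":
        kw.setdefault("frame_interval", 2.0)
        return cls(**kw)


@dataclass(frozen=True)
class StimulusProtocol:
    """Electrical stimulation: trains of brief pulses at a fixed rate."""

    onsets: tuple[float, ...]           # s, train start times
    pulses_per_train: int = 100
    pulse_rate: float = 50.0            # Hz
    pulse_width_ms: float = 0.1

    def __post_init__(self):
        onsets = tuple(float(t) for t in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if self.pulses_per_train < 1:
            raise ValueError("pulses_per_train must be a positive integer")
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        dur = self.train_duration
        for a, b in zip(onsets, onsets[1:]):
            if b <= a + dur:
                raise ValueError("stimulus trains overlap or are unordered")

    @property
    def train_duration(self) -> float:
        return self.pulses_per_train / self.pulse_rate


def _alpha_shape(t, rise_tau, decay_tau):
    """Difference-of-exponentials transient normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("time constants must be positive")
    if abs(decay_tau - rise_tau) < 1e-12 * decay_tau:
        tp = decay_tau
        h = (t / tp) * np.exp(1.0 - t / tp)
    else:
        tp = math.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
        norm = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
        h = (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / norm
    return np.where(t > 0, h, 0.0)


@dataclass(frozen=True)
class GroundTruthWaveform:
    """Programmed time course of one readout.

    ``amplitude`` is the peak of the slow (alpha-shaped) phase, in the
    readout's native units (ns for lifetimes, % for Delta-F/F, uM for O2).
    For the biphasic autofluorescence kinds (``nadph``, ``fad``) a brief
    Gaussian "dip" of depth ``dip_amplitude`` and FWHM-like duration
    ``dip_duration`` precedes the slow phase, which starts at
    ``onset + dip_duration``; the fad waveform is the mirror image
    (oxidative fast phase up, reductive slow phase down).
    """

    kind: str                            # peredox|rcamp|nadph|fad|o2|pyronic_ratio
    baseline: float
    onset: float = 0.0                   # s; None-like large onset => flat
    amplitude: float = 0.0               # peak of the slow/alpha phase
    rise_tau: float = 5.0                # s
    decay_tau: float = 30.0              # s
    dip_amplitude: float = 0.0           # depth of the fast phase (>= 0)
    dip_duration: float = 2.0            # s

    def __post_init__(self):
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("decay constants must be positive")
        if self.kind in ("nadph", "fad") and self.dip_amplitude and self.dip_duration <= 0:
            raise ValueError("the dip must precede the overshoot: dip_duration > 0")

    def shape(self, t, stim_onsets=(None,)):
        """Transient deviation from baseline, summed over stimuli, in
        amplitude units."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for s in stim_onsets:
            t0 = self.onset if s is None else s
            rel = t - t0
            if self.kind in ("nadph", "fad"):
                sign = 1.0 if self.kind == "nadph" else -1.0
                center = 0.5 * self.dip_duration
                sd = self.dip_duration / 4.0
                if self.dip_amplitude:
                    out += -sign * self.dip_amplitude * np.exp(
                        -0.5 * ((rel - center) / sd) ** 2) * (rel > 0)
                out += sign * self.amplitude * _alpha_shape(
                    rel - self.dip_duration, self.rise_tau, self.decay_tau)
            else:
                out += self.amplitude * _alpha_shape(rel, self.rise_tau, self.decay_tau)
        return out

    def value(self, t, stim_onsets=(None,)):
        """baseline + transient, in native units (lifetime, uM, ratio)."""
        return self.baseline + self.shape(t, stim_onsets)

    def intensity(self, t, stim_onsets=(None,)):
        """Fluorescence in A.U. when amplitudes are Delta-F/F percentages."""
        return self.baseline * (1.0 + self.shape(t, stim_onsets) / 100.0)


# ---------------------------------------------------------------------------
# photon histograms

def gen_photon_histogram(truth: DecayParams, n_photons: int,
                         acq: AcquisitionConfig, seed,
                         roi_id: str = "roi0", frame_index: int = 0,
                         channel: str = "green") -> PhotonHistogram:
    """Sample a TCSPC histogram from a two-exponential decay with Gaussian IRF.

    Each photon draws its component by amplitude fraction, an IRF jitter
    from N(t0, sigma) and a decay delay from Exp(tau); the arrival time is
    wrapped modulo the laser period, exactly as re-excitation by the
    periodic pulse train dictates.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    total = truth.total_amplitude
    if total <= 0:
        raise ValueError("amplitudes must sum to a positive total")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n1 = rng.binomial(n_photons, truth.a1 / total)
    taus = np.empty(n_photons)
    taus[:n1] = truth.tau1
    taus[n1:] = truth.tau2
    t = truth.t0 + rng.normal(0.0, truth.sigma, n_photons) \
        + rng.exponential(1.0, n_photons) * taus
    t = np.mod(t, acq.laser_period)
    counts, _ = np.histogram(t, bins=acq.bin_edges)
    return PhotonHistogram(bin_edges=acq.bin_edges, counts=counts,
                           laser_period=acq.laser_period, roi_id=roi_id,
                           frame_index=frame_index, channel=channel)


# ---------------------------------------------------------------------------
# dual-sensor 2p-FLIM experiment

@dataclass(frozen=True)
class DualSensorExperiment:
    """Per-frame two-channel histograms plus the programmed ground truth."""

    acq: AcquisitionConfig
    protocol: StimulusProtocol
    frame_times: np.ndarray                  # s
    counts: np.ndarray                       # [frame, channel(0=green,1=red), bin]
    bin_edges: np.ndarray                    # ns
    truth: pd.DataFrame                      # per-frame programmed values
    bleed: BleedthroughParams
    roi_id: str = "cell0"

    def histogram(self, frame: int, channel: int) -> PhotonHistogram:
        return PhotonHistogram(bin_edges=self.bin_edges,
                               counts=self.counts[frame, channel],
                               laser_period=self.acq.laser_period,
                               roi_id=self.roi_id, frame_index=frame,
                               channel="green" if channel == 0 else "red")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def gen_dual_sensor_experiment(protocol: StimulusProtocol,
                               peredox_truth: GroundTruthWaveform,
                               rcamp_truth: GroundTruthWaveform,
                               bleed: BleedthroughParams,
                               photons_per_frame: int,
                               acq: AcquisitionConfig,
                               seed,
                               duration: float = 240.0,
                               green_intensity: float = 1.0,
                               red_intensity: float = 0.6,
                               tau8_window: float = 8.0,
                               roi_id: str = "cell0") -> DualSensorExperiment:
    """Simulate a dual-expression FLIM session frame by frame.

    The two waveforms program the *tau8* time course of each sensor; each
    frame's lifetime is realized as the single-exponential decay with that
    tau8.  Channel histograms mix the resident sensor with the other
    sensor's bleedthrough species: in the green channel the red sensor
    contributes ``r_into_g * red_intensity`` photons of a fixed
    short-lifetime species; in the red channel the green sensor leaks
    ``g_into_r * green_intensity`` photons carrying its own (time-varying)
    lifetime.  Photon totals per channel scale with the measured (mixed)
    intensity, ``photons_per_frame`` photons per unit intensity.
    """
    if photons_per_frame < 1:
        raise ValueError("photons_per_frame must be >= 1")
    rng = np.random.default_rng(seed)
    frame_times = np.arange(0.0, duration, acq.frame_interval)
    stims = protocol.onsets
    tau_c = single_exp_for_tau8(bleed.contaminant_tau8, tau8_window)

    # programmed tau8 -> realized single-exponential lifetime, interpolated
    # from a dense inversion table (the mapping is smooth and monotone)
    def _realize(targets):
        grid = np.linspace(min(targets.min(), 0.3), targets.max() + 1e-6, 64)
        inv = np.array([single_exp_for_tau8(g, tau8_window) for g in grid])
        return np.interp(targets, grid, inv)

    tau8_p = peredox_truth.value(frame_times, stims)
    tau8_r = rcamp_truth.value(frame_times, stims)
    tau_p = _realize(tau8_p)
    tau_r = _realize(tau8_r)

    g_mix = green_intensity + bleed.r_into_g * red_intensity
    r_mix = red_intensity + bleed.g_into_r * green_intensity
    n_g = int(round(photons_per_frame * g_mix))
    n_r = int(round(photons_per_frame * r_mix))

    n_bins = acq.n_bins
    counts = np.zeros((len(frame_times), 2, n_bins), dtype=np.int64)
    rows = []
    for i, t in enumerate(frame_times):
        green = DecayParams(t0=acq.irf_t0, sigma=acq.irf_sigma,
                            a1=green_intensity, a2=bleed.r_into_g * red_intensity,
                            tau1=tau_p[i], tau2=tau_c)
        red = DecayParams(t0=acq.irf_t0, sigma=acq.irf_sigma,
                          a1=red_intensity, a2=bleed.g_into_r * green_intensity,
                          tau1=tau_r[i], tau2=tau_p[i])
        counts[i, 0] = gen_photon_histogram(green, n_g, acq, rng).counts
        counts[i, 1] = gen_photon_histogram(red, n_r, acq, rng).counts
        rows.append((t, tau8_p[i], tau8_r[i], tau8(green, tau8_window),
                     tau8(red, tau8_window)))
    truth = pd.DataFrame(rows, columns=["time_s", "tau8_peredox", "tau8_rcamp",
                                        "tau8_green_mixed", "tau8_red_mixed"])
    truth["intensity_green"] = green_intensity
    truth["intensity_red"] = red_intensity
    return DualSensorExperiment(acq=acq, protocol=protocol,
                                frame_times=frame_times, counts=counts,
                                bin_edges=acq.bin_edges, truth=truth,
                                bleed=bleed, roi_id=roi_id)


# ---------------------------------------------------------------------------
# widefield autofluorescence

@dataclass(frozen=True)
class WidefieldTraceSet:
    """Irregularly sampled three-channel ROI fluorescence with ground truth."""

    frames: pd.DataFrame     # columns: time_s, channel, value (A.U.)
    truth: pd.DataFrame      # columns: time_s, channel, dff_percent
    protocol: StimulusProtocol
    burst_samples_per_stim: int


def widefield_timestamps(protocol: StimulusProtocol, acq: AcquisitionConfig,
                         duration: float) -> tuple[np.ndarray, int]:
    """Slow-cadence grid with a fast burst around each stimulus.

    Baseline frames every ``acq.frame_interval`` (2 s); from
    ``stim + burst_span[0]`` the camera runs at ``burst_rate`` for the span
    (10 s -> exactly 60 frames), then the slow cadence resumes.  Slow frames
    that would fall inside a burst window are replaced by the burst frames.
    """
    span0, span1 = acq.burst_span
    width = span1 - span0
    n_burst = int(round(width * acq.burst_rate))
    windows = [(s + span0, s + span1) for s in protocol.onsets]
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if b0 < a1:
            raise ValueError("burst windows of consecutive stimuli overlap")
    slow = np.arange(0.0, duration, acq.frame_interval)
    keep = np.ones(len(slow), dtype=bool)
    for w0, w1 in windows:
        keep &= ~((slow >= w0) & (slow < w1))
    parts = [slow[keep]]
    for w0, _ in windows:
        parts.append(w0 + np.arange(n_burst) / acq.burst_rate)
    ts = np.concatenate(parts)
    ts = np.unique(ts)
    ts = ts[ts < duration]
    return ts, n_burst


def gen_autofluorescence_traces(protocol: StimulusProtocol,
                                nadph_truth: GroundTruthWaveform,
                                fad_truth: GroundTruthWaveform,
                                rcamp_truth: GroundTruthWaveform,
                                noise_sd: float,
                                acq: AcquisitionConfig,
                                seed,
                                duration: float = 300.0) -> WidefieldTraceSet:
    """Three-channel widefield traces on the burst-augmented time base.

    ``noise_sd`` is additive Gaussian noise on the Delta-F/F (%) scale;
    waveform amplitudes are interpreted as Delta-F/F percentages on each
    channel's baseline fluorescence (A.U.).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ts, n_burst = widefield_timestamps(protocol, acq, duration)
    rng = np.random.default_rng(seed)
    frames = []
    truths = []
    for name, wf in (("nadph", nadph_truth), ("fad", fad_truth),
                     ("rcamp", rcamp_truth)):
        dff = wf.shape(ts, protocol.onsets)
        noisy = wf.baseline * (1.0 + (dff + rng.normal(0.0, noise_sd, len(ts))) / 100.0)
        frames.append(pd.DataFrame({"time_s": ts, "channel": name, "value": noisy}))
        truths.append(pd.DataFrame({"time_s": ts, "channel": name,
                                    "dff_percent": dff}))
    return WidefieldTraceSet(frames=pd.concat(frames, ignore_index=True),
                             truth=pd.concat(truths, ignore_index=True),
                             protocol=protocol,
                             burst_samples_per_stim=n_burst)


# ---------------------------------------------------------------------------
# O2 microsensor

@dataclass(frozen=True)
class O2Trace:
    """Raw electrode series plus the calibration standards and the truth."""

    time_s: np.ndarray
    raw: np.ndarray
    truth_uM: np.ndarray
    signal_zero: float
    signal_high: float
    conc_high: float


def gen_o2_trace(baseline_uM: float,
                 dip: GroundTruthWaveform | None,
                 drift_rate: float,
                 cal_signals: tuple[float, float],
                 seed,
                 conc_high: float = 220.0,
                 duration: float = 600.0,
                 sample_rate: float = 1.0,
                 noise_sd: float = 0.0,
                 baseline_step: tuple[float, float] | None = None) -> O2Trace:
    """Clark-electrode series: affine map of true [O2] plus drift and noise.

    ``cal_signals = (signal_zero, signal_high)`` are the raw readings at the
    anoxic standard (0 uM) and at the high standard (``conc_high`` uM, the
    20 % O2 ACSF).  ``baseline_step=(t_event, fraction)`` scales the
    baseline by (1 + fraction) from t_event on, emulating a sustained shift
    in tissue oxygenation.  ``drift_rate`` is raw units per second.
    """
    s0, s1 = cal_signals
    if s0 == s1:
        raise ValueError("degenerate calibration: identical standard signals")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    truth = np.full_like(t, float(baseline_uM))
    if baseline_step is not None:
        t_ev, frac = baseline_step
        truth = np.where(t >= t_ev, baseline_uM * (1.0 + frac), truth)
    if dip is not None:
        truth = truth + dip.shape(t)
    gain = (s1 - s0) / conc_high
    raw = s0 + gain * truth + drift_rate * t
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, len(t))
    return O2Trace(time_s=t, raw=raw, truth_uM=truth,
                   signal_zero=s0, signal_high=s1, conc_high=conc_high)
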