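"""Synthetic generators: determinism, photon statistics, cadence, O2."""

import numpy as np
import pytest

from flimmetab.flim import DecayParams, fit_histogram
from flimmetab.oxygen import CalibrationPair, calibrate
from flimmetab.synth import (AcquisitionConfig, GroundTruthWaveform,
                             StimulusProtocol, gen_autofluorescence_traces,
                             gen_dual_sensor_experiment, gen_o2_trace,
                             gen_photon_histogram, widefield_timestamps)
from flimmetab.unmix import BleedthroughParams

T = 12.5


# --- photon histograms --------------------------------------------------

def test_histogram_conserves_photon_count(acq):
    p = DecayParams(2.0, 0.2, 1.0, 1.0, 0.5, 2.5)
    h = gen_photon_histogram(p, 12345, acq, seed=0)
    assert h.counts.sum() == 12345


def test_same_seed_same_histogram(acq):
    p = DecayParams(2.0, 0.2, 3.0, 1.0, 0.5, 2.5)
    h1 = gen_photon_histogram(p, 10000, acq, seed=42)
    h2 = gen_photon_histogram(p, 10000, acq, seed=42)
    assert np.array_equal(h1.counts, h2.counts)
    h3 = gen_photon_histogram(p, 10000, acq, seed=43)
    assert not np.array_equal(h1.counts, h3.counts)


def test_zero_photons_forbidden(acq):
    p = DecayParams(2.0, 0.2, 1.0, 0.0, 2.0, 2.0)
    with pytest.raises(ValueError):
        gen_photon_histogram(p, 0, acq, seed=0)


def test_empirical_mean_matches_wrapped_exponential(acq):
    """Single exponential tau=2 ns, delta IRF at t0=0: the mean of the
    wrapped arrival time is tau - T e^(-T/tau)/(1 - e^(-T/tau))."""
    tau = 2.0
    p = DecayParams(t0=0.0, sigma=0.0, a1=1.0, a2=0.0, tau1=tau, tau2=tau)
    h = gen_photon_histogram(p, 10 ** 6, acq, seed=1)
    centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
    w = h.counts / h.counts.sum()
    emp_mean = float((centers * w).sum())
    emp_sd = float(np.sqrt(((centers - emp_mean) ** 2 * w).sum()))
    r = np.exp(-T / tau)
    model_mean = tau - T * r / (1 - r)
    se = emp_sd / np.sqrt(h.counts.sum())
    # binning offsets the empirical mean by O(bin_width^2/12/tau) at most
    assert abs(emp_mean - model_mean) < 3 * se + acq.bin_width ** 2 / (12 * tau)


def test_histogram_chi2_consistent_with_poisson(acq):
    from flimmetab.flim import expected_counts
    p = DecayParams(2.0, 0.3, 0.6, 0.4, 0.7, 3.0)
    n = 500000
    h = gen_photon_histogram(p, n, acq, seed=9)
    scaled = DecayParams(2.0, 0.3, 0.6 * n, 0.4 * n, 0.7, 3.0)
    e = expected_counts(scaled, acq.bin_edges, T)
    mask = e > 20
    chi2 = float((((h.counts - e) ** 2) / e)[mask].sum())
    df = int(mask.sum())
    assert abs(chi2 - df) < 5 * np.sqrt(2 * df)


# --- dual-sensor experiment ---------------------------------------------

def _waveforms(dp=0.10, dr=0.50):
    per = GroundTruthWaveform(kind="peredox", baseline=1.55, amplitude=dp,
                              rise_tau=15.0, decay_tau=60.0)
    rca = GroundTruthWaveform(kind="rcamp", baseline=1.10, amplitude=dr,
                              rise_tau=1.0, decay_tau=10.0)
    return per, rca


def test_no_bleedthrough_fits_recover_programmed_waveforms():
    acq = AcquisitionConfig(frame_interval=10.0)
    prot = StimulusProtocol(onsets=(30.0,))
    per, rca = _waveforms()
    exp = gen_dual_sensor_experiment(prot, per, rca,
                                     BleedthroughParams(0.0, 0.0, 0.675),
                                     photons_per_frame=50000, acq=acq,
                                     seed=2, duration=80.0)
    for i in range(exp.n_frames):
        fg = fit_histogram(exp.histogram(i, 0))
        fr = fit_histogram(exp.histogram(i, 1))
        assert fg.tau8 == pytest.approx(exp.truth.tau8_peredox[i], abs=0.02)
        assert fr.tau8 == pytest.approx(exp.truth.tau8_rcamp[i], abs=0.02)


def test_no_stimulus_traces_are_flat():
    acq = AcquisitionConfig(frame_interval=10.0)
    prot = StimulusProtocol(onsets=())
    per, rca = _waveforms()
    exp = gen_dual_sensor_experiment(prot, per, rca, BleedthroughParams(),
                                     photons_per_frame=5000, acq=acq,
                                     seed=3, duration=60.0)
    assert np.allclose(exp.truth.tau8_peredox, 1.55)
    assert np.allclose(exp.truth.tau8_rcamp, 1.10)


def test_bad_bleedthrough_fraction_rejected():
    with pytest.raises(ValueError):
        BleedthroughParams(g_into_r=1.2)


def test_dual_sensor_determinism():
    acq = AcquisitionConfig(frame_interval=20.0)
    prot = StimulusProtocol(onsets=(30.0,))
    per, rca = _waveforms()
    kw = dict(photons_per_frame=3000, acq=acq, seed=11, duration=60.0)
    e1 = gen_dual_sensor_experiment(prot, per, rca, BleedthroughParams(), **kw)
    e2 = gen_dual_sensor_experiment(prot, per, rca, BleedthroughParams(), **kw)
    assert np.array_equal(e1.counts, e2.counts)


# --- widefield autofluorescence -----------------------------------------

def _af_waveforms():
    nad = GroundTruthWaveform(kind="nadph", baseline=1000.0, amplitude=4.0,
                              rise_tau=5.0, decay_tau=30.0,
                              dip_amplitude=2.0, dip_duration=2.0)
    fad = GroundTruthWaveform(kind="fad", baseline=800.0, amplitude=2.0,
                              rise_tau=5.0, decay_tau=30.0,
                              dip_amplitude=1.0, dip_duration=2.0)
    rca = GroundTruthWaveform(kind="rcamp", baseline=500.0, amplitude=8.0,
                              rise_tau=0.5, decay_tau=3.0)
    return nad, fad, rca


def test_widefield_cadence_and_burst_count():
    """0.5 Hz baseline, 6 Hz for 10 s starting 2 s pre-stimulus: exactly
    60 burst frames per stimulus, strictly increasing timestamps."""
    acqw = AcquisitionConfig.widefield()
    prot = StimulusProtocol(onsets=(60.0, 200.0))
    ts, n_burst = widefield_timestamps(prot, acqw, duration=300.0)
    assert n_burst == 60
    assert np.all(np.diff(ts) > 0)
    for s in prot.onsets:
        in_burst = (ts >= s - 2.0) & (ts < s + 8.0)
        assert in_burst.sum() == 60
        burst_dt = np.diff(ts[in_burst])
        assert np.allclose(burst_dt, 1 / 6, atol=1e-9)


def test_overlapping_burst_windows_rejected():
    acqw = AcquisitionConfig.widefield()
    prot = StimulusProtocol(onsets=(60.0, 64.0), pulses_per_train=25)
    with pytest.raises(ValueError, match="overlap"):
        widefield_timestamps(prot, acqw, duration=120.0)


def test_noiseless_traces_reproduce_programmed_dff():
    acqw = AcquisitionConfig.widefield()
    prot = StimulusProtocol(onsets=(60.0,))
    nad, fad, rca = _af_waveforms()
    tset = gen_autofluorescence_traces(prot, nad, fad, rca, noise_sd=0.0,
                                       acq=acqw, seed=0, duration=200.0)
    sub = tset.frames[tset.frames.channel == "nadph"]
    truth = tset.truth[tset.truth.channel == "nadph"]
    dff = 100.0 * (sub.value.to_numpy() / 1000.0 - 1.0)
    assert np.allclose(dff, truth.dff_percent.to_numpy(), atol=1e-9)
    # dip precedes overshoot, with the programmed signs
    assert truth.dff_percent.min() == pytest.approx(-2.0, abs=0.05)
    assert truth.dff_percent.max() == pytest.approx(4.0, abs=0.05)
    t_min = truth.time_s.iloc[truth.dff_percent.idxmin()]
    t_max = truth.time_s.iloc[truth.dff_percent.idxmax()]
    assert t_min < t_max


def test_fad_waveform_mirrors_nadph():
    acqw = AcquisitionConfig.widefield()
    prot = StimulusProtocol(onsets=(60.0,))
    nad, fad, rca = _af_waveforms()
    tset = gen_autofluorescence_traces(prot, nad, fad, rca, noise_sd=0.0,
                                       acq=acqw, seed=0, duration=200.0)
    truth = tset.truth[tset.truth.channel == "fad"].reset_index(drop=True)
    # fast phase up (oxidative), slow phase down (reductive)
    assert truth.dff_percent.max() == pytest.approx(1.0, abs=0.05)
    assert truth.dff_percent.min() == pytest.approx(-2.0, abs=0.05)
    t_up = truth.time_s[truth.dff_percent.idxmax()]
    t_dn = truth.time_s[truth.dff_percent.idxmin()]
    assert t_up < t_dn


def test_negative_noise_rejected():
    acqw = AcquisitionConfig.widefield()
    prot = StimulusProtocol(onsets=(60.0,))
    nad, fad, rca = _af_waveforms()
    with pytest.raises(ValueError):
        gen_autofluorescence_traces(prot, nad, fad, rca, noise_sd=-1.0,
                                    acq=acqw, seed=0)


# --- O2 -----------------------------------------------------------------

def test_o2_noiseless_calibration_roundtrip():
    dip = GroundTruthWaveform(kind="o2", baseline=0.0, onset=100.0,
                              amplitude=-40.0, rise_tau=3.0, decay_tau=20.0)
    o2 = gen_o2_trace(baseline_uM=180.0, dip=dip, drift_rate=0.0,
                      cal_signals=(50.0, 950.0), seed=0, conc_high=220.0,
                      duration=300.0)
    cal = CalibrationPair(signal_zero=50.0, signal_high=950.0, conc_high=220.0)
    trace = calibrate(o2.time_s, o2.raw, cal)
    assert np.allclose(trace.values, o2.truth_uM, atol=1e-9)


def test_o2_degenerate_calibration_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        gen_o2_trace(180.0, None, 0.0, cal_signals=(100.0, 100.0), seed=0)


def test_o2_baseline_step_programs_fractional_shift():
    o2 = gen_o2_trace(200.0, None, 0.0, cal_signals=(0.0, 1000.0), seed=0,
                      duration=400.0, baseline_step=(200.0, 0.25))
    assert o2.truth_uM[:200].mean() == pytest.approx(200.0)
    assert o2.truth_uM[200:].mean() == pytest.approx(250.0)
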