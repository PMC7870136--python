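"""Stimulus-locked trace quantification."""

import numpy as np
import pytest

from flimmetab.synth import GroundTruthWaveform
from flimmetab.traces import (LifetimeTrace, apply_inclusion_filters,
                              auc_overshoot, detect_baseline_step, dff_trace,
                              fret_ratio_change, peredox_rcamp_ratio,
                              rebin_trace, transient_metrics)


def _trace(t, v, stims=(), **kw):
    return LifetimeTrace(np.asarray(t, float), np.asarray(v, float),
                         stim_onsets=stims, **kw)


# --- rebinning ----------------------------------------------------------

def test_rebin_window_one_is_identity():
    tr = _trace(np.arange(10.0), np.arange(10.0) * 2)
    out = rebin_trace(tr, window=1)
    assert np.array_equal(out.values, tr.values)


def test_rebin_constant_trace_stays_constant():
    tr = _trace(np.arange(100.0), np.full(100, 3.14))
    out = rebin_trace(tr, window=20)
    assert np.allclose(out.values, 3.14)
    assert len(out) == 5


def test_rebin_fast_channel_keeps_single_frames_post_stimulus():
    """40 pre-stimulus frames then 60 frames inside the 10 s fast window:
    2 averaged points followed by 60 single-frame points."""
    t = np.concatenate([np.linspace(0, 39 * 0.25, 40),
                        10.0 + np.arange(60) / 6.0])
    v = np.arange(100.0)
    tr = _trace(t, v, stims=(10.0,))
    out = rebin_trace(tr, window=20, fast_span=10.0, fast=True)
    assert len(out) == 62
    assert out.values[0] == pytest.approx(v[:20].mean())
    assert out.values[1] == pytest.approx(v[20:40].mean())
    assert np.array_equal(out.values[2:], v[40:])


def test_rebin_idempotent_composition():
    tr = _trace(np.arange(40.0), np.sin(np.arange(40.0)))
    once = rebin_trace(tr, window=20)
    again = rebin_trace(once, window=1)
    assert np.array_equal(once.values, again.values)


# --- transient metrics --------------------------------------------------

def test_flat_trace_has_zero_delta():
    t = np.arange(0.0, 120.0)
    tr = _trace(t, np.full_like(t, 1.5), stims=(60.0,))
    m = transient_metrics(tr, 60.0, (-30.0, 0.0), (0.0, 30.0))
    assert m.delta == 0.0
    assert m.dff == 0.0


def test_programmed_alpha_transient_recovered():
    """Peak +4 units at a known time: delta and time_to_peak match the
    programmed waveform within one sample interval."""
    wf = GroundTruthWaveform(kind="rcamp", baseline=10.0, onset=30.0,
                             amplitude=4.0, rise_tau=2.0, decay_tau=12.0)
    t = np.arange(0.0, 120.0, 0.5)
    tr = _trace(t, wf.value(t), stims=(30.0,))
    m = transient_metrics(tr, 30.0, (-20.0, 0.0), (0.0, 60.0))
    assert m.baseline == pytest.approx(10.0, abs=1e-9)
    assert m.delta == pytest.approx(4.0, abs=0.02)
    # analytic alpha-function peak time
    tp = np.log(12.0 / 2.0) * 2.0 * 12.0 / 10.0
    assert m.time_to_peak == pytest.approx(tp, abs=0.5)


def test_negative_polarity_finds_dip():
    t = np.arange(0.0, 60.0, 0.25)
    v = np.zeros_like(t)
    v[(t > 30.0) & (t < 32.0)] = -2.0
    tr = _trace(t, v + 100.0)
    m = transient_metrics(tr, 30.0, (-10.0, 0.0), (0.0, 10.0),
                          polarity="negative")
    assert m.delta == pytest.approx(-2.0)
    assert m.dff == pytest.approx(-2.0)


def test_windows_outside_trace_rejected():
    tr = _trace(np.arange(10.0), np.ones(10))
    with pytest.raises(ValueError):
        transient_metrics(tr, 5.0, (-20.0, -15.0), (0.0, 2.0))
    with pytest.raises(ValueError):
        transient_metrics(tr, 5.0, (-2.0, 1.0), (0.0, 2.0))  # crosses stimulus


def test_metrics_shift_with_constant_offset():
    t = np.arange(0.0, 100.0, 0.5)
    wf = GroundTruthWaveform(kind="rcamp", baseline=0.0, onset=40.0,
                             amplitude=2.0, rise_tau=1.0, decay_tau=8.0)
    v = wf.value(t)
    m0 = transient_metrics(_trace(t, v + 5.0), 40.0, (-20.0, 0.0), (0.0, 30.0))
    m1 = transient_metrics(_trace(t, v + 6.0), 40.0, (-20.0, 0.0), (0.0, 30.0))
    assert m1.delta == pytest.approx(m0.delta, abs=1e-12)
    assert m1.baseline == pytest.approx(m0.baseline + 1.0, abs=1e-12)


# --- ratio & filters ----------------------------------------------------

def test_peredox_rcamp_ratio_arithmetic():
    a = transient_metrics(_trace(np.arange(0.0, 100.0),
                                 np.where(np.arange(100.0) >= 50, 1.65, 1.55)),
                          50.0, (-30.0, 0.0), (0.0, 40.0))
    b = transient_metrics(_trace(np.arange(0.0, 100.0),
                                 np.where(np.arange(100.0) >= 50, 1.60, 1.10)),
                          50.0, (-30.0, 0.0), (0.0, 40.0))
    assert peredox_rcamp_ratio(a, b) == pytest.approx(0.10 / 0.50, rel=1e-9)


def test_ratio_undefined_for_nonpositive_rcamp():
    t = np.arange(0.0, 100.0)
    flat = transient_metrics(_trace(t, np.full_like(t, 1.0)), 50.0,
                             (-30.0, 0.0), (0.0, 40.0))
    with pytest.raises(ValueError):
        peredox_rcamp_ratio(flat, flat)


def _metric(delta, dff=None):
    from flimmetab.traces import TransientMetrics
    return TransientMetrics(roi_id="c", stim_time=0.0, baseline=1.0,
                            peak=1.0 + delta, delta=delta, dff=dff,
                            time_to_peak=1.0, recovery_time=None)


def test_threshold_is_inclusive_at_boundary():
    """A DeltaPeredox of exactly 0.05 ns passes the >= 0.05 ns filter."""
    included, cells = apply_inclusion_filters(
        {"at": _metric(0.05), "below": _metric(0.049999)}, {"delta": 0.05})
    assert included == ["at"]
    assert cells["below"].reasons == ("delta<0.05",)


def test_percent_rule_excludes_small_peak():
    included, cells = apply_inclusion_filters(
        {"small": _metric(0.009, dff=0.9), "big": _metric(0.02, dff=2.0)},
        {"dff": 1.0})
    assert included == ["big"]


def test_cohort_filter_counts():
    deltas = [0.10, 0.03, 0.08, 0.12, 0.04, 0.06, 0.30, 0.02, 0.05, 0.07]
    cells = {f"c{i}": _metric(d) for i, d in enumerate(deltas)}
    included, _ = apply_inclusion_filters(cells, {"delta": 0.05})
    assert len(included) == 7


def test_unknown_rule_field_rejected():
    with pytest.raises(KeyError):
        apply_inclusion_filters({"c": _metric(0.1)}, {"nope": 1.0})


# --- baseline step detection --------------------------------------------

def test_clean_trace_not_flagged():
    t = np.arange(0.0, 300.0, 5.0)
    flagged, _ = detect_baseline_step(_trace(t, np.full_like(t, 1.5)),
                                      step_threshold=0.1, persistence=60.0)
    assert not flagged


def test_permanent_step_flagged_at_injection_time():
    t = np.arange(0.0, 300.0, 5.0)
    v = np.where(t >= 150.0, 1.65, 1.50)
    flagged, when = detect_baseline_step(_trace(t, v), step_threshold=0.1,
                                         persistence=60.0)
    assert flagged
    assert abs(when - 150.0) <= 5.0


def test_recovering_excursion_not_flagged():
    t = np.arange(0.0, 300.0, 5.0)
    v = np.full_like(t, 1.50)
    v[(t >= 150.0) & (t < 180.0)] = 1.65   # 30 s < 60 s persistence
    flagged, _ = detect_baseline_step(_trace(t, v), step_threshold=0.1,
                                      persistence=60.0)
    assert not flagged


# --- dF/F, AUC, FRET ----------------------------------------------------

def test_dff_trivial_points():
    t = np.arange(0.0, 20.0)
    v = np.full_like(t, 50.0)
    v[10] = 100.0
    out = dff_trace(_trace(t, v), (0.0, 10.0))
    assert out.values[0] == 0.0
    assert out.values[10] == pytest.approx(100.0)


def test_dff_rejects_nonpositive_baseline():
    t = np.arange(0.0, 10.0)
    with pytest.raises(ValueError):
        dff_trace(_trace(t, np.zeros_like(t)), (0.0, 5.0))


def test_auc_rectangle():
    t = np.arange(0.0, 121.0)
    tr = _trace(t, np.ones_like(t))
    assert auc_overshoot(tr, 0.0, 120.0) == pytest.approx(2.0, abs=1e-12)


def test_auc_zero_trace():
    t = np.arange(0.0, 121.0)
    assert auc_overshoot(_trace(t, np.zeros_like(t)), 0.0, 120.0) == 0.0


def test_auc_triangle():
    t = np.arange(0.0, 121.0)
    v = np.interp(t, [0.0, 60.0, 120.0], [0.0, 3.0, 0.0])
    assert auc_overshoot(_trace(t, v), 0.0, 120.0) == pytest.approx(3.0, abs=1e-12)


def test_auc_additive_over_adjacent_spans():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0.0, 240.0, 400))
    t[0], t[-1] = 0.0, 240.0
    v = rng.normal(size=len(t))
    whole = auc_overshoot(_trace(t, v), 0.0, 240.0)
    parts = auc_overshoot(_trace(t, v), 0.0, 120.0) + \
        auc_overshoot(_trace(t, v), 120.0, 120.0)
    assert whole == pytest.approx(parts, abs=1e-9)


def test_auc_insufficient_coverage_rejected():
    t = np.arange(0.0, 60.0)
    with pytest.raises(ValueError):
        auc_overshoot(_trace(t, np.ones_like(t)), 0.0, 120.0)


def test_fret_ratio_invariances():
    t = np.arange(0.0, 50.0)
    donor = np.full_like(t, 200.0)
    acceptor = np.full_like(t, 400.0)
    # doubling both channels leaves the ratio change at 0 %
    out = fret_ratio_change(_trace(t, 2 * donor), _trace(t, 2 * acceptor),
                            (0.0, 20.0))
    assert np.allclose(out.values, 0.0)
    # a 1.5x ratio step reads +50 %
    donor2 = donor.copy()
    donor2[25:] *= 1.5
    out2 = fret_ratio_change(_trace(t, donor2), _trace(t, acceptor), (0.0, 20.0))
    assert out2.values[30] == pytest.approx(50.0)


def test_fret_zero_acceptor_rejected():
    t = np.arange(0.0, 10.0)
    acc = np.ones_like(t)
    acc[5] = 0.0
    with pytest.raises(ValueError):
        fret_ratio_change(_trace(t, np.ones_like(t)), _trace(t, acc), (0.0, 5.0))


def test_pyronic_plateau_recovered():
    wf = GroundTruthWaveform(kind="pyronic_ratio", baseline=0.5, onset=100.0,
                             amplitude=0.05, rise_tau=20.0, decay_tau=400.0)
    t = np.arange(0.0, 400.0, 2.0)
    ratio = wf.value(t)
    donor = 300.0 * ratio          # acceptor constant -> ratio carries signal
    acceptor = np.full_like(t, 300.0)
    out = fret_ratio_change(_trace(t, donor), _trace(t, acceptor), (0.0, 80.0))
    m = transient_metrics(LifetimeTrace(t, out.values, stim_onsets=(100.0,)),
                          100.0, (-60.0, 0.0), (0.0, 290.0))
    assert m.delta == pytest.approx(100.0 * 0.05 / 0.5, rel=0.05)
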