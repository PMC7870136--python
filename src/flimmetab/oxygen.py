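"""Two-point calibration of Clark-type O2 microsensor traces.

The electrode signal is linear in dissolved [O2]; routine calibration uses
an anoxic standard (assigned 0 uM) and ACSF equilibrated with 20 % O2.  The
micromolar value of the high standard is not a universal constant -- it
follows from Henry's law at the calibration temperature -- so it is carried
explicitly on the calibration pair and a solubility helper is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .traces import LifetimeTrace

__all__ = ["CalibrationPair", "henry_o2_uM", "calibrate", "baseline_shift"]


@dataclass(frozen=True)
class CalibrationPair:
    """Raw readings at the anoxic (0 uM) and high standards."""

    signal_zero: float
    signal_high: float
    conc_high: float                 # uM assigned to the high standard
    temperature: float = 34.0        # degC

    def __post_init__(self):
        if self.signal_high == self.signal_zero:
            raise ValueError("degenerate calibration: identical standard signals")
        if self.conc_high <= 0:
            raise ValueError("conc_high must be positive")


def henry_o2_uM(temperature: float = 34.0, o2_fraction: float = 0.20,
                pressure_atm: float = 1.0) -> float:
    """Dissolved [O2] (uM) of water equilibrated with an O2 gas fraction.

    Van't Hoff form of Henry's law, k(298 K) = 1.3e-3 mol/L/atm with a
    temperature coefficient of 1700 K; at 34 degC and 20 % O2 this gives
    ~220 uM, the conventional value for oxygenated ACSF standards.
    """
    T = temperature + 273.15
    k = 1.3e-3 * math.exp(1700.0 * (1.0 / T - 1.0 / 298.15))   # mol/L/atm
    return k * o2_fraction * pressure_atm * 1e6


def calibrate(time_s, raw, cal: CalibrationPair,
              roi_id: str = "electrode") -> LifetimeTrace:
    """Affine map sending signal_zero -> 0 uM and signal_high -> conc_high."""
    t = np.asarray(time_s, dtype=float)
    r = np.asarray(raw, dtype=float)
    gain = cal.conc_high / (cal.signal_high - cal.signal_zero)
    return LifetimeTrace(timestamps=t, values=gain * (r - cal.signal_zero),
                         roi_id=roi_id, label="o2_uM")


def baseline_shift(trace: LifetimeTrace,
                   pre_window: tuple[float, float],
                   post_window: tuple[float, float]) -> float:
    """Percent change of the mean level between two windows.

    100 * (mean_post - mean_pre) / mean_pre, the statistic used to report
    sustained shifts in baseline tissue oxygenation.
    """
    pre = trace.window(*pre_window)
    post = trace.window(*post_window)
    if not pre.any() or not post.any():
        raise ValueError("empty pre or post window")
    m_pre = trace.values[pre].mean()
    if m_pre == 0:
        raise ValueError("pre-window mean is zero; percent change undefined")
    return float(100.0 * (trace.values[post].mean() - m_pre) / m_pre)
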