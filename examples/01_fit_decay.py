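"""Fit a single TCSPC photon histogram and report tau8.

Simulates one ROI-frame of a two-component fluorescence decay under 80 MHz
pulsed excitation (lifetimes 0.5 and 2.5 ns, Gaussian IRF of 0.2 ns) and
fits it with the wrapped exGaussian model.
"""

from flimmetab.flim import DecayParams, fit_histogram
from flimmetab.synth import AcquisitionConfig, gen_photon_histogram

acq = AcquisitionConfig()           # 12.5 ns period, 125 bins of 0.1 ns
truth = DecayParams(t0=2.0, sigma=0.2, a1=5e4, a2=5e4, tau1=0.5, tau2=2.5)
hist = gen_photon_histogram(truth, n_photons=100_000, acq=acq, seed=7)

fit = fit_histogram(hist)
p = fit.params
print(f"true lifetimes : 0.500 / 2.500 ns")
print(f"fitted         : {p.tau1:.3f} / {p.tau2:.3f} ns "
      f"(sigma {p.sigma:.3f} ns, t0 {p.t0:.3f} ns)")
print(f"tau8           : {fit.tau8:.4f} ns")
print(f"converged      : {fit.converged} after {fit.n_iter} evaluations")
# tau8 is the photon-weighted mean arrival time of the deconvolved decay
# restricted to an 8 ns window -- the per-frame lifetime readout that the
# rest of the pipeline consumes.
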