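"""File formats: HDF5 histogram containers, TSV tables, YAML recipes."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .chelation import SolutionRecipe
from .synth import AcquisitionConfig, DualSensorExperiment, StimulusProtocol
from .unmix import BleedthroughParams

__all__ = [
    "save_experiment",
    "load_experiment",
    "write_table",
    "read_table",
    "load_recipe",
]

FLOAT_FMT = "%.9g"


def save_experiment(path, exp: DualSensorExperiment) -> None:
    """Write a dual-sensor experiment to an HDF5 container.

    Datasets: bin_edges (ns), counts[frame, channel, bin], timestamps (s);
    acquisition / protocol / bleedthrough metadata as JSON attributes;
    the ground-truth table as a dedicated group of columns.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("bin_edges", data=exp.bin_edges)
        f.create_dataset("counts", data=exp.counts, compression="gzip")
        f.create_dataset("timestamps", data=exp.frame_times)
        f.attrs["roi_id"] = exp.roi_id
        f.attrs["acquisition"] = json.dumps({
            "laser_period": exp.acq.laser_period, "irf_sigma": exp.acq.irf_sigma,
            "irf_t0": exp.acq.irf_t0, "bin_width": exp.acq.bin_width,
            "n_bins": exp.acq.n_bins, "frame_interval": exp.acq.frame_interval,
            "burst_rate": exp.acq.burst_rate, "burst_span": list(exp.acq.burst_span),
        })
        f.attrs["protocol"] = json.dumps({
            "onsets": list(exp.protocol.onsets),
            "pulses_per_train": exp.protocol.pulses_per_train,
            "pulse_rate": exp.protocol.pulse_rate,
            "pulse_width_ms": exp.protocol.pulse_width_ms,
        })
        f.attrs["bleedthrough"] = json.dumps({
            "g_into_r": exp.bleed.g_into_r, "r_into_g": exp.bleed.r_into_g,
            "contaminant_tau8": exp.bleed.contaminant_tau8,
        })
        g = f.create_group("truth")
        for col in exp.truth.columns:
            g.create_dataset(col, data=exp.truth[col].to_numpy())


def load_experiment(path) -> DualSensorExperiment:
    with h5py.File(path, "r") as f:
        acq = AcquisitionConfig(**{
            k: tuple(v) if k == "burst_span" else v
            for k, v in json.loads(f.attrs["acquisition"]).items()})
        prot = StimulusProtocol(**json.loads(f.attrs["protocol"]))
        bleed = BleedthroughParams(**json.loads(f.attrs["bleedthrough"]))
        truth = pd.DataFrame({k: f["truth"][k][...] for k in f["truth"]})
        return DualSensorExperiment(
            acq=acq, protocol=prot, frame_times=f["timestamps"][...],
            counts=f["counts"][...], bin_edges=f["bin_edges"][...],
            truth=truth, bleed=bleed, roi_id=str(f.attrs["roi_id"]))


def write_table(path, frame: pd.DataFrame) -> None:
    """TSV with a fixed float format, so identical inputs give identical bytes."""
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
                 lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_recipe(path) -> SolutionRecipe:
    """Solution recipe from YAML: metals/ligands in mM plus conditions.

    Example::

        metals: {Ca: 3.0, Mg: 1.0}
        ligands: {EGTA: 1.0}
        pH: 7.4
        temperature: 34.0
        ionic_strength: 0.15
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SolutionRecipe(
        metals={k: float(v) for k, v in (raw.get("metals") or {}).items()},
        ligands={k: float(v) for k, v in (raw.get("ligands") or {}).items()},
        pH=float(raw.get("pH", 7.4)),
        temperature=float(raw.get("temperature", 34.0)),
        ionic_strength=float(raw.get("ionic_strength", 0.15)))
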