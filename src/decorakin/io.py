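"""Plain-text readers and writers for the pipeline's data formats.

Formats: sensorgram CSV (time_s, response_RU, concentration_M, phase),
relaxation TSV, SAXS 3-column .dat (q, I, sigma), bead coordinates as
plain xyz, and melt CSV (temperature_C, fluorescence, metadata columns).
Writers accept a ``header`` mapping echoed as ``# key = value`` comment
lines for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .melt import MeltCurve
from .relax import RelaxationDataset
from .saxs import BeadModel, ScatteringCurve
from .spr import Sensorgram, SensorgramSet

__all__ = [
    "write_sensorgrams",
    "read_sensorgrams",
    "write_relaxation",
    "read_relaxation",
    "write_saxs_dat",
    "read_saxs_dat",
    "write_xyz",
    "read_xyz",
    "write_melt_csv",
    "read_melt_csv",
]


def _header_lines(header: Mapping | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in header.items())


def _read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def write_sensorgrams(path, sgs: SensorgramSet | list, header: Mapping | None = None) -> None:
    frames = []
    for sg in sgs:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": sg.time,
                    "response_RU": sg.response,
                    "concentration_M": sg.analyte_conc,
                    "phase": sg.phase,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        out.to_csv(fh, index=False)


def read_sensorgrams(path) -> SensorgramSet:
    df = _read_table(path)
    sgs = []
    for conc, grp in df.groupby("concentration_M", sort=True):
        sgs.append(
            Sensorgram(
                time=grp["time_s"].to_numpy(),
                response=grp["response_RU"].to_numpy(),
                analyte_conc=float(conc),
                phase=grp["phase"].to_numpy(dtype=object),
            )
        )
    return SensorgramSet(sensorgrams=sgs)


def write_relaxation(path, dataset: RelaxationDataset, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        dataset.frame.to_csv(fh, sep="\t", index=False)


def read_relaxation(path) -> RelaxationDataset:
    return RelaxationDataset(_read_table(path, sep="\t"))


def write_saxs_dat(path, curve: ScatteringCurve, header: Mapping | None = None) -> None:
    sigma = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        for q, i, s in zip(curve.q, curve.intensity, sigma):
            fh.write(f"{q:.8e} {i:.8e} {s:.8e}\n")


def read_saxs_dat(path) -> ScatteringCurve:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected 2-3 columns (q, I[, sigma])")
    sigma = data[:, 2] if data.shape[1] >= 3 and np.any(data[:, 2] > 0) else None
    return ScatteringCurve(q=data[:, 0], intensity=data[:, 1], sigma=sigma)


def write_xyz(path, model: BeadModel, comment: str = "pseudo-residue bead model (A)") -> None:
    with open(path, "w") as fh:
        fh.write(f"{model.n_beads}\n{comment}\n")
        for (x, y, z), w in zip(model.coords, model.weights):
            fh.write(f"C {x:.4f} {y:.4f} {z:.4f} {w:.4f}\n")


def read_xyz(path) -> BeadModel:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    coords, weights = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        coords.append([float(v) for v in parts[1:4]])
        weights.append(float(parts[4]) if len(parts) > 4 else 1.0)
    return BeadModel(coords=np.asarray(coords), weights=np.asarray(weights))


def write_melt_csv(path, curve: MeltCurve, header: Mapping | None = None) -> None:
    df = pd.DataFrame({"temperature_C": curve.temperature, "fluorescence": curve.fluorescence})
    for k, v in curve.metadata.items():
        df[k] = v
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, index=False)


def read_melt_csv(path) -> MeltCurve:
    df = _read_table(path)
    meta_cols = [c for c in df.columns if c not in ("temperature_C", "fluorescence")]
    metadata = {c: df[c].iloc[0] for c in meta_cols}
    return MeltCurve(
        temperature=df["temperature_C"].to_numpy(),
        fluorescence=df["fluorescence"].to_numpy(),
        metadata=metadata,
    )
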