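"""Configuration and file round-tripping.

Formats: TOML for run configuration, HDF5 for grids (STAFs, rendered frames,
comparison maps), CSV for one-dimensional traces and sequences (with JSON
sidecars for generator metadata).  Every ``load_*`` is the exact inverse of
the matching ``save_*``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .estimation import STAF, EstimationConfig, ProtocolConfig
from .msequence import MSequence
from .plant import GroundTruthParams, PlantModel, ResponseTrace, \
    make_ground_truth_stafs
from .stats import ComparisonResult
from .stimulus import DisplayGeometry

__all__ = [
    "RunConfig", "load_config", "save_config", "config_hash",
    "save_sequence", "load_sequence",
    "save_trace", "load_trace", "save_run_dir", "load_run_dir",
    "save_staf", "load_staf", "save_comparison", "load_comparison",
    "save_plant_spec", "load_plant_spec",
]

log = logging.getLogger("stafkit")


# --------------------------------------------------------------------------
# run configuration

class GeometrySection(BaseModel):
    n_pixels_azimuth: int = 96
    pixel_pitch: float = 3.75
    figure_width_pixels: int = 8
    frame_rate: float = 25.0
    rear_gap_pixels: int = 8


class SequenceSection(BaseModel):
    order: int = 7
    taps_fm: list[int] | None = None
    taps_em: list[int] | None = None


class ProtocolSection(BaseModel):
    start_azimuths: list[float] | None = None
    n_periods: int = 4
    n_repeats: int = 20
    mode: str = "block"
    drift_balanced: bool = False


class EstimationSection(BaseModel):
    dc_window: list[float] = Field(default_factory=lambda: [2.0, 5.0])
    normalization: str = "p_plus_1"
    boxcar_width: int = 4
    n_transient_periods: int = 1
    dc_correction: str = "closed_form"
    em_dc_correction: bool = False


class PlantSection(BaseModel):
    noise_sigma: float = 2.5
    drift_amplitude: float = 0.0
    saturation: float | None = None
    params: dict = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Everything needed to reproduce a full synthetic STAF run."""

    seed: int = 0
    output_dir: str = "staf_output"
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    sequence: SequenceSection = Field(default_factory=SequenceSection)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    estimation: EstimationSection = Field(default_factory=EstimationSection)
    plant: PlantSection = Field(default_factory=PlantSection)

    def display_geometry(self) -> DisplayGeometry:
        return DisplayGeometry(**self.geometry.model_dump())

    def protocol_config(self) -> ProtocolConfig:
        s, p = self.sequence, self.protocol
        return ProtocolConfig(
            order=s.order,
            taps_fm=tuple(s.taps_fm) if s.taps_fm else None,
            taps_em=tuple(s.taps_em) if s.taps_em else None,
            start_azimuths=(tuple(p.start_azimuths)
                            if p.start_azimuths else None),
            n_periods=p.n_periods, n_repeats=p.n_repeats, mode=p.mode,
            drift_balanced=p.drift_balanced)

    def estimation_config(self) -> EstimationConfig:
        e = self.estimation
        return EstimationConfig(
            dc_window=tuple(e.dc_window), normalization=e.normalization,
            boxcar_width=e.boxcar_width,
            n_transient_periods=e.n_transient_periods,
            dc_correction=e.dc_correction,
            em_dc_correction=e.em_dc_correction)

    def plant_model(self) -> PlantModel:
        geometry = self.display_geometry()
        params = GroundTruthParams(**self.plant.params)
        em, fm = make_ground_truth_stafs(geometry, params)
        return PlantModel(staf_em_true=em, staf_fm_true=fm,
                          noise_sigma=self.plant.noise_sigma,
                          drift_amplitude=self.plant.drift_amplitude,
                          saturation=self.plant.saturation,
                          rng_seed=self.seed)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        fields = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ValueError(f"invalid run config {path}: {fields}") from err


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def save_config(config: RunConfig, path) -> None:
    data = config.model_dump()
    lines = []
    for key, val in data.items():
        if not isinstance(val, dict):
            lines.append(f"{key} = {_toml_value(val)}")
    for key, val in data.items():
        if isinstance(val, dict):
            lines.append(f"\n[{key}]")
            for k, v in val.items():
                if v is None or (isinstance(v, dict) and not v):
                    continue
                if isinstance(v, dict):
                    raise TypeError("nested tables beyond one level")
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# sequences

def save_sequence(seq: MSequence, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"value": seq.values.astype(int)}).to_csv(csv_path,
                                                           index=False)
    meta = {"order": seq.order, "polynomial_taps": list(seq.polynomial_taps),
            "initial_state": list(seq.initial_state)}
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_sequence(csv_path) -> MSequence:
    csv_path = Path(csv_path)
    values = pd.read_csv(csv_path)["value"].to_numpy()
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return MSequence(order=meta["order"],
                     polynomial_taps=tuple(meta["polynomial_taps"]),
                     initial_state=tuple(meta["initial_state"]),
                     values=values)


# --------------------------------------------------------------------------
# traces

def save_trace(trace: ResponseTrace, path) -> None:
    pd.DataFrame({
        "frame_index": np.arange(len(trace.y)),
        "time_s": trace.time,
        "dwba": trace.y,
    }).to_csv(path, index=False)


def load_trace(path, frame_rate: float | None = None,
               alignment: int = 0) -> ResponseTrace:
    df = pd.read_csv(path)
    if frame_rate is None:
        dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
        frame_rate = 1.0 / dt
    return ResponseTrace(y=df["dwba"].to_numpy(), frame_rate=frame_rate,
                         alignment=alignment)


def save_run_dir(runs, directory, frame_rate: float) -> None:
    """Persist a list of protocol run records (see run_staf_protocol)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, run in enumerate(runs):
        name = f"run_{i:04d}.csv"
        trace = run["y"]
        if not isinstance(trace, ResponseTrace):
            trace = ResponseTrace(y=trace, frame_rate=frame_rate)
        save_trace(trace, directory / name)
        np.savetxt(directory / f"run_{i:04d}_gamma.csv", run["gamma"],
                   fmt="%.6f")
        manifest.append({
            "file": name, "gamma_file": f"run_{i:04d}_gamma.csv",
            "start_azimuth": float(run["start_azimuth"]),
            "sign": int(run["sign"]), "repeat": int(run.get("repeat", 0)),
            "alignment": int(getattr(run["y"], "alignment", 1)),
        })
    (directory / "manifest.json").write_text(
        json.dumps({"frame_rate": frame_rate, "runs": manifest}, indent=1))


def load_run_dir(directory) -> tuple[list, float]:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    runs = []
    for entry in manifest["runs"]:
        trace = load_trace(directory / entry["file"],
                           frame_rate=manifest["frame_rate"],
                           alignment=entry["alignment"])
        gamma = np.loadtxt(directory / entry["gamma_file"])
        runs.append({"start_azimuth": entry["start_azimuth"],
                     "sign": entry["sign"], "repeat": entry["repeat"],
                     "y": trace, "gamma": gamma})
    return runs, manifest["frame_rate"]


# --------------------------------------------------------------------------
# STAFs and comparison maps (HDF5)

def save_staf(staf: STAF, path, name: str | None = None) -> None:
    name = name or staf.kind
    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        grp = fh.create_group(name)
        grp.create_dataset("grid", data=staf.grid)
        grp.create_dataset("time_axis", data=staf.time_axis)
        grp.create_dataset("azimuth_axis", data=staf.azimuth_axis)
        grp.attrs["kind"] = staf.kind
        grp.attrs["smoothing"] = json.dumps(staf.smoothing)
        grp.attrs["provenance"] = json.dumps(staf.provenance, default=str)


def load_staf(path, name: str) -> STAF:
    with h5py.File(path, "r") as fh:
        if name not in fh:
            raise KeyError(f"no STAF named {name!r} in {path}")
        grp = fh[name]
        return STAF(grid=grp["grid"][()], time_axis=grp["time_axis"][()],
                    azimuth_axis=grp["azimuth_axis"][()],
                    kind=str(grp.attrs["kind"]),
                    smoothing=json.loads(grp.attrs["smoothing"]),
                    provenance=json.loads(grp.attrs["provenance"]))


def save_comparison(result: ComparisonResult, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("t_map", data=result.t_map)
        fh.create_dataset("p_map", data=result.p_map)
        if result.rejection_mask is not None:
            fh.create_dataset("rejection_mask",
                              data=result.rejection_mask.astype(np.uint8))
        if result.q is not None:
            fh.attrs["q"] = result.q


def load_comparison(path) -> ComparisonResult:
    with h5py.File(path, "r") as fh:
        mask = (fh["rejection_mask"][()].astype(bool)
                if "rejection_mask" in fh else None)
        q = float(fh.attrs["q"]) if "q" in fh.attrs else None
        return ComparisonResult(t_map=fh["t_map"][()], p_map=fh["p_map"][()],
                                q=q, rejection_mask=mask)


# --------------------------------------------------------------------------
# plant specs

def save_plant_spec(plant_section: PlantSection, path) -> None:
    Path(path).write_text(json.dumps(plant_section.model_dump(), indent=1))


def load_plant_spec(path) -> PlantSection:
    try:
        return PlantSection.model_validate(
            json.loads(Path(path).read_text()))
    except ValidationError as err:
        fields = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors())
        raise ValueError(f"invalid plant spec {path}: {fields}") from err
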