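"""File I/O and pipeline orchestration.

HDF5 containers for lead fields, simulated datasets, reconstructions and
sampler chains; TSV sensor layouts; CSV localization reports; YAML run
configurations; and the simulate -> invert -> metrics pipeline with a
provenance record.

Lead-field container schema (HDF5)
----------------------------------
``/leadfield`` (m x 3N), ``/positions`` (N x 3 mm), ``/normals`` (N x 3),
``/regions`` (N, bytes), ``/sensors`` (m x 3 mm), optionally
``/sensor_orientations`` (m x 3, MEG), with attributes ``modality``,
``units``, ``amplitude_norm`` and the geometry parameters.  Any container
with this schema — e.g. an externally computed FEM lead field — is accepted
by the inversion code as a drop-in replacement for the built-in spherical
model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import JP_REF_AM
from .forward_synthetic import (GeometryConfig, LeadField, Scenario,
                                SensorArray, SimulatedDataset, SourceSpace,
                                TruthSource, scenario_p20n20_like)
from .hyperprior import HyperpriorSpec
from .inversion import (ROI, ReconstructionResult, SamplerChain, cm_estimate,
                        gibbs_sample, ias_map, mce, mne)
from .metrics import localization_report
from .parametrization import NoiseModel, pm_snr, theta0_from_pm_snr

__all__ = [
    "SchemaError", "RunConfig",
    "write_leadfield", "read_leadfield",
    "write_dataset", "read_dataset",
    "write_chain", "read_chain",
    "read_sensor_layout_tsv", "write_sensor_layout_tsv",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A file does not conform to the expected container schema."""


def write_leadfield(path, leadfield: LeadField) -> None:
    space, sensors = leadfield.source_space, leadfield.sensor_array
    with h5py.File(path, "w") as f:
        f.create_dataset("leadfield", data=leadfield.matrix)
        f.create_dataset("positions", data=space.positions)
        f.create_dataset("normals", data=space.normals)
        f.create_dataset("regions",
                         data=np.array(space.region, dtype="S"))
        f.create_dataset("sensors", data=sensors.positions)
        if sensors.orientations is not None:
            f.create_dataset("sensor_orientations", data=sensors.orientations)
        f.attrs["modality"] = sensors.modality
        f.attrs["units"] = "V/Am" if sensors.modality == "EEG" else "T/Am"
        f.attrs["coordinates"] = "head-centered Cartesian, mm"
        f.attrs["amplitude_norm"] = leadfield.amplitude_norm
        f.attrs["density"] = space.density
        for k, v in dataclasses.asdict(space.geometry).items():
            if v is not None:
                f.attrs[f"geometry_{k}"] = v


def read_leadfield(path) -> LeadField:
    required = ["leadfield", "positions", "normals", "regions", "sensors"]
    with h5py.File(path, "r") as f:
        for name in required:
            if name not in f:
                raise SchemaError(f"lead-field container missing /{name}")
        modality = str(f.attrs.get("modality", "EEG"))
        matrix = f["leadfield"][()]
        positions = f["positions"][()]
        normals = f["normals"][()]
        region = f["regions"][()].astype(str)
        sens_pos = f["sensors"][()]
        sens_ori = (f["sensor_orientations"][()]
                    if "sensor_orientations" in f else None)
        geo_kwargs = {k[len("geometry_"):]: float(v)
                      for k, v in f.attrs.items() if k.startswith("geometry_")}
        amplitude_norm = float(f.attrs.get("amplitude_norm", 1.0))
        density = str(f.attrs.get("density", "dense"))
    if matrix.shape[1] != 3 * len(positions):
        raise SchemaError("leadfield columns != 3 * number of positions")
    if modality == "MEG" and sens_ori is None:
        raise SchemaError("MEG container missing /sensor_orientations")
    geometry = GeometryConfig(**geo_kwargs) if geo_kwargs else GeometryConfig()
    space = SourceSpace(positions, normals, region, density, geometry)
    sensors = SensorArray(modality, sens_pos, sens_ori)
    return LeadField(matrix, space, sensors, amplitude_norm)


def write_dataset(path, dataset: SimulatedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("y_clean", data=dataset.y_clean)
        f.create_dataset("y_noisy", data=dataset.y_noisy)
        f.create_dataset("x_truth", data=dataset.x_truth)
        f.create_dataset("truth_positions",
                         data=np.array([t.position for t in dataset.truth]))
        f.create_dataset("truth_orientations",
                         data=np.array([t.orientation for t in dataset.truth]))
        f.create_dataset("truth_moments",
                         data=np.array([t.moment for t in dataset.truth]))
        f.create_dataset("truth_indices", data=np.array(dataset.truth_indices))
        f.create_dataset("truth_offsets_mm",
                         data=np.array(dataset.truth_offsets_mm))
        f.attrs["sigma"] = dataset.sigma
        f.attrs["epochs"] = dataset.epochs
        f.attrs["amplitude"] = dataset.amplitude
        f.attrs["noise_convention"] = dataset.noise_convention
        if dataset.seed is not None:
            f.attrs["seed"] = dataset.seed


def read_dataset(path) -> SimulatedDataset:
    with h5py.File(path, "r") as f:
        for name in ["y_clean", "y_noisy"]:
            if name not in f:
                raise SchemaError(f"dataset container missing /{name}")
        truth = tuple(
            TruthSource(p, o, float(m))
            for p, o, m in zip(f["truth_positions"][()],
                               f["truth_orientations"][()],
                               f["truth_moments"][()]))
        return SimulatedDataset(
            y_clean=f["y_clean"][()], y_noisy=f["y_noisy"][()],
            sigma=float(f.attrs["sigma"]), epochs=int(f.attrs["epochs"]),
            amplitude=float(f.attrs["amplitude"]), truth=truth,
            truth_indices=tuple(int(i) for i in f["truth_indices"][()]),
            truth_offsets_mm=tuple(float(v)
                                   for v in f["truth_offsets_mm"][()]),
            x_truth=f["x_truth"][()],
            noise_convention=str(f.attrs["noise_convention"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None)


def write_chain(path, chain: SamplerChain) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples_x", data=chain.samples_x)
        f.create_dataset("samples_theta", data=chain.samples_theta)
        f.create_dataset("position_indices", data=chain.position_indices)
        f.attrs["burn_in"] = chain.burn_in
        f.attrs["n_positions_total"] = chain.n_positions_total
        if chain.seed is not None:
            f.attrs["seed"] = chain.seed
        f.attrs["diagnostics"] = json.dumps(chain.diagnostics)


def read_chain(path) -> SamplerChain:
    with h5py.File(path, "r") as f:
        for name in ["samples_x", "samples_theta"]:
            if name not in f:
                raise SchemaError(f"chain container missing /{name}")
        return SamplerChain(
            samples_x=f["samples_x"][()],
            samples_theta=f["samples_theta"][()],
            burn_in=int(f.attrs["burn_in"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            position_indices=f["position_indices"][()],
            n_positions_total=int(f.attrs["n_positions_total"]),
            diagnostics=json.loads(f.attrs.get("diagnostics", "{}")))


def write_sensor_layout_tsv(path, sensors: SensorArray) -> None:
    names = sensors.names or [f"{sensors.modality}{i:03d}"
                              for i in range(sensors.count)]
    cols = {"name": names,
            "x": sensors.positions[:, 0], "y": sensors.positions[:, 1],
            "z": sensors.positions[:, 2]}
    if sensors.orientations is not None:
        cols.update(ox=sensors.orientations[:, 0],
                    oy=sensors.orientations[:, 1],
                    oz=sensors.orientations[:, 2])
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_sensor_layout_tsv(path, modality: str = "EEG") -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    for col in ["name", "x", "y", "z"]:
        if col not in df.columns:
            raise SchemaError(f"sensor layout missing column {col!r}")
    positions = df[["x", "y", "z"]].to_numpy(float)
    orientations = None
    if {"ox", "oy", "oz"} <= set(df.columns):
        orientations = df[["ox", "oy", "oz"]].to_numpy(float)
    return SensorArray(modality.upper(), positions, orientations,
                       names=tuple(df["name"].astype(str)))


@dataclass
class RunConfig:
    """Resolved configuration of one simulate -> invert -> metrics run.

    Exactly one of ``theta0`` / ``pm_snr_db`` may be given; the other is
    derived and logged.  All randomness flows from ``seed``.
    """

    modality: str = "EEG"
    density: str = "dense"
    n_dense: int = 4000
    n_sensors: int = 128
    include_deep: bool = False
    method: str = "ias"             # ias | mne | mce | mcmc-cm
    family: str = "G"
    beta: float = 3.0
    theta0: float | None = None
    pm_snr_db: float | None = None
    sigma_known: float = 0.03
    latent_factor: float = 1.0
    epochs: int = 1200
    reference_epochs: int = 1200
    n_iterations: int = 3
    n_samples: int = 10_000
    burn_in: int = 1_000
    roi_diameter_mm: float = 24.0
    seed: int = 0
    jp_ref: float = JP_REF_AM

    def __post_init__(self):
        if (self.theta0 is None) == (self.pm_snr_db is None):
            raise ValueError(
                "exactly one of theta0 / pm_snr_db must be specified")
        if self.method not in ("ias", "mne", "mce", "mcmc-cm"):
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.sigma_known, self.latent_factor,
                          self.epochs, self.reference_epochs)


def _resolve_theta0(config: RunConfig, n_positions: int) -> tuple[float, float]:
    """(theta0, pm_snr_db) with the missing one derived from the other."""
    if config.theta0 is not None:
        t0 = config.theta0
        p = pm_snr(t0, n_positions, config.noise, 1.0, config.jp_ref)
    else:
        p = config.pm_snr_db
        t0 = theta0_from_pm_snr(p, n_positions, config.noise, 1.0,
                                config.jp_ref)
    return float(t0), float(p)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute simulate -> invert -> metrics; write the artifact bundle.

    Writes ``leadfield.h5``, ``data.h5``, ``reconstruction.h5`` (or
    ``chain.h5``), ``report.csv`` and ``provenance.json`` under ``out_dir``;
    returns the in-memory results.  Identical config and seed give
    byte-identical numeric outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = scenario_p20n20_like(
        modality=config.modality, density=config.density,
        n_dense=config.n_dense, n_sensors=config.n_sensors,
        include_deep=config.include_deep, noise=config.noise,
        seed=config.seed)
    dataset = scenario.dataset
    lf = scenario.normalized_leadfield()  # consistent with normalized y
    space = lf.source_space
    theta0, pm_snr_db = _resolve_theta0(config, space.n_positions)
    spec = HyperpriorSpec(config.family, config.beta, theta0)
    sigma = dataset.sigma
    y = dataset.y_noisy
    roi = ROI("sphere", scenario.roi_center_mm, config.roi_diameter_mm)

    chain = None
    if config.method == "mne":
        result = mne(lf, y, sigma, theta0)
    elif config.method == "mce":
        result = mce(lf, y, sigma, theta0)
    elif config.method == "ias":
        result = ias_map(lf, y, sigma, spec, config.n_iterations)
    else:
        chain = gibbs_sample(lf, y, sigma, spec, roi,
                             n_samples=config.n_samples,
                             burn_in=config.burn_in, rng=config.seed)
        result = cm_estimate(chain)

    ref = dataset.truth[0]
    report = localization_report(result, space, ref.position, ref.orientation,
                                 roi=roi)

    write_leadfield(out / "leadfield.h5", lf)
    write_dataset(out / "data.h5", dataset)
    if chain is not None:
        write_chain(out / "chain.h5", chain)
    with h5py.File(out / "reconstruction.h5", "w") as f:
        f.create_dataset("x", data=result.x)
        f.create_dataset("theta", data=result.theta)
        f.attrs["method"] = result.method
    pd.DataFrame([report.as_dict()]).to_csv(out / "report.csv", index=False)

    provenance = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "derived": {
            "theta0": theta0, "pm_snr_db": pm_snr_db,
            "sigma_effective": sigma,
            "sigma_known": config.noise.sigma_known,
            "latent_factor": config.noise.latent_factor,
            "epoch_factor": float(np.sqrt(config.reference_epochs
                                          / config.epochs)),
            "amplitude": dataset.amplitude,
            "noise_convention": dataset.noise_convention,
            "n_positions": int(space.n_positions),
            "db_conventions": "amplitude: 20*log10, power/variance: 10*log10",
        },
        "seed": config.seed,
    }
    with open(out / "provenance.json", "w") as f:
        json.dump(provenance, f, indent=2)

    return {"scenario": scenario, "result": result, "chain": chain,
            "report": report, "provenance": provenance}
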