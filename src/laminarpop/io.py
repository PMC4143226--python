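"""Serialization: delimited text and HDF5 containers, scenario YAML files.

Recordings and CSD estimates round-trip through either a tab-delimited text
file with a one-line ``#``-prefixed JSON header (depths/grid, dt, sigma) or
an HDF5 container with datasets ``depths`` (or ``grid``) and ``values`` and
attributes ``dt_ms`` / ``sigma_S_per_m``.  Ground-truth datasets use groups
``population/<name>/{positions,currents,lfp}`` and ``total/{lfp,lfp_noisy}``;
ICA results use datasets ``spatial``, ``temporal``, ``mixing``, ``scales``.
Scenario files are YAML and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .decompose import ICAResult
from .forward import ElectrodeArray, PointSourceSet, PotentialRecording
from .kcsd import CSDEstimate
from .synth import GroundTruthDataset, Population, Scenario

__all__ = [
    "save_recording_txt",
    "load_recording_txt",
    "save_recording_h5",
    "load_recording_h5",
    "save_csd_txt",
    "load_csd_txt",
    "save_csd_h5",
    "load_csd_h5",
    "save_dataset_h5",
    "load_dataset_h5",
    "save_ica_h5",
    "load_ica_h5",
    "save_scenario",
    "load_scenario",
]


# -- text ------------------------------------------------------------------


def save_recording_txt(path, recording: PotentialRecording) -> None:
    header = json.dumps(
        {
            "depths_um": recording.array.depths.tolist(),
            "lateral_um": list(recording.array.lateral),
            "dt_ms": recording.dt,
            "sigma_S_per_m": recording.sigma,
        }
    )
    np.savetxt(path, recording.values, delimiter="\t", header=header)


def load_recording_txt(path) -> PotentialRecording:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = json.loads(header)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    array = ElectrodeArray(
        depths=np.asarray(meta["depths_um"]), lateral=tuple(meta["lateral_um"])
    )
    return PotentialRecording(
        array=array, values=values, sigma=meta["sigma_S_per_m"], dt=meta["dt_ms"]
    )


def save_csd_txt(path, csd: CSDEstimate) -> None:
    header = json.dumps(
        {"grid_um": csd.grid.tolist(), "dt_ms": csd.dt, "lambda": csd.lam}
    )
    np.savetxt(path, csd.values, delimiter="\t", header=header)


def load_csd_txt(path) -> CSDEstimate:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = json.loads(header)
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return CSDEstimate(
        grid=np.asarray(meta["grid_um"]), values=values,
        lam=meta.get("lambda"), dt=meta.get("dt_ms"),
    )


# -- HDF5 ------------------------------------------------------------------


def _write_recording(group, recording: PotentialRecording) -> None:
    group.create_dataset("depths", data=recording.array.depths)
    group.create_dataset("values", data=recording.values)
    group.attrs["dt_ms"] = recording.dt
    group.attrs["sigma_S_per_m"] = recording.sigma
    group.attrs["lateral_um"] = list(recording.array.lateral)


def _read_recording(group) -> PotentialRecording:
    array = ElectrodeArray(
        depths=group["depths"][()],
        lateral=tuple(group.attrs.get("lateral_um", (0.0, 0.0))),
    )
    return PotentialRecording(
        array=array,
        values=group["values"][()],
        sigma=float(group.attrs["sigma_S_per_m"]),
        dt=float(group.attrs["dt_ms"]),
    )


def save_recording_h5(path, recording: PotentialRecording) -> None:
    with h5py.File(path, "w") as fh:
        _write_recording(fh, recording)


def load_recording_h5(path) -> PotentialRecording:
    with h5py.File(path, "r") as fh:
        return _read_recording(fh)


def save_csd_h5(path, csd: CSDEstimate) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("grid", data=csd.grid)
        fh.create_dataset("values", data=csd.values)
        if csd.dt is not None:
            fh.attrs["dt_ms"] = csd.dt
        if csd.lam is not None:
            fh.attrs["lambda"] = csd.lam


def load_csd_h5(path) -> CSDEstimate:
    with h5py.File(path, "r") as fh:
        return CSDEstimate(
            grid=fh["grid"][()],
            values=fh["values"][()],
            lam=float(fh.attrs["lambda"]) if "lambda" in fh.attrs else None,
            dt=float(fh.attrs["dt_ms"]) if "dt_ms" in fh.attrs else None,
        )


def save_dataset_h5(path, dataset: GroundTruthDataset) -> None:
    """Write a ground-truth dataset: per-population sources + LFPs, totals."""
    with h5py.File(path, "w") as fh:
        fh.attrs["seed"] = dataset.seed
        fh.attrs["noise_percent"] = dataset.noise_percent
        fh.attrs["cutoff_hz"] = dataset.cutoff_hz
        if dataset.noise_seed is not None:
            fh.attrs["noise_seed"] = dataset.noise_seed
        geo = fh.create_group("geometry")
        geo.attrs["radius_um"] = dataset.geometry.radius
        geo.attrs["layers"] = json.dumps(
            {k: list(v) for k, v in dataset.geometry.layers.items()}
        )
        for name, pop in dataset.populations.items():
            g = fh.create_group(f"population/{name}")
            g.create_dataset("positions", data=pop.sources.positions)
            g.create_dataset("currents", data=pop.sources.currents)
            g.attrs["spec"] = json.dumps(
                {**pop.spec.__dict__, "depth_range": list(pop.spec.depth_range)}
            )
            _write_recording(g.create_group("lfp"), pop.lfp)
        total = fh.create_group("total")
        _write_recording(total.create_group("lfp"), dataset.total)
        _write_recording(total.create_group("lfp_noisy"), dataset.total_noisy)


def load_dataset_h5(path) -> GroundTruthDataset:
    from .synth import ColumnGeometry, PopulationSpec

    with h5py.File(path, "r") as fh:
        geometry = ColumnGeometry(
            layers={
                k: tuple(v)
                for k, v in json.loads(fh["geometry"].attrs["layers"]).items()
            },
            radius=float(fh["geometry"].attrs["radius_um"]),
        )
        populations = {}
        for name, g in fh["population"].items():
            spec_d = json.loads(g.attrs["spec"])
            spec_d["depth_range"] = tuple(spec_d["depth_range"])
            spec = PopulationSpec(**spec_d)
            lfp = _read_recording(g["lfp"])
            sources = PointSourceSet(
                positions=g["positions"][()],
                currents=g["currents"][()],
                dt=lfp.dt,
                labels=np.full(g["positions"].shape[0], name),
                conserve_current=True,
            )
            populations[name] = Population(spec=spec, sources=sources, lfp=lfp)
        total = _read_recording(fh["total/lfp"])
        total_noisy = _read_recording(fh["total/lfp_noisy"])
        return GroundTruthDataset(
            populations=populations,
            total=total,
            total_noisy=total_noisy,
            geometry=geometry,
            seed=int(fh.attrs["seed"]),
            noise_percent=float(fh.attrs["noise_percent"]),
            noise_seed=int(fh.attrs["noise_seed"]) if "noise_seed" in fh.attrs else None,
            cutoff_hz=float(fh.attrs.get("cutoff_hz", 500.0)),
        )


def save_ica_h5(path, ica: ICAResult, seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("spatial", data=ica.spatial)
        fh.create_dataset("temporal", data=ica.temporal)
        fh.create_dataset("scales", data=ica.scales)
        fh.create_dataset("mixing", data=ica.unmixing)
        fh.attrs["mode"] = ica.mode
        fh.attrs["alpha"] = ica.alpha
        fh.attrs["objective"] = ica.objective
        fh.attrs["n_iter"] = ica.n_iter
        fh.attrs["converged"] = ica.converged
        if seed is not None:
            fh.attrs["seed"] = seed


def load_ica_h5(path) -> ICAResult:
    with h5py.File(path, "r") as fh:
        return ICAResult(
            spatial=fh["spatial"][()],
            temporal=fh["temporal"][()],
            scales=fh["scales"][()],
            unmixing=fh["mixing"][()],
            mode=str(fh.attrs["mode"]),
            alpha=float(fh.attrs["alpha"]),
            objective=float(fh.attrs["objective"]),
            n_iter=int(fh.attrs["n_iter"]),
            converged=bool(fh.attrs["converged"]),
        )


# -- scenarios -------------------------------------------------------------


def save_scenario(path, scenario: Scenario) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return Scenario.from_dict(yaml.safe_load(fh))
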