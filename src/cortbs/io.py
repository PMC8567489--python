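"""Container I/O: HDF5 for populations/RF/spectra, TIFF+JSON for volumes,
CSV for cohorts and distributions."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ctsim import MicroCTVolume
from .pores import MatrixProperties, PoreFluidProperties, PorePopulation
from .rf import AcousticsConfig, AcquisitionGeometry, RFDataset

FORMAT_VERSION = "1"


class ContainerError(RuntimeError):
    pass


def write_rf_container(path, rf: RFDataset, pop: PorePopulation | None = None) -> None:
    """Write pores / RF / geometry groups with units as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("rf")
        d = g.create_dataset("samples", data=rf.samples, compression="gzip")
        d.attrs["axes"] = "tilt,steering,scanline,time"
        g.attrs["sampling_mhz"] = rf.sampling_mhz
        gg = f.create_group("geometry")
        for k, v in vars(rf.geometry).items():
            gg.attrs[k] = v
        if rf.acoustics is not None:
            ga = f.create_group("acoustics")
            for k, v in vars(rf.acoustics).items():
                ga.attrs[k] = v
        if rf.truth:
            gt = f.create_group("truth")
            for k, v in rf.truth.items():
                gt.attrs[k] = v
        if pop is not None:
            gp = f.create_group("pores")
            gp.create_dataset("centers", data=pop.centers)
            gp["centers"].attrs["units"] = "mm"
            gp.create_dataset("diameters", data=pop.diameters_um)
            gp["diameters"].attrs["units"] = "um"
            gp.attrs["slab_extent_mm"] = pop.slab_extent
            gp.attrs["pore_axis"] = pop.pore_axis
            gp.attrs["matrix_sound_speed"] = pop.matrix.sound_speed
            gp.attrs["matrix_density"] = pop.matrix.density
            gp.attrs["matrix_vbmd"] = pop.matrix.vbmd
            gp.attrs["fluid_sound_speed"] = pop.pore_fluid.sound_speed
            gp.attrs["fluid_density"] = pop.pore_fluid.density


def read_rf_container(path):
    """Read back ``(RFDataset, PorePopulation | None)``."""
    with h5py.File(path, "r") as f:
        ver = f.attrs.get("format_version")
        if ver != FORMAT_VERSION:
            raise ContainerError(f"unrecognized container version {ver!r}")
        geom = AcquisitionGeometry(**{
            k: (tuple(v) if isinstance(v, np.ndarray) else
                v.item() if hasattr(v, "item") else v)
            for k, v in f["geometry"].attrs.items()
        })
        ac = None
        if "acoustics" in f:
            ac = AcousticsConfig(**{
                k: (bool(v) if k == "decorrelate_tilts" else
                    v.item() if hasattr(v, "item") else v)
                for k, v in f["acoustics"].attrs.items()
            })
        truth = {k: (v.item() if hasattr(v, "item") else v)
                 for k, v in f["truth"].attrs.items()} if "truth" in f else {}
        rf = RFDataset(
            samples=f["rf/samples"][...],
            sampling_mhz=float(f["rf"].attrs["sampling_mhz"]),
            geometry=geom,
            acoustics=ac,
            truth=truth,
        )
        pop = None
        if "pores" in f:
            gp = f["pores"]
            pop = PorePopulation(
                slab_extent=tuple(gp.attrs["slab_extent_mm"]),
                centers=gp["centers"][...],
                diameters_um=gp["diameters"][...],
                matrix=MatrixProperties(
                    sound_speed=float(gp.attrs["matrix_sound_speed"]),
                    density=float(gp.attrs["matrix_density"]),
                    vbmd=float(gp.attrs["matrix_vbmd"]),
                ),
                pore_fluid=PoreFluidProperties(
                    sound_speed=float(gp.attrs["fluid_sound_speed"]),
                    density=float(gp.attrs["fluid_density"]),
                ),
            )
    return rf, pop


def write_volume(path, vol: MicroCTVolume) -> None:
    """Multi-page TIFF plus a JSON sidecar with calibration metadata."""
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32))
    sidecar = {
        "format_version": FORMAT_VERSION,
        "voxel_um": vol.voxel_um,
        "calibration": vol.calibration,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path) -> MicroCTVolume:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("format_version") != FORMAT_VERSION:
        raise ContainerError("unrecognized volume sidecar version")
    data = tifffile.imread(path).astype(float)
    return MicroCTVolume(
        data=data, voxel_um=float(sidecar["voxel_um"]), calibration=sidecar["calibration"]
    )


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spectra(h5_path, nds=None, att=None, bsc=None) -> None:
    """NDS / attenuation / BSC results as an HDF5 group."""
    with h5py.File(h5_path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        if nds is not None:
            g = f.create_group("nds")
            g.create_dataset("values_db", data=nds.values)
            g.create_dataset("depth_mm", data=nds.depth_mm)
            g.create_dataset("freq_mhz", data=nds.freq_mhz)
            g.create_dataset("counts", data=nds.counts)
            g.create_dataset("reference_spectrum", data=nds.reference_spectrum)
        if att is not None:
            g = f.create_group("attenuation")
            g.create_dataset("alpha_db_mm", data=att.alpha_db_mm)
            g.create_dataset("freq_mhz", data=att.freq_mhz)
            g.attrs["alpha0"] = att.alpha0
            g.attrs["alphaf"] = att.alphaf
            g.attrs["r_squared"] = att.r_squared
        if bsc is not None:
            g = f.create_group("bsc")
            g.create_dataset("bsc", data=bsc.bsc)
            g.create_dataset("freq_mhz", data=bsc.freq_mhz)
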