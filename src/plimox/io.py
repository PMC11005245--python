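"""Container formats: HDF5 cohort files, truth sidecars, TIFF stacks, CSVs.

The cohort container lays out raw acquisitions as
``/animals/<animal>/day_<d>/<vessel_id>/{decays, traces}`` with per-group
attributes for metadata and root attributes for the schema version,
protocol and calibration.  Ground truth (when the data are synthetic)
travels in a sidecar CSV next to the container.  All summary tables are
plain CSVs carrying a ``config_hash`` provenance column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import h5py
import numpy as np
import pandas as pd
import tifffile

from .dataset import SCHEMA_VERSION, CohortDataset, PointAcquisition
from .errors import IntegrityError
from .plim import DecayHistogram
from .protocol import AcquisitionProtocol, CalibrationParams
from .rbcflux import IntensityTrace

__all__ = [
    "config_hash",
    "write_cohort",
    "read_cohort",
    "write_if_stack",
    "read_if_stack",
    "write_table",
]

PathLike = Union[str, Path]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration for output provenance."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_cohort(dataset: CohortDataset, path: PathLike) -> Path:
    """Write a cohort dataset to HDF5 plus a ground-truth sidecar CSV."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = dataset.schema_version
        f.attrs["protocol"] = json.dumps(_jsonable(dataset.protocol))
        f.attrs["calib"] = json.dumps(_jsonable(dataset.calib))
        if dataset.config is not None:
            f.attrs["config"] = json.dumps(_jsonable(dataset.config))
        root = f.create_group("animals")
        for p in dataset.points:
            grp = root.require_group(p.animal_id).require_group(
                f"day_{p.day}"
            ).create_group(p.vessel_id)
            grp.attrs.update(
                {
                    "parent_id": p.parent_id,
                    "cohort": p.cohort,
                    "day": p.day,
                    "depth_um": p.depth_um,
                    "morphology": p.morphology,
                    "is_primary_branch": p.is_primary_branch,
                }
            )
            decays = np.stack([d.counts for d in p.decays])
            grp.create_dataset("decays", data=decays, compression="gzip")
            if p.traces is not None:
                traces = np.stack([t.counts for t in p.traces])
                grp.create_dataset("traces", data=traces, compression="gzip")
    truth = dataset.truth_table()
    if not truth.empty:
        truth.to_csv(path.with_suffix(path.suffix + ".truth.csv"), index=False)
    return path


def read_cohort(path: PathLike) -> CohortDataset:
    """Read a cohort container back into memory, validating integrity.

    A vessel group without its ``decays`` dataset raises
    :class:`IntegrityError` naming the vessel; an unknown schema version is
    a versioned error; an empty container is a valid empty dataset.
    """
    path = Path(path)
    points: list[PointAcquisition] = []
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version", "")
        if version != SCHEMA_VERSION:
            raise IntegrityError(
                f"unsupported schema version {version!r} "
                f"(supported: {SCHEMA_VERSION!r})"
            )
        protocol = AcquisitionProtocol(**json.loads(f.attrs["protocol"]))
        calib = CalibrationParams(**json.loads(f.attrs["calib"]))
        config = (
            json.loads(f.attrs["config"]) if "config" in f.attrs else None
        )
        t_us = protocol.bin_times_us()
        for animal_id in sorted(f.get("animals", {})):
            agrp = f["animals"][animal_id]
            for day_key in sorted(agrp):
                day = int(day_key.split("_", 1)[1])
                dgrp = agrp[day_key]
                for vessel_id in sorted(dgrp):
                    vgrp = dgrp[vessel_id]
                    if "decays" not in vgrp:
                        raise IntegrityError(
                            f"vessel {vessel_id!r} ({animal_id}, day {day}) "
                            "is missing its decays"
                        )
                    decays = [
                        DecayHistogram(t=t_us, counts=row, protocol=protocol)
                        for row in vgrp["decays"][()]
                    ]
                    traces = None
                    if "traces" in vgrp:
                        traces = [
                            IntensityTrace(
                                counts=row,
                                protocol=protocol,
                                vessel_id=vessel_id,
                            )
                            for row in vgrp["traces"][()]
                        ]
                    points.append(
                        PointAcquisition(
                            vessel_id=vessel_id,
                            parent_id=str(vgrp.attrs["parent_id"]),
                            animal_id=animal_id,
                            cohort=str(vgrp.attrs["cohort"]),
                            day=day,
                            depth_um=float(vgrp.attrs["depth_um"]),
                            morphology=str(vgrp.attrs["morphology"]),
                            is_primary_branch=bool(
                                vgrp.attrs["is_primary_branch"]
                            ),
                            decays=decays,
                            traces=traces,
                        )
                    )
    return CohortDataset(
        points=points, protocol=protocol, calib=calib, config=config
    )


def write_if_stack(stack, path: PathLike) -> Path:
    """Write an IF stack as a multi-page TIFF (channel-major pages) with a
    JSON sidecar of scalar ground truth (masks are not serialized)."""
    path = Path(path)
    pages = stack.data.reshape(-1, *stack.data.shape[2:]).astype(np.float32)
    tifffile.imwrite(
        path,
        pages,
        metadata={
            "channels": list(stack.channels),
            "n_z": stack.data.shape[1],
            "z_step_um": stack.z_step_um,
            "pixel_size_um": stack.pixel_size_um,
            "image_id": stack.image_id,
        },
    )
    if stack.truth is not None:
        sidecar = {
            k: _jsonable(v)
            for k, v in stack.truth.items()
            if k != "masks"
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_if_stack(path: PathLike):
    """Read a multi-page TIFF written by :func:`write_if_stack`."""
    from .histology import IFImageStack

    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    channels = tuple(meta.get("channels", ["ch0"]))
    n_z = int(meta.get("n_z", pages.shape[0] // len(channels)))
    data = pages.reshape(len(channels), n_z, *pages.shape[1:])
    return IFImageStack(
        data=data,
        channels=channels,
        z_step_um=float(meta.get("z_step_um", 3.96)),
        pixel_size_um=float(meta.get("pixel_size_um", 0.69)),
        image_id=str(meta.get("image_id", path.stem)),
    )


def write_table(
    df: pd.DataFrame, path: PathLike, cfg_hash: Optional[str] = None
) -> Path:
    """Write a tidy CSV, stamping a ``config_hash`` provenance column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if cfg_hash is not None:
        out["config_hash"] = cfg_hash
    out.to_csv(path, index=False)
    return path
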