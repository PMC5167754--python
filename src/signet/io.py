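"""Record serialization (HDF5) and run manifests."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass
from typing import Optional

import h5py
import numpy as np
import yaml

from . import __version__
from .config import config_from_dict, config_to_dict
from .core_model import NeuralSignature
from .network_sim import ActivityRecord, StimulusEntry

__all__ = ["save_record", "load_record", "RunManifest", "write_manifest"]


def save_record(record: ActivityRecord, path) -> None:
    """Write an :class:`ActivityRecord` to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["signet_version"] = __version__
        f.attrs["config_yaml"] = yaml.safe_dump(
            config_to_dict(record.config), sort_keys=False
        )
        f.attrs["frame_stride"] = record.frame_stride
        f.attrs["label_stride"] = record.label_stride
        if record.complexity_eps is not None:
            f.attrs["complexity_eps"] = record.complexity_eps
        f.create_dataset(
            "tracked_cells", data=np.asarray(record.tracked_cells, dtype=np.int64)
        )
        if record.tracked_signatures:
            f.create_dataset(
                "tracked_signatures",
                data=np.array(
                    [s.isis for s in record.tracked_signatures], dtype=np.int64
                ),
            )
        f.create_dataset(
            "stimuli",
            data=np.array(
                [
                    [
                        s.cell,
                        s.period,
                        s.t_start,
                        -1 if s.t_end is None else s.t_end,
                        s.g_e,
                    ]
                    for s in record.stimuli
                ],
                dtype=np.int64,
            ).reshape(-1, 5),
        )
        f.create_dataset(
            "signature_counts", data=record.signature_counts, compression="gzip"
        )
        for name in (
            "v_frames",
            "frame_times",
            "label_frames",
            "label_times",
            "spike_times",
            "spike_cells",
            "complexity",
        ):
            value = getattr(record, name)
            if value is not None:
                f.create_dataset(name, data=value, compression="gzip")


def load_record(path) -> ActivityRecord:
    """Read an :class:`ActivityRecord` back from an HDF5 container."""
    with h5py.File(path, "r") as f:
        if "config_yaml" not in f.attrs:
            raise ValueError(f"{path} is not a signet activity record")
        config = config_from_dict(yaml.safe_load(f.attrs["config_yaml"]))
        stim_rows = f["stimuli"][()]
        stimuli = tuple(
            StimulusEntry(
                cell=int(r[0]),
                period=int(r[1]),
                t_start=int(r[2]),
                t_end=None if r[3] < 0 else int(r[3]),
                g_e=int(r[4]),
            )
            for r in stim_rows
        )
        tracked_cells = tuple(int(c) for c in f["tracked_cells"][()])
        if "tracked_signatures" in f:
            tracked_signatures = tuple(
                NeuralSignature(row) for row in f["tracked_signatures"][()]
            )
        else:
            tracked_signatures = ()

        def get(name):
            return f[name][()] if name in f else None

        return ActivityRecord(
            config=config,
            stimuli=stimuli,
            tracked_cells=tracked_cells,
            tracked_signatures=tracked_signatures,
            signature_counts=f["signature_counts"][()],
            frame_stride=int(f.attrs["frame_stride"]),
            v_frames=get("v_frames"),
            frame_times=get("frame_times"),
            label_stride=int(f.attrs["label_stride"]),
            label_frames=get("label_frames"),
            label_times=get("label_times"),
            spike_times=get("spike_times"),
            spike_cells=get("spike_cells"),
            complexity=get("complexity"),
            complexity_eps=f.attrs.get("complexity_eps"),
        )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility metadata for one simulation run."""

    config: dict
    seed: int
    version: str
    outputs: dict  # path -> sha256
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def write_manifest(
    record: ActivityRecord,
    record_path,
    manifest_path,
    started: Optional[datetime.datetime] = None,
) -> RunManifest:
    now = datetime.datetime.now().isoformat(timespec="seconds")
    manifest = RunManifest(
        config=config_to_dict(record.config),
        seed=record.config.seed,
        version=__version__,
        outputs={str(record_path): _sha256(record_path)},
        started=(started.isoformat(timespec="seconds") if started else now),
        finished=now,
    )
    with open(manifest_path, "w") as fh:
        fh.write(manifest.to_json())
    return manifest
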