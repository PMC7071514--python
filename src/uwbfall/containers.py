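"""Dataset container: a self-describing HDF5 file plus a CSV manifest.

No standard interchange format exists for raw IR-UWB activity recordings,
so the package defines a versioned schema:

* ``samples``      (n, M, n_bins_raw) float64 — raw echo frames
* ``references``   (n, n_bins_raw)    float64 — no-target reference frames
* ``labels``       (n,) int                  — activity labels 1..K
* ``subject_ids``  (n,) str
* ``environment_ids`` (n,) str
* attrs: ``format_version``, ``config_json`` (scene snapshot),
  ``class_map_json``, ``sha256`` over the numeric payload.

``<name>.manifest.csv`` lists (sample_id, label, subject, environment) as
plain text.  Round trips are lossless and integrity-checked on read.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .radar_sim import ActivityLabel, RawRecording

FORMAT_VERSION = 1

CLASS_MAP = {int(a): a.name.lower() for a in ActivityLabel}


class ContainerIntegrityError(IOError):
    """The file's payload hash does not match its recorded hash."""


class ContainerVersionError(IOError):
    """The file was written by an incompatible format version."""


@dataclass
class DatasetContainer:
    samples: np.ndarray
    references: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    environment_ids: np.ndarray
    config: dict = field(default_factory=dict)
    format_version: int = FORMAT_VERSION

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @staticmethod
    def from_recordings(recordings: list[RawRecording], config: dict | None = None) -> "DatasetContainer":
        if not recordings:
            raise ValueError("cannot build a container from zero recordings")
        return DatasetContainer(
            samples=np.stack([r.frames for r in recordings]),
            references=np.stack([r.reference for r in recordings]),
            labels=np.array([int(r.label) for r in recordings]),
            subject_ids=np.array([r.subject_id for r in recordings]),
            environment_ids=np.array([r.environment_id for r in recordings]),
            config=dict(config or {}),
        )

    def to_recordings(self) -> list[RawRecording]:
        return [
            RawRecording(
                frames=self.samples[i],
                reference=self.references[i],
                label=ActivityLabel(int(self.labels[i])),
                subject_id=str(self.subject_ids[i]),
                environment_id=str(self.environment_ids[i]),
            )
            for i in range(self.n_samples)
        ]

    def payload_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.samples, self.references, self.labels):
            h.update(np.ascontiguousarray(arr).tobytes())
        for arr in (self.subject_ids, self.environment_ids):
            h.update("\x00".join(str(x) for x in arr).encode())
        return h.hexdigest()


def write_container(path, container: DatasetContainer) -> None:
    """Write the container and its CSV manifest next to it."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=container.samples)
        f.create_dataset("references", data=container.references)
        f.create_dataset("labels", data=container.labels)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("subject_ids", data=np.asarray(container.subject_ids, dtype=object), dtype=str_dt)
        f.create_dataset(
            "environment_ids", data=np.asarray(container.environment_ids, dtype=object), dtype=str_dt
        )
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["config_json"] = json.dumps(container.config)
        f.attrs["class_map_json"] = json.dumps(CLASS_MAP)
        f.attrs["sha256"] = container.payload_hash()
    manifest = pd.DataFrame(
        {
            "sample_id": np.arange(container.n_samples),
            "label": container.labels,
            "subject": container.subject_ids,
            "environment": container.environment_ids,
        }
    )
    manifest.to_csv(manifest_path(path), index=False)


def manifest_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".manifest.csv")


def read_container(path) -> DatasetContainer:
    """Read and integrity-check a dataset container."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("format_version", -1))
        if version != FORMAT_VERSION:
            raise ContainerVersionError(
                f"container version {version} != supported {FORMAT_VERSION}; migrate the file"
            )
        container = DatasetContainer(
            samples=f["samples"][...],
            references=f["references"][...],
            labels=f["labels"][...],
            subject_ids=np.array([s.decode() if isinstance(s, bytes) else str(s) for s in f["subject_ids"][...]]),
            environment_ids=np.array(
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["environment_ids"][...]]
            ),
            config=json.loads(f.attrs.get("config_json", "{}")),
            format_version=version,
        )
        recorded = f.attrs.get("sha256", "")
    if container.payload_hash() != recorded:
        raise ContainerIntegrityError(f"payload hash mismatch in {path}")
    return container
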