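"""On-disk formats: HDF5 recording containers and tidy TSV/JSON outputs.

Recordings are stored one HDF5 group per recording (voltage vector plus
sampling/onset/condition/subject attributes) together with a manifest
table; the round trip is lossless.  Derived tables go to TSV with a
comment header carrying the configuration hash and stage seed so every
output is traceable to the run that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .recording import ABRRecording
from .stimuli import StimulusCondition

__all__ = [
    "write_recordings",
    "read_recordings",
    "write_table",
    "write_metrics",
]

_REQUIRED_ATTRS = (
    "sampling_rate_hz",
    "nb1_onset_ms",
    "nb2_onset_ms",
    "nb1_ms",
    "gap_ms",
    "nb2_ms",
    "subject_id",
)


def write_recordings(recordings: Sequence[ABRRecording], path: str | Path) -> None:
    """Write a recording collection to an HDF5 container (lossless)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "abrgap-recordings"
        f.attrs["version"] = 1
        names = []
        for i, rec in enumerate(recordings):
            name = f"rec_{i:04d}"
            g = f.create_group(name)
            g.create_dataset("trace_uv", data=rec.trace_uv)
            g.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
            g.attrs["nb1_onset_ms"] = rec.nb1_onset_ms
            g.attrs["nb2_onset_ms"] = rec.nb2_onset_ms
            g.attrs["nb1_ms"] = rec.condition.nb1_ms
            g.attrs["gap_ms"] = rec.condition.gap_ms
            g.attrs["nb2_ms"] = rec.condition.nb2_ms
            g.attrs["subject_id"] = rec.subject_id
            names.append(name)
        manifest = f.create_group("manifest")
        str_dtype = h5py.string_dtype()
        manifest.create_dataset("group", data=names, dtype=str_dtype)
        manifest.create_dataset(
            "subject_id", data=[r.subject_id for r in recordings], dtype=str_dtype
        )
        manifest.create_dataset("nb1_ms", data=[r.condition.nb1_ms for r in recordings])
        manifest.create_dataset("gap_ms", data=[r.condition.gap_ms for r in recordings])


def read_recordings(path: str | Path) -> list[ABRRecording]:
    """Read a recording collection; validates the manifest and schema."""
    path = Path(path)
    recordings = []
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "abrgap-recordings":
            raise ValueError(f"{path} is not an abrgap recording container")
        if "manifest" not in f:
            raise ValueError("missing manifest group")
        names = [n.decode() if isinstance(n, bytes) else n for n in f["manifest/group"][()]]
        for name in names:
            if name not in f:
                raise ValueError(f"manifest names missing group {name!r}")
            g = f[name]
            for attr in _REQUIRED_ATTRS:
                if attr not in g.attrs:
                    raise ValueError(f"group {name!r} missing field {attr!r}")
            if "trace_uv" not in g:
                raise ValueError(f"group {name!r} missing field 'trace_uv'")
            subject = g.attrs["subject_id"]
            if isinstance(subject, bytes):
                subject = subject.decode()
            recordings.append(
                ABRRecording(
                    trace_uv=g["trace_uv"][()],
                    sampling_rate_hz=float(g.attrs["sampling_rate_hz"]),
                    nb1_onset_ms=float(g.attrs["nb1_onset_ms"]),
                    nb2_onset_ms=float(g.attrs["nb2_onset_ms"]),
                    condition=StimulusCondition(
                        nb1_ms=float(g.attrs["nb1_ms"]),
                        gap_ms=float(g.attrs["gap_ms"]),
                        nb2_ms=float(g.attrs["nb2_ms"]),
                    ),
                    subject_id=str(subject),
                )
            )
    return recordings


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    config_hash: str | None = None,
    stage_seed: int | None = None,
) -> None:
    """Write a tidy TSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash} stage_seed={stage_seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_metrics(metrics: dict, path: str | Path) -> None:
    """Deterministically serialized metrics JSON (sorted keys)."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(metrics, indent=2, sort_keys=True, default=_default))
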