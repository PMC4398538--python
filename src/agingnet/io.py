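"""Plain-text readers and writers for every pipeline artifact.

All tables are UTF-8 TSV with one header row (cohort tables are CSV).
Regions are labelled ``<hemisphere>:<name>`` in matrix headers.  A dataset
directory is described by ``manifest.json`` recording the generating spec,
seed and SHA-256 checksums of every file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import Atlas
from .netbuild import ConnectivityMatrix, FiberRecord, FiberTally, Modality
from .preprocess import NuisanceSet, TimeSeriesPanel


def _region_labels(atlas: Atlas) -> list[str]:
    return [f"{r.hemisphere.value}:{r.name}" for r in atlas.regions]


# -- time series ------------------------------------------------------------


def write_timeseries(panel: TimeSeriesPanel, path: str | Path, labels=None) -> None:
    cols = labels if labels is not None else [f"series{j}" for j in range(panel.n_series)]
    pd.DataFrame(panel.data, columns=cols).to_csv(path, sep="\t", index=False)
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    sidecar.write_text(
        json.dumps({"tr_seconds": panel.tr_seconds, "subject_id": panel.subject_id})
    )


def read_timeseries(path: str | Path, tr_seconds: float | None = None) -> TimeSeriesPanel:
    df = pd.read_csv(path, sep="\t")
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    subject_id = ""
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        tr_seconds = tr_seconds if tr_seconds is not None else meta.get("tr_seconds")
        subject_id = meta.get("subject_id", "")
    if tr_seconds is None:
        raise ValueError(f"no repetition time: pass tr_seconds or provide {sidecar}")
    return TimeSeriesPanel(df.to_numpy(float), tr_seconds, subject_id)


def write_nuisance(nuisance: NuisanceSet, path: str | Path) -> None:
    cols = nuisance.names or [f"nuisance{j}" for j in range(nuisance.data.shape[1])]
    pd.DataFrame(nuisance.data, columns=list(cols)).to_csv(path, sep="\t", index=False)


def read_nuisance(path: str | Path, subject_id: str = "") -> NuisanceSet:
    df = pd.read_csv(path, sep="\t")
    return NuisanceSet(df.to_numpy(float), subject_id, tuple(df.columns))


# -- fibers -----------------------------------------------------------------


def write_tally(tally: FiberTally, atlas: Atlas, counts_path, metadata_path) -> None:
    labels = _region_labels(atlas)
    pd.DataFrame(tally.fcount, columns=labels).to_csv(counts_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "name": [r.name for r in atlas.regions],
            "hemisphere": [r.hemisphere.value for r in atlas.regions],
            "n_voxels": tally.voxel_count,
            "volume_mm3": tally.volume_mm3,
            "streamlines_per_voxel": tally.streamlines_per_voxel,
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_tally(counts_path, metadata_path, subject_id: str = "") -> FiberTally:
    counts = pd.read_csv(counts_path, sep="\t")
    meta = pd.read_csv(metadata_path, sep="\t")
    if len(counts) != len(meta):
        raise ValueError("tally matrix and metadata disagree on region count")
    spv = int(meta["streamlines_per_voxel"].iloc[0]) if "streamlines_per_voxel" in meta else 1000
    return FiberTally(
        fcount=counts.to_numpy(np.int64),
        voxel_count=meta["n_voxels"].to_numpy(int),
        volume_mm3=meta["volume_mm3"].to_numpy(float),
        streamlines_per_voxel=spv,
        subject_id=subject_id,
    )


def write_fiber_records(records, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "seed_region": [r.seed_region for r in records],
            "end_region": [r.end_region for r in records],
            "length_mm": [r.length_mm for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fiber_records(path: str | Path) -> list[FiberRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        FiberRecord(int(s), int(e), float(l))
        for s, e, l in zip(df["seed_region"], df["end_region"], df["length_mm"])
    ]


# -- networks ---------------------------------------------------------------


def write_network(net: ConnectivityMatrix, atlas: Atlas, path: str | Path) -> None:
    pd.DataFrame(net.weights, columns=_region_labels(atlas)).to_csv(
        path, sep="\t", index=False
    )


def read_network(path, modality: Modality | str, subject_id: str = "") -> ConnectivityMatrix:
    w = pd.read_csv(path, sep="\t").to_numpy(float)
    w = 0.5 * (w + w.T)  # guard against decimal-formatting asymmetry
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, Modality(modality), subject_id)


# -- manifests --------------------------------------------------------------


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, spec, files: list[str], extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    manifest = {
        "spec": asdict(spec) if hasattr(spec, "__dataclass_fields__") else spec,
        "files": {f: sha256_file(out_dir / f) for f in sorted(files)},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str) + "\n")
    return path
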