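"""Volume and study-table I/O.

Volumes travel as NIfTI-1 (via nibabel), float32, RAS orientation, spacing
in the header; the modality/units tag rides in the header ``descrip`` field
so a round trip preserves the full :class:`~fibropet.grids.VolumeGrid`.
Study metadata is a CSV table with one row per scan; pipeline configuration
is YAML or JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Dict, List

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import MODALITY_UNITS, VolumeGrid
from .meta import ScanMeta

REQUIRED_COLUMNS = ("animal_id", "group", "day", "tracer", "dose_MBq",
                    "t_injection_ISO8601", "t_scan_ISO8601", "weight_g", "file")


def write_volume(path, vol: VolumeGrid) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz), float32, RAS affine."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = f"modality={vol.modality};units={vol.units}".encode()
    nib.save(img, str(path))
    return path


def read_volume(path, modality: str | None = None) -> VolumeGrid:
    """Read a NIfTI volume back into a :class:`VolumeGrid`.

    The modality is taken from the header tag written by
    :func:`write_volume`; for foreign files pass ``modality`` explicitly.
    Values are loaded as float32; write -> read is bitwise for float32 data
    and preserves spacing exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as e:  # corrupt/truncated file: no partial volume
        raise IOError(f"cannot read NIfTI volume {path}: {e}") from e
    if data.ndim != 3:
        raise IOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise IOError(f"{path}: missing or non-positive voxel spacing {zooms}")
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    tags = dict(kv.split("=", 1) for kv in descrip.split(";") if "=" in kv)
    mod = modality or tags.get("modality")
    if mod not in MODALITY_UNITS:
        raise IOError(f"{path}: modality tag missing or unknown ({mod!r}); pass modality=")
    return VolumeGrid(data, tuple(float(z) for z in zooms), mod)


@dataclass
class StudyTable:
    """Validated scan table: ScanMeta records joined to volume paths.

    ``frame`` keeps the raw rows (including CT rows, which carry no tracer
    metadata); ``pet_meta`` maps (animal, day, tracer) to ScanMeta.
    """

    frame: pd.DataFrame
    root: Path
    pet_meta: Dict[tuple, ScanMeta]

    def volume_path(self, row) -> Path:
        return self.root / row["file"]


def load_study(table_path, root=None) -> StudyTable:
    """Load and validate a study CSV.

    Enforces: required columns present, unique (animal, day, tracer) keys,
    positive doses and weights, acquisition after injection, and that every
    referenced volume file exists under ``root``.
    """
    table_path = Path(table_path)
    root = Path(root) if root is not None else table_path.parent
    df = pd.read_csv(table_path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study table {table_path} missing columns: {missing}")

    keys = list(zip(df["animal_id"], df["day"], df["tracer"]))
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    if dupes:
        raise ValueError(f"duplicate (animal, day, tracer) keys in study table: {dupes}")

    pet_meta: Dict[tuple, ScanMeta] = {}
    for _, row in df.iterrows():
        fpath = root / row["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"study table references missing volume: {fpath}")
        if row["tracer"] == "CT":
            continue
        meta = ScanMeta(
            animal_id=str(row["animal_id"]), group=str(row["group"]),
            day=int(row["day"]), tracer=str(row["tracer"]),
            dose_mbq=float(row["dose_MBq"]),
            t_injection=datetime.fromisoformat(str(row["t_injection_ISO8601"])),
            t_scan=datetime.fromisoformat(str(row["t_scan_ISO8601"])),
            weight_g=float(row["weight_g"]),
        )  # ScanMeta validates dose/weight/time ordering
        pet_meta[(meta.animal_id, meta.day, meta.tracer)] = meta
    return StudyTable(frame=df, root=root, pet_meta=pet_meta)


def load_config(path) -> dict:
    """Load a YAML or JSON pipeline/phantom configuration file."""
    import json

    import yaml

    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)
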