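"""Volume, mask, manifest and climate I/O.

Conventions used throughout the toolkit:

* arrays are indexed ``(z, y, x)`` with axis 0 the depth axis,
  index 0 at the top of the scan; ``depth_mm = index * spacing``;
* spacing is per-axis in millimetres, same ``(z, y, x)`` order;
* timestamps are ISO-8601 and assumed UTC when no zone is given;
* all text I/O is locale-independent (dot decimal separator).

Supported volume formats are MetaImage (``.mhd`` text header plus raw
voxel file; the dialect is restricted to ``ObjectType=Image``,
``BinaryData=True`` and uncompressed data) and TIFF (a single multipage
file, or a directory of equally-shaped numbered slices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

__all__ = [
    "Volume3D",
    "ClimateRecord",
    "PlantManifest",
    "read_volume",
    "write_volume",
    "load_climate",
    "join_climate",
    "load_manifest",
    "write_trait_table",
    "read_trait_table",
    "TRAIT_COLUMNS",
]

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


@dataclass
class Volume3D:
    """A reconstructed grayscale CT volume with physical voxel spacing.

    ``voxels`` holds attenuation values in arbitrary units; gray value
    correlates with material density. ``spacing_mm`` is per-axis voxel
    edge length in (z, y, x) order, with axis ``depth_axis`` (default 0)
    pointing downward into the pot.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    depth_axis: int = 0
    source_path: str | None = None
    plant_id: str | None = None
    timestamp: str | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 strictly positive values, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite gray values")
        if self.depth_axis != 0:
            raise ValueError("only depth_axis=0 is supported; transpose the array first")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mhd":
        return "mhd"
    if suffix in (".tif", ".tiff") or path.is_dir():
        return "tiff_stack"
    raise ValueError(f"cannot infer volume format from {path!s}; pass format='mhd' or 'tiff_stack'")


def read_volume(path: str | Path, format: str | None = None) -> Volume3D:
    """Read a volume from MHD+RAW or a TIFF stack.

    Raises ``ValueError`` with the offending field named for unsupported
    element types, missing raw files, or inconsistent slice shapes.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mhd":
        return _read_mhd(path)
    if fmt == "tiff_stack":
        return _read_tiff(path)
    raise ValueError(f"unsupported format {fmt!r}; expected 'mhd' or 'tiff_stack'")


def _read_mhd(path: Path) -> Volume3D:
    if not path.exists():
        raise FileNotFoundError(f"MHD header not found: {path}")
    header = _parse_mhd_header(path)
    ndims = int(header.get("NDims", "0"))
    if ndims != 3:
        raise ValueError(f"MHD field NDims must be 3, got {ndims}")
    raw_name = header.get("ElementDataFile")
    if raw_name is None:
        raise ValueError("MHD field ElementDataFile is missing")
    if raw_name != "LOCAL" and not (path.parent / raw_name).exists():
        raise FileNotFoundError(f"MHD field ElementDataFile points to a missing raw file: {raw_name}")
    elem = header.get("ElementType", "")
    if elem not in ("MET_UCHAR", "MET_USHORT", "MET_FLOAT"):
        raise ValueError(
            f"MHD field ElementType {elem!r} unsupported; expected MET_UCHAR, MET_USHORT or MET_FLOAT"
        )
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing_xyz = img.GetSpacing()
    spacing = (float(spacing_xyz[2]), float(spacing_xyz[1]), float(spacing_xyz[0]))
    return Volume3D(arr, spacing, source_path=str(path))


def _parse_mhd_header(path: Path) -> dict[str, str]:
    fields: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    return fields


def _read_tiff(path: Path) -> Volume3D:
    if path.is_dir():
        slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not slices:
            raise FileNotFoundError(f"no TIFF slices found in directory {path}")
        arrays = [tifffile.imread(str(p)) for p in slices]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"TIFF slices have inconsistent shapes: {sorted(shapes)}")
        arr = np.stack(arrays, axis=0)
        spacing = (1.0, 1.0, 1.0)
        meta = path / "spacing.json"
        if meta.exists():
            spacing = tuple(json.loads(meta.read_text())["spacing_mm"])
        return Volume3D(arr, spacing, source_path=str(path))
    if not path.exists():
        raise FileNotFoundError(f"TIFF file not found: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        spacing = (1.0, 1.0, 1.0)
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                spacing = tuple(json.loads(desc.value)["spacing_mm"])
            except (json.JSONDecodeError, KeyError, TypeError):
                pass
    if arr.ndim != 3:
        raise ValueError(f"TIFF stack must be 3D, got shape {arr.shape}")
    return Volume3D(arr, spacing, source_path=str(path))


def write_volume(vol: Volume3D, path: str | Path, format: str | None = None) -> Path:
    """Write a volume as MHD+RAW or a multipage TIFF; round-trips with read_volume."""
    path = Path(path)
    fmt = format or _infer_format(path)
    arr = vol.voxels
    if arr.dtype not in _SUPPORTED_DTYPES:
        if np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        elif np.issubdtype(arr.dtype, np.integer):
            arr = arr.astype(np.uint16)
        else:
            raise ValueError(f"unsupported voxel dtype {arr.dtype}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mhd":
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing((vol.spacing_mm[2], vol.spacing_mm[1], vol.spacing_mm[0]))
        sitk.WriteImage(img, str(path), useCompression=False)
    elif fmt == "tiff_stack":
        desc = json.dumps({"spacing_mm": list(vol.spacing_mm)})
        tifffile.imwrite(str(path), arr, description=desc)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# climate metadata


@dataclass(frozen=True)
class ClimateRecord:
    """One climate-chamber log entry (temperature, humidity, CO2, light)."""

    timestamp: pd.Timestamp
    temperature_c: float = np.nan
    humidity_pct: float = np.nan
    co2_ppm: float = np.nan
    light: float = np.nan
    irrigation: float = np.nan


_CLIMATE_FIELDS = ("temperature_c", "humidity_pct", "co2_ppm", "light", "irrigation")


def load_climate(path: str | Path) -> list[ClimateRecord]:
    """Load a climate time series from CSV or JSON with ISO timestamps.

    Timestamps must be strictly increasing; the first offending row is
    named in the error otherwise.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    if "timestamp" not in df.columns:
        raise ValueError("climate data must have a 'timestamp' column")
    ts = pd.to_datetime(df["timestamp"], utc=True)
    bad = np.flatnonzero((ts.diff().iloc[1:] <= pd.Timedelta(0)).to_numpy())
    if bad.size:
        raise ValueError(
            f"climate timestamps not strictly increasing at row {bad[0] + 1} "
            f"({df['timestamp'].iloc[bad[0] + 1]!r})"
        )
    records = []
    for i in range(len(df)):
        kwargs = {f: float(df[f].iloc[i]) for f in _CLIMATE_FIELDS if f in df.columns}
        records.append(ClimateRecord(timestamp=ts.iloc[i], **kwargs))
    return records


def _climate_frame(climate: Sequence[ClimateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [c.timestamp for c in climate],
            **{f: [getattr(c, f) for c in climate] for f in _CLIMATE_FIELDS},
        }
    )


def join_climate(
    manifest: "PlantManifest",
    climate: Sequence[ClimateRecord],
    window_hours: float = 24.0,
) -> pd.DataFrame:
    """Summarize climate over the window preceding each scan.

    Returns one row per manifest scan with mean/min/max of each climate
    variable over the ``window_hours`` before the scan timestamp, plus a
    ``has_climate`` flag. Scans with no climate data in the window keep
    NaN summaries and ``has_climate=False`` — no silent fill.
    """
    cdf = _climate_frame(climate) if climate else pd.DataFrame(columns=["timestamp", *_CLIMATE_FIELDS])
    rows = []
    window = pd.Timedelta(hours=window_hours)
    for _, scan in manifest.frame.iterrows():
        t = pd.to_datetime(scan["timestamp"], utc=True)
        row: dict[str, object] = {"plant_id": scan["plant_id"], "timestamp": scan["timestamp"]}
        if len(cdf):
            sel = cdf[(cdf["timestamp"] > t - window) & (cdf["timestamp"] <= t)]
        else:
            sel = cdf
        row["has_climate"] = bool(len(sel))
        for f in _CLIMATE_FIELDS:
            vals = sel[f].dropna() if len(sel) else pd.Series(dtype=float)
            row[f"{f}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{f}_min"] = float(vals.min()) if len(vals) else np.nan
            row[f"{f}_max"] = float(vals.max()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plant manifest


@dataclass
class PlantManifest:
    """Scan inventory: one row per (pot barcode, plant, scan timestamp).

    Required columns: barcode, plant_id, timestamp, volume_path.
    Optional: genotype, treatment, sowing_date.
    """

    frame: pd.DataFrame
    base_dir: Path | None = None
    missing_paths: list[str] = field(default_factory=list)

    REQUIRED = ("barcode", "plant_id", "timestamp", "volume_path")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"manifest is missing required column {col!r}")
        dup = self.frame.duplicated(subset=["plant_id", "timestamp"])
        if dup.any():
            row = self.frame[dup].iloc[0]
            raise ValueError(
                f"duplicate manifest key (plant_id={row['plant_id']!r}, timestamp={row['timestamp']!r})"
            )
        self.frame = self.frame.sort_values(["plant_id", "timestamp"]).reset_index(drop=True)

    def resolve_path(self, volume_path: str) -> Path:
        p = Path(volume_path)
        if not p.is_absolute() and self.base_dir is not None:
            p = self.base_dir / p
        return p

    def validate_paths(self) -> list[str]:
        """Flag unresolvable volume paths; returns the missing ones."""
        self.missing_paths = [
            str(vp) for vp in self.frame["volume_path"] if not self.resolve_path(vp).exists()
        ]
        return self.missing_paths


def load_manifest(path: str | Path) -> PlantManifest:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"barcode": str, "plant_id": str})
    return PlantManifest(frame, base_dir=path.parent)


# ---------------------------------------------------------------------------
# trait tables

#: Fixed column order of the per-scan trait table; units in headers.
#: The density relation factor is oriented soil/root × 100.
TRAIT_COLUMNS = [
    "plant_id",
    "timestamp",
    "V_root_mm3",
    "L_root_mm",
    "d25_mm",
    "d50_mm",
    "d75_mm",
    "d90_mm",
    "form_fraction_pct",
    "theta_min_deg",
    "theta_max_deg",
    "theta_mean_deg",
    "root_density_au",
    "soil_density_au",
    "soil_root_density_relation_pct",
    "B_total_au",
    "dry_weight_g",
]


def write_trait_table(records: Iterable, path: str | Path) -> Path:
    """Write trait records as CSV with a fixed column order.

    Undefined traits (NaN) serialize as empty cells, never 0. Duplicate
    (plant_id, timestamp) keys are rejected.
    """
    from rootct.traits import TraitRecord  # local import to avoid a cycle

    rows = []
    for rec in records:
        if isinstance(rec, TraitRecord):
            rows.append(rec.to_row())
        else:
            rows.append(dict(rec))
    df = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    if len(df):
        dup = df.duplicated(subset=["plant_id", "timestamp"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValueError(
                f"duplicate trait key (plant_id={row['plant_id']!r}, timestamp={row['timestamp']!r})"
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
    return path


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"plant_id": str})
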