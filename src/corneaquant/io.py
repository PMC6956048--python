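"""Readers and writers for the pipeline's on-disk formats.

Images travel as single-channel 16-bit TIFF or 8-bit PNG plus a JSON sidecar
(same stem, ``.json``) holding ``pixel_size_nm`` and, for synthetic data, the
full truth record. Tabular data are one-header-line CSVs with fixed column
names: tensile ``(time_s, displacement_mm, load_N)``, thermogram
``(temperature_C, heat_flow_mW)``, Ct table ``(sample_id, group, gene, ct)``.
Geometry that the CSV cannot carry (strip dimensions, gauge length) lives in
the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .mechanics import TensileRecord
from .synthetic.fibrils import FibrilField
from .thermal import Thermogram

__all__ = [
    "write_image",
    "read_image",
    "write_tensile_csv",
    "read_tensile_csv",
    "write_thermogram_csv",
    "read_thermogram_csv",
    "write_ct_csv",
    "read_ct_csv",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(
    path: str | Path,
    image: np.ndarray,
    pixel_size_nm: float,
    truth: FibrilField | None = None,
) -> Path:
    """Write a float image in [0, 1] as 16-bit TIFF or 8-bit PNG (+ sidecar)."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(img * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r} (use .tif/.tiff/.png)")
    sidecar: dict[str, Any] = {"pixel_size_nm": pixel_size_nm}
    if truth is not None:
        sidecar["truth"] = {
            "centers_nm": np.asarray(truth.centers_nm).tolist(),
            "diameters_nm": np.asarray(truth.diameters_nm).tolist(),
            "realized_density_per_um2": truth.realized_density,
        }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read an image back to float [0, 1] together with its sidecar (or {})."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel image, got shape {arr.shape}")
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    img = arr.astype(float) / scale
    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    return img, sidecar


def write_tensile_csv(path: str | Path, record: TensileRecord) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": record.time_s,
            "displacement_mm": record.displacement_mm,
            "load_N": record.load_N,
        }
    ).to_csv(path, index=False)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "strip_width_mm": record.strip_width_mm,
                "thickness_mm": record.thickness_mm,
                "gauge_length_mm": record.gauge_length_mm,
            }
        )
    )
    return path


def read_tensile_csv(
    path: str | Path,
    strip_width_mm: float | None = None,
    thickness_mm: float | None = None,
    gauge_length_mm: float | None = None,
) -> TensileRecord:
    """Read a tensile CSV; geometry comes from the sidecar unless overridden."""
    path = Path(path)
    df = pd.read_csv(path)
    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    geom = {
        "strip_width_mm": strip_width_mm or sidecar.get("strip_width_mm"),
        "thickness_mm": thickness_mm or sidecar.get("thickness_mm"),
        "gauge_length_mm": gauge_length_mm or sidecar.get("gauge_length_mm"),
    }
    missing = [k for k, v in geom.items() if v is None]
    if missing:
        raise ValueError(f"strip geometry missing (no sidecar and no override): {missing}")
    return TensileRecord(
        time_s=df["time_s"].to_numpy(),
        displacement_mm=df["displacement_mm"].to_numpy(),
        load_N=df["load_N"].to_numpy(),
        **{k: float(v) for k, v in geom.items()},
    )


def write_thermogram_csv(path: str | Path, tg: Thermogram) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"temperature_C": tg.temperature_C, "heat_flow_mW": tg.heat_flow_mW}
    ).to_csv(path, index=False)
    return path


def read_thermogram_csv(path: str | Path) -> Thermogram:
    df = pd.read_csv(path)
    return Thermogram(
        temperature_C=df["temperature_C"].to_numpy(),
        heat_flow_mW=df["heat_flow_mW"].to_numpy(),
    )


def write_ct_csv(path: str | Path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table[["sample_id", "group", "gene", "ct"]].to_csv(path, index=False)
    return path


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
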