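"""Reading and writing the package's file formats.

Nucleus records travel as delimited text (CSV/TSV) with documented column
names; images as 16-bit grayscale TIFF (PNG also readable); configuration
as flat YAML mappings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ValidationError
from .synthetic import RECORD_COLUMNS

__all__ = [
    "read_records",
    "write_records",
    "read_image",
    "write_image",
    "read_config",
    "validate_records",
]


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the nucleus-record contract.

    Areas must be positive and finite, and the ``gamete`` portion may only
    appear on records flagged reproductive (gametes exist only in fertile
    thalli).
    """
    if "area_um2" not in df.columns:
        raise ValidationError("records need an 'area_um2' column")
    areas = df["area_um2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(areas)) or np.any(areas <= 0):
        raise ValidationError("areas must be finite and > 0")
    if "portion" in df.columns and "reproductive" in df.columns:
        bad = (df["portion"] == "gamete") & ~df["reproductive"].astype(bool)
        if bad.any():
            raise ValidationError(
                "gamete records must carry the reproductive flag"
            )
    return df


def read_records(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return validate_records(df)


def write_records(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    lead = [c for c in RECORD_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in lead]
    df[lead + rest].to_csv(path, sep=sep, index=False)


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        raise ValidationError("expected a single-channel grayscale image")
    return img


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.uint16))


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a flat key/value mapping")
    return cfg
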