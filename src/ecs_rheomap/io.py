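"""File formats: multi-page TIFF movies with metadata sidecars, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

LOCALIZATION_COLUMNS = ["frame", "x_um", "y_um", "intensity", "sigma_um", "quality"]
TRAJECTORY_COLUMNS = ["traj_id", "frame", "x_um", "y_um"]


def write_movie(path, stack: np.ndarray, metadata: dict) -> None:
    """Write a movie as multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)


def read_movie(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF and its metadata sidecar (YAML or JSON)."""
    path = Path(path)
    stack = tifffile.imread(path)
    meta: dict = {}
    for ext, loader in ((".yaml", yaml.safe_load), (".json", json.load)):
        sidecar = path.with_suffix(path.suffix + ext)
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = loader(fh)
            break
    return stack, meta


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
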