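"""File formats: fixation tables, saliency maps, parameter configs.

Fixation tables are CSV with header ``subject,image,x_deg,y_deg,dur_s``,
one row per fixation; scan paths are delimited by the (subject, image)
grouping and fixation order equals row order.  Coordinates are degrees of
visual angle, never pixels.

Saliency maps are whitespace- or comma-delimited numeric matrices, or 8/16
bit grayscale PNG images; negative values and all-zero maps are rejected.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .core import Fixation, Grid, ModelParams, Scanpath

__all__ = [
    "read_fixations",
    "write_fixations",
    "scanpaths_to_frame",
    "load_saliency",
    "save_saliency",
    "load_params",
    "save_params",
]

FIXATION_COLUMNS = ["subject", "image", "x_deg", "y_deg", "dur_s"]


def scanpaths_to_frame(paths: Iterable[Scanpath]) -> pd.DataFrame:
    rows = [
        (p.subject, p.image, f.x, f.y, f.duration)
        for p in paths
        for f in p.fixations
    ]
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def write_fixations(paths: Iterable[Scanpath], path: str | Path) -> None:
    scanpaths_to_frame(paths).to_csv(path, index=False)


def read_fixations(path: str | Path) -> list[Scanpath]:
    """Read a fixation CSV into scan paths grouped by (subject, image)."""
    df = pd.read_csv(path)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixation table misses columns {missing}")
    out: list[Scanpath] = []
    for (subject, image), g in df.groupby(["subject", "image"], sort=False):
        fixes = tuple(
            Fixation(x=row.x_deg, y=row.y_deg, duration=row.dur_s)
            for row in g.itertuples()
        )
        out.append(Scanpath(fixations=fixes, image=str(image), subject=str(subject)))
    return out


def load_saliency(path: str | Path) -> np.ndarray:
    """Load a nonnegative saliency matrix from text or grayscale PNG."""
    path = Path(path)
    if path.suffix.lower() in {".png", ".tif", ".tiff"}:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=-1)
    else:
        text = path.read_text()
        delimiter = "," if "," in text.splitlines()[0] else None
        arr = np.loadtxt(path, delimiter=delimiter, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"saliency map must be 2-D, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("saliency map contains negative values")
    if not (arr.sum() > 0):
        raise ValueError("saliency map is identically zero")
    return arr


def save_saliency(S: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(S, dtype=float))


def save_params(params: ModelParams, grid: Grid, path: str | Path) -> None:
    """Write the full parameter set (plus grid geometry) as YAML."""
    payload = {
        "params": {k: v for k, v in dataclasses.asdict(params).items()},
        "grid": dataclasses.asdict(grid),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_params(path: str | Path) -> tuple[ModelParams, Grid]:
    payload = yaml.safe_load(Path(path).read_text())
    raw = dict(payload["params"])
    raw.pop("slow_ratio", None)
    if raw.get("log_psi") is None:
        raw["log_psi"] = float("-inf")
    params = ModelParams(**raw)
    grid = Grid(**payload["grid"])
    return params, grid
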