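"""File I/O helpers: multi-page TIFF stacks, CSV tables, sidecar JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def write_stack(path, stack: np.ndarray) -> None:
    """Write a frame stack (or 2-D matrix) as multi-page 16-bit TIFF."""
    arr = np.asarray(stack)
    if arr.dtype != np.uint16:
        lo, hi = float(arr.min()), float(arr.max())
        scale = (2 ** 16 - 1) / (hi - lo) if hi > lo else 1.0
        arr = ((arr - lo) * scale).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_table(path, table: pd.DataFrame, metadata: dict | None = None):
    """CSV table plus optional sidecar JSON of generation parameters."""
    path = Path(path)
    table.to_csv(path, index=False)
    if metadata is not None:
        clean = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in metadata.items()}
        path.with_suffix(".json").write_text(json.dumps(clean, indent=2,
                                                        default=str))


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_metadata(path) -> dict:
    return json.loads(Path(path).with_suffix(".json").read_text())
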