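"""Heatmap rendering and fold-value clustering.

Expression and fold tables are drawn as gradient heatmaps: a white-to-red
ramp, linear in the chosen display scale and normalized to the table
maximum, with cells that are undetectable in the underlying library (raw
count 0) drawn gray regardless of value. Rendering goes through a plain
RGB array so the color semantics are exact and testable pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import ValidationError
from .extraction import FoldMatrix, scale_transform

GRAY = (128, 128, 128)
CELL_PX = 16


@dataclass
class HeatmapSpec:
    """What to render and how: value kind, display scale, clustering, output."""

    output_path: str | Path
    value_kind: str = "tpm"  # "tpm" or "fold"
    scale: str = "linear"
    cluster: bool = False

    def __post_init__(self):
        if self.value_kind not in ("tpm", "fold"):
            raise ValidationError(f"value_kind must be 'tpm' or 'fold', got {self.value_kind!r}")


def heatmap_rgb(values, flags=None, scale: str = "linear") -> np.ndarray:
    """RGB array (rows x cols x 3, uint8) for a value table.

    Red intensity is ``scale_transform(values)`` normalized by the table
    maximum: 0 maps to white, the maximum to full red. ``flags`` is an
    optional boolean mask (True = undetected) rendered gray.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot render an empty table")
    if arr.ndim == 1:
        arr = arr[None, :]
    scaled = np.asarray(scale_transform(arr, scale), dtype=float)
    top = scaled.max()
    t = scaled / top if top > 0 else np.zeros_like(scaled)
    rgb = np.empty(arr.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = 255
    rgb[..., 1] = rgb[..., 2] = np.round(255 * (1.0 - t)).astype(np.uint8)
    if flags is not None:
        mask = np.asarray(flags, dtype=bool)
        if mask.ndim == 1:
            mask = mask[None, :]
        if mask.shape != arr.shape:
            raise ValidationError(
                f"flags shape {mask.shape} does not match values shape {arr.shape}"
            )
        rgb[mask] = GRAY
    return rgb


def render_heatmap(values, flags, spec: HeatmapSpec) -> Path:
    """Write the heatmap PNG described by ``spec``; returns the output path.

    ``values`` may be a DataFrame (tags x libraries or tags x conditions)
    or an array. With ``spec.cluster`` and >= 2 rows, rows are reordered
    by hierarchical clustering of the scale-transformed values first.
    """
    df = values if isinstance(values, pd.DataFrame) else pd.DataFrame(np.atleast_2d(values))
    if df.size == 0:
        raise ValidationError("cannot render an empty table")
    flag_df = None
    if flags is not None:
        flag_df = flags if isinstance(flags, pd.DataFrame) else pd.DataFrame(np.atleast_2d(flags))
    if spec.cluster and len(df) >= 2:
        order, _ = cluster_rows(df, spec.scale)
        df = df.loc[order]
        if flag_df is not None:
            flag_df = flag_df.loc[order]
    rgb = heatmap_rgb(
        df.to_numpy(), None if flag_df is None else flag_df.to_numpy(), spec.scale
    )
    img = Image.fromarray(np.kron(rgb, np.ones((CELL_PX, CELL_PX, 1), dtype=np.uint8)))
    out = Path(spec.output_path)
    img.save(out, format="PNG")
    return out


def cluster_rows(df: pd.DataFrame, scale: str = "linear") -> tuple[list, np.ndarray]:
    """Hierarchical clustering of table rows on scale-transformed values.

    Average-linkage agglomerative clustering with Euclidean distance.
    Rows are canonicalized (sorted by label) before linkage, so the merge
    structure and leaf order are invariant to the input row order; exact
    distance ties resolve toward the lexicographically smallest label.

    Returns (row labels in leaf order, scipy linkage matrix).
    """
    if len(df) < 2:
        raise ValidationError("clustering requires at least 2 rows")
    canon = df.sort_index(kind="stable")
    data = np.asarray(scale_transform(canon.to_numpy(dtype=float), scale))
    Z = linkage(data, method="average", metric="euclidean")
    order = [canon.index[i] for i in leaves_list(Z)]
    return order, Z


def cluster_tags(fm: FoldMatrix, scale: str = "linear") -> tuple[list[str], np.ndarray]:
    """Cluster the mined tags of a fold matrix; see :func:`cluster_rows`."""
    return cluster_rows(fm.fold, scale)


def undetected_mask(raw: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask of cells with raw count 0 ("undetectable" → gray)."""
    return raw == 0
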