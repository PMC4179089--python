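"""Image and table input/output helpers.

Sample images are 8- or 16-bit grayscale PNG/TIFF; colour inputs are
converted to grayscale by averaging the channels.  Correlation surfaces and
cluster sets export as flat CSV tables.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import ClusterSet
from .ncc import CorrelationSurface, SampleImage

__all__ = [
    "read_image",
    "write_image",
    "surface_to_frame",
    "clusters_to_frame",
    "write_overlay",
]


def read_image(path: "str | Path") -> SampleImage:
    """Read a grayscale (or colour, averaged) raster image as float64."""
    arr = np.asarray(iio.imread(Path(path)), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)  # luminance by channel average
    return SampleImage(pixels=arr)


def write_image(path: "str | Path", image: "SampleImage | np.ndarray", bit_depth: int = 8) -> None:
    """Write intensities (0..255 convention) as an 8- or 16-bit grayscale file."""
    px = image.pixels if isinstance(image, SampleImage) else np.asarray(image, dtype=np.float64)
    if bit_depth == 8:
        out = np.clip(np.round(px), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.round(px * 256.0), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(Path(path), out)


def surface_to_frame(surface: CorrelationSurface) -> pd.DataFrame:
    """Flatten a surface to (i, j, value, evaluated) rows."""
    rows, cols = np.indices(surface.shape)
    return pd.DataFrame(
        {
            "i": rows.ravel(),
            "j": cols.ravel(),
            "value": surface.values.ravel(),
            "evaluated": surface.evaluated.ravel(),
        }
    )


def clusters_to_frame(clusters: ClusterSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": k,
                "centroid_row": cl.centroid[0],
                "centroid_col": cl.centroid[1],
                "size": cl.size,
                "template_id": cl.template_id,
            }
            for k, cl in enumerate(clusters.clusters)
        ],
        columns=["cluster_id", "centroid_row", "centroid_col", "size", "template_id"],
    )


def write_overlay(
    path: "str | Path",
    sample: SampleImage,
    clusters: ClusterSet,
    box_half: int = 8,
) -> None:
    """Write the sample as RGB PNG with a red box around each counted cell.

    Cluster centroids live on the offset grid (template top-left anchors);
    the box is drawn around the corresponding window centre.
    """
    px = np.clip(np.round(sample.pixels), 0, 255).astype(np.uint8)
    rgb = np.stack([px, px, px], axis=2)
    H, W = px.shape
    for cl in clusters.clusters:
        r = int(round(cl.centroid[0])) + box_half
        c = int(round(cl.centroid[1])) + box_half
        r0, r1 = max(r - box_half, 0), min(r + box_half, H - 1)
        c0, c1 = max(c - box_half, 0), min(c + box_half, W - 1)
        rgb[r0, c0 : c1 + 1] = (255, 0, 0)
        rgb[r1, c0 : c1 + 1] = (255, 0, 0)
        rgb[r0 : r1 + 1, c0] = (255, 0, 0)
        rgb[r0 : r1 + 1, c1] = (255, 0, 0)
    iio.imwrite(Path(path), rgb)
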