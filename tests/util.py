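"""Shared helpers for building small in-memory test objects."""

from __future__ import annotations

import numpy as np
import pandas as pd

from slicetox.detect import DETECTION_COLUMNS, DetectionSet
from slicetox.prep import Projection


def make_detections(
    xy,
    channel: str = "red",
    mip_index=0,
    z_um=None,
    mean_green=50.0,
    mean_red=50.0,
    ids=None,
) -> DetectionSet:
    """DetectionSet from a list of (x, y) centroids with broadcastable extras."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    mip = np.broadcast_to(np.asarray(mip_index), n).astype(int)
    z = np.broadcast_to(np.asarray(7.5 if z_um is None else z_um, dtype=float), n)
    df = pd.DataFrame(
        {
            "det_id": np.arange(n) if ids is None else np.asarray(ids),
            "channel": channel,
            "mip_index": mip,
            "z_um": z,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "area_um2": 50.0,
            "circularity": 0.9,
            "mean_green": np.broadcast_to(np.asarray(mean_green, dtype=float), n),
            "mean_red": np.broadcast_to(np.asarray(mean_red, dtype=float), n),
        }
    )
    return DetectionSet(df[DETECTION_COLUMNS])


def make_projection(image, z_lo=0.0, z_hi=15.0, mip_index=0, channel="red", pixel_size=1.2) -> Projection:
    return Projection(
        image=np.asarray(image, dtype=float),
        z_lo=z_lo,
        z_hi=z_hi,
        mip_index=mip_index,
        channel=channel,
        pixel_size=pixel_size,
    )


def detections_from_depths(depths, **kw) -> DetectionSet:
    """DetectionSet whose only meaningful column is z_um (for binning tests)."""
    depths = np.asarray(depths, dtype=float)
    xy = np.column_stack([np.zeros_like(depths), np.zeros_like(depths)])
    return make_detections(xy, z_um=depths, **kw)
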