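"""Mean-image rendering and axon-map visual QC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from phoskit.axon import AxonMap
from phoskit.io import DrawingMask
from phoskit.shapes import centroid


def mean_image(masks: list[DrawingMask], *, align: str = "centroid",
               shape: tuple[int, int] | None = None) -> np.ndarray:
    """Average drawings across trials, aligned at their centers of mass.

    Returns a float image in [0, 1]: the per-pixel fraction of trials in
    which the (aligned) pixel was drawn.
    """
    if not masks:
        raise ValueError("need at least one mask")
    if align not in ("centroid", "none"):
        raise ValueError("align must be 'centroid' or 'none'")
    h = shape[0] if shape else max(m.pixels.shape[0] for m in masks) * 2 + 1
    w = shape[1] if shape else max(m.pixels.shape[1] for m in masks) * 2 + 1
    acc = np.zeros((h, w))
    for m in masks:
        ys, xs = np.nonzero(m.pixels)
        if xs.size == 0:
            continue
        if align == "centroid":
            cx, cy = centroid(m.pixels)
        else:
            cy, cx = (m.pixels.shape[0] - 1) / 2, (m.pixels.shape[1] - 1) / 2
        ty = np.round(ys - cy + h // 2).astype(int)
        tx = np.round(xs - cx + w // 2).astype(int)
        ok = (ty >= 0) & (ty < h) & (tx >= 0) & (tx < w)
        acc[ty[ok], tx[ok]] += 1
    return acc / len(masks)


def plot_axon_map(amap: AxonMap, ax=None, *, color: str = "0.6", lw: float = 0.4):
    """Draw all bundle trajectories (µm, fovea origin) for visual QC."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for poly in amap.bundles:
        ax.plot(poly[:, 0], poly[:, 1], color=color, lw=lw)
    ax.plot(0, 0, "k*", ms=10)
    ax.set_xlabel("x (µm, nasal →)")
    ax.set_ylabel("y (µm, superior →)")
    ax.set_aspect("equal")
    return ax


def save_axon_map_figure(amap: AxonMap, path: str | Path) -> None:
    ax = plot_axon_map(amap)
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
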