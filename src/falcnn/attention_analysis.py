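"""Turn feedback attention activations into heatmaps, contours and centroids.

The per-channel attention logits of one FAM site are averaged into a single
H_l x W_l map, min-max normalised to [0, 1], and bilinearly interpolated up
to the input resolution.  The centre of attention (CoA) is the unweighted
centroid of the suprathreshold region — by default the pixels at or above
80% of the maximum — which the saccade model uses as a proxy for the peak
of attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.transform import resize

from .model_core import LevelActivation


@dataclass
class AttentionHeatmap:
    """Normalised [0,1] attention map at (or rescaled towards) input scale."""
    values: np.ndarray
    source_level: int = -1
    iteration: int = -1
    constant_input: bool = False  # raw map was flat; values are all zero

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class ContourSet:
    level_fraction: float
    polygons: list[np.ndarray] = field(default_factory=list)
    region_mask: np.ndarray | None = None
    empty: bool = False


def mean_channel_map(features: LevelActivation | np.ndarray) -> np.ndarray:
    """Mean over the channel axis of (C, H, W) or batched (B, C, H, W) features.

    Batched input is averaged over both batch and channel axes, giving the
    per-level mean spatial activation for the whole batch.
    """
    arr = features.features if isinstance(features, LevelActivation) else features
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 4:
        arr = arr.mean(axis=0)
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W) features, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise ValueError("empty channel axis")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in feature map")
    return arr.mean(axis=0)


def normalize_map(m: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max normalise to [0,1]; a constant map becomes all zeros."""
    m = np.asarray(m, dtype=np.float64)
    lo, hi = m.min(), m.max()
    if hi - lo <= 0:
        return np.zeros_like(m), True
    return (m - lo) / (hi - lo), False


def normalize_and_upscale(m: np.ndarray, target_size: int,
                          source_level: int = -1,
                          iteration: int = -1) -> AttentionHeatmap:
    """Normalise then bilinearly rescale a map to target_size x target_size.

    Interpolation can pull the maximum slightly below 1 when the peak falls
    between output samples, so the result is renormalised once more; the
    returned heatmap therefore attains 1 exactly unless the input was flat.
    """
    if target_size <= 0:
        raise ValueError(f"target_size must be positive, got {target_size}")
    norm, flat = normalize_map(m)
    if flat:
        return AttentionHeatmap(np.zeros((target_size, target_size)),
                                source_level, iteration, constant_input=True)
    if norm.shape != (target_size, target_size):
        norm = resize(norm, (target_size, target_size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
        norm, flat = normalize_map(norm)
    return AttentionHeatmap(np.clip(norm, 0.0, 1.0), source_level, iteration,
                            constant_input=flat)


def attention_region(h: AttentionHeatmap, fraction: float = 0.8) -> ContourSet:
    """Pixels at or above ``fraction`` of the peak, with traced contours.

    Contour polygons come from marching squares on the heatmap at the given
    iso-level; coordinates are (row, col), 0-based, at pixel centres.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    v = h.values
    mask = v >= fraction
    if h.constant_input or not mask.any():
        return ContourSet(fraction, [], np.zeros_like(v, dtype=bool), empty=True)
    polygons = [p for p in measure.find_contours(v, fraction)]
    return ContourSet(fraction, polygons, mask)


def centre_of_attention(h: AttentionHeatmap,
                        fraction: float = 0.8,
                        largest_component: bool = False) -> tuple[float, float]:
    """Centroid of the suprathreshold region of a heatmap.

    By default the centroid of the union of all pixels >= fraction; with
    ``largest_component`` only the biggest connected region contributes.
    Falls back to the argmax pixel when the region is empty (flat map).
    """
    region = attention_region(h, fraction) if not h.constant_input else None
    if region is None or region.empty:
        r, c = np.unravel_index(int(np.argmax(h.values)), h.values.shape)
        return float(r), float(c)
    mask = region.region_mask
    if largest_component:
        labels = measure.label(mask)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def aggregate_heatmaps(maps: list[AttentionHeatmap]) -> AttentionHeatmap:
    """Per-pixel mean of same-sized heatmaps, renormalised to [0, 1]."""
    if not maps:
        raise ValueError("empty heatmap group")
    shape = maps[0].values.shape
    for m in maps:
        if m.values.shape != shape:
            raise ValueError("heatmaps in a group must share a size")
    mean = np.mean([m.values for m in maps], axis=0)
    norm, flat = normalize_map(mean)
    return AttentionHeatmap(norm, maps[0].source_level, maps[0].iteration,
                            constant_input=flat)


def group_and_aggregate(maps: list[AttentionHeatmap]
                        ) -> dict[tuple[int, int], AttentionHeatmap]:
    """Aggregate a mixed collection grouped by (source_level, iteration)."""
    groups: dict[tuple[int, int], list[AttentionHeatmap]] = {}
    for m in maps:
        groups.setdefault((m.source_level, m.iteration), []).append(m)
    return {k: aggregate_heatmaps(v) for k, v in sorted(groups.items())}


def render_heatmap(h: AttentionHeatmap, path: str) -> None:
    """Save a heatmap as an RGB PNG with the perceptually uniform viridis
    (blue-to-yellow) colour mapping."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import cm
    from PIL import Image
    rgba = cm.viridis(h.values)
    Image.fromarray((rgba[:, :, :3] * 255).astype(np.uint8)).save(path)


def render_contour_overlay(image: np.ndarray, contours: ContourSet,
                           path: str) -> None:
    """Draw contour polygons over an RGB patch image and save as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4), dpi=112)
    ax.imshow(image)
    for poly in contours.polygons:
        ax.plot(poly[:, 1], poly[:, 0], color="yellow", linewidth=1.5)
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path)
    plt.close(fig)


def heatmap_from_stack(stack_logits: list[np.ndarray], level: int,
                       target_size: int, iteration: int = -1) -> AttentionHeatmap:
    """Convenience: mean-channel map of one FAM site's logits -> heatmap."""
    arr = stack_logits[level]
    return normalize_and_upscale(mean_channel_map(arr), target_size,
                                 source_level=level, iteration=iteration)
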