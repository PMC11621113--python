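"""Saccadic resampling: re-centre a crop on the model's centre of attention.

A parent image (canonically 448 x 448 px) is sampled with a crop of half its
side (224 x 224).  Cycle 0 classifies the central crop; each subsequent
cycle either re-centres the crop on the centre of attention (CoA) derived
from the deepest-level feedback attention heatmap of the embedded FAL-CNN
(attention mode), or applies independent uniform integer offsets of up to
half a crop per axis (random-walk mode).  Crops are always clamped fully
inside the parent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .attention_analysis import (AttentionHeatmap, centre_of_attention,
                                 heatmap_from_stack)
from .model_core import Model, classify


@dataclass
class SaccadeCycle:
    crop_centre: tuple[int, int]            # parent coordinates
    coa_parent: tuple[float, float] | None  # None in random mode
    predicted_class: int
    probs: np.ndarray


@dataclass
class SaccadeTrace:
    cycles: list[SaccadeCycle] = field(default_factory=list)
    mode: str = "attention"
    seed: int = 0

    def centres(self) -> np.ndarray:
        return np.asarray([c.crop_centre for c in self.cycles], dtype=float)

    def to_json(self) -> str:
        return json.dumps({
            "mode": self.mode, "seed": self.seed,
            "cycles": [{
                "crop_centre": list(c.crop_centre),
                "coa_parent": None if c.coa_parent is None else
                              [float(v) for v in c.coa_parent],
                "predicted_class": int(c.predicted_class),
                "probs": [float(p) for p in c.probs],
            } for c in self.cycles]}, indent=2)


# ------------------------------------------------------------------- crops

def clamp_centre(centre: tuple[float, float], parent_size: int,
                 crop_size: int) -> tuple[int, int]:
    """Clamp a crop centre so the crop lies fully inside the parent."""
    half = crop_size // 2
    lo, hi = half, parent_size - half
    r = int(min(max(round(centre[0]), lo), hi))
    c = int(min(max(round(centre[1]), lo), hi))
    return r, c


def crop_patch(parent: np.ndarray, centre: tuple[float, float],
               size: int = 224) -> np.ndarray:
    """Exact pixel crop of ``size`` centred at ``centre`` (clamped inside)."""
    P = parent.shape[0]
    if parent.shape[0] < size or parent.shape[1] < size:
        raise ValueError(f"parent {parent.shape[:2]} smaller than crop {size}")
    r, c = clamp_centre(centre, P, size)
    half = size // 2
    return parent[r - half:r - half + size, c - half:c - half + size]


def coa_to_parent(coa_crop: tuple[float, float],
                  crop_origin: tuple[float, float]) -> tuple[float, float]:
    """Map a CoA in crop coordinates into parent coordinates."""
    return (coa_crop[0] + crop_origin[0], coa_crop[1] + crop_origin[1])


# -------------------------------------------------------------- classifier

class AttentionClassifier:
    """Adapter: FAL-CNN -> (class probabilities, deepest-level heatmap).

    The heatmap comes from the last feedback iteration's deepest FAM site,
    averaged over channels, normalised and rescaled to the crop size — the
    map whose 80%-contour centroid defines the centre of attention.
    """

    def __init__(self, model: Model, n_iterations: int | None = None):
        if model.spec.n_iterations < 1:
            raise ValueError("attention-guided saccades need a model with "
                             "at least 1 feedback iteration")
        self.model = model
        self.n_iterations = n_iterations or model.spec.n_iterations
        self.crop_size = model.spec.input_size

    def __call__(self, patch: np.ndarray
                 ) -> tuple[np.ndarray, AttentionHeatmap]:
        out = classify(self.model, patch[None], self.n_iterations)
        stack = out.attention[-1]
        deepest = len(stack.logits) - 1
        heat = heatmap_from_stack(stack.logits, deepest, self.crop_size,
                                  iteration=stack.iteration)
        return out.probs[0], heat


# --------------------------------------------------------------- main loop

def saccade_run(model, parent: np.ndarray, n_saccades: int = 8,
                mode: str = "attention", seed: int = 0,
                fraction: float = 0.8) -> SaccadeTrace:
    """Run ``n_saccades`` re-sampling cycles over one parent image.

    ``model`` may be a built FAL-CNN or any callable mapping a crop to
    (probs, AttentionHeatmap).  Cycle 0 is the initial central sample, so the
    trace holds n_saccades + 1 cycles.  In attention mode the next centre is
    the CoA mapped to parent coordinates; in random mode it is the current
    centre plus fresh uniform integer offsets within +/- half a crop.
    """
    if n_saccades < 0:
        raise ValueError(f"n_saccades must be >= 0, got {n_saccades}")
    if n_saccades > 10:
        warnings.warn(f"n_saccades={n_saccades} exceeds the evaluated "
                      "range of up to 10 cycles", stacklevel=2)
    if mode not in ("attention", "random"):
        raise ValueError(f"unknown mode {mode!r}")
    classifier = AttentionClassifier(model) if isinstance(model, Model) else model
    crop_size = getattr(classifier, "crop_size", None)
    P = parent.shape[0]
    rng = np.random.default_rng(seed)
    half_for_offsets = None

    trace = SaccadeTrace(mode=mode, seed=seed)
    centre = (P // 2, P // 2)
    for _cycle in range(n_saccades + 1):
        if crop_size is None:
            # infer from the classifier's heatmap on the first call
            probe = classifier(parent)  # pragma: no cover - stub convenience
            crop_size = probe[1].size
        centre = clamp_centre(centre, P, crop_size)
        half = crop_size // 2
        patch = crop_patch(parent, centre, crop_size)
        probs, heat = classifier(patch)
        origin = (centre[0] - half, centre[1] - half)
        if mode == "attention":
            coa = centre_of_attention(heat, fraction)
            coa_par = coa_to_parent(coa, origin)
            next_centre = (coa_par[0], coa_par[1])
        else:
            coa_par = None
            off = rng.integers(-half, half + 1, size=2)
            next_centre = (centre[0] + int(off[0]), centre[1] + int(off[1]))
        trace.cycles.append(SaccadeCycle(
            crop_centre=centre, coa_parent=coa_par,
            predicted_class=int(np.argmax(probs)), probs=np.asarray(probs)))
        centre = next_centre
    return trace


# ---------------------------------------------------------------- benchmark

def trace_distances(trace: SaccadeTrace,
                    target: tuple[float, float]) -> np.ndarray:
    """Euclidean distance from each cycle's crop centre to a target point."""
    d = trace.centres() - np.asarray(target, dtype=float)
    return np.hypot(d[:, 0], d[:, 1])


def saccade_benchmark(model, parents: list[dict], n_saccades: int = 8,
                      seed: int = 0) -> dict:
    """Attention vs random-walk saccades over synthetic off-centre targets.

    ``parents`` as produced by synthetic_data.make_saccade_parents.  Returns
    per-mode distance-to-object-centroid trajectories (cycle x parent mean)
    and mean final distances.
    """
    classifier = AttentionClassifier(model) if isinstance(model, Model) else model
    results = {}
    for mode in ("attention", "random"):
        dists = []
        for i, p in enumerate(parents):
            trace = saccade_run(classifier, p["image"], n_saccades, mode,
                                seed=seed * 100003 + i)
            dists.append(trace_distances(trace, p["centroid"]))
        dists = np.asarray(dists)               # (n_parents, n_cycles)
        results[mode] = {
            "per_cycle_mean": dists.mean(axis=0),
            "final_mean": float(dists[:, -1].mean()),
            "initial_mean": float(dists[:, 0].mean()),
        }
    return results
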