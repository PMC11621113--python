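"""Seeded synthetic image data shaped like the histopathology patch corpus.

Real inputs are RGB tissue patches cut from whole-slide images (WSIs),
organised in class-labelled directories and grouped by parent slide.  The
generator emulates that structure with texture-separable classes: each class
is a coloured, noisy background scattered with nucleus-like discs whose
colour, density and radius distribution carry the class identity.  For the
saccade experiments it renders larger parent images containing a compact,
class-defining object cluster at a known (possibly off-centre) location and
reports the rendered object's mass centroid as ground truth.

Everything is a pure function of (parameters, seed), so datasets are
bitwise reproducible and never shipped.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class ClassDef:
    """Texture parameters defining one synthetic tissue class."""
    class_id: int
    base_colour: tuple[int, int, int]
    blob_colour: tuple[int, int, int]
    blob_density: float          # expected discs per pixel
    blob_radius: tuple[float, float]  # uniform range, px
    noise_scale: float           # std of per-pixel Gaussian noise


@dataclass
class PatchRecord:
    """One patch on disk plus the metadata the pipeline needs."""
    path: str
    class_label: int
    parent_id: str
    centre_xy: tuple[int, int]
    object_centroid: tuple[float, float] | None = None

    def load(self) -> np.ndarray:
        return np.asarray(Image.open(self.path).convert("RGB"))


# Nine available classes (tests typically use the first three).  Colours and
# disc statistics are chosen to be separable by local texture, mirroring how
# tissue classes differ in stain colour and nuclear density.
_PALETTE = [
    ((200, 170, 200), (90, 40, 120), 0.0030, (2.0, 4.0), 10.0),
    ((235, 190, 200), (60, 30, 90), 0.0080, (2.5, 4.5), 8.0),
    ((210, 220, 170), (150, 90, 60), 0.0015, (3.5, 6.5), 12.0),
    ((180, 180, 230), (40, 70, 140), 0.0050, (1.5, 3.0), 9.0),
    ((230, 210, 160), (170, 60, 60), 0.0040, (4.0, 7.0), 11.0),
    ((190, 230, 210), (50, 110, 80), 0.0065, (2.0, 3.5), 7.0),
    ((225, 225, 225), (120, 120, 60), 0.0010, (5.0, 9.0), 14.0),
    ((205, 185, 235), (130, 50, 130), 0.0055, (3.0, 5.0), 10.0),
    ((240, 200, 180), (90, 90, 150), 0.0025, (2.0, 5.5), 13.0),
]

# Neutral backdrop used for parent images so the object cluster is the only
# class-bearing content.
BACKGROUND = ClassDef(-1, (150, 150, 150), (140, 140, 140), 0.0005, (2.0, 4.0), 8.0)


def default_classes(k: int) -> list[ClassDef]:
    if not 2 <= k <= len(_PALETTE):
        raise ValueError(f"k must be in 2..{len(_PALETTE)}, got {k}")
    return [ClassDef(i, *_PALETTE[i]) for i in range(k)]


def _rng(*parts) -> np.random.Generator:
    return np.random.default_rng([int(p) & 0x7FFFFFFF for p in parts])


def _draw_discs(img: np.ndarray, mask: np.ndarray | None,
                centres: np.ndarray, radii: np.ndarray,
                colours: np.ndarray) -> None:
    h, w = img.shape[:2]
    for (r, c), rad, col in zip(centres, radii, colours):
        r0, r1 = max(0, int(r - rad)), min(h, int(r + rad) + 2)
        c0, c1 = max(0, int(c - rad)), min(w, int(c + rad) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.ogrid[r0:r1, c0:c1]
        m = (yy - r) ** 2 + (xx - c) ** 2 <= rad * rad
        img[r0:r1, c0:c1][m] = col
        if mask is not None:
            mask[r0:r1, c0:c1][m] = True


def _texture(cd: ClassDef, size: int, rng: np.random.Generator,
             with_blobs: bool = True) -> np.ndarray:
    base = np.asarray(cd.base_colour, dtype=np.float64)
    img = base + rng.normal(0.0, cd.noise_scale, size=(size, size, 3))
    if with_blobs:
        n = rng.poisson(cd.blob_density * size * size)
        centres = rng.uniform(0, size, size=(n, 2))
        radii = rng.uniform(*cd.blob_radius, size=n)
        colours = (np.asarray(cd.blob_colour, dtype=np.float64)
                   + rng.normal(0, 12, size=(n, 3)))
        _draw_discs(img, None, centres, radii, colours)
    return np.clip(img, 0, 255).astype(np.uint8)


def render_patch(cd: ClassDef, size: int, seed: int) -> np.ndarray:
    """Deterministic RGB texture patch of one class, shape (size, size, 3)."""
    if size < 16:
        raise ValueError(f"size must be >= 16, got {size}")
    return _texture(cd, size, _rng(seed, cd.class_id, size))


def render_parent(cd: ClassDef, object_centre: tuple[float, float],
                  size: int = 448, seed: int = 0,
                  background: ClassDef = BACKGROUND,
                  object_discs: int = 60,
                  object_sigma: float = 26.0
                  ) -> tuple[np.ndarray, tuple[float, float]]:
    """Parent image: neutral background plus a class-defining object cluster.

    Returns the rendered image and the mass centroid of the object's pixel
    mask, which serves as ground truth for saccade-convergence tests.
    """
    r0, c0 = object_centre
    margin = min(32, size // 4)  # 32 px at the canonical 448 parent size
    if not (margin <= r0 <= size - margin and margin <= c0 <= size - margin):
        raise ValueError(f"object_centre {object_centre} outside "
                         f"[{margin}, {size - margin}] margins")
    rng = _rng(seed, cd.class_id, size, int(r0), int(c0))
    img = _texture(background, size, rng).astype(np.float64)
    mask = np.zeros((size, size), dtype=bool)
    centres = rng.normal(loc=(r0, c0), scale=object_sigma,
                         size=(object_discs, 2))
    centres = np.clip(centres, 2, size - 3)
    radii = rng.uniform(*cd.blob_radius, size=object_discs) + 1.0
    colours = (np.asarray(cd.blob_colour, dtype=np.float64)
               + rng.normal(0, 12, size=(object_discs, 3)))
    _draw_discs(img, mask, centres, radii, colours)
    img = np.clip(img, 0, 255).astype(np.uint8)
    rows, cols = np.nonzero(mask)
    centroid = (float(rows.mean()), float(cols.mean()))
    return img, centroid


def make_dataset(k: int, n_parents: int, patches_per_parent: int,
                 seed: int, out_dir: str, size: int = 224
                 ) -> list[PatchRecord]:
    """Class-balanced on-disk dataset: k classes x n_parents parents each.

    Layout ``out_dir/class_<k>/<parent>_<i>.png`` plus a ``manifest.csv``;
    parent ids group patches so grouped cross-validation is exercisable.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    classes = default_classes(k)
    records: list[PatchRecord] = []
    os.makedirs(out_dir, exist_ok=True)
    for cd in classes:
        cls_dir = os.path.join(out_dir, f"class_{cd.class_id}")
        os.makedirs(cls_dir, exist_ok=True)
        for p in range(n_parents):
            parent_id = f"wsi{cd.class_id:02d}_{p:03d}"
            for i in range(patches_per_parent):
                patch_seed = ((seed * 1000003 + cd.class_id * 9176
                               + p * 131 + i) & 0x7FFFFFFF)
                img = render_patch(cd, size, patch_seed)
                path = os.path.join(cls_dir, f"{parent_id}_{i}.png")
                Image.fromarray(img).save(path)
                records.append(PatchRecord(
                    path=path, class_label=cd.class_id, parent_id=parent_id,
                    centre_xy=(size // 2, size // 2)))
    _write_manifest(out_dir, records)
    return records


def _write_manifest(out_dir: str, records: list[PatchRecord]) -> None:
    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["path", "class", "parent_id", "centre_row", "centre_col",
                     "obj_row", "obj_col"])
        for r in records:
            obj = r.object_centroid or ("", "")
            wr.writerow([os.path.relpath(r.path, out_dir), r.class_label,
                         r.parent_id, r.centre_xy[0], r.centre_xy[1],
                         obj[0], obj[1]])


def load_manifest(root: str) -> list[PatchRecord]:
    records = []
    with open(os.path.join(root, "manifest.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            obj = None
            if row["obj_row"] != "":
                obj = (float(row["obj_row"]), float(row["obj_col"]))
            records.append(PatchRecord(
                path=os.path.join(root, row["path"]),
                class_label=int(row["class"]), parent_id=row["parent_id"],
                centre_xy=(int(row["centre_row"]), int(row["centre_col"])),
                object_centroid=obj))
    return records


# ---------------------------------------------------- saccade-scale fixtures

def make_object_training_set(k: int, n_per_class: int, size: int = 224,
                             seed: int = 0
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Training images for object localisation: each image is the neutral
    background with one class's object cluster at a random position, so the
    class signal is spatially localised (as tissue of interest is in a patch).

    Returns (images (N, size, size, 3) uint8, labels (N,)).
    """
    classes = default_classes(k)
    rng = _rng(seed, k, size, 7)
    images, labels = [], []
    lo, hi = size // 4, 3 * size // 4
    for cd in classes:
        for i in range(n_per_class):
            centre = rng.uniform(lo, hi, size=2)
            img, _ = render_parent(cd, tuple(centre), size=size,
                                   seed=int(rng.integers(2 ** 31)),
                                   object_discs=max(20, 60 * size // 448),
                                   object_sigma=26.0 * size / 448)
            images.append(img)
            labels.append(cd.class_id)
    return np.stack(images), np.asarray(labels)


def make_saccade_parents(k: int, n_parents: int, seed: int = 0,
                         size: int = 448, min_offset: float = 60.0,
                         max_offset: float = 100.0):
    """Parents for the saccade benchmark: object clusters placed off-centre.

    Returns a list of dicts with image, ground-truth centroid, class id and
    the nominal object centre.  Offsets from the parent centre are uniform in
    [min_offset, max_offset] at a uniform random angle, so the object is
    off-centre but inside the initial central crop's field of view.
    """
    classes = default_classes(k)
    rng = _rng(seed, k, size, 13)
    out = []
    for i in range(n_parents):
        cd = classes[i % k]
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(min_offset, max_offset)
        centre = (size / 2 + dist * np.sin(ang), size / 2 + dist * np.cos(ang))
        img, centroid = render_parent(cd, centre, size=size,
                                      seed=int(rng.integers(2 ** 31)))
        out.append({"image": img, "centroid": centroid,
                    "class_id": cd.class_id, "object_centre": centre})
    return out
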