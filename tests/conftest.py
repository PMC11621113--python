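import numpy as np
import pytest

import falcnn as f


@pytest.fixture(scope="session")
def mini_spec():
    """Small 3-level spec at 32 px input: cheap but structurally complete."""
    return f.ModelSpec.mini(n_classes=3, n_iterations=1, input_size=32)


@pytest.fixture(scope="session")
def mini_model(mini_spec):
    return f.build_model(mini_spec, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture_dataset(tmp_path_factory):
    """K=3 texture dataset on disk: 6 parents/class x 6 patches, 64 px."""
    root = tmp_path_factory.mktemp("synthdata")
    records = f.make_dataset(3, 6, 6, seed=7, out_dir=str(root), size=64)
    return root, records


def make_memory_records(n_parents: int, patches_per_parent: int,
                        n_classes: int = 3) -> list:
    """In-memory PatchRecords (no files) for split/bootstrap logic tests."""
    records = []
    for p in range(n_parents):
        for i in range(patches_per_parent):
            records.append(f.PatchRecord(
                path=f"<mem>/{p}/{i}.png",
                class_label=(p + i) % n_classes,
                parent_id=f"parent{p:03d}",
                centre_xy=(0, 0)))
    return records


class GaussianStubClassifier:
    """Stub saccade classifier emitting a Gaussian heatmap at a fixed
    position in crop coordinates (independent of the patch content)."""

    def __init__(self, crop_size: int, peak, sigma: float = 8.0,
                 n_classes: int = 3):
        self.crop_size = crop_size
        self.peak = peak  # (row, col) in crop coordinates
        self.sigma = sigma
        self.n_classes = n_classes

    def __call__(self, patch):
        s = self.crop_size
        pr, pc = self.peak
        rr, cc = np.mgrid[0:s, 0:s]
        vals = np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2 * self.sigma ** 2))
        heat = f.normalize_and_upscale(vals, s)
        probs = np.full(self.n_classes, 1.0 / self.n_classes)
        return probs, heat


class BrightnessClassifier:
    """Toy attention model: the heatmap is the crop's own brightness.

    On a dark parent with one bright blob this is an oracle-attention model,
    so saccades should converge on the blob; used to test saccade mechanics
    independently of the CNN."""

    def __init__(self, crop_size: int, n_classes: int = 3):
        self.crop_size = crop_size
        self.n_classes = n_classes

    def __call__(self, patch):
        gray = np.asarray(patch, dtype=float).mean(axis=2)
        heat = f.normalize_and_upscale(gray, self.crop_size)
        probs = np.full(self.n_classes, 1.0 / self.n_classes)
        return probs, heat


def bright_blob_parent(size: int, blob_centre, sigma: float = 12.0):
    """Dark parent image with one bright Gaussian blob (uint8 RGB)."""
    rr, cc = np.mgrid[0:size, 0:size]
    g = np.exp(-((rr - blob_centre[0]) ** 2 + (cc - blob_centre[1]) ** 2)
               / (2 * sigma ** 2))
    img = (g * 255)[:, :, None].repeat(3, axis=2)
    return img.astype(np.uint8)
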