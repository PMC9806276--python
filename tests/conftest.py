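import numpy as np
import pytest

from spotspray import CameraSetup, GrilleConfig, GroundScale


@pytest.fixture(scope="session")
def reference_setup() -> CameraSetup:
    """The reference boom: 3.3 m width, two cameras, 1920x1080, 1 m height."""
    return CameraSetup()


@pytest.fixture(scope="session")
def reference_scale(reference_setup) -> GroundScale:
    from spotspray import ground_scale

    return ground_scale(reference_setup)


@pytest.fixture(scope="session")
def reference_grille() -> GrilleConfig:
    return GrilleConfig()


def make_blob_dataset(n_images: int = 10, size: int = 96, seed: int = 7
                      ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Synthetic detector samples: bright green rectangles on a soil-gray
    background, with exact box targets (class, cx, cy, w, h)."""
    rng = np.random.default_rng(seed)
    dataset = []
    for _ in range(n_images):
        img = np.full((3, size, size), 0.35) + rng.normal(0, 0.03, (3, size, size))
        targets = []
        for _ in range(int(rng.integers(1, 3))):
            w, h = rng.uniform(14, 30, 2)
            cx, cy = rng.uniform(16, size - 16, 2)
            x1, y1 = int(max(cx - w / 2, 0)), int(max(cy - h / 2, 0))
            x2, y2 = int(min(cx + w / 2, size)), int(min(cy + h / 2, size))
            img[1, y1:y2, x1:x2] = 0.8
            targets.append([0, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1])
        dataset.append((img, np.array(targets)))
    return dataset


TOY_ANCHORS = np.array([[12, 12], [18, 24], [24, 18],
                        [20, 20], [28, 28], [24, 32],
                        [32, 24], [40, 40], [48, 48]], dtype=float)
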