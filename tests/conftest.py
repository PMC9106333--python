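import numpy as np
import pandas as pd
import pytest

from seedtrace import BrainArea, Parcellation, VolumeImage


@pytest.fixture
def parc3() -> Parcellation:
    """Three single-area groups with volume fractions 0.1 / 0.3 / 0.6."""
    return Parcellation(
        (
            BrainArea("A", "A", 100.0),
            BrainArea("B", "B", 300.0),
            BrainArea("C", "C", 600.0),
        )
    )


@pytest.fixture
def parc_grouped() -> Parcellation:
    """Five raw areas in three groups (A has two members, 0.1 + 0.2)."""
    return Parcellation(
        (
            BrainArea("a1", "A", 100.0),
            BrainArea("a2", "A", 200.0),
            BrainArea("b1", "B", 300.0),
            BrainArea("c1", "C", 250.0),
            BrainArea("c2", "C", 150.0),
        )
    )


def make_image(
    data: np.ndarray,
    voxel_mm=(2.0, 2.0, 2.0),
    tr: float | None = 2.0,
    mask: np.ndarray | None = None,
) -> VolumeImage:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel_mm)
    affine[:3, 3] = -(np.asarray(data.shape[:3]) - 1) / 2.0 * np.asarray(voxel_mm)
    return VolumeImage(
        np.asarray(data, dtype=float), affine, mask,
        tr if np.asarray(data).ndim == 4 else None,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
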