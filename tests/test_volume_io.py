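import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from trabecula.synthetic import make_synthetic_vertebra
from trabecula.volume_io import (
    BinaryVolume,
    PrismVOI,
    SphereROI,
    binarize,
    default_centrum_mask,
    extract_prism_voi,
    inscribed_sphere,
    largest_inscribed_square,
    load_stack,
    save_stack,
    sphere_mask,
)


def random_volume(seed=0, shape=(9, 8, 7)):
    rng = np.random.default_rng(seed)
    return BinaryVolume(mask=rng.random(shape) > 0.5, voxel_size_um=12.5)


# ---------------------------------------------------------------------------
# I/O


def test_save_load_roundtrip(tmp_path):
    vol = random_volume()
    path = save_stack(vol, tmp_path / "stack.tif")
    assert (tmp_path / "stack.tif.json").exists()
    back = load_stack(path)
    assert back == vol


def test_load_requires_sidecar(tmp_path):
    vol = random_volume()
    path = save_stack(vol, tmp_path / "stack.tif")
    (tmp_path / "stack.tif.json").unlink()
    with pytest.raises(FileNotFoundError, match="voxel_size_um"):
        load_stack(path)


def test_load_rejects_grayscale(tmp_path):
    import tifffile

    gray = np.arange(6 * 16 * 16, dtype=np.uint8).reshape(6, 16, 16)
    tifffile.imwrite(tmp_path / "gray.tif", gray)
    (tmp_path / "gray.tif.json").write_text(json.dumps({"voxel_size_um": 10}))
    with pytest.raises(ValueError, match="binarize"):
        load_stack(tmp_path / "gray.tif")


def test_binarize_threshold_inclusive():
    gray = np.zeros((2, 2, 2), np.uint8)
    gray[0, 0, 0] = 127
    gray[0, 0, 1] = 126
    vol = binarize(gray, 10.0, method="fixed", threshold=127)
    assert vol.mask[0, 0, 0] and not vol.mask[0, 0, 1]


def test_binarize_otsu_separates_modes():
    rng = np.random.default_rng(1)
    gray = np.where(
        rng.random((10, 10, 10)) > 0.5,
        rng.integers(200, 230, (10, 10, 10)),
        rng.integers(10, 40, (10, 10, 10)),
    ).astype(np.uint8)
    vol = binarize(gray, 10.0, method="otsu")
    assert vol.mask.sum() == (gray > 100).sum()


def test_binarize_otsu_rejects_constant():
    with pytest.raises(ValueError, match="constant"):
        binarize(np.full((3, 3, 3), 7, np.uint8), 10.0, method="otsu")


def test_binary_volume_validation():
    with pytest.raises(ValueError):
        BinaryVolume(mask=np.ones((2, 2), bool), voxel_size_um=10)
    with pytest.raises(ValueError):
        BinaryVolume(mask=np.ones((2, 2, 2), bool), voxel_size_um=0)


# ---------------------------------------------------------------------------
# Largest inscribed square


def brute_force_square(region):
    reg = np.asarray(region, bool)
    n0, n1 = reg.shape
    best = 0
    for s in range(1, min(n0, n1) + 1):
        for r in range(n0 - s + 1):
            for c in range(n1 - s + 1):
                if reg[r : r + s, c : c + s].all():
                    best = max(best, s)
    return best


@settings(max_examples=40, deadline=None)
@given(arrays(bool, (8, 9), elements=st.booleans()))
def test_square_side_matches_brute_force(region):
    side, r, c = largest_inscribed_square(region)
    assert side == brute_force_square(region)
    if side:
        assert region[r : r + side, c : c + side].all()


def test_square_tie_breaks_toward_centroid():
    region = np.zeros((5, 11), bool)
    region[1:4, 0:3] = True  # far square
    region[1:4, 4:7] = True  # centered square
    region[1:4, 8:11] = True  # far square
    side, r, c = largest_inscribed_square(region)
    assert (side, r, c) == (3, 1, 4)


# ---------------------------------------------------------------------------
# VOI protocol


def test_waist_is_narrowest_slice():
    vert, info = make_synthetic_vertebra()
    voi = extract_prism_voi(vert)
    centrum = default_centrum_mask(vert)
    widths = []
    for k in range(vert.shape[2]):
        rows = np.nonzero(centrum[:, :, k].any(axis=1))[0]
        widths.append(rows[-1] - rows[0] + 1 if len(rows) else np.inf)
    waist = int(np.argmin(widths))
    # the footprint was chosen on the narrowest slice and must fit there
    interior_rows = voi.row0, voi.row0 + voi.side
    assert widths[waist] == min(widths)
    assert voi.z0 <= waist < voi.z1
    assert interior_rows[1] - interior_rows[0] == voi.side


def test_prism_footprint_contains_only_compartment():
    vert, _ = make_synthetic_vertebra()
    voi = extract_prism_voi(vert)
    assert voi.side >= 3
    assert 0 <= voi.z0 < voi.z1 <= vert.shape[2]


def test_inscribed_sphere_radius_rule():
    voi = PrismVOI(side=20, row0=5, col0=5, z0=10, z1=22)
    roi = inscribed_sphere(voi)
    assert roi.radius == min(20, 12) / 2.0
    assert roi.center == voi.center


def test_sphere_mask_center_inclusion():
    roi = SphereROI(center=(2.0, 2.0, 2.0), radius=1.0)
    m = sphere_mask((5, 5, 5), roi)
    assert m[2, 2, 2]
    assert m.sum() == 7  # center + 6 face neighbours at distance exactly 1
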