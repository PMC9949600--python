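"""Shared fixtures. Heavy phantoms are session-scoped so they are built
and measured once."""

import warnings

import numpy as np
import pytest

from trabecula.metrics import DirectionSet, bv_tv, mil_analysis, tb_n, tb_th
from trabecula.synthetic import make_plate_stack, rod_lattice_with_nodes
from trabecula.volume_io import BinaryVolume, SphereROI


@pytest.fixture(scope="session")
def plate_stack():
    """Plate phantom: t=0.1 mm, g=0.4 mm, 10 um voxels, 1.5 mm cube."""
    volume, truth = make_plate_stack(
        0.1, 0.4, normal_axis=0, extent_mm=(1.5, 1.5, 1.5), voxel_size_um=10.0
    )
    return volume, truth


@pytest.fixture(scope="session")
def plate_measurements(plate_stack):
    """Metric battery on the plate phantom (computed once)."""
    volume, truth = plate_stack
    center = tuple((s - 1) / 2.0 for s in volume.shape)
    roi = SphereROI(center=center, radius=min(volume.shape) / 2 - 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bvtv = bv_tv(volume, None)  # whole volume spans exact periods
        mil = mil_analysis(volume, roi, dirs=DirectionSet(128))
        th = tb_th(volume, None, mil_result=mil, bvtv=bvtv)
        n = tb_n(volume, None, mil_result=mil, tb_th_um=th["local_spheres_um"])
    return {"bvtv": bvtv, "mil": mil, "tb_th": th, "tb_n": n, "truth": truth}


@pytest.fixture(scope="session")
def iso_lattice():
    """Isotropic 3x3x3-node rod lattice, 20 um voxels."""
    return rod_lattice_with_nodes(3)


@pytest.fixture
def small_slab():
    """A flat slab 5 voxels thick inside a 40^3 volume, 25 um voxels."""
    mask = np.zeros((40, 40, 40), bool)
    mask[18:23, :, :] = True
    return BinaryVolume(mask=mask, voxel_size_um=25.0)
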