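import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trabecula.synthetic import (
    CLADE_ECOLOGY,
    GENERATING_EXPONENTS,
    METRICS,
    SPECIES_TABLE,
    XENARTHRAN_FIXTURE_NEWICK,
    CladeSimSpec,
    LatticeSpec,
    lattice_bvtv_oracle,
    lattice_cycle_rank,
    make_plate_stack,
    make_rod_lattice,
    make_synthetic_vertebra,
    rod_lattice_with_nodes,
    simulate_clade,
)


# ---------------------------------------------------------------------------
# Lattices


def graph_cycle_rank(k):
    """Independent oracle: cycle rank of the k^3 grid graph via networkx."""
    g = nx.grid_graph(dim=(k, k, k))
    return g.number_of_edges() - g.number_of_nodes() + 1


@pytest.mark.parametrize("k", [2, 3, 4])
def test_cycle_rank_matches_networkx(k):
    _, truth = rod_lattice_with_nodes(k, voxel_size_um=40.0)
    assert truth.connectivity == graph_cycle_rank(k)


def test_lattice_bvtv_oracle_converges():
    # voxel-count oracle converges once the pitch resolves the struts
    # (radius 0.05 mm = 5 voxels at 10 um)
    spec = LatticeSpec()
    coarse = lattice_bvtv_oracle(spec, fine_voxel_um=10.0)
    fine = lattice_bvtv_oracle(spec, fine_voxel_um=5.0)
    assert abs(coarse - fine) / fine < 0.05


def test_lattice_spec_invariants():
    with pytest.raises(ValueError):
        LatticeSpec(strut_radius_mm=-0.1)
    with pytest.raises(ValueError):
        LatticeSpec(spacing_mm=(0.5, 0.5, 0.0))


def test_rod_lattice_ground_truth_fields():
    vol, truth = rod_lattice_with_nodes(2, voxel_size_um=40.0)
    assert truth.tb_th_um == 100.0  # 2 * strut radius
    assert truth.tb_n_per_mm == pytest.approx(2.0)  # 1 / 0.5 mm spacing
    assert 0 < truth.bv_tv < 1
    assert vol.mask.any()


# ---------------------------------------------------------------------------
# Plates


def test_plate_stack_exact_fraction():
    vol, truth = make_plate_stack(
        0.1, 0.4, normal_axis=0, extent_mm=(1.5, 1.0, 1.0), voxel_size_um=10.0
    )
    # 1.5 mm extent = exactly 3 periods, so the raster fraction is exact
    assert truth.bv_tv == pytest.approx(0.2)
    assert vol.mask.mean() == pytest.approx(0.2)


def test_plate_stack_phase_centered():
    vol, _ = make_plate_stack(
        0.1, 0.4, normal_axis=0, extent_mm=(1.5, 0.2, 0.2), voxel_size_um=10.0
    )
    profile = vol.mask.any(axis=(1, 2))
    mid = len(profile) // 2
    # a plate straddles mid-extent symmetrically
    assert profile[mid - 4 : mid + 4].all()
    assert not profile[mid - 10]


@pytest.mark.parametrize("axis", [0, 1, 2])
def test_plate_stack_normal_axis(axis):
    vol, _ = make_plate_stack(
        0.1, 0.4, normal_axis=axis, extent_mm=(1.0, 1.0, 1.0), voxel_size_um=20.0
    )
    others = tuple(a for a in range(3) if a != axis)
    profile = vol.mask.all(axis=others)
    assert profile.any() and not profile.all()


# ---------------------------------------------------------------------------
# Synthetic vertebra


def test_vertebra_waist_is_narrowest():
    vol, info = make_synthetic_vertebra()
    assert 0 < info["waist_index"] < vol.shape[2]


def test_vertebra_rejects_bad_geometry():
    with pytest.raises(ValueError):
        make_synthetic_vertebra(waist_fraction=1.5)
    with pytest.raises(ValueError):
        make_synthetic_vertebra(arch_inner_radius_mm=1.0, centrum_radius_mm=1.5)


# ---------------------------------------------------------------------------
# Clade simulation


def test_simulate_clade_shape_and_columns():
    table, newick = simulate_clade(CladeSimSpec(seed=3))
    assert len(table) == int(SPECIES_TABLE["n_specimens"].sum()) * 6
    for col in ("taxon", "clade", "ecology", "mass_g", "izl_mm", *METRICS):
        assert col in table.columns
    assert newick == XENARTHRAN_FIXTURE_NEWICK
    assert (table.groupby("clade")["ecology"].nunique() == 1).all()
    assert set(table["ecology"]) == set(CLADE_ECOLOGY.values())


def test_simulate_clade_deterministic():
    a, _ = simulate_clade(CladeSimSpec(seed=11))
    b, _ = simulate_clade(CladeSimSpec(seed=11))
    pd.testing.assert_frame_equal(a, b)
    c, _ = simulate_clade(CladeSimSpec(seed=12))
    assert not np.allclose(a["bv_tv"], c["bv_tv"])


def test_simulate_clade_zero_noise_recovers_exponents():
    spec = CladeSimSpec(
        seed=0,
        brownian_share=0.0,
        izl_noise_sd=0.0,
        noise_sd={m: 0.0 for m in METRICS},
    )
    table, _ = simulate_clade(spec)
    lx = np.log10(table["izl_mm"].to_numpy())
    for m in METRICS:
        ly = np.log10(table[m].to_numpy())
        slope = np.polyfit(lx, ly, 1)[0]
        assert slope == pytest.approx(GENERATING_EXPONENTS[m], abs=1e-9)


def test_simulate_clade_validation():
    with pytest.raises(ValueError):
        CladeSimSpec(brownian_share=1.5)
    bad = SPECIES_TABLE.copy()
    bad.loc[0, "n_specimens"] = 0
    with pytest.raises(ValueError):
        CladeSimSpec(species_table=bad)


def test_ecology_effect_shifts_group_intercepts():
    eff = {"bv_tv": {"arboreal": 0.5, "hook-and-pull": 0.0, "scratch": 0.0}}
    spec = CladeSimSpec(seed=5, ecology_effects=eff, brownian_share=0.0)
    table, _ = simulate_clade(spec)
    base, _ = simulate_clade(CladeSimSpec(seed=5, brownian_share=0.0))
    arboreal = table["ecology"] == "arboreal"
    ratio = table.loc[arboreal, "bv_tv"].to_numpy() / base.loc[
        arboreal, "bv_tv"
    ].to_numpy()
    assert np.allclose(np.log10(ratio), 0.5)
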