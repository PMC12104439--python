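"""Fixture generation: determinism, idealness, perturbations, motion series."""

import numpy as np
import pytest

from gmmrefine import chemdata, synthetic
from gmmrefine.geometry import GeometryEngine
from gmmrefine.gmm_density import frc
from gmmrefine.synthetic import FixtureSpec, HingeSpec


@pytest.mark.parametrize(
    "seq,mol,recipe",
    [
        ("AAAAA", "protein", "helix"),
        ("AALKEAALKE", "protein", "helix"),
        ("GSNDHKRWEF", "protein", "strand"),
        ("IVTQM", "protein", "helix"),
        ("GGGG", "rna", "helix"),
        ("ACGUACGU", "rna", "helix"),
    ],
)
def test_fixtures_are_outlier_free(seq, mol, recipe, templates):
    m = synthetic.make_toy_structure(
        FixtureSpec(seq, molecule=mol, recipe=recipe)
    )
    topo = chemdata.compile_topology(m, templates)
    rep = GeometryEngine(topo, templates).report(m.coords)
    assert rep.bond_outliers == 0
    assert rep.angle_outliers == 0
    assert rep.planarity_violations == 0
    assert rep.clash_count == 0
    if mol == "protein":
        assert rep.rama_outlier_fraction == 0.0
        if not np.isnan(rep.rotamer_outlier_fraction):
            assert rep.rotamer_outlier_fraction == 0.0
    else:
        assert rep.rna_outliers == 0
        assert np.all(np.array([rep.rna_mean_suite_score]) > 0.001)


def test_generation_is_bit_reproducible():
    a = synthetic.make_toy_structure(FixtureSpec("AALKE", seed=3))
    b = synthetic.make_toy_structure(FixtureSpec("AALKE", seed=3))
    np.testing.assert_array_equal(a.coords, b.coords)


def test_unknown_letters_rejected():
    with pytest.raises(ValueError):
        synthetic.make_toy_structure(FixtureSpec("AAXA"))
    with pytest.raises(ValueError):
        synthetic.make_toy_structure(FixtureSpec(""))
    with pytest.raises(ValueError):
        synthetic.make_toy_structure(FixtureSpec("GAXU", molecule="rna"))


def test_map_of_single_atom_is_centered_blob(templates):
    m = synthetic.make_toy_structure(FixtureSpec("G"))
    one = m.with_coords(m.coords)
    # reduce to one atom
    from gmmrefine.model_io import AtomicModel

    one = AtomicModel(m.element[:1], m.atom_name[:1], m.res_name[:1],
                      m.res_seq[:1], m.icode[:1], m.chain_id[:1],
                      m.coords[:1], m.occupancy[:1], dict(m.chain_types))
    dmap = synthetic.simulate_map(one, 8.0, 2.0, 16)
    peak = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
    zyx = (np.array(peak) + 0.5) * dmap.voxel + dmap.origin[::-1]
    np.testing.assert_allclose(zyx[::-1], one.coords[0], atol=dmap.voxel / 2)


def test_identical_settings_give_identical_maps(helix_model):
    a = synthetic.simulate_map(helix_model, 8.0, 2.5, 24)
    b = synthetic.simulate_map(helix_model, 8.0, 2.5, 24)
    r = frc(a.grid[12], b.grid[12])
    np.testing.assert_array_equal(a.grid, b.grid)
    nonzero = r.per_ring != 0
    np.testing.assert_allclose(r.per_ring[nonzero], 1.0, atol=1e-12)


def test_model_outside_box_rejected(helix_model):
    with pytest.raises(ValueError):
        synthetic.simulate_map(helix_model, 8.0, 1.0, 8)


def test_hinge_preserves_internal_geometry(templates):
    m = synthetic.make_toy_structure(FixtureSpec("A" * 40))
    pert, rmsd = synthetic.perturb(m, HingeSpec(21, 15.0))
    assert rmsd > 2.0
    topo = chemdata.compile_topology(m, templates)
    from gmmrefine import dgeom
    from gmmrefine.autodiff import Var

    L0 = dgeom.bond_lengths(Var(m.coords), topo.bond_index).data
    L1 = dgeom.bond_lengths(Var(pert.coords), topo.bond_index).data
    np.testing.assert_allclose(L0, L1, atol=1e-9)
    A0 = dgeom.bond_angles(Var(m.coords), topo.angle_index).data
    A1 = dgeom.bond_angles(Var(pert.coords), topo.angle_index).data
    np.testing.assert_allclose(A0, A1, atol=1e-9)


def test_jitter_mean_displacement_matches_chi_distribution():
    """3D Gaussian jitter: mean |d| = sigma * 2 * sqrt(2/pi) * ... (chi_3)."""
    m = synthetic.make_toy_structure(FixtureSpec("A" * 40))
    sigma = 0.1
    pert, _ = synthetic.perturb(m, jitter_sigma=sigma, seed=9)
    d = np.linalg.norm(pert.coords - m.coords, axis=1)
    expected_mean = sigma * np.sqrt(2) * 2 / np.sqrt(np.pi)  # chi_3 mean
    assert d.mean() == pytest.approx(expected_mean, rel=0.15)


def test_perturbation_is_seeded(helix_model):
    a, _ = synthetic.perturb(helix_model, jitter_sigma=0.2, seed=5)
    b, _ = synthetic.perturb(helix_model, jitter_sigma=0.2, seed=5)
    np.testing.assert_array_equal(a.coords, b.coords)


def test_motion_series_interpolates_uniformly(templates):
    m = synthetic.make_toy_structure(FixtureSpec("A" * 30))
    series, truths = synthetic.make_motion_series(
        m, HingeSpec(16, 20.0), 5, resolution=8.0, voxel=2.5, box=36
    )
    assert len(series.maps) == 5
    np.testing.assert_allclose(series.latent_coords.ravel(),
                               np.linspace(0, 1, 5))
    # hinge angles grow linearly: the psi of residue 16 shifts by 5 deg/state
    topo = chemdata.compile_topology(m, templates)
    from gmmrefine import dgeom
    from gmmrefine.autodiff import Var

    k = np.flatnonzero(topo.rama_residue == 15)[0]   # residue 16, 0-based 15
    psis = [
        dgeom.dihedrals(Var(t.coords), topo.psi_quads).data[k] for t in truths
    ]
    steps = np.diff(psis)
    np.testing.assert_allclose(np.abs(steps), 5.0, atol=0.2)


def test_motion_series_end_maps_differ(templates):
    m = synthetic.make_toy_structure(FixtureSpec("A" * 30))
    series, _ = synthetic.make_motion_series(
        m, HingeSpec(16, 20.0), 5, resolution=8.0, voxel=2.5, box=36
    )
    from gmmrefine.gmm_density import make_projections

    pa = make_projections(series.maps[0], 4, seed=0)
    pb = make_projections(series.maps[-1], 4, seed=0)
    r = frc(pa.images[0], pb.images[0], pixel=2.5, cutoff_resolution=8.0)
    assert r.mean_to_cutoff < 0.95
    # adjacent maps are similar
    pc = make_projections(series.maps[1], 4, seed=0)
    r2 = frc(pa.images[0], pc.images[0], pixel=2.5, cutoff_resolution=8.0)
    assert r2.mean_to_cutoff > r.mean_to_cutoff


def test_motion_series_truth_models_are_clean(templates):
    m = synthetic.make_toy_structure(FixtureSpec("A" * 30))
    _, truths = synthetic.make_motion_series(
        m, HingeSpec(16, 20.0), 3, resolution=8.0, voxel=2.5, box=36
    )
    for t in truths:
        topo = chemdata.compile_topology(t, templates)
        rep = GeometryEngine(topo, templates).report(t.coords)
        assert rep.bond_outliers == 0
        assert rep.clash_count == 0
        assert rep.rama_outlier_fraction == 0.0
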