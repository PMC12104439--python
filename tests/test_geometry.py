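"""Stereochemical scoring: hard thresholds, oracles, gradients, invariances."""

import numpy as np
import pytest

from gmmrefine import chemdata, dgeom, synthetic
from gmmrefine.autodiff import Var
from gmmrefine.geometry import GeometryEngine, combined_loss
from gmmrefine.model_io import place_hydrogens
from gmmrefine.surfaces import (
    RAMA_OUTLIER,
    ROTAMER_OUTLIER,
    histogram_lookup,
    rama_histogram,
    rotamer_histogram,
)
from gmmrefine.synthetic import FixtureSpec


def terminal_bond(model, topo):
    """Index of a CA-CB bond whose CB moves no other bonded term when
    displaced radially (ALA CB is a leaf of the bond graph)."""
    for k, (i, j) in enumerate(topo.bond_index):
        if (model.atom_name[i] == "CA" and model.atom_name[j] == "CB"
                and model.res_name[j] == "ALA"):
            return k
    raise AssertionError("no ALA CA-CB bond in fixture")


def stretch_bond(model, topo, bond_no, delta):
    """Displace the second atom of a bond along the bond axis."""
    i, j = topo.bond_index[bond_no]
    coords = model.coords.copy()
    v = coords[j] - coords[i]
    coords[j] += v / np.linalg.norm(v) * delta
    return coords


# -- bonds and angles --------------------------------------------------------


def test_ideal_fixture_has_no_outliers_and_minimal_likelihood(helix_engine,
                                                              helix_model):
    bl, al, info = helix_engine.bond_angle_score(helix_model.coords)
    assert info["bond_outliers"] == 0
    assert info["angle_outliers"] == 0
    assert info["bond_rms_z"] < 1e-3
    assert float(bl.data) < 1e-6


def test_bond_outlier_reported_beyond_5_sigma(helix_model, helix_topo,
                                              helix_engine):
    k = terminal_bond(helix_model, helix_topo)
    sigma = helix_topo.bond_sigma[k]
    coords = stretch_bond(helix_model, helix_topo, k, 6.0 * sigma)
    _, _, info = helix_engine.bond_angle_score(coords)
    assert info["bond_outliers"] == 1


def test_bond_at_4p7_sigma_penalised_but_not_reported(helix_model, helix_topo,
                                                      helix_engine):
    """Penalty activates at 4.5 sigma, reporting only at 5 sigma."""
    k = terminal_bond(helix_model, helix_topo)
    sigma = helix_topo.bond_sigma[k]
    c_ok = stretch_bond(helix_model, helix_topo, k, 4.2 * sigma)
    c_pen = stretch_bond(helix_model, helix_topo, k, 4.7 * sigma)
    l_ok, _, info_ok = helix_engine.bond_angle_score(c_ok)
    l_pen, _, info_pen = helix_engine.bond_angle_score(c_pen)
    assert info_pen["bond_outliers"] == 0 and info_ok["bond_outliers"] == 0
    # hinge contribution: the 4.7-sigma loss exceeds the likelihood-only
    # prediction by much more than the 4.2-sigma one does
    n = len(helix_topo.bond_index)
    hinge_pen = float(l_pen.data) - float(l_ok.data) - 0.5 * (4.7**2 - 4.2**2) / n
    assert hinge_pen > 1.0 / n


# -- planarity ---------------------------------------------------------------


def omega_atoms(model, topo):
    k = np.flatnonzero(topo.planar_is_omega)[0]
    return k, topo.planar_index[k]


def test_peptide_omega_threshold(helix_model, helix_topo, helix_engine):
    # rotate the second half of the model about the peptide bond N-C axis
    k, quad = omega_atoms(helix_model, helix_topo)
    coords = helix_model.coords.copy()
    d0 = dgeom.dihedrals(Var(coords), helix_topo.planar_index).data[k]
    assert abs(abs(d0) - 180) < 3
    _, viol = helix_engine.planarity_score(coords)
    assert viol == 0
    # twist residues after the bond by 40 degrees -> omega 140, violation
    from gmmrefine.synthetic import _rotate_about_axis

    c_at, n_at = quad[1], quad[2]
    move = np.arange(len(coords)) >= n_at
    coords[move] = _rotate_about_axis(coords[move], coords[c_at],
                                      coords[n_at] - coords[c_at], 40.0)
    d1 = dgeom.dihedrals(Var(coords), helix_topo.planar_index).data[k]
    assert abs(abs(d1) - 180) == pytest.approx(40.0, abs=1.0)
    _, viol = helix_engine.planarity_score(coords)
    assert viol >= 1


def test_aromatic_ring_10_degree_threshold(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AFA"))
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    _, viol0 = eng.planarity_score(m.coords)
    assert viol0 == 0
    # bend CZ out of the ring plane to break ring quads by > 10 degrees
    coords = m.coords.copy()
    ring = [i for i in range(m.n_atoms)
            if m.res_name[i] == "PHE" and m.atom_name[i] in
            ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")]
    plane = coords[ring]
    normal = np.linalg.svd(plane - plane.mean(0))[2][2]
    cz = [i for i in ring if m.atom_name[i] == "CZ"][0]
    coords[cz] += normal * 0.4
    _, viol = eng.planarity_score(coords)
    assert viol >= 1


# -- Ramachandran ------------------------------------------------------------


def test_helix_is_rama_favored(helix_engine, helix_model):
    _, frac = helix_engine.rama_score(helix_model.coords)
    assert frac["outlier"] == 0.0
    assert frac["favored"] == 1.0


def test_rama_outlier_matches_histogram_oracle(templates):
    """A residue forced to (60, -120) is an outlier by both the discrete
    histogram lookup and the fitted surface."""
    m = synthetic.make_toy_structure(
        FixtureSpec("AAAAA", phi_psi=[(-60, -45), (-60, -45), (60, -120),
                                      (-60, -45), (-60, -45)])
    )
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    phi, psi, classes = eng._rama_angles(Var(m.coords))
    k = 1  # interior residue index with (60, -120): residues 2..4 scored
    ang = np.stack([phi.data, psi.data], axis=1)
    assert ang[k] == pytest.approx([60, -120], abs=2)
    hist = rama_histogram("General", 64)
    oracle = histogram_lookup(hist, ang, (360.0, 360.0)) < RAMA_OUTLIER
    surf_call = (
        eng.rama_surfaces["General"].evaluate(ang).data
        < eng.rama_surfaces["General"].outlier_threshold
    )
    np.testing.assert_array_equal(oracle, surf_call)
    assert oracle[k]
    _, frac = eng.rama_score(m.coords)
    assert frac["outlier"] == pytest.approx(1 / 3)


def test_pre_proline_uses_its_own_class(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AAPAA"))
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    _, _, classes = eng._rama_angles(Var(m.coords))
    # scored residues are 2,3,4: residue 2 precedes PRO
    assert classes[0] == "pre-Pro"
    assert classes[1] == "trans-Pro"
    assert classes[2] == "General"


def test_glycine_and_ile_val_classes(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AGIVA"))
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    _, _, classes = eng._rama_angles(Var(m.coords))
    assert list(classes) == ["Gly", "Ile", "Ile"]


# -- rotamers ----------------------------------------------------------------


def test_gly_ala_only_peptide_has_no_rotamer_terms(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AGAGA"))
    topo = chemdata.compile_topology(m, templates)
    assert len(topo.chi_quads) == 0


def test_leucine_at_peak_scores_maximum(templates):
    m = synthetic.make_toy_structure(FixtureSpec("ALA"))
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    loss, info = eng.rotamer_score(m.coords)
    assert info["outlier"] == 0.0


def test_displaced_leucine_is_outlier_matching_oracle(templates):
    from gmmrefine.refine_single import _apply_chi, _chi_machinery

    m = synthetic.make_toy_structure(FixtureSpec("ALA"))
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    ents = _chi_machinery(m, eng, templates)
    coords = m.coords.copy()
    coords = _apply_chi(coords, ents[0], 60.0)
    coords = _apply_chi(coords, ents[1], 60.0)
    chi = eng.chi_angles(coords)["LEU"][1].data
    surf = eng.rotamer_surfaces["LEU"]
    hist = rotamer_histogram("LEU", 36)
    oracle = histogram_lookup(hist, chi, surf.periods) < ROTAMER_OUTLIER
    mine = surf.evaluate(chi).data < surf.outlier_threshold
    np.testing.assert_array_equal(mine, oracle)
    assert oracle[0]
    _, info = eng.rotamer_score(coords)
    assert info["outlier"] == 1.0


# -- clashes -----------------------------------------------------------------


def test_far_fragments_do_not_clash(helix_engine, helix_model):
    _, count, per1000 = helix_engine.clash_score(helix_model.coords)
    assert count == 0 and per1000 == 0.0


def test_clash_thresholds_carbon_and_hbond(templates):
    """C-C pairs clash beyond 0.4 Å overlap; H...O gets an extra 0.4 Å."""
    m = synthetic.make_toy_structure(FixtureSpec("AAAA"))
    topo = chemdata.compile_topology(m, templates)
    # find a candidate C-C pair and an H...O pair and verify thresholds
    eC = topo.elements
    cc = [(i, j) for i, j in topo.pair_index if eC[i] == "C" and eC[j] == "C"]
    thr = dict(zip(map(tuple, topo.pair_index.tolist()), topo.pair_thresh))
    i, j = cc[0]
    assert thr[(i, j)] == pytest.approx(1.70 + 1.70 - 0.4)
    ho = [(i, j) for i, j in topo.pair_index
          if {eC[i], eC[j]} == {"H", "O"}]
    i, j = ho[0]
    radii = topo.radii[i] + topo.radii[j]
    assert thr[(i, j)] == pytest.approx(radii - 0.8)


def test_clash_counts_match_all_vs_all_oracle(templates):
    """Engine clash count equals a brute-force all-vs-all distance oracle."""
    m = synthetic.make_toy_structure(FixtureSpec("GSNDHKRWEF", recipe="helix"))
    pert, _ = synthetic.perturb(m, jitter_sigma=0.15, seed=4)
    topo = chemdata.compile_topology(pert, templates)
    eng = GeometryEngine(topo, templates)
    _, count, _ = eng.clash_score(pert.coords)
    h = place_hydrogens(pert.coords, topo.hspec)
    X = np.vstack([pert.coords, h])
    radii, elems = topo.radii, topo.elements
    brute = 0
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            if j in set(topo.excluded[i]):
                continue
            t = radii[i] + radii[j] - 0.4
            if (elems[i] == "H" and elems[j] in "NO") or (
                elems[j] == "H" and elems[i] in "NO"
            ):
                t -= 0.4
            if np.linalg.norm(X[i] - X[j]) < t:
                brute += 1
    assert count == brute


def test_neighbor_refresh_detects_new_contacts(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AAAAAAAA"))
    topo = chemdata.compile_topology(m, templates)
    eng = GeometryEngine(topo, templates)
    # slam the two chain halves together
    coords = m.coords.copy()
    half = m.res_seq > 4
    coords[half] -= (coords[half].mean(0) - coords[~half].mean(0)) * 0.9
    stale_loss, stale_count, _ = eng.clash_score(coords)
    eng.refresh_neighbors(coords, force=True)
    _, fresh_count, _ = eng.clash_score(coords)
    assert fresh_count >= stale_count
    assert fresh_count > 0


def test_refresh_is_deterministic_for_unchanged_coords(helix_topo,
                                                       helix_model, templates):
    before = [nb.copy() for nb in helix_topo.neighbor_index]
    eng = GeometryEngine(helix_topo, templates)
    eng.refresh_neighbors(helix_model.coords, force=True)
    for a, b in zip(before, helix_topo.neighbor_index):
        np.testing.assert_array_equal(a, b)


# -- RNA ---------------------------------------------------------------------


def test_rna_fixture_suites_all_assigned(rna_engine, rna_model):
    _, info = rna_engine.rna_suite_score(rna_model.coords)
    assert info["outliers"] == 0
    assert info["mean_score"] > 0.25
    assert np.all(info["scores"] > 0.001)


def test_rna_outlier_excluded_from_mean_but_in_loss(rna_engine, rna_model):
    """Mangling one base's backbone keeps it in the loss but not the mean."""
    coords = rna_model.coords.copy()
    loss0, info0 = rna_engine.rna_suite_score(coords)
    # rotate one O3' wildly to break the torsions of one suite
    sel = (rna_model.res_seq == 3) & np.isin(rna_model.atom_name,
                                             ("O3'", "C3'", "C2'", "O2'"))
    from gmmrefine.synthetic import _rotate_about_axis

    c4 = np.flatnonzero((rna_model.res_seq == 3)
                        & (rna_model.atom_name == "C4'"))[0]
    c5 = np.flatnonzero((rna_model.res_seq == 3)
                        & (rna_model.atom_name == "C5'"))[0]
    coords[sel] = _rotate_about_axis(coords[sel], coords[c4],
                                     coords[c4] - coords[c5], 150.0)
    loss1, info1 = rna_engine.rna_suite_score(coords)
    assert info1["outliers"] >= 1
    assert float(loss1.data) > float(loss0.data)
    # outlier bases do not drag the reported mean below the assigned-only mean
    assigned = info1["scores"] >= 0.001
    assert info1["mean_score"] == pytest.approx(
        float(info1["scores"][assigned].mean())
    )


# -- aggregation and invariances ---------------------------------------------


def test_combined_loss_weights():
    comps = {"a": 2.0, "b": 3.0}
    assert float(combined_loss(comps, {"a": 0.0, "b": 1.0}).data) == 3.0
    assert float(combined_loss(comps, {"a": 2.0, "b": 1.0}).data) == 7.0
    with pytest.raises(ValueError):
        combined_loss(comps, {"a": -1.0})


def test_doubling_weight_doubles_contribution(helix_engine, helix_model):
    coords = helix_model.coords + 0.05
    t1, c1 = helix_engine.loss(coords, weights={"bond": 1.0})
    t2, c2 = helix_engine.loss(coords, weights={"bond": 2.0})
    assert float(t2.data) - float(t1.data) == pytest.approx(c1["bond"],
                                                            rel=1e-9)


def test_losses_invariant_under_rigid_motion(helix_engine, helix_model):
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec([0.5, 0.2, -0.4]).as_matrix()
    t = np.array([11.0, -4.0, 7.0])
    c0 = helix_model.coords
    l0, comps0 = helix_engine.loss(c0)
    l1, comps1 = helix_engine.loss(c0 @ R.T + t)
    for k in comps0:
        assert comps1[k] == pytest.approx(comps0[k], abs=1e-6), k


def test_geometry_gradients_finite_difference(templates):
    """Every differentiable term passes a directional derivative check."""
    m = synthetic.make_toy_structure(FixtureSpec("ALSA"))
    pert, _ = synthetic.perturb(m, jitter_sigma=0.05, seed=2)
    topo = chemdata.compile_topology(pert, templates)
    eng = GeometryEngine(topo, templates)
    rng = np.random.default_rng(3)
    x0 = pert.coords
    for terms in (("bond",), ("angle",), ("planarity",), ("rama",),
                  ("rotamer",), ("clash",)):
        v = Var(x0.copy(), requires_grad=True)
        total, _ = eng.loss(v, terms=terms)
        total.backward()
        g = v.grad
        d = rng.normal(size=x0.shape)
        d /= np.linalg.norm(d)
        h = 1e-5
        lp, _ = eng.loss(x0 + h * d, terms=terms)
        lm, _ = eng.loss(x0 - h * d, terms=terms)
        num = (float(lp.data) - float(lm.data)) / (2 * h)
        ana = float((g * d).sum())
        assert ana == pytest.approx(num, rel=1e-3, abs=1e-10), terms


def test_rna_gradient_finite_difference(rna_engine, rna_model):
    rng = np.random.default_rng(4)
    x0 = rna_model.coords + rng.normal(0, 0.03, rna_model.coords.shape)
    v = Var(x0.copy(), requires_grad=True)
    total, _ = rna_engine.loss(v, terms=("rna",))
    total.backward()
    d = rng.normal(size=x0.shape)
    d /= np.linalg.norm(d)
    h = 1e-5
    lp, _ = rna_engine.loss(x0 + h * d, terms=("rna",))
    lm, _ = rna_engine.loss(x0 - h * d, terms=("rna",))
    num = (float(lp.data) - float(lm.data)) / (2 * h)
    assert float((v.grad * d).sum()) == pytest.approx(num, rel=1e-3)
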