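"""Desk-scale benchmark experiments.

Each function generates its synthetic inputs, runs the relevant part of the
refinement stack, and returns plain numbers.  They are shared by the
acceptance test suite and by ``scripts/acceptance.py`` so the reported
quantities are always recomputed from scratch.

Problem sizes are chosen for a single CPU: a 40-residue two-domain helix,
8 Å maps in a 40³ box at 2.5 Å voxels, 24 projections per map for
single-model refinement and 16 per map for the 5-map series.
"""

from __future__ import annotations

import numpy as np

from . import chemdata, dgeom, synthetic
from .autodiff import Var
from .geometry import GeometryEngine
from .gmm_density import frc, make_projections, frc_loss
from .model_io import model_to_gmm, place_hydrogens
from .refine_single import RefinementConfig, refine
from .refine_series import SeriesConfig, refine_series, sample_series
from .surfaces import (
    RAMA_OUTLIER,
    ROTAMER_OUTLIER,
    default_rama_surfaces,
    default_rotamer_surfaces,
    fit_reference_gmm,
    histogram_lookup,
    load_suite_library,
    make_histogram,
    rama_histogram,
    rotamer_histogram,
    wrap_deg,
)
from .synthetic import FixtureSpec, HingeSpec


def _rmsd(a, b):
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def single_model_config(seed: int) -> RefinementConfig:
    return RefinementConfig(
        target_resolution=8.0, n_projections=24, n_patches=6, seed=seed,
        iters_patch=400, iters_residue=250, iters_atom=350,
    )


def hinge_fixture(seed: int = 0):
    truth = synthetic.make_toy_structure(
        FixtureSpec("A" * 40, recipe="helix", seed=seed)
    )
    pert, rmsd0 = synthetic.perturb(truth, HingeSpec(21, 15.0))
    dmap = synthetic.simulate_map(truth, resolution=8.0, voxel=2.5, box=40)
    return truth, pert, rmsd0, dmap


def single_model_recovery(seed: int = 1) -> dict:
    """Hinge-perturbed 40-residue helix refined against the true-state map."""
    truth, pert, rmsd0, dmap = hinge_fixture()
    out, report = refine(pert, dmap, single_model_config(seed))
    rmsd1 = _rmsd(out.coords, truth.coords)
    return {
        "start_rmsd": rmsd0,
        "final_rmsd": rmsd1,
        "rmsd_reduction_percent": 100.0 * (1.0 - rmsd1 / rmsd0),
        "rama_outliers": report.rama_outlier_fraction,
        "bond_outliers": report.bond_outliers,
        "clash_score": report.clash_score,
        "n_atoms": truth.n_atoms,
    }


def series_recovery(seed: int = 1, n_latents: int = 20) -> dict:
    """5-map hinge series: end-state recovery + geometry at random latents."""
    base = synthetic.make_toy_structure(FixtureSpec("A" * 40, recipe="helix"))
    series, truths = synthetic.make_motion_series(
        base, HingeSpec(21, 20.0), 5, resolution=8.0, voxel=2.5, box=40
    )
    inter = _rmsd(truths[0].coords, truths[-1].coords)
    cfg = SeriesConfig(target_resolution=8.0, n_patches=6, seed=seed,
                       iters_polish=400)
    refiner = refine_series(truths[0], series, cfg)
    end_rmsds = []
    for k in (0, len(truths) - 1):
        m = sample_series(refiner, [series.latent_coords[k]])[0]
        end_rmsds.append(_rmsd(m.coords, truths[k].coords))
    engine = GeometryEngine(chemdata.compile_topology(truths[0]))
    rng = np.random.default_rng(seed)
    worst = {"bond_outliers": 0, "rama_outliers": 0.0, "clash_count": 0,
             "planarity_violations": 0}
    for z in rng.uniform(0, 1, n_latents):
        m = sample_series(refiner, [[z]])[0]
        engine.refresh_neighbors(m.coords, force=True)
        rep = engine.report(m.coords)
        worst["bond_outliers"] = max(worst["bond_outliers"], rep.bond_outliers)
        worst["rama_outliers"] = max(worst["rama_outliers"],
                                     rep.rama_outlier_fraction)
        worst["clash_count"] = max(worst["clash_count"], rep.clash_count)
        worst["planarity_violations"] = max(worst["planarity_violations"],
                                            rep.planarity_violations)
    return {
        "inter_state_rmsd": inter,
        "end_state_rmsd": max(end_rmsds),
        "end_state_rmsd_percent_of_inter": 100.0 * max(end_rmsds) / inter,
        "n_latent_frames": n_latents,
        **{f"worst_{k}": v for k, v in worst.items()},
    }


def determinism(seed: int = 1) -> dict:
    """Max per-atom deviation between two refinements with the same seed."""
    truth, pert, _, dmap = hinge_fixture()
    cfg = RefinementConfig(target_resolution=8.0, n_projections=16,
                           n_patches=6, seed=seed, iters_patch=120,
                           iters_residue=80, iters_atom=100)
    a, _ = refine(pert, dmap, cfg)
    b, _ = refine(pert, dmap, cfg)
    return {"max_atom_deviation": float(np.abs(a.coords - b.coords).max())}


def zero_penalty_baseline(seed: int = 0) -> dict:
    """Outlier counts over the ideal synthetic fixtures (expect all zero)."""
    total = {"bond_outliers": 0, "angle_outliers": 0,
             "planarity_violations": 0, "clash_count": 0, "rama_outliers": 0,
             "rotamer_outliers": 0, "rna_suite_outliers": 0}
    fixtures = [
        ("AALKEAALKE", "protein", "helix"),
        ("GSNDHKRWEF", "protein", "strand"),
        ("IVTQM", "protein", "helix"),
        ("ACGUACGU", "rna", "helix"),
    ]
    for seq, mol, recipe in fixtures:
        m = synthetic.make_toy_structure(
            FixtureSpec(seq, molecule=mol, recipe=recipe, seed=seed)
        )
        rep = GeometryEngine(chemdata.compile_topology(m)).report(m.coords)
        total["bond_outliers"] += rep.bond_outliers
        total["angle_outliers"] += rep.angle_outliers
        total["planarity_violations"] += rep.planarity_violations
        total["clash_count"] += rep.clash_count
        if mol == "protein":
            total["rama_outliers"] += int(
                round(rep.rama_outlier_fraction * 100)
            )
            if not np.isnan(rep.rotamer_outlier_fraction):
                total["rotamer_outliers"] += int(
                    round(rep.rotamer_outlier_fraction * 100)
                )
        else:
            total["rna_suite_outliers"] += rep.rna_outliers
    total["n_fixtures"] = len(fixtures)
    return total


def oracle_equivalence(seed: int = 0) -> dict:
    """Fraction of hard-threshold calls agreeing with independent oracles."""
    out = {}
    # clash count vs all-vs-all brute force on a jittered fixture
    m = synthetic.make_toy_structure(FixtureSpec("GSNDHKRWEF", recipe="helix"))
    pert, _ = synthetic.perturb(m, jitter_sigma=0.15, seed=seed + 4)
    topo = chemdata.compile_topology(pert)
    engine = GeometryEngine(topo)
    _, count, _ = engine.clash_score(pert.coords)
    h = place_hydrogens(pert.coords, topo.hspec)
    X = np.vstack([pert.coords, h])
    brute = 0
    for i in range(len(X)):
        excl = set(topo.excluded[i])
        for j in range(i + 1, len(X)):
            if j in excl:
                continue
            t = topo.radii[i] + topo.radii[j] - 0.4
            ei, ej = topo.elements[i], topo.elements[j]
            if (ei == "H" and ej in "NO") or (ej == "H" and ei in "NO"):
                t -= 0.4
            if np.linalg.norm(X[i] - X[j]) < t:
                brute += 1
    out["clash_count"] = count
    out["clash_count_brute_force"] = brute
    out["clash_agreement"] = float(count == brute)

    # Ramachandran outlier calls vs histogram lookup (fixture + displaced)
    m2 = synthetic.make_toy_structure(
        FixtureSpec("AAAAAAAA",
                    phi_psi=[(-60, -45)] * 3 + [(60, -120)] + [(-60, -45)] * 4)
    )
    topo2 = chemdata.compile_topology(m2)
    eng2 = GeometryEngine(topo2)
    phi, psi, classes = eng2._rama_angles(Var(m2.coords))
    ang = np.stack([phi.data, psi.data], axis=1)
    hist = rama_histogram("General", 64)
    oracle = histogram_lookup(hist, ang, (360.0, 360.0)) < RAMA_OUTLIER
    surf = eng2.rama_surfaces["General"]
    mine = surf.evaluate(ang).data < surf.outlier_threshold
    out["rama_agreement"] = float(np.mean(oracle == mine))

    # rotamer outlier calls vs histogram lookup
    from .refine_single import _apply_chi, _chi_machinery

    m3 = synthetic.make_toy_structure(FixtureSpec("ALA"))
    topo3 = chemdata.compile_topology(m3)
    eng3 = GeometryEngine(topo3)
    ents = _chi_machinery(m3, eng3, chemdata.load_templates())
    agree = []
    for delta in (0.0, 60.0, 120.0):
        coords = m3.coords.copy()
        for e in ents:
            coords = _apply_chi(coords, e, delta)
        chi = eng3.chi_angles(coords)["LEU"][1].data
        surf3 = eng3.rotamer_surfaces["LEU"]
        hist3 = rotamer_histogram("LEU", 36)
        oracle3 = histogram_lookup(hist3, chi, surf3.periods) < ROTAMER_OUTLIER
        mine3 = surf3.evaluate(chi).data < surf3.outlier_threshold
        agree.append(float(np.mean(oracle3 == mine3)))
    out["rotamer_agreement"] = float(np.mean(agree))

    # RNA suite assignment vs exhaustive 46-center search
    lib = load_suite_library()
    rng = np.random.default_rng(seed)
    vecs = lib.centers[rng.integers(0, 46, 50)] + rng.normal(0, 25, (50, 7))
    idx, _ = lib.assign(vecs)
    ok = 0
    for v, i in zip(vecs, idx):
        d = [np.sqrt(np.mean((wrap_deg(v - c) / lib.halfwidth) ** 2))
             for c in lib.centers]
        ok += int(np.argmin(d) == i)
    out["suite_agreement"] = ok / len(vecs)

    # FRC vs explicit ring-masked correlation
    A = rng.normal(size=(32, 32))
    B = rng.normal(size=(32, 32)) + 0.5 * A
    got = frc(A, B).per_ring
    FA, FB = np.fft.fft2(A), np.fft.fft2(B)
    f = np.fft.fftfreq(32) * 32
    fx, fy = np.meshgrid(f, f, indexing="ij")
    ring = np.rint(np.sqrt(fx**2 + fy**2)).astype(int)
    errs = []
    for k in range(16):
        msk = ring == k
        num = np.sum(FA[msk] * np.conj(FB[msk])).real
        den = np.sqrt(np.sum(np.abs(FA[msk]) ** 2)
                      * np.sum(np.abs(FB[msk]) ** 2))
        errs.append(abs(got[k] - num / den))
    out["frc_max_abs_error"] = float(max(errs))
    return out


def gradient_checks(seed: int = 0) -> dict:
    """Max relative directional-derivative error over every loss term."""
    rng = np.random.default_rng(seed)
    m = synthetic.make_toy_structure(FixtureSpec("ALSA"))
    pert, _ = synthetic.perturb(m, jitter_sigma=0.05, seed=seed + 2)
    engine = GeometryEngine(chemdata.compile_topology(pert))
    x0 = pert.coords
    errs = {}
    for terms in (("bond",), ("angle",), ("planarity",), ("rama",),
                  ("rotamer",), ("clash",)):
        v = Var(x0.copy(), requires_grad=True)
        total, _ = engine.loss(v, terms=terms)
        total.backward()
        d = rng.normal(size=x0.shape)
        d /= np.linalg.norm(d)
        h = 1e-5
        lp, _ = engine.loss(x0 + h * d, terms=terms)
        lm, _ = engine.loss(x0 - h * d, terms=terms)
        num = (float(lp.data) - float(lm.data)) / (2 * h)
        ana = float((v.grad * d).sum())
        errs[terms[0]] = abs(ana - num) / max(abs(num), 1e-9)
    # RNA term
    r = synthetic.make_toy_structure(FixtureSpec("GGACUG", molecule="rna"))
    er = GeometryEngine(chemdata.compile_topology(r))
    x0 = r.coords + rng.normal(0, 0.03, r.coords.shape)
    v = Var(x0.copy(), requires_grad=True)
    total, _ = er.loss(v, terms=("rna",))
    total.backward()
    d = rng.normal(size=x0.shape)
    d /= np.linalg.norm(d)
    h = 1e-5
    lp, _ = er.loss(x0 + h * d, terms=("rna",))
    lm, _ = er.loss(x0 - h * d, terms=("rna",))
    num = (float(lp.data) - float(lm.data)) / (2 * h)
    errs["rna"] = abs(float((v.grad * d).sum()) - num) / max(abs(num), 1e-9)
    # map term
    mm = synthetic.make_toy_structure(FixtureSpec("A" * 12))
    dmap = synthetic.simulate_map(mm, 8.0, 2.5, 24)
    proj = make_projections(dmap, 6, seed=seed)
    gmm = model_to_gmm(mm, resolution=8.0)
    v = Var(mm.coords.copy(), requires_grad=True)
    loss = frc_loss((v, gmm.amplitudes, gmm.widths), proj, 8.0, batch=[0, 1])
    loss.backward()
    d = rng.normal(size=mm.coords.shape)
    d /= np.linalg.norm(d)
    h = 1e-4
    lp = float(frc_loss((Var(mm.coords + h * d), gmm.amplitudes, gmm.widths),
                        proj, 8.0, batch=[0, 1]).data)
    lm = float(frc_loss((Var(mm.coords - h * d), gmm.amplitudes, gmm.widths),
                        proj, 8.0, batch=[0, 1]).data)
    num = (lp - lm) / (2 * h)
    errs["frc"] = abs(float((v.grad * d).sum()) - num) / max(abs(num), 1e-9)
    return {"max_relative_error": max(errs.values()), "per_term": errs}


def surface_fit(seed: int = 0) -> dict:
    """Self-representable fit accuracy + outlier-boundary classification."""
    basins = [(-60, -40, 15, 15, 1.0), (80, 100, 20, 12, 0.6),
              (150, -150, 18, 18, 0.3)]
    hist = make_histogram(basins, n_bins=48)
    surf = fit_reference_gmm(hist, 25, log_domain=False,
                             boundary_penalty=False, seed=seed + 3)
    out = {"self_representable_rmsd": surf.fit_rmsd}
    fracs = []
    for cls, s in default_rama_surfaces().items():
        h = rama_histogram(cls, 64)
        n = h.shape[0]
        centers = np.linspace(-180, 180, n, endpoint=False) + 180.0 / n
        gx, gy = np.meshgrid(centers, centers, indexing="ij")
        bins = np.stack([gx.ravel(), gy.ravel()], axis=1)
        outb = h.ravel() < RAMA_OUTLIER
        vals = s.evaluate(bins[outb]).data
        fracs.append(float(np.mean(vals < s.outlier_threshold)))
    out["outlier_boundary_classified_percent"] = 100.0 * float(np.min(fracs))
    return out
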