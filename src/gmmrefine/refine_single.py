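"""Hierarchical decoder-based single-model refinement.

The model is refined in five steps: (1) precompile topology and restraint
tables; (2) train a decoder that outputs per-patch rigid transforms (patches
from K-means over residue centers) against the map term alone; (3) add a
per-residue transform decoder and the basic restraints (bonds, angles,
clashes); (4) optionally rebuild sidechain rotamers against the map and
locally optimise chi angles; (5) train the per-atom decoder with every
stereochemical term active.  After each step the decoder output is baked
into the baseline coordinates, so the next step starts from the previous
step's model — weights never need to be saved in single-model mode.

The relative weight of the geometry terms is calibrated from the data by a
two-iteration map-only probe (the gain in map similarity divided by the
degradation in geometry score); the decoders are re-initialised afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import dgeom
from .autodiff import Adam, Var
from .chemdata import compile_topology, load_templates
from .geometry import GeometryEngine
from .gmm_density import ProjectionSet, frc_loss, make_projections
from .model_io import (
    AtomicModel,
    DensityMap,
    model_to_gmm,
    resolution_to_width,
)

__all__ = [
    "RefinementConfig",
    "PatchDecomposition",
    "DenseDecoder",
    "partition_patches",
    "balance_weights",
    "refine",
    "rebuild_rotamers",
]


@dataclass
class RefinementConfig:
    target_resolution: float = 3.0
    outlier_sigma: float = 4.5
    n_patches: int = 64
    neighbor_k: int = 128
    neighbor_refresh: int = 100
    batch_size: int = 4
    n_projections: int = 32
    iters_patch: int = 400       # step 2
    iters_residue: int = 300     # step 3
    iters_chi: int = 60          # step 4
    iters_atom: int = 400        # step 5
    lr: float = 2e-3
    decoder_width: int = 64
    rot_scale: float = 0.2       # radians per unit decoder output
    trans_scale: float = 1.0     # Å per unit decoder output
    atom_scale: float = 0.3      # Å per unit decoder output
    seed: int = 0
    rebuild_rotamers: bool = False
    geometry_only: bool = False
    geometry_weight: float | None = None   # None -> balance automatically


@dataclass
class PatchDecomposition:
    patch_assignment: np.ndarray   # (n_res,) residue -> patch id
    atom_assignment: np.ndarray    # (n_atoms,)
    centers: np.ndarray            # (P, 3) Å
    n_patches: int


def partition_patches(model: AtomicModel, n_patches: int, seed: int = 0) -> PatchDecomposition:
    """K-means over residue centers; all atoms of a residue share a patch."""
    from sklearn.cluster import KMeans

    starts = list(model.residue_starts()) + [model.n_atoms]
    res_of_atom = np.empty(model.n_atoms, int)
    centers = []
    for r, (s, e) in enumerate(zip(starts[:-1], starts[1:])):
        res_of_atom[s:e] = r
        centers.append(model.coords[s:e].mean(axis=0))
    centers = np.array(centers)
    k = min(n_patches, len(centers))
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    res_patch = km.fit_predict(centers)
    return PatchDecomposition(
        patch_assignment=res_patch,
        atom_assignment=res_patch[res_of_atom],
        centers=km.cluster_centers_.copy(),
        n_patches=k,
    )


class DenseDecoder:
    """Four-layer densely connected decoder with a zero-initialised head.

    The zero head makes the decoder output exactly zero at initialisation,
    so refinement starts from the baseline model; hidden weights start with
    small random values from the given seed.
    """

    def __init__(self, n_out: int, width: int = 64, seed: int = 0, n_in: int = 4):
        rng = np.random.default_rng(seed)
        dims = [n_in, width, width, width, n_out]
        self.weights, self.biases = [], []
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            scale = 0.0 if last else np.sqrt(2.0 / a)
            self.weights.append(Var(rng.normal(0, 1, (a, b)) * scale,
                                    requires_grad=True))
            self.biases.append(Var(np.zeros(b), requires_grad=True))

    @property
    def params(self):
        return self.weights + self.biases

    def __call__(self, latent) -> Var:
        h = ad.as_var(latent)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ W + b
            if i < len(self.weights) - 1:
                h = ad.relu(h)
        return h


def apply_rigid(coords, params: Var, assignment: np.ndarray,
                centers: np.ndarray, rot_scale: float, trans_scale: float) -> Var:
    """Per-group rigid transform: params (P, 6) = (rotvec, translation)."""
    p = params.reshape(-1, 6)
    rot = p[:, 0:3] * rot_scale
    tra = p[:, 3:6] * trans_scale
    r_at = rot[assignment]
    t_at = tra[assignment]
    c_at = centers[assignment]
    return dgeom.rodrigues_apply(coords, r_at, center=c_at) + t_at


CONST_INPUT = np.ones(4)   # single-model conformation input


class _SingleModelStack:
    """Decoder stack evaluated at the constant input (single-model mode)."""

    def __init__(self, baseline: np.ndarray, patches: PatchDecomposition,
                 res_assign: np.ndarray, res_centers: np.ndarray,
                 cfg: RefinementConfig, seed: int, active=("patch",)):
        self.baseline = baseline
        self.patches = patches
        self.res_assign = res_assign
        self.res_centers = res_centers
        self.cfg = cfg
        self.active = active
        n_res = len(res_centers)
        self.d_patch = DenseDecoder(patches.n_patches * 6, cfg.decoder_width,
                                    seed=seed)
        self.d_res = DenseDecoder(n_res * 6, cfg.decoder_width, seed=seed + 1)
        self.d_atom = DenseDecoder(len(baseline) * 3, cfg.decoder_width,
                                   seed=seed + 2)

    @property
    def params(self):
        out = []
        if "patch" in self.active:
            out += self.d_patch.params
        if "residue" in self.active:
            out += self.d_res.params
        if "atom" in self.active:
            out += self.d_atom.params
        return out

    def coords(self) -> Var:
        x = Var(self.baseline)
        if "patch" in self.active:
            out = self.d_patch(CONST_INPUT)
            x = apply_rigid(x, out, self.patches.atom_assignment,
                            self.patches.centers, self.cfg.rot_scale,
                            self.cfg.trans_scale)
        if "residue" in self.active:
            out = self.d_res(CONST_INPUT)
            x = apply_rigid(x, out, self.res_assign, self.res_centers,
                            self.cfg.rot_scale * 0.5, self.cfg.trans_scale * 0.5)
        if "atom" in self.active:
            out = self.d_atom(CONST_INPUT)
            x = x + out.reshape(-1, 3) * self.cfg.atom_scale
        return x


def _residue_assignment(model: AtomicModel):
    starts = list(model.residue_starts()) + [model.n_atoms]
    assign = np.empty(model.n_atoms, int)
    centers = []
    for r, (s, e) in enumerate(zip(starts[:-1], starts[1:])):
        assign[s:e] = r
        centers.append(model.coords[s:e].mean(axis=0))
    return assign, np.array(centers)


def _train(stack, engine: GeometryEngine, projections, cfg: RefinementConfig,
           rng, iters: int, terms, geo_weight: float, amps, widths,
           use_map=True, log=None):
    opt = Adam(stack.params, lr=cfg.lr)
    n_img = projections.n_images if projections is not None else 0
    for it in range(iters):
        opt.zero_grad()
        coords = stack.coords()
        total = Var(0.0)
        if use_map and projections is not None:
            batch = rng.choice(n_img, size=min(cfg.batch_size, n_img),
                               replace=False)
            total = total + frc_loss((coords, amps, widths), projections,
                                     cfg.target_resolution, batch=batch)
        if terms:
            geo, comps = engine.loss(coords, terms=terms)
            total = total + geo_weight * geo
        if not np.isfinite(total.data):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}; aborting refinement step"
            )
        total.backward()
        opt.step()
        engine.refresh_neighbors(stack.coords().data, every=cfg.neighbor_refresh)
        if log is not None:
            log.append(float(total.data))
    return stack


def balance_weights(baseline: np.ndarray, engine: GeometryEngine,
                    projections: ProjectionSet, cfg: RefinementConfig,
                    patches: PatchDecomposition, res_assign, res_centers,
                    amps, widths) -> float:
    """Two-iteration map-only probe; weight = Δ(map score)/Δ(geometry score).

    The probe state is discarded (decoders are re-initialised by the
    caller), matching the re-initialise-and-restart rule.
    """
    stack = _SingleModelStack(baseline, patches, res_assign, res_centers,
                              cfg, seed=cfg.seed + 900, active=("patch", "residue", "atom"))
    rng = np.random.default_rng(cfg.seed + 901)

    def map_score(coords):
        l = frc_loss((Var(coords), amps, widths), projections,
                     cfg.target_resolution)
        return -float(l.data)

    s0 = map_score(baseline)
    g0 = engine.geometry_scalar(baseline)
    _train(stack, engine, projections, cfg, rng, iters=2, terms=None,
           geo_weight=0.0, amps=amps, widths=widths)
    after = stack.coords().data
    s1 = map_score(after)
    g1 = engine.geometry_scalar(after)
    d_map, d_geo = s1 - s0, g1 - g0
    if d_geo <= 1e-12 or d_map <= 0:
        warnings.warn("probe produced no geometry degradation; using weight 1.0")
        return 1.0
    return float(d_map / d_geo)


BASIC_TERMS = ("bond", "angle", "clash")
ALL_TERMS = ("bond", "angle", "planarity", "rama", "rotamer", "clash", "rna")


def refine(model: AtomicModel, density, config: RefinementConfig | None = None,
           templates=None):
    """Five-step refinement; returns (refined model, GeometryReport).

    `density` may be a DensityMap, a ProjectionSet, or None (geometry-only:
    runs the final step without a map term).
    """
    cfg = config or RefinementConfig()
    templates = templates or load_templates()
    topo = compile_topology(model, templates, neighbor_k=cfg.neighbor_k)
    engine = GeometryEngine(topo, templates, outlier_sigma=cfg.outlier_sigma)
    rng = np.random.default_rng(cfg.seed)

    projections = None
    dmap = None
    if isinstance(density, DensityMap):
        dmap = density
        if density.voxel > cfg.target_resolution / 2.0:
            raise ValueError("map voxel size violates Nyquist for the target "
                             "resolution")
        projections = make_projections(density, cfg.n_projections,
                                       seed=cfg.seed + 1)
    elif isinstance(density, ProjectionSet):
        projections = density
    elif density is not None:
        raise TypeError("density must be DensityMap, ProjectionSet, or None")

    gmm = model_to_gmm(model, resolution=cfg.target_resolution)
    amps, widths = gmm.amplitudes, gmm.widths
    baseline = model.coords.copy()
    cur = model

    if projections is not None and not cfg.geometry_only:
        res_assign, res_centers = _residue_assignment(cur)
        patches = partition_patches(cur, cfg.n_patches, seed=cfg.seed)
        if cfg.geometry_weight is None:
            w_geo = balance_weights(baseline, engine, projections, cfg,
                                    patches, res_assign, res_centers,
                                    amps, widths)
        else:
            w_geo = float(cfg.geometry_weight)

        # step 2: large-scale patch morphing, map term only
        stack = _SingleModelStack(baseline, patches, res_assign, res_centers,
                                  cfg, seed=cfg.seed + 10, active=("patch",))
        _train(stack, engine, projections, cfg, rng, cfg.iters_patch,
               terms=None, geo_weight=0.0, amps=amps, widths=widths)
        baseline = stack.coords().data.copy()
        cur = cur.with_coords(baseline)

        # step 3: residue-level adjustment + basic restraints
        engine.refresh_neighbors(baseline, force=True)
        res_assign, res_centers = _residue_assignment(cur)
        patches = partition_patches(cur, cfg.n_patches, seed=cfg.seed)
        stack = _SingleModelStack(baseline, patches, res_assign, res_centers,
                                  cfg, seed=cfg.seed + 20,
                                  active=("patch", "residue"))
        _train(stack, engine, projections, cfg, rng, cfg.iters_residue,
               terms=BASIC_TERMS, geo_weight=w_geo, amps=amps, widths=widths)
        baseline = stack.coords().data.copy()
        cur = cur.with_coords(baseline)

        # step 4: rotamer rebuild + local chi refinement
        if cfg.rebuild_rotamers and dmap is not None:
            cur = rebuild_rotamers(cur, dmap, engine=engine, cfg=cfg,
                                   templates=templates)
            baseline = cur.coords.copy()
    else:
        w_geo = cfg.geometry_weight if cfg.geometry_weight is not None else 1.0

    # step 5: full-atom refinement with every constraint (runs without a map
    # in geometry-only mode)
    engine.refresh_neighbors(baseline, force=True)
    res_assign, res_centers = _residue_assignment(cur)
    patches = partition_patches(cur, cfg.n_patches, seed=cfg.seed)
    stack = _SingleModelStack(baseline, patches, res_assign, res_centers,
                              cfg, seed=cfg.seed + 30,
                              active=("patch", "residue", "atom"))
    use_map = projections is not None and not cfg.geometry_only
    _train(stack, engine, projections if use_map else None, cfg, rng,
           cfg.iters_atom, terms=ALL_TERMS, geo_weight=w_geo if use_map else 1.0,
           amps=amps, widths=widths, use_map=use_map)
    final = stack.coords().data.copy()
    out = cur.with_coords(final)
    engine.refresh_neighbors(final, force=True)
    report = engine.report(final)
    return out, report


# ---------------------------------------------------------------------------
# rotamer rebuild (step 4)


def _map_values(dmap: DensityMap, pts: np.ndarray) -> np.ndarray:
    from scipy import ndimage

    idx = (pts - dmap.origin) / dmap.voxel - 0.5
    return ndimage.map_coordinates(dmap.grid, idx.T[::-1], order=1,
                                   mode="constant", cval=0.0)


def map_interp(dmap: DensityMap, coords) -> Var:
    """Differentiable trilinear map sampling at atom positions."""
    X = ad.as_var(coords)
    vals = _map_values(dmap, X.data)
    h = 0.5 * dmap.voxel

    def vjp(g):
        out = np.zeros_like(X.data)
        for k in range(3):
            e = np.zeros(3)
            e[k] = h
            out[:, k] = g * (
                _map_values(dmap, X.data + e) - _map_values(dmap, X.data - e)
            ) / (2 * h)
        return out

    return Var.op(vals, (X,), (vjp,))


def _chi_machinery(model: AtomicModel, engine: GeometryEngine, templates):
    """Per-chi (axis atoms, moved atom indices) from the compiled topology."""
    topo = engine.topo
    entries = []
    for quad, ridx, k in zip(topo.chi_quads, topo.chi_res, topo.chi_k):
        res = topo.residues[ridx]
        tpl = templates[res.name]
        names = tpl.chi_definitions[k]
        moved_names = tpl.distal_atoms(names[1], names[2])
        moved = [res.atoms[nm] for nm in moved_names if nm in res.atoms]
        entries.append({"quad": quad, "res": int(ridx), "k": int(k),
                        "moved": np.array(moved, int)})
    return entries


def _apply_chi(coords: np.ndarray, entry, delta_deg: float) -> np.ndarray:
    from .synthetic import _rotate_about_axis

    b, c = entry["quad"][1], entry["quad"][2]
    out = coords.copy()
    out[entry["moved"]] = _rotate_about_axis(
        coords[entry["moved"]], coords[b], coords[c] - coords[b], delta_deg
    )
    return out


def rebuild_rotamers(model: AtomicModel, dmap: DensityMap, engine=None,
                     cfg: RefinementConfig | None = None, templates=None):
    """Library-peak rotamer search against the map, then local chi polish.

    For every chi-bearing residue each library peak is instantiated
    geometrically and scored by the mean map density over its moved
    sidechain atoms; the best-scoring peak is kept (ties keep the input
    rotamer).  A short Adam run then refines all chi angles jointly against
    map density, the rotamer surfaces, and the clash term.
    """
    cfg = cfg or RefinementConfig()
    templates = templates or load_templates()
    if engine is None:
        topo = compile_topology(model, templates, neighbor_k=cfg.neighbor_k)
        engine = GeometryEngine(topo, templates,
                                outlier_sigma=cfg.outlier_sigma)
    entries = _chi_machinery(model, engine, templates)
    by_res = {}
    for e in entries:
        by_res.setdefault(e["res"], []).append(e)
    coords = model.coords.copy()
    surfaces = engine.rotamer_surfaces
    for ridx, ents in sorted(by_res.items()):
        res = engine.topo.residues[ridx]
        surf = surfaces.get(res.name)
        if surf is None or not surf.peaks:
            continue
        ents = sorted(ents, key=lambda e: e["k"])
        if len(ents) != len(surf.peaks[0]):
            continue
        cur_chi = [
            float(dgeom.dihedrals(Var(coords), e["quad"][None, :]).data[0])
            for e in ents
        ]
        sc_atoms = ents[0]["moved"]

        def score(c):
            return float(np.mean(_map_values(dmap, c[sc_atoms])))

        best_c, best_s, switched = coords, score(coords), False
        for peak in surf.peaks:
            trial = coords.copy()
            for e, cur, target in zip(ents, cur_chi, peak):
                cur_t = float(
                    dgeom.dihedrals(Var(trial), e["quad"][None, :]).data[0]
                )
                trial = _apply_chi(trial, e, target - cur_t)
            s = score(trial)
            if s > best_s + 1e-9:
                best_c, best_s, switched = trial, s, True
        coords = best_c
    # local joint chi polish
    coords = _chi_polish(coords, entries, dmap, engine, cfg)
    return model.with_coords(coords)


def _scatter_rows(delta: Var, idx: np.ndarray, n: int) -> Var:
    """Lift a (m, 3) row block into an (n, 3) array (rows `idx`), keeping
    gradients flowing back to the block."""
    data = np.zeros((n, 3))
    data[idx] = delta.data
    return Var.op(data, (delta,), (lambda g: g[idx],))


def _chi_polish(coords0: np.ndarray, entries, dmap, engine, cfg):
    """Joint local chi optimisation, linearised about the current rotation
    axes (re-derived from the rebuilt coordinates)."""
    if not entries:
        return coords0
    n_atoms = len(coords0)
    dchi = Var(np.zeros(len(entries)), requires_grad=True)
    opt = Adam([dchi], lr=2.0)  # degrees
    scale = 1.0 / max(np.abs(dmap.grid).max(), 1e-9)
    for _ in range(cfg.iters_chi):
        opt.zero_grad()
        X = Var(coords0)
        for i, e in enumerate(entries):
            b, c = e["quad"][1], e["quad"][2]
            axis = coords0[c] - coords0[b]
            axis = axis / np.linalg.norm(axis)
            moved = e["moved"]
            rv = (dchi[i] * (np.pi / 180.0)).reshape(1, 1) * axis[None, :]
            sub = X[moved]
            rot = dgeom.rodrigues_apply(sub, rv * np.ones((len(moved), 1)),
                                        center=coords0[b])
            X = X + _scatter_rows(rot - sub, moved, n_atoms)
        dens = map_interp(dmap, X).mean()
        geo, _ = engine.loss(X, terms=("rotamer", "clash"))
        total = -dens * scale + geo
        total.backward()
        opt.step()
    out = coords0.copy()
    for i, e in enumerate(entries):
        out = _apply_chi(out, e, float(dchi.data[i]))
    return out
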