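"""Conformation-conditioned refinement of a continuous model series.

Inputs are a stack of 3D reconstructions with per-map latent conformation
coordinates (the output of any continuous heterogeneity analysis).  The
same three-decoder hierarchy as single-model refinement is trained, but the
decoder input is the map's latent coordinate (padded to the 4-vector input;
the single-model mode's constant [1,1,1,1] is the degenerate case) plus a
small seeded Gaussian perturbation, so the learned mapping latent -> model
is continuous and can be sampled between the training maps.  Unlike
single-model refinement the decoder weights are the artifact: they are kept
through all phases and serialised with the refiner.

A final geometry-only polish trains on latents drawn uniformly over the
trajectory, with a weak anchor to the pre-polish models so the map-facing
frames stay put while stereochemistry is cleaned up everywhere on the
trajectory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dgeom
from .autodiff import Adam, Var
from .chemdata import compile_topology, load_templates
from .geometry import GeometryEngine
from .gmm_density import frc_loss, make_projections
from .model_io import AtomicModel, DensityMap, model_to_gmm
from .refine_single import (
    ALL_TERMS,
    BASIC_TERMS,
    DenseDecoder,
    RefinementConfig,
    _residue_assignment,
    apply_rigid,
    partition_patches,
)

__all__ = [
    "ConformationSeries",
    "SeriesRefiner",
    "SeriesConfig",
    "refine_series",
    "geometry_polish",
    "sample_series",
]


@dataclass
class ConformationSeries:
    latent_coords: np.ndarray          # (M, d), d <= 4
    maps: list                         # M DensityMap (or ProjectionSet)
    trajectory: np.ndarray | None = None   # ordered latent points to sample

    def __post_init__(self):
        self.latent_coords = np.atleast_2d(np.asarray(self.latent_coords, float))
        if self.latent_coords.shape[1] > 4:
            raise ValueError("latent dimensionality must be <= 4")
        if len(self.maps) != len(self.latent_coords):
            raise ValueError("one latent point per reconstruction required")


@dataclass
class SeriesConfig(RefinementConfig):
    n_projections: int = 16            # per map (reduced vs single-model)
    latent_noise: float = 0.05         # fraction of the latent range
    iters_patch: int = 400
    iters_residue: int = 300
    iters_atom: int = 400
    iters_polish: int = 300
    polish_anchor: float = 1.0         # Å^-2 pull toward pre-polish frames


class SeriesRefiner:
    """Trained decoder stack mapping latent coordinates to models."""

    def __init__(self, model: AtomicModel, series: ConformationSeries,
                 cfg: SeriesConfig, templates=None):
        self.model = model
        self.cfg = cfg
        self.templates = templates or load_templates()
        self.baseline = model.coords.copy()
        self.latent_dim = series.latent_coords.shape[1]
        self.latent_lo = series.latent_coords.min(axis=0)
        self.latent_hi = series.latent_coords.max(axis=0)
        self.res_assign, self.res_centers = _residue_assignment(model)
        self.patches = partition_patches(model, cfg.n_patches, seed=cfg.seed)
        n_res = len(self.res_centers)
        self.d_patch = DenseDecoder(self.patches.n_patches * 6,
                                    cfg.decoder_width, seed=cfg.seed + 10)
        self.d_res = DenseDecoder(n_res * 6, cfg.decoder_width,
                                  seed=cfg.seed + 11)
        self.d_atom = DenseDecoder(len(self.baseline) * 3, cfg.decoder_width,
                                   seed=cfg.seed + 12)
        gmm = model_to_gmm(model, resolution=cfg.target_resolution)
        self.amps, self.widths = gmm.amplitudes, gmm.widths

    # -- latent handling -------------------------------------------------
    def pad_latent(self, latent) -> np.ndarray:
        z = np.atleast_1d(np.asarray(latent, float))
        if len(z) != self.latent_dim:
            raise ValueError(
                f"latent dimensionality {len(z)} != {self.latent_dim}"
            )
        return np.concatenate([z, np.ones(4 - len(z))])

    # -- forward ---------------------------------------------------------
    def coords(self, latent, active=("patch", "residue", "atom")) -> Var:
        inp = self.pad_latent(latent)
        x = Var(self.baseline)
        if "patch" in active:
            x = apply_rigid(x, self.d_patch(inp), self.patches.atom_assignment,
                            self.patches.centers, self.cfg.rot_scale,
                            self.cfg.trans_scale)
        if "residue" in active:
            x = apply_rigid(x, self.d_res(inp), self.res_assign,
                            self.res_centers, self.cfg.rot_scale * 0.5,
                            self.cfg.trans_scale * 0.5)
        if "atom" in active:
            x = x + self.d_atom(inp).reshape(-1, 3) * self.cfg.atom_scale
        return x

    def params(self, active):
        out = []
        if "patch" in active:
            out += self.d_patch.params
        if "residue" in active:
            out += self.d_res.params
        if "atom" in active:
            out += self.d_atom.params
        return out

    # -- persistence -----------------------------------------------------
    def save(self, path):
        arrays = {"baseline": self.baseline,
                  "latent_lo": self.latent_lo, "latent_hi": self.latent_hi}
        for name, dec in (("patch", self.d_patch), ("res", self.d_res),
                          ("atom", self.d_atom)):
            for i, (W, b) in enumerate(zip(dec.weights, dec.biases)):
                arrays[f"{name}_W{i}"] = W.data
                arrays[f"{name}_b{i}"] = b.data
        meta = {"latent_dim": self.latent_dim,
                "config": {k: v for k, v in vars(self.cfg).items()
                           if isinstance(v, (int, float, bool, str))}}
        np.savez(path, meta=json.dumps(meta), **arrays)

    def load_weights(self, path):
        data = np.load(path, allow_pickle=False)
        self.baseline = data["baseline"]
        self.latent_lo, self.latent_hi = data["latent_lo"], data["latent_hi"]
        self.latent_dim = int(json.loads(str(data["meta"]))["latent_dim"])
        for name, dec in (("patch", self.d_patch), ("res", self.d_res),
                          ("atom", self.d_atom)):
            for i in range(len(dec.weights)):
                dec.weights[i].data = data[f"{name}_W{i}"]
                dec.biases[i].data = data[f"{name}_b{i}"]
        return self


def _series_projections(series: ConformationSeries, cfg: SeriesConfig):
    from .gmm_density import ProjectionSet

    out = []
    ref = None
    for k, m in enumerate(series.maps):
        if isinstance(m, DensityMap):
            key = (m.size, m.voxel)
            if ref is None:
                ref = key
            elif key != ref:
                raise ValueError("all maps must share box and voxel size")
            out.append(make_projections(m, cfg.n_projections, seed=cfg.seed + 50 + k))
        elif isinstance(m, ProjectionSet):
            out.append(m)
        else:
            raise TypeError("series entries must be DensityMap or ProjectionSet")
    return out


def _train_series(refiner: SeriesRefiner, series, projections, engine, cfg,
                  rng, iters, active, terms, geo_weight):
    opt = Adam(refiner.params(active), lr=cfg.lr)
    M = len(projections)
    span = np.maximum(refiner.latent_hi - refiner.latent_lo, 1e-9)
    for it in range(iters):
        opt.zero_grad()
        k = it % M                      # cycle maps; batch within one map
        noise = rng.normal(0.0, cfg.latent_noise, refiner.latent_dim) * span
        z = series.latent_coords[k] + noise
        coords = refiner.coords(z, active=active)
        proj = projections[k]
        batch = rng.choice(proj.n_images, size=min(cfg.batch_size, proj.n_images),
                           replace=False)
        total = frc_loss((coords, refiner.amps, refiner.widths), proj,
                         cfg.target_resolution, batch=batch)
        if terms:
            geo, _ = engine.loss(coords, terms=terms)
            total = total + geo_weight * geo
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        total.backward()
        opt.step()
        engine.refresh_neighbors(coords.data, every=cfg.neighbor_refresh)
    return refiner


def refine_series(model: AtomicModel, series: ConformationSeries,
                  config: SeriesConfig | None = None, templates=None,
                  polish: bool = True) -> SeriesRefiner:
    """Train the conformation-conditioned decoder hierarchy.

    The model should already be refined against the neutral/consensus map.
    Phases mirror single-model refinement (patch -> +residue -> +atom,
    growing the constraint set), but all decoders keep their weights across
    phases.  With `polish`, a geometry-only pass over the trajectory runs at
    the end.
    """
    cfg = config or SeriesConfig()
    if len(series.maps) < 2:
        raise ValueError("need at least 2 maps for a continuous series")
    templates = templates or load_templates()
    projections = _series_projections(series, cfg)
    topo = compile_topology(model, templates, neighbor_k=cfg.neighbor_k)
    engine = GeometryEngine(topo, templates, outlier_sigma=cfg.outlier_sigma)
    refiner = SeriesRefiner(model, series, cfg, templates)
    rng = np.random.default_rng(cfg.seed + 2)

    if cfg.geometry_weight is None:
        from .refine_single import balance_weights

        # probe against the worst-fitting map: the pre-refined input model
        # typically matches the neutral map already, which would leave the
        # probe with no map gain to measure
        scores = [
            -float(frc_loss((Var(model.coords), refiner.amps, refiner.widths),
                            p, cfg.target_resolution).data)
            for p in projections
        ]
        probe_proj = projections[int(np.argmin(scores))]
        w_geo = balance_weights(model.coords, engine, probe_proj, cfg,
                                refiner.patches, refiner.res_assign,
                                refiner.res_centers, refiner.amps,
                                refiner.widths)
    else:
        w_geo = float(cfg.geometry_weight)

    _train_series(refiner, series, projections, engine, cfg, rng,
                  cfg.iters_patch, ("patch",), None, 0.0)
    _train_series(refiner, series, projections, engine, cfg, rng,
                  cfg.iters_residue, ("patch", "residue"), BASIC_TERMS, w_geo)
    _train_series(refiner, series, projections, engine, cfg, rng,
                  cfg.iters_atom, ("patch", "residue", "atom"), ALL_TERMS,
                  w_geo)
    refiner._engine = engine
    if polish:
        traj = series.trajectory
        if traj is None:
            traj = np.stack([refiner.latent_lo, refiner.latent_hi])
        geometry_polish(refiner, traj, n_samples=cfg.iters_polish, config=cfg,
                        engine=engine)
    return refiner


def geometry_polish(refiner: SeriesRefiner, trajectory, n_samples,
                    config: SeriesConfig | None = None, engine=None):
    """Geometry-only training on latents drawn uniformly over the trajectory.

    A weak quadratic anchor to the pre-polish model at each latent keeps
    the map-facing frames essentially unchanged.
    """
    cfg = config or refiner.cfg
    if engine is None:
        topo = compile_topology(refiner.model, refiner.templates,
                                neighbor_k=cfg.neighbor_k)
        engine = GeometryEngine(topo, refiner.templates,
                                outlier_sigma=cfg.outlier_sigma)
    traj = np.atleast_2d(np.asarray(trajectory, float))
    lo, hi = traj.min(axis=0), traj.max(axis=0)
    # snapshot: pre-polish decoder state for the anchor term
    import copy

    frozen = copy.deepcopy(
        {"patch": [p.data.copy() for p in refiner.d_patch.params],
         "res": [p.data.copy() for p in refiner.d_res.params],
         "atom": [p.data.copy() for p in refiner.d_atom.params]}
    )

    def pre_polish_coords(z):
        saved = {}
        for name, dec in (("patch", refiner.d_patch), ("res", refiner.d_res),
                          ("atom", refiner.d_atom)):
            saved[name] = [p.data for p in dec.params]
            for p, w in zip(dec.params, frozen[name]):
                p.data = w
        out = refiner.coords(z).data.copy()
        for name, dec in (("patch", refiner.d_patch), ("res", refiner.d_res),
                          ("atom", refiner.d_atom)):
            for p, w in zip(dec.params, saved[name]):
                p.data = w
        return out

    active = ("patch", "residue", "atom")
    opt = Adam(refiner.params(active), lr=cfg.lr * 0.5)
    rng = np.random.default_rng(cfg.seed + 7)
    for it in range(n_samples):
        opt.zero_grad()
        z = lo + rng.uniform(0, 1, len(lo)) * (hi - lo)
        coords = refiner.coords(z, active=active)
        geo, _ = engine.loss(coords, terms=ALL_TERMS)
        anchor = ((coords - pre_polish_coords(z)) ** 2).mean()
        total = geo + cfg.polish_anchor * anchor
        total.backward()
        opt.step()
        engine.refresh_neighbors(coords.data, every=cfg.neighbor_refresh)
    return refiner


def sample_series(refiner: SeriesRefiner, latents) -> list:
    """Deterministic inference (no latent noise): one model per latent."""
    out = []
    for z in np.atleast_2d(np.asarray(latents, float)):
        coords = refiner.coords(z).data
        out.append(refiner.model.with_coords(coords))
    return out
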