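"""Gaussian-mixture projection and Fourier ring correlation scoring.

Training compares 2D projections rather than 3D volumes: the mixture has an
analytic projection (each isotropic 3D Gaussian projects to a 2D Gaussian
of the same width), and map projections are line integrals along seeded,
quasi-uniformly distributed viewing directions.  Similarity is the Fourier
ring correlation (FRC): every ring is independently normalised, which makes
the score insensitive to radial filtering or sharpening of either image.

The ring-restricted mean FRC up to the target resolution, negated, is the
map-model loss; it is differentiable with respect to Gaussian centers,
amplitudes and widths.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.stats import qmc

from . import autodiff as ad
from .autodiff import Var, as_var
from .model_io import DensityMap, GaussianMixture

__all__ = [
    "ProjectionSet",
    "FrcResult",
    "make_projections",
    "project_gmm",
    "frc",
    "frc_loss",
]


@dataclass
class ProjectionSet:
    images: np.ndarray        # (M, S, S)
    rotations: np.ndarray     # (M, 3, 3) object rotations
    pixel: float              # Å
    center: np.ndarray        # (3,) Å rotation center (map center)

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def size(self) -> int:
        return self.images.shape[-1]


@dataclass
class FrcResult:
    per_ring: np.ndarray      # (S//2,) correlation per integer-frequency ring
    mean_to_cutoff: float
    cutoff_frequency: float   # 1/Å


def quasi_uniform_rotations(n: int, seed: int = 0) -> np.ndarray:
    """Quasi-uniform SO(3) samples: Sobol points through Shoemake's map."""
    import warnings

    eng = qmc.Sobol(d=3, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # arbitrary sample counts are fine here: we want low discrepancy,
        # not strict digital-net balance
        warnings.simplefilter("ignore", UserWarning)
        u = eng.random(n)
    u1, u2, u3 = u[:, 0], u[:, 1], u[:, 2]
    q = np.stack(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )
    from scipy.spatial.transform import Rotation

    return Rotation.from_quat(q).as_matrix()


def _pixel_axis(size: int, pixel: float) -> np.ndarray:
    return (np.arange(size) + 0.5 - size / 2.0) * pixel


def make_projections(dmap: DensityMap, n_orientations: int, seed: int = 0) -> ProjectionSet:
    """Line-integral projections of a map along seeded quasi-uniform views."""
    if n_orientations < 1:
        raise ValueError("need at least one orientation")
    S = dmap.size
    rots = quasi_uniform_rotations(n_orientations, seed)
    center = dmap.origin + 0.5 * S * dmap.voxel
    ax = _pixel_axis(S, dmap.voxel)
    U, V, W = np.meshgrid(ax, ax, ax, indexing="ij")  # (u=x, v=y, w=depth)
    pts = np.stack([U.ravel(), V.ravel(), W.ravel()], axis=0)  # (3, S^3)
    images = np.empty((n_orientations, S, S))
    for m, R in enumerate(rots):
        src = R.T @ pts + center[:, None]               # object-frame points
        idx = (src - dmap.origin[:, None]) / dmap.voxel - 0.5
        # grid is (z, y, x)
        vals = ndimage.map_coordinates(
            dmap.grid, idx[::-1], order=3, mode="constant", cval=0.0
        ).reshape(S, S, S)
        # integrate along the viewing depth; image[y, x]
        images[m] = vals.sum(axis=2).T * dmap.voxel
    return ProjectionSet(images=images, rotations=rots, pixel=dmap.voxel,
                         center=center)


# ---------------------------------------------------------------------------
# analytic GMM projection (differentiable)


def gauss_splat(px, py, amp, width, grid: np.ndarray) -> Var:
    """Differentiable rendering of 2D Gaussians onto a square pixel grid.

    `px, py, amp, width` are (N,) arrays or Vars; `grid` is the (S,) pixel
    coordinate axis.  Returns the (S, S) image [row=y, col=x].  Forward and
    backward passes are matrix products, so cost is O(N·S²) with BLAS.
    """
    px, py, amp, width = (as_var(v) for v in (px, py, amp, width))
    g = np.asarray(grid, float)
    w = np.broadcast_to(width.data, amp.data.shape)
    dx = g[None, :] - px.data[:, None]
    dy = g[None, :] - py.data[:, None]
    Ex = np.exp(-0.5 * (dx / w[:, None]) ** 2)
    Ey = np.exp(-0.5 * (dy / w[:, None]) ** 2)
    img = (amp.data[:, None] * Ey).T @ Ex

    def vjp_px(G):
        M = (amp.data[:, None] * Ey) @ G
        return np.einsum("nc,nc->n", M * Ex, dx) / w**2

    def vjp_py(G):
        N_ = (amp.data[:, None] * Ex) @ G.T
        return np.einsum("nr,nr->n", N_ * Ey, dy) / w**2

    def vjp_amp(G):
        return np.einsum("nr,rn->n", Ey, G @ Ex.T)

    def vjp_width(G):
        M = (amp.data[:, None] * Ey) @ G
        N_ = (amp.data[:, None] * Ex) @ G.T
        gw = (
            np.einsum("nc,nc->n", M * Ex, dx**2)
            + np.einsum("nr,nr->n", N_ * Ey, dy**2)
        ) / w**3
        if width.data.shape == ():
            return gw.sum()
        return np.broadcast_to(gw, width.data.shape) if width.data.shape != gw.shape else gw

    return Var.op(img, (px, py, amp, width), (vjp_px, vjp_py, vjp_amp, vjp_width))


def project_gmm(gmm, rotation: np.ndarray, size: int, pixel: float,
                center=None) -> Var:
    """Analytic projection of a 3D GMM along a viewing rotation.

    Accepts a :class:`GaussianMixture` or an (centers, amplitudes, widths)
    triple of Vars/arrays; differentiable in all three.
    """
    if isinstance(gmm, GaussianMixture):
        centers, amps, widths = gmm.centers, gmm.amplitudes, gmm.widths
    else:
        centers, amps, widths = gmm
    centers = as_var(centers)
    amps, widths = as_var(amps), as_var(widths)
    if center is None:
        center = centers.data.mean(axis=0)
    rot = np.asarray(rotation, float)
    p = (centers - np.asarray(center, float)) @ rot.T
    # line integral of a 3D Gaussian: amplitude * width * sqrt(2 pi)
    amp_eff = amps * widths * np.sqrt(2 * np.pi)
    grid = _pixel_axis(size, pixel)
    return gauss_splat(p[:, 0], p[:, 1], amp_eff, widths, grid)


# ---------------------------------------------------------------------------
# Fourier ring correlation


@lru_cache(maxsize=32)
def _ring_index(size: int) -> tuple:
    f = np.fft.fftfreq(size) * size          # integer frequency units
    fx, fy = np.meshgrid(f, f, indexing="ij")
    r = np.rint(np.sqrt(fx**2 + fy**2)).astype(int)
    masks = tuple(r == k for k in range(size // 2))
    return masks


def frc(image_a: np.ndarray, image_b: np.ndarray, pixel: float = 1.0,
        cutoff_resolution: float | None = None) -> FrcResult:
    """Fourier ring correlation between two square images."""
    A = np.fft.fft2(np.asarray(image_a, float))
    B = np.fft.fft2(np.asarray(image_b, float))
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("images must be square and of equal size")
    S = A.shape[0]
    masks = _ring_index(S)
    per_ring = np.zeros(S // 2)
    # rings holding only numerical noise count as zero-power
    floor_a = np.sum(np.abs(A) ** 2) * 1e-14
    floor_b = np.sum(np.abs(B) ** 2) * 1e-14
    for k, m in enumerate(masks):
        num = np.real(np.sum(A[m] * np.conj(B[m])))
        da = np.sum(np.abs(A[m]) ** 2)
        db = np.sum(np.abs(B[m]) ** 2)
        if da <= floor_a or db <= floor_b:
            per_ring[k] = 0.0
        else:
            per_ring[k] = num / np.sqrt(da * db)
    r_cut = _cutoff_ring(S, pixel, cutoff_resolution)
    sel = per_ring[1: r_cut + 1]
    mean = float(sel.mean()) if len(sel) else 0.0
    cutoff_frequency = (
        1.0 / cutoff_resolution if cutoff_resolution else (S // 2) / (S * pixel)
    )
    return FrcResult(per_ring=per_ring, mean_to_cutoff=mean,
                     cutoff_frequency=cutoff_frequency)


def _cutoff_ring(size: int, pixel: float, resolution: float | None) -> int:
    if resolution is None:
        return size // 2 - 1
    r = int(np.floor(size * pixel / resolution))
    return max(1, min(r, size // 2 - 1))


def frc_mean_diff(img: Var, ref: np.ndarray, pixel: float,
                  cutoff_resolution: float) -> Var:
    """Differentiable ring-restricted mean FRC of `img` against fixed `ref`."""
    S = img.data.shape[0]
    masks = _ring_index(S)
    r_cut = _cutoff_ring(S, pixel, cutoff_resolution)
    B = np.fft.fft2(np.asarray(ref, float))
    Are, Aim = ad.fft2_ri(img)
    floor_b = float(np.sum(np.abs(B) ** 2)) * 1e-14
    terms = []
    for k in range(1, r_cut + 1):
        m = masks[k]
        db = float(np.sum(np.abs(B[m]) ** 2))
        if db <= floor_b:
            continue  # zero-power reference ring contributes nothing
        bre, bim = B[m].real, B[m].imag
        are, aim = Are[m], Aim[m]
        num = (are * bre).sum() + (aim * bim).sum()
        da = (are * are).sum() + (aim * aim).sum()
        terms.append(num / ad.sqrt(da * db + 1e-30))
    if not terms:
        return Var(0.0)
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def frc_loss(gmm, projections: ProjectionSet, target_resolution: float,
             batch: np.ndarray | None = None) -> Var:
    """Negative mean FRC of GMM projections against a projection set.

    Rings are restricted to spatial frequencies at or below
    1/target_resolution (hard cutoff); differentiable when `gmm` carries
    Vars.  `batch` selects a subset of projection indices.
    """
    if projections.pixel > target_resolution / 2.0 + 1e-9:
        raise ValueError(
            f"pixel size {projections.pixel} Å violates Nyquist for "
            f"{target_resolution} Å target resolution"
        )
    idx = np.arange(projections.n_images) if batch is None else np.asarray(batch)
    total = None
    for m in idx:
        img = project_gmm(
            gmm, projections.rotations[m], projections.size,
            projections.pixel, center=projections.center,
        )
        val = frc_mean_diff(img, projections.images[m], projections.pixel,
                            target_resolution)
        total = val if total is None else total + val
    return -(total * (1.0 / len(idx)))
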