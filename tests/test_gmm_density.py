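"""Projection and Fourier-ring-correlation scoring."""

import numpy as np
import pytest

from gmmrefine import gmm_density as gd
from gmmrefine import synthetic
from gmmrefine.autodiff import Var
from gmmrefine.model_io import GaussianMixture, model_to_gmm
from gmmrefine.synthetic import FixtureSpec


@pytest.fixture(scope="module")
def small_map(helix_model):
    return synthetic.simulate_map(helix_model, 8.0, 2.5, 32)


@pytest.fixture(scope="module")
def projections(small_map):
    return gd.make_projections(small_map, 8, seed=1)


def test_projections_are_deterministic(small_map):
    a = gd.make_projections(small_map, 6, seed=42)
    b = gd.make_projections(small_map, 6, seed=42)
    np.testing.assert_array_equal(a.images, b.images)
    np.testing.assert_array_equal(a.rotations, b.rotations)


def test_spherical_map_projects_identically():
    """A single-Gaussian (spherically symmetric) map looks the same from
    every direction."""
    one = synthetic.make_toy_structure(FixtureSpec("G")).copy()
    one.coords = one.coords[:1] * 0  # single atom at the origin
    for attr in ("element", "atom_name", "res_name", "res_seq", "icode",
                 "chain_id", "occupancy"):
        setattr(one, attr, getattr(one, attr)[:1])
    dmap = synthetic.simulate_map(one, 8.0, 1.0, 32)
    proj = gd.make_projections(dmap, 6, seed=0)
    ref = proj.images[0]
    scale = np.sqrt(np.mean(ref**2))
    for img in proj.images[1:]:
        assert np.sqrt(np.mean((img - ref) ** 2)) / scale < 0.01


def test_projection_matches_analytic_gaussian_integral():
    """Line-integral projection of one 3D Gaussian equals the closed form."""
    w = 3.0
    gmm = GaussianMixture(np.zeros((1, 3)), np.array([2.0]), np.array([w]))
    S, px = 32, 1.5
    img = gd.project_gmm(gmm, np.eye(3), S, px, center=np.zeros(3)).data
    ax = (np.arange(S) + 0.5 - S / 2) * px
    gx, gy = np.meshgrid(ax, ax, indexing="xy")
    expected = 2.0 * w * np.sqrt(2 * np.pi) * np.exp(
        -(gx**2 + gy**2) / (2 * w**2)
    )
    np.testing.assert_allclose(img, expected, rtol=1e-12)


def test_two_gaussians_superpose_along_view_axis():
    gmm = GaussianMixture(np.array([[4.0, 0, 0], [-4.0, 0, 0]]),
                          np.array([1.0, 1.0]), np.array([2.0, 2.0]))
    # view down x: rotation mapping x -> z
    R = np.array([[0.0, 0, 1], [0, 1, 0], [-1, 0, 0]])
    img = gd.project_gmm(gmm, R, 32, 1.0, center=np.zeros(3)).data
    single = GaussianMixture(np.zeros((1, 3)), np.array([2.0]),
                             np.array([2.0]))
    ref = gd.project_gmm(single, np.eye(3), 32, 1.0, center=np.zeros(3)).data
    np.testing.assert_allclose(img, ref, atol=1e-10)


def test_frc_self_is_one_and_scale_invariant(projections):
    X = projections.images[0]
    r = gd.frc(X, X, pixel=2.5, cutoff_resolution=8.0)
    nonzero = r.per_ring != 0
    np.testing.assert_allclose(r.per_ring[nonzero], 1.0, atol=1e-9)
    r2 = gd.frc(X, 5.0 * X, pixel=2.5, cutoff_resolution=8.0)
    np.testing.assert_allclose(r.per_ring, r2.per_ring, atol=1e-9)


def test_frc_insensitive_to_lowpass_within_passband(projections):
    """Rings inside a low-pass filter band keep correlation 1."""
    X = projections.images[0]
    F = np.fft.fft2(X)
    f = np.fft.fftfreq(X.shape[0]) * X.shape[0]
    fx, fy = np.meshgrid(f, f, indexing="ij")
    ring = np.rint(np.sqrt(fx**2 + fy**2))
    band = 10.0
    # ring-wise attenuation, zero beyond the band
    filt = np.clip(1 - ring / band, 0, None)
    Y = np.real(np.fft.ifft2(F * filt))
    r = gd.frc(X, Y)
    for k in range(1, 9):
        assert r.per_ring[k] == pytest.approx(1.0, abs=1e-9)
    assert abs(r.per_ring[12]) < 1e-6   # fully filtered ring has no signal


def test_frc_matches_explicit_ring_masked_oracle():
    """Independent per-ring Pearson-style correlation oracle, 1e-6."""
    rng = np.random.default_rng(0)
    A = rng.normal(size=(32, 32))
    B = rng.normal(size=(32, 32)) + 0.5 * A
    got = gd.frc(A, B).per_ring
    FA, FB = np.fft.fft2(A), np.fft.fft2(B)
    f = np.fft.fftfreq(32) * 32
    fx, fy = np.meshgrid(f, f, indexing="ij")
    ring = np.rint(np.sqrt(fx**2 + fy**2)).astype(int)
    for k in range(16):
        m = ring == k
        num = np.sum(FA[m] * np.conj(FB[m])).real
        den = np.sqrt(np.sum(np.abs(FA[m]) ** 2) * np.sum(np.abs(FB[m]) ** 2))
        assert got[k] == pytest.approx(num / den, abs=1e-6)


def test_frc_loss_self_consistency(helix_model, small_map, projections):
    gmm = model_to_gmm(helix_model, resolution=8.0)
    loss = gd.frc_loss(gmm, projections, 8.0)
    assert float(loss.data) == pytest.approx(-1.0, abs=0.05)


def test_frc_loss_invariant_under_sharpening(helix_model, small_map):
    """B-factor-like radial rescaling of the map leaves the loss unchanged."""
    gmm = model_to_gmm(helix_model, resolution=8.0)
    base = gd.make_projections(small_map, 6, seed=3)
    sharp_images = []
    f = np.fft.fftfreq(base.size) * base.size
    fx, fy = np.meshgrid(f, f, indexing="ij")
    ring = np.rint(np.sqrt(fx**2 + fy**2))
    for img in base.images:
        F = np.fft.fft2(img) * np.exp(0.05 * ring)   # inverse-B sharpening
        sharp_images.append(np.real(np.fft.ifft2(F)))
    sharp = gd.ProjectionSet(np.array(sharp_images), base.rotations,
                             base.pixel, base.center)
    l0 = float(gd.frc_loss(gmm, base, 8.0).data)
    l1 = float(gd.frc_loss(gmm, sharp, 8.0).data)
    assert l1 == pytest.approx(l0, abs=1e-9)


def test_translation_increases_loss(helix_model, projections):
    gmm = model_to_gmm(helix_model, resolution=8.0)
    moved = model_to_gmm(
        helix_model.with_coords(helix_model.coords + 10.0), resolution=8.0
    )
    l0 = float(gd.frc_loss(gmm, projections, 8.0).data)
    l1 = float(gd.frc_loss(moved, projections, 8.0).data)
    assert l1 > l0 + 0.1


def test_nyquist_violation_rejected(helix_model, projections):
    gmm = model_to_gmm(helix_model, resolution=8.0)
    with pytest.raises(ValueError, match="Nyquist"):
        gd.frc_loss(gmm, projections, 3.0)     # pixel 2.5 > 1.5


def test_projection_gradient_finite_difference(helix_model, projections):
    gmm = model_to_gmm(helix_model, resolution=8.0)
    c0 = gmm.centers.copy()
    v = Var(c0.copy(), requires_grad=True)
    loss = gd.frc_loss((v, gmm.amplitudes, gmm.widths), projections, 8.0,
                       batch=[0, 1])
    loss.backward()
    rng = np.random.default_rng(1)
    for _ in range(4):
        i = int(rng.integers(0, len(c0)))
        j = int(rng.integers(0, 3))
        h = 1e-4
        cp, cm = c0.copy(), c0.copy()
        cp[i, j] += h
        cm[i, j] -= h
        lp = float(gd.frc_loss((Var(cp), gmm.amplitudes, gmm.widths),
                               projections, 8.0, batch=[0, 1]).data)
        lm = float(gd.frc_loss((Var(cm), gmm.amplitudes, gmm.widths),
                               projections, 8.0, batch=[0, 1]).data)
        num = (lp - lm) / (2 * h)
        assert v.grad[i, j] == pytest.approx(num, rel=1e-4, abs=1e-10)
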