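"""Continuous, differentiable reference distributions for torsion-angle scores.

Ramachandran plots and rotamer preferences are discrete histograms in the
validation literature; to use them inside gradient-based refinement they are
represented here as periodic Gaussian mixtures fitted to the (log-)histogram,
so the score and its gradient exist everywhere.  The package ships synthetic
reference histograms generated from canonical basin/peak definitions; an
importer can load user-provided histograms in the same gridded form.

Scores live on a max-1 scale.  Following validation conventions the
Ramachandran outlier level is 0.0005 and the allowed level 0.02; fitting is
done on ln(R + C) with C = e^-10 so that the tiny outlier level remains
resolvable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

from . import autodiff as ad
from .autodiff import Var, as_var

LOG_C = np.exp(-10.0)          # additive constant inside the log
RAMA_OUTLIER = 0.0005          # on the max-1 histogram scale
RAMA_ALLOWED = 0.02
ROTAMER_OUTLIER = 0.002

RAMA_CLASSES = ("General", "Gly", "trans-Pro", "cis-Pro", "pre-Pro", "Ile")

# --------------------------------------------------------------------------
# synthetic reference definitions
#
# Ramachandran basins per class: (phi, psi, sigma_phi, sigma_psi, weight).
# These reproduce the canonical alpha / beta / PII / left-handed-alpha
# structure of the real distributions; they are a self-contained synthetic
# stand-in, not the top8000 data.
RAMA_BASINS = {
    "General": [
        (-63, -43, 12, 14, 1.0),
        (-120, 135, 28, 22, 0.85),
        (-65, 145, 15, 20, 0.8),
        (62, 42, 10, 12, 0.2),
        (-100, 10, 20, 30, 0.1),
    ],
    "Gly": [
        (-63, -41, 14, 14, 1.0),
        (63, 41, 14, 14, 1.0),
        (-90, 150, 28, 24, 0.8),
        (90, -150, 28, 24, 0.8),
        (-170, 175, 20, 20, 0.3),
    ],
    "trans-Pro": [
        (-63, -35, 8, 13, 1.0),
        (-63, 150, 8, 20, 0.9),
        (-85, 70, 10, 15, 0.15),
    ],
    "cis-Pro": [
        (-75, -20, 9, 14, 1.0),
        (-85, 160, 9, 18, 0.7),
    ],
    "pre-Pro": [
        (-63, -43, 11, 13, 1.0),
        (-120, 130, 25, 22, 0.9),
        (-65, 140, 14, 18, 0.8),
        (55, 40, 8, 10, 0.05),
    ],
    "Ile": [
        (-63, -45, 10, 13, 1.0),
        (-115, 125, 20, 20, 0.9),
        (-65, 140, 12, 16, 0.6),
    ],
}

# Rotamer peaks per residue type: (chi angles ..., weight).  The terminal
# chi of PHE/TYR/ASP/GLU is two-fold symmetric (period 180).
ROTAMER_PEAKS = {
    "SER": [(64, 1.0), (-65, 0.9), (178, 0.7)],
    "CYS": [(-65, 1.0), (178, 0.6), (64, 0.5)],
    "THR": [(62, 1.0), (-60, 0.9), (178, 0.3)],
    "VAL": [(175, 1.0), (-60, 0.7), (64, 0.4)],
    "PRO": [(-27, 36, 1.0), (27, -34, 0.8)],
    "ILE": [(-65, 170, 1.0), (-60, -60, 0.5), (62, 170, 0.3), (-65, 100, 0.2)],
    "LEU": [(-65, 175, 1.0), (177, 65, 0.7), (-85, 65, 0.15), (62, 80, 0.05)],
    "ASP": [(-70, -15, 1.0), (-170, 15, 0.6), (62, 10, 0.4)],
    "ASN": [(-65, -40, 1.0), (-170, 30, 0.5), (62, 30, 0.4), (-65, 120, 0.2)],
    "HIS": [(-65, -70, 1.0), (177, 70, 0.7), (62, -85, 0.5), (-175, -100, 0.3)],
    "PHE": [(-65, -85, 1.0), (177, 75, 0.8), (62, 90, 0.3)],
    "TYR": [(-65, -85, 1.0), (177, 75, 0.8), (62, 90, 0.3)],
    "TRP": [(-65, 95, 1.0), (177, -105, 0.7), (62, -90, 0.4), (-177, 75, 0.3)],
    "MET": [(-65, 180, 75, 1.0), (-65, 180, -75, 0.8), (177, 180, 75, 0.6),
            (-65, -65, -70, 0.5), (177, 65, 75, 0.3)],
    "GLU": [(-67, 180, -10, 1.0), (177, 180, 0, 0.7), (-65, -65, -40, 0.6),
            (-80, 75, 0, 0.2)],
    "GLN": [(-67, 180, -25, 1.0), (177, 180, 0, 0.7), (-65, -65, -40, 0.6),
            (177, 65, 25, 0.3)],
    "LYS": [(-65, 180, 180, 180, 1.0), (177, 180, 180, 180, 0.7),
            (-65, -65, 180, 180, 0.4), (-65, 180, 180, 65, 0.3),
            (177, 180, 65, 180, 0.2)],
    "ARG": [(-65, 180, 180, 180, 1.0), (-65, 180, 180, -85, 0.7),
            (177, 180, 65, 85, 0.5), (-65, -65, 180, 180, 0.4),
            (177, 180, 180, 85, 0.3)],
}
ROTAMER_SIGMA = 12.0  # degrees, per chi, synthetic peak width
# residues whose last chi is symmetric under a 180-degree flip
CHI_PERIOD_180 = {"PHE", "TYR", "ASP", "GLU"}
ROTAMER_COMPONENTS = {1: 4, 2: 25, 3: 64, 4: 160}


def wrap_deg(x, period=360.0):
    """Wrap to [-period/2, period/2)."""
    return (x + period / 2.0) % period - period / 2.0


# --------------------------------------------------------------------------
# histograms


def make_histogram(basins, n_bins=72, periods=(360.0, 360.0)) -> np.ndarray:
    """Gridded synthetic density (max 1) from wrapped-Gaussian basins."""
    d = len(periods)
    axes = [np.linspace(-p / 2, p / 2, n_bins, endpoint=False) + p / (2 * n_bins)
            for p in periods]
    mesh = np.meshgrid(*axes, indexing="ij")
    out = np.zeros(mesh[0].shape)
    for basin in basins:
        *mu_sig, w = basin
        mu = mu_sig[:d]
        sig = mu_sig[d:]
        if len(sig) != d:
            sig = [ROTAMER_SIGMA] * d
        z = np.zeros_like(out)
        for k in range(d):
            z += (wrap_deg(mesh[k] - mu[k], periods[k]) / sig[k]) ** 2
        out += w * np.exp(-0.5 * z)
    return out / out.max()


@lru_cache(maxsize=8)
def rama_histogram(residue_class: str, n_bins: int = 72) -> np.ndarray:
    if residue_class not in RAMA_BASINS:
        raise ValueError(f"unknown Ramachandran class {residue_class!r}")
    return make_histogram(tuple(RAMA_BASINS[residue_class]), n_bins)


def rotamer_histogram(res_name: str, n_bins: int = 36) -> np.ndarray:
    peaks = ROTAMER_PEAKS[res_name]
    n_chi = len(peaks[0]) - 1
    periods = [360.0] * n_chi
    if res_name in CHI_PERIOD_180:
        periods[-1] = 180.0
    return make_histogram(tuple(peaks), n_bins, tuple(periods))


def histogram_lookup(hist: np.ndarray, angles, periods) -> np.ndarray:
    """Discrete oracle: nearest-bin histogram value for angle vectors."""
    angles = np.atleast_2d(np.asarray(angles, float))
    d = angles.shape[1]
    n = hist.shape[0]
    idx = []
    for k in range(d):
        p = periods[k]
        # bins centred as in make_histogram
        b = np.floor((wrap_deg(angles[:, k], p) + p / 2) / (p / n)).astype(int)
        idx.append(np.clip(b, 0, n - 1))
    return hist[tuple(idx)]


# --------------------------------------------------------------------------
# GMM surfaces


@dataclass
class TorsionSurface:
    """Periodic Gaussian mixture over a torsion-angle domain, in log space.

    Evaluation returns ln(score + C) where score is on the max-1 histogram
    scale. `outlier_threshold` / `allowed_threshold` are log-space levels.
    """

    centers: np.ndarray        # (K, d) degrees
    widths: np.ndarray         # (K, d) degrees
    amplitudes: np.ndarray     # (K,)
    offset: float              # constant added in log space
    periods: tuple
    outlier_threshold: float = float(np.log(RAMA_OUTLIER + LOG_C))
    allowed_threshold: float = float(np.log(RAMA_ALLOWED + LOG_C))
    fit_rmsd: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.amplitudes)

    def evaluate(self, angles) -> Var:
        """Log-score ln(R+C) at angle vectors (n, d); differentiable."""
        ang = as_var(angles)
        if ang.data.ndim == 1:
            ang = ang.reshape(1, -1)
        terms = []
        for k in range(ang.data.shape[1]):
            delta = _wrap_var(ang[:, k].reshape(-1, 1) - self.centers[None, :, k],
                              self.periods[k])
            terms.append((delta / self.widths[None, :, k]) ** 2)
        z = terms[0]
        for t in terms[1:]:
            z = z + t
        surf = (ad.exp(z * -0.5) * self.amplitudes[None, :]).sum(axis=1)
        return surf + self.offset

    def linear_score(self, angles) -> np.ndarray:
        """exp(log-score) - C, clipped at 0: score on the max-1 scale."""
        s = np.exp(self.evaluate(angles).data) - LOG_C
        return np.maximum(s, 0.0)

    def classify(self, angles):
        """Hard labels 'favored' / 'allowed' / 'outlier' from log thresholds."""
        v = self.evaluate(angles).data
        out = np.full(len(v), "favored", dtype="U8")
        out[v < self.allowed_threshold] = "allowed"
        out[v < self.outlier_threshold] = "outlier"
        return out


@dataclass
class RamaSurface(TorsionSurface):
    residue_class: str = "General"


@dataclass
class RotamerSurface(TorsionSurface):
    residue_type: str = ""
    n_chi: int = 1
    peaks: list = field(default_factory=list)   # chi-vector modes for rebuild


def _wrap_var(x: Var, period: float) -> Var:
    """Periodic wrap with pass-through gradient (shift by a constant)."""
    x = as_var(x)
    shift = np.floor(x.data / period + 0.5) * period
    return x - shift


# --------------------------------------------------------------------------
# fitting


def _polish(bin_coords, centers, widths, amps, y_eff, w_rows, offset, periods,
            max_nfev):
    """Joint nonlinear refinement of centers/widths/amplitudes.

    Least squares on the (row-weighted) residuals; for large component
    counts this is skipped by the caller (the linear amplitude solve alone
    is already accurate when components tile the domain densely).
    """
    from scipy.optimize import least_squares

    K, d = centers.shape
    sw = np.sqrt(w_rows)

    def unpack(p):
        c = p[: K * d].reshape(K, d)
        w = np.exp(p[K * d: 2 * K * d]).reshape(K, d)
        a = p[2 * K * d:]
        return c, w, a

    def resid(p):
        c, w, a = unpack(p)
        return sw * (_design_matrix(bin_coords, c, w, periods) @ a - y_eff)

    def jac(p):
        c, w, a = unpack(p)
        E = _design_matrix(bin_coords, c, w, periods)       # (m, K)
        m = len(bin_coords)
        cols = []
        delta = np.empty((m, K, d))
        for k, per in enumerate(periods):
            delta[:, :, k] = wrap_deg(bin_coords[:, k, None] - c[None, :, k],
                                      per)
        aE = E * a[None, :]
        for k in range(d):
            cols.append(aE * delta[:, :, k] / w[None, :, k] ** 2)
        for k in range(d):
            cols.append(aE * delta[:, :, k] ** 2 / w[None, :, k] ** 2)
        # column order must match unpack: centers dims interleaved per
        # component, then log-widths, then amplitudes
        Jc = np.empty((m, K * d))
        Jw = np.empty((m, K * d))
        for k in range(d):
            Jc[:, k::d] = cols[k]
            Jw[:, k::d] = cols[d + k]
        return sw[:, None] * np.concatenate([Jc, Jw, E], axis=1)

    p0 = np.concatenate([centers.ravel(), np.log(widths).ravel(), amps])
    sol = least_squares(resid, p0, jac=jac, max_nfev=max_nfev, method="trf")
    centers, widths, amps = unpack(sol.x)
    vals = _design_matrix(bin_coords, centers, widths, periods) @ amps + offset
    return centers, widths, amps, vals


def _design_matrix(bin_coords, centers, widths, periods):
    """(n_bins, K) matrix of wrapped Gaussian values."""
    z = np.zeros((len(bin_coords), len(centers)))
    for k, p in enumerate(periods):
        delta = wrap_deg(bin_coords[:, k, None] - centers[None, :, k], p)
        z += (delta / widths[None, :, k]) ** 2
    return np.exp(-0.5 * z)


def fit_reference_gmm(
    histogram: np.ndarray,
    n_components: int,
    log_domain: bool = True,
    boundary_penalty: bool = True,
    seed: int = 0,
    periods=None,
    outlier_level: float = RAMA_OUTLIER,
    max_iter: int = 200,
    surface_cls=TorsionSurface,
    **surface_kw,
) -> TorsionSurface:
    """Fit a periodic GMM surface to a gridded density (max normalised to 1).

    Centers are initialised by seeded k-means over density-weighted bins and
    widths from the bin spacing; amplitudes — the linear parameters of the
    mixture — are then solved by iteratively reweighted ridge least squares.
    With `boundary_penalty`, bins below the outlier level are iteratively
    re-targeted and up-weighted until every histogram-outlier bin also
    evaluates below the surface's outlier threshold.  `max_iter` > 0 adds a
    final Adam polish of all parameters on the mean squared error.
    """
    from sklearn.cluster import KMeans

    hist = np.asarray(histogram, float)
    if hist.min() < 0:
        raise ValueError("histogram must be nonnegative")
    hist = hist / hist.max()
    d = hist.ndim
    if periods is None:
        periods = (360.0,) * d
    n = hist.shape[0]
    axes = [np.linspace(-p / 2, p / 2, n, endpoint=False) + p / (2 * n)
            for p in periods]
    mesh = np.meshgrid(*axes, indexing="ij")
    bin_coords = np.stack([m.ravel() for m in mesh], axis=1)
    target_lin = hist.ravel()
    target = np.log(target_lin + LOG_C) if log_domain else target_lin
    offset = float(target.min()) if log_domain else 0.0

    rng = np.random.default_rng(seed)
    weight = target - target.min() + 1e-3 * (target.max() - target.min() + 1e-12)
    km = KMeans(n_clusters=min(n_components, len(bin_coords)), n_init=1,
                random_state=int(rng.integers(2**31 - 1)))
    km.fit(bin_coords, sample_weight=weight)
    centers = km.cluster_centers_.copy()
    if len(centers) < n_components:  # duplicate-pad to the requested count
        extra = centers[rng.integers(0, len(centers), n_components - len(centers))]
        centers = np.vstack([centers, extra + rng.normal(0, 1, extra.shape)])
    spacing = np.array([p / n for p in periods])
    widths = np.tile(spacing * 1.8, (n_components, 1))

    out_thresh = float(np.log(outlier_level + LOG_C)) if log_domain else outlier_level
    outlier_bins = target_lin < outlier_level
    margin = 0.05 * abs(out_thresh - offset) if log_domain else 0.1 * outlier_level

    A = _design_matrix(bin_coords, centers, widths, periods)
    y = target - offset
    w_rows = np.ones(len(y))
    y_eff = y.copy()
    amps = None
    for attempt in range(25):
        Aw = A * w_rows[:, None]
        AtA = A.T @ Aw + 1e-8 * np.eye(A.shape[1])
        amps = np.linalg.solve(AtA, Aw.T @ y_eff)
        vals = A @ amps + offset
        if not boundary_penalty:
            break
        viol = outlier_bins & (vals >= out_thresh - margin)
        if not np.any(viol):
            break
        # pull violating outlier bins further down and re-solve
        y_eff[viol] = np.minimum(y_eff[viol], (out_thresh - 3 * margin) - offset)
        w_rows[viol] *= 4.0
    else:
        warnings.warn("boundary penalty did not converge; best fit returned")

    if max_iter > 0 and n_components * (2 * d + 1) <= 400:
        centers, widths, amps, vals = _polish(
            bin_coords, centers, widths, amps, y_eff, w_rows, offset, periods,
            max_iter,
        )
        if boundary_penalty:
            # the polish optimises weighted MSE; re-tighten any bins that
            # drifted back above the outlier boundary
            A = _design_matrix(bin_coords, centers, widths, periods)
            for _ in range(15):
                viol = outlier_bins & (vals >= out_thresh - margin)
                if not np.any(viol):
                    break
                y_eff[viol] = np.minimum(
                    y_eff[viol], (out_thresh - 3 * margin) - offset
                )
                w_rows[viol] *= 4.0
                Aw = A * w_rows[:, None]
                amps = np.linalg.solve(
                    A.T @ Aw + 1e-8 * np.eye(A.shape[1]), Aw.T @ y_eff
                )
                vals = A @ amps + offset

    rmsd = float(np.sqrt(np.mean((vals - target) ** 2)))
    surf = surface_cls(
        centers=centers, widths=widths, amplitudes=amps,
        offset=offset, periods=tuple(periods),
        outlier_threshold=out_thresh if log_domain
        else float(np.log(outlier_level + LOG_C)),
        fit_rmsd=rmsd, **surface_kw,
    )
    if not log_domain:
        # store as linear surface: evaluation contract stays log-space, so
        # callers wanting the raw fit use `fit_rmsd` / raw params directly
        surf.meta["domain"] = "linear"
    return surf


def _peak_surface(res_name: str) -> RotamerSurface:
    """Rotamer surface built directly at the library peaks (log domain).

    Used for the 3- and 4-chi residues, where gridding the torsion space is
    wasteful: the reference density is itself a sparse Gaussian mixture, so
    the components are placed at the peaks (duplicated to the standard
    component count) and the log-space offset chosen to match ln(R + C).
    """
    peaks = ROTAMER_PEAKS[res_name]
    n_chi = len(peaks[0]) - 1
    periods = [360.0] * n_chi
    if res_name in CHI_PERIOD_180:
        periods[-1] = 180.0
    target_n = ROTAMER_COMPONENTS[n_chi]

    # Build on a sampled set of points: peak mixture in linear space,
    # then fit log-values with components pinned at peak locations.
    mu = np.array([p[:-1] for p in peaks], float)
    w = np.array([p[-1] for p in peaks], float)
    w = w / w.max()
    reps = int(np.ceil(target_n / len(peaks)))
    centers = np.tile(mu, (reps, 1))[:target_n]
    amps = np.repeat(w / reps, reps)[:target_n]
    widths = np.full((target_n, n_chi), ROTAMER_SIGMA)

    # log-domain correction: ln(R + C) ~ offset + GMM; calibrate amplitude so
    # the value at each peak matches ln(w_k + C) and far away matches ln(C)
    offset = float(np.log(LOG_C))
    # scale so summed duplicates reproduce ln(w+C)-ln(C) at each peak
    scale = (np.log(w + LOG_C) - offset)
    amps = np.repeat(scale / reps, reps)[:target_n]
    return RotamerSurface(
        centers=centers, widths=widths, amplitudes=amps, offset=offset,
        periods=tuple(periods),
        outlier_threshold=float(np.log(ROTAMER_OUTLIER + LOG_C)),
        allowed_threshold=float(np.log(0.02 + LOG_C)),
        residue_type=res_name, n_chi=n_chi,
        peaks=[tuple(p[:-1]) for p in peaks],
    )


@lru_cache(maxsize=2)
def default_rama_surfaces(n_bins: int = 64, n_components: int = 324):
    """Fitted surfaces for the six Ramachandran classes (cached)."""
    out = {}
    for i, cls in enumerate(RAMA_CLASSES):
        hist = rama_histogram(cls, n_bins)
        out[cls] = fit_reference_gmm(
            hist, n_components, log_domain=True, boundary_penalty=True,
            seed=1000 + i,
            surface_cls=RamaSurface, residue_class=cls,
        )
    return out


@lru_cache(maxsize=2)
def default_rotamer_surfaces():
    """Rotamer surfaces for all chi-bearing residue types (cached).

    1- and 2-chi residues are fitted from gridded synthetic histograms with
    the standard component counts (4 and 25); 3- and 4-chi residues use the
    peak-pinned construction.
    """
    out = {}
    for res, peaks in ROTAMER_PEAKS.items():
        n_chi = len(peaks[0]) - 1
        if n_chi <= 2:
            periods = [360.0] * n_chi
            if res in CHI_PERIOD_180:
                periods[-1] = 180.0
            # bin spacing sets the component widths; ~8-10 degree bins match
            # the log-domain footprint of a 12-degree rotamer peak
            hist = rotamer_histogram(res, n_bins=36 if n_chi == 2 else 45)
            surf = fit_reference_gmm(
                hist, ROTAMER_COMPONENTS[n_chi], log_domain=True,
                boundary_penalty=True, seed=sum(ord(c) for c in res),
                periods=tuple(periods), outlier_level=ROTAMER_OUTLIER,
                max_iter=200, surface_cls=RotamerSurface,
                residue_type=res, n_chi=n_chi,
                peaks=[tuple(p[:-1]) for p in peaks],
            )
            surf.allowed_threshold = float(np.log(0.02 + LOG_C))
            out[res] = surf
        else:
            out[res] = _peak_surface(res)
    return out


# --------------------------------------------------------------------------
# RNA suite library


@dataclass
class SuiteLibrary:
    names: list
    centers: np.ndarray          # (46, 7) degrees
    halfwidth: np.ndarray        # (7,) degrees
    assignment_threshold: float = 0.001

    def distances(self, vectors) -> np.ndarray:
        """Scaled 7D distances (n, 46) of angle vectors to every center."""
        v = np.atleast_2d(np.asarray(vectors, float))
        delta = wrap_deg(v[:, None, :] - self.centers[None, :, :])
        return np.sqrt(np.mean((delta / self.halfwidth) ** 2, axis=2))

    def score_from_distance(self, d) -> np.ndarray:
        d = np.minimum(np.asarray(d, float), 1.0)
        return ((np.cos(np.pi * d) + 1.0) / 2.0) ** 3

    def assign(self, vectors):
        """Nearest-center assignment: (indices, suiteness scores)."""
        dist = self.distances(vectors)
        idx = np.argmin(dist, axis=1)
        score = self.score_from_distance(dist[np.arange(len(idx)), idx])
        return idx, score


@lru_cache(maxsize=2)
def load_suite_library() -> SuiteLibrary:
    with resources.files("gmmrefine.data").joinpath(
        "rna_suites_synthetic.json"
    ).open() as fh:
        lib = json.load(fh)
    return SuiteLibrary(
        names=[s["name"] for s in lib["suites"]],
        centers=np.array([s["center"] for s in lib["suites"]], float),
        halfwidth=np.array(lib["halfwidth"], float),
        assignment_threshold=float(lib["assignment_threshold"]),
    )
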