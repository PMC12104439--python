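"""Synthetic fixtures: toy structures, simulated maps, perturbations, motion.

Everything here is generated from first principles so the full refinement
stack can be exercised without any external data: polypeptides are grown
from internal coordinates at recipe backbone dihedrals with sidechains at
library peak rotamers, RNA chains are grown with A-form-like backbone
torsions from rigid CCD-ideal nucleotides, maps are Gaussian-blurred atom
densities at a stated resolution, and two-state hinge motions provide
ground-truth recovery experiments.

All generation is seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemdata
from .model_io import (
    ATOMIC_NUMBER,
    AtomicModel,
    DensityMap,
    resolution_to_width,
)
from .surfaces import ROTAMER_PEAKS, wrap_deg

AA1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
RNA1 = {"A": "A", "C": "C", "G": "G", "U": "U"}

RECIPES = {
    "helix": (-60.0, -45.0),
    "strand": (-120.0, 135.0),
    "extended": (-120.0, 135.0),
}

# A-form-like junction torsions used to grow RNA chains.  Slightly displaced
# from the textbook A-form values so that, combined with the CCD ideal sugar
# conformation, the chain is free of steric clashes while its suite vector
# stays firmly assigned to the A-form cluster.
AFORM = {"alpha": -80.0, "beta": 174.0, "gamma": 54.0, "eps": -148.0,
         "zeta": -90.0}

BACKBONE_SET = {"N", "CA", "C", "O", "OXT"}


@dataclass
class FixtureSpec:
    sequence: str
    molecule: str = "protein"          # "protein" | "rna"
    recipe: str = "helix"              # or explicit list of (phi, psi)
    phi_psi: list = None               # overrides recipe when given
    chain_id: str = "A"
    seed: int = 0


# --------------------------------------------------------------------------
# numpy-only helpers


def _nerf1(c, b, a, L, theta, tau):
    from .autodiff import Var
    from .dgeom import nerf_place

    out = nerf_place(
        Var(np.asarray(c, float).reshape(1, 3)),
        Var(np.asarray(b, float).reshape(1, 3)),
        Var(np.asarray(a, float).reshape(1, 3)),
        np.array([L]), np.array([theta]), np.array([tau]),
    )
    return out.data[0]


def _dih_np(p0, p1, p2, p3):
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _superpose_3pt(src, dst):
    """Rigid transform (R, t) mapping the 3x3 `src` points onto `dst`."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs


def _rotate_about_axis(points, origin, axis, angle_deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    return (points - origin) @ R.T + origin


def _set_torsion(coords: dict, tpl, quad, target_deg):
    """Rotate the distal side of bond quad[1]-quad[2] to reach the target."""
    cur = _dih_np(*(coords[q] for q in quad))
    delta = wrap_deg(target_deg - cur)
    distal = tpl.distal_atoms(quad[1], quad[2])
    origin = coords[quad[1]]
    axis = coords[quad[2]] - coords[quad[1]]
    for nm in distal:
        if nm in coords:
            coords[nm] = _rotate_about_axis(
                coords[nm][None], origin, axis, delta
            )[0]


def _template_val(tpl, kind, *names):
    """Ideal value from a template bond/angle entry, name-order agnostic."""
    if kind == "bond":
        for a, b, mu, _ in tpl.bonds:
            if {a, b} == set(names):
                return mu
    else:
        for a, b, c, mu, _ in tpl.angles:
            if b == names[1] and {a, c} == {names[0], names[2]}:
                return mu
    raise KeyError(f"{kind} {names} not in template {tpl.residue_name}")


# --------------------------------------------------------------------------
# structure building


def make_toy_structure(spec: FixtureSpec) -> AtomicModel:
    """Build an idealised toy chain; the result scores zero outliers."""
    if not spec.sequence:
        raise ValueError("empty sequence")
    templates = chemdata.load_templates()
    if spec.molecule == "protein":
        return _build_protein(spec, templates)
    if spec.molecule == "rna":
        return _build_rna(spec, templates)
    raise ValueError(f"unknown molecule kind {spec.molecule!r}")


def _phi_psi_list(spec, n):
    if spec.phi_psi is not None:
        if len(spec.phi_psi) != n:
            raise ValueError("phi_psi list must match sequence length")
        return [tuple(map(float, t)) for t in spec.phi_psi]
    if spec.recipe not in RECIPES:
        raise ValueError(f"unknown recipe {spec.recipe!r}")
    return [RECIPES[spec.recipe]] * n

def _build_protein(spec, templates):
    try:
        seq = [AA1TO3[c] for c in spec.sequence.upper()]
    except KeyError as e:
        raise ValueError(f"unknown amino-acid letter {e.args[0]!r}") from e
    phipsi = _phi_psi_list(spec, len(seq))
    omega = 180.0
    residues = []       # list of dict name->xyz
    for i, name in enumerate(seq):
        tpl = templates[name]
        phi, psi = phipsi[i]
        L_nca = _template_val(tpl, "bond", "N", "CA")
        L_cac = _template_val(tpl, "bond", "CA", "C")
        ang_ncac = _template_val(tpl, "angle", "N", "CA", "C")
        if i == 0:
            N = np.zeros(3)
            CA = np.array([L_nca, 0.0, 0.0])
            th = np.radians(180.0 - ang_ncac)
            C = CA + L_cac * np.array([np.cos(th), np.sin(th), 0.0])
        else:
            prev = residues[-1]
            ppsi = phipsi[i - 1][1]
            N = _nerf1(prev["C"], prev["CA"], prev["N"], 1.329, 116.2, ppsi)
            CA = _nerf1(N, prev["C"], prev["CA"], L_nca, 121.7, omega)
            C = _nerf1(CA, N, prev["C"], L_cac, ang_ncac, phi)
        coords = {"N": N, "CA": CA, "C": C}
        # carbonyl O in the peptide plane (anti to the next N)
        L_co = _template_val(tpl, "bond", "C", "O")
        ang_caco = _template_val(tpl, "angle", "CA", "C", "O")
        coords["O"] = _nerf1(C, CA, N, L_co, ang_caco, psi - 180.0)
        # sidechain atoms by rigid CCD placement in the N/CA/C frame
        src = np.stack([tpl.ideal_coords[k] for k in ("N", "CA", "C")])
        dst = np.stack([N, CA, C])
        R, t = _superpose_3pt(src, dst)
        for nm in tpl.atom_names:
            if nm in BACKBONE_SET:
                continue
            coords[nm] = R @ tpl.ideal_coords[nm] + t
        if name in ROTAMER_PEAKS and name != "PRO":
            peak = ROTAMER_PEAKS[name][0]
            for k, quad in enumerate(tpl.chi_definitions):
                _set_torsion(coords, tpl, quad, peak[k])
        residues.append(coords)
    _declash_rotamers(seq, residues, templates)
    return _assemble(spec, seq, residues, templates)


def _declash_rotamers(seq, residues, templates):
    """Greedy pass: for each sidechain, keep the library peak with the least
    heavy-atom overlap against the rest of the chain (ties keep the
    higher-ranked rotamer)."""
    from .chemdata import load_vdw_table

    vdw = load_vdw_table()

    def radius(nm):
        return vdw.radius("".join(c for c in nm if c.isalpha())[:1])

    def overlap(i):
        tpl = templates[seq[i]]
        moving = [nm for nm in residues[i]
                  if nm not in BACKBONE_SET and nm != "CB"]
        total = 0.0
        for nm in moving:
            p = residues[i][nm]
            rp = radius(nm)
            for j, other in enumerate(residues):
                for om, q in other.items():
                    if j == i and om != "O":
                        continue  # own residue: only the carbonyl O is >3 bonds
                    d = np.linalg.norm(p - q)
                    t = rp + radius(om) - 0.4
                    if d < t:
                        total += t - d
        return total

    for i, name in enumerate(seq):
        if name == "PRO" or name not in ROTAMER_PEAKS:
            continue
        tpl = templates[name]
        if not tpl.chi_definitions:
            continue
        peaks = ROTAMER_PEAKS[name]
        best, best_ov = 0, overlap(i)
        for k in range(1, len(peaks)):
            if best_ov <= 0:
                break
            for c, quad in enumerate(tpl.chi_definitions):
                _set_torsion(residues[i], tpl, quad, peaks[k][c])
            ov = overlap(i)
            if ov < best_ov - 1e-9:
                best, best_ov = k, ov
        # restore the winning rotamer
        for c, quad in enumerate(tpl.chi_definitions):
            _set_torsion(residues[i], tpl, quad, peaks[best][c])


def _build_rna(spec, templates):
    try:
        seq = [RNA1[c] for c in spec.sequence.upper()]
    except KeyError as e:
        raise ValueError(f"unknown nucleotide letter {e.args[0]!r}") from e
    residues = []
    for i, name in enumerate(seq):
        tpl = templates[name]
        L_po5 = _template_val(tpl, "bond", "P", "O5'")
        L_o5c5 = _template_val(tpl, "bond", "O5'", "C5'")
        ang_po5c5 = _template_val(tpl, "angle", "P", "O5'", "C5'")
        if i == 0:
            P = np.zeros(3)
            O5 = np.array([L_po5, 0.0, 0.0])
            th = np.radians(180.0 - ang_po5c5)
            C5 = O5 + L_o5c5 * np.array([np.cos(th), np.sin(th), 0.0])
        else:
            prev = residues[-1]
            P = _nerf1(prev["O3'"], prev["C3'"], prev["C4'"],
                       1.607, 119.7, AFORM["eps"])
            O5 = _nerf1(P, prev["O3'"], prev["C3'"],
                        L_po5, 104.0, AFORM["zeta"])
            C5 = _nerf1(O5, P, prev["O3'"],
                        L_o5c5, ang_po5c5, AFORM["alpha"])
        src = np.stack([tpl.ideal_coords[k] for k in ("P", "O5'", "C5'")])
        dst = np.stack([P, O5, C5])
        R, t = _superpose_3pt(src, dst)
        coords = {}
        for nm in tpl.atom_names:
            if nm == "OP3":
                continue
            coords[nm] = R @ tpl.ideal_coords[nm] + t
        coords["P"], coords["O5'"], coords["C5'"] = P, O5, C5
        # re-place the free phosphate oxygens around the P-O5' axis so they
        # straddle the incoming O3' (which sits at azimuth alpha)
        for nm, azi in (("OP1", 120.3), ("OP2", -120.3)):
            coords[nm] = _nerf1(
                P, O5, C5,
                _template_val(tpl, "bond", "P", nm),
                _template_val(tpl, "angle", nm, "P", "O5'"),
                AFORM["alpha"] + azi,
            )
        # pull the internal beta/gamma torsions to A-form values
        _set_torsion(coords, tpl, ("P", "O5'", "C5'", "C4'"), AFORM["beta"])
        _set_torsion(coords, tpl, ("O5'", "C5'", "C4'", "C3'"), AFORM["gamma"])
        residues.append(coords)
    return _assemble(spec, seq, residues, templates)


def _assemble(spec, seq, residues, templates):
    rows = []
    for i, (name, coords) in enumerate(zip(seq, residues)):
        tpl = templates[name]
        for nm in tpl.atom_names:
            if nm not in coords:
                continue
            elem = "".join(c for c in nm if c.isalpha())[:1]
            # first alphabetic char is the element for C/N/O/S/P H-free names
            rows.append((elem, nm, name, i + 1, coords[nm]))
    element, atom_name, res_name, res_seq, xyz = zip(*rows)
    n = len(rows)
    model = AtomicModel(
        element=np.array(element), atom_name=np.array(atom_name),
        res_name=np.array(res_name), res_seq=np.array(res_seq, int),
        icode=np.array([""] * n), chain_id=np.array([spec.chain_id] * n),
        coords=np.array(xyz, float), occupancy=np.ones(n),
    )
    model.chain_types[spec.chain_id] = spec.molecule
    return model


# --------------------------------------------------------------------------
# maps


def simulate_map(
    model: AtomicModel,
    resolution: float,
    voxel: float,
    box: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    origin: np.ndarray | None = None,
) -> DensityMap:
    """Gaussian-blurred atom density at the stated resolution.

    Each heavy atom contributes an isotropic Gaussian with amplitude equal
    to its atomic number; optional white noise is expressed as a fraction of
    the noise-free map's standard deviation.
    """
    w = resolution_to_width(resolution)
    if origin is None:
        center = model.coords.mean(axis=0)
        origin = center - 0.5 * box * voxel
    origin = np.asarray(origin, float)
    rel = model.coords - origin
    if np.any(rel < 0) or np.any(rel > box * voxel):
        raise ValueError("model does not fit inside the requested box")
    axes = (np.arange(box) + 0.5) * voxel
    amps = np.array([ATOMIC_NUMBER.get(e.upper(), 6) for e in model.element], float)
    grid = np.zeros((box, box, box))
    for s in range(0, model.n_atoms, 64):
        sl = slice(s, s + 64)
        ex = np.exp(-0.5 * ((axes[None, :] - rel[sl, 0:1]) / w) ** 2)
        ey = np.exp(-0.5 * ((axes[None, :] - rel[sl, 1:2]) / w) ** 2)
        ez = np.exp(-0.5 * ((axes[None, :] - rel[sl, 2:3]) / w) ** 2)
        grid += np.einsum("nz,ny,nx->zyx", ez * amps[sl, None], ey, ex)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        grid = grid + rng.normal(0.0, noise_sigma * grid.std(), grid.shape)
    return DensityMap(grid=grid, voxel=float(voxel), origin=origin)


# --------------------------------------------------------------------------
# perturbations


@dataclass
class HingeSpec:
    """Torsion-hinge rotation: the carbonyl O of `start_res` (1-based) and
    all residues after it rotate rigidly about that residue's CA-C bond.
    Only the residue's psi changes, so all internal geometry stays exactly
    ideal; positive angles swing the moving domain away from the carbonyl
    contact so intermediate states remain clash-free."""

    start_res: int
    angle_deg: float


def perturb(
    model: AtomicModel,
    hinge: HingeSpec | None = None,
    jitter_sigma: float = 0.0,
    seed: int = 0,
):
    """Apply a hinge rotation and/or coordinate jitter; returns (model, rmsd)."""
    coords = model.coords.copy()
    if hinge is not None:
        res_ids = model.res_seq
        if not np.any(res_ids == hinge.start_res):
            raise ValueError(f"hinge residue {hinge.start_res} not in model")
        sel_res = res_ids == hinge.start_res
        ca_i = np.flatnonzero(sel_res & (model.atom_name == "CA"))[0]
        c_i = np.flatnonzero(sel_res & (model.atom_name == "C"))[0]
        move = (res_ids > hinge.start_res) | (sel_res & (model.atom_name == "O"))
        coords[move] = _rotate_about_axis(
            coords[move], coords[ca_i], coords[c_i] - coords[ca_i],
            hinge.angle_deg,
        )
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
    rmsd = float(np.sqrt(np.mean(np.sum((coords - model.coords) ** 2, axis=1))))
    return model.with_coords(coords), rmsd


def make_motion_series(
    model: AtomicModel,
    hinge: HingeSpec,
    n_states: int,
    resolution: float,
    voxel: float,
    box: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """Uniform hinge interpolation: maps + latents + ground-truth models.

    States interpolate the hinge angle uniformly from 0 to `angle_deg`;
    latent coordinates are the normalised state index in [0, 1].  All maps
    share one origin/box so they live in a common frame.
    """
    from .refine_series import ConformationSeries

    if n_states < 2:
        raise ValueError("need at least 2 states")
    angles = np.linspace(0.0, hinge.angle_deg, n_states)
    truths = []
    for k, a in enumerate(angles):
        m, _ = perturb(model, HingeSpec(hinge.start_res, a))
        truths.append(m)
    allxyz = np.vstack([m.coords for m in truths])
    origin = allxyz.mean(axis=0) - 0.5 * box * voxel
    maps = [
        simulate_map(m, resolution, voxel, box, noise_sigma=noise_sigma,
                     seed=seed + k, origin=origin)
        for k, m in enumerate(truths)
    ]
    latents = np.linspace(0.0, 1.0, n_states).reshape(-1, 1)
    series = ConformationSeries(latent_coords=latents, maps=maps)
    return series, truths
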