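"""Atomic model and density map I/O, GMM conversion, hydrogen placement.

Models are read with gemmi (PDB and mmCIF), stripped of hydrogens, waters
and alternate conformers, and held in a flat array-of-atoms container that
maps one-to-one onto the Gaussian mixture used during refinement.  Maps are
MRC/CCP4 grids with the origin honoured in Å; internally grids are indexed
(z, y, x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

# residue-name sets used to infer chain types
PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RNA_RESIDUES = {"A", "C", "G", "U"}
WATER_RESIDUES = {"HOH", "WAT", "DOD"}

# amplitudes default to atomic number (electron count)
ATOMIC_NUMBER = {
    "H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "SE": 34, "F": 9,
    "CL": 17, "BR": 35, "I": 53, "MG": 12, "ZN": 30, "FE": 26, "CA": 20,
    "NA": 11, "K": 19, "MN": 25,
}


@dataclass
class AtomicModel:
    """Ordered heavy-atom records of a protein/RNA model.

    Atoms are grouped contiguously by residue; hydrogens are never stored
    here (they are placed deterministically from heavy atoms when needed).
    """

    element: np.ndarray       # (N,) str
    atom_name: np.ndarray     # (N,) str
    res_name: np.ndarray      # (N,) str
    res_seq: np.ndarray       # (N,) int
    icode: np.ndarray         # (N,) str
    chain_id: np.ndarray      # (N,) str
    coords: np.ndarray        # (N,3) float Å
    occupancy: np.ndarray     # (N,) float
    chain_types: dict = field(default_factory=dict)  # chain id -> "protein"|"rna"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")
        if self.coords.shape != (len(self.atom_name), 3):
            raise ValueError("coordinate array must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def residue_starts(self) -> np.ndarray:
        """Indices where a new residue begins (atom order groups residues)."""
        key = np.array(
            [f"{c}|{s}|{i}" for c, s, i in zip(self.chain_id, self.res_seq, self.icode)]
        )
        starts = np.flatnonzero(np.r_[True, key[1:] != key[:-1]])
        return starts

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        """Same atoms and metadata, new coordinates (atom<->Gaussian bijection)."""
        out = AtomicModel(
            self.element, self.atom_name, self.res_name, self.res_seq,
            self.icode, self.chain_id, np.asarray(coords, float).copy(),
            self.occupancy, dict(self.chain_types),
        )
        return out

    def copy(self) -> "AtomicModel":
        return self.with_coords(self.coords)


@dataclass
class GaussianMixture:
    """Per-atom isotropic 3D Gaussians: five parameters each."""

    centers: np.ndarray      # (N,3) Å
    amplitudes: np.ndarray   # (N,) > 0
    widths: np.ndarray       # (N,) Å standard deviations, > 0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        self.widths = np.broadcast_to(
            np.asarray(self.widths, float), self.amplitudes.shape
        ).copy()
        if np.any(self.amplitudes <= 0) or np.any(self.widths <= 0):
            raise ValueError("amplitudes and widths must be positive")


@dataclass
class DensityMap:
    """Cubic voxel grid with physical voxel size and origin in Å.

    `grid` is indexed (z, y, x); `origin` is the Å position of voxel
    (0, 0, 0).
    """

    grid: np.ndarray
    voxel: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("density map must be a cubic box")
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def size(self) -> int:
        return self.grid.shape[0]


# ---------------------------------------------------------------------------
# model reading / writing


def _infer_chain_type(res_names) -> str:
    names = set(res_names)
    if names & RNA_RESIDUES:
        return "rna"
    return "protein"


def read_model(path) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Hydrogens and waters are stripped; for alternate locations only the
    highest-occupancy conformer is kept (ties broken by altloc letter).
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"cannot parse structure file {path}: {e}") from e
    st.setup_entities()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name in WATER_RESIDUES:
                continue
            # pick best altloc per atom name
            best = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ or (
                    atom.occ == prev.occ and (atom.altloc or "~") < (prev.altloc or "~")
                ):
                    best[atom.name] = atom
            for atom in best.values():
                rows.append(
                    (
                        atom.element.name.upper(), atom.name, res.name,
                        res.seqid.num, res.seqid.icode.strip(), chain.name,
                        (atom.pos.x, atom.pos.y, atom.pos.z), atom.occ,
                    )
                )
    if not rows:
        raise ValueError(f"no heavy atoms found in {path}")
    element, atom_name, res_name, res_seq, icode, chain_id, xyz, occ = zip(*rows)
    m = AtomicModel(
        np.array(element), np.array(atom_name), np.array(res_name),
        np.array(res_seq, dtype=int), np.array(icode), np.array(chain_id),
        np.array(xyz, dtype=float), np.array(occ, dtype=float),
    )
    for cid in dict.fromkeys(m.chain_id):
        m.chain_types[cid] = _infer_chain_type(m.res_name[m.chain_id == cid])
    return m


def _to_gemmi(models, name="gmmrefine") -> gemmi.Structure:
    ref = models[0]
    st = gemmi.Structure()
    st.name = name
    for k, m in enumerate(models):
        if m.n_atoms != ref.n_atoms or not np.array_equal(m.atom_name, ref.atom_name):
            raise ValueError("models in a series must share atom ordering")
        gm = gemmi.Model(k + 1)
        starts = list(m.residue_starts()) + [m.n_atoms]
        cur_chain = None
        for s, e in zip(starts[:-1], starts[1:]):
            cid = m.chain_id[s]
            if cur_chain is None or cur_chain.name != cid:
                cur_chain = gemmi.Chain(cid)
                gm.add_chain(cur_chain)
                cur_chain = gm[-1]
            res = gemmi.Residue()
            res.name = str(m.res_name[s])
            res.seqid = gemmi.SeqId(int(m.res_seq[s]), m.icode[s] or " ")
            for i in range(s, e):
                at = gemmi.Atom()
                at.name = str(m.atom_name[i])
                at.element = gemmi.Element(str(m.element[i]))
                at.pos = gemmi.Position(*m.coords[i])
                at.occ = float(m.occupancy[i])
                res.add_atom(at)
            cur_chain.add_residue(res)
        st.add_model(gm)
    return st


def write_model(model: AtomicModel, path, fmt=None):
    """Write a single model as PDB or mmCIF (by extension or `fmt`)."""
    write_series([model], path, fmt=fmt)


def write_series(models, path, fmt=None):
    """Write one model or an ordered series (multi-model PDB) to disk."""
    path = str(path)
    if fmt is None:
        fmt = "cif" if path.endswith((".cif", ".mmcif")) else "pdb"
    st = _to_gemmi(list(models))
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)


# ---------------------------------------------------------------------------
# GMM conversion


def resolution_to_width(resolution: float) -> float:
    """Gaussian sigma (Å) for a target resolution.

    Uses sigma = resolution / (pi * sqrt(2)), which places the Gaussian's
    Fourier amplitude at ~exp(-1) at the target spatial frequency.  The FRC
    loss is ring-normalised, so this choice only sets a radial envelope.
    """
    return float(resolution) / (np.pi * np.sqrt(2.0))


def model_to_gmm(
    model: AtomicModel,
    width_policy: float | str = "resolution",
    amplitude_policy: str = "atomic_number",
    resolution: float = 3.0,
) -> GaussianMixture:
    """One Gaussian per heavy atom: centers are the atom coordinates.

    Default policies: amplitude proportional to atomic number, one shared
    width derived from the target resolution.
    """
    n = model.n_atoms
    if amplitude_policy == "atomic_number":
        amps = np.array([ATOMIC_NUMBER.get(e.upper(), 6) for e in model.element], float)
    elif amplitude_policy == "uniform":
        amps = np.ones(n)
    else:
        raise ValueError(f"unknown amplitude policy {amplitude_policy!r}")
    if width_policy == "resolution":
        w = resolution_to_width(resolution)
    else:
        w = float(width_policy)
    return GaussianMixture(model.coords.copy(), amps, np.full(n, w))


# ---------------------------------------------------------------------------
# hydrogens


def add_hydrogens(model: AtomicModel, templates) -> "HydrogenSet":
    """Deterministic zero-torsion hydrogen placement (overlay; model unchanged).

    Positions are a pure function of the heavy-atom coordinates: each H is
    reconstructed from internal coordinates stored in the residue templates,
    with every rotatable H torsion (methyl, hydroxyl, thiol, ammonium)
    pinned at zero degrees.
    """
    from . import chemdata

    spec = chemdata.build_h_spec(model, templates)
    coords = place_hydrogens(model.coords, spec)
    return HydrogenSet(spec=spec, coords=coords)


@dataclass
class HydrogenSet:
    spec: object              # chemdata.HSpec
    coords: np.ndarray        # (M,3)

    @property
    def n_atoms(self):
        return len(self.coords)


def place_hydrogens(heavy_coords, spec):
    """Recompute H coordinates (ndarray in, ndarray out)."""
    from . import dgeom
    from .autodiff import Var

    out = dgeom.nerf_place(
        Var(heavy_coords)[spec.parent], Var(heavy_coords)[spec.ref1],
        Var(heavy_coords)[spec.ref2], spec.length, spec.theta, spec.tau,
    )
    return out.data


# ---------------------------------------------------------------------------
# maps


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map, normalising axis order to internal (z, y, x)."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)  # normalise axis order
    grid = np.array(m.grid, copy=True).transpose(2, 1, 0)  # gemmi is (x,y,z)
    cell = m.grid.unit_cell
    nx, ny, nz = m.grid.shape
    vx = (cell.a / nx, cell.b / ny, cell.c / nz)
    if abs(vx[0] - vx[1]) > 1e-4 or abs(vx[0] - vx[2]) > 1e-4:
        raise ValueError("anisotropic voxels are not supported")
    if len({nx, ny, nz}) != 1:
        raise ValueError("non-cubic maps are not supported")
    # origin: prefer explicit ORIGIN header, else voxel start offsets
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    if not np.any(origin):
        start = [m.header_i32(5), m.header_i32(6), m.header_i32(7)]
        origin = np.array(start, float) * vx[0]
    if np.any(np.isnan(grid)):
        grid = np.nan_to_num(grid)
    return DensityMap(grid=grid, voxel=float(vx[0]), origin=origin)


def write_map(dmap: DensityMap, path):
    """Write a DensityMap as an MRC/CCP4 2014 file."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid.transpose(2, 1, 0), dtype=np.float32))
    n = dmap.size
    a = n * dmap.voxel
    m.grid.unit_cell = gemmi.UnitCell(a, a, a, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for k, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(k, float(v))
    m.write_ccp4_map(str(path))
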