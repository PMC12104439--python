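"""Chemical reference tables and per-model topology compilation.

Residue templates (ideal bond lengths/angles, planar groups, chi torsion
quads, hydrogen internal coordinates) are compiled at load time from the
Chemical Component Dictionary ideal coordinates bundled with biotite,
combined with restraint-class standard deviations, van der Waals radii and
chi definitions shipped as JSON files in ``gmmrefine/data``.

``compile_topology`` turns a model plus the templates into flat integer
index tables (bond pairs, angle triples, dihedral quads, planarity quads,
clash-neighbour candidate pairs) so every geometry score reduces to
vectorised gathers during refinement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .model_io import AtomicModel, PROTEIN_RESIDUES, RNA_RESIDUES

__all__ = [
    "ResidueTemplate",
    "VdwTable",
    "TopologyTables",
    "HSpec",
    "load_templates",
    "load_vdw_table",
    "compile_topology",
    "build_h_spec",
    "rebuild_neighbor_pairs",
    "UnsupportedResidueError",
]

CHAIN_BREAK_DISTANCE = 2.5  # Å, C-N (protein) / O3'-P (RNA)
OPTIONAL_ATOMS = {"OXT", "OP3"}

# residues sharing the isoleucine/valine Ramachandran class
ILE_CLASS = {"ILE", "VAL"}


class UnsupportedResidueError(ValueError):
    pass


def _data(name: str) -> dict:
    with resources.files("gmmrefine.data").joinpath(name).open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# numpy-only internal geometry (used at template-build time)


def _dih(p0, p1, p2, p3):
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def _ang(a, b, c):
    u, v = a - b, c - b
    return np.degrees(
        np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))
    )


# ---------------------------------------------------------------------------
# templates


@dataclass
class ResidueTemplate:
    residue_name: str
    atom_names: list                     # heavy atoms, CCD order
    bonds: list                          # (a, b, mu_Å, sigma_Å)
    angles: list                         # (a, b, c, mu_deg, sigma_deg)
    planar_groups: list                  # ([a,b,c,d], class) class: "other_planar"
    chi_definitions: list                # list of 4-atom-name lists
    h_placements: list                   # dicts, see _build_template
    ideal_coords: dict = None            # heavy atom name -> CCD ideal xyz
    is_rna: bool = False

    def bond_adjacency(self) -> dict:
        adj = {n: set() for n in self.atom_names}
        for a, b, _, _ in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def distal_atoms(self, axis_b: str, axis_c: str) -> set:
        """Atom names on the `axis_c` side of the rotatable bond b-c."""
        adj = self.bond_adjacency()
        seen = {axis_b, axis_c}
        stack = [axis_c]
        out = set()
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    out.add(v)
                    stack.append(v)
        return out


@dataclass
class VdwTable:
    radii: dict

    def radius(self, element: str, polar_h: bool = False) -> float:
        e = element.upper()
        if e == "H" and polar_h:
            return self.radii["H_POLAR"]
        return self.radii.get(e, self.radii["default"])


@lru_cache(maxsize=4)
def load_vdw_table(dialect: str = "default") -> VdwTable:
    if dialect != "default":
        raise ValueError(f"unknown VdW table dialect {dialect!r}")
    return VdwTable(_data("vdw_radii.json")["radii"])


def _bond_sigma(tbl, e1, e2):
    key = "-".join(sorted((e1.upper(), e2.upper())))
    return tbl["bond_sigma"].get(key, tbl["bond_sigma"]["default"])


def _build_template(name: str, sig_tbl: dict, chi_tbl: dict) -> ResidueTemplate:
    import biotite.structure.info as info
    from biotite.structure import BondType

    res = info.residue(name)
    if res is None:
        raise UnsupportedResidueError(f"no CCD entry for residue {name!r}")
    names = list(res.atom_name)
    elems = {n: e.upper() for n, e in zip(res.atom_name, res.element)}
    coord = {n: res.coord[i] for i, n in enumerate(names)}
    bond_dict = info.bonds_in_residue(name)
    is_rna = name in RNA_RESIDUES

    heavy = [n for n in names if elems[n] != "H"]
    adj = {n: [] for n in names}
    btype = {}
    for (a, b), t in bond_dict.items():
        adj[a].append(b)
        adj[b].append(a)
        btype[frozenset((a, b))] = t
    order = {n: i for i, n in enumerate(names)}
    for n in adj:
        adj[n].sort(key=order.__getitem__)

    def heavy_nb(n):
        return [m for m in adj[n] if elems[m] != "H"]

    multiple = {BondType.DOUBLE, BondType.TRIPLE, BondType.AROMATIC,
                BondType.AROMATIC_SINGLE, BondType.AROMATIC_DOUBLE,
                BondType.AROMATIC_TRIPLE}

    def is_multiple(a, b):
        return btype.get(frozenset((a, b))) in multiple

    bonds = []
    for (a, b) in bond_dict:
        if elems[a] == "H" or elems[b] == "H":
            continue
        mu = float(np.linalg.norm(coord[a] - coord[b]))
        bonds.append((a, b, mu, _bond_sigma(sig_tbl, elems[a], elems[b])))

    angles = []
    sig_default = sig_tbl["angle_sigma"]["default"]
    for b in heavy:
        nbs = heavy_nb(b)
        for i in range(len(nbs)):
            for j in range(i + 1, len(nbs)):
                a, c = nbs[i], nbs[j]
                mu = float(_ang(coord[a], coord[b], coord[c]))
                key = f"{a}-{b}-{c}"
                sig = sig_tbl["angle_overrides"].get(key, sig_default)
                angles.append((a, b, c, mu, sig))

    # planar groups: sp2 impropers and multiple-bond path torsions, detected
    # from the ideal coordinates (coplanar within 2 degrees)
    planar = []
    seen = set()

    def add_planar(quad):
        key = tuple(quad)
        if key in seen or tuple(reversed(quad)) in seen:
            return
        val = _dih(*(coord[q] for q in quad))
        dev = min(abs(val), abs(abs(val) - 180.0))
        if dev < 2.0:
            seen.add(key)
            planar.append((list(quad), "other_planar"))

    for x in heavy:
        nbs = heavy_nb(x)
        if len(nbs) >= 3 and any(is_multiple(x, n) for n in adj[x]):
            add_planar((nbs[0], nbs[1], x, nbs[2]))
    for b in heavy:
        for c in heavy_nb(b):
            if order[b] >= order[c] or not is_multiple(b, c):
                continue
            for a in heavy_nb(b):
                if a == c:
                    continue
                for d in heavy_nb(c):
                    if d == b or d == a:
                        continue
                    add_planar((a, b, c, d))

    # hydrogens: internal coordinates in the (parent, ref1, ref2) frame
    h_specs = []
    for h in names:
        if elems[h] != "H":
            continue
        parents = heavy_nb(h)
        if not parents:
            continue
        p = parents[0]
        if not is_rna and p in ("N", "OXT"):
            continue  # backbone amide / terminal H handled per-model
        if is_rna and p in ("O5'", "OP3", "OP1", "OP2"):
            continue  # 5'-end hydroxyl/phosphate H not modelled
        when = "3prime" if (is_rna and p == "O3'") else "always"
        r1cands = [m for m in heavy_nb(p) if m != h]
        if not r1cands:
            continue
        r1 = r1cands[0]
        r2cands = [m for m in heavy_nb(r1) if m != p]
        if not r2cands:
            # fall back to a second substituent of the parent (e.g. free
            # amino-acid N has no second-shell heavy atom through CA)
            r2cands = [m for m in r1cands[1:]]
        if not r2cands:
            continue
        r2 = r2cands[0]
        # electron-cloud H bond lengths (validation convention), not nuclear
        ecloud = {"C": 0.97, "N": 0.86, "O": 0.84, "S": 1.20}
        h_specs.append(
            {
                "name": h, "parent": p, "ref1": r1, "ref2": r2,
                "length": ecloud.get(elems[p],
                                     float(np.linalg.norm(coord[h] - coord[p]))),
                "theta": float(_ang(coord[h], coord[p], coord[r1])),
                "tau": float(_dih(coord[h], coord[p], coord[r1], coord[r2])),
                "when": when,
            }
        )

    # Rotatable H groups (methyl, hydroxyl, thiol, ammonium) are pinned at
    # the dictionary's staggered default torsion: the torsional degree of
    # freedom is deliberately frozen rather than optimised, mirroring how
    # the validation server re-places hydrogens at a fixed default rotation.
    # The CCD ideal conformation provides that canonical offset, so no
    # adjustment is needed here; `tau` stays a constant of the template.

    return ResidueTemplate(
        residue_name=name,
        atom_names=heavy,
        bonds=bonds,
        angles=angles,
        planar_groups=planar,
        chi_definitions=[list(q) for q in chi_tbl.get(name, [])],
        h_placements=h_specs,
        ideal_coords={n: np.asarray(coord[n], float) for n in heavy},
        is_rna=is_rna,
    )


@lru_cache(maxsize=4)
def load_templates(dialect: str = "default") -> dict:
    """Templates for the 20 amino acids and 4 RNA nucleotides."""
    if dialect != "default":
        raise ValueError(f"unknown template dialect {dialect!r}")
    sig_tbl = _data("restraint_sigmas.json")
    chi_tbl = _data("chi_definitions.json")["chi"]
    out = {}
    for name in sorted(PROTEIN_RESIDUES) + sorted(RNA_RESIDUES):
        out[name] = _build_template(name, sig_tbl, chi_tbl)
    return out


# ---------------------------------------------------------------------------
# per-model topology


@dataclass
class HSpec:
    """Internal-coordinate description of every placed hydrogen."""

    parent: np.ndarray   # (M,) heavy-atom index the H is bonded to
    ref1: np.ndarray
    ref2: np.ndarray
    length: np.ndarray
    theta: np.ndarray    # degrees
    tau: np.ndarray      # degrees
    name: np.ndarray     # (M,) str
    polar: np.ndarray    # (M,) bool — bonded to N/O (H-bond donor H)
    residue: np.ndarray  # (M,) residue index


@dataclass
class Residue:
    chain: str
    seq: int
    icode: str
    name: str
    atoms: dict          # atom name -> global heavy index
    chain_type: str
    index: int = 0
    prev: int = -1       # previous bonded residue index or -1
    next: int = -1


@dataclass
class TopologyTables:
    residues: list
    n_heavy: int
    # bonded terms
    bond_index: np.ndarray       # (B,2)
    bond_mu: np.ndarray
    bond_sigma: np.ndarray
    angle_index: np.ndarray      # (A,3)
    angle_mu: np.ndarray
    angle_sigma: np.ndarray
    planar_index: np.ndarray     # (P,4)
    planar_thresh: np.ndarray    # degrees
    planar_is_omega: np.ndarray  # bool
    # backbone torsions
    phi_quads: np.ndarray        # (R,4) for residues with both neighbours
    psi_quads: np.ndarray
    omega_quads: np.ndarray      # (R,4) or row of -1 when prev missing
    rama_residue: np.ndarray     # (R,) residue indices
    rama_class_static: np.ndarray  # (R,) str: General/Gly/Ile/pre-Pro/Pro
    # sidechain torsions
    chi_quads: np.ndarray        # (Q,4)
    chi_res: np.ndarray          # (Q,) residue index
    chi_k: np.ndarray            # (Q,) chi index 0..3
    # rna
    rna_quads: np.ndarray        # (S,7,4)
    rna_res: np.ndarray          # (S,) residue index of the suite's 2nd base
    # hydrogens / clash
    hspec: HSpec
    radii: np.ndarray            # (n_heavy+M,) vdw radius per combined atom
    elements: np.ndarray         # (n_heavy+M,) str
    neighbor_index: list         # per combined atom: ndarray of candidates
    pair_index: np.ndarray       # (K,2) unique candidate pairs, combined idx
    pair_thresh: np.ndarray      # (K,) clash threshold distance
    neighbor_k: int = 128
    # covalent-graph exclusion (graph distance <= 3), kept for refreshes
    excluded: list = None
    chain_breaks: list = field(default_factory=list)

    @property
    def n_combined(self):
        return self.n_heavy + len(self.hspec.parent)


def _segment_residues(model: AtomicModel, templates) -> list:
    starts = list(model.residue_starts()) + [model.n_atoms]
    residues = []
    for ridx, (s, e) in enumerate(zip(starts[:-1], starts[1:])):
        name = str(model.res_name[s])
        if name not in templates:
            raise UnsupportedResidueError(
                f"residue {name} {model.chain_id[s]}{model.res_seq[s]} has no template"
            )
        atoms = {}
        for i in range(s, e):
            atoms[str(model.atom_name[i])] = i
        residues.append(
            Residue(
                chain=str(model.chain_id[s]), seq=int(model.res_seq[s]),
                icode=str(model.icode[s]), name=name, atoms=atoms,
                chain_type=model.chain_types.get(str(model.chain_id[s]), "protein"),
                index=ridx,
            )
        )
    return residues


def _link_residues(model, residues, log_breaks):
    """Mark consecutive same-chain residues as bonded unless broken."""
    for k in range(len(residues) - 1):
        a, b = residues[k], residues[k + 1]
        if a.chain != b.chain:
            continue
        if a.chain_type == "rna":
            i, j = a.atoms.get("O3'"), b.atoms.get("P")
        else:
            i, j = a.atoms.get("C"), b.atoms.get("N")
        if i is None or j is None:
            log_breaks.append((a.index, b.index, "missing link atom"))
            continue
        d = np.linalg.norm(model.coords[i] - model.coords[j])
        if d > CHAIN_BREAK_DISTANCE:
            log_breaks.append((a.index, b.index, f"link distance {d:.2f} Å"))
            continue
        a.next, b.prev = b.index, a.index


def build_h_spec(model: AtomicModel, templates) -> HSpec:
    residues = _segment_residues(model, templates)
    _link_residues(model, residues, [])
    return _h_spec_from_residues(model, residues, templates)


def _h_spec_from_residues(model, residues, templates) -> HSpec:
    rows = []  # (parent, ref1, ref2, L, theta, tau, name, polar, res)

    def add(name, p, r1, r2, L, th, ta, ridx):
        polar = model.element[p].upper() in ("N", "O", "S")
        rows.append((p, r1, r2, L, th, ta, name, polar, ridx))

    for res in residues:
        tpl = templates[res.name]
        for spec in tpl.h_placements:
            if spec["when"] == "3prime" and res.next != -1:
                continue
            ids = [res.atoms.get(spec[k]) for k in ("parent", "ref1", "ref2")]
            if any(i is None for i in ids):
                warnings.warn(
                    f"H {spec['name']} skipped in {res.name} {res.chain}{res.seq}:"
                    " missing parent atoms"
                )
                continue
            add(spec["name"], ids[0], ids[1], ids[2], spec["length"],
                spec["theta"], spec["tau"], res.index)
        if tpl.is_rna:
            continue
        # backbone amide / N-terminal hydrogens
        n, ca, c = (res.atoms.get(k) for k in ("N", "CA", "C"))
        if n is None or ca is None or c is None:
            continue
        if res.prev != -1:
            if res.name != "PRO":
                prev = residues[res.prev]
                cp, op = prev.atoms.get("C"), prev.atoms.get("O")
                if cp is not None and op is not None:
                    add("H", n, cp, op, 0.86, 119.3, 180.0, res.index)
        else:
            taus = (60.0, 180.0) if res.name == "PRO" else (60.0, 180.0, -60.0)
            for k, tau in enumerate(taus, start=1):
                add(f"H{k}", n, ca, c, 0.86, 109.5, tau, res.index)

    if not rows:
        return HSpec(*(np.zeros(0, dtype=int),) * 3,
                     *(np.zeros(0),) * 3,
                     np.zeros(0, dtype="U6"), np.zeros(0, dtype=bool),
                     np.zeros(0, dtype=int))
    p, r1, r2, L, th, ta, nm, pol, ridx = zip(*rows)
    return HSpec(
        np.array(p, int), np.array(r1, int), np.array(r2, int),
        np.array(L, float), np.array(th, float), np.array(ta, float),
        np.array(nm), np.array(pol, bool), np.array(ridx, int),
    )


def _covalent_exclusions(n_total, bond_pairs, max_bonds=3):
    """Per-atom sets of atoms within `max_bonds` covalent steps (BFS)."""
    adj = [[] for _ in range(n_total)]
    for i, j in bond_pairs:
        adj[i].append(j)
        adj[j].append(i)
    excluded = []
    for s in range(n_total):
        seen = {s: 0}
        frontier = [s]
        for depth in range(1, max_bonds + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        excluded.append(np.array(sorted(seen), dtype=int))
    return excluded


def rebuild_neighbor_pairs(coords_combined, topo: "TopologyTables"):
    """Recompute the clash-candidate lists from current coordinates.

    Keeps the `neighbor_k` nearest covalently-ineligible-free atoms per atom
    and updates `topo.neighbor_index` / `topo.pair_index` / `topo.pair_thresh`
    in place.
    """
    n = len(coords_combined)
    k = min(topo.neighbor_k + 1, n)
    tree = cKDTree(coords_combined)
    # query generously, then filter exclusions
    kq = min(n, topo.neighbor_k + 16)
    dists, idxs = tree.query(coords_combined, k=kq)
    neighbor_index = []
    for i in range(n):
        excl = topo.excluded[i]
        cand = idxs[i]
        mask = ~np.isin(cand, excl)
        sel = cand[mask][: topo.neighbor_k]
        if len(cand[mask]) < topo.neighbor_k and kq < n:
            # fall back to a full sort when the generous query was not enough
            d_all = np.linalg.norm(coords_combined - coords_combined[i], axis=1)
            order = np.argsort(d_all, kind="stable")
            mask = ~np.isin(order, excl)
            sel = order[mask][: topo.neighbor_k]
        neighbor_index.append(np.asarray(sel, dtype=int))
    pairs = set()
    for i, sel in enumerate(neighbor_index):
        for j in sel:
            pairs.add((min(i, int(j)), max(i, int(j))))
    pair_index = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    pair_thresh = _pair_thresholds(pair_index, topo.radii, topo.elements,
                                   topo.n_heavy)
    topo.neighbor_index = neighbor_index
    topo.pair_index = pair_index
    topo.pair_thresh = pair_thresh
    return topo


def _pair_thresholds(pair_index, radii, elements, n_heavy):
    """Clash threshold per candidate pair: r_i + r_j - 0.4 Å, with the
    hydrogen-bond allowance (an extra 0.4 Å) for H...O/N pairs."""
    if len(pair_index) == 0:
        return np.zeros(0)
    ei = elements[pair_index[:, 0]]
    ej = elements[pair_index[:, 1]]
    thr = radii[pair_index[:, 0]] + radii[pair_index[:, 1]] - 0.4
    hb = ((ei == "H") & np.isin(ej, ("N", "O"))) | (
        (ej == "H") & np.isin(ei, ("N", "O"))
    )
    thr[hb] -= 0.4
    return thr


def compile_topology(
    model: AtomicModel, templates=None, neighbor_k: int = 128,
    vdw: VdwTable | None = None,
) -> TopologyTables:
    """Compile all index tables for a model (see module docstring)."""
    if templates is None:
        templates = load_templates()
    if vdw is None:
        vdw = load_vdw_table()
    breaks = []
    residues = _segment_residues(model, templates)
    _link_residues(model, residues, breaks)
    sig_tbl = _data("restraint_sigmas.json")

    bond_rows, angle_rows, planar_rows = [], [], []
    for res in residues:
        tpl = templates[res.name]
        A = res.atoms
        for nm in A:
            if nm not in tpl.atom_names and nm not in OPTIONAL_ATOMS:
                warnings.warn(
                    f"atom {nm} in {res.name} {res.chain}{res.seq} not in template"
                )
        for a, b, mu, sig in tpl.bonds:
            if a in A and b in A:
                bond_rows.append((A[a], A[b], mu, sig))
        for a, b, c, mu, sig in tpl.angles:
            if a in A and b in A and c in A:
                angle_rows.append((A[a], A[b], A[c], mu, sig))
        for quad, _cls in tpl.planar_groups:
            if all(q in A for q in quad):
                planar_rows.append(([A[q] for q in quad], 10.0, False))

    ov = sig_tbl["bond_overrides"]
    aov = sig_tbl["angle_overrides"]
    for res in residues:
        if res.next == -1:
            continue
        nres = residues[res.next]
        A, B = res.atoms, nres.atoms
        if res.chain_type == "rna":
            mu, sig = ov["phosphodiester_O3'-P"]
            bond_rows.append((A["O3'"], B["P"], mu, sig))
            for key, names, src in (
                ("inter_C3'-O3'-P", ("C3'", "O3'", "P"), (A, A, B)),
                ("inter_O3'-P-O5'", ("O3'", "P", "O5'"), (A, B, B)),
                ("inter_O3'-P-OP1", ("O3'", "P", "OP1"), (A, B, B)),
                ("inter_O3'-P-OP2", ("O3'", "P", "OP2"), (A, B, B)),
            ):
                ids = [s.get(n) for s, n in zip(src, names)]
                if None not in ids:
                    mu, sig = aov[key]
                    angle_rows.append((*ids, mu, sig))
        else:
            mu, sig = ov["peptide_C-N"]
            bond_rows.append((A["C"], B["N"], mu, sig))
            for key, names, src in (
                ("inter_CA-C-N", ("CA", "C", "N"), (A, A, B)),
                ("inter_O-C-N", ("O", "C", "N"), (A, A, B)),
                ("inter_C-N-CA", ("C", "N", "CA"), (A, B, B)),
            ):
                ids = [s.get(n) for s, n in zip(src, names)]
                if None not in ids:
                    mu, sig = aov[key]
                    angle_rows.append((*ids, mu, sig))
            if nres.name == "PRO" and "CD" in B:
                mu, sig = aov["inter_C-N-CD"]
                angle_rows.append((A["C"], B["N"], B["CD"], mu, sig))
            # peptide omega + carbonyl improper
            if all(k in A for k in ("CA", "C", "O")) and all(
                k in B for k in ("N", "CA")
            ):
                planar_rows.append(
                    ([A["CA"], A["C"], B["N"], B["CA"]], 30.0, True)
                )
                planar_rows.append(([A["O"], A["CA"], A["C"], B["N"]], 10.0, False))

    # backbone phi/psi (+omega for cis/trans classification)
    phi, psi, omega, rama_res, rama_cls = [], [], [], [], []
    for res in residues:
        if res.chain_type == "rna" or res.prev == -1 or res.next == -1:
            continue
        p, n = residues[res.prev], residues[res.next]
        need = (
            p.atoms.get("C"), res.atoms.get("N"), res.atoms.get("CA"),
            res.atoms.get("C"), n.atoms.get("N"),
        )
        if None in need:
            continue
        cp, ni, cai, ci, nn = need
        phi.append((cp, ni, cai, ci))
        psi.append((ni, cai, ci, nn))
        cap = p.atoms.get("CA")
        omega.append((cap, cp, ni, cai) if cap is not None else (-1,) * 4)
        rama_res.append(res.index)
        if res.name == "PRO":
            cls = "Pro"        # resolved to cis/trans from omega at runtime
        elif n.name == "PRO":
            cls = "pre-Pro"
        elif res.name == "GLY":
            cls = "Gly"
        elif res.name in ILE_CLASS:
            cls = "Ile"
        else:
            cls = "General"
        rama_cls.append(cls)

    # chi quads
    chi_quads, chi_res, chi_k = [], [], []
    for res in residues:
        tpl = templates[res.name]
        for k, quad in enumerate(tpl.chi_definitions):
            ids = [res.atoms.get(q) for q in quad]
            if None in ids:
                if res.atoms:
                    warnings.warn(
                        f"chi{k+1} of {res.name} {res.chain}{res.seq} skipped:"
                        " missing sidechain atoms"
                    )
                break
            chi_quads.append(ids)
            chi_res.append(res.index)
            chi_k.append(k)

    # RNA suites: 7 torsions spanning base i-1 -> i
    rna_quads, rna_res = [], []
    suite_names = [
        ("C5'", "C4'", "C3'", "O3'", 0),   # delta-1
        ("C4'", "C3'", "O3'", "P", 1),     # eps-1  (P from residue i)
        ("C3'", "O3'", "P", "O5'", 2),     # zeta-1
        ("O3'", "P", "O5'", "C5'", 3),     # alpha
        ("P", "O5'", "C5'", "C4'", 4),     # beta
        ("O5'", "C5'", "C4'", "C3'", 5),   # gamma
        ("C5'", "C4'", "C3'", "O3'", 6),   # delta
    ]
    for res in residues:
        if res.chain_type != "rna" or res.prev == -1:
            continue
        prev = residues[res.prev]
        quads = []
        ok = True
        for names_idx in suite_names:
            *names, pos = names_idx
            # torsions 0-2 start in the previous residue
            if pos == 0:
                src = [prev] * 4
            elif pos == 1:
                src = [prev, prev, prev, res]
            elif pos == 2:
                src = [prev, prev, res, res]
            elif pos == 3:
                src = [prev, res, res, res]
            else:
                src = [res] * 4
            ids = [s.atoms.get(nm) for s, nm in zip(src, names)]
            if None in ids:
                ok = False
                break
            quads.append(ids)
        if ok:
            rna_quads.append(quads)
            rna_res.append(res.index)

    # hydrogens + clash candidates
    hspec = _h_spec_from_residues(model, residues, templates)
    n_heavy = model.n_atoms
    n_h = len(hspec.parent)
    elements = np.concatenate(
        [np.char.upper(model.element.astype("U2")), np.full(n_h, "H")]
    )
    radii = np.empty(n_heavy + n_h)
    for i in range(n_heavy):
        radii[i] = vdw.radius(elements[i])
    for j in range(n_h):
        radii[n_heavy + j] = vdw.radius("H", polar_h=bool(hspec.polar[j]))

    all_bonds = [(int(i), int(j)) for i, j, _, _ in bond_rows]
    all_bonds += [(int(hspec.parent[j]), n_heavy + j) for j in range(n_h)]
    excluded = _covalent_exclusions(n_heavy + n_h, all_bonds)

    topo = TopologyTables(
        residues=residues,
        n_heavy=n_heavy,
        bond_index=np.array([(i, j) for i, j, _, _ in bond_rows], int).reshape(-1, 2),
        bond_mu=np.array([r[2] for r in bond_rows]),
        bond_sigma=np.array([r[3] for r in bond_rows]),
        angle_index=np.array([(r[0], r[1], r[2]) for r in angle_rows], int).reshape(-1, 3),
        angle_mu=np.array([r[3] for r in angle_rows]),
        angle_sigma=np.array([r[4] for r in angle_rows]),
        planar_index=np.array([r[0] for r in planar_rows], int).reshape(-1, 4),
        planar_thresh=np.array([r[1] for r in planar_rows]),
        planar_is_omega=np.array([r[2] for r in planar_rows], bool),
        phi_quads=np.array(phi, int).reshape(-1, 4),
        psi_quads=np.array(psi, int).reshape(-1, 4),
        omega_quads=np.array(omega, int).reshape(-1, 4),
        rama_residue=np.array(rama_res, int),
        rama_class_static=np.array(rama_cls, dtype="U8"),
        chi_quads=np.array(chi_quads, int).reshape(-1, 4),
        chi_res=np.array(chi_res, int),
        chi_k=np.array(chi_k, int),
        rna_quads=np.array(rna_quads, int).reshape(-1, 7, 4),
        rna_res=np.array(rna_res, int),
        hspec=hspec,
        radii=radii,
        elements=elements,
        neighbor_index=[],
        pair_index=np.zeros((0, 2), int),
        pair_thresh=np.zeros(0),
        neighbor_k=neighbor_k,
        excluded=excluded,
        chain_breaks=breaks,
    )
    from .model_io import place_hydrogens

    h_xyz = place_hydrogens(model.coords, hspec) if n_h else np.zeros((0, 3))
    combined = np.vstack([model.coords, h_xyz])
    rebuild_neighbor_pairs(combined, topo)
    return topo
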