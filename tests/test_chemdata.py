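"""Reference tables and topology compilation."""

import numpy as np
import pytest

from gmmrefine import chemdata, synthetic
from gmmrefine.chemdata import (
    UnsupportedResidueError,
    compile_topology,
    load_templates,
    load_vdw_table,
)
from gmmrefine.model_io import AtomicModel
from gmmrefine.synthetic import FixtureSpec


def test_template_chi_counts(templates):
    assert len(templates["GLY"].chi_definitions) == 0
    assert len(templates["ARG"].chi_definitions) == 4
    assert len(templates["LYS"].chi_definitions) == 4
    assert len(templates["ALA"].chi_definitions) == 0
    assert len(templates["SER"].chi_definitions) == 1


def test_templates_cover_proteins_and_rna(templates):
    assert len(templates) == 24
    for tpl in templates.values():
        names = set(tpl.atom_names)
        for a, b, mu, sig in tpl.bonds:
            assert a in names and b in names
            assert sig > 0 and 0.5 < mu < 2.5
        for *_, mu, sig in tpl.angles:
            assert sig > 0 and 60 < mu < 180


def test_unknown_dialect_rejected():
    with pytest.raises(ValueError):
        load_templates("exotic")
    with pytest.raises(ValueError):
        load_vdw_table("exotic")


def test_vdw_radii_in_physical_range():
    vdw = load_vdw_table()
    for key, r in vdw.radii.items():
        assert 0.8 < r < 2.5, key


def test_aromatic_residues_have_planar_groups(templates):
    for res in ("PHE", "TYR", "TRP", "HIS", "ARG", "ASP", "ASN"):
        assert templates[res].planar_groups, res
    # sp3-only residues carry no intra-residue planar quads beyond carboxyl
    assert all("OXT" in q or "O" in q
               for q, _ in templates["ALA"].planar_groups)


def test_peptide_link_compilation(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AA"))
    topo = compile_topology(m, templates)
    inter = [
        (i, j) for i, j in topo.bond_index
        if m.res_seq[i] != m.res_seq[j]
    ]
    assert len(inter) == 1
    i, j = inter[0]
    assert {m.atom_name[i], m.atom_name[j]} == {"C", "N"}
    # every omega quad is classed as a peptide plane with the 30 deg threshold
    om = topo.planar_thresh[topo.planar_is_omega]
    assert len(om) == 1 and om[0] == 30.0


def test_neighbor_lists_capped_at_default(helix_topo):
    assert all(len(nb) <= 128 for nb in helix_topo.neighbor_index)


def test_neighbor_lists_match_brute_force(templates):
    """k-nearest eligible neighbours equal an all-vs-all distance oracle."""
    from gmmrefine.model_io import place_hydrogens

    base = synthetic.make_toy_structure(FixtureSpec("AAAAAAAAAA"))
    # jitter breaks the exact distance ties of the idealised repeat
    m, _ = synthetic.perturb(base, jitter_sigma=0.05, seed=1)
    topo = compile_topology(m, templates, neighbor_k=10)
    h = place_hydrogens(m.coords, topo.hspec)
    X = np.vstack([m.coords, h])
    for i in range(len(X)):
        d = np.linalg.norm(X - X[i], axis=1)
        order = np.argsort(d, kind="stable")
        eligible = [j for j in order if j not in set(topo.excluded[i])][:10]
        got = sorted(topo.neighbor_index[i], key=lambda j: (d[j], j))
        assert set(got) == set(eligible), f"atom {i}"


def test_covalent_exclusion_via_bfs(helix_topo):
    """No clash-candidate pair is within 3 covalent bonds (BFS oracle)."""
    n = helix_topo.n_combined
    adj = [[] for _ in range(n)]
    for i, j in helix_topo.bond_index:
        adj[i].append(int(j))
        adj[j].append(int(i))
    for k, p in enumerate(helix_topo.hspec.parent):
        adj[int(p)].append(helix_topo.n_heavy + k)
        adj[helix_topo.n_heavy + k].append(int(p))

    def within(src, dst, steps=3):
        frontier = {src}
        for _ in range(steps):
            frontier = {v for u in frontier for v in adj[u]} | frontier
            if dst in frontier:
                return True
        return dst in frontier

    rng = np.random.default_rng(0)
    sample = rng.integers(0, len(helix_topo.pair_index), 200)
    for k in sample:
        i, j = helix_topo.pair_index[k]
        assert not within(int(i), int(j))


def test_bond_count_is_template_sum_plus_links(templates):
    m = synthetic.make_toy_structure(FixtureSpec("GAVL"))
    topo = compile_topology(m, templates)
    expected = 0
    for name in ("GLY", "ALA", "VAL", "LEU"):
        tpl = templates[name]
        present = {a for a in tpl.atom_names if a != "OXT"}
        expected += sum(1 for a, b, *_ in tpl.bonds
                        if a in present and b in present)
    expected += 3  # inter-residue peptide bonds
    assert len(topo.bond_index) == expected


def test_chain_break_suppresses_link(templates):
    m = synthetic.make_toy_structure(FixtureSpec("AAAA"))
    coords = m.coords.copy()
    coords[m.res_seq >= 3] += 30.0      # pull the tail far away
    broken = m.with_coords(coords)
    topo = compile_topology(broken, templates)
    inter = [(i, j) for i, j in topo.bond_index
             if m.res_seq[i] != m.res_seq[j]]
    assert len(inter) == 2              # 1-2 and 3-4 links only
    assert len(topo.chain_breaks) == 1


def test_unsupported_residue_named_in_error(templates, helix_model):
    m = helix_model
    bad = AtomicModel(
        m.element, m.atom_name, np.where(m.res_seq == 2, "XYZ", m.res_name),
        m.res_seq, m.icode, m.chain_id, m.coords, m.occupancy,
        dict(m.chain_types),
    )
    with pytest.raises(UnsupportedResidueError, match="XYZ"):
        compile_topology(bad, templates)


def test_compilation_is_permutation_consistent(templates):
    """Shuffling atoms within residues permutes the index tables identically."""
    m = synthetic.make_toy_structure(FixtureSpec("AGL"))
    rng = np.random.default_rng(5)
    perm = np.arange(m.n_atoms)
    starts = list(m.residue_starts()) + [m.n_atoms]
    for s, e in zip(starts[:-1], starts[1:]):
        perm[s:e] = s + rng.permutation(e - s)
    m2 = AtomicModel(
        m.element[perm], m.atom_name[perm], m.res_name[perm], m.res_seq[perm],
        m.icode[perm], m.chain_id[perm], m.coords[perm], m.occupancy[perm],
        dict(m.chain_types),
    )
    t1 = compile_topology(m, templates)
    t2 = compile_topology(m2, templates)
    # index j of the permuted model refers to original atom perm[j]

    def canon(pairs):
        return {tuple(sorted(p)) for p in pairs}

    assert canon(t1.bond_index.tolist()) == canon(
        [[int(perm[i]), int(perm[j])] for i, j in t2.bond_index]
    )


def test_rna_suite_quads_span_two_residues(rna_topo, rna_model):
    assert len(rna_topo.rna_quads) == 5    # 6 bases -> 5 suites
    for quads in rna_topo.rna_quads:
        res_of = {rna_model.res_seq[i] for q in quads for i in q}
        assert len(res_of) == 2
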