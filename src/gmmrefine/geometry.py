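"""Differentiable stereochemical scoring.

Every validation-style metric (bond/angle restraints, planarity, the
Ramachandran plot, sidechain rotamers, atomic clashes with hydrogens, RNA
backbone suites) is expressed twice over the same index tables: as a smooth
loss with exact gradients for refinement, and as a hard-threshold report
that mirrors how the validation counts are defined.  Smooth hinges use
softplus so thresholds emerge sharply in the report while gradients stay
finite.

Conventions: bond/angle outliers are *reported* at 5 sigma but *penalised*
from 4.5 sigma; the peptide-bond (omega) planarity threshold is 30 degrees
and 10 degrees for all other planar groups; clashes are overlaps beyond
0.4 Å of the summed van der Waals radii (0.8 Å for potential hydrogen-bond
pairs); Ramachandran outlier/allowed levels are 0.0005/0.02 on the max-1
histogram scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import dgeom
from .autodiff import Var, as_var
from .chemdata import TopologyTables, rebuild_neighbor_pairs
from .model_io import place_hydrogens
from .surfaces import (
    LOG_C,
    default_rama_surfaces,
    default_rotamer_surfaces,
    load_suite_library,
    wrap_deg,
)

OUTLIER_REPORT_SIGMA = 5.0       # validation reporting threshold
DEFAULT_OUTLIER_SIGMA = 4.5      # penalty activation threshold

DEFAULT_WEIGHTS = {
    "bond": 1.0, "angle": 1.0, "planarity": 1.0, "rama": 1.0,
    "rotamer": 0.5, "clash": 1.0, "rna": 1.0,
}


def _abs_smooth(x: Var) -> Var:
    return ad.sqrt(x * x + 1e-12)


def _wrap_var(x: Var, period: float) -> Var:
    x = as_var(x)
    shift = np.floor(x.data / period + 0.5) * period
    return x - shift


@dataclass
class GeometryReport:
    """Hard-threshold validation-style summary of one set of coordinates."""

    n_atoms: int = 0
    n_hydrogens: int = 0
    bond_outliers: int = 0
    angle_outliers: int = 0
    bond_rms_z: float = 0.0
    angle_rms_z: float = 0.0
    planarity_violations: int = 0
    rama_favored_fraction: float = float("nan")
    rama_allowed_fraction: float = float("nan")
    rama_outlier_fraction: float = float("nan")
    rotamer_outlier_fraction: float = float("nan")
    clash_count: int = 0
    clash_score: float = 0.0          # per 1000 atoms, hydrogens included
    rna_mean_suite_score: float = float("nan")
    rna_outliers: int = 0
    loss: float = float("nan")
    loss_components: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)


class GeometryEngine:
    """Evaluates all stereochemical terms for one compiled topology."""

    def __init__(
        self,
        topo: TopologyTables,
        templates=None,
        rama_surfaces=None,
        rotamer_surfaces=None,
        suite_library=None,
        outlier_sigma: float = DEFAULT_OUTLIER_SIGMA,
        weights: dict | None = None,
    ):
        from .chemdata import load_templates

        self.topo = topo
        self.templates = templates or load_templates()
        self._rama = rama_surfaces
        self._rotamer = rotamer_surfaces
        self._suites = suite_library
        self.outlier_sigma = float(outlier_sigma)
        self.weights = dict(DEFAULT_WEIGHTS)
        if weights:
            for k, v in weights.items():
                if v < 0:
                    raise ValueError(f"negative weight for {k!r}")
                self.weights[k] = float(v)
        self._iteration = 0
        self._chi_groups = self._compile_chi_groups()

    # surfaces are lazy: fitting them is not free and pure bond/clash use
    # cases should not pay for it
    @property
    def rama_surfaces(self):
        if self._rama is None:
            self._rama = default_rama_surfaces()
        return self._rama

    @property
    def rotamer_surfaces(self):
        if self._rotamer is None:
            self._rotamer = default_rotamer_surfaces()
        return self._rotamer

    @property
    def suite_library(self):
        if self._suites is None:
            self._suites = load_suite_library()
        return self._suites

    def _compile_chi_groups(self):
        """Group complete chi sets by residue type for batched evaluation."""
        topo = self.topo
        per_res = {}
        for q, r, k in zip(topo.chi_quads, topo.chi_res, topo.chi_k):
            per_res.setdefault(int(r), {})[int(k)] = q
        groups = {}
        for ridx, quads in per_res.items():
            res = topo.residues[ridx]
            tpl = self.templates[res.name]
            n_chi = len(tpl.chi_definitions)
            if len(quads) != n_chi:
                continue  # incomplete sidechain: skipped (warned at compile)
            groups.setdefault(res.name, []).append(
                (ridx, np.array([quads[k] for k in range(n_chi)], int))
            )
        return groups

    # ------------------------------------------------------------------
    # individual terms

    def bond_angle_score(self, coords):
        """Gaussian log-likelihood + outlier hinge for bonds and angles."""
        X = as_var(coords)
        topo = self.topo
        out = {}
        terms = []
        for kind, vals, mu, sig in (
            ("bond", dgeom.bond_lengths(X, topo.bond_index), topo.bond_mu,
             topo.bond_sigma),
            ("angle", dgeom.bond_angles(X, topo.angle_index), topo.angle_mu,
             topo.angle_sigma),
        ):
            if len(mu) == 0:
                out[f"{kind}_outliers"] = 0
                out[f"{kind}_rms_z"] = 0.0
                terms.append(Var(0.0))
                continue
            z = (vals - mu) / sig
            az = _abs_smooth(z)
            nll = (z * z).mean() * 0.5
            hinge = ad.softplus((az - self.outlier_sigma) * 10.0, beta=1.0).mean()
            terms.append(nll + hinge)
            out[f"{kind}_outliers"] = int(np.sum(np.abs(z.data) > OUTLIER_REPORT_SIGMA))
            out[f"{kind}_rms_z"] = float(np.sqrt(np.mean(z.data**2)))
        return terms[0], terms[1], out

    def planarity_score(self, coords):
        X = as_var(coords)
        topo = self.topo
        if len(topo.planar_index) == 0:
            return Var(0.0), 0
        d = dgeom.dihedrals(X, topo.planar_index)
        dev = _abs_smooth(_wrap_var(d, 180.0))       # distance to 0/180
        thr = topo.planar_thresh
        hinge = ad.softplus((dev - thr) * 2.0, beta=1.0).mean()
        quad = ((dev / thr) ** 2).mean() * 0.05      # weak pull to planarity
        violations = int(np.sum(dev.data > thr))
        return hinge + quad, violations

    def _rama_angles(self, X: Var):
        topo = self.topo
        if len(topo.phi_quads) == 0:
            return None
        phi = dgeom.dihedrals(X, topo.phi_quads)
        psi = dgeom.dihedrals(X, topo.psi_quads)
        # resolve Pro -> cis/trans from omega (hard decision)
        classes = topo.rama_class_static.copy()
        pro = classes == "Pro"
        if np.any(pro):
            om = np.full(len(classes), 180.0)
            valid = topo.omega_quads[:, 0] >= 0
            if np.any(valid):
                om_v = dgeom.dihedrals(Var(X.data), topo.omega_quads[valid]).data
                om[valid] = om_v
            cis = np.abs(wrap_deg(om)) < 30.0
            classes = classes.astype("U9")
            classes[pro & cis] = "cis-Pro"
            classes[pro & ~cis] = "trans-Pro"
        return phi, psi, classes

    def rama_score(self, coords):
        """Loss plus hard favored/allowed/outlier fractions."""
        X = as_var(coords)
        got = self._rama_angles(X)
        if got is None:
            return Var(0.0), {"favored": float("nan"), "allowed": float("nan"),
                              "outlier": float("nan")}
        phi, psi, classes = got
        surfaces = self.rama_surfaces
        loss_terms = []
        n_fav = n_allow = n_out = 0
        for cls in np.unique(classes):
            sel = np.flatnonzero(classes == cls)
            surf = surfaces[str(cls)]
            ang = ad.stack([phi[sel], psi[sel]], axis=1)
            logS = surf.evaluate(ang)
            # only the allowed/outlier counts act on the loss: the sharp
            # hinges leave favored residues on a flat plateau instead of
            # pulling them toward basin centers
            loss_terms.append(
                ad.softplus((surf.allowed_threshold - logS) * 3.0, beta=1.0).sum()
                + 4.0 * ad.softplus((surf.outlier_threshold - logS) * 3.0,
                                    beta=1.0).sum()
            )
            lab = surf.classify(np.stack([phi.data[sel], psi.data[sel]], axis=1))
            n_fav += int(np.sum(lab == "favored"))
            n_allow += int(np.sum(lab == "allowed"))
            n_out += int(np.sum(lab == "outlier"))
        n = len(classes)
        loss = loss_terms[0]
        for t in loss_terms[1:]:
            loss = loss + t
        loss = loss * (1.0 / n)
        return loss, {"favored": n_fav / n, "allowed": n_allow / n,
                      "outlier": n_out / n}

    def chi_angles(self, coords):
        """Per-residue chi vectors: {res_name: (res_indices, (m, n_chi) Var)}."""
        X = as_var(coords)
        out = {}
        for res_name, entries in self._chi_groups.items():
            quads = np.stack([e[1] for e in entries])       # (m, n_chi, 4)
            m, n_chi, _ = quads.shape
            vals = dgeom.dihedrals(X, quads.reshape(-1, 4)).reshape(m, n_chi)
            out[res_name] = (np.array([e[0] for e in entries]), vals)
        return out

    def rotamer_score(self, coords):
        chi = self.chi_angles(coords)
        if not chi:
            return Var(0.0), {"outlier": float("nan"), "n": 0}
        surfaces = self.rotamer_surfaces
        loss_terms, n_res, n_out = [], 0, 0
        for res_name, (ridx, vals) in chi.items():
            surf = surfaces[res_name]
            logS = surf.evaluate(vals)
            loss_terms.append(
                (logS * -0.05).sum()
                + 2.0 * ad.softplus((surf.outlier_threshold - logS) * 2.0,
                                    beta=1.0).sum()
            )
            n_res += len(ridx)
            n_out += int(np.sum(logS.data < surf.outlier_threshold))
        loss = loss_terms[0]
        for t in loss_terms[1:]:
            loss = loss + t
        loss = loss * (1.0 / n_res)
        return loss, {"outlier": n_out / n_res, "n": n_res}

    def combined_coords(self, coords):
        """Heavy atoms + zero-torsion hydrogens, in the autodiff graph."""
        X = as_var(coords)
        spec = self.topo.hspec
        if len(spec.parent) == 0:
            return X
        H = dgeom.nerf_place(
            X[spec.parent], X[spec.ref1], X[spec.ref2],
            spec.length, spec.theta, spec.tau,
        )
        return ad.concatenate([X, H], axis=0)

    def clash_score(self, coords, combined=None):
        topo = self.topo
        Xc = self.combined_coords(coords) if combined is None else combined
        if len(topo.pair_index) == 0:
            return Var(0.0), 0, 0.0
        d = dgeom.vnorm(Xc[topo.pair_index[:, 0]] - Xc[topo.pair_index[:, 1]])
        overlap = topo.pair_thresh - d
        # train with a small margin so contacts settle clearly below the
        # reporting threshold instead of hovering at zero overlap
        loss = ad.softplus((overlap + 0.05) * 20.0, beta=1.0).mean()
        count = int(np.sum(overlap.data > 0))
        per1000 = 1000.0 * count / topo.n_combined
        return loss, count, per1000

    def refresh_neighbors(self, coords, every: int = 100, force: bool = False):
        """Rebuild clash candidate lists; call at the stated cadence."""
        self._iteration += 1
        if force or self._iteration % every == 0:
            X = np.asarray(coords if not isinstance(coords, Var) else coords.data)
            h = (place_hydrogens(X, self.topo.hspec)
                 if len(self.topo.hspec.parent) else np.zeros((0, 3)))
            rebuild_neighbor_pairs(np.vstack([X, h]), self.topo)

    def rna_suite_score(self, coords):
        topo = self.topo
        if len(topo.rna_quads) == 0:
            return Var(0.0), {"mean_score": float("nan"), "outliers": 0, "n": 0}
        X = as_var(coords)
        S = len(topo.rna_quads)
        vals = dgeom.dihedrals(X, topo.rna_quads.reshape(-1, 4)).reshape(S, 7)
        lib = self.suite_library
        idx, score = lib.assign(vals.data)
        centers = lib.centers[idx]                   # (S,7)
        delta = _wrap_var(vals - centers, 360.0)
        d2 = ((delta / lib.halfwidth[None, :]) ** 2).mean(axis=1)
        loss = d2.mean()
        assigned = score >= lib.assignment_threshold
        mean_score = float(score[assigned].mean()) if np.any(assigned) else 0.0
        return loss, {
            "mean_score": mean_score,
            "outliers": int(np.sum(~assigned)),
            "n": S,
            "scores": score,
            "assignments": idx,
        }

    # ------------------------------------------------------------------
    # aggregation

    def loss(self, coords, terms=None, weights=None):
        """Weighted differentiable total; returns (Var, components dict)."""
        w = dict(self.weights)
        if weights:
            for k, v in weights.items():
                if v < 0:
                    raise ValueError(f"negative weight for {k!r}")
                w[k] = float(v)
        if terms is None:
            terms = set(w)
        comps = {}
        total = Var(0.0)
        if "bond" in terms or "angle" in terms:
            bl, al, _ = self.bond_angle_score(coords)
            if "bond" in terms:
                comps["bond"] = bl
            if "angle" in terms:
                comps["angle"] = al
        if "planarity" in terms:
            comps["planarity"], _ = self.planarity_score(coords)
        if "rama" in terms and len(self.topo.phi_quads):
            comps["rama"], _ = self.rama_score(coords)
        if "rotamer" in terms and len(self.topo.chi_quads):
            comps["rotamer"], _ = self.rotamer_score(coords)
        if "clash" in terms:
            comps["clash"], _, _ = self.clash_score(coords)
        if "rna" in terms and len(self.topo.rna_quads):
            comps["rna"], _ = self.rna_suite_score(coords)
        for k, v in comps.items():
            total = total + w[k] * v
        return total, {k: float(v.data) for k, v in comps.items()}

    def geometry_scalar(self, coords) -> float:
        """Unweighted sum of likelihood terms (used for weight balancing)."""
        total, _ = self.loss(coords)
        return float(total.data)

    def report(self, coords) -> GeometryReport:
        X = Var(np.asarray(coords, float))
        bl, al, ba = self.bond_angle_score(X)
        pl, pviol = self.planarity_score(X)
        rl, rama = (Var(0.0), {"favored": float("nan"), "allowed": float("nan"),
                               "outlier": float("nan")})
        if len(self.topo.phi_quads):
            rl, rama = self.rama_score(X)
        tl, rot = (Var(0.0), {"outlier": float("nan"), "n": 0})
        if len(self.topo.chi_quads):
            tl, rot = self.rotamer_score(X)
        cl, ccount, cscore = self.clash_score(X)
        nl, rna = (Var(0.0), {"mean_score": float("nan"), "outliers": 0, "n": 0})
        if len(self.topo.rna_quads):
            nl, rna = self.rna_suite_score(X)
        comps = {"bond": float(bl.data), "angle": float(al.data),
                 "planarity": float(pl.data), "rama": float(rl.data),
                 "rotamer": float(tl.data), "clash": float(cl.data),
                 "rna": float(nl.data)}
        total = sum(self.weights[k] * v for k, v in comps.items())
        return GeometryReport(
            n_atoms=self.topo.n_heavy,
            n_hydrogens=len(self.topo.hspec.parent),
            bond_outliers=ba["bond_outliers"],
            angle_outliers=ba["angle_outliers"],
            bond_rms_z=ba["bond_rms_z"],
            angle_rms_z=ba["angle_rms_z"],
            planarity_violations=pviol,
            rama_favored_fraction=rama["favored"],
            rama_allowed_fraction=rama["allowed"],
            rama_outlier_fraction=rama["outlier"],
            rotamer_outlier_fraction=rot["outlier"],
            clash_count=ccount,
            clash_score=cscore,
            rna_mean_suite_score=rna["mean_score"],
            rna_outliers=rna["outliers"],
            loss=total,
            loss_components=comps,
        )


def combined_loss(components: dict, weights: dict) -> Var:
    """Weighted sum of loss components (negative weights rejected)."""
    total = Var(0.0)
    for k, v in components.items():
        w = weights.get(k, 1.0)
        if w < 0:
            raise ValueError(f"negative weight for {k!r}")
        total = total + w * as_var(v)
    return total
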