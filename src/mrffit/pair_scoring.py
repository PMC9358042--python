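"""Physics-based pairwise interaction scoring between placed subunits.

The interaction of two candidate poses is scored by a docking-style energy
with four physical terms plus a steric clash count:

* van der Waals: Lennard-Jones 12-6 on heavy-atom pairs with per-element
  radii/epsilons, soft-cored by capping the repulsive branch at +10 energy
  units per pair so the score stays finite at overlap;
* electrostatics: Coulomb with the distance-dependent dielectric
  ``eps(r) = 4 r`` and residue-level formal charges (charged side chains
  carry +-1 split over their terminal atoms, all other atoms are neutral);
* hydrogen / disulfide bonds: distance-window terms — each N/O donor-acceptor
  pair at 2.6-3.5 Å contributes -1, each S-S pair at 1.8-2.4 Å contributes -2;
* solvation: a pairwise contact approximation — carbon-carbon contacts
  within 5 Å are rewarded, carbon-polar burial is penalized.

``f_ph`` is the unweighted sum of the four energy terms; the clash count is
kept separate (``f_cl``) because the combined assembly score weights the two
independently.  All terms are exactly zero whenever the minimum inter-subunit
heavy-atom distance exceeds the interaction cutoff (default 10 Å); this is
guaranteed by a bounding-sphere pre-filter so distant pose pairs cost O(1).

All terms are energies: lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "InteractionScore",
    "pair_score",
    "clash_count",
    "significant_clash",
    "DEFAULT_INTERACTION_CUTOFF",
    "DEFAULT_CLASH_CUTOFF",
    "DEFAULT_CLASH_FRACTION",
]

DEFAULT_INTERACTION_CUTOFF = 10.0
DEFAULT_CLASH_CUTOFF = 3.0
DEFAULT_CLASH_FRACTION = 0.1
VDW_CAP = 10.0

# per-element Lennard-Jones parameters: r_min (Å, pair optimum = sum of radii)
# and epsilon (well depth, energy units)
_LJ_RADIUS = {"C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1}
_LJ_EPS = {"C": 0.12, "N": 0.16, "O": 0.20, "S": 0.20, "P": 0.20}
_DEFAULT_RADIUS = 1.9
_DEFAULT_EPS = 0.15

# atomic solvation-like contact parameters (energy per contact pair < 5 Å):
# apolar-apolar contact favorable, apolar-polar burial unfavorable
_SOLV_CONTACT = 5.0
_SOLV_CC = -0.02
_SOLV_CP = +0.01

# residue-level formal charges split over terminal side-chain atoms
_PARTIAL_CHARGES = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): +1.0,
    ("ARG", "NH1"): +0.5, ("ARG", "NH2"): +0.5,
    ("HIS", "ND1"): +0.25, ("HIS", "NE2"): +0.25,
}
_COULOMB_K = 332.0637  # kcal mol^-1 Å e^-2

_HBOND_MIN, _HBOND_MAX, _HBOND_E = 2.6, 3.5, -1.0
_SS_MIN, _SS_MAX, _SS_E = 1.8, 2.4, -2.0


@dataclass
class InteractionScore:
    """Per-pose-pair physics terms; all energies, lower is better."""

    vdw: float = 0.0
    elec: float = 0.0
    hbond_ss: float = 0.0
    solvation: float = 0.0
    clash_count: int = 0

    @property
    def f_ph(self) -> float:
        return self.vdw + self.elec + self.hbond_ss + self.solvation

    @property
    def f_cl(self) -> float:
        return float(self.clash_count)


ZERO_SCORE = InteractionScore()


def _charges(subunit) -> np.ndarray:
    return np.array([
        _PARTIAL_CHARGES.get((rn, an), 0.0)
        for rn, an in zip(subunit.res_names, subunit.atom_names)
    ])


def clash_count(coords_a: np.ndarray, coords_b: np.ndarray,
                cutoff: float = DEFAULT_CLASH_CUTOFF) -> int:
    """Number of cross heavy-atom pairs closer than ``cutoff`` Å."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return 0
    pairs = cKDTree(a).sparse_distance_matrix(
        cKDTree(b), cutoff, output_type="coo_matrix"
    )
    # sparse_distance_matrix is inclusive of the radius; a clash is strict
    return int(np.sum(pairs.data < cutoff))


def pair_score(
    a,
    b,
    pose_a=None,
    pose_b=None,
    cutoff: float = DEFAULT_INTERACTION_CUTOFF,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> InteractionScore:
    """Score the physical interaction of two placed subunits.

    ``a`` and ``b`` are :class:`~mrffit.rigid_structures.Subunit` objects;
    if poses are given their transforms are applied first.  The score is
    symmetric term-by-term and exactly zero (including the clash count) when
    the bounding spheres put every atom pair beyond ``cutoff``.
    """
    if a.id == b.id:
        raise ValueError("pair_score requires two different subunits")
    ca = pose_a.transform.apply(a.coords) if pose_a is not None else a.coords
    cb = pose_b.transform.apply(b.coords) if pose_b is not None else b.coords

    # bounding-sphere rejection: exact all-zero score for distant pairs
    ctr_a, ctr_b = ca.mean(axis=0), cb.mean(axis=0)
    ra = float(np.max(np.linalg.norm(ca - ctr_a, axis=1)))
    rb = float(np.max(np.linalg.norm(cb - ctr_b, axis=1)))
    if np.linalg.norm(ctr_a - ctr_b) > ra + rb + cutoff:
        return InteractionScore()

    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    pairs = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    if pairs.nnz == 0:
        return InteractionScore()
    ii, jj, dist = pairs.row, pairs.col, pairs.data
    dist = np.maximum(dist, 1e-6)

    elem_a = np.array([e.upper() for e in a.elements])
    elem_b = np.array([e.upper() for e in b.elements])
    ea, eb = elem_a[ii], elem_b[jj]

    # Lennard-Jones 12-6, capped (soft core)
    rad_a = np.array([_LJ_RADIUS.get(e, _DEFAULT_RADIUS) for e in elem_a])
    rad_b = np.array([_LJ_RADIUS.get(e, _DEFAULT_RADIUS) for e in elem_b])
    eps_a = np.array([_LJ_EPS.get(e, _DEFAULT_EPS) for e in elem_a])
    eps_b = np.array([_LJ_EPS.get(e, _DEFAULT_EPS) for e in elem_b])
    rmin = rad_a[ii] + rad_b[jj]
    eps = np.sqrt(eps_a[ii] * eps_b[jj])
    sr6 = (rmin / dist) ** 6
    vdw_terms = np.minimum(eps * (sr6 * sr6 - 2.0 * sr6), VDW_CAP)
    vdw = float(vdw_terms.sum())

    # Coulomb with distance-dependent dielectric eps(r) = 4 r
    qa, qb = _charges(a)[ii], _charges(b)[jj]
    elec = float(np.sum(_COULOMB_K * qa * qb / (4.0 * dist * dist)))

    # hydrogen bonds (N/O donor-acceptor windows) and disulfides (S-S)
    polar_a = np.isin(ea, ("N", "O"))
    polar_b = np.isin(eb, ("N", "O"))
    hb = np.sum(polar_a & polar_b & (dist >= _HBOND_MIN) & (dist <= _HBOND_MAX)) * _HBOND_E
    ss = np.sum((ea == "S") & (eb == "S") & (dist >= _SS_MIN) & (dist <= _SS_MAX)) * _SS_E
    hbond_ss = float(hb + ss)

    # contact solvation
    contact = dist < _SOLV_CONTACT
    cc_pairs = contact & (ea == "C") & (eb == "C")
    cp_pairs = contact & ((ea == "C") ^ (eb == "C"))
    solvation = float(np.sum(cc_pairs) * _SOLV_CC + np.sum(cp_pairs) * _SOLV_CP)

    n_clash = int(np.sum(dist < clash_cutoff))
    return InteractionScore(vdw=vdw, elec=elec, hbond_ss=hbond_ss,
                            solvation=solvation, clash_count=n_clash)


def edge_tables_for_pair(a, b, poses_a, poses_b, weights,
                         cutoff: float = DEFAULT_INTERACTION_CUTOFF):
    """Interaction-energy and clash-count tables over all cross pose pairs.

    Returns ``(energy, clashes)`` arrays of shape (len(poses_a), len(poses_b))
    where ``energy = w_ph * f_ph + w_cl * f_cl``.  Placed coordinates are
    computed once per pose; distant pose pairs short-circuit to zero via the
    bounding-sphere test.
    """
    placed_a = [p.transform.apply(a.coords) for p in poses_a]
    placed_b = [p.transform.apply(b.coords) for p in poses_b]
    energy = np.zeros((len(placed_a), len(placed_b)))
    clashes = np.zeros_like(energy, dtype=int)
    for i, ca in enumerate(placed_a):
        pa = _PlacedPose(a, ca)
        for j, cb in enumerate(placed_b):
            score = pair_score(pa, _PlacedPose(b, cb), cutoff=cutoff)
            energy[i, j] = weights.w_ph * score.f_ph + weights.w_cl * score.f_cl
            clashes[i, j] = score.clash_count
    return energy, clashes


class _PlacedPose:
    """Lightweight placed-subunit view reusing another subunit's atom typing."""

    def __init__(self, subunit, coords):
        self.id = subunit.id
        self.elements = subunit.elements
        self.atom_names = subunit.atom_names
        self.res_names = subunit.res_names
        self.coords = coords


def significant_clash(
    placed_coords: list[np.ndarray],
    threshold_fraction: float = DEFAULT_CLASH_FRACTION,
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
    pair_clashes: np.ndarray | None = None,
) -> bool:
    """Whether an assembly has a significant amount of inter-subunit clashes.

    True iff the total cross-subunit clash count exceeds
    ``threshold_fraction`` times the total heavy-atom count of the assembly.
    ``pair_clashes`` may supply precomputed per-pair counts (upper-triangle
    matrix) to avoid re-scanning.
    """
    n_atoms = sum(len(c) for c in placed_coords)
    if pair_clashes is not None:
        total = float(np.triu(np.asarray(pair_clashes), k=1).sum())
    else:
        total = 0
        for i in range(len(placed_coords)):
            for j in range(i + 1, len(placed_coords)):
                total += clash_count(placed_coords[i], placed_coords[j], clash_cutoff)
    return total > threshold_fraction * n_atoms
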