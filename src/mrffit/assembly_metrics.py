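"""Evaluation of assembly models against a reference complex.

Two metrics are computed from Cα coordinates:

* permutation-aware complex RMSD — the whole model is superimposed onto the
  reference with a single Kabsch fit over all Cα atoms; when the complex
  contains sequence-identical chains, every admissible chain permutation is
  tried and the minimum RMSD is reported;
* Assembly Placement Score (APS) — after the global superposition with the
  RMSD-optimal permutation, each subunit's residual placement error is
  summarized by its centroid shift (Å) and the rotation angle (degrees) of
  its own optimal superposition; the APS is the residue-count-weighted mean
  of the shifts and of the angles across subunits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .rigid_structures import RigidTransform, Subunit, rotation_angle_deg

__all__ = ["EvalResult", "kabsch", "complex_rmsd", "aps", "evaluate"]


@dataclass
class EvalResult:
    """RMSD/APS summary of one model against the reference assembly."""

    rmsd: float
    aps_shift: float
    aps_angle: float
    per_subunit: list
    permutation: tuple


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid superposition of paired point sets.

    Returns the transform T minimizing ||T(moving) - fixed|| and the residual
    RMSD after the fit.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"point set shapes differ: {moving.shape} vs {fixed.shape}")
    if len(moving) < 3:
        raise ValueError("kabsch needs at least 3 point pairs")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    a = moving - cm
    b = fixed - cf
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    transform = RigidTransform.from_matrix(rot, cf - rot @ cm)
    return transform, rmsd


def _identity_groups(model: list[Subunit], reference: list[Subunit]) -> list[tuple[list, list]]:
    """Pair up model and reference chains by identical residue sequence."""
    groups: dict = {}
    for i, s in enumerate(model):
        groups.setdefault(s.sequence, ([], []))[0].append(i)
    for j, s in enumerate(reference):
        if s.sequence not in groups:
            raise ValueError(f"reference chain {s.id!r} has no sequence match in the model")
        groups[s.sequence][1].append(j)
    for seq, (mi, rj) in groups.items():
        if len(mi) != len(rj):
            raise ValueError("model and reference disagree on identical-chain copy numbers")
    return list(groups.values())


def _permutations(model: list[Subunit], reference: list[Subunit]):
    """Yield mappings model-index -> reference-index over identity groups."""
    groups = _identity_groups(model, reference)
    per_group = [
        [list(zip(mi, perm)) for perm in itertools.permutations(rj)]
        for mi, rj in groups
    ]
    for combo in itertools.product(*per_group):
        mapping = dict(pair for grp in combo for pair in grp)
        yield tuple(mapping[i] for i in range(len(model)))


def complex_rmsd(model: list[Subunit], reference: list[Subunit]):
    """Minimum global-superposition Cα RMSD over identical-chain permutations.

    Returns ``(rmsd, permutation, transform)`` where ``permutation[i]`` is the
    reference-chain index matched to model chain ``i`` and ``transform`` is
    the optimal global Kabsch fit for that permutation.
    """
    if len(model) != len(reference):
        raise ValueError("model and reference have different chain counts")
    best = None
    for perm in _permutations(model, reference):
        mov, fix = [], []
        ok = True
        for i, j in enumerate(perm):
            ca_m = model[i].calpha
            ca_r = reference[j].calpha
            if len(ca_m) != len(ca_r):
                ok = False
                break
            mov.append(ca_m)
            fix.append(ca_r)
        if not ok:
            continue
        transform, rmsd = kabsch(np.vstack(mov), np.vstack(fix))
        if best is None or rmsd < best[0] - 1e-12:
            best = (rmsd, perm, transform)
    if best is None:
        raise ValueError("no valid chain correspondence between model and reference")
    return best


def aps(model: list[Subunit], reference: list[Subunit], permutation: tuple,
        global_transform: RigidTransform | None = None):
    """Assembly Placement Score after global superposition.

    Per subunit: shift = distance between the (globally superimposed) model
    subunit's Cα centroid and its reference partner's; angle = rotation angle
    of the subunit's own optimal superposition onto the partner.  The
    APS pair is the residue-count-weighted mean of shifts and of angles.
    Returns ``(aps_shift, aps_angle, per_subunit_rows)``.
    """
    rows = []
    shifts, angles, weights = [], [], []
    for i, j in enumerate(permutation):
        ca_m = model[i].calpha
        if global_transform is not None:
            ca_m = global_transform.apply(ca_m)
        ca_r = reference[j].calpha
        shift = float(np.linalg.norm(ca_m.mean(axis=0) - ca_r.mean(axis=0)))
        sub_tf, _ = kabsch(ca_m, ca_r)
        angle = rotation_angle_deg(sub_tf.q)
        w = model[i].residue_count
        rows.append((model[i].id, shift, angle))
        shifts.append(shift)
        angles.append(angle)
        weights.append(w)
    weights_arr = np.asarray(weights, dtype=float)
    aps_shift = float(np.average(shifts, weights=weights_arr))
    aps_angle = float(np.average(angles, weights=weights_arr))
    return aps_shift, aps_angle, rows


def evaluate(model: list[Subunit], reference: list[Subunit]) -> EvalResult:
    """Full evaluation: permutation-aware RMSD plus APS, one call."""
    rmsd, perm, transform = complex_rmsd(model, reference)
    aps_shift, aps_angle, rows = aps(model, reference, perm, transform)
    return EvalResult(rmsd=rmsd, aps_shift=aps_shift, aps_angle=aps_angle,
                      per_subunit=rows, permutation=perm)
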